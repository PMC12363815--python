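"""Crossover-table I/O, segment-to-crossover conversion, and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from xover.data_model import (
    ChromatidCrossovers,
    GeneticMap,
    MeiosisDataset,
    read_crossover_table,
    segments_to_crossovers,
    size_bin,
    summarize_dataset,
    write_crossover_table,
)


class TestGeneticMap:
    def test_lengths_and_totals(self, two_chrom_map):
        assert two_chrom_map.length("1", "female") == 0.90
        assert two_chrom_map.total_length("male") == pytest.approx(1.35)
        assert two_chrom_map.chromosomes("female") == ["1", "2"]

    def test_rejects_nonpositive_length(self):
        with pytest.raises(ValueError):
            GeneticMap({("1", "female"): 0.0})

    def test_rejects_duplicate_entry(self):
        with pytest.raises(ValueError):
            GeneticMap.from_frame(pd.DataFrame({
                "chromosome": ["1", "1"], "sex": ["F", "female"],
                "length_cM": [90.0, 91.0],
            }))

    def test_tsv_round_trip(self, two_chrom_map, tmp_path):
        path = tmp_path / "map.tsv"
        two_chrom_map.to_tsv(path)
        assert GeneticMap.from_tsv(path) == two_chrom_map


class TestChromatidInvariants:
    def test_duplicate_positions_named_in_error(self):
        with pytest.raises(ValueError, match="f01"):
            ChromatidCrossovers("f01", "female", "1", [0.2, 0.2], 0.9)

    def test_one_chromatid_per_chromosome_per_meiosis(self):
        a = ChromatidCrossovers("f01", "female", "1", [0.1], 0.9)
        b = ChromatidCrossovers("f01", "female", "1", [], 0.9)
        with pytest.raises(ValueError, match="more than one chromatid"):
            MeiosisDataset([a, b])


class TestReadCrossoverTable:
    def test_cm_to_morgan_conversion(self, crossover_files):
        ds = read_crossover_table(
            crossover_files["crossovers"], crossover_files["map"],
            manifest_path=crossover_files["manifest"],
        )
        by_key = {(c.meiosis_id, c.chromosome): c for c in ds.chromatids}
        assert by_key[("f01", "1")].positions == pytest.approx([0.22, 0.70])
        assert by_key[("f01", "2")].positions == pytest.approx([0.10])
        assert by_key[("f01", "1")].L == pytest.approx(0.90)

    def test_out_of_range_row_rejected_with_report(self, crossover_files):
        ds = read_crossover_table(
            crossover_files["crossovers"], crossover_files["map"],
            manifest_path=crossover_files["manifest"],
        )
        assert len(ds.rejected_rows) == 1
        row = ds.rejected_rows.iloc[0]
        assert row.meiosis_id == "f02" and row.position_morgan == pytest.approx(0.95)

    def test_zero_crossover_chromatids_materialized(self, crossover_files):
        ds = read_crossover_table(
            crossover_files["crossovers"], crossover_files["map"],
            manifest_path=crossover_files["manifest"],
        )
        # manifest names f02 (whose only row was rejected) and chromosome 2
        # has no rows for it either: both chromatids exist with k = 0
        by_key = {(c.meiosis_id, c.chromosome): c for c in ds.chromatids}
        assert len(ds) == 4
        assert by_key[("f02", "1")].n_crossovers == 0
        assert by_key[("f02", "2")].n_crossovers == 0

    def test_write_read_round_trip(self, small_dataset, tmp_path):
        paths = write_crossover_table(small_dataset, tmp_path / "rt")
        back = read_crossover_table(
            paths["crossovers"], paths["map"], manifest_path=paths["manifest"]
        )
        orig = {(c.meiosis_id, c.chromosome): c for c in small_dataset.chromatids}
        new = {(c.meiosis_id, c.chromosome): c for c in back.chromatids}
        assert set(orig) == set(new)
        for key in orig:
            assert new[key].positions == pytest.approx(orig[key].positions)
            assert new[key].L == pytest.approx(orig[key].L)
            assert new[key].parent_sex == orig[key].parent_sex

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(
        st.lists(st.integers(1, 79), min_size=0, max_size=4, unique=True),
        min_size=1, max_size=6,
    ))
    def test_round_trip_property(self, tmp_path_factory, position_lists):
        tmp_path = tmp_path_factory.mktemp("rt")
        chroms = [
            ChromatidCrossovers(f"m{i:02d}", "male", "1",
                                np.sort(np.array(pos, float)) / 100.0, 0.80)
            for i, pos in enumerate(position_lists)
        ]
        ds = MeiosisDataset(chroms)
        paths = write_crossover_table(ds, tmp_path / "ds")
        back = read_crossover_table(paths["crossovers"], paths["map"],
                                    manifest_path=paths["manifest"])
        assert len(back) == len(ds)
        orig = {(c.meiosis_id, c.chromosome): c.positions for c in ds.chromatids}
        for c in back.chromatids:
            assert c.positions == pytest.approx(orig[(c.meiosis_id, c.chromosome)])


class TestSegmentsToCrossovers:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=[
            "meiosis_id", "sex", "chromosome", "start_cM", "end_cM", "haplotype",
        ])

    def test_shared_boundary(self):
        ds = segments_to_crossovers(self._frame([
            ("f01", "female", "1", 0.0, 40.0, "A"),
            ("f01", "female", "1", 40.0, 90.0, "B"),
        ]))
        assert ds.chromatids[0].positions == pytest.approx([0.40])

    def test_midpoint_of_uncertainty_gap(self):
        ds = segments_to_crossovers(self._frame([
            ("f01", "female", "1", 0.0, 38.0, "A"),
            ("f01", "female", "1", 42.0, 90.0, "B"),
        ]))
        assert ds.chromatids[0].positions == pytest.approx([0.40])

    def test_left_right_placement(self):
        frame = self._frame([
            ("f01", "female", "1", 0.0, 38.0, "A"),
            ("f01", "female", "1", 42.0, 90.0, "B"),
        ])
        assert segments_to_crossovers(frame, placement="left").chromatids[0].positions \
            == pytest.approx([0.38])
        assert segments_to_crossovers(frame, placement="right").chromatids[0].positions \
            == pytest.approx([0.42])

    def test_aba_gives_two_crossovers(self):
        ds = segments_to_crossovers(self._frame([
            ("f01", "female", "1", 0.0, 30.0, "A"),
            ("f01", "female", "1", 30.0, 60.0, "B"),
            ("f01", "female", "1", 60.0, 90.0, "A"),
        ]))
        assert ds.chromatids[0].n_crossovers == 2

    def test_same_label_junction_is_not_a_crossover(self):
        ds = segments_to_crossovers(self._frame([
            ("f01", "female", "1", 0.0, 30.0, "A"),
            ("f01", "female", "1", 30.0, 90.0, "A"),
        ]))
        assert ds.chromatids[0].n_crossovers == 0

    def test_overlapping_segments_raise(self):
        with pytest.raises(ValueError, match="overlap"):
            segments_to_crossovers(self._frame([
                ("f01", "female", "1", 0.0, 50.0, "A"),
                ("f01", "female", "1", 45.0, 90.0, "B"),
            ]))


class TestSummarize:
    def test_counts_and_distances(self):
        ds = MeiosisDataset([
            ChromatidCrossovers("f01", "female", "1", [], 0.9),
            ChromatidCrossovers("f01", "female", "2", [0.1, 0.5], 0.6),
        ])
        s = summarize_dataset(ds)
        f = s.per_sex["female"]
        assert (f.count_0, f.count_1, f.count_2plus) == (1, 0, 1)
        assert f.total_crossovers == 2
        assert f.mean_adjacent_cM == pytest.approx(40.0)

    def test_totals_conserved(self, small_dataset):
        s = summarize_dataset(small_dataset)
        assert sum(x.total_crossovers for x in s.per_sex.values()) == s.total_crossovers
        assert sum(x.count_0 + x.count_1 + x.count_2plus
                   for x in s.per_sex.values()) == s.n_chromatids

    def test_empty_dataset_raises(self):
        with pytest.raises(ValueError):
            summarize_dataset(MeiosisDataset([]))


class TestGrouping:
    def test_size_bins(self):
        assert size_bin("1") == "long"
        assert size_bin("chr6") == "medium"
        assert size_bin("19") == "short"
        with pytest.raises(ValueError):
            size_bin("X")

    def test_cell_labels_per_grouping(self, small_dataset):
        assert set(small_dataset.cell_labels()) == {("female", "all"), ("male", "all")}
        per_chrom = small_dataset.with_grouping("per-chromosome")
        assert ("female", "1") in per_chrom.cell_labels()
        bins = small_dataset.with_grouping("size-bin")
        assert set(lbl for _, lbl in bins.cell_labels()) == {"long"}
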