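"""Domain types and I/O for crossover tables and genetic maps.

Positions are stored internally in Morgans; centimorgans are accepted and
emitted at the file boundary, since published tables are in cM while the
renewal likelihood is natural in Morgans.  Coordinates are genetic (map)
positions on a single transmitted chromatid — there is no physical-bp or
strand concept here.

Zero-crossover chromatids are first-class records: the k = 0 outcome
carries likelihood information, so every (meiosis, chromosome) pair named
by a meiosis manifest is materialized even when no crossover row exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FEMALE",
    "MALE",
    "GeneticMap",
    "ChromatidCrossovers",
    "MeiosisDataset",
    "SexSummary",
    "DatasetSummary",
    "size_bin",
    "read_crossover_table",
    "write_crossover_table",
    "segments_to_crossovers",
    "summarize_dataset",
    "read_figshare_crossovers",
]

FEMALE = "female"
MALE = "male"
SEXES = (FEMALE, MALE)

_SEX_ALIASES = {
    "f": FEMALE, "female": FEMALE, "dam": FEMALE, "maternal": FEMALE,
    "m": MALE, "male": MALE, "sire": MALE, "paternal": MALE,
}

# Fixed size bins for the 19 mouse autosomes: roughly equal thirds of the
# cumulative genetic map.
SIZE_BINS = {"long": range(1, 6), "medium": range(6, 13), "short": range(13, 20)}


def normalize_sex(value: str) -> str:
    try:
        return _SEX_ALIASES[str(value).strip().lower()]
    except KeyError:
        raise ValueError(f"unrecognized parent sex label: {value!r}") from None


def _chrom_number(chromosome: str) -> int:
    s = str(chromosome).lower().removeprefix("chr")
    try:
        return int(s)
    except ValueError:
        raise ValueError(f"cannot derive a chromosome number from {chromosome!r}") from None


def size_bin(chromosome: str) -> str:
    """Size-bin label (long: chr1-5, medium: chr6-12, short: chr13-19)."""
    num = _chrom_number(chromosome)
    for label, rng in SIZE_BINS.items():
        if num in rng:
            return label
    raise ValueError(f"chromosome {chromosome!r} outside the autosome range 1-19")


class GeneticMap:
    """Per-(chromosome, sex) genetic map lengths in Morgans."""

    def __init__(self, lengths: Mapping[tuple[str, str], float]):
        self._lengths: dict[tuple[str, str], float] = {}
        for (chrom, sex), L in lengths.items():
            sex = normalize_sex(sex)
            key = (str(chrom), sex)
            if key in self._lengths:
                raise ValueError(f"duplicate map entry for chromosome {chrom!r}, sex {sex}")
            if not L > 0:
                raise ValueError(f"map length must be > 0 for {key}, got {L}")
            self._lengths[key] = float(L)

    def length(self, chromosome: str, sex: str) -> float:
        """Map length in Morgans for one chromosome in one parental sex."""
        key = (str(chromosome), normalize_sex(sex))
        try:
            return self._lengths[key]
        except KeyError:
            raise KeyError(f"no map entry for chromosome/sex {key}") from None

    def chromosomes(self, sex: str | None = None) -> list[str]:
        sexes = [normalize_sex(sex)] if sex else SEXES
        seen: dict[str, None] = {}
        for (chrom, s) in self._lengths:
            if s in sexes:
                seen.setdefault(chrom, None)
        return list(seen)

    def total_length(self, sex: str) -> float:
        sex = normalize_sex(sex)
        return sum(L for (c, s), L in self._lengths.items() if s == sex)

    def items(self):
        return self._lengths.items()

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneticMap) and self._lengths == other._lengths

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GeneticMap":
        """Build from a table with columns chromosome, sex, length_cM."""
        return cls({
            (str(row.chromosome), row.sex): row.length_cM / 100.0
            for row in frame.itertuples()
        })

    @classmethod
    def from_tsv(cls, path) -> "GeneticMap":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype={"chromosome": str}))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"chromosome": c, "sex": s, "length_cM": L * 100.0}
            for (c, s), L in sorted(self._lengths.items(), key=lambda kv: (_chrom_number(kv[0][0]), kv[0][1]))
        ]
        return pd.DataFrame(rows, columns=["chromosome", "sex", "length_cM"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class ChromatidCrossovers:
    """Ordered crossover positions (Morgans) on one transmitted chromatid."""

    meiosis_id: str
    parent_sex: str
    chromosome: str
    positions: np.ndarray
    L: float

    def __post_init__(self) -> None:
        self.parent_sex = normalize_sex(self.parent_sex)
        self.chromosome = str(self.chromosome)
        x = np.asarray(self.positions, dtype=float)
        if x.size:
            if np.any(np.diff(x) <= 0):
                if np.any(np.diff(x) == 0):
                    raise ValueError(
                        f"duplicate crossover positions on chromatid "
                        f"({self.meiosis_id}, chr {self.chromosome})"
                    )
                raise ValueError(
                    f"positions out of order on chromatid "
                    f"({self.meiosis_id}, chr {self.chromosome})"
                )
            if x[0] < 0 or x[-1] > self.L:
                raise ValueError(
                    f"positions outside [0, L={self.L}] on chromatid "
                    f"({self.meiosis_id}, chr {self.chromosome})"
                )
        self.positions = x

    @property
    def n_crossovers(self) -> int:
        return int(self.positions.size)


class MeiosisDataset:
    """All scored chromatids, with sex and chromosome group labels.

    ``chromosome_grouping`` chooses the chromosome-group factor used by the
    hierarchical model: ``"none"`` (a single level), ``"per-chromosome"``
    or ``"size-bin"`` (long/medium/short thirds of the map).
    """

    GROUPINGS = ("none", "per-chromosome", "size-bin")

    def __init__(self, chromatids: Iterable[ChromatidCrossovers],
                 chromosome_grouping: str = "none"):
        self.chromatids: list[ChromatidCrossovers] = list(chromatids)
        if chromosome_grouping not in self.GROUPINGS:
            raise ValueError(f"unknown chromosome grouping {chromosome_grouping!r}")
        self.chromosome_grouping = chromosome_grouping
        seen: set[tuple[str, str]] = set()
        for c in self.chromatids:
            key = (c.meiosis_id, c.chromosome)
            if key in seen:
                raise ValueError(
                    f"meiosis {c.meiosis_id!r} contributes more than one chromatid "
                    f"for chromosome {c.chromosome!r}"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.chromatids)

    def chromosome_group(self, chromatid: ChromatidCrossovers) -> str:
        if self.chromosome_grouping == "none":
            return "all"
        if self.chromosome_grouping == "per-chromosome":
            return chromatid.chromosome
        return size_bin(chromatid.chromosome)

    def meiosis_group_labels(self) -> list[str]:
        return [c.parent_sex for c in self.chromatids]

    def chromosome_group_labels(self) -> list[str]:
        return [self.chromosome_group(c) for c in self.chromatids]

    def cell_labels(self) -> list[tuple[str, str]]:
        """(sex, chromosome-group) cell per chromatid."""
        return [(c.parent_sex, self.chromosome_group(c)) for c in self.chromatids]

    def with_grouping(self, chromosome_grouping: str) -> "MeiosisDataset":
        return MeiosisDataset(self.chromatids, chromosome_grouping)

    def subset(self, predicate) -> "MeiosisDataset":
        return MeiosisDataset(
            [c for c in self.chromatids if predicate(c)], self.chromosome_grouping
        )

    def genetic_map(self) -> GeneticMap:
        lengths: dict[tuple[str, str], float] = {}
        for c in self.chromatids:
            lengths.setdefault((c.chromosome, c.parent_sex), c.L)
        return GeneticMap(lengths)

    def manifest(self) -> pd.DataFrame:
        rows = sorted({(c.meiosis_id, c.parent_sex) for c in self.chromatids})
        return pd.DataFrame(rows, columns=["meiosis_id", "sex"])

    def to_frame(self) -> pd.DataFrame:
        """One row per crossover, positions in cM (the on-disk layout)."""
        rows = [
            {
                "meiosis_id": c.meiosis_id,
                "sex": c.parent_sex,
                "chromosome": c.chromosome,
                "position_cM": pos * 100.0,
            }
            for c in self.chromatids
            for pos in c.positions
        ]
        return pd.DataFrame(rows, columns=["meiosis_id", "sex", "chromosome", "position_cM"])


@dataclass
class SexSummary:
    n_meioses: int
    n_chromatids: int
    total_crossovers: int
    crossovers_per_meiosis: float
    count_0: int
    count_1: int
    count_2plus: int
    mean_adjacent_cM: float
    sd_adjacent_cM: float


@dataclass
class DatasetSummary:
    per_sex: dict[str, SexSummary]
    total_crossovers: int
    n_chromatids: int
    frac_nonrecombinant: float
    frac_single: float
    frac_multi: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {sex: vars(s) for sex, s in self.per_sex.items()}
        ).T.rename_axis("sex")


def summarize_dataset(dataset: MeiosisDataset) -> DatasetSummary:
    """Descriptive summary: crossover totals, per-meiosis rates, chromatid
    crossover-count classes, and adjacent inter-crossover distances (cM)."""
    if not len(dataset):
        raise ValueError("cannot summarize an empty dataset")
    per_sex: dict[str, SexSummary] = {}
    for sex in SEXES:
        chroms = [c for c in dataset.chromatids if c.parent_sex == sex]
        if not chroms:
            continue
        counts = np.array([c.n_crossovers for c in chroms])
        meioses = {c.meiosis_id for c in chroms}
        gaps = np.concatenate(
            [np.diff(c.positions) for c in chroms if c.n_crossovers >= 2] or [np.empty(0)]
        )
        per_sex[sex] = SexSummary(
            n_meioses=len(meioses),
            n_chromatids=len(chroms),
            total_crossovers=int(counts.sum()),
            crossovers_per_meiosis=float(counts.sum() / len(meioses)),
            count_0=int((counts == 0).sum()),
            count_1=int((counts == 1).sum()),
            count_2plus=int((counts >= 2).sum()),
            mean_adjacent_cM=float(gaps.mean() * 100.0) if gaps.size else float("nan"),
            sd_adjacent_cM=float(gaps.std(ddof=1) * 100.0) if gaps.size > 1 else float("nan"),
        )
    n = len(dataset)
    k = np.array([c.n_crossovers for c in dataset.chromatids])
    return DatasetSummary(
        per_sex=per_sex,
        total_crossovers=int(k.sum()),
        n_chromatids=n,
        frac_nonrecombinant=float((k == 0).mean()),
        frac_single=float((k == 1).mean()),
        frac_multi=float((k >= 2).mean()),
    )


def _positions_from_rows(group: pd.DataFrame, L_morgan: float, scale: float,
                         meiosis: str, chrom: str, rejected: list[dict]) -> np.ndarray:
    pos = np.sort(group["position_cM"].to_numpy(dtype=float) * scale)
    ok = (pos >= 0) & (pos <= L_morgan)
    for bad in pos[~ok]:
        rejected.append({
            "meiosis_id": meiosis, "chromosome": chrom,
            "position_morgan": bad, "map_length_morgan": L_morgan,
            "reason": "position outside [0, map length]",
        })
    pos = pos[ok]
    if pos.size and np.any(np.diff(pos) == 0):
        raise ValueError(
            f"duplicate crossover positions on chromatid ({meiosis}, chr {chrom})"
        )
    return pos


def read_crossover_table(
    path,
    map_path,
    units: str = "cM",
    manifest_path=None,
    chromosome_grouping: str = "none",
) -> MeiosisDataset:
    """Read a crossover table plus its companion genetic map.

    The crossover table is TSV with header
    ``meiosis_id  sex  chromosome  position_cM`` (the position column is
    interpreted per ``units``).  The meiosis manifest (TSV ``meiosis_id
    sex``) names every scored meiosis so that chromosomes without crossover
    rows are materialized as explicit zero-crossover chromatids; if omitted,
    the manifest is inferred from the meioses present in the table.

    Rows whose position falls outside the chromosome's map are rejected and
    collected on the returned dataset's ``rejected_rows`` frame; exact
    duplicate positions on one chromatid raise.
    """
    if units not in ("cM", "Morgan"):
        raise ValueError(f"units must be 'cM' or 'Morgan', got {units!r}")
    scale = 0.01 if units == "cM" else 1.0
    gmap = GeneticMap.from_tsv(map_path)
    table = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "meiosis_id": str})
    table["sex"] = table["sex"].map(normalize_sex)
    if manifest_path is not None:
        manifest = pd.read_csv(manifest_path, sep="\t", dtype={"meiosis_id": str})
        manifest["sex"] = manifest["sex"].map(normalize_sex)
    else:
        manifest = table[["meiosis_id", "sex"]].drop_duplicates()

    grouped = {
        (str(m), str(c)): g
        for (m, c), g in table.groupby(["meiosis_id", "chromosome"], sort=False)
    }
    rejected: list[dict] = []
    chromatids = []
    for row in manifest.itertuples():
        for chrom in gmap.chromosomes(row.sex):
            L = gmap.length(chrom, row.sex)
            g = grouped.get((row.meiosis_id, chrom))
            if g is None:
                pos = np.empty(0)
            else:
                pos = _positions_from_rows(g, L, scale, row.meiosis_id, chrom, rejected)
            chromatids.append(
                ChromatidCrossovers(row.meiosis_id, row.sex, chrom, pos, L)
            )
    dataset = MeiosisDataset(chromatids, chromosome_grouping)
    dataset.rejected_rows = pd.DataFrame(
        rejected,
        columns=["meiosis_id", "chromosome", "position_morgan",
                 "map_length_morgan", "reason"],
    )
    return dataset


def write_crossover_table(dataset: MeiosisDataset, prefix) -> dict[str, Path]:
    """Write crossovers, map and manifest TSVs under ``prefix``; the trio
    round-trips through :func:`read_crossover_table`."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "crossovers": prefix.with_suffix(".crossovers.tsv"),
        "map": prefix.with_suffix(".map.tsv"),
        "manifest": prefix.with_suffix(".manifest.tsv"),
    }
    dataset.to_frame().to_csv(paths["crossovers"], sep="\t", index=False)
    dataset.genetic_map().to_tsv(paths["map"])
    dataset.manifest().to_csv(paths["manifest"], sep="\t", index=False)
    return paths


def segments_to_crossovers(
    segments: pd.DataFrame | str | Path,
    genetic_map: GeneticMap | None = None,
    placement: str = "midpoint",
    chromosome_grouping: str = "none",
) -> MeiosisDataset:
    """Derive crossover positions from haplotype segments.

    Each junction between adjacent segments carrying different haplotype
    labels becomes one crossover.  Junctions may have an uncertainty gap
    (end of the left segment < start of the right one); the crossover is
    placed at the ``midpoint`` of that interval by default (``left`` /
    ``right`` use the respective endpoint).  Segments must be in order and
    non-overlapping within each chromatid.
    """
    if placement not in ("midpoint", "left", "right"):
        raise ValueError(f"placement must be midpoint|left|right, got {placement!r}")
    if not isinstance(segments, pd.DataFrame):
        segments = pd.read_csv(segments, sep="\t", dtype={"chromosome": str, "meiosis_id": str})
    chromatids = []
    for (meiosis, sex, chrom), g in segments.groupby(
        ["meiosis_id", "sex", "chromosome"], sort=False
    ):
        sex = normalize_sex(sex)
        g = g.reset_index(drop=True)
        starts = g["start_cM"].to_numpy(float) / 100.0
        ends = g["end_cM"].to_numpy(float) / 100.0
        if np.any(ends < starts) or np.any(starts[1:] < ends[:-1]):
            raise ValueError(
                f"overlapping or out-of-order segments on ({meiosis}, chr {chrom})"
            )
        labels = g["haplotype"].to_numpy()
        junctions = []
        for i in range(len(g) - 1):
            if labels[i + 1] == labels[i]:
                continue
            lo, hi = ends[i], starts[i + 1]
            junctions.append({"midpoint": 0.5 * (lo + hi), "left": lo, "right": hi}[placement])
        if genetic_map is not None:
            L = genetic_map.length(chrom, sex)
        else:
            L = float(ends[-1])
        chromatids.append(
            ChromatidCrossovers(str(meiosis), sex, str(chrom), np.asarray(junctions), L)
        )
    return MeiosisDataset(chromatids, chromosome_grouping)


def read_figshare_crossovers(path, map_path, **kwargs) -> MeiosisDataset:
    """Adapter for the deposited processed-crossover archive layout.

    Isolated here so that any difference between the archive's column names
    and the package's canonical ``meiosis_id/sex/chromosome/position_cM``
    layout is absorbed in one place.  Extra keyword arguments pass through
    to :func:`read_crossover_table`.
    """
    table = pd.read_csv(path, sep=None, engine="python")
    renames = {
        "meiosis": "meiosis_id", "id": "meiosis_id",
        "parent_sex": "sex", "parent": "sex",
        "chrom": "chromosome", "chr": "chromosome",
        "pos_cM": "position_cM", "position": "position_cM", "cM": "position_cM",
    }
    table = table.rename(columns={c: renames.get(c, c) for c in table.columns})
    missing = {"meiosis_id", "sex", "chromosome", "position_cM"} - set(table.columns)
    if missing:
        raise ValueError(f"archive table lacks recognizable columns for {sorted(missing)}")
    import tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".tsv", delete=False) as fh:
        table[["meiosis_id", "sex", "chromosome", "position_cM"]].to_csv(
            fh, sep="\t", index=False
        )
        tmp = fh.name
    return read_crossover_table(tmp, map_path, **kwargs)
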