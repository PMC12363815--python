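import numpy as np
import pytest

from xover.data_model import ChromatidCrossovers, GeneticMap, MeiosisDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20250929)


@pytest.fixture
def two_chrom_map():
    return GeneticMap({
        ("1", "female"): 0.90, ("2", "female"): 0.60,
        ("1", "male"): 0.80, ("2", "male"): 0.55,
    })


@pytest.fixture
def small_dataset():
    """Two meioses, two chromosomes each, mixed crossover counts."""
    return MeiosisDataset([
        ChromatidCrossovers("f01", "female", "1", [0.22, 0.70], 0.90),
        ChromatidCrossovers("f01", "female", "2", [0.10], 0.60),
        ChromatidCrossovers("m01", "male", "1", [], 0.80),
        ChromatidCrossovers("m01", "male", "2", [0.05, 0.35, 0.50], 0.55),
    ])


@pytest.fixture
def crossover_files(tmp_path):
    """On-disk crossover/map/manifest trio with one out-of-range row."""
    crossovers = tmp_path / "xo.tsv"
    crossovers.write_text(
        "meiosis_id\tsex\tchromosome\tposition_cM\n"
        "f01\tfemale\t1\t22.0\n"
        "f01\tfemale\t1\t70.0\n"
        "f01\tfemale\t2\t10.0\n"
        "f02\tfemale\t1\t95.0\n"  # beyond the 90 cM map: rejected
    )
    gmap = tmp_path / "map.tsv"
    gmap.write_text(
        "chromosome\tsex\tlength_cM\n1\tfemale\t90.0\n2\tfemale\t60.0\n"
    )
    manifest = tmp_path / "manifest.tsv"
    manifest.write_text("meiosis_id\tsex\nf01\tfemale\nf02\tfemale\n")
    return {"crossovers": crossovers, "map": gmap, "manifest": manifest}
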