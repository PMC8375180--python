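import numpy as np
import pytest

from xcnv.core import CNVRecord, CNVType
from xcnv.features import (
    AnnotationBundle,
    CCRE_CLASSES,
    CODING_TRACK_FEATURES,
    GENE_SCORE_FEATURES,
    GENOMEWIDE_FEATURES,
    GeneScoreTable,
    RegionSet,
    ScoreTrack,
)
from xcnv.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """One small synthetic dataset shared across tests (150 true CNVs)."""
    return simulate_dataset(SimConfig(seed=11, n_true_cnvs=150))


@pytest.fixture()
def toy_bundle():
    """Deterministic hand-built annotation bundle covering chr1:1-10000."""
    rng = np.random.default_rng(42)
    tracks = {}
    for name in CODING_TRACK_FEATURES + GENOMEWIDE_FEATURES + ["CDTS"]:
        pos = np.arange(100, 10001, 100)
        tracks[name] = ScoreTrack.from_arrays(
            name, ["1"] * len(pos), pos, rng.normal(size=len(pos))
        )
    gene_tables = {
        name: GeneScoreTable(name, [("1", 2000, 3000, "GENE_A", 0.9),
                                    ("1", 6000, 7000, "GENE_B", 0.2)])
        for name in GENE_SCORE_FEATURES
    }
    region_sets = {
        name: RegionSet(name, [("1", 1000, 1499), ("1", 8000, 8999)])
        for name in CCRE_CLASSES
    }
    return AnnotationBundle(tracks=tracks, gene_tables=gene_tables,
                            region_sets=region_sets)


@pytest.fixture()
def loss_record():
    return CNVRecord("1", 1001, 9000, CNVType.LOSS)
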