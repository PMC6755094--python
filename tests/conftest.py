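import warnings

import pytest

from parekit.annotation_io import LibraryInfo, TranscriptModel
from parekit.synthetic_data import SimulationConfig, null_config, simulate_dataset


@pytest.fixture
def model():
    """The running example transcript: length 500, 5'UTR 30 nt, CDS 31-400, 3'UTR 100 nt."""
    return TranscriptModel(
        transcript_id="t1", gene_id="g1", length=500,
        utr5_len=30, cds_start=31, cds_end=400, utr3_len=100,
    )


@pytest.fixture
def wt_libraries():
    """Two WT polyA+ replicates of 10M and 25M mapped tags."""
    return [
        LibraryInfo("WT_plus_r1", "WT", "WT", "polyA_plus", 1, 10_000_000),
        LibraryInfo("WT_plus_r2", "WT", "WT", "polyA_plus", 2, 25_000_000),
    ]


@pytest.fixture(scope="session")
def default_dataset():
    """The standard synthetic scenario (2000 transcripts, 8-fold cap amplification)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_dataset(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def null_dataset():
    """Same scenario with all genotype effects removed (folds = 1)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_dataset(null_config(SimulationConfig(seed=11)))


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic study used by pipeline/CLI tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_dataset(SimulationConfig(n_transcripts=120, seed=5))
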