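import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from spongenet.io import CountMatrix
from spongenet.synthetic import SimConfig, simulate_counts, simulate_sequences

#: mature sequence printed for miR156x (5'-3')
MIR156X = "AACUGUCUUCUCUCUCUCGUG"


@pytest.fixture(scope="session")
def default_dataset():
    cfg = SimConfig(seed=11)
    m, truth = simulate_counts(cfg)
    mirnas, transcripts = simulate_sequences(cfg, truth)
    return cfg, m, truth, mirnas, transcripts


@pytest.fixture()
def toy_matrix():
    """Small two-group matrix with equal library sizes."""
    rng = np.random.default_rng(5)
    counts = rng.poisson(100, size=(40, 6))
    # make column sums exactly equal so normalization is the identity
    counts[-1] += counts.sum(axis=0).max() - counts.sum(axis=0)
    return CountMatrix(
        feature_ids=[f"mRNA_{i:03d}" for i in range(40)],
        classes=["mRNA"] * 40,
        sample_ids=[f"s{i}" for i in range(6)],
        groups=["a"] * 3 + ["b"] * 3,
        counts=counts,
    )
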