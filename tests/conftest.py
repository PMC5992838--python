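import numpy as np
import pytest

from psnpipe import (CohortSpec, PatientSimilarityNetwork, generate_cohort,
                     modular_profiles)


@pytest.fixture(scope="session")
def easy_cohort():
    """Well-separated single-source cohort: strong planted signal."""
    spec = CohortSpec(n_patients=100, sources=[("rnaseq", 300)],
                      endpoints=[("outcome", 0.4)], n_signal_features=50,
                      effect_size=2.0, rng_seed=11)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def modular_net():
    """PSN-ready profiles with 4 planted patient blocks."""
    return modular_profiles(120, 4, 0.7, 300, rng_seed=0)


def block_psn(n=40, n_blocks=4, within=0.8, between=0.15, noise=0.05, seed=0):
    """Weight matrix with planted blocks, wrapped as a network."""
    rng = np.random.default_rng(seed)
    blocks = np.arange(n) % n_blocks
    w = np.where(blocks[:, None] == blocks[None, :], within, between)
    w = w + rng.normal(0, noise, (n, n))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0)
    ids = [f"p{i:03d}" for i in range(n)]
    return PatientSimilarityNetwork(ids, np.clip(w, 0, 1)), blocks


@pytest.fixture
def small_block_psn():
    return block_psn()


def random_psn(n=12, seed=0):
    rng = np.random.default_rng(seed)
    w = rng.random((n, n))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0)
    ids = [f"p{i:03d}" for i in range(n)]
    return PatientSimilarityNetwork(ids, w)
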