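import numpy as np
import pytest

from diallelgp.genotypes import GenotypeMatrix
from diallelgp.synthetic_data import SimConfig, simulate_study


def make_matrix(dosages, chrom=None, pos=None, biallelic=None, prefix="L"):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    return GenotypeMatrix(
        line_ids=np.array([f"{prefix}{i+1}" for i in range(n)], dtype=object),
        marker_ids=np.array([f"M{j+1}" for j in range(m)], dtype=object),
        dosages=dosages,
        chrom=None if chrom is None else np.asarray(chrom, dtype=object),
        pos=None if pos is None else np.asarray(pos),
        biallelic=biallelic,
    )


@pytest.fixture(scope="session")
def two_pool_study():
    """Small structured study shared by read-only tests."""
    cfg = SimConfig(
        n_lines=60,
        n_markers=500,
        n_pools=2,
        divergence=0.3,
        n_diallel_parents=16,
        cross_fraction=0.8,
        n_envs=4,
        seed=11,
    )
    return simulate_study(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
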