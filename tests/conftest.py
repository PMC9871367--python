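import numpy as np
import pytest

from snpboost import GenotypeMatrix, SimConfig, VariantInfo, simulate_genotypes


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_matrix(dosages, missing=None, ids=None):
    """Build a GenotypeMatrix from a plain array (NaN marks missing)."""
    dosages = np.asarray(dosages, dtype=float)
    n, p = dosages.shape
    if missing is None:
        missing = np.isnan(dosages)
    variants = [VariantInfo(f"var{j}", "1", j + 1, "A", "C") for j in range(p)]
    sample_ids = ids or [f"s{i}" for i in range(n)]
    return GenotypeMatrix(dosages, missing, variants, sample_ids)


@pytest.fixture
def toy_genotypes(rng):
    """60 x 12 hard-call matrix with scattered missingness."""
    dosages = rng.binomial(2, 0.3, size=(60, 12)).astype(float)
    missing = rng.random((60, 12)) < 0.05
    dosages[missing] = np.nan
    return make_matrix(dosages, missing)


@pytest.fixture
def small_sim():
    """Complete simulated dataset small enough for exhaustive checks."""
    cfg = SimConfig(n=250, p=40, h2=0.6, s=0.1, seed=42)
    G = simulate_genotypes(cfg)
    return cfg, G
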