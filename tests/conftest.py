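import numpy as np
import pytest

from namdd import AnalysisConfig, OmicsDataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_dataset(rng):
    """Strong-signal toy: site 0 drives gene 0 drives disease."""
    n = 60
    z = np.array([0, 1] * (n // 2))
    x0 = z + 0.1 * rng.standard_normal(n)
    X = np.column_stack([x0] + [rng.standard_normal(n) for _ in range(4)])
    y0 = 1.5 * x0 + 0.1 * rng.standard_normal(n)
    Y = np.column_stack([y0] + [rng.standard_normal(n) for _ in range(2)])
    return OmicsDataset(
        X=X,
        Y=Y,
        z=z,
        sample_ids=[f"s{i}" for i in range(n)],
        site_ids=[f"cg{p}" for p in range(5)],
        gene_ids=[f"g{q}" for q in range(3)],
    )


@pytest.fixture
def fast_config():
    return AnalysisConfig(
        T=10,
        phi=0.6,
        K=100,
        alpha_grid=[4.0, 8.0],
        beta_grid=[2.0, 4.0],
        lambda_grid=[0.3, 1.0],
        n_cv_folds=3,
        n_perm=10,
        seed=1,
        max_iter=200,
        tol=1e-5,
        rho=5.0,
    )
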