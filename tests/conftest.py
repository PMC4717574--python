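import numpy as np
import pytest

import assortmate as am


@pytest.fixture(scope="session")
def small_cohort():
    """300-couple, 400-SNP cohort with the default study conditions."""
    cfg = am.SimConfig(n_couples=300, n_snps=400, seed=7)
    G, phenos, couples = am.simulate_cohort(cfg)
    return cfg, G, phenos, couples


@pytest.fixture(scope="session")
def greml_instance():
    """Moderate GREML problem with known generating variances (0.6 / 0.4)."""
    rng = np.random.default_rng(42)
    n, M = 500, 800
    Z = rng.binomial(2, rng.uniform(0.1, 0.5, M), size=(n, M)).astype(float)
    Zs = (Z - Z.mean(0)) / Z.std(0)
    A = Zs @ Zs.T / M
    beta = rng.standard_normal(M)
    g = Zs @ beta
    g *= np.sqrt(0.6) / g.std()
    y = g + rng.standard_normal(n) * np.sqrt(0.4)
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    return {"y": y, "X": X, "A": A, "Z": Zs, "M": M, "g_true": g}
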