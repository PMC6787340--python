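import numpy as np
import pytest

import dc3


@pytest.fixture(scope="session")
def small_mixture():
    """Separated 2-cluster mixture, small enough for repeated fits."""
    return dc3.generate_mixture(
        K=2, m=60, n=80, cells=(50, 80, 40), separation=0.4,
        n_loops=400, mean_loop_count=15, seed=101,
    )


@pytest.fixture(scope="session")
def fitted_small(small_mixture):
    E, O, loops, _, truth = small_mixture
    est = dc3.DC3(n_clusters=2, init="als", n_restarts=3, als_iter=50,
                  max_iter=120, random_state=7)
    est.fit(E, O, loops)
    return est


def random_loop_table(rng, m, n, n_pairs, max_count=20.0):
    flat = rng.choice(m * n, size=n_pairs, replace=False)
    gi, ei = np.unravel_index(flat, (m, n))
    counts = rng.uniform(0, max_count, size=n_pairs)
    return dc3.LoopTable(
        gene_index=gi, enhancer_index=ei, count=counts,
        gene_ids=[f"g{i}" for i in range(m)],
        enhancer_ids=[f"e{j}" for j in range(n)],
    )


def random_model(rng, m, n, n1, n2, K, mu1=1.0, mu2=1.0):
    from dc3.factorization import FactorModel, _normalize_columns

    H1 = _normalize_columns(rng.random((K, n1)) + 0.05)
    H2 = _normalize_columns(rng.random((K, n2)) + 0.05)
    lam = rng.random(K) + 0.2
    lam /= lam.sum()
    return FactorModel(
        W1=rng.random((m, K)) * 3 + 0.01, H1=H1,
        W2=rng.random((n, K)) * 3 + 0.01, H2=H2,
        lam=lam, alpha=float(rng.uniform(0.3, 3.0)),
        mu1=mu1, mu2=mu2, K=K,
    )
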