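import numpy as np
import pytest

from oroniche.grid import Grid


def maxent_objective_oracle(X, presence_idx, lambdas):
    """Independent convex-optimizer solution of the regularised maxent
    objective, via a positive/negative coefficient split and L-BFGS-B.

    Returns (coefficients, objective value).
    """
    from scipy.optimize import minimize
    from scipy.special import logsumexp

    X = np.asarray(X, dtype=float)
    N, J = X.shape
    pbar = X[presence_idx].mean(axis=0)
    lam = np.asarray(lambdas, dtype=float)

    def f(uv):
        w = uv[:J] - uv[J:]
        return logsumexp(X @ w) - pbar @ w + lam @ (uv[:J] + uv[J:])

    def grad(uv):
        w = uv[:J] - uv[J:]
        eta = X @ w
        raw = np.exp(eta - logsumexp(eta))
        g = X.T @ raw - pbar
        return np.concatenate([g + lam, -g + lam])

    res = minimize(
        f, np.zeros(2 * J), jac=grad, method="L-BFGS-B",
        bounds=[(0, None)] * (2 * J),
        options={"maxiter": 20000, "ftol": 1e-15, "gtol": 1e-10},
    )
    return res.x[:J] - res.x[J:], float(res.fun)


def random_maxent_instance(rng, max_cells=200, max_features=6):
    """A small random presence-background problem on a feature matrix."""
    N = int(rng.integers(30, max_cells + 1))
    J = int(rng.integers(2, max_features + 1))
    m = int(rng.integers(5, 16))
    X = rng.random((N, J))
    presence_idx = rng.choice(N, size=m, replace=False)
    return X, presence_idx


@pytest.fixture(scope="session")
def small_broad_data():
    """A compact broad-scale synthetic dataset shared across tests."""
    import oroniche as o

    return o.make_broad_dataset(
        seed=11, landscape=o.LandscapeConfig(n_rows=80, n_cols=80, seed=11)
    )


@pytest.fixture(scope="session")
def abr_species(small_broad_data):
    """Virtual species driven by abruptness and summer temperature."""
    import oroniche as o

    terms = [
        ("ABR", "linear", {"lo": 200.0, "hi": 1500.0}),
        ("B10", "gaussian", {"optimum": 14.0, "width": 5.0}),
    ]
    suit = o.build_suitability(small_broad_data["stack"], terms)
    records = o.sample_virtual_occurrences(
        suit,
        o.VirtualSpeciesConfig(response_terms=terms, n_presences=80, seed=13),
        regions=small_broad_data["regions"],
    )
    return {"terms": terms, "suitability": suit, "records": records}


def make_mask_pair(rng, shape=(15, 15)):
    """Random pair of aligned boolean range masks (at least one true cell)."""
    from oroniche.overlap import RangeMask

    ref = Grid(np.zeros(shape), cell_size=1000.0)
    a = rng.random(shape) < rng.uniform(0.1, 0.6)
    b = rng.random(shape) < rng.uniform(0.1, 0.6)
    a.flat[0] = True
    b.flat[0] = True
    return (RangeMask(grid=ref.like(a), species_id="a"),
            RangeMask(grid=ref.like(b), species_id="b"))
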