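"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import sparse
from scipy.optimize import linprog

import countqr as cq


def lp_pinball_oracle(design, t, p):
    """Global pinball-loss minimum via the linear-programming reformulation.

    min_b p 1'u + (1-p) 1'v  s.t.  X b + u - v = t, u, v >= 0 — an
    independent route to the optimum used to validate the production solver.
    """
    n, k = design.shape
    c = np.concatenate([np.zeros(2 * k), p * np.ones(n), (1 - p) * np.ones(n)])
    A = sparse.hstack(
        [sparse.csr_matrix(design), -sparse.csr_matrix(design),
         sparse.eye(n, format="csr"), -sparse.eye(n, format="csr")]
    )
    res = linprog(c, A_eq=A, b_eq=t, method="highs")
    assert res.status == 0, f"oracle LP failed: {res.message}"
    beta = res.x[:k] - res.x[k : 2 * k]
    return beta, res.fun


def lp_integrated_oracle(design, t, spec, n_nodes=199):
    """Global integrated-loss minimum via one big weighted-check-loss LP.

    The quadrature sum of pinball losses is itself a weighted quantile
    regression on an expanded design (rows = observation x node, columns =
    free theta entries), solved exactly by HiGHS; independent of the
    package's quasi-Newton route.
    """
    from countqr.qrcm import _gauss_legendre_01

    nodes, w = _gauss_legendre_01(n_nodes)
    Bn = spec.basis_matrix(nodes)  # K x k
    mask = spec.mask
    n, ncoef = design.shape
    K = n_nodes
    # expanded design: row (i, k) has entries X[i, c] * Bn[k, j] for free (c, j)
    cols = []
    for c in range(ncoef):
        for j in np.flatnonzero(mask[c]):
            cols.append(np.repeat(design[:, c], K) * np.tile(Bn[:, j], n))
    A_x = np.column_stack(cols)
    t_big = np.repeat(t, K)
    p_big = np.tile(nodes, n)
    w_big = np.tile(w, n)
    nf = A_x.shape[1]
    nrow = n * K
    c_obj = np.concatenate([np.zeros(2 * nf), w_big * p_big, w_big * (1 - p_big)])
    A = sparse.hstack(
        [sparse.csr_matrix(A_x), -sparse.csr_matrix(A_x),
         sparse.eye(nrow, format="csr"), -sparse.eye(nrow, format="csr")]
    )
    res = linprog(c_obj, A_eq=A, b_eq=t_big, method="highs")
    assert res.status == 0, f"oracle LP failed: {res.message}"
    return res.x[:nf] - res.x[nf : 2 * nf], res.fun


def stair_pmf():
    """A known count pmf whose jittered quantiles sit midway between integers
    at every tested decile: P(0)=P(10)=0.05, P(1..9)=0.1."""
    pmf = np.full(11, 0.1)
    pmf[0] = pmf[10] = 0.05
    return pmf


def pmf_quantile(pmf, p):
    """Brute-force discrete quantile: min k with cdf(k) >= p."""
    return int(np.searchsorted(np.cumsum(pmf), p - 1e-12))


def simple_line_model(slope=0.5):
    """Intercept linear in p plus one constant-coefficient covariate.

    Q(p | x) = 4 + 8p + slope * x, strictly increasing in p; with x standard
    normal the counts stay inside [0, 21] except in astronomically rare
    tails.  Used by the size/coverage simulations where many refits are
    needed.
    """
    spec = cq.ModelSpec([
        [cq.legendre(0), cq.legendre(1)],
        [cq.legendre(0)],
    ])
    from countqr.basis import monomial_to_shifted_legendre

    theta = np.zeros((2, 2))
    theta[0, :] = monomial_to_shifted_legendre([4.0, 8.0])
    theta[1, 0] = slope
    from countqr.synthetic import TrueModel

    return TrueModel(spec=spec, theta_true=cq.ThetaMatrix(theta, spec.mask))


def simulate_line_dataset(n, seed, slope=0.5):
    """Draw one dataset from :func:`simple_line_model` with one N(0,1) covariate."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    X = np.column_stack([np.ones(n), x])
    model = simple_line_model(slope)
    from countqr.synthetic import sample_response

    y, latent = sample_response(X, model, seed=seed + 10_000)
    return cq.Dataset(design=X, response=y, names=["const", "x"]), model, latent


@pytest.fixture(scope="session")
def psych_data():
    """Default-size synthetic credits dataset (n = 649)."""
    return cq.generate_dataset(n=649, seed=11)


@pytest.fixture(scope="session")
def model2_fit(psych_data):
    """The flexible-intercept/cohort specification fitted on psych_data,
    with its sandwich covariance."""
    fit = cq.fit_qrcm(psych_data.dataset, psych_data.model.spec)
    cq.covariance_sandwich(fit)
    return fit
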