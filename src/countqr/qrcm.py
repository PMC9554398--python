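"""Quantile-regression-coefficients modelling (QRCM) by integrated-loss minimisation.

Instead of fitting one quantile regression per quantile order, each
coefficient is modelled as a parametric function of p,

    beta_c(p | theta) = theta_c1 b_1(p) + ... + theta_ck b_k(p),

with known basis functions b(p) and a (q+1) x k parameter matrix theta in
which some entries may be restricted to zero.  All parameters are estimated
jointly by minimising the pinball loss integrated over the quantile order,

    Lbar(theta) = integral_0^1 L(beta(p | theta)) dp,

approximated by a fixed Gauss-Legendre rule on (0, 1).  For a count response
Y the model is fitted to the offset working variable Y0 = Y + 0.5 (the mean
of the jittering noise), which acts as an implicit, deterministic jittering:
the parametric structure smooths away the mass points.

Because the integrated loss is smooth in theta (almost everywhere, with the
indicator set ignored on a null set), standard quasi-Newton minimisation and
the usual M-estimation sandwich covariance apply; no sparsity estimation or
bootstrap is needed for inference.  Count quantiles are recovered with the
ceiling rule Q_Y(p|x) = ceil(x' beta(p | theta) - 1) (identity transform).

Goodness of fit uses the probability integral transform F(y | x, theta):
under a correctly specified continuous working model it is Uniform(0, 1);
distances (Kolmogorov-Smirnov or Cramer-von Mises) are calibrated by a
parametric Monte-Carlo that simulates from the fitted continuous working
model and refits each replicate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import optimize, stats

from .basis import BasisFunction
from .core import Dataset, check_quantile_level

__all__ = [
    "ModelSpec",
    "ThetaMatrix",
    "QRCMFit",
    "GofResult",
    "QrcmConvergenceError",
    "eval_basis",
    "beta_curve",
    "integrated_loss",
    "fit_qrcm",
    "covariance_sandwich",
    "wald_test_global",
    "predict_quantile_count",
    "pit",
    "pit_values",
    "gof_test",
]

DEFAULT_NODES = 199
PIT_EPS = 1e-4


class QrcmConvergenceError(RuntimeError):
    """Raised when the integrated-loss minimisation does not converge."""


@lru_cache(maxsize=8)
def _gauss_legendre_01(n_nodes: int):
    """Gauss-Legendre nodes/weights mapped from [-1, 1] to (0, 1).

    All nodes are interior, which keeps tail-divergent basis members such as
    -log(1-p) finite.
    """
    x, w = np.polynomial.legendre.leggauss(n_nodes)
    return 0.5 * (x + 1.0), 0.5 * w


@dataclass(frozen=True)
class ModelSpec:
    """Per-coefficient basis lists with implied basis union and sparsity mask.

    ``coef_bases[c]`` lists the basis functions allowed for coefficient c
    (c = 0 is the intercept).  The union of all lists, in order of first
    appearance, forms the shared basis b(p) of size k; entries of theta
    outside a coefficient's own list are restricted to zero.
    """

    coef_bases: tuple[tuple[BasisFunction, ...], ...]
    names: tuple[str, ...] = ()

    def __init__(self, coef_bases, names=()):
        coef_bases = tuple(tuple(row) for row in coef_bases)
        for c, row in enumerate(coef_bases):
            if len(row) == 0:
                raise ValueError(f"coefficient {c} needs at least one basis function")
            if len(set(row)) != len(row):
                raise ValueError(f"duplicate basis function for coefficient {c}")
        object.__setattr__(self, "coef_bases", coef_bases)
        object.__setattr__(self, "names", tuple(names))

    @property
    def n_coef(self) -> int:
        return len(self.coef_bases)

    @property
    def basis_union(self) -> tuple[BasisFunction, ...]:
        seen: list[BasisFunction] = []
        for row in self.coef_bases:
            for bf in row:
                if bf not in seen:
                    seen.append(bf)
        return tuple(seen)

    @property
    def k(self) -> int:
        return len(self.basis_union)

    @property
    def mask(self) -> np.ndarray:
        union = self.basis_union
        mask = np.zeros((self.n_coef, len(union)), dtype=bool)
        for c, row in enumerate(self.coef_bases):
            for bf in row:
                mask[c, union.index(bf)] = True
        return mask

    @property
    def n_free(self) -> int:
        return sum(len(row) for row in self.coef_bases)

    def basis_matrix(self, p) -> np.ndarray:
        """Evaluate the basis union at quantile orders p, shape (len(p), k)."""
        p = np.atleast_1d(np.asarray(p, dtype=float))
        return np.column_stack([bf(p) for bf in self.basis_union])

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "coefficients": [[bf.to_dict() for bf in row] for row in self.coef_bases],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        rows = [[BasisFunction.from_dict(b) for b in row] for row in d["coefficients"]]
        return cls(rows, names=tuple(d.get("names", ())))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, s: str) -> "ModelSpec":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class ThetaMatrix:
    """The (q+1) x k parameter matrix with its sparsity mask.

    Entries outside the mask are exactly zero.
    """

    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        if values.shape != mask.shape:
            raise ValueError("values and mask must have the same shape")
        if np.any(values[~mask] != 0.0):
            raise ValueError("masked-out theta entries must be exactly 0")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "mask", mask)

    @classmethod
    def from_free(cls, phi, mask) -> "ThetaMatrix":
        mask = np.asarray(mask, dtype=bool)
        values = np.zeros(mask.shape)
        values[mask] = np.asarray(phi, dtype=float)
        return cls(values=values, mask=mask)

    @property
    def free(self) -> np.ndarray:
        return self.values[self.mask]


@dataclass
class QRCMFit:
    """A fitted QRCM model: theta-hat, loss, diagnostics, inference inputs.

    The model is fitted to the working response y0 (by default y + 0.5);
    ``covariance`` over the free parameters is filled in lazily by
    :func:`covariance_sandwich`.
    """

    theta_hat: ThetaMatrix
    spec: ModelSpec
    integrated_loss_value: float
    gradient_norm: float
    converged: bool
    n_nodes: int
    design: np.ndarray
    working_response: np.ndarray
    names: list[str] = field(default_factory=list)
    covariance: np.ndarray | None = None
    n_iter: int = 0

    @property
    def gradient_tol(self) -> float:
        """Convergence tolerance on the max-abs integrated-loss gradient."""
        return 1e-2 * (1.0 + abs(self.integrated_loss_value))

    def beta_at(self, p) -> np.ndarray:
        """Coefficient curves beta(p | theta-hat), shape (len(p), q+1)."""
        p = np.atleast_1d(np.asarray(p, dtype=float))
        return self.spec.basis_matrix(p) @ self.theta_hat.values.T

    def free_indices_of(self, covariate_index: int) -> np.ndarray:
        """Positions, within the free-parameter vector, of one covariate's entries."""
        mask = self.spec.mask
        flat_rows = np.repeat(np.arange(mask.shape[0]), mask.shape[1])[mask.ravel()]
        return np.flatnonzero(flat_rows == covariate_index)

    def standard_errors(self) -> ThetaMatrix:
        if self.covariance is None:
            raise ValueError("covariance not computed; call covariance_sandwich first")
        return ThetaMatrix.from_free(np.sqrt(np.diag(self.covariance)), self.spec.mask)


def eval_basis(spec: ModelSpec, p: float) -> np.ndarray:
    """Evaluate the spec's basis union b(p) at one interior quantile order."""
    check_quantile_level(p)
    return spec.basis_matrix(p)[0]


def beta_curve(theta: ThetaMatrix, spec: ModelSpec, p: float) -> np.ndarray:
    """Coefficient vector beta(p | theta) = theta b(p) at one quantile order."""
    if theta.mask.shape != spec.mask.shape or not np.array_equal(theta.mask, spec.mask):
        raise ValueError("theta mask does not match the model specification")
    return theta.values @ eval_basis(spec, p)


def _loss_grad(phi, X, t, Bnodes, nodes, weights, mask):
    """Integrated loss and analytic gradient over the free parameters.

    The indicator's dependence on theta is ignored (valid almost everywhere,
    the standard subgradient of the check loss).
    """
    theta = np.zeros(mask.shape)
    theta[mask] = phi
    F = (X @ theta) @ Bnodes.T  # n x K fitted quantiles at the nodes
    R = t[:, None] - F
    PW = nodes[None, :] - (R <= 0)
    loss = float(np.sum((PW * R) @ weights))
    if loss < 0:  # numerically impossible except for rounding at ~0
        loss = 0.0
    Gfull = -((X.T @ (PW * weights[None, :])) @ Bnodes)
    return loss, Gfull[mask]


def integrated_loss(theta: ThetaMatrix, dataset: Dataset, spec: ModelSpec,
                    n_nodes: int = DEFAULT_NODES,
                    working_response=None) -> float:
    """Gauss-Legendre approximation of the integrated pinball loss at theta.

    The working response defaults to y + 0.5.
    """
    if theta.mask.shape != spec.mask.shape or not np.array_equal(theta.mask, spec.mask):
        raise ValueError("theta mask does not match the model specification")
    t = (dataset.response + 0.5 if working_response is None
         else np.asarray(working_response, dtype=float))
    nodes, weights = _gauss_legendre_01(n_nodes)
    Bnodes = spec.basis_matrix(nodes)
    if not np.all(np.isfinite(Bnodes)):
        raise ValueError("basis evaluation non-finite at a quadrature node")
    loss, _ = _loss_grad(theta.free, dataset.design, t, Bnodes, nodes,
                         weights, spec.mask)
    return loss


def _initial_theta(X, t, spec: ModelSpec) -> np.ndarray:
    """Deterministic start: the working-response median on the intercept's
    constant-basis entry, zero elsewhere."""
    theta0 = np.zeros(spec.mask.shape)
    const = BasisFunction("legendre_shifted", degree=0)
    if const in spec.coef_bases[0]:
        theta0[0, spec.basis_union.index(const)] = float(np.median(t))
    return theta0


def fit_qrcm(dataset: Dataset, spec: ModelSpec, init: ThetaMatrix | None = None,
             *, working_response=None, n_nodes: int = DEFAULT_NODES,
             max_iter: int = 2000) -> QRCMFit:
    """Minimise the integrated pinball loss over the free entries of theta.

    Deterministic given the data and the (optional) initial theta.  The
    response used is the working variable y0 = y + 0.5 unless an explicit
    continuous ``working_response`` (e.g. a jittered sample) is supplied.
    Monotonicity of the fitted quantile function is not enforced; violations
    over the node grid at observed covariate rows produce a warning.
    """
    if spec.n_coef != dataset.design.shape[1]:
        raise ValueError("spec has a basis list per design column; counts differ")
    if spec.n_free >= dataset.n:
        raise ValueError("free-parameter count must be below the sample size")
    X = dataset.design
    t = (dataset.response + 0.5 if working_response is None
         else np.asarray(working_response, dtype=float))
    if t.shape != (dataset.n,):
        raise ValueError("working response length must match dataset rows")
    mask = spec.mask
    nodes, weights = _gauss_legendre_01(n_nodes)
    Bnodes = spec.basis_matrix(nodes)
    if not np.all(np.isfinite(Bnodes)):
        raise ValueError("basis evaluation non-finite at a quadrature node")

    if init is not None:
        if not np.array_equal(init.mask, mask):
            raise ValueError("init mask does not match the model specification")
        theta0 = init.values
    else:
        theta0 = _initial_theta(X, t, spec)
    phi0 = theta0[mask]

    res = optimize.minimize(
        _loss_grad, phi0, args=(X, t, Bnodes, nodes, weights, mask),
        jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "maxfun": 10 * max_iter,
                 "ftol": 1e-11, "gtol": 1e-10},
    )
    gradient_norm = float(np.max(np.abs(res.jac)))
    fit = QRCMFit(
        theta_hat=ThetaMatrix.from_free(res.x, mask),
        spec=spec,
        integrated_loss_value=float(res.fun),
        gradient_norm=gradient_norm,
        converged=bool(res.success or res.status == 0),
        n_nodes=n_nodes,
        design=X,
        working_response=t,
        names=list(dataset.names) if dataset.names else [],
        n_iter=int(res.nit),
    )
    if not fit.converged or gradient_norm > fit.gradient_tol:
        raise QrcmConvergenceError(
            f"integrated-loss minimisation did not converge: status={res.status} "
            f"({res.message}), |grad|_max={gradient_norm:.3g}, "
            f"tol={fit.gradient_tol:.3g}, iterations={res.nit}"
        )
    Q = (X @ fit.theta_hat.values) @ Bnodes.T
    if np.any(np.diff(Q[:, np.argsort(nodes)], axis=1) < -1e-8):
        warnings.warn(
            "fitted quantile function is non-monotone in p at some observed "
            "covariate rows (quantile crossing)", stacklevel=2,
        )
    return fit


def _per_obs_gradients(fit: QRCMFit) -> np.ndarray:
    """Per-observation integrated-gradient contributions, shape (n, n_free)."""
    X, t = fit.design, fit.working_response
    mask = fit.spec.mask
    nodes, weights = _gauss_legendre_01(fit.n_nodes)
    Bnodes = fit.spec.basis_matrix(nodes)
    F = (X @ fit.theta_hat.values) @ Bnodes.T
    PW = nodes[None, :] - ((t[:, None] - F) <= 0)
    M = (PW * weights[None, :]) @ Bnodes  # n x k
    Gfull = -np.einsum("ic,ij->icj", X, M)  # n x (q+1) x k
    return Gfull.reshape(X.shape[0], -1)[:, mask.ravel()]


def covariance_sandwich(fit: QRCMFit, dataset: Dataset | None = None,
                        step: float | None = None) -> np.ndarray:
    """M-estimation sandwich covariance H^-1 G H^-1 of the free parameters.

    H is a central finite-difference Hessian of the analytic integrated-loss
    gradient and G the outer-product sum of per-observation integrated
    gradients.  Because the pointwise loss is kinked, the difference step
    acts as a smoothing bandwidth: it must cover enough residual sign
    changes to estimate the local curvature (a density, in effect), so the
    default scales as 0.5 sd(t) n^(-1/3), the usual nonsmooth-M-estimation
    rate.  The result is stored on the fit and returned.
    """
    X, t = fit.design, fit.working_response
    mask = fit.spec.mask
    nodes, weights = _gauss_legendre_01(fit.n_nodes)
    Bnodes = fit.spec.basis_matrix(nodes)
    phi = fit.theta_hat.free
    nf = phi.size
    if step is None:
        step = 0.5 * max(1.0, float(np.std(t))) * X.shape[0] ** (-1 / 3)

    H = np.empty((nf, nf))
    for j in range(nf):
        h = step
        up = phi.copy(); up[j] += h
        dn = phi.copy(); dn[j] -= h
        _, gu = _loss_grad(up, X, t, Bnodes, nodes, weights, mask)
        _, gd = _loss_grad(dn, X, t, Bnodes, nodes, weights, mask)
        H[:, j] = (gu - gd) / (2.0 * h)
    H = 0.5 * (H + H.T)

    Gi = _per_obs_gradients(fit)
    G = Gi.T @ Gi

    try:
        Hinv = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular Hessian of the integrated loss; the model is too rich "
            "for the data — simplify the basis specification"
        ) from exc
    cond = np.linalg.cond(H)
    if cond > 1e10:
        raise np.linalg.LinAlgError(
            f"near-singular Hessian (cond={cond:.2g}); simplify the model"
        )
    V = Hinv @ G @ Hinv
    V = 0.5 * (V + V.T)
    fit.covariance = V
    return V


def wald_test_global(fit: QRCMFit, covariate_index: int):
    """Wald test that every basis coefficient of one covariate is zero.

    Returns (statistic, df, p_value); the statistic is the quadratic form of
    the covariate's free theta entries against their covariance block and the
    p-value comes from the chi-square upper tail with df tested entries.
    """
    idx = fit.free_indices_of(covariate_index)
    if idx.size == 0:
        raise ValueError(f"covariate {covariate_index} has no free parameters")
    if fit.covariance is None:
        covariance_sandwich(fit)
    block = fit.covariance[np.ix_(idx, idx)]
    est = fit.theta_hat.free[idx]
    try:
        stat = float(est @ np.linalg.solve(block, est))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular covariance block in Wald test") from exc
    df = int(idx.size)
    return stat, df, float(stats.chi2.sf(stat, df))


def predict_quantile_count(fit: QRCMFit, x, p: float) -> int:
    """Predicted count quantile ceil(x' beta(p | theta-hat) - 1).

    With the identity working transform; negative values are possible under a
    linear specification and are returned unclamped.
    """
    check_quantile_level(p)
    x = np.asarray(x, dtype=float)
    val = float(x @ beta_curve(fit.theta_hat, fit.spec, p))
    return int(np.ceil(val - 1.0))


def _pit_working(fit: QRCMFit, X, t) -> np.ndarray:
    """PIT of working responses: p* with x' beta(p*) = t, by grid inversion.

    The fitted quantile curve is evaluated on the quadrature node grid; the
    first upward crossing is located and refined by linear interpolation
    (first-crossing rule if the curve is non-monotone), then clamped to
    [eps, 1-eps].
    """
    nodes, _ = _gauss_legendre_01(fit.n_nodes)
    order = np.argsort(nodes)
    nodes = nodes[order]
    Q = (X @ fit.theta_hat.values) @ fit.spec.basis_matrix(nodes).T
    t = np.asarray(t, dtype=float)
    ge = Q >= t[:, None]
    first = np.argmax(ge, axis=1)
    any_cross = ge.any(axis=1)
    p_star = np.empty(t.shape[0])
    for i in range(t.shape[0]):
        if not any_cross[i]:
            p_star[i] = 1.0 - PIT_EPS
            continue
        k = first[i]
        if k == 0:
            p_star[i] = PIT_EPS
            continue
        q0, q1 = Q[i, k - 1], Q[i, k]
        frac = 0.0 if q1 == q0 else (t[i] - q0) / (q1 - q0)
        p_star[i] = nodes[k - 1] + frac * (nodes[k] - nodes[k - 1])
    return np.clip(p_star, PIT_EPS, 1.0 - PIT_EPS)


def pit(fit: QRCMFit, x, y) -> float:
    """Probability integral transform F(y | x, theta-hat) at y0 = y + 0.5."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    t = np.atleast_1d(np.asarray(y, dtype=float)) + 0.5
    return float(_pit_working(fit, x, t)[0])


def pit_values(fit: QRCMFit, dataset: Dataset | None = None) -> np.ndarray:
    """PIT of every observation of the fitted (or a supplied) dataset."""
    if dataset is None:
        return _pit_working(fit, fit.design, fit.working_response)
    return _pit_working(fit, dataset.design, dataset.response + 0.5)


@dataclass(frozen=True)
class GofResult:
    statistic_name: str
    statistic: float
    mc_p_value: float
    n_replicates_used: int


def _uniform_distance(u: np.ndarray, statistic: str) -> float:
    if statistic == "KS":
        return float(stats.kstest(u, "uniform").statistic)
    if statistic == "CvM":
        return float(stats.cramervonmises(u, "uniform").statistic)
    raise ValueError("statistic must be 'KS' or 'CvM'")


def gof_test(fit: QRCMFit, dataset: Dataset, statistic: str = "KS",
             n_mc: int = 100, seed: int = 0) -> GofResult:
    """PIT goodness-of-fit with a Monte-Carlo p-value.

    The observed statistic is the distance of the empirical PIT distribution
    from Uniform(0, 1).  Each Monte-Carlo replicate simulates continuous
    working responses from the fitted model at the observed covariates
    (p ~ Uniform, y0 = x' beta(p | theta-hat)), refits the same specification
    (warm-started at theta-hat) and recomputes the statistic; the p-value is
    the fraction of replicate statistics at least as large as the observed
    one.  Replicates whose refit fails are dropped with a warning.
    """
    if n_mc < 50:
        raise ValueError("n_mc must be at least 50")
    u_obs = pit_values(fit, dataset)
    stat_obs = _uniform_distance(u_obs, statistic)
    rng = np.random.default_rng(seed)
    X = dataset.design
    stats_mc = []
    failures = 0
    for _ in range(n_mc):
        p_sim = rng.uniform(size=dataset.n)
        t_sim = np.einsum("ij,ij->i", X @ fit.theta_hat.values,
                          fit.spec.basis_matrix(p_sim))
        try:
            refit = fit_qrcm(dataset, fit.spec, init=fit.theta_hat,
                             working_response=t_sim, n_nodes=fit.n_nodes)
        except QrcmConvergenceError:
            failures += 1
            continue
        u_sim = _pit_working(refit, X, t_sim)
        stats_mc.append(_uniform_distance(u_sim, statistic))
    if failures:
        warnings.warn(f"{failures} of {n_mc} Monte-Carlo refits failed and "
                      "were dropped", stacklevel=2)
    stats_mc = np.asarray(stats_mc)
    if stats_mc.size == 0:
        raise QrcmConvergenceError("all Monte-Carlo refits failed")
    p_value = float(np.mean(stats_mc >= stat_obs))
    return GofResult(statistic_name=statistic, statistic=stat_obs,
                     mc_p_value=p_value, n_replicates_used=int(stats_mc.size))
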