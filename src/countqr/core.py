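"""Single-quantile linear quantile regression by pinball-loss minimisation.

The conditional quantile model is ``Q_{T(Y)}(p | x) = x' beta(p)`` for a
quantile order ``p`` in (0, 1), fitted by minimising the check (pinball)
objective

    L(beta) = sum_i (p - w_i) * (t_i - x_i' beta),   w_i = 1{t_i <= x_i' beta},

where ``t`` is a (possibly transformed) response.  This is the building block
used by the jittering estimator and the pointwise reference for the
integrated-loss (QRCM) estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.regression.quantile_regression import QuantReg
from statsmodels.tools.sm_exceptions import IterationLimitWarning


__all__ = [
    "Dataset",
    "PinballEvaluation",
    "QrSolution",
    "QrConvergenceError",
    "check_quantile_level",
    "pinball_objective",
    "solve_qr",
    "percentile_grid",
]


class QrConvergenceError(RuntimeError):
    """Raised when the quantile-regression solver fails to reach an optimum."""


def check_quantile_level(p: float) -> float:
    """Validate a quantile order, which must lie strictly inside (0, 1)."""
    p = float(p)
    if not 0.0 < p < 1.0:
        raise ValueError(f"quantile level must be in (0, 1), got {p}")
    return p


@dataclass(frozen=True)
class Dataset:
    """A design matrix with intercept column plus an integer count response.

    Parameters
    ----------
    design : (n, q+1) array
        Model matrix; the first column must be identically 1.
    response : (n,) array
        Non-negative integer counts.
    names : list of str
        Labels for the q+1 design columns (intercept first).
    """

    design: np.ndarray
    response: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self):
        design = np.asarray(self.design, dtype=float)
        response = np.asarray(self.response)
        if design.ndim != 2:
            raise ValueError("design must be a 2-d matrix")
        n, k = design.shape
        if response.shape != (n,):
            raise ValueError("response length must match design rows")
        if not np.all(np.isfinite(design)):
            raise ValueError("design contains non-finite values")
        if not np.allclose(design[:, 0], 1.0):
            raise ValueError("first design column must be the constant 1")
        if n <= k:
            raise ValueError(f"need n > q+1, got n={n}, q+1={k}")
        if np.any(response < 0) or np.any(response != np.floor(response)):
            raise ValueError("response must contain non-negative integers")
        object.__setattr__(self, "design", design)
        object.__setattr__(self, "response", np.asarray(response, dtype=int))
        if not self.names:
            object.__setattr__(
                self, "names", ["const"] + [f"x{j}" for j in range(1, k)]
            )
        elif len(self.names) != k:
            raise ValueError("names length must match design columns")

    @property
    def n(self) -> int:
        return self.design.shape[0]

    @property
    def q(self) -> int:
        """Number of covariates, excluding the intercept."""
        return self.design.shape[1] - 1


@dataclass(frozen=True)
class PinballEvaluation:
    """Value and pieces of the check-loss objective at one coefficient vector."""

    loss: float
    indicators: np.ndarray  # w_i = 1{t_i <= x_i' beta}
    residuals: np.ndarray  # t_i - x_i' beta


@dataclass(frozen=True)
class QrSolution:
    """A minimiser of the pinball objective at quantile order ``p``.

    Quantile-regression solutions are set-valued at finite n; downstream
    contracts compare achieved losses, never coefficients.
    """

    beta: np.ndarray
    p: float
    achieved_loss: float


def pinball_objective(beta, p, t, design) -> PinballEvaluation:
    """Evaluate the check-loss objective term by term.

    Returns the loss ``sum_i (p - w_i)(t_i - x_i'beta)`` together with the
    indicators ``w_i`` and the residuals; every summand is non-negative.
    """
    p = check_quantile_level(p)
    beta = np.asarray(beta, dtype=float)
    t = np.asarray(t, dtype=float)
    design = np.asarray(design, dtype=float)
    if beta.shape != (design.shape[1],):
        raise ValueError("beta length must equal the number of design columns")
    if t.shape != (design.shape[0],):
        raise ValueError("t length must equal the number of design rows")
    if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(t)) and np.all(np.isfinite(design))):
        raise ValueError("non-finite inputs to pinball_objective")
    residuals = t - design @ beta
    indicators = (residuals <= 0).astype(int)
    loss = float(np.sum((p - indicators) * residuals))
    return PinballEvaluation(loss=loss, indicators=indicators, residuals=residuals)


def solve_qr(dataset: Dataset, t, p: float, max_iter: int = 5000) -> QrSolution:
    """Minimise the pinball objective for transformed responses ``t`` at order ``p``.

    Uses the iteratively-reweighted-least-squares solver of statsmodels'
    ``QuantReg``.  Rank-deficient designs produce a warning and return some
    minimiser; a failure to converge raises :class:`QrConvergenceError`.
    """
    p = check_quantile_level(p)
    t = np.asarray(t, dtype=float)
    design = dataset.design
    if t.shape != (dataset.n,):
        raise ValueError("t length must match dataset rows")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn(
            "design matrix is rank deficient; quantile solution not unique",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("error", IterationLimitWarning)
        warnings.simplefilter("ignore")  # pinv / degenerate-weight chatter
        try:
            res = QuantReg(t, design).fit(q=p, max_iter=max_iter, p_tol=1e-8)
        except IterationLimitWarning as exc:  # pragma: no cover - rare
            raise QrConvergenceError(
                f"quantile regression did not converge at p={p}: {exc}"
            ) from exc
    beta = np.asarray(res.params, dtype=float)
    if not np.all(np.isfinite(beta)):
        raise QrConvergenceError(f"non-finite solution at p={p}")
    loss = pinball_objective(beta, p, t, design).loss
    return QrSolution(beta=beta, p=p, achieved_loss=loss)


def percentile_grid() -> np.ndarray:
    """The percentile grid {0.01, 0.02, ..., 0.99} used for per-quantile fits."""
    return np.round(np.arange(1, 100) / 100.0, 2)
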