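"""The candidate QRCM specifications for the credits analysis, and diagnostics.

Five nested-ish specifications are considered for the 11-coefficient design
(intercept + 10 covariates).  ``poly(p, r)`` denotes the shifted Legendre
polynomials up to degree r (r+1 terms); the cohort dummy is covariate 2 and
the school-type dummies are covariates 5..10, which keep a constant
coefficient in all but the baseline model.  Model selection combines the
minimised integrated loss (which only compares models of equal complexity),
Wald tests, and visual comparison of the parametric cohort-effect curve
against the pointwise jittering estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import minus_log1mp, poly_basis
from .core import Dataset
from .jitter import JitterFit
from .qrcm import ModelSpec, QRCMFit, covariance_sandwich, fit_qrcm

__all__ = [
    "GridEntry",
    "build_table2_models",
    "count_free_parameters",
    "fit_grid",
    "loss_table",
    "beta2_overlay",
]

#: design layout of the credits analysis: intercept + X1..X10
N_COEF = 11
COHORT_INDEX = 2


@dataclass
class GridEntry:
    """One candidate specification: label, spec, parameter count, optional fit."""

    label: str
    spec: ModelSpec
    n_params: int
    fitted: QRCMFit | None = None


def count_free_parameters(spec: ModelSpec) -> int:
    """Number of free theta entries: the sum of basis-list lengths."""
    return spec.n_free


def _spec(intercept, cohort, controls, schools) -> ModelSpec:
    rows = [None] * N_COEF
    rows[0] = intercept
    rows[COHORT_INDEX] = cohort
    for c in (1, 3, 4):
        rows[c] = list(controls)
    for c in range(5, N_COEF):
        rows[c] = list(schools)
    return ModelSpec(rows)


def build_table2_models() -> list[GridEntry]:
    """The five candidate specifications of the credits case study.

    Model 0 gives every coefficient a linear-in-p curve.  Models 1-4 model
    the intercept and the cohort effect flexibly (degree-5 or degree-8
    shifted Legendre polynomials, optionally plus -log(1-p)) while the
    controls X1, X3, X4 get low-order polynomials and the school dummies
    X5..X10 a constant coefficient.
    """
    lin = poly_basis(1)
    const = poly_basis(0)
    p5log = poly_basis(5) + [minus_log1mp()]
    p5 = poly_basis(5)
    p8log = poly_basis(8) + [minus_log1mp()]
    entries = [
        GridEntry("Model 0", _spec(lin, lin, lin, lin), 0),
        GridEntry("Model 1", _spec(p5log, p5, lin, const), 0),
        GridEntry("Model 2", _spec(p5log, p5log, lin, const), 0),
        GridEntry("Model 3", _spec(p5log, p5log, poly_basis(3), const), 0),
        GridEntry("Model 4", _spec(p8log, p8log, lin, const), 0),
    ]
    for e in entries:
        e.n_params = count_free_parameters(e.spec)
    return entries


def fit_grid(entries: list[GridEntry], dataset: Dataset,
             with_covariance: bool = False) -> list[GridEntry]:
    """Fit every grid entry on one dataset (in place; entries are returned)."""
    for e in entries:
        e.fitted = fit_qrcm(dataset, e.spec)
        if with_covariance:
            covariance_sandwich(e.fitted)
    return entries


def loss_table(entries: list[GridEntry]) -> pd.DataFrame:
    """Minimised integrated loss by model, in the given order.

    All entries must be fitted on the same dataset; for nested pairs the
    richer model attains a loss no larger than the nested one.
    """
    for e in entries:
        if e.fitted is None:
            raise ValueError(f"{e.label} has not been fitted")
    return pd.DataFrame(
        {
            "model": [e.label for e in entries],
            "parameters": [e.n_params for e in entries],
            "loss": [e.fitted.integrated_loss_value for e in entries],
        }
    )


def beta2_overlay(fit: QRCMFit, jfit: JitterFit,
                  covariate_index: int = COHORT_INDEX) -> pd.DataFrame:
    """Pointwise overlay of a parametric coefficient curve and jittering estimates.

    For each order of the jittering grid: the QRCM point estimate, the
    pointwise 95% band (+/- 1.96 delta-method SE of b(p)' theta_c), and the
    jittering estimate — as a plain table ready for plotting.
    """
    p_grid = np.asarray(jfit.p_grid, dtype=float)
    if np.any(p_grid <= 0) or np.any(p_grid >= 1):
        raise ValueError("jittering grid must lie inside (0, 1)")
    if fit.covariance is None:
        covariance_sandwich(fit)
    if jfit.beta_avg.shape[1] != fit.spec.n_coef:
        raise ValueError("jittering fit and QRCM fit use different designs")
    B = fit.spec.basis_matrix(p_grid)  # len(grid) x k
    curve = B @ fit.theta_hat.values[covariate_index]
    idx = fit.free_indices_of(covariate_index)
    cols = np.flatnonzero(fit.spec.mask[covariate_index])
    Bsel = B[:, cols]
    block = fit.covariance[np.ix_(idx, idx)]
    se = np.sqrt(np.einsum("pj,jk,pk->p", Bsel, block, Bsel))
    return pd.DataFrame(
        {
            "p": p_grid,
            "qrcm": curve,
            "lower": curve - 1.96 * se,
            "upper": curve + 1.96 * se,
            "jittering": jfit.beta_avg[:, covariate_index],
        }
    )
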