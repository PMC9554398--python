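"""Synthetic student-credits data with a known conditional quantile model.

The original analysis uses administrative records that are not public, so
this module generates datasets that emulate their structure: background
covariates with marginals close to the published summary table (about 79.5%
female students, seven high-school types, high-school grade with mean 81.2
and SD 11, first-semester credits in positive multiples of 3 with mean 21.6
and SD 6.6), and a count response on {0, ..., 21} (credits divided by 3)
drawn from a known parametric conditional quantile function so that the true
coefficients are recoverable by either estimator.

The response is generated by inversion: p ~ Uniform(0, 1), a continuous
working value y0 = x' beta(p | theta_true), and the count y = ceil(y0 - 1)
(clamped to the support, which by construction is hit in well under 1% of
draws).  This mirrors exactly the ceiling rule the estimators use to map
working quantiles back to count quantiles, so the generator's true count
quantiles are exactly what the estimators target.  Covariates are sampled
independently of one another (the published table reports only marginals).

All structural constants of the default true model are synthetic: they are
chosen to resemble the published fitted curves in location and shape, not
copied from any data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import Dataset
from .basis import monomial_to_shifted_legendre
from .qrcm import ModelSpec, ThetaMatrix

__all__ = [
    "SCHOOL_TYPES",
    "COLUMN_NAMES",
    "CovariateConfig",
    "TrueModel",
    "SyntheticData",
    "sample_covariates",
    "sample_response",
    "default_true_model",
    "generate_dataset",
]

SCHOOL_TYPES = (
    "Scientific",
    "Humanities",
    "Language",
    "Human sciences",
    "Art school",
    "Technical",
    "Other",
)

#: design-column labels: intercept, X1..X10
COLUMN_NAMES = [
    "const",
    "credits1_std",
    "cohort2019",
    "male",
    "grade_std",
    "hs_humanities",
    "hs_language",
    "hs_human_sciences",
    "hs_art",
    "hs_technical",
    "hs_other",
]

# marginal shares of the seven school types (Psychology totals), renormalised
_SCHOOL_PROBS = np.array([35.1, 16.6, 7.24, 22.2, 2.16, 12.3, 4.31])
_SCHOOL_PROBS = _SCHOOL_PROBS / _SCHOOL_PROBS.sum()


@dataclass(frozen=True)
class CovariateConfig:
    """Marginals of the covariate generator (defaults: Psychology cohort totals)."""

    n: int = 649
    prop_female: float = 0.795
    prop_cohort2019: float = 0.5
    school_type_probs: tuple = tuple(_SCHOOL_PROBS)
    grade_mean: float = 81.17
    grade_sd: float = 11.00
    grade_lo: float = 60.0
    grade_hi: float = 100.0
    credits1_mean: float = 21.6
    credits1_sd: float = 6.64
    seed: int = 0

    def __post_init__(self):
        probs = np.asarray(self.school_type_probs, dtype=float)
        if probs.size != len(SCHOOL_TYPES) or np.any(probs < 0) or np.any(probs > 1):
            raise ValueError("school_type_probs must be 7 probabilities")
        if abs(probs.sum() - 1.0) > 1e-8:
            raise ValueError("school_type_probs must sum to 1")
        for name in ("prop_female", "prop_cohort2019"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.grade_sd <= 0 or self.credits1_sd <= 0:
            raise ValueError("standard deviations must be positive")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["school_type_probs"] = list(d["school_type_probs"])
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, s: str) -> "CovariateConfig":
        d = json.loads(s)
        d["school_type_probs"] = tuple(d["school_type_probs"])
        return cls(**d)


@dataclass(frozen=True)
class TrueModel:
    """A known conditional quantile model for the count response.

    ``theta_true`` lives on ``spec``'s basis; the implied Q(p | x) must be
    strictly increasing in p on every covariate profile of a validation hull
    (checked by :func:`validate_monotone`), and the clamp to the support
    [0, support_cap] must be hit rarely.
    """

    spec: ModelSpec
    theta_true: ThetaMatrix
    support_cap: int = 21

    def quantile_working(self, X, p) -> np.ndarray:
        """Working-scale quantiles x' beta(p | theta_true), rows paired with p."""
        B = self.spec.basis_matrix(np.asarray(p, dtype=float))
        return np.einsum("ij,ij->i", np.atleast_2d(X) @ self.theta_true.values, B)

    def quantile_count(self, x, p) -> np.ndarray:
        """True count quantile ceil(Q0(p | x) - 1), clamped to the support."""
        p = np.atleast_1d(np.asarray(p, dtype=float))
        x = np.asarray(x, dtype=float)
        q0 = (x @ self.theta_true.values) @ self.spec.basis_matrix(p).T
        return np.clip(np.ceil(q0 - 1.0), 0, self.support_cap).astype(int)


def validate_monotone(model: TrueModel, X, n_grid: int = 201, tol: float = 1e-9):
    """Check strict monotonicity of Q(p | x) in p over each row of X.

    Raises with the offending row index if any profile's quantile function
    decreases on the interior grid.
    """
    p = np.linspace(0.001, 0.999, n_grid)
    Q = (np.atleast_2d(X) @ model.theta_true.values) @ model.spec.basis_matrix(p).T
    bad = np.flatnonzero(np.any(np.diff(Q, axis=1) <= tol, axis=1))
    if bad.size:
        raise ValueError(
            f"quantile function non-monotone in p for covariate profile(s) "
            f"{bad[:5].tolist()}{'...' if bad.size > 5 else ''}"
        )


def _truncnorm_parent_params(target_mean, target_sd, lo, hi):
    """Parent normal (mu, sigma) whose [lo, hi]-truncation has given moments."""

    def moments(x):
        mu, sigma = x
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [m - target_mean, np.sqrt(v) - target_sd]

    sol, info, ier, msg = optimize.fsolve(
        moments, x0=[target_mean, 2.0 * target_sd], full_output=True
    )
    if ier != 1 or sol[1] <= 0:
        raise ValueError(
            f"cannot match truncated-normal moments mean={target_mean}, "
            f"sd={target_sd} on [{lo}, {hi}]: {msg}"
        )
    return float(sol[0]), float(sol[1])


def sample_covariates(config: CovariateConfig) -> pd.DataFrame:
    """Sample a raw covariate table with the configured marginals.

    Gender and cohort are Bernoulli, school type categorical, the high-school
    grade a truncated normal on [grade_lo, grade_hi] whose truncated moments
    match the configured mean/SD, and first-semester credits positive
    multiples of 3 with approximately the configured mean/SD.  Standardised
    versions of the continuous covariates (centred at the configured mean,
    divided by the configured SD) are exposed alongside the raw values.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    cohort = np.where(rng.uniform(size=n) < config.prop_cohort2019, 2019, 2018)
    gender = np.where(rng.uniform(size=n) < config.prop_female, "female", "male")
    school = rng.choice(SCHOOL_TYPES, size=n, p=np.asarray(config.school_type_probs))
    mu, sigma = _truncnorm_parent_params(
        config.grade_mean, config.grade_sd, config.grade_lo, config.grade_hi
    )
    a, b = (config.grade_lo - mu) / sigma, (config.grade_hi - mu) / sigma
    grade = stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=n, random_state=rng)
    # first-semester credits: positive multiples of 3
    k = np.rint(rng.normal(config.credits1_mean / 3.0, config.credits1_sd / 3.0, size=n))
    credits1 = 3 * np.clip(k, 1, 15).astype(int)
    return pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "cohort": cohort,
            "gender": gender,
            "school_type": school,
            "grade": grade,
            "credits_sem1": credits1,
            "grade_std": (grade - config.grade_mean) / config.grade_sd,
            "credits1_std": (credits1 - config.credits1_mean) / config.credits1_sd,
        }
    )


def design_from_covariates(cov: pd.DataFrame) -> np.ndarray:
    """Design matrix (intercept + X1..X10) from a covariate table.

    Continuous covariates enter through their standardised columns; the
    school-type dummies use 'Scientific' as the baseline.
    """
    n = len(cov)
    X = np.zeros((n, len(COLUMN_NAMES)))
    X[:, 0] = 1.0
    X[:, 1] = cov["credits1_std"].to_numpy()
    X[:, 2] = (cov["cohort"].to_numpy() == 2019).astype(float)
    X[:, 3] = (cov["gender"].to_numpy() == "male").astype(float)
    X[:, 4] = cov["grade_std"].to_numpy()
    for j, st in enumerate(SCHOOL_TYPES[1:], start=5):
        X[:, j] = (cov["school_type"].to_numpy() == st).astype(float)
    return X


def default_true_model() -> TrueModel:
    """A synthetic true model with the selected-specification structure.

    The intercept rises from about 7.5 to about 14 across p (with a mild
    -log(1-p) right tail); the cohort effect is a parabola that is null at
    the median and negative in both tails; the controls have gentle linear
    curves and the school-type contrasts are constants.  All values are
    synthetic stand-ins, sized so the implied quantile function is strictly
    monotone over the realistic covariate hull and the median count of the
    reference profile is about 10.
    """
    from .models import build_table2_models

    spec = build_table2_models()[2].spec  # flexible intercept & cohort effect
    k = spec.k  # legendre degrees 0..5 plus -log(1-p)
    theta = np.zeros((spec.n_coef, k))

    def set_row(c, mono, log_coef=0.0):
        leg = monomial_to_shifted_legendre(mono)
        theta[c, : leg.size] = leg
        theta[c, k - 1] = log_coef

    # intercept: cubic with derivative 5 + 14 (2p-1)^2 (steep in both tails,
    # flat in the middle — the sparse-tail shape of the credits data) plus a
    # mild -log(1-p) right tail; 8.1 + 5p + 7/3 (2p-1)^3 in monomials
    set_row(0, [8.1 - 7 / 3, 5.0 + 14.0, -28.0, 56.0 / 3], log_coef=0.3)
    set_row(1, [1.2, -1.2])                        # credits sem 1 (std)
    set_row(2, [-0.6, 2.4, -2.4], log_coef=0.0)    # cohort 2019
    set_row(3, [-0.5, 1.2])                        # male
    set_row(4, [0.12, 0.02])                       # grade (std)
    for c, val in zip(range(5, 11), (-0.18, -0.30, -0.20, -0.40, -0.35, -0.79)):
        theta[c, 0] = val                          # school-type contrasts
    theta[~spec.mask] = 0.0
    return TrueModel(spec=spec, theta_true=ThetaMatrix(theta, spec.mask))


def sample_response(X, model: TrueModel, seed: int = 0):
    """Draw counts from the true model by quantile inversion.

    Per row: p ~ Uniform(0, 1), y0 = x' beta(p | theta_true),
    y = clamp(ceil(y0 - 1), 0, support_cap).  Returns (counts, latent p).
    Monotonicity is validated on the sampled profiles first.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    validate_monotone(model, X)
    rng = np.random.default_rng(seed)
    p = np.clip(rng.uniform(size=X.shape[0]), 1e-12, 1 - 1e-12)
    y0 = model.quantile_working(X, p)
    y = np.clip(np.ceil(y0 - 1.0), 0, model.support_cap).astype(int)
    return y, p


@dataclass
class SyntheticData:
    """A generated dataset: raw records, ready-made design, and the truth."""

    raw: pd.DataFrame
    dataset: Dataset
    latent_p: np.ndarray
    model: TrueModel
    config: CovariateConfig


def generate_dataset(n: int = 649, seed: int = 0,
                     config: CovariateConfig | None = None,
                     model: TrueModel | None = None) -> SyntheticData:
    """Generate a full synthetic dataset in the pipeline's CSV schema.

    The returned ``dataset`` standardises continuous covariates by the
    configured (population) constants, so ``model.theta_true`` is exactly the
    truth for it; the ``raw`` table additionally carries the second-semester
    credits (3 x count) for round-tripping through the file-based pipeline.
    """
    if config is None:
        config = CovariateConfig(n=n, seed=seed)
    elif config.n != n or config.seed != seed:
        raise ValueError("config.n/config.seed must agree with n/seed")
    if model is None:
        model = default_true_model()
    cov = sample_covariates(config)
    X = design_from_covariates(cov)
    # separate response stream so covariates are reusable across responses
    y, latent_p = sample_response(X, model, seed=int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31)))
    raw = cov.copy()
    raw["credits_sem2"] = 3 * y
    dataset = Dataset(design=X, response=y, names=list(COLUMN_NAMES))
    return SyntheticData(raw=raw, dataset=dataset, latent_p=latent_p,
                         model=model, config=config)
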