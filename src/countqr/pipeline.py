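"""End-to-end credits analysis: load, preprocess, fit both estimators, report.

The pipeline reads student records (CSV), applies the preprocessing of the
credits case study (exclusion of students with zero first-semester credits,
response = second-semester credits / 3, standardised continuous covariates,
school-type dummies against the 'Scientific' baseline), fits the average
jittering estimator on the percentile grid and the candidate QRCM models,
and writes plain-text reports: a coefficient/SE table for both methods at
selected quantile orders, an average-SE table with a QRCM/jittering ratio
row, the cohort-effect overlay, the model-grid loss table, per-covariate
Wald tests and the PIT goodness-of-fit result.  Every random seed consumed
is recorded in a run manifest so reruns are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Dataset, percentile_grid
from .jitter import JitterConfig, JitterFit, average_jittering_fit, bootstrap_se
from .models import (
    COHORT_INDEX,
    GridEntry,
    beta2_overlay,
    build_table2_models,
    fit_grid,
    loss_table,
)
from .qrcm import QRCMFit, covariance_sandwich, gof_test, wald_test_global

__all__ = [
    "REQUIRED_COLUMNS",
    "AnalysisConfig",
    "ReportBundle",
    "load_records",
    "preprocess",
    "run_full_analysis",
]

REQUIRED_COLUMNS = (
    "id", "cohort", "gender", "school_type", "grade", "credits_sem1", "credits_sem2",
)

_SCHOOL_LEVELS = (
    "Scientific", "Humanities", "Language", "Human sciences",
    "Art school", "Technical", "Other",
)

_COEF_LABELS = [
    "Intercept", "Credits 1st sem. (std)", "Cohort 2019", "Male",
    "High school grade (std)", "Humanities", "Language", "Human sciences",
    "Art", "Technical", "Other",
]


@dataclass
class AnalysisConfig:
    """Settings of a full pipeline run.

    ``p_report`` are the quantile orders of the coefficient and SE tables;
    ``m`` jitter replications are used for point estimates on the percentile
    grid, with ``bootstrap_B`` row resamples (each re-jittered ``bootstrap_m``
    times) for jittering standard errors at the reported orders; ``n_mc``
    Monte-Carlo replicates calibrate the goodness-of-fit p-value.  The
    selected model (for inference tables) defaults to the specification with
    flexible intercept and cohort-effect curves.
    """

    input: str | None = None
    p_report: tuple = (0.10, 0.25, 0.50, 0.75, 0.90)
    m: int = 30
    transform: str = "linear"
    zeta: float = 1e-5
    bootstrap_B: int = 50
    bootstrap_m: int = 10
    n_mc: int = 50
    models: tuple = ("Model 0", "Model 1", "Model 2", "Model 3", "Model 4")
    selected_model: str = "Model 2"
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self):
        grid = percentile_grid()
        for p in self.p_report:
            if not (grid.min() - 1e-9 <= p <= grid.max() + 1e-9):
                raise ValueError(f"reported order {p} outside the percentile grid")

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def load_records(path) -> pd.DataFrame:
    """Read and validate a student-records CSV.

    Requires the columns id, cohort, gender, school_type, grade,
    credits_sem1, credits_sem2; ids must be unique, cells parseable, and
    credit totals non-negative multiples of 3 (every exam is worth 6, 9 or
    12 credits).
    """
    raw = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    dup = raw["id"][raw["id"].duplicated()]
    if len(dup):
        rows = (raw.index[raw["id"].duplicated()] + 2).tolist()[:5]
        raise ValueError(f"duplicate id values at file row(s) {rows}")
    for col in ("cohort", "grade", "credits_sem1", "credits_sem2"):
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = raw.index[coerced.isna()]
        if len(bad):
            raise ValueError(
                f"unparseable value in column '{col}' at file row(s) "
                f"{(bad + 2).tolist()[:5]}"
            )
        raw[col] = coerced
    for col in ("credits_sem1", "credits_sem2"):
        vals = raw[col].to_numpy()
        bad = raw.index[(vals < 0) | (vals % 3 != 0)]
        if len(bad):
            raise ValueError(
                f"column '{col}' must hold non-negative multiples of 3 "
                f"(exams are worth 6, 9 or 12 credits); bad file row(s) "
                f"{(bad + 2).tolist()[:5]}"
            )
    return raw


@dataclass
class Preprocessed:
    dataset: Dataset
    n_excluded: int


def preprocess(raw: pd.DataFrame) -> Preprocessed:
    """Apply the case-study preprocessing to validated records.

    Students with zero first-semester credits are dropped (their second
    semester mostly consists of first-semester exams).  The response is
    credits_sem2 / 3; first-semester credits and the high-school grade are
    centred at their sample means and divided by their sample SDs; cohort
    2019 and male are dummies; the six school-type dummies use 'Scientific'
    as the baseline.
    """
    unseen = set(raw["school_type"].unique()) - set(_SCHOOL_LEVELS)
    if unseen:
        raise ValueError(f"unseen school_type level(s): {sorted(unseen)}")
    keep = raw[raw["credits_sem1"] > 0].reset_index(drop=True)
    n_excluded = len(raw) - len(keep)
    if len(keep) == 0:
        raise ValueError("all rows excluded (no student earned first-semester credits)")
    y = (keep["credits_sem2"].to_numpy() // 3).astype(int)
    n = len(keep)
    X = np.zeros((n, 11))
    X[:, 0] = 1.0
    for j, col in ((1, "credits_sem1"), (4, "grade")):
        v = keep[col].to_numpy(dtype=float)
        X[:, j] = (v - v.mean()) / v.std(ddof=1)
    X[:, 2] = (keep["cohort"].to_numpy() == 2019).astype(float)
    X[:, 3] = (keep["gender"].astype(str).str.lower().to_numpy() == "male").astype(float)
    for j, st in enumerate(_SCHOOL_LEVELS[1:], start=5):
        X[:, j] = (keep["school_type"].to_numpy() == st).astype(float)
    names = ["const", "credits1_std", "cohort2019", "male", "grade_std"] + [
        "hs_" + st.lower().replace(" ", "_") for st in _SCHOOL_LEVELS[1:]
    ]
    return Preprocessed(dataset=Dataset(design=X, response=y, names=names),
                        n_excluded=n_excluded)


@dataclass
class ReportBundle:
    """All tables of one analysis run, plus seeds and any failed stages."""

    coefficients: pd.DataFrame | None = None
    average_se: pd.DataFrame | None = None
    overlay: pd.DataFrame | None = None
    losses: pd.DataFrame | None = None
    wald: pd.DataFrame | None = None
    gof: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)
    failed_stages: dict = field(default_factory=dict)
    jitter_fit: JitterFit | None = None
    qrcm_fit: QRCMFit | None = None
    grid: list[GridEntry] | None = None

    @property
    def partial(self) -> bool:
        return bool(self.failed_stages)


def _coefficient_table(jfit: JitterFit, se_j: np.ndarray, fit: QRCMFit,
                       p_report) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-form coefficient/SE table and the average-SE table with ratio row."""
    p_report = np.asarray(p_report, dtype=float)
    beta_q = fit.beta_at(p_report)  # len(p) x 11
    B = fit.spec.basis_matrix(p_report)
    se_q = np.empty_like(beta_q)
    for c in range(fit.spec.n_coef):
        idx = fit.free_indices_of(c)
        cols = np.flatnonzero(fit.spec.mask[c])
        block = fit.covariance[np.ix_(idx, idx)]
        se_q[:, c] = np.sqrt(np.einsum("pj,jk,pk->p", B[:, cols], block, B[:, cols]))
    rows = []
    for c, label in enumerate(_COEF_LABELS):
        for ip, p in enumerate(p_report):
            jidx = int(np.argmin(np.abs(jfit.p_grid - p)))
            rows.append({
                "coefficient": label, "p": p,
                "jittering_est": jfit.beta_avg[jidx, c],
                "jittering_se": se_j[ip, c],
                "qrcm_est": beta_q[ip, c],
                "qrcm_se": se_q[ip, c],
            })
    coef = pd.DataFrame(rows)
    avg = coef.groupby("p", as_index=False).agg(
        jittering=("jittering_se", "mean"), qrcm=("qrcm_se", "mean"))
    avg["ratio"] = avg["qrcm"] / avg["jittering"]
    return coef, avg


def run_full_analysis(config: AnalysisConfig,
                      dataset: Dataset | None = None) -> ReportBundle:
    """Run the whole analysis and (optionally) write the report CSVs.

    ``dataset`` may be passed directly (e.g. from the synthetic generator);
    otherwise ``config.input`` is loaded and preprocessed.  Stage failures do
    not abort the run: the bundle is marked partial with the failing stage
    named in ``failed_stages``.
    """
    bundle = ReportBundle()
    n_excluded = 0
    if dataset is None:
        if config.input is None:
            raise ValueError("either a dataset or config.input is required")
        pre = preprocess(load_records(config.input))
        dataset, n_excluded = pre.dataset, pre.n_excluded

    ss = np.random.SeedSequence(config.seed)
    seed_jitter, seed_boot, seed_gof = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    )
    p_grid = percentile_grid()
    p_report = np.asarray(config.p_report, dtype=float)

    jcfg = JitterConfig(m=config.m, transform=config.transform,
                        zeta=config.zeta, seed=seed_jitter)
    try:
        bundle.jitter_fit = average_jittering_fit(dataset, p_grid, jcfg)
        se_j = bootstrap_se(
            dataset, p_report,
            JitterConfig(m=config.m, transform=config.transform,
                         zeta=config.zeta, seed=seed_boot),
            B=config.bootstrap_B, m_boot=config.bootstrap_m,
        )
    except Exception as exc:
        bundle.failed_stages["jittering"] = str(exc)
        se_j = None

    try:
        entries = [e for e in build_table2_models() if e.label in config.models]
        bundle.grid = fit_grid(entries, dataset)
        bundle.losses = loss_table(entries)
        selected = next(e for e in entries if e.label == config.selected_model)
        bundle.qrcm_fit = selected.fitted
        covariance_sandwich(bundle.qrcm_fit)
    except Exception as exc:
        bundle.failed_stages["qrcm"] = str(exc)

    if bundle.qrcm_fit is not None and bundle.jitter_fit is not None and se_j is not None:
        try:
            bundle.coefficients, bundle.average_se = _coefficient_table(
                bundle.jitter_fit, se_j, bundle.qrcm_fit, p_report)
            bundle.overlay = beta2_overlay(bundle.qrcm_fit, bundle.jitter_fit,
                                           COHORT_INDEX)
        except Exception as exc:
            bundle.failed_stages["tables"] = str(exc)

    if bundle.qrcm_fit is not None:
        try:
            wrows = []
            for c in range(1, dataset.design.shape[1]):
                stat, df, pval = wald_test_global(bundle.qrcm_fit, c)
                wrows.append({"covariate": _COEF_LABELS[c], "statistic": stat,
                              "df": df, "p_value": pval})
            bundle.wald = pd.DataFrame(wrows)
        except Exception as exc:
            bundle.failed_stages["wald"] = str(exc)
        try:
            gof = gof_test(bundle.qrcm_fit, dataset, statistic="KS",
                           n_mc=config.n_mc, seed=seed_gof)
            bundle.gof = pd.DataFrame([{
                "statistic": gof.statistic_name, "value": gof.statistic,
                "mc_p_value": gof.mc_p_value,
                "replicates_used": gof.n_replicates_used,
            }])
        except Exception as exc:
            bundle.failed_stages["gof"] = str(exc)

    bundle.manifest = {
        "settings": {k: v for k, v in asdict(config).items()},
        "seeds": {"master": config.seed, "jitter": seed_jitter,
                  "bootstrap": seed_boot, "gof": seed_gof},
        "n_rows": int(dataset.n),
        "n_excluded_zero_credits1": int(n_excluded),
        "partial": bundle.partial,
        "failed_stages": bundle.failed_stages,
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tables = {
            "coefficients.csv": bundle.coefficients,
            "average_se.csv": bundle.average_se,
            "beta2_overlay.csv": bundle.overlay,
            "loss_table.csv": bundle.losses,
            "wald_tests.csv": bundle.wald,
            "gof.csv": bundle.gof,
        }
        for name, df in tables.items():
            if df is not None:
                df.to_csv(out / name, index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(bundle.manifest, fh, indent=2, sort_keys=True)
    return bundle
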