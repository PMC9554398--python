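"""Quantile regression for counts via jittering.

A count ``Y`` is turned into a continuous working variable ``Z = Y + U`` with
``U ~ Uniform[0, 1)``; the quantiles of ``Z`` are in one-to-one correspondence
with those of ``Y``.  Linear quantile regression is applied to a monotone
transform ``T`` of ``Z`` — here either the linear transform ``T(Z, p) = Z - p``
(the quantile function of Z is bounded below by p) or the classical log
transform ``log(Z - p)`` with a floor ``log(zeta)`` for ``Z <= p``.  Because a
single fit depends on the realised noise, estimation is repeated over m
independent jitterings and the coefficient estimates averaged ("average
jittering").  Count quantiles are recovered with the ceiling rule
``Q_Y(p|x) = ceil(T^{-1}(x'beta(p)) - 1)``.

Standard errors are obtained by a nonparametric bootstrap over rows,
re-jittering with fresh noise inside each resample.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .core import Dataset, check_quantile_level, solve_qr

__all__ = [
    "JitterConfig",
    "WorkingSample",
    "JitterFit",
    "jitter_sample",
    "transform_working",
    "invert_to_count",
    "average_jittering_fit",
    "bootstrap_se",
]


@dataclass(frozen=True)
class JitterConfig:
    """Settings of the average-jittering estimator.

    m : number of jitter replications averaged over (default 100).
    transform : "linear" for T(Z,p) = Z - p, or "log" for the classical
        log(Z - p) transform with floor log(zeta).
    zeta : floor constant of the log transform, a suitably small positive
        number (default 1e-5).
    seed : seed of the jitter-noise stream.
    """

    m: int = 100
    transform: str = "linear"
    zeta: float = 1e-5
    seed: int = 0

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("m must be a positive integer")
        if self.transform not in ("linear", "log"):
            raise ValueError("transform must be 'linear' or 'log'")
        if not 0.0 < self.zeta < 1.0:
            raise ValueError("zeta must lie in (0, 1)")


@dataclass(frozen=True)
class WorkingSample:
    """One jittered sample ``z_i = y_i + u_i`` with ``u_i ~ Uniform[0, 1)``."""

    z: np.ndarray


@dataclass(frozen=True)
class JitterFit:
    """Average-jittering estimates over a grid of quantile orders.

    ``beta_avg`` is the elementwise arithmetic mean of the per-replication
    estimates stored in ``beta_reps`` (shape m x grid x (q+1)); ``se_boot``
    holds bootstrap standard errors when computed.
    """

    p_grid: np.ndarray
    beta_avg: np.ndarray
    beta_reps: np.ndarray
    config: JitterConfig
    se_boot: np.ndarray | None = None
    names: list[str] = field(default_factory=list)

    def beta_at(self, p: float) -> np.ndarray:
        idx = int(np.argmin(np.abs(self.p_grid - p)))
        if not math.isclose(self.p_grid[idx], p, abs_tol=1e-9):
            raise KeyError(f"quantile order {p} not in the fitted grid")
        return self.beta_avg[idx]


def jitter_sample(response, rng: np.random.Generator) -> WorkingSample:
    """Draw one jittered working sample ``z = y + u``, ``u ~ Uniform[0, 1)``."""
    y = np.asarray(response)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("response must contain non-negative integers")
    u = rng.uniform(0.0, 1.0, size=y.shape)
    return WorkingSample(z=y.astype(float) + u)


def transform_working(z, p: float, config: JitterConfig) -> np.ndarray:
    """Apply the working transform T(z, p): linear ``z - p`` or floored log."""
    p = check_quantile_level(p)
    z = np.asarray(z, dtype=float)
    if config.transform == "linear":
        return z - p
    out = np.full_like(z, math.log(config.zeta))
    pos = z > p
    out[pos] = np.log(z[pos] - p)
    return out


def invert_to_count(fitted, p: float, config: JitterConfig):
    """Recover a count quantile: ``ceil(T^{-1}(fitted) - 1)``.

    The inverse transform is ``v + p`` (linear) or ``exp(v) + p`` (log).
    Values may be negative under the linear transform and are reported as-is.
    """
    p = check_quantile_level(p)
    fitted = np.asarray(fitted, dtype=float)
    if config.transform == "linear":
        inv = fitted + p
    else:
        inv = np.exp(fitted) + p
    out = np.ceil(inv - 1.0).astype(int)
    return out if out.ndim else int(out)


def _avg_fit_arrays(dataset: Dataset, p_grid, config: JitterConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """Per-replication estimates, shape (m, len(grid), q+1).

    One working sample is drawn per replication and reused across all
    quantile orders in the grid (replications index jitter draws, not p).
    """
    p_grid = np.asarray(p_grid, dtype=float)
    reps = np.empty((config.m, p_grid.size, dataset.design.shape[1]))
    for l in range(config.m):
        ws = jitter_sample(dataset.response, rng)
        for j, p in enumerate(p_grid):
            t = transform_working(ws.z, p, config)
            try:
                reps[l, j] = solve_qr(dataset, t, p).beta
            except Exception as exc:
                raise RuntimeError(
                    f"quantile fit failed at replication {l}, p={p}: {exc}"
                ) from exc
    return reps


def average_jittering_fit(dataset: Dataset, p_grid, config: JitterConfig) -> JitterFit:
    """Fit the average-jittering estimator on a grid of quantile orders.

    For each of m independent jitterings, the transformed working variable is
    fitted by single-quantile regression at every grid order; the returned
    ``beta_avg`` is the mean of the m per-replication estimates.
    """
    p_grid = np.asarray(p_grid, dtype=float)
    for p in p_grid:
        check_quantile_level(p)
    rng = np.random.default_rng(config.seed)
    reps = _avg_fit_arrays(dataset, p_grid, config, rng)
    return JitterFit(
        p_grid=p_grid,
        beta_avg=reps.mean(axis=0),
        beta_reps=reps,
        config=config,
        names=list(dataset.names),
    )


def bootstrap_se(dataset: Dataset, p_grid, config: JitterConfig, B: int = 100,
                 m_boot: int | None = None) -> np.ndarray:
    """Bootstrap standard errors of the average-jittering estimates.

    Rows (cases) are resampled with replacement B times; each resample is
    re-jittered with fresh noise and refitted, and the SE is the standard
    deviation of the average-jittering estimate across resamples.  ``m_boot``
    optionally lowers the number of jitter replications inside each resample
    to bound the computational cost.
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    p_grid = np.asarray(p_grid, dtype=float)
    rng = np.random.default_rng(config.seed)
    inner = config if m_boot is None else replace(config, m=m_boot)
    if np.all(dataset.response == dataset.response[0]):
        warnings.warn("constant response in bootstrap; standard errors are 0",
                      stacklevel=2)
    boots = np.empty((B, p_grid.size, dataset.design.shape[1]))
    n = dataset.n
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        dsb = Dataset(design=dataset.design[idx], response=dataset.response[idx],
                      names=list(dataset.names))
        boots[b] = _avg_fit_arrays(dsb, p_grid, inner, rng).mean(axis=0)
    return boots.std(axis=0, ddof=1)
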