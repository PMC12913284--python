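"""Percentile-bootstrap inference and group-level statistics.

All individual-level uncertainty statements use the percentile bootstrap:
trials are resampled within each (condition, d) cell — multinomially, with
the observed cell proportions and the observed per-cell n — the threshold
estimator is re-applied to each resample, and the 2.5th and 97.5th
percentiles of the resulting distribution bound the 95% CI.  Threshold
invariance between two conditions is declared violated only when the
bootstrap CI of the threshold difference excludes zero.  Group-level
comparisons use the paired t test with the within-subject effect size
d_z = mean(differences) / SD(differences).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .nonparametric import SKConfig, sk_threshold
from .parametric import fit_two_threshold
from .preprocess import ConditionCounts, tabulate_counts

__all__ = [
    "BootstrapResult",
    "InvarianceResult",
    "GroupStats",
    "sk_estimator",
    "ttm_estimator",
    "bootstrap_threshold",
    "invariance_test",
    "practice_curve",
    "paired_t_dz",
]

_RETRY_CAP = 5  # redraws allowed when an estimator fails on a resample


@dataclass(frozen=True)
class BootstrapResult:
    """Point estimate with percentile-bootstrap 95% CI.

    Percentiles are computed with ``numpy.percentile``'s default linear
    interpolation between order statistics.
    """

    point: float
    ci_lo: float
    ci_hi: float
    B: int
    seed: int
    n_retries: int = 0

    def covers(self, value: float) -> bool:
        return self.ci_lo <= value <= self.ci_hi

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class InvarianceResult:
    """Bootstrap verdict on the equality of two conditions' thresholds."""

    condition_a: str
    condition_b: str
    estimator: str
    diff: BootstrapResult
    violated: bool

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class GroupStats:
    """Paired t test with d_z effect size on per-subject thresholds."""

    n: int
    mean_a: float
    mean_b: float
    t: float
    df: int
    p: float
    d_z: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def sk_estimator(cfg: SKConfig) -> Callable[[ConditionCounts], float]:
    """Estimator closure: nonparametric Spearman-Karber threshold."""

    def estimate(counts: ConditionCounts) -> float:
        return sk_threshold(counts, cfg).threshold

    estimate.__name__ = "nonparametric"
    return estimate


def ttm_estimator(
    param: str = "c_su",
    *,
    restarts: int = 1,
    seed: int = 0,
    warm: Sequence[float] | None = None,
) -> Callable[[ConditionCounts], float]:
    """Estimator closure: a two-threshold model parameter (c_su or c_o).

    For bootstrap use, ``warm`` (mu, sigma, c_su, c_o, gamma) from the
    full-data fit warm-starts each refit so that one restart per resample
    suffices; pass higher ``restarts`` for cold fits.
    """
    if param not in ("c_su", "c_o", "mu", "sigma", "gamma"):
        raise ValueError(f"unknown parameter {param!r}")

    def estimate(counts: ConditionCounts) -> float:
        fit = fit_two_threshold(
            counts,
            restarts=restarts,
            seed=seed,
            x0=None if warm is None else np.asarray(warm, dtype=float),
        )
        return float(getattr(fit, param))

    estimate.__name__ = f"parametric_{param}"
    return estimate


def _resample(
    counts: ConditionCounts, rng: np.random.Generator
) -> ConditionCounts:
    """Multinomial resample within each d cell, per-cell n held fixed."""
    totals = counts.totals.astype(int)
    p = np.stack([counts.n_xy, counts.n_si, counts.n_yx], axis=1)
    p = p / np.maximum(totals[:, None], 1)
    new = np.empty_like(p)
    for i, (n_i, p_i) in enumerate(zip(totals, p)):
        new[i] = rng.multinomial(n_i, p_i)
    return ConditionCounts(
        condition=counts.condition,
        d_values=counts.d_values,
        n_xy=new[:, 0],
        n_si=new[:, 1],
        n_yx=new[:, 2],
    )


def _bootstrap_draws(
    counts_list: list[ConditionCounts],
    estimator: Callable[[ConditionCounts], float],
    combine: Callable[[list[float]], float],
    B: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    draws = np.empty(B)
    retries = 0
    for b in range(B):
        for attempt in range(_RETRY_CAP + 1):
            try:
                draws[b] = combine([estimator(_resample(c, rng)) for c in counts_list])
                break
            except (ValueError, FloatingPointError):
                retries += 1
                if attempt == _RETRY_CAP:
                    raise
    return draws, retries


def bootstrap_threshold(
    counts: ConditionCounts,
    estimator: Callable[[ConditionCounts], float],
    *,
    B: int = 1000,
    seed: int = 0,
) -> BootstrapResult:
    """Percentile-bootstrap 95% CI for one condition's threshold.

    Deterministic given ``seed``.  If the estimator fails on a resample
    the resample is redrawn (up to a cap); redraws are reported in
    ``n_retries``.
    """
    rng = np.random.default_rng(seed)
    point = estimator(counts)
    draws, retries = _bootstrap_draws([counts], estimator, lambda v: v[0], B, rng)
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return BootstrapResult(
        point=float(point), ci_lo=float(lo), ci_hi=float(hi), B=B, seed=seed,
        n_retries=retries,
    )


def invariance_test(
    counts_a: ConditionCounts,
    counts_b: ConditionCounts,
    estimator: Callable[[ConditionCounts], float],
    *,
    B: int = 1000,
    seed: int = 0,
) -> InvarianceResult:
    """Bootstrap the threshold difference (a minus b) between conditions.

    Both conditions are resampled on every iteration; invariance is
    violated iff the 95% CI of the difference excludes zero.
    """
    rng = np.random.default_rng(seed)
    point = estimator(counts_a) - estimator(counts_b)
    draws, retries = _bootstrap_draws(
        [counts_a, counts_b], estimator, lambda v: v[0] - v[1], B, rng
    )
    lo, hi = np.percentile(draws, [2.5, 97.5])
    diff = BootstrapResult(
        point=float(point), ci_lo=float(lo), ci_hi=float(hi), B=B, seed=seed,
        n_retries=retries,
    )
    return InvarianceResult(
        condition_a=counts_a.condition,
        condition_b=counts_b.condition,
        estimator=getattr(estimator, "__name__", "estimator"),
        diff=diff,
        violated=not diff.covers(0.0),
    )


def practice_curve(
    trials: pd.DataFrame,
    estimator: Callable[[ConditionCounts], float],
    *,
    sessions_per_level: int = 5,
    B: int = 1000,
    seed: int = 0,
    d_grid: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Threshold trajectory across consecutive practice levels.

    Sessions (sorted) are partitioned into consecutive levels of
    ``sessions_per_level``; each level is estimated per condition with a
    bootstrap CI.  Returns a tidy frame (level, sessions, condition,
    threshold, ci_lo, ci_hi).
    """
    sessions = np.sort(trials["session"].unique())
    if sessions.size % sessions_per_level:
        raise ValueError(
            f"{sessions.size} sessions do not divide into levels of "
            f"{sessions_per_level}"
        )
    rows = []
    for level, start in enumerate(range(0, sessions.size, sessions_per_level), 1):
        members = sessions[start : start + sessions_per_level]
        chunk = trials[trials["session"].isin(members)]
        for counts in tabulate_counts(chunk, d_grid=d_grid):
            if np.any(counts.totals == 0):
                empty = counts.d_values[counts.totals == 0].tolist()
                raise ValueError(
                    f"practice level {level}, condition {counts.condition!r}: "
                    f"no trials at d = {empty}"
                )
            boot = bootstrap_threshold(
                counts, estimator, B=B, seed=seed + 1000 * level
            )
            rows.append(
                {
                    "level": level,
                    "sessions": "-".join(str(s) for s in members),
                    "condition": counts.condition,
                    "threshold": boot.point,
                    "ci_lo": boot.ci_lo,
                    "ci_hi": boot.ci_hi,
                }
            )
    return pd.DataFrame(rows)


def paired_t_dz(values_a: Sequence[float], values_b: Sequence[float]) -> GroupStats:
    """Paired two-sided t test with the within-subject effect size d_z.

    d_z = mean(a - b) / SD(a - b), with the n-1 denominator in the SD.
    With zero variance of the differences and a nonzero mean the t
    statistic is reported as signed infinity (p = 0).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    diff = a - b
    n = diff.size
    sd = diff.std(ddof=1)
    mean = diff.mean()
    if sd == 0.0:
        t = 0.0 if mean == 0.0 else np.copysign(np.inf, mean)
        p = 1.0 if mean == 0.0 else 0.0
        d_z = 0.0 if mean == 0.0 else np.copysign(np.inf, mean)
    else:
        t, p = stats.ttest_rel(a, b)
        d_z = mean / sd
    return GroupStats(
        n=n,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        t=float(t),
        df=n - 1,
        p=float(p),
        d_z=float(d_z),
    )
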