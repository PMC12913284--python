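"""Distribution-free central-threshold estimation.

The ternary-response task yields two psychometric functions, F_R(d) =
P(xy|d) and F_L(d) = 1 - P(yx|d).  Under additivity of peripheral
latencies and central threshold, the distance between the means of the two
functions equals twice the mean central threshold — independent of the
latency distribution.  The estimator here is the modified Spearman-Karber
method: each empirical function is monotonized by weighted
pool-adjacent-violators (the binomial maximum-likelihood monotone fit),
anchored at grid points where it is taken to reach 0 and 1 exactly, and
its mean computed as the mean of the discrete distribution of increments.
The central threshold is half the difference of the two means; the
midpoint (point of subjective simultaneity) is their average.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .preprocess import ConditionCounts, empirical_functions

__all__ = [
    "SKConfig",
    "EXP1_SK",
    "EXP2_SK",
    "SKEstimate",
    "pav_monotonize",
    "sk_mean",
    "sk_threshold",
]


@dataclass(frozen=True)
class SKConfig:
    """Anchor placement: d values where the function is fixed to 0 and 1.

    The anchors must bracket the stimulus grid.  Threshold-difference
    conclusions are robust to moderate perturbation of the anchors, which
    is asserted by the test suite rather than assumed.
    """

    anchor_lo: float = -225.0
    anchor_hi: float = 225.0

    def __post_init__(self) -> None:
        if not self.anchor_lo < self.anchor_hi:
            raise ValueError("anchor_lo must be below anchor_hi")

    def validate_grid(self, d_values: Sequence[float]) -> None:
        d = np.asarray(d_values, dtype=float)
        if self.anchor_lo >= d.min() or self.anchor_hi <= d.max():
            raise ValueError(
                f"anchors ({self.anchor_lo}, {self.anchor_hi}) must strictly "
                f"bracket the d grid [{d.min()}, {d.max()}]"
            )


#: Anchors for the ±200 ms modality grid.
EXP1_SK = SKConfig(-225.0, 225.0)
#: Anchors for the ±350 ms intensity grid.
EXP2_SK = SKConfig(-400.0, 400.0)


@dataclass(frozen=True)
class SKEstimate:
    """Spearman-Karber means of F_R and F_L and the derived quantities.

    ``threshold = (mean_R - mean_L) / 2`` (the central threshold, ms) and
    ``midpoint = (mean_R + mean_L) / 2`` (the point of subjective
    simultaneity, ms).
    """

    condition: str
    mean_R: float
    mean_L: float
    threshold: float
    midpoint: float
    anchors: tuple[float, float]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def pav_monotonize(p: Sequence[float], w: Sequence[float]) -> np.ndarray:
    """Weighted pool-adjacent-violators: nondecreasing fit to proportions.

    Returns the minimizer of sum_i w_i (q_i - p_i)^2 subject to q being
    nondecreasing — equivalently the binomial-ML monotone fit when ``w``
    are trial counts.  Pooled blocks carry their weighted mean, so the
    output stays in [0, 1] and the weighted mean is preserved within each
    block.  Idempotent.
    """
    p = np.asarray(p, dtype=float)
    w = np.asarray(w, dtype=float)
    if p.shape != w.shape or p.ndim != 1:
        raise ValueError("p and w must be 1-d arrays of equal length")
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("proportions must lie in [0, 1]")

    # Stack of (value, weight, run-length) blocks; merge while decreasing.
    values: list[float] = []
    weights: list[float] = []
    sizes: list[int] = []
    for pi, wi in zip(p, w):
        values.append(float(pi))
        weights.append(float(wi))
        sizes.append(1)
        while len(values) > 1 and values[-2] >= values[-1]:
            v2, w2, s2 = values.pop(), weights.pop(), sizes.pop()
            v1, w1, s1 = values.pop(), weights.pop(), sizes.pop()
            if v1 == v2:  # equal blocks merge without changing the fit
                values.append(v1)
            else:
                values.append((v1 * w1 + v2 * w2) / (w1 + w2))
            weights.append(w1 + w2)
            sizes.append(s1 + s2)
    return np.repeat(values, sizes)


def sk_mean(
    d_values: Sequence[float],
    p_monotone: Sequence[float],
    cfg: SKConfig,
    *,
    atol: float = 1e-9,
) -> float:
    """Spearman-Karber mean of a monotone psychometric function.

    The grid is augmented with the anchors, where the function is pinned
    to 0 and 1 exactly, and the mean of the induced discrete increment
    distribution is returned:

        sum_i (p_{i+1} - p_i) * (d_i + d_{i+1}) / 2.

    Raises ``ValueError`` on a non-monotone input — monotonize first.
    """
    d = np.asarray(d_values, dtype=float)
    p = np.asarray(p_monotone, dtype=float)
    if d.shape != p.shape or d.ndim != 1:
        raise ValueError("d_values and p_monotone must be 1-d of equal length")
    if np.any(np.diff(p) < -atol):
        raise ValueError("p_monotone is not nondecreasing; apply pav_monotonize")
    cfg.validate_grid(d)
    d_aug = np.concatenate(([cfg.anchor_lo], d, [cfg.anchor_hi]))
    p_aug = np.concatenate(([0.0], np.clip(p, 0.0, 1.0), [1.0]))
    inc = np.diff(p_aug)
    mid = 0.5 * (d_aug[:-1] + d_aug[1:])
    return float(np.sum(inc * mid))


def sk_threshold(counts: ConditionCounts, cfg: SKConfig) -> SKEstimate:
    """Nonparametric central threshold for one condition.

    F_R and F_L are monotonized separately (weights = per-d trial totals)
    and their Spearman-Karber means combined into the half-difference
    threshold and the midpoint.  If monotonization leaves F_R above F_L
    somewhere, the means are still computed independently and a diagnostic
    warning is emitted.
    """
    funcs = empirical_functions(counts)
    w = counts.totals
    F_R = pav_monotonize(funcs.F_R, w)
    F_L = pav_monotonize(funcs.F_L, w)
    if np.any(F_R > F_L + 1e-12):
        warnings.warn(
            f"condition {counts.condition!r}: monotonized F_R exceeds F_L at "
            "some d; SK means computed independently",
            RuntimeWarning,
            stacklevel=2,
        )
    mean_R = sk_mean(funcs.d_values, F_R, cfg)
    mean_L = sk_mean(funcs.d_values, F_L, cfg)
    return SKEstimate(
        condition=counts.condition,
        mean_R=mean_R,
        mean_L=mean_L,
        threshold=0.5 * (mean_R - mean_L),
        midpoint=0.5 * (mean_R + mean_L),
        anchors=(cfg.anchor_lo, cfg.anchor_hi),
    )
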