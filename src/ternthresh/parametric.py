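"""Maximum-likelihood fitting of the two-threshold observer model.

The model: the peripheral latency difference is Gaussian, dL ~ N(mu,
sigma^2), and the central arrival-time difference dA = dL + d is compared
against two thresholds, the successiveness threshold c_su and the order
threshold c_o >= c_su.  Simultaneity is reported when |dA| < c_su; order
is perceived (and reported veridically) when |dA| >= c_o; in between,
successiveness is detected but order must be guessed — *xy* with
probability gamma.  The trinomial cell probabilities at stimulus-onset
difference d, writing z(c) = Phi((c - mu - d) / sigma), are

    p_si = z(c_su) - z(-c_su)
    p_xy = [1 - z(c_o)] + gamma * ([z(c_o) - z(c_su)] + [z(-c_su) - z(-c_o)])
    p_yx = 1 - p_xy - p_si.

Fitting maximizes the multinomial log-likelihood over (mu, sigma, c_su,
delta = c_o - c_su, gamma) with multi-start optimization; the ordering
c_o >= c_su is enforced by the delta >= 0 parameterization.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit, ndtr

from .nonparametric import SKConfig, sk_threshold
from .preprocess import ConditionCounts

__all__ = ["TwoThresholdFit", "ttm_probabilities", "fit_two_threshold"]

_P_FLOOR = 1e-9  # probability floor inside the log-likelihood
_FTOL = 1e-6  # relative log-likelihood convergence tolerance


@dataclass(frozen=True)
class TwoThresholdFit:
    """Fitted two-threshold observer parameters for one condition."""

    condition: str
    mu: float
    sigma: float
    c_su: float
    c_o: float
    gamma: float
    loglik: float
    converged: bool
    n_restarts_used: int

    def __post_init__(self) -> None:
        if self.c_o < self.c_su - 1e-9 or self.c_su < -1e-9 or self.sigma <= 0:
            raise ValueError("invalid fitted parameters: need c_o >= c_su >= 0, sigma > 0")

    def predict(self, d) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Predicted (p_xy, p_si, p_yx) on a d grid."""
        return ttm_probabilities(
            self.mu, self.sigma, self.c_su, self.c_o, self.gamma, d
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _validate_params(mu, sigma, c_su, c_o, gamma) -> None:
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    if c_su < 0:
        raise ValueError(f"c_su must be >= 0, got {c_su}")
    if c_o < c_su:
        raise ValueError(f"c_o must be >= c_su, got c_o={c_o} < c_su={c_su}")
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must be in [0, 1], got {gamma}")


def ttm_probabilities(
    mu: float, sigma: float, c_su: float, c_o: float, gamma: float, d
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Trinomial response probabilities (p_xy, p_si, p_yx) at d (ms).

    Vectorized over d; the three outputs are nonnegative and sum to one.
    """
    _validate_params(mu, sigma, c_su, c_o, gamma)
    d = np.asarray(d, dtype=float)
    z = lambda c: ndtr((c - mu - d) / sigma)
    z_su, z_nsu = z(c_su), z(-c_su)
    z_o, z_no = z(c_o), z(-c_o)
    p_si = z_su - z_nsu
    p_guess = (z_o - z_su) + (z_nsu - z_no)
    p_xy = (1.0 - z_o) + gamma * p_guess
    p_yx = 1.0 - p_xy - p_si
    # guard tiny negative round-off
    p_si = np.clip(p_si, 0.0, 1.0)
    p_xy = np.clip(p_xy, 0.0, 1.0)
    p_yx = np.clip(p_yx, 0.0, 1.0)
    return p_xy, p_si, p_yx


def _negloglik(theta: np.ndarray, counts: ConditionCounts) -> float:
    mu, log_sigma, c_su, delta, lgamma = theta
    sigma = float(np.exp(log_sigma))
    gamma = float(expit(lgamma))
    p_xy, p_si, p_yx = ttm_probabilities(
        mu, sigma, max(c_su, 0.0), max(c_su, 0.0) + max(delta, 0.0), gamma, counts.d_values
    )
    ll = (
        counts.n_xy * np.log(np.maximum(p_xy, _P_FLOOR))
        + counts.n_si * np.log(np.maximum(p_si, _P_FLOOR))
        + counts.n_yx * np.log(np.maximum(p_yx, _P_FLOOR))
    )
    return -float(ll.sum())


def _quantile_spread(d: np.ndarray, p: np.ndarray, lo=0.25, hi=0.75) -> float:
    """Crude sigma estimate from the d span between two quantiles of a
    nondecreasing proportion profile (interquartile range / 1.349)."""
    p = np.maximum.accumulate(p)
    if p[-1] <= p[0]:
        return float(d[-1] - d[0]) / 4.0
    d_lo = float(np.interp(lo, p, d, left=d[0], right=d[-1]))
    d_hi = float(np.interp(hi, p, d, left=d[0], right=d[-1]))
    return max((d_hi - d_lo) / 1.349, 1.0)


def _starts(counts: ConditionCounts, restarts: int, rng: np.random.Generator) -> list[np.ndarray]:
    d = counts.d_values
    span = float(d[-1] - d[0])
    cfg = SKConfig(d[0] - 0.25 * span, d[-1] + 0.25 * span)
    try:
        sk = sk_threshold(counts, cfg)
        mu0, c0 = -sk.midpoint, max(sk.threshold, 2.0)
    except ValueError:
        mu0, c0 = 0.0, span / 8.0
    totals = counts.totals
    sigma0 = _quantile_spread(d, counts.n_xy / np.maximum(totals, 1.0))
    base = []
    for delta0 in (1.0, 0.25 * c0 + 5.0):
        base.append(
            np.array([mu0, np.log(sigma0), c0, delta0, logit(0.5)])
        )
    starts = list(base)
    while len(starts) < restarts:
        starts.append(
            np.array(
                [
                    mu0 + rng.normal(0.0, 0.15 * span / 2),
                    np.log(sigma0) + rng.normal(0.0, 0.5),
                    max(c0 * np.exp(rng.normal(0.0, 0.5)), 0.5),
                    rng.exponential(0.3 * c0 + 5.0),
                    logit(rng.uniform(0.2, 0.8)),
                ]
            )
        )
    return starts[:restarts]


def fit_two_threshold(
    counts: ConditionCounts,
    *,
    restarts: int = 20,
    seed: int = 0,
    single_threshold: bool = False,
    x0: np.ndarray | None = None,
) -> TwoThresholdFit:
    """Fit the two-threshold model to ternary counts by multi-start ML.

    Parameters
    ----------
    counts
        Per-d response counts; at least 5 distinct d values with trials.
    restarts
        Number of optimization starts (data-driven initials plus
        Latin-style jitter); the best optimum is returned.
    seed
        Seeds the jittered starts; the fit is deterministic given it.
    single_threshold
        Fix delta = c_o - c_su at 0 (the classical one-threshold rule),
        giving the nested submodel for likelihood-ratio comparisons.
    x0
        Optional warm start ``(mu, sigma, c_su, c_o, gamma)`` prepended to
        the start list — used when refitting bootstrap resamples.

    Returns the best :class:`TwoThresholdFit`; ``converged`` is False when
    no start converged (the best point found is still returned).
    """
    if np.count_nonzero(counts.totals > 0) < 5:
        raise ValueError("need at least 5 d values with nonzero trial totals")
    rng = np.random.default_rng(seed)
    starts = _starts(counts, restarts, rng)
    if x0 is not None:
        mu, sigma, c_su, c_o, gamma = x0
        gamma = min(max(gamma, 1e-4), 1 - 1e-4)
        starts = [
            np.array([mu, np.log(sigma), c_su, max(c_o - c_su, 0.0), logit(gamma)])
        ] + starts
        starts = starts[:max(restarts, 1)]
    bounds = [
        (None, None),
        (np.log(1e-2), np.log(1e4)),
        (0.0, None),
        (0.0, 0.0) if single_threshold else (0.0, None),
        (-15.0, 15.0),
    ]
    best = None
    best_res = None
    n_used = 0
    for theta0 in starts:
        t0 = theta0.copy()
        if single_threshold:
            t0[3] = 0.0
        res = minimize(
            _negloglik,
            t0,
            args=(counts,),
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": _FTOL, "maxiter": 500},
        )
        n_used += 1
        if best is None or res.fun < best:
            best, best_res = res.fun, res
    mu, log_sigma, c_su, delta, lgamma = best_res.x
    return TwoThresholdFit(
        condition=counts.condition,
        mu=float(mu),
        sigma=float(np.exp(log_sigma)),
        c_su=float(max(c_su, 0.0)),
        c_o=float(max(c_su, 0.0) + max(delta, 0.0)),
        gamma=float(expit(lgamma)),
        loglik=-float(best_res.fun),
        converged=bool(best_res.success),
        n_restarts_used=n_used,
    )
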