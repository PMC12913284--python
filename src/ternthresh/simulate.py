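"""Synthetic observers for the ternary-response timing task.

An observer judges two stimuli *x* and *y* separated by a stimulus-onset
difference ``d = t_y - t_x`` (ms) and reports one of three responses:
``xy`` (*x* first), ``si`` (simultaneous), or ``yx`` (*y* first).  The
generating model is an independent-channels observer with two central
thresholds: the peripheral latency difference ``dL ~ Normal(mu, sigma^2)``
adds to ``d`` to give the central arrival-time difference ``dA = dL + d``,
which is compared against the successiveness threshold ``c_su`` and the
order threshold ``c_o >= c_su``:

* ``|dA| < c_su``      -> *si* (successiveness not detected)
* ``dA >= c_o``        -> *xy*;  ``dA <= -c_o`` -> *yx* (order detected)
* ``c_su <= |dA| < c_o`` -> successiveness detected but order guessed:
  *xy* with probability ``gamma``, *yx* otherwise.

Setting ``c_su == c_o == C`` recovers the classical single-threshold rule
(*xy* iff ``dA >= C``, *si* iff ``|dA| < C``).

Trials are returned as a tidy :class:`pandas.DataFrame` (one row per trial,
columns :data:`TRIAL_COLUMNS`) which is also the on-disk CSV interchange
format used by the rest of the package.  Response times and the
contamination channels (premature/delayed presses, double-click lapses,
corrected finger errors) exist only so that the cleaning rules downstream
have something realistic to act on; RT distributions are otherwise not
modelled.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TRIAL_COLUMNS",
    "RESPONSES",
    "DesignSpec",
    "ObserverSpec",
    "exp1_design",
    "exp2_design",
    "simulate_observer",
    "simulate_experiment",
    "write_trials",
    "read_trials",
]

#: Column order of the tidy trial table / CSV interchange format.
TRIAL_COLUMNS = (
    "subject",
    "session",
    "block",
    "condition",
    "d",
    "response",
    "rt",
    "corrected",
    "lapse",
)

#: Valid ternary responses.
RESPONSES = ("xy", "si", "yx")

# RT generation: lognormal body well inside the (150, 5000) ms window, so
# that only explicit contamination produces out-of-range RTs.
_RT_LOG_MEDIAN = np.log(600.0)
_RT_LOG_SIGMA = 0.35
_RT_CLIP = (160.0, 4900.0)


@dataclass(frozen=True)
class DesignSpec:
    """Layout of a ternary-response session grid.

    Parameters
    ----------
    d_values
        Strictly increasing stimulus-onset differences (ms).
    trials_per_d
        Trials per d value per condition over the whole experiment.
    conditions
        Condition labels.
    sessions
        Number of sessions.
    blocks_per_session
        Number of blocks per session.
    condition_layout
        ``"alternating"`` — each block holds a single condition and blocks
        alternate between conditions (two-light vs light+click mini-blocks);
        ``"interleaved"`` — every block mixes all conditions trial-by-trial
        (the intensity design).
    """

    d_values: tuple[float, ...]
    trials_per_d: int
    conditions: tuple[str, ...]
    sessions: int
    blocks_per_session: int
    condition_layout: str = "alternating"

    def __post_init__(self) -> None:
        d = np.asarray(self.d_values, dtype=float)
        if d.ndim != 1 or d.size < 2:
            raise ValueError("d_values must be a 1-d grid with at least 2 points")
        if not np.all(np.diff(d) > 0):
            raise ValueError("d_values must be strictly increasing")
        if self.trials_per_d <= 0:
            raise ValueError(f"trials_per_d must be positive, got {self.trials_per_d}")
        if self.sessions <= 0 or self.blocks_per_session <= 0:
            raise ValueError("sessions and blocks_per_session must be positive")
        if not self.conditions:
            raise ValueError("at least one condition label is required")
        if self.condition_layout not in ("alternating", "interleaved"):
            raise ValueError(
                f"condition_layout must be 'alternating' or 'interleaved', "
                f"got {self.condition_layout!r}"
            )
        n_blocks = self.sessions * self.blocks_per_session
        if self.condition_layout == "alternating":
            if n_blocks % len(self.conditions):
                raise ValueError(
                    "total block count must be divisible by the number of "
                    "conditions under the alternating layout"
                )
            blocks_per_cond = n_blocks // len(self.conditions)
        else:
            blocks_per_cond = n_blocks
        if self.trials_per_d % blocks_per_cond:
            raise ValueError(
                f"trials_per_d={self.trials_per_d} not divisible into "
                f"{blocks_per_cond} blocks per condition"
            )

    @property
    def n_trials(self) -> int:
        """Total trial count across all conditions."""
        return self.trials_per_d * len(self.d_values) * len(self.conditions)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: Mapping) -> "DesignSpec":
        d = dict(d)
        d["d_values"] = tuple(float(v) for v in d["d_values"])
        d["conditions"] = tuple(d["conditions"])
        return cls(**d)


@dataclass(frozen=True)
class ObserverSpec:
    """Parameters of the two-threshold observer plus contamination rates.

    ``mu``/``sigma`` are the mean and SD of the peripheral latency
    difference dL (ms); ``c_su``/``c_o`` the successiveness and order
    thresholds (ms); ``gamma`` the probability of guessing *xy* when
    successiveness is detected but order is not.  Contamination rates are
    per-trial probabilities of a premature press (RT < 150 ms), a delayed
    press (RT > 5000 ms), a double-click lapse, and a corrected finger
    error (the final response remains valid).
    """

    mu: float = 0.0
    sigma: float = 60.0
    c_su: float = 50.0
    c_o: float = 50.0
    gamma: float = 0.5
    premature: float = 0.002
    delayed: float = 0.001
    lapse: float = 0.002
    finger_error: float = 0.010

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.c_su < 0:
            raise ValueError(f"c_su must be >= 0, got {self.c_su}")
        if self.c_o < self.c_su:
            raise ValueError(
                f"c_o must be >= c_su, got c_o={self.c_o} < c_su={self.c_su}"
            )
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")
        for name in ("premature", "delayed", "lapse", "finger_error"):
            rate = getattr(self, name)
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"{name} rate must be in [0, 1), got {rate}")
        if self.premature + self.delayed + self.lapse + self.finger_error >= 1.0:
            raise ValueError("contamination rates must sum to < 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ObserverSpec":
        return cls(**dict(d))


def exp1_design() -> DesignSpec:
    """Modality design: 25 d values −200..200 ms in steps of 16.6̄ ms,
    400 trials per d per condition, intramodal/intermodal mini-blocks
    alternating within 20 sessions of 20 blocks (50 trials each)."""
    return DesignSpec(
        d_values=tuple(np.linspace(-200.0, 200.0, 25)),
        trials_per_d=400,
        conditions=("intermodal", "intramodal"),
        sessions=20,
        blocks_per_session=20,
        condition_layout="alternating",
    )


def exp2_design() -> DesignSpec:
    """Intensity design: 15 d values −350..350 ms in steps of 50 ms,
    180 trials per d per condition, strong/weak interleaved trial-by-trial
    within 18-block sessions (60 trials each), 5 sessions."""
    return DesignSpec(
        d_values=tuple(np.linspace(-350.0, 350.0, 15)),
        trials_per_d=180,
        conditions=("strong", "weak"),
        sessions=5,
        blocks_per_session=18,
        condition_layout="interleaved",
    )


def _decide(dA: np.ndarray, obs: ObserverSpec, rng: np.random.Generator) -> np.ndarray:
    """Apply the two-threshold decision rule to arrival-time differences."""
    resp = np.empty(dA.shape, dtype=object)
    si = np.abs(dA) < obs.c_su
    det_xy = dA >= obs.c_o
    det_yx = dA <= -obs.c_o
    guess = ~(si | det_xy | det_yx)
    resp[si] = "si"
    resp[det_xy] = "xy"
    resp[det_yx] = "yx"
    if guess.any():
        g = rng.random(int(guess.sum())) < obs.gamma
        resp[guess] = np.where(g, "xy", "yx")
    return resp


def _contaminate(frame: pd.DataFrame, obs: ObserverSpec, rng: np.random.Generator) -> None:
    """Overwrite RTs / set flags in place, one exclusive channel per trial."""
    n = len(frame)
    rt = np.clip(
        rng.lognormal(_RT_LOG_MEDIAN, _RT_LOG_SIGMA, size=n), *_RT_CLIP
    )
    u = rng.random(n)
    lo = 0.0
    premature = (u >= lo) & (u < (lo := lo + obs.premature))
    delayed = (u >= lo) & (u < (lo := lo + obs.delayed))
    lapse = (u >= lo) & (u < (lo := lo + obs.lapse))
    corrected = (u >= lo) & (u < lo + obs.finger_error)
    rt[premature] = rng.uniform(0.0, 149.0, int(premature.sum()))
    rt[delayed] = rng.uniform(5001.0, 8000.0, int(delayed.sum()))
    frame["rt"] = rt
    frame["corrected"] = corrected
    frame["lapse"] = lapse


def _block_conditions(design: DesignSpec) -> list[tuple[int, int, tuple[str, ...]]]:
    """Yield (session, block, conditions-in-block) in presentation order."""
    out = []
    flat = 0
    for session in range(1, design.sessions + 1):
        for block in range(1, design.blocks_per_session + 1):
            if design.condition_layout == "alternating":
                conds = (design.conditions[flat % len(design.conditions)],)
            else:
                conds = design.conditions
            out.append((session, block, conds))
            flat += 1
    return out


def simulate_observer(
    design: DesignSpec,
    observer: ObserverSpec | Mapping[str, ObserverSpec],
    *,
    seed: int,
    subject: str = "S1",
) -> pd.DataFrame:
    """Simulate one subject's full run of ``design``.

    ``observer`` is either a single :class:`ObserverSpec` shared by all
    conditions or a mapping ``{condition: ObserverSpec}``.  Deterministic
    given ``seed``.  Returns a tidy trial table with columns
    :data:`TRIAL_COLUMNS`.
    """
    if isinstance(observer, ObserverSpec):
        observers = {c: observer for c in design.conditions}
    else:
        observers = dict(observer)
        missing = set(design.conditions) - set(observers)
        if missing:
            raise ValueError(f"no ObserverSpec for conditions: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    layout = _block_conditions(design)
    blocks_per_cond = sum(len(conds) == 1 for _, _, conds in layout) or len(layout)
    if design.condition_layout == "alternating":
        per_block = design.trials_per_d // (blocks_per_cond // len(design.conditions))
    else:
        per_block = design.trials_per_d // len(layout)

    frames = []
    for session, block, conds in layout:
        d_col = np.repeat(
            np.asarray(design.d_values, dtype=float), per_block * len(conds)
        )
        cond_col = np.tile(
            np.repeat(np.asarray(conds, dtype=object), per_block),
            len(design.d_values),
        )
        order = rng.permutation(d_col.size)
        frames.append(
            pd.DataFrame(
                {
                    "subject": subject,
                    "session": session,
                    "block": block,
                    "condition": cond_col[order],
                    "d": d_col[order],
                }
            )
        )
    trials = pd.concat(frames, ignore_index=True)

    # Responses per condition from that condition's observer.
    trials["response"] = ""
    for cond, obs in observers.items():
        mask = trials["condition"] == cond
        d = trials.loc[mask, "d"].to_numpy()
        dA = rng.normal(obs.mu, obs.sigma, size=d.size) + d
        trials.loc[mask, "response"] = _decide(dA, obs, rng)

    trials["rt"] = 0.0
    trials["corrected"] = False
    trials["lapse"] = False
    for cond, obs in observers.items():
        mask = (trials["condition"] == cond).to_numpy()
        sub = trials.loc[mask, ["rt", "corrected", "lapse"]].copy()
        _contaminate(sub, obs, rng)
        trials.loc[mask, ["rt", "corrected", "lapse"]] = sub

    trials["corrected"] = trials["corrected"].astype(bool)
    trials["lapse"] = trials["lapse"].astype(bool)
    return trials[list(TRIAL_COLUMNS)]


def simulate_experiment(
    design: DesignSpec,
    observers: Mapping[str, ObserverSpec | Mapping[str, ObserverSpec]],
    *,
    seed: int,
) -> pd.DataFrame:
    """Simulate several subjects; ``observers`` maps subject label to the
    per-subject observer (shared or per-condition).  Subject streams use
    independent seeds spawned from ``seed``."""
    seeds = np.random.SeedSequence(seed).spawn(len(observers))
    frames = [
        simulate_observer(
            design, obs, seed=int(ss.generate_state(1)[0] % (2**31)), subject=label
        )
        for (label, obs), ss in zip(observers.items(), seeds)
    ]
    return pd.concat(frames, ignore_index=True)


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write the tidy trial CSV (fixed header, one row per trial)."""
    trials.loc[:, list(TRIAL_COLUMNS)].to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read a tidy trial CSV, validating the schema.

    Raises ``ValueError`` naming the offending rows for unknown responses,
    negative RTs, or missing columns.
    """
    trials = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(trials.columns)
    if missing:
        raise ValueError(f"trial file missing columns: {sorted(missing)}")
    if trials.empty:
        raise ValueError("trial file contains no trials")
    bad = ~trials["response"].isin(RESPONSES)
    if bad.any():
        rows = trials.index[bad].tolist()[:10]
        raise ValueError(f"invalid response values at rows {rows}")
    neg = trials["rt"] < 0
    if neg.any():
        rows = trials.index[neg].tolist()[:10]
        raise ValueError(f"negative rt at rows {rows}")
    trials["corrected"] = trials["corrected"].astype(bool)
    trials["lapse"] = trials["lapse"].astype(bool)
    return trials[list(TRIAL_COLUMNS)]
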