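"""Trial cleaning and tabulation into per-condition response counts.

Cleaning applies the standard exclusion rules of the ternary-response
paradigm: practice trials at the start of the first session, premature
responses (RT strictly below 150 ms), delayed responses (RT strictly above
5000 ms) and double-click attentional lapses are removed; trials on which
the subject corrected a finger error keep their final, valid response.
Cleaned trials are tabulated into per-(condition, d) counts of the three
responses, from which the two empirical psychometric functions follow:
``F_R(d) = P(xy|d)`` and ``F_L(d) = P(xy|d) + P(si|d) = 1 - P(yx|d)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PracticeRule",
    "EXP1_PRACTICE",
    "EXP2_PRACTICE",
    "CleaningReport",
    "ConditionCounts",
    "PsychometricFunctions",
    "clean_trials",
    "tabulate_counts",
    "empirical_functions",
    "counts_to_frame",
    "counts_from_frame",
]


@dataclass(frozen=True)
class PracticeRule:
    """Practice trials = the first ``n_blocks`` blocks of session ``session``."""

    session: int = 1
    n_blocks: int = 0


#: Modality design: first two blocks of session 1 (100 trials) are practice.
EXP1_PRACTICE = PracticeRule(session=1, n_blocks=2)
#: Intensity design: first block of session 1 is practice.
EXP2_PRACTICE = PracticeRule(session=1, n_blocks=1)


@dataclass
class CleaningReport:
    """Bookkeeping of the exclusion cascade.

    ``n_retained = n_input - n_practice - n_excluded_blocks - n_premature
    - n_delayed - n_lapse``; ``n_corrected`` counts retained trials whose
    response was corrected after a finger error.
    """

    n_input: int = 0
    n_practice: int = 0
    n_excluded_blocks: int = 0
    n_premature: int = 0
    n_delayed: int = 0
    n_lapse: int = 0
    n_corrected: int = 0
    n_retained: int = 0
    per_subject: dict = field(default_factory=dict)

    def proportions(self) -> dict[str, float]:
        base = max(self.n_input - self.n_practice - self.n_excluded_blocks, 1)
        return {
            "premature": self.n_premature / base,
            "delayed": self.n_delayed / base,
            "lapse": self.n_lapse / base,
            "corrected": self.n_corrected / base,
        }

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["proportions"] = self.proportions()
        return d


@dataclass(frozen=True)
class ConditionCounts:
    """Response counts per d for one condition — the data behind F_R, F_L."""

    condition: str
    d_values: np.ndarray
    n_xy: np.ndarray
    n_si: np.ndarray
    n_yx: np.ndarray

    def __post_init__(self) -> None:
        for name in ("d_values", "n_xy", "n_si", "n_yx"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=float)
            )
        if not (
            self.d_values.shape
            == self.n_xy.shape
            == self.n_si.shape
            == self.n_yx.shape
        ):
            raise ValueError("count vectors must align with d_values")
        if np.any(np.diff(self.d_values) <= 0):
            raise ValueError("d_values must be strictly increasing")
        if min(self.n_xy.min(), self.n_si.min(), self.n_yx.min()) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def totals(self) -> np.ndarray:
        return self.n_xy + self.n_si + self.n_yx

    @property
    def n_trials(self) -> int:
        return int(self.totals.sum())


@dataclass(frozen=True)
class PsychometricFunctions:
    """Empirical proportions ``F_R = P(xy|d)`` and ``F_L = 1 - P(yx|d)``."""

    d_values: np.ndarray
    F_R: np.ndarray
    F_L: np.ndarray


def _practice_mask(trials: pd.DataFrame, rule: PracticeRule | None) -> np.ndarray:
    if rule is None or rule.n_blocks == 0:
        return np.zeros(len(trials), dtype=bool)
    return (
        (trials["session"] == rule.session) & (trials["block"] <= rule.n_blocks)
    ).to_numpy()


def clean_trials(
    trials: pd.DataFrame,
    *,
    rt_min: float = 150.0,
    rt_max: float = 5000.0,
    practice: PracticeRule | None = None,
    excluded_blocks: Iterable[tuple[int, int]] = (),
) -> tuple[pd.DataFrame, CleaningReport]:
    """Apply the exclusion cascade; return retained trials and a report.

    Exclusion boundaries are strict: an RT of exactly ``rt_min`` or
    ``rt_max`` is retained.  ``excluded_blocks`` lists (session, block)
    pairs dropped wholesale (e.g. blocks lost to technical issues).
    Corrected (finger-error) trials are retained — their final response is
    valid.  Cleaning is idempotent.

    Raises ``ValueError`` if no trials survive.
    """
    report = CleaningReport(n_input=len(trials))
    practice_m = _practice_mask(trials, practice)
    excl_m = np.zeros(len(trials), dtype=bool)
    for session, block in excluded_blocks:
        excl_m |= (
            (trials["session"] == session) & (trials["block"] == block)
        ).to_numpy()
    excl_m &= ~practice_m
    report.n_practice = int(practice_m.sum())
    report.n_excluded_blocks = int(excl_m.sum())

    body = trials.loc[~(practice_m | excl_m)]
    premature = (body["rt"] < rt_min).to_numpy()
    delayed = (body["rt"] > rt_max).to_numpy() & ~premature
    lapse = body["lapse"].to_numpy(dtype=bool) & ~premature & ~delayed
    report.n_premature = int(premature.sum())
    report.n_delayed = int(delayed.sum())
    report.n_lapse = int(lapse.sum())

    retained = body.loc[~(premature | delayed | lapse)]
    report.n_corrected = int(retained["corrected"].sum())
    report.n_retained = len(retained)
    if retained.empty:
        raise ValueError("no trials retained after cleaning")

    for subject, grp in trials.groupby("subject"):
        sub_ret = retained.loc[retained["subject"] == subject]
        base = max(len(grp) - int(_practice_mask(grp, practice).sum()), 1)
        report.per_subject[str(subject)] = {
            "premature": float((grp["rt"] < rt_min).sum() / base),
            "delayed": float((grp["rt"] > rt_max).sum() / base),
            "lapse": float(grp["lapse"].sum() / base),
            "corrected": float(sub_ret["corrected"].sum() / base),
        }
    return retained.reset_index(drop=True), report


def tabulate_counts(
    trials: pd.DataFrame,
    *,
    d_grid: Sequence[float] | None = None,
    atol: float = 1e-6,
) -> list[ConditionCounts]:
    """Partition cleaned trials into per-(condition, d) response counts.

    If ``d_grid`` is given, every trial's d must match a grid value within
    ``atol`` (d values are snapped to the grid); otherwise the grid is the
    set of observed d values.  Conservation: total counts equal the number
    of input trials.
    """
    d = trials["d"].to_numpy(dtype=float)
    if d_grid is not None:
        grid = np.asarray(sorted(d_grid), dtype=float)
        idx = np.abs(d[:, None] - grid[None, :]).argmin(axis=1)
        off = np.abs(d - grid[idx]) > atol
        if off.any():
            bad = sorted(set(np.round(d[off], 3)))[:10]
            raise ValueError(f"d values outside declared grid: {bad}")
        d = grid[idx]
    out = []
    work = trials.assign(d=d)
    for condition, grp in work.groupby("condition", sort=True):
        grid_c = np.asarray(
            sorted(grp["d"].unique()) if d_grid is None else sorted(d_grid),
            dtype=float,
        )
        tab = (
            grp.groupby(["d", "response"]).size().unstack(fill_value=0)
            .reindex(index=grid_c, columns=["xy", "si", "yx"], fill_value=0)
        )
        out.append(
            ConditionCounts(
                condition=str(condition),
                d_values=grid_c,
                n_xy=tab["xy"].to_numpy(),
                n_si=tab["si"].to_numpy(),
                n_yx=tab["yx"].to_numpy(),
            )
        )
    return out


def empirical_functions(counts: ConditionCounts) -> PsychometricFunctions:
    """Empirical F_R and F_L from counts; every d cell must have trials."""
    totals = counts.totals
    if np.any(totals <= 0):
        empty = counts.d_values[totals <= 0].tolist()
        raise ValueError(
            f"condition {counts.condition!r}: no trials at d = {empty}"
        )
    F_R = counts.n_xy / totals
    F_L = (counts.n_xy + counts.n_si) / totals
    return PsychometricFunctions(d_values=counts.d_values.copy(), F_R=F_R, F_L=F_L)


def counts_to_frame(counts: Iterable[ConditionCounts]) -> pd.DataFrame:
    """Long-format counts table (condition, d, n_xy, n_si, n_yx)."""
    rows = []
    for c in counts:
        rows.append(
            pd.DataFrame(
                {
                    "condition": c.condition,
                    "d": c.d_values,
                    "n_xy": c.n_xy.astype(int),
                    "n_si": c.n_si.astype(int),
                    "n_yx": c.n_yx.astype(int),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def counts_from_frame(frame: pd.DataFrame) -> list[ConditionCounts]:
    """Inverse of :func:`counts_to_frame`."""
    out = []
    for condition, grp in frame.groupby("condition", sort=True):
        grp = grp.sort_values("d")
        out.append(
            ConditionCounts(
                condition=str(condition),
                d_values=grp["d"].to_numpy(dtype=float),
                n_xy=grp["n_xy"].to_numpy(dtype=float),
                n_si=grp["n_si"].to_numpy(dtype=float),
                n_yx=grp["n_yx"].to_numpy(dtype=float),
            )
        )
    return out
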