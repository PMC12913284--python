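"""Packaged per-subject threshold tables from the two published experiments.

The tables hold the published point estimates (ms, rounded to the nearest
millisecond) and bootstrap 95% CI limits for every subject, estimator
(nonparametric Spearman-Karber, parametric c_su, parametric c_o) and
condition, including the within-subject condition difference.  They are
used for group-level statistics and for choosing realistic generating
parameters in simulations; the underlying raw trial data are not shipped.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_fixture_tables", "table_values"]

_EXPERIMENTS = {"exp1": "table1.csv", "exp2": "table2.csv"}


def load_fixture_tables() -> dict[str, pd.DataFrame]:
    """Return ``{"exp1": ..., "exp2": ...}`` threshold tables.

    Columns: subject, estimator (nonparametric | parametric_c_su |
    parametric_c_o), condition (exp1: intermodal/intramodal/difference;
    exp2: weak/strong/difference), value, ci_lo, ci_hi (all ms).
    """
    out = {}
    for key, fname in _EXPERIMENTS.items():
        with resources.files("ternthresh.data").joinpath(fname).open() as fh:
            out[key] = pd.read_csv(fh)
    return out


def table_values(
    experiment: str, estimator: str, condition: str
) -> pd.Series:
    """Per-subject point estimates for one (estimator, condition) cell,
    indexed by subject in table order."""
    tables = load_fixture_tables()
    if experiment not in tables:
        raise ValueError(f"unknown experiment {experiment!r}")
    tab = tables[experiment]
    sel = tab[(tab["estimator"] == estimator) & (tab["condition"] == condition)]
    if sel.empty:
        raise ValueError(
            f"no rows for estimator={estimator!r}, condition={condition!r}"
        )
    return sel.set_index("subject")["value"].astype(float)
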