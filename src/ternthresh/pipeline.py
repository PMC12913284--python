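"""End-to-end analysis pipeline: clean -> tabulate -> estimate -> infer.

:class:`AnalysisConfig` bundles the experiment layout (design grid,
practice rule, Spearman-Karber anchors, excluded blocks), estimator
selection and bootstrap settings; :func:`run_pipeline` executes the whole
chain on a tidy trial table and writes JSON/CSV results.  All randomness
flows from the config seed, so two runs on identical input are
byte-identical (timestamps appear only in the log).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import simulate
from .inference import (
    bootstrap_threshold,
    invariance_test,
    paired_t_dz,
    practice_curve,
    sk_estimator,
    ttm_estimator,
)
from .nonparametric import EXP1_SK, EXP2_SK, SKConfig, sk_threshold
from .parametric import fit_two_threshold
from .preprocess import (
    EXP1_PRACTICE,
    EXP2_PRACTICE,
    PracticeRule,
    clean_trials,
    counts_to_frame,
    tabulate_counts,
)

__all__ = ["AnalysisConfig", "run_pipeline"]

logger = logging.getLogger("ternthresh")


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings for one full analysis run.

    ``layout`` selects the built-in experiment geometry (``"exp1"`` for
    the ±200 ms modality design, ``"exp2"`` for the ±350 ms intensity
    design); anchors, practice rule and d grid default accordingly but can
    be overridden.  ``estimators`` selects any subset of
    {"nonparametric", "parametric"}.
    """

    layout: str = "exp1"
    anchors: tuple[float, float] | None = None
    practice: PracticeRule | None = None
    excluded_blocks: tuple[tuple[int, int], ...] = ()
    estimators: tuple[str, ...] = ("nonparametric", "parametric")
    B: int = 1000
    seed: int = 0
    restarts: int = 20
    sessions_per_level: int | None = None
    out_dir: str | None = None

    def design(self) -> simulate.DesignSpec:
        if self.layout == "exp1":
            return simulate.exp1_design()
        if self.layout == "exp2":
            return simulate.exp2_design()
        raise ValueError(f"unknown layout {self.layout!r}")

    def sk_config(self) -> SKConfig:
        if self.anchors is not None:
            return SKConfig(*self.anchors)
        return EXP1_SK if self.layout == "exp1" else EXP2_SK

    def practice_rule(self) -> PracticeRule:
        if self.practice is not None:
            return self.practice
        return EXP1_PRACTICE if self.layout == "exp1" else EXP2_PRACTICE

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.practice is not None:
            d["practice"] = dataclasses.asdict(self.practice)
        return d

    @classmethod
    def from_dict(cls, raw: Mapping) -> "AnalysisConfig":
        d = dict(raw)
        if d.get("practice") is not None:
            d["practice"] = PracticeRule(**d["practice"])
        if d.get("anchors") is not None:
            d["anchors"] = tuple(d["anchors"])
        if "excluded_blocks" in d:
            d["excluded_blocks"] = tuple(tuple(b) for b in d["excluded_blocks"])
        if "estimators" in d:
            d["estimators"] = tuple(d["estimators"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        """Load from YAML (also accepts flat ``key: value`` files)."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, Mapping):
            raise ValueError(f"config file {path} did not parse to a mapping")
        return cls.from_dict(raw)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _analyze_subject(
    trials: pd.DataFrame, config: AnalysisConfig, seed: int
) -> dict:
    """Estimate thresholds + CIs and invariance verdicts for one subject."""
    design = config.design()
    cfg = config.sk_config()
    counts = tabulate_counts(trials, d_grid=design.d_values)
    by_cond = {c.condition: c for c in counts}
    result: dict = {"conditions": {}, "invariance": []}

    estimators: dict[str, dict] = {}  # name -> {condition: estimator fn}
    if "nonparametric" in config.estimators:
        est = sk_estimator(cfg)
        estimators["nonparametric"] = {c: est for c in by_cond}
    if "parametric" in config.estimators:
        fits = {
            cond: fit_two_threshold(c, restarts=config.restarts, seed=seed)
            for cond, c in by_cond.items()
        }
        for cond, c in by_cond.items():
            result["conditions"].setdefault(cond, {})["parametric_fit"] = fits[
                cond
            ].to_dict()
        for param in ("c_su", "c_o"):
            estimators[f"parametric_{param}"] = {
                cond: ttm_estimator(
                    param,
                    restarts=1,
                    seed=seed,
                    warm=(f.mu, f.sigma, f.c_su, f.c_o, f.gamma),
                )
                for cond, f in fits.items()
            }

    for name, per_cond in estimators.items():
        for cond, c in by_cond.items():
            boot = bootstrap_threshold(
                c, per_cond[cond], B=config.B, seed=seed
            )
            result["conditions"].setdefault(cond, {})[name] = boot.to_dict()
            if name == "nonparametric":
                result["conditions"][cond]["sk_estimate"] = sk_threshold(
                    c, cfg
                ).to_dict()
        conds = sorted(by_cond)
        for i, a in enumerate(conds):
            for b in conds[i + 1 :]:
                # Paired-difference bootstrap needs one estimator applicable
                # to both conditions; parametric warm starts differ per
                # condition, so wrap them by condition label.
                est_a, est_b = per_cond[a], per_cond[b]

                def est(c, _ea=est_a, _eb=est_b, _a=a):
                    return _ea(c) if c.condition == _a else _eb(c)

                est.__name__ = name
                inv = invariance_test(
                    by_cond[a], by_cond[b], est, B=config.B, seed=seed
                )
                result["invariance"].append(inv.to_dict())

    if config.sessions_per_level:
        curves = {}
        for name, per_cond in estimators.items():
            # a single estimator fn per analysis; for the parametric case use
            # condition-dispatching wrapper as above
            def est(c, _pc=per_cond):
                return _pc[c.condition](c)

            est.__name__ = name
            curves[name] = practice_curve(
                trials,
                est,
                sessions_per_level=config.sessions_per_level,
                B=config.B,
                seed=seed,
                d_grid=design.d_values,
            ).to_dict(orient="records")
        result["practice_curve"] = curves
    return result


def run_pipeline(
    config: AnalysisConfig,
    trials: pd.DataFrame | str | Path,
) -> dict:
    """Run the full analysis on a tidy trial table or CSV path.

    Per subject: clean, tabulate, estimate the nonparametric and/or
    parametric thresholds with percentile-bootstrap CIs, and test
    threshold invariance between every condition pair.  With more than
    one subject, paired group statistics (t, d_z) are added per estimator
    and condition pair.  Results are returned as a JSON-serializable dict
    and, when ``config.out_dir`` is set, written to ``results.json``,
    ``counts.csv`` and ``cleaning.json``.
    """
    if not isinstance(trials, pd.DataFrame):
        trials = simulate.read_trials(trials)
    if trials.empty:
        raise ValueError("no trials provided")

    design = config.design()
    retained, report = clean_trials(
        trials,
        practice=config.practice_rule(),
        excluded_blocks=config.excluded_blocks,
    )
    props = report.proportions()
    logger.info(
        "cleaning: %d input, %d retained; premature %.2f%%, delayed %.2f%%, "
        "lapse %.2f%%, corrected %.2f%%",
        report.n_input,
        report.n_retained,
        100 * props["premature"],
        100 * props["delayed"],
        100 * props["lapse"],
        100 * props["corrected"],
    )
    if report.per_subject:
        for key in ("premature", "delayed", "lapse", "corrected"):
            vals = [v[key] for v in report.per_subject.values()]
            logger.info(
                "%s: mean across subjects %.2f%%, range %.2f-%.2f%%",
                key, 100 * float(np.mean(vals)),
                100 * min(vals), 100 * max(vals),
            )
    logger.info("seed: %d, bootstrap B: %d", config.seed, config.B)

    subjects = sorted(retained["subject"].unique())
    ss = np.random.SeedSequence(config.seed).spawn(len(subjects))
    per_subject = {
        str(subj): _analyze_subject(
            retained[retained["subject"] == subj],
            config,
            int(s.generate_state(1)[0] % (2**31)),
        )
        for subj, s in zip(subjects, ss)
    }

    results: dict = {
        "config": config.to_dict(),
        "cleaning": report.to_dict(),
        "subjects": per_subject,
    }

    if len(subjects) > 1:
        group: dict = {}
        conds = sorted(retained["condition"].unique())
        est_names = next(iter(per_subject.values()))["conditions"][conds[0]]
        names = [
            k for k in est_names
            if k in ("nonparametric", "parametric_c_su", "parametric_c_o")
        ]
        for name in names:
            for i, a in enumerate(conds):
                for b in conds[i + 1 :]:
                    va = [per_subject[s]["conditions"][a][name]["point"] for s in map(str, subjects)]
                    vb = [per_subject[s]["conditions"][b][name]["point"] for s in map(str, subjects)]
                    group[f"{name}:{a}-vs-{b}"] = paired_t_dz(va, vb).to_dict()
        results["group"] = group

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "results.json", "w") as fh:
            json.dump(results, fh, indent=2)
        counts_to_frame(
            tabulate_counts(retained, d_grid=design.d_values)
        ).to_csv(out / "counts.csv", index=False)
        with open(out / "cleaning.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
    return results
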