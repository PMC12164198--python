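"""Orchestration of the many-exposure screen and the classification rule.

Each exposure runs through instrument selection, the four estimators and the
sensitivity suite; verdicts are labelled ``not_significant``, ``potential``,
``robust`` or ``strong`` (precedence strong > robust > potential), with
exposures lacking enough instruments reported as ``insufficient_instruments``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from mrscreen.instrument_selection import LdSource, select_instruments
from mrscreen.mr_estimators import (
    EggerResult,
    MethodResult,
    PressoResult,
    egger,
    ivw,
    mr_presso,
    to_odds_ratio,
    weighted_median,
)
from mrscreen.sensitivity import (
    LooSeries,
    QResult,
    SteigerResult,
    cochran_q,
    leave_one_out,
    steiger,
)
from mrscreen.sumstats_io import HarmonizedSet, SummaryDataset

logger = logging.getLogger(__name__)

FLAGS = ("not_significant", "potential", "robust", "strong")


@dataclass
class ScreenConfig:
    """All thresholds, estimator settings and seeds for one screen run."""

    pval_threshold: float = 1e-5
    r2_max: float = 0.1
    window_kb: int = 500
    f_min: float = 10.0
    outcome_pval_threshold: float = 1e-5
    palindrome_policy: str = "drop_ambiguous"
    min_instruments: int = 3
    ivw_mode: str = "multiplicative_random"
    n_boot: int = 1000
    n_sim: int = 1000
    seed: int = 0
    alpha: float = 0.05
    n_exposures_for_bonferroni: int | None = None
    methods: tuple[str, ...] = ("ivw", "egger", "wm", "presso")

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        for name in ("pval_threshold", "outcome_pval_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0,1]")
        if not 0 <= self.r2_max <= 1:
            raise ValueError("r2_max must be in [0,1]")
        if "ivw" not in self.methods:
            raise ValueError("the primary method 'ivw' cannot be disabled")


@dataclass
class MetaboliteVerdict:
    """Per-exposure outcome of the screen."""

    trait_id: str
    trait_label: str
    category: str
    n_iv: int
    flag: str
    direction_consistent: bool | None = None
    ivw: MethodResult | None = None
    egger: EggerResult | None = None
    wm: MethodResult | None = None
    presso: PressoResult | None = None
    q_ivw: QResult | None = None
    q_egger: QResult | None = None
    loo: LooSeries | None = None
    steiger: SteigerResult | None = None
    selection_log: dict = field(default_factory=dict)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha/m for m tests."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return alpha / m


def _sign(x: float) -> int:
    return (x > 0) - (x < 0)


def classify(
    ivw_result: MethodResult,
    egger_result: MethodResult | None,
    wm_result: MethodResult | None,
    presso_result: MethodResult | None,
    bonferroni: float,
    alpha: float = 0.05,
) -> tuple[str, bool]:
    """Apply the screening classification rule.

    * ``not_significant`` — IVW p >= alpha;
    * ``potential``       — IVW p < alpha only;
    * ``robust``          — IVW p < alpha, at least two of {Egger, weighted
      median, PRESSO} at p < alpha, and IVW/Egger/WM estimates sharing one
      direction (PRESSO's sign is not part of the consistency check);
    * ``strong``          — robust criteria and IVW p < ``bonferroni``.

    Returns (flag, direction_consistent); the consistency flag is reported
    regardless of the label and is False when Egger or WM is unavailable.
    """
    supplementary = [egger_result, wm_result, presso_result]
    direction_consistent = (
        egger_result is not None
        and wm_result is not None
        and _sign(ivw_result.estimate) != 0
        and _sign(egger_result.estimate) == _sign(ivw_result.estimate)
        and _sign(wm_result.estimate) == _sign(ivw_result.estimate)
    )
    if not ivw_result.pval < alpha:
        return "not_significant", direction_consistent
    n_significant = sum(
        1 for m in supplementary if m is not None and m.pval < alpha
    )
    if n_significant >= 2 and direction_consistent:
        if ivw_result.pval < bonferroni:
            return "strong", direction_consistent
        return "robust", direction_consistent
    return "potential", direction_consistent


def analyze_harmonized(
    hs: HarmonizedSet,
    cfg: ScreenConfig,
    bonferroni: float,
    seed: int,
) -> MetaboliteVerdict:
    """Run estimators, sensitivity suite and classification on one
    already-selected harmonized instrument set."""
    k = len(hs)
    ivw_res = ivw(hs, mode=cfg.ivw_mode)
    egger_res = (
        egger(hs) if "egger" in cfg.methods and k >= 3 else None
    )
    wm_res = (
        weighted_median(hs, n_boot=cfg.n_boot, seed=seed)
        if "wm" in cfg.methods and k >= 3
        else None
    )
    presso_res = (
        mr_presso(hs, n_sim=cfg.n_sim, seed=seed, ivw_mode=cfg.ivw_mode)
        if "presso" in cfg.methods and k >= 4
        else None
    )
    presso_estimate = None
    if presso_res is not None and presso_res.testable:
        presso_estimate = presso_res.corrected or presso_res.raw

    flag, consistent = classify(
        ivw_res,
        egger_res.slope if egger_res else None,
        wm_res,
        presso_estimate,
        bonferroni,
        alpha=cfg.alpha,
    )
    return MetaboliteVerdict(
        trait_id=hs.exposure_id,
        trait_label=hs.exposure_id,
        category="",
        n_iv=k,
        flag=flag,
        direction_consistent=consistent,
        ivw=ivw_res,
        egger=egger_res,
        wm=wm_res,
        presso=presso_res,
        q_ivw=cochran_q(hs, "ivw") if k >= 2 else None,
        q_egger=cochran_q(hs, "egger") if k >= 3 else None,
        loo=leave_one_out(hs, mode=cfg.ivw_mode) if k >= 3 else None,
        steiger=steiger(hs),
    )


def screen(
    exposures: Sequence[SummaryDataset],
    outcome: SummaryDataset,
    ld: LdSource,
    cfg: ScreenConfig | None = None,
) -> "ScreenResult":
    """Screen every exposure against the outcome.

    Per exposure: p-filter → clump → F-filter → harmonize →
    outcome-association exclusion → estimators → sensitivity → classify.
    Deterministic given ``cfg.seed`` (exposure i uses child seed
    cfg.seed + i).
    """
    exposures = list(exposures)
    if not exposures:
        raise ValueError("screen requires at least one exposure")
    cfg = cfg or ScreenConfig()
    m = cfg.n_exposures_for_bonferroni or len(exposures)
    bonferroni = bonferroni_threshold(cfg.alpha, m)

    verdicts: list[MetaboliteVerdict] = []
    for i, exposure in enumerate(exposures):
        hs, inst = select_instruments(
            exposure,
            outcome,
            ld,
            pval_threshold=cfg.pval_threshold,
            r2_max=cfg.r2_max,
            window_kb=cfg.window_kb,
            f_min=cfg.f_min,
            outcome_pval_threshold=cfg.outcome_pval_threshold,
            palindrome_policy=cfg.palindrome_policy,
        )
        k = 0 if hs is None else len(hs)
        if hs is None or k < cfg.min_instruments:
            verdicts.append(
                MetaboliteVerdict(
                    trait_id=exposure.trait_id,
                    trait_label=exposure.trait_label,
                    category=exposure.category,
                    n_iv=k,
                    flag="insufficient_instruments",
                    selection_log=inst.selection_log,
                )
            )
            continue
        v = analyze_harmonized(hs, cfg, bonferroni, seed=cfg.seed + i)
        v.trait_label = exposure.trait_label
        v.category = exposure.category
        v.selection_log = inst.selection_log
        verdicts.append(v)
    return ScreenResult(verdicts=verdicts, bonferroni=bonferroni, config=cfg)


@dataclass
class ScreenResult:
    verdicts: list[MetaboliteVerdict]
    bonferroni: float
    config: ScreenConfig

    def summary(self) -> dict:
        counts = {flag: 0 for flag in FLAGS + ("insufficient_instruments",)}
        by_category: dict[str, int] = {}
        for v in self.verdicts:
            counts[v.flag] = counts.get(v.flag, 0) + 1
            if v.flag in ("potential", "robust", "strong"):
                by_category[v.category] = by_category.get(v.category, 0) + 1
        n_sig = sum(counts[f] for f in ("potential", "robust", "strong"))
        return {
            "n_exposures": len(self.verdicts),
            "n_significant": n_sig,
            "n_strong": counts["strong"],
            "n_robust": counts["robust"],
            "n_potential": counts["potential"],
            "n_not_significant": counts["not_significant"],
            "n_insufficient_instruments": counts["insufficient_instruments"],
            "bonferroni_threshold": self.bonferroni,
            "significant_by_category": by_category,
        }

    def table(self) -> pd.DataFrame:
        """Flatten verdicts into one row per exposure."""
        rows = []
        for v in self.verdicts:
            row: dict = {
                "trait_id": v.trait_id,
                "label": v.trait_label,
                "category": v.category,
                "n_iv": v.n_iv,
                "flag": v.flag,
                "direction_consistent": v.direction_consistent,
            }
            for name, m in (
                ("ivw", v.ivw),
                ("egger", v.egger.slope if v.egger else None),
                ("wm", v.wm),
            ):
                if m is not None:
                    row[f"{name}_lnor"] = m.estimate
                    row[f"{name}_se"] = m.se
                    row[f"{name}_ci_low"] = m.ci_low
                    row[f"{name}_ci_high"] = m.ci_high
                    row[f"{name}_p"] = m.pval
            if v.ivw is not None:
                or_, (lo, hi) = to_odds_ratio(v.ivw)
                row["ivw_or"] = or_
                row["ivw_or_ci_low"] = lo
                row["ivw_or_ci_high"] = hi
            if v.egger is not None:
                row["egger_intercept"] = v.egger.intercept
                row["egger_intercept_se"] = v.egger.intercept_se
                row["egger_intercept_p"] = v.egger.intercept_pval
            if v.presso is not None and v.presso.testable:
                m = v.presso.corrected or v.presso.raw
                row["presso_lnor"] = m.estimate
                row["presso_se"] = m.se
                row["presso_p"] = m.pval
                row["presso_global_rss"] = v.presso.global_rss
                row["presso_global_p"] = v.presso.global_pval
                row["presso_n_outliers"] = len(v.presso.outlier_indices)
            if v.q_ivw is not None:
                row["q_ivw"] = v.q_ivw.q
                row["q_ivw_df"] = v.q_ivw.df
                row["q_ivw_p"] = v.q_ivw.pval
                row["no_heterogeneity"] = v.q_ivw.pval > 0.05
            if v.q_egger is not None:
                row["q_egger"] = v.q_egger.q
                row["q_egger_df"] = v.q_egger.df
                row["q_egger_p"] = v.q_egger.pval
            if v.steiger is not None:
                row["steiger_r2_exposure"] = v.steiger.r2_exposure
                row["steiger_r2_outcome"] = v.steiger.r2_outcome
                row["steiger_direction"] = v.steiger.direction
                row["steiger_p"] = v.steiger.pval
            rows.append(row)
        return pd.DataFrame(rows)

    def forest_table(self) -> pd.DataFrame:
        """Forest-plot-ready table (label, OR, ci_low, ci_high) of IVW
        estimates for significant exposures."""
        rows = []
        for v in self.verdicts:
            if v.flag in ("potential", "robust", "strong") and v.ivw is not None:
                or_, (lo, hi) = to_odds_ratio(v.ivw)
                rows.append(
                    {"label": v.trait_label, "or": or_, "ci_low": lo, "ci_high": hi}
                )
        return pd.DataFrame(rows)
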