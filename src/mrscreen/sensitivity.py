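"""Heterogeneity, influence and directionality diagnostics.

Cochran's Q (under the IVW and Egger fits), leave-one-out IVW refits, and
the Steiger direction test comparing instrument variance explained in the
exposure versus the outcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from mrscreen.mr_estimators import MethodResult, _ivw_arrays, _orient, ivw
from mrscreen.sumstats_io import HarmonizedSet


@dataclass(frozen=True)
class QResult:
    """Cochran's Q heterogeneity statistic; chi-square with ``df`` degrees of
    freedom under homogeneity (df = k−1 for ivw, k−2 for egger)."""

    model: str
    q: float
    df: int
    pval: float


@dataclass(frozen=True)
class LooEntry:
    left_out: str
    result: MethodResult
    influential: bool


@dataclass(frozen=True)
class LooSeries:
    """k leave-one-out IVW refits plus the all-variant fit.

    An entry is flagged influential when omitting its variant flips the sign
    of the estimate or moves it outside the all-variant confidence interval.
    """

    full: MethodResult
    entries: tuple[LooEntry, ...]

    def estimates(self) -> np.ndarray:
        return np.array([e.result.estimate for e in self.entries])


@dataclass(frozen=True)
class SteigerResult:
    r2_exposure: float
    r2_outcome: float
    direction: bool
    pval: float | None


def cochran_q(hs: HarmonizedSet, model: str = "ivw") -> QResult:
    """Cochran's Q over the weighted residuals of the IVW (zero-intercept)
    or Egger (with-intercept) fit, with w = 1/se_out²."""
    k = len(hs)
    bx, _, by, sy = hs.arrays()
    w = 1.0 / sy**2
    if model == "ivw":
        if k < 2:
            raise ValueError("cochran_q(ivw) requires at least two variants")
        _, _, q = _ivw_arrays(bx, by, sy, "fixed")
        df = k - 1
    elif model == "egger":
        if k < 3:
            raise ValueError("cochran_q(egger) requires at least three variants")
        obx, oby = _orient(bx, by)
        sw, swx = w.sum(), np.sum(w * obx)
        swx2, swy, swxy = np.sum(w * obx**2), np.sum(w * oby), np.sum(w * obx * oby)
        det = sw * swx2 - swx**2
        slope = (sw * swxy - swx * swy) / det
        intercept = (swx2 * swy - swx * swxy) / det
        q = float(np.sum(w * (oby - intercept - slope * obx) ** 2))
        df = k - 2
    else:
        raise ValueError(f"unknown model {model!r}")
    return QResult(model=model, q=float(q), df=df, pval=float(stats.chi2.sf(q, df)))


def leave_one_out(hs: HarmonizedSet, mode: str = "multiplicative_random") -> LooSeries:
    """Refit IVW k times, omitting one variant per refit."""
    k = len(hs)
    if k < 3:
        raise ValueError("leave_one_out requires at least three variants")
    full = ivw(hs, mode=mode)
    entries = []
    for j in range(k):
        sub = hs.subset_indices([i for i in range(k) if i != j])
        res = ivw(sub, mode=mode)
        influential = (
            (res.estimate > 0) != (full.estimate > 0)
            and res.estimate != 0
            and full.estimate != 0
        ) or not (full.ci_low <= res.estimate <= full.ci_high)
        entries.append(
            LooEntry(
                left_out=hs.variants[j].variant_id,
                result=res,
                influential=bool(influential),
            )
        )
    return LooSeries(full=full, entries=tuple(entries))


def _sum_r2(beta: np.ndarray, se: np.ndarray, n: int) -> float:
    t2 = (beta / se) ** 2
    return float(min(1.0, np.sum(t2 / (t2 + n - 2))))


def steiger(hs: HarmonizedSet) -> SteigerResult:
    """Directionality test: instrument variance explained in the exposure
    versus the outcome.

    Per-variant r² uses the t-statistic approximation t²/(t² + n − 2) and is
    summed over instruments for each trait (binary outcomes on the observed
    log-odds scale).  Direction is TRUE when strictly more variance is
    explained in the exposure.  The p-value compares the two correlations
    r = sqrt(r²) with a Fisher-transform z test using variance
    1/(n_exp − 3) + 1/(n_out − 3); it is None when either sample size is
    unknown.
    """
    if len(hs) < 1:
        raise ValueError("steiger requires at least one variant")
    bx, sx, by, sy = hs.arrays()
    n_exp, n_out = hs.n_exposure, hs.n_outcome
    # the t-approximation needs a sample size; fall back to a large-n df of
    # +inf-like behaviour only when n is given
    if n_exp is None or n_out is None:
        # direction can still be compared with a shared nominal df
        nominal = 10_000
        r2_exp = _sum_r2(bx, sx, n_exp or nominal)
        r2_out = _sum_r2(by, sy, n_out or nominal)
        return SteigerResult(
            r2_exposure=r2_exp,
            r2_outcome=r2_out,
            direction=r2_exp > r2_out,
            pval=None,
        )
    r2_exp = _sum_r2(bx, sx, n_exp)
    r2_out = _sum_r2(by, sy, n_out)
    direction = r2_exp > r2_out
    z = (math.atanh(math.sqrt(r2_exp)) - math.atanh(math.sqrt(r2_out))) / math.sqrt(
        1.0 / (n_exp - 3) + 1.0 / (n_out - 3)
    )
    pval = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return SteigerResult(
        r2_exposure=r2_exp, r2_outcome=r2_out, direction=direction, pval=pval
    )


def steiger_direction(r2_exposure: float, r2_outcome: float) -> bool:
    """The Steiger direction rule on already-computed variance-explained
    values: TRUE iff strictly more variance is explained in the exposure."""
    return r2_exposure > r2_outcome
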