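"""Causal-effect estimators on harmonized summary statistics.

Four estimators are provided as bespoke numerics on a
:class:`~mrscreen.sumstats_io.HarmonizedSet`:

* ``ivw``             — inverse-variance-weighted zero-intercept regression
                        (the primary estimator; multiplicative random effects
                        by default),
* ``egger``           — weighted regression with an intercept after orienting
                        variants to the exposure-increasing allele; the
                        intercept is a directional-pleiotropy test,
* ``weighted_median`` — interpolated weighted median of per-variant ratio
                        estimates with a parametric-bootstrap SE,
* ``mr_presso``       — residual-sum-of-squares resampling with a global
                        pleiotropy test, per-variant outlier test, an
                        outlier-corrected estimate and a distortion test.

All estimates are on the log-odds (lnOR) scale for a binary outcome;
``to_odds_ratio`` converts to the OR display scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from mrscreen.sumstats_io import HarmonizedSet, HarmonizedVariant

Z95 = 1.96  # display-CI multiplier


@dataclass(frozen=True)
class MethodResult:
    """One estimator's causal-effect estimate on the lnOR scale."""

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int


@dataclass(frozen=True)
class EggerResult:
    slope: MethodResult
    intercept: float
    intercept_se: float
    intercept_pval: float


@dataclass(frozen=True)
class PressoResult:
    """Global pleiotropy test, outlier flags and corrected estimate.

    ``testable`` is False (with all test fields None) when fewer than four
    variants are available; ``corrected`` and ``distortion_pval`` are present
    only when outliers were detected.
    """

    testable: bool
    global_rss: float | None
    global_pval: float | None
    outlier_indices: tuple[int, ...]
    outlier_pvals: tuple[float, ...]
    raw: MethodResult | None
    corrected: MethodResult | None
    distortion_pval: float | None


def _norm_p(z: float) -> float:
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def _result(method: str, est: float, se: float, pval: float, k: int) -> MethodResult:
    return MethodResult(
        method=method,
        estimate=float(est),
        se=float(se),
        ci_low=float(est - Z95 * se),
        ci_high=float(est + Z95 * se),
        pval=float(pval),
        n_snps=int(k),
    )


def wald_ratio(v: HarmonizedVariant) -> MethodResult:
    """Single-variant causal estimate beta_out/beta_exp with first-order SE."""
    if v.beta_exp == 0:
        raise ZeroDivisionError(
            f"wald ratio undefined for {v.variant_id}: beta_exp = 0"
        )
    est = v.beta_out / v.beta_exp
    se = abs(v.se_out / v.beta_exp)
    return _result("wald_ratio", est, se, _norm_p(est / se), 1)


def _ivw_arrays(bx: np.ndarray, by: np.ndarray, sy: np.ndarray, mode: str):
    """Core IVW computation returning (estimate, se, Q)."""
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    est = float(np.sum(w * bx * by)) / denom
    se = 1.0 / math.sqrt(denom)
    q = float(np.sum(w * (by - est * bx) ** 2))
    if mode == "multiplicative_random" and len(bx) > 1:
        se *= math.sqrt(max(1.0, q / (len(bx) - 1)))
    elif mode not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown ivw mode {mode!r}")
    return est, se, q


def ivw(hs: HarmonizedSet, mode: str = "multiplicative_random") -> MethodResult:
    """Inverse-variance-weighted estimate: zero-intercept regression of
    beta_out on beta_exp with weights 1/se_out².

    ``fixed`` uses the analytic SE 1/sqrt(sum(beta_exp²/se_out²));
    ``multiplicative_random`` (default) scales it by
    sqrt(max(1, Q/(k−1))).  A single variant reduces to the Wald ratio.
    """
    k = len(hs)
    if k < 1:
        raise ValueError("ivw requires at least one variant")
    if k == 1:
        r = wald_ratio(hs.variants[0])
        return _result("ivw", r.estimate, r.se, r.pval, 1)
    bx, _, by, sy = hs.arrays()
    est, se, _ = _ivw_arrays(bx, by, sy, mode)
    return _result("ivw", est, se, _norm_p(est / se), k)


def _orient(bx: np.ndarray, by: np.ndarray):
    """Orient variants to the exposure-increasing allele (negate both effects
    wherever beta_exp < 0)."""
    sign = np.where(bx < 0, -1.0, 1.0)
    return bx * sign, by * sign


def egger(hs: HarmonizedSet) -> EggerResult:
    """MR-Egger: weighted regression of beta_out on beta_exp with intercept.

    Variants are first oriented to the exposure-increasing allele.  SEs are
    scaled by sqrt(max(1, Q/(k−2))) and p-values use the t distribution with
    k−2 degrees of freedom; a non-zero intercept indicates directional
    pleiotropy.
    """
    k = len(hs)
    if k < 3:
        raise ValueError("egger requires at least three variants")
    bx, _, by, sy = hs.arrays()
    bx, by = _orient(bx, by)
    w = 1.0 / sy**2

    sw = w.sum()
    swx = float(np.sum(w * bx))
    swx2 = float(np.sum(w * bx**2))
    swy = float(np.sum(w * by))
    swxy = float(np.sum(w * bx * by))
    det = sw * swx2 - swx**2
    slope = (sw * swxy - swx * swy) / det
    intercept = (swx2 * swy - swx * swxy) / det

    resid = by - intercept - slope * bx
    q = float(np.sum(w * resid**2))
    scale = math.sqrt(max(1.0, q / (k - 2)))
    se_slope = math.sqrt(sw / det) * scale
    se_int = math.sqrt(swx2 / det) * scale

    df = k - 2
    p_slope = float(min(1.0, 2.0 * stats.t.sf(abs(slope / se_slope), df)))
    p_int = float(min(1.0, 2.0 * stats.t.sf(abs(intercept / se_int), df)))
    return EggerResult(
        slope=_result("egger", slope, se_slope, p_slope, k),
        intercept=float(intercept),
        intercept_se=float(se_int),
        intercept_pval=p_int,
    )


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order]
    p = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, p, r))


def weighted_median(
    hs: HarmonizedSet, n_boot: int = 1000, seed: int = 0
) -> MethodResult:
    """Weighted-median estimate of per-variant ratios beta_out/beta_exp.

    Ratios are weighted by beta_exp²/se_out² (inverse variance of the ratio);
    the estimate interpolates the sorted ratios at standardized cumulative
    weight 0.5.  The SE is the standard deviation of the estimate over
    ``n_boot`` parametric-bootstrap resamples (deterministic given ``seed``).
    """
    k = len(hs)
    if k < 3:
        raise ValueError("weighted_median requires at least three variants")
    bx, sx, by, sy = hs.arrays()
    est = _weighted_median(by / bx, bx**2 / sy**2)

    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(n_boot, k))
    by_b = rng.normal(by, sy, size=(n_boot, k))
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = _weighted_median(by_b[i] / bx_b[i], bx_b[i] ** 2 / sy**2)
    se = float(np.std(boots))
    return _result("weighted_median", est, se, _norm_p(est / se), k)


def _loo_ivw_terms(bx, by, w):
    """Leave-one-out zero-intercept fit for every variant at once."""
    num = np.sum(w * bx * by)
    den = np.sum(w * bx**2)
    return (num - w * bx * by) / (den - w * bx**2)


def mr_presso(
    hs: HarmonizedSet,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int = 0,
    sim_exposure: bool = True,
    ivw_mode: str = "multiplicative_random",
) -> PressoResult:
    """Pleiotropy residual-sum-of-squares resampling test.

    The observed statistic is RSS = Σ_j w_j (beta_out_j − b(−j)·beta_exp_j)²
    with w_j = 1/se_out_j² and b(−j) the IVW estimate excluding variant j.
    The null distribution is built by simulating beta_out* ~
    N(b(−j)·beta_exp_j, se_out_j²) (and, unless ``sim_exposure`` is False,
    beta_exp* ~ N(beta_exp_j, se_exp_j²)) and recomputing RSS ``n_sim``
    times; empirical p-values carry the +1/(n_sim+1) correction.  Per-variant
    residual terms give outlier p-values, Bonferroni-thresholded at
    ``outlier_alpha``/k; when outliers are flagged, an IVW estimate excluding
    them and a distortion p-value are reported.  Fewer than four variants
    yields an untestable marker rather than an error.
    """
    k = len(hs)
    if k < 4:
        return PressoResult(
            testable=False,
            global_rss=None,
            global_pval=None,
            outlier_indices=(),
            outlier_pvals=(),
            raw=ivw(hs, mode=ivw_mode) if k >= 1 else None,
            corrected=None,
            distortion_pval=None,
        )
    bx, sx, by, sy = hs.arrays()
    w = 1.0 / sy**2
    rng = np.random.default_rng(seed)

    b_loo = _loo_ivw_terms(bx, by, w)
    obs_terms = w * (by - b_loo * bx) ** 2
    rss_obs = float(np.sum(obs_terms))

    if sim_exposure:
        bx_s = rng.normal(bx, sx, size=(n_sim, k))
    else:
        bx_s = np.broadcast_to(bx, (n_sim, k))
    by_s = rng.normal(b_loo * bx, sy, size=(n_sim, k))

    num_s = np.sum(w * bx_s * by_s, axis=1, keepdims=True)
    den_s = np.sum(w * bx_s**2, axis=1, keepdims=True)
    b_loo_s = (num_s - w * bx_s * by_s) / (den_s - w * bx_s**2)
    sim_terms = w * (by_s - b_loo_s * bx_s) ** 2
    rss_sim = np.sum(sim_terms, axis=1)

    global_pval = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    outlier_pvals = (1 + np.sum(sim_terms >= obs_terms, axis=0)) / (n_sim + 1)
    flagged = tuple(int(i) for i in np.nonzero(outlier_pvals < outlier_alpha / k)[0])

    raw = ivw(hs, mode=ivw_mode)
    corrected = None
    distortion_pval = None
    if flagged and len(flagged) < k - 1:
        keep = [i for i in range(k) if i not in flagged]
        corrected = ivw(hs.subset_indices(keep), mode=ivw_mode)
        # distortion: compare the raw-vs-corrected shift with shifts obtained
        # by dropping |flagged| randomly chosen variants
        d_obs = corrected.estimate - raw.estimate
        d_sim = np.empty(n_sim)
        idx = np.arange(k)
        for i in range(n_sim):
            drop = rng.choice(idx, size=len(flagged), replace=False)
            mask = np.ones(k, dtype=bool)
            mask[drop] = False
            est_i, _, _ = _ivw_arrays(bx[mask], by[mask], sy[mask], "fixed")
            d_sim[i] = est_i - raw.estimate
        distortion_pval = float(
            (1 + np.sum(np.abs(d_sim) >= abs(d_obs))) / (n_sim + 1)
        )
    return PressoResult(
        testable=True,
        global_rss=rss_obs,
        global_pval=global_pval,
        outlier_indices=flagged,
        outlier_pvals=tuple(float(p) for p in outlier_pvals),
        raw=raw,
        corrected=corrected,
        distortion_pval=distortion_pval,
    )


def to_odds_ratio(m: MethodResult) -> tuple[float, tuple[float, float]]:
    """Convert a lnOR-scale result to the OR display scale (3 decimals)."""
    return (
        round(math.exp(m.estimate), 3),
        (round(math.exp(m.ci_low), 3), round(math.exp(m.ci_high), 3)),
    )
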