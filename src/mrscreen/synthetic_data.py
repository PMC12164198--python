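"""Summary-statistic simulator with known ground truth.

Generates matched exposure/outcome GWAS summary datasets at the
summary-statistic level (no individual genotypes): true per-variant exposure
effects, optional pleiotropic direct effects (balanced or directional,
InSIDE-satisfying or violating), a binary outcome on the log-odds scale with
configurable case/control imbalance, allele scrambling to exercise
harmonization, and LD-correlated decoy variants to exercise clumping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mrscreen.instrument_selection import LdSource
from mrscreen.mr_estimators import egger, ivw, mr_presso, weighted_median
from mrscreen.sensitivity import steiger
from mrscreen.sumstats_io import (
    COMPLEMENT,
    GwasRecord,
    HarmonizedSet,
    HarmonizedVariant,
    SummaryDataset,
)

# outcome defaults mirror a heavily imbalanced binary GWAS
# (1028 cases, 196,986 controls)
DEFAULT_N_CASES = 1028
DEFAULT_N_CONTROLS = 196_986
DEFAULT_N_OUT = DEFAULT_N_CASES + DEFAULT_N_CONTROLS
DEFAULT_CASE_FRACTION = DEFAULT_N_CASES / DEFAULT_N_OUT

# default exposure sample size is a stand-in: typical metabolite GWAS
# cohorts are in the low thousands
DEFAULT_N_EXP = 7000

_P_FLOOR = 1e-300  # keep p-values strictly positive

_ALLELE_PAIRS = [  # non-palindromic ordered pairs
    ("A", "G"),
    ("A", "C"),
    ("T", "G"),
    ("T", "C"),
    ("G", "A"),
    ("C", "A"),
    ("G", "T"),
    ("C", "T"),
]


@dataclass
class TruthRecord:
    """Ground-truth parameters behind one simulated exposure/outcome pair."""

    theta: float = 0.0
    pi_pleio: float = 0.0
    mu_alpha: float = 0.0
    sigma_alpha: float = 0.0
    inside_violated: bool = False
    inside_slope: float = 0.5
    n_exp: int = DEFAULT_N_EXP
    n_out: int = DEFAULT_N_OUT
    case_fraction: float = DEFAULT_CASE_FRACTION
    seed: int = 0
    # filled by the simulator
    gamma: np.ndarray | None = None
    alpha: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi_pleio <= 1.0:
            raise ValueError("pi_pleio must be in [0,1]")
        if not 0.0 < self.case_fraction < 1.0:
            raise ValueError("case_fraction must be in (0,1)")


@dataclass
class SimScenario:
    """Structural knobs of one simulated dataset."""

    k: int = 30
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2_exposure: float = 0.15
    swap_fraction: float = 0.3
    strand_flip_fraction: float = 0.15
    n_decoys: int = 0
    decoy_r2: float = 0.5
    decoy_window_kb: int = 100

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0.0 <= self.decoy_r2 <= 1.0:
            raise ValueError("decoy_r2 must be in [0,1]")


@dataclass
class SimulatedPair:
    """One simulated two-sample dataset plus everything needed to check it."""

    exposure: SummaryDataset
    outcome: SummaryDataset
    truth: TruthRecord
    ld: LdSource
    instrument_ids: tuple[str, ...]
    # instrument-level arrays on the exposure's effect-allele orientation
    # (before any allele scrambling of the written outcome records)
    beta_exp: np.ndarray = field(repr=False, default=None)
    se_exp: np.ndarray = field(repr=False, default=None)
    pval_exp: np.ndarray = field(repr=False, default=None)
    beta_out: np.ndarray = field(repr=False, default=None)
    se_out: np.ndarray = field(repr=False, default=None)
    pval_out: np.ndarray = field(repr=False, default=None)


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return np.maximum(2.0 * stats.norm.sf(np.abs(beta / se)), _P_FLOOR)


def _positions(k: int) -> tuple[list[str], list[int]]:
    """Spread variants across chromosomes, 2 Mb apart within a chromosome so
    instruments never fall in each other's clumping window."""
    chroms = [str(j % 22 + 1) for j in range(k)]
    pos = [10_000_000 + (j // 22) * 2_000_000 for j in range(k)]
    return chroms, pos


def simulate_pair(
    scn: SimScenario, truth: TruthRecord
) -> SimulatedPair:
    """Simulate one exposure/outcome summary-statistics pair.

    Per instrument j: maf ~ U(maf_range); true exposure effects gamma_j are
    Gaussian, rescaled so the instruments explain ``h2_exposure`` of exposure
    variance; direct (pleiotropic) outcome effects alpha_j are 0 with
    probability 1−pi_pleio, else N(mu_alpha, sigma_alpha²), plus
    ``inside_slope``·gamma_j when InSIDE is violated; the total outcome
    effect is theta·gamma_j + alpha_j.  Standard errors follow the usual
    1/sqrt(2·maf·(1−maf)·n) scaling (with an extra case_fraction·(1−case_
    fraction) factor for the binary outcome) and observed effects are drawn
    around the truth.  A fraction of outcome records is written
    allele-swapped and/or strand-complemented; decoy variants in LD with
    instruments are appended per the scenario.  Fully deterministic given
    ``truth.seed``.
    """
    rng = np.random.default_rng(truth.seed)
    k = scn.k

    maf = rng.uniform(*scn.maf_range, size=k)
    # true effects are coded on the exposure-increasing allele (gamma >= 0);
    # sign diversity in the written files comes from the allele scrambling
    # below, so directional pleiotropy keeps a well-defined direction after
    # orientation
    raw = np.abs(rng.standard_normal(k))
    var_per_unit = 2.0 * maf * (1.0 - maf)
    scale = np.sqrt(scn.h2_exposure / np.sum(var_per_unit * raw**2))
    gamma = raw * scale

    pleio = rng.random(k) < truth.pi_pleio
    alpha = np.where(
        pleio, rng.normal(truth.mu_alpha, truth.sigma_alpha, size=k), 0.0
    )
    if truth.inside_violated:
        alpha = alpha + np.where(pleio, truth.inside_slope * gamma, 0.0)
    big_gamma = truth.theta * gamma + alpha

    cf = truth.case_fraction
    se_x = 1.0 / np.sqrt(var_per_unit * truth.n_exp)
    se_y = 1.0 / np.sqrt(var_per_unit * truth.n_out * cf * (1.0 - cf))
    bx = rng.normal(gamma, se_x)
    by = rng.normal(big_gamma, se_y)
    px = _two_sided_p(bx, se_x)
    py = _two_sided_p(by, se_y)

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=k)
    swap = rng.random(k) < scn.swap_fraction
    flip_strand = rng.random(k) < scn.strand_flip_fraction
    chroms, pos = _positions(k)

    ids = tuple(f"rs{j + 1}" for j in range(k))
    exp_records: list[GwasRecord] = []
    out_records: list[GwasRecord] = []
    for j in range(k):
        ea, oa = _ALLELE_PAIRS[pair_idx[j]]
        exp_records.append(
            GwasRecord(
                variant_id=ids[j],
                chrom=chroms[j],
                pos=pos[j],
                effect_allele=ea,
                other_allele=oa,
                eaf=float(maf[j]),
                beta=float(bx[j]),
                se=float(se_x[j]),
                pval=float(px[j]),
                n=truth.n_exp,
            )
        )
        o_ea, o_oa, o_beta, o_eaf = ea, oa, float(by[j]), float(maf[j])
        if swap[j]:
            o_ea, o_oa = o_oa, o_ea
            o_beta = -o_beta
            o_eaf = 1.0 - o_eaf
        if flip_strand[j]:
            o_ea, o_oa = COMPLEMENT[o_ea], COMPLEMENT[o_oa]
        out_records.append(
            GwasRecord(
                variant_id=ids[j],
                chrom=chroms[j],
                pos=pos[j],
                effect_allele=o_ea,
                other_allele=o_oa,
                eaf=o_eaf,
                beta=o_beta,
                se=float(se_y[j]),
                pval=float(py[j]),
                n=truth.n_out,
            )
        )

    ld = LdSource()
    window_bp = scn.decoy_window_kb * 1000
    for d in range(scn.n_decoys):
        j = d % k
        did = f"rs{k + d + 1}"
        offset = int(rng.integers(1, window_bp))
        r = np.sqrt(scn.decoy_r2)
        d_bx = float(r * bx[j])
        d_by = float(r * by[j])
        ea, oa = _ALLELE_PAIRS[pair_idx[j]]
        exp_records.append(
            GwasRecord(
                variant_id=did,
                chrom=chroms[j],
                pos=pos[j] + offset,
                effect_allele=ea,
                other_allele=oa,
                eaf=float(maf[j]),
                beta=d_bx,
                se=float(se_x[j]),
                pval=float(_two_sided_p(np.array(d_bx), np.array(se_x[j]))),
                n=truth.n_exp,
            )
        )
        out_records.append(
            GwasRecord(
                variant_id=did,
                chrom=chroms[j],
                pos=pos[j] + offset,
                effect_allele=ea,
                other_allele=oa,
                eaf=float(maf[j]),
                beta=d_by,
                se=float(se_y[j]),
                pval=float(_two_sided_p(np.array(d_by), np.array(se_y[j]))),
                n=truth.n_out,
            )
        )
        ld.add(ids[j], did, scn.decoy_r2)

    truth = replace(truth, gamma=gamma, alpha=alpha)
    exposure = SummaryDataset(
        trait_id=f"sim_exposure_{truth.seed}",
        records=exp_records,
        sample_size=truth.n_exp,
    )
    outcome = SummaryDataset(
        trait_id=f"sim_outcome_{truth.seed}",
        records=out_records,
        sample_size=truth.n_out,
    )
    return SimulatedPair(
        exposure=exposure,
        outcome=outcome,
        truth=truth,
        ld=ld,
        instrument_ids=ids,
        beta_exp=bx,
        se_exp=se_x,
        pval_exp=px,
        beta_out=by,
        se_out=se_y,
        pval_out=py,
    )


def harmonized_from_sim(pair: SimulatedPair) -> HarmonizedSet:
    """Build the instrument HarmonizedSet directly from the simulator's
    oriented arrays (fast path that bypasses file round-trips and allele
    matching; equivalent to harmonizing the written datasets)."""
    variants = [
        HarmonizedVariant(
            variant_id=pair.instrument_ids[j],
            beta_exp=float(pair.beta_exp[j]),
            se_exp=float(pair.se_exp[j]),
            pval_exp=float(pair.pval_exp[j]),
            beta_out=float(pair.beta_out[j]),
            se_out=float(pair.se_out[j]),
            pval_out=float(pair.pval_out[j]),
        )
        for j in range(len(pair.instrument_ids))
    ]
    return HarmonizedSet(
        exposure_id=pair.exposure.trait_id,
        outcome_id=pair.outcome.trait_id,
        variants=variants,
        n_exposure=pair.truth.n_exp,
        n_outcome=pair.truth.n_out,
    )


def ld_table(pair: SimulatedPair) -> pd.DataFrame:
    """Pairwise LD rows (snp_id_1, snp_id_2, r2) for the simulated decoys."""
    rows = [
        {"snp_id_1": sorted(key)[0], "snp_id_2": sorted(key)[1], "r2": r2}
        for key, r2 in pair.ld._r2.items()
    ]
    return pd.DataFrame(rows, columns=["snp_id_1", "snp_id_2", "r2"])


def operating_characteristics(
    scenarios: dict[str, tuple[SimScenario, TruthRecord]],
    n_reps: int = 50,
    seed: int = 0,
    alpha: float = 0.05,
    n_boot: int = 200,
    n_sim: int = 200,
    methods: Sequence[str] = ("ivw", "egger", "wm"),
) -> pd.DataFrame:
    """Monte-Carlo operating characteristics of the estimators.

    For each named scenario, runs ``n_reps`` simulate→estimate cycles
    (replicate r uses child seed ``seed + r``, so any replicate is
    independently reproducible) and aggregates rejection rate at ``alpha``
    (type-I error when theta = 0, power otherwise), bias, CI coverage, the
    Egger-intercept rejection rate, PRESSO outlier sensitivity/specificity
    and Steiger direction accuracy.  Deterministic given ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rows = []
    for name, (scn, truth0) in scenarios.items():
        est_ivw, est_egger, est_wm = [], [], []
        reject, cover, egger_reject = [], [], []
        presso_sens, presso_spec, steiger_ok = [], [], []
        for r in range(n_reps):
            truth = replace(truth0, seed=seed + r)
            pair = simulate_pair(scn, truth)
            hs = harmonized_from_sim(pair)
            res = ivw(hs)
            est_ivw.append(res.estimate)
            reject.append(res.pval < alpha)
            cover.append(res.ci_low <= truth.theta <= res.ci_high)
            if "egger" in methods and len(hs) >= 3:
                e = egger(hs)
                est_egger.append(e.slope.estimate)
                egger_reject.append(e.intercept_pval < alpha)
            if "wm" in methods and len(hs) >= 3:
                est_wm.append(
                    weighted_median(hs, n_boot=n_boot, seed=seed + r).estimate
                )
            if "presso" in methods and len(hs) >= 4:
                pr = mr_presso(hs, n_sim=n_sim, seed=seed + r)
                flagged = set(pr.outlier_indices)
                true_pleio = set(np.nonzero(pair.truth.alpha != 0)[0])
                if true_pleio:
                    presso_sens.append(
                        len(flagged & true_pleio) / len(true_pleio)
                    )
                n_valid = len(hs) - len(true_pleio)
                if n_valid:
                    presso_spec.append(
                        1.0 - len(flagged - true_pleio) / n_valid
                    )
            if truth.theta != 0:
                steiger_ok.append(steiger(hs).direction)
        row = {
            "scenario": name,
            "theta": truth0.theta,
            "n_reps": n_reps,
            "rejection_rate": float(np.mean(reject)),
            "bias_ivw": float(np.mean(est_ivw) - truth0.theta),
            "sd_ivw": float(np.std(est_ivw)),
            "coverage_ivw": float(np.mean(cover)),
        }
        if est_egger:
            row["bias_egger"] = float(np.mean(est_egger) - truth0.theta)
            row["egger_intercept_rejection_rate"] = float(np.mean(egger_reject))
        if est_wm:
            row["bias_wm"] = float(np.mean(est_wm) - truth0.theta)
        if presso_sens:
            row["presso_outlier_sensitivity"] = float(np.mean(presso_sens))
        if presso_spec:
            row["presso_outlier_specificity"] = float(np.mean(presso_spec))
        if steiger_ok:
            row["steiger_accuracy"] = float(np.mean(steiger_ok))
        rows.append(row)
    return pd.DataFrame(rows)
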