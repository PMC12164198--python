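"""Bundled worked example: a published 486-metabolite screen against
idiopathic pulmonary fibrosis.

The package ships the printed per-metabolite summary of that screen's 23
IVW-significant hits: the supplementary-estimator table (MR-Egger, weighted
median, MR-PRESSO lnOR/CI/p with the IVW effect direction) and the Steiger
variance-explained table.  These tables let the classification and
directionality rules be exercised end-to-end on real printed numbers without
any of the underlying genome-wide input data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from mrscreen.mr_estimators import MethodResult
from mrscreen.pipeline_screen import classify
from mrscreen.sensitivity import steiger_direction

#: IVW p-value stand-in for the example rows: every row of the bundled table
#: is IVW-significant by construction (the table only contains the screen's
#: IVW hits), but the table itself does not print the IVW p-values.
IVW_SIGNIFICANT_P = 0.01


def _load(name: str) -> pd.DataFrame:
    with resources.files("mrscreen.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_sensitivity_table() -> pd.DataFrame:
    """Supplementary-estimator results for the 23 IVW-significant
    metabolites (lnOR, 95% CI bounds and p per method, plus the IVW effect
    direction and chemical category; 'Unknown' marks unidentified
    compounds)."""
    return _load("ipf_screen_sensitivity.tsv")


def load_steiger_table() -> pd.DataFrame:
    """Instrument variance explained in exposure and outcome for the same 23
    metabolites."""
    return _load("ipf_screen_steiger.tsv")


def _method_result(method: str, row: pd.Series) -> MethodResult:
    est = float(row[f"{method}_lnor"])
    lo = float(row[f"{method}_ci_low"])
    hi = float(row[f"{method}_ci_high"])
    return MethodResult(
        method=method,
        estimate=est,
        se=max((hi - lo) / (2 * 1.96), 1e-12),
        ci_low=lo,
        ci_high=hi,
        pval=float(row[f"{method}_p"]),
        n_snps=0,
    )


def classify_example(bonferroni: float = 0.05 / 486) -> pd.DataFrame:
    """Apply the classification rule to the bundled example table.

    Each row is classified from its printed supplementary p-values and lnOR
    signs, with IVW significance given (see ``IVW_SIGNIFICANT_P``).  Returns
    the table with ``flag`` and ``direction_consistent`` columns added.
    """
    df = load_sensitivity_table().copy()
    flags, consistent = [], []
    for _, row in df.iterrows():
        ivw_stub = MethodResult(
            method="ivw",
            estimate=float(row["ivw_sign"]),
            se=1.0,
            ci_low=0.0,
            ci_high=0.0,
            pval=IVW_SIGNIFICANT_P,
            n_snps=0,
        )
        flag, ok = classify(
            ivw_stub,
            _method_result("egger", row),
            _method_result("wm", row),
            _method_result("presso", row),
            bonferroni=bonferroni,
        )
        flags.append(flag)
        consistent.append(ok)
    df["flag"] = flags
    df["direction_consistent"] = consistent
    return df


def steiger_example() -> pd.DataFrame:
    """Apply the Steiger direction rule to the bundled variance-explained
    table; adds a boolean ``direction`` column."""
    df = load_steiger_table().copy()
    df["direction"] = [
        steiger_direction(r2x, r2y)
        for r2x, r2y in zip(df["r2_exposure"], df["r2_outcome"])
    ]
    return df
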