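"""Relative expression by the 2^-ddCt method with replicate statistics.

Input is a tidy table of Ct values, one row per technical replicate:

    gene  tissue  bio_rep  tech_rep  ct_target  ct_reference

Technical replicates are averaged first; each biological replicate then
gives dCt = mean(target Ct) - mean(reference Ct).  ddCt is taken against
the mean dCt of a named calibrator tissue, and the tissue-level fold
change is 2**-(mean dCt - calibrator mean dCt), so the calibrator's own
fold change is 1 by construction.  The spread reported is the standard
deviation of per-replicate fold changes.

Significance between tissues is a two-sided Welch t-test on the dCt
values (approximately normal on the log2 scale), starred at
p <= 0.05 (*), 0.01 (**), 0.001 (***).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["delta_ct", "ddct", "significance", "relative_expression", "stars"]

CT_COLUMNS = ["gene", "tissue", "bio_rep", "tech_rep", "ct_target", "ct_reference"]


def stars(p: float) -> str:
    if np.isnan(p):
        return "ns"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def _validate(ct: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in ct.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    bad = ct[ct["ct_reference"].isna()]
    if len(bad):
        row = bad.iloc[0]
        raise ValueError(
            f"missing reference Ct for sample {row['gene']}/{row['tissue']}"
            f"/rep{row['bio_rep']}"
        )
    if (ct[["ct_target", "ct_reference"]] <= 0).any().any():
        raise ValueError("Ct values must be positive")
    return ct


def delta_ct(ct: pd.DataFrame) -> pd.DataFrame:
    """Per-biological-replicate dCt (technical replicates averaged)."""
    ct = _validate(ct)
    grouped = ct.groupby(["gene", "tissue", "bio_rep"], sort=True).agg(
        ct_target=("ct_target", "mean"),
        ct_reference=("ct_reference", "mean"),
    )
    grouped["dct"] = grouped["ct_target"] - grouped["ct_reference"]
    return grouped.reset_index()


def ddct(ct: pd.DataFrame, calibrator_tissue: str) -> pd.DataFrame:
    """Tissue-level relative expression, one row per gene x tissue."""
    dct = delta_ct(ct)
    rows = []
    for gene, sub in dct.groupby("gene", sort=True):
        calib = sub.loc[sub["tissue"] == calibrator_tissue, "dct"]
        if calib.empty:
            raise ValueError(f"{gene}: calibrator tissue {calibrator_tissue!r} absent")
        calib_mean = calib.mean()
        for tissue, tsub in sub.groupby("tissue", sort=True):
            rep_folds = 2.0 ** -(tsub["dct"] - calib_mean)
            rows.append(
                {
                    "gene": gene,
                    "tissue": tissue,
                    "n_bio_reps": len(tsub),
                    "fold_change": float(2.0 ** -(tsub["dct"].mean() - calib_mean)),
                    "sd": float(rep_folds.std(ddof=1)) if len(tsub) > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)


def significance(
    ct: pd.DataFrame, baseline_tissue: str
) -> pd.DataFrame:
    """Welch t-test of each tissue's dCt values against a baseline tissue.

    Returns one row per gene x tissue with p_value and stars; tissues with
    a single replicate get p = NaN, 'ns' and an explanatory flag.
    """
    dct = delta_ct(ct)
    rows = []
    for gene, sub in dct.groupby("gene", sort=True):
        base = sub.loc[sub["tissue"] == baseline_tissue, "dct"].to_numpy()
        for tissue, tsub in sub.groupby("tissue", sort=True):
            vals = tsub["dct"].to_numpy()
            flag = ""
            if tissue == baseline_tissue:
                p = np.nan
                flag = "baseline"
            elif len(vals) < 2 or len(base) < 2:
                p = np.nan
                flag = "single replicate: p undefined"
            elif np.ptp(vals) == 0 and np.ptp(base) == 0:
                # degenerate zero-variance case: identical sets are not
                # distinguishable, disjoint ones trivially are
                p = 1.0 if np.allclose(vals.mean(), base.mean()) else 0.0
            else:
                p = float(
                    stats.ttest_ind(vals, base, equal_var=False).pvalue
                )
            rows.append(
                {
                    "gene": gene,
                    "tissue": tissue,
                    "p_value": p,
                    "stars": stars(p),
                    "flags": flag,
                }
            )
    return pd.DataFrame(rows)


def relative_expression(
    ct: pd.DataFrame, calibrator_tissue: str, baseline_tissue: str | None = None
) -> pd.DataFrame:
    """Fold changes plus significance annotation in one table.

    ``baseline_tissue`` for the t-test defaults to the calibrator.
    """
    baseline = baseline_tissue or calibrator_tissue
    folds = ddct(ct, calibrator_tissue)
    sig = significance(ct, baseline)
    return folds.merge(sig, on=["gene", "tissue"], how="left")
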