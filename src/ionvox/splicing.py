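"""RNA maturation analysis from exon/intron fragment counts.

For each gene, exon counts out of (exon + intron) totals are modelled with a
binomial (logistic) GLM with condition as the sole covariate; genes whose
exon/intron ratio differs between conditions are selected at a
Benjamini-Hochberg adjusted p below alpha. For display, a per-gene
immature-enrichment splicing score summarises the change:

    IE = log2( sum over treatment replicates of exon/intron
               / sum over control replicates of exon/intron )

IE < 0 means reduced splicing (relative intron retention) under treatment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "exon_intron_glm",
    "bh_adjust",
    "splicing_score",
    "analyze_splicing",
    "splicing_summary",
    "read_splicing_table",
]

REQUIRED_COLUMNS = ["gene_id", "condition", "replicate",
                    "exon_count", "intron_count"]


def _validate(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"splicing table is missing columns {missing}")
    conditions = set(table["condition"].unique())
    if conditions != {"control", "treatment"}:
        raise ValueError(
            f"expected conditions {{'control', 'treatment'}}, got {conditions}"
        )


def read_splicing_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    _validate(table)
    return table


def exon_intron_glm(table: pd.DataFrame) -> pd.DataFrame:
    """Per-gene binomial GLM: exon successes of (exon + intron) trials,
    condition (treatment vs control) as the sole covariate.

    Returns one row per gene: coefficient (log-odds change in the exon
    fraction under treatment), p_value (Wald), and a status note. Genes with
    degenerate counts (zero totals in a replicate, or complete separation)
    get p = NaN and an explanatory status rather than raising.
    """
    _validate(table)
    rows = []
    for gene, g in table.groupby("gene_id", sort=True):
        exon = g["exon_count"].to_numpy(dtype=float)
        intron = g["intron_count"].to_numpy(dtype=float)
        treated = (g["condition"] == "treatment").to_numpy(dtype=float)
        if treated.min() == treated.max():
            rows.append({"gene_id": gene, "coefficient": np.nan,
                         "p_value": np.nan, "status": "one condition only"})
            continue
        if np.any(exon + intron <= 0):
            rows.append({"gene_id": gene, "coefficient": np.nan,
                         "p_value": np.nan, "status": "zero total counts"})
            continue
        # complete separation: a condition with all-exon or all-intron counts
        sep = False
        for cond_mask in (treated == 1, treated == 0):
            if exon[cond_mask].sum() == 0 or intron[cond_mask].sum() == 0:
                sep = True
        if sep:
            rows.append({"gene_id": gene, "coefficient": np.nan,
                         "p_value": np.nan, "status": "separation"})
            continue
        endog = np.column_stack([exon, intron])
        exog = sm.add_constant(treated)
        try:
            fit = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
            rows.append({"gene_id": gene,
                         "coefficient": float(fit.params[1]),
                         "p_value": float(fit.pvalues[1]), "status": "ok"})
        except Exception as err:  # pragma: no cover - defensive
            rows.append({"gene_id": gene, "coefficient": np.nan,
                         "p_value": np.nan, "status": f"fit failed: {err}"})
    return pd.DataFrame(rows)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs passed through)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def splicing_score(table: pd.DataFrame) -> pd.DataFrame:
    """Per-gene immature-enrichment score IE.

    IE = log2 of the treatment-summed exon/intron replicate ratios over the
    control-summed ratios. Genes with a zero intron count in any replicate
    are flagged and get IE = NaN (the ratio is undefined; no pseudocount is
    applied by default).
    """
    _validate(table)
    rows = []
    for gene, g in table.groupby("gene_id", sort=True):
        if np.any(g["intron_count"].to_numpy() == 0):
            rows.append({"gene_id": gene, "IE": np.nan,
                         "ie_status": "zero intron count"})
            continue
        ratio = g["exon_count"].to_numpy(float) / g["intron_count"].to_numpy(float)
        treat = ratio[(g["condition"] == "treatment").to_numpy()].sum()
        ctrl = ratio[(g["condition"] == "control").to_numpy()].sum()
        if treat == 0 or ctrl == 0:
            rows.append({"gene_id": gene, "IE": np.nan,
                         "ie_status": "zero ratio sum"})
            continue
        rows.append({"gene_id": gene, "IE": float(np.log2(treat / ctrl)),
                     "ie_status": "ok"})
    return pd.DataFrame(rows)


def analyze_splicing(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Full per-gene analysis: GLM p, BH adjustment, IE, significance flag."""
    glm = exon_intron_glm(table)
    glm["p_adj"] = bh_adjust(glm["p_value"])
    ie = splicing_score(table)
    out = glm.merge(ie, on="gene_id", how="left")
    out["significant"] = out["p_adj"] < alpha
    return out


def splicing_summary(results: pd.DataFrame, alpha: float = 0.05) -> dict:
    """IE distribution over significantly changed genes.

    Returns the significant-gene IE values plus counts suitable for a
    violin-style display (n significant, n with IE defined, median IE).
    """
    sig = results[(results["p_adj"] < alpha) & results["p_value"].notna()]
    ie = sig["IE"].dropna().to_numpy()
    return {
        "n_genes": int(len(results)),
        "n_significant": int(len(sig)),
        "n_ie_defined": int(len(ie)),
        "median_IE": float(np.median(ie)) if len(ie) else np.nan,
        "IE_values": ie,
    }
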