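"""Per-neighborhood drug quantification and condition comparison.

Drug (e.g. cisplatin, 194Pt) levels are summarised per neighborhood either
as the full count distribution or, after clip normalisation, as the fraction
of drug-positive voxels per field of view; conditions are compared per
neighborhood with a two-sided Wilcoxon rank-sum test on the per-FOV
fractions (exact with midranks for small samples).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

__all__ = [
    "channel_distribution_by_neighborhood",
    "positive_fraction",
    "wilcoxon_rank_sum",
    "compare_conditions",
    "condition_positive_summary",
]


def channel_distribution_by_neighborhood(table: pd.DataFrame,
                                         labels: np.ndarray,
                                         channel: str) -> pd.DataFrame:
    """Summary statistics of a channel per neighborhood.

    Returns one row per neighborhood: n, mean, median, q25, q75. The raw
    per-neighborhood value lists are attached as ``result.attrs['values']``.
    """
    if len(labels) != len(table):
        raise ValueError("labels must align with table rows")
    if channel not in table.columns:
        raise ValueError(f"channel {channel!r} not in table")
    df = pd.DataFrame({"neighborhood": np.asarray(labels),
                       "value": table[channel].to_numpy(dtype=float)})
    grouped = df.groupby("neighborhood")["value"]
    out = grouped.agg(
        n="size", mean="mean", median="median",
        q25=lambda v: v.quantile(0.25), q75=lambda v: v.quantile(0.75),
    ).reset_index()
    out.attrs["values"] = {k: g.to_numpy() for k, g in grouped}
    return out


def _positive(values: np.ndarray, positive_rule) -> np.ndarray:
    if callable(positive_rule):
        return np.asarray(positive_rule(values), dtype=bool)
    if isinstance(positive_rule, str):
        # "gt:<threshold>" or the default "gt:0" (positive after clipping)
        if positive_rule.startswith("gt:"):
            return values > float(positive_rule[3:])
        raise ValueError(f"unknown positive rule {positive_rule!r}")
    raise ValueError(f"unknown positive rule {positive_rule!r}")


def positive_fraction(table: pd.DataFrame, labels: np.ndarray, channel: str,
                      positive_rule="gt:0",
                      fov_column: str = "fov_id") -> pd.DataFrame:
    """Fraction of drug-positive voxels per (FOV, neighborhood).

    The default rule (value > 0) corresponds, after clip normalisation, to a
    raw mean count above the lower clip limit. Returns columns fov_id,
    neighborhood, n_voxels, fraction.
    """
    if len(labels) != len(table):
        raise ValueError("labels must align with table rows")
    df = pd.DataFrame({
        "fov_id": table[fov_column].to_numpy(),
        "neighborhood": np.asarray(labels),
        "positive": _positive(table[channel].to_numpy(dtype=float),
                              positive_rule),
    })
    out = df.groupby(["fov_id", "neighborhood"]).agg(
        n_voxels=("positive", "size"), fraction=("positive", "mean")
    ).reset_index()
    return out


def wilcoxon_rank_sum(a, b, exact_max_n: int = 12) -> float:
    """Two-sided Wilcoxon rank-sum p-value with midranks.

    For combined sample size <= ``exact_max_n`` the null distribution of the
    rank sum is enumerated over all group assignments and the smaller tail
    probability doubled (capped at 1). Larger samples use the normal
    approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    n = len(a) + len(b)
    if n <= exact_max_n:
        pooled = np.concatenate([a, b])
        ranks = rankdata(pooled)  # midranks
        t_obs = ranks[: len(a)].sum()
        sums = np.array([ranks[list(c)].sum()
                         for c in combinations(range(n), len(a))])
        # float-safe comparisons: midranks are multiples of 0.5
        eps = 1e-9
        p_low = np.mean(sums <= t_obs + eps)
        p_high = np.mean(sums >= t_obs - eps)
        return float(min(1.0, 2.0 * min(p_low, p_high)))
    return float(mannwhitneyu(a, b, alternative="two-sided",
                              method="asymptotic").pvalue)


def compare_conditions(fractions: pd.DataFrame, group_a, group_b,
                       condition_column: str = "condition",
                       value_column: str = "fraction") -> pd.DataFrame:
    """Per-neighborhood two-sided rank-sum comparison of per-FOV fractions.

    ``fractions`` is the long-form output of :func:`positive_fraction` with a
    condition column added. Returns one row per neighborhood: n per group,
    group means, and the p-value.
    """
    rows = []
    for nb, g in fractions.groupby("neighborhood"):
        va = g.loc[g[condition_column] == group_a, value_column].to_numpy()
        vb = g.loc[g[condition_column] == group_b, value_column].to_numpy()
        if len(va) == 0 or len(vb) == 0:
            raise ValueError(
                f"neighborhood {nb}: empty group ({group_a}: {len(va)}, "
                f"{group_b}: {len(vb)})"
            )
        rows.append({
            "neighborhood": nb,
            "n_a": len(va), "n_b": len(vb),
            "mean_a": va.mean(), "mean_b": vb.mean(),
            "p_value": wilcoxon_rank_sum(va, vb),
        })
    return pd.DataFrame(rows)


def condition_positive_summary(tables_by_condition: dict[str, pd.DataFrame],
                               channel: str,
                               positive_rule="gt:0") -> pd.DataFrame:
    """Overall drug-positive voxel fraction per condition.

    The overall fraction pools voxels across FOVs (per-FOV fractions
    weighted by voxel count); the per-FOV breakdown is attached as
    ``result.attrs['per_fov']``.
    """
    rows, per_fov = [], []
    for condition, table in tables_by_condition.items():
        pos = _positive(table[channel].to_numpy(dtype=float), positive_rule)
        rows.append({"condition": condition, "n_voxels": len(table),
                     "fraction": float(pos.mean()) if len(table) else 0.0})
        df = pd.DataFrame({"fov_id": table["fov_id"].to_numpy(),
                           "positive": pos})
        fov = df.groupby("fov_id")["positive"].agg(["size", "mean"])
        fov.columns = ["n_voxels", "fraction"]
        fov["condition"] = condition
        per_fov.append(fov.reset_index())
    out = pd.DataFrame(rows)
    out.attrs["per_fov"] = pd.concat(per_fov, ignore_index=True)
    return out
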