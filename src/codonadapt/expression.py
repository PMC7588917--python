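"""Two-condition expression integration: groups A–D, rank tests, correlations.

The expression table carries per-gene log2 signals under a control carbon
source (glucose) and an inducing one (ball-milled aspen, BMA), plus a
p-value for the difference. Genes are partitioned by fold change and
significance:

    A: repressed >= fold_threshold-fold, p < alpha
    B: induced   >= fold_threshold-fold, p < alpha
    C: not significant (p >= alpha)
    D: significant but < fold_threshold-fold either way

Group B — wood-induced genes — is the focal set; each index is compared
between B and each other group with a two-sided Mann–Whitney test, and
correlated (Spearman) with the expression variables, optionally within
p-value strata.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence, TextIO

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

GROUPS = ("A", "B", "C", "D")

#: default p-value strata: (label, lower inclusive, upper exclusive)
DEFAULT_STRATA = (
    ("p<0.001", 0.0, 0.001),
    ("0.001<=p<0.05", 0.001, 0.05),
    ("p>=0.05", 0.05, np.inf),
)


class ExpressionFormatError(ValueError):
    pass


def load_expression(source: str | Path | TextIO) -> pd.DataFrame:
    """Load a per-gene two-condition expression TSV.

    Expected columns: ``id``, ``log2_glucose``, ``log2_bma``, ``p_value``.
    The fold change ``ratio = 2**(log2_bma - log2_glucose)`` is recomputed
    from the signals rather than trusted from an input column. Rows with
    unparseable numbers are dropped with a warning; duplicate ids and
    p-values outside [0, 1] are errors.
    """
    table = pd.read_csv(source, sep="\t", dtype={"id": str})
    required = {"id", "log2_glucose", "log2_bma", "p_value"}
    missing = required - set(table.columns)
    if missing:
        raise ExpressionFormatError(f"missing columns: {sorted(missing)}")
    if table["id"].duplicated().any():
        dupes = table.loc[table["id"].duplicated(), "id"].tolist()
        raise ExpressionFormatError(f"duplicate gene ids: {dupes[:5]}")

    numeric = table[["log2_glucose", "log2_bma", "p_value"]].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        logger.warning("dropped %d malformed expression rows", int(bad.sum()))
        table = table.loc[~bad].copy()
        numeric = numeric.loc[~bad]
    table[["log2_glucose", "log2_bma", "p_value"]] = numeric

    if ((table["p_value"] < 0) | (table["p_value"] > 1)).any():
        raise ExpressionFormatError("p-values outside [0, 1]")
    table["ratio"] = 2.0 ** (table["log2_bma"] - table["log2_glucose"])
    return table.reset_index(drop=True)


def classify_groups(
    table: pd.DataFrame,
    fold_threshold: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Assign each gene exactly one group label A–D.

    Boundary policy (fixed): the fold threshold is inclusive (ratio >= 2 or
    <= 1/2), significance strict (p < alpha); exact p == alpha falls in C.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    out = table.copy()
    ratio = out["ratio"].to_numpy(dtype=float)
    p = out["p_value"].to_numpy(dtype=float)
    group = np.full(len(out), "C", dtype="<U1")
    significant = p < alpha
    group[significant & (ratio >= fold_threshold)] = "B"
    group[significant & (ratio <= 1.0 / fold_threshold)] = "A"
    group[significant & (ratio > 1.0 / fold_threshold) & (ratio < fold_threshold)] = "D"
    out["group"] = group
    logger.info(
        "group sizes: %s",
        {g: int((group == g).sum()) for g in GROUPS},
    )
    return out


def compare_index_by_group(
    merged: pd.DataFrame,
    index_names: Sequence[str],
    focal: str = "B",
) -> pd.DataFrame:
    """Two-sided Mann–Whitney comparisons of the focal group against the rest.

    Uses the exact null for small untied samples and the tie-corrected normal
    approximation otherwise. Empty or singleton groups are skipped with a
    warning. Returns one row per (index, comparison) with the U statistic,
    p-value, group sizes and medians.
    """
    rows = []
    for index_name in index_names:
        focal_vals = merged.loc[merged["group"] == focal, index_name].dropna().to_numpy()
        for other in GROUPS:
            if other == focal:
                continue
            other_vals = merged.loc[merged["group"] == other, index_name].dropna().to_numpy()
            if len(focal_vals) < 2 or len(other_vals) < 2:
                logger.warning(
                    "skipping %s %s-vs-%s: group too small (%d vs %d)",
                    index_name, focal, other, len(focal_vals), len(other_vals),
                )
                continue
            result = stats.mannwhitneyu(
                focal_vals, other_vals, alternative="two-sided", method="auto"
            )
            rows.append(
                {
                    "index": index_name,
                    "comparison": f"{focal}-vs-{other}",
                    "U": float(result.statistic),
                    "p_value": float(result.pvalue),
                    f"n_{focal}": len(focal_vals),
                    "n_other": len(other_vals),
                    f"median_{focal}": float(np.median(focal_vals)),
                    "median_other": float(np.median(other_vals)),
                }
            )
    return pd.DataFrame(rows)


def correlate_index_expression(
    merged: pd.DataFrame,
    index_names: Sequence[str],
    strata: Sequence[tuple[str, float, float]] = DEFAULT_STRATA,
    expression_vars: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Spearman correlations of each index with each expression variable.

    Computed unstratified ("all") and within disjoint, exhaustive p-value
    strata (lower bound inclusive, upper exclusive). Average ranks handle
    ties. Strata with < 3 pairs, or a constant vector on either side, yield a
    flagged NaN row instead of a coefficient.
    """
    if expression_vars is None:
        expression_vars = {
            "glucose": "log2_glucose",
            "bma": "log2_bma",
            "ratio": "ratio",
        }
    p = merged["p_value"].to_numpy(dtype=float)
    masks = [("all", np.ones(len(merged), dtype=bool))]
    masks += [(label, (p >= lo) & (p < hi)) for label, lo, hi in strata]

    rows = []
    for index_name in index_names:
        for var_label, var_col in expression_vars.items():
            for stratum_label, mask in masks:
                sub = merged.loc[mask, [index_name, var_col]].dropna()
                n = len(sub)
                x = sub[index_name].to_numpy()
                y = sub[var_col].to_numpy()
                if n < 3 or np.all(x == x[0]) or np.all(y == y[0]):
                    rho, pval, flag = float("nan"), float("nan"), "undefined"
                else:
                    rho, pval = stats.spearmanr(x, y)
                    flag = ""
                rows.append(
                    {
                        "index": index_name,
                        "expression_var": var_label,
                        "stratum": stratum_label,
                        "rho": float(rho),
                        "p_value": float(pval),
                        "n": n,
                        "flag": flag,
                    }
                )
    return pd.DataFrame(rows)
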