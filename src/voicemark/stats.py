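"""Group-comparison layer: per-variable tests with Benjamini-Hochberg FDR.

Continuous variables are compared with Welch's (unequal-variance) two-sided
t-test — appropriate for the unequal group sizes (41 vs 150) — and
categorical variables with Pearson's chi-squared test on the group-by-level
contingency table.  Because many variables are compared across the
demographic, linguistic, sentiment and acoustic families, raw p-values are
adjusted with the Benjamini-Hochberg step-up procedure; by default one
pooled family across all compared variables (a per-family mode is
available), and adjusted p < 0.05 marks significance.

Group summaries report mean, median and interquartile range for continuous
variables and per-level counts (percent) for categorical ones.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import InputError

DEFAULT_ALPHA = 0.05


def _summary(values: np.ndarray) -> Dict[str, float]:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {"mean": float(np.mean(values)), "median": float(med),
            "iqr": float(q3 - q1)}


def compare_continuous(x: Sequence[float], y: Sequence[float]
                       ) -> Tuple[float, Dict[str, Dict[str, float]]]:
    """Welch two-sided t-test p-value plus per-group summaries."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise InputError("each group needs at least 2 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InputError("non-finite values in comparison")
    if np.var(x) == 0 and np.var(y) == 0:
        # degenerate: no within-group variation
        p = 1.0 if np.mean(x) == np.mean(y) else 0.0
    else:
        p = float(sps.ttest_ind(x, y, equal_var=False).pvalue)
    return p, {"a": _summary(x), "b": _summary(y)}


def compare_categorical(table: np.ndarray) -> float:
    """Pearson chi-squared p-value on an r x c contingency table."""
    table = np.asarray(table)
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.number):
        raise InputError("contingency table must hold non-negative counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise InputError("degenerate contingency margin")
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise InputError("contingency table must be at least 2x2")
    res = sps.chi2_contingency(table, correction=False)
    return float(res.pvalue)


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-aligned with
    the input."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def build_tables(fm, alpha: float = DEFAULT_ALPHA, pooled: bool = True
                 ) -> pd.DataFrame:
    """Per-variable comparison table across the two diagnostic groups.

    One row per compared variable (TF-IDF keyword columns are not
    individually compared, mirroring the published table layout).  With
    ``pooled`` (default) the BH adjustment spans all compared variables;
    otherwise it is applied within each feature family.
    """
    df = fm.df
    labels = sorted(df["label"].unique())
    if len(labels) != 2:
        raise InputError("comparison tables require exactly two groups")
    ga, gb = labels
    rows = []
    for col in fm.feature_columns:
        family = fm.families[col]
        if family == "TF-IDF":
            continue
        sub = df[[col, "label"]].dropna()
        excluded = len(df) - len(sub)
        a = sub.loc[sub["label"] == ga, col].to_numpy()
        b = sub.loc[sub["label"] == gb, col].to_numpy()
        if col in fm.categorical:
            levels = np.unique(sub[col])
            table = np.array([[np.sum(a == lv) for lv in levels],
                              [np.sum(b == lv) for lv in levels]])
            if table.shape[1] < 2:
                p = 1.0  # single observed level: no association testable
            else:
                p = compare_categorical(table)
            summ_a = " / ".join(
                f"{int(lv)}:{np.sum(a == lv)} ({100 * np.mean(a == lv):.1f}%)"
                for lv in levels)
            summ_b = " / ".join(
                f"{int(lv)}:{np.sum(b == lv)} ({100 * np.mean(b == lv):.1f}%)"
                for lv in levels)
            rows.append({"variable": col, "family": family, "test": "chi2",
                         f"{ga}_summary": summ_a, f"{gb}_summary": summ_b,
                         f"{ga}_mean": np.nan, f"{ga}_median": np.nan,
                         f"{ga}_iqr": np.nan, f"{gb}_mean": np.nan,
                         f"{gb}_median": np.nan, f"{gb}_iqr": np.nan,
                         "p_raw": p, "n_excluded": excluded})
        else:
            p, summ = compare_continuous(a, b)
            rows.append({"variable": col, "family": family, "test": "welch_t",
                         f"{ga}_summary": "", f"{gb}_summary": "",
                         f"{ga}_mean": summ["a"]["mean"],
                         f"{ga}_median": summ["a"]["median"],
                         f"{ga}_iqr": summ["a"]["iqr"],
                         f"{gb}_mean": summ["b"]["mean"],
                         f"{gb}_median": summ["b"]["median"],
                         f"{gb}_iqr": summ["b"]["iqr"],
                         "p_raw": p, "n_excluded": excluded})
    out = pd.DataFrame(rows)
    if pooled:
        out["p_adj"] = bh_fdr(out["p_raw"].to_numpy())
    else:
        out["p_adj"] = np.nan
        for family in out["family"].unique():
            mask = out["family"] == family
            out.loc[mask, "p_adj"] = bh_fdr(out.loc[mask, "p_raw"].to_numpy())
    out["significant"] = out["p_adj"] < alpha
    return out


def render_markdown(table: pd.DataFrame, group_a: Optional[str] = None,
                    group_b: Optional[str] = None) -> str:
    """Compact markdown rendering: mean (IQR) per group plus adjusted p."""
    mean_cols = [c for c in table.columns if c.endswith("_mean")]
    ga = group_a or mean_cols[0][:-5]
    gb = group_b or mean_cols[1][:-5]
    lines = [f"| Variable | Family | {ga} | {gb} | adj. p | |",
             "|---|---|---|---|---|---|"]
    for _, r in table.iterrows():
        if r["test"] == "chi2":
            ca, cb = r[f"{ga}_summary"], r[f"{gb}_summary"]
        else:
            ca = f"{r[f'{ga}_mean']:.4f} ({r[f'{ga}_iqr']:.4f})"
            cb = f"{r[f'{gb}_mean']:.4f} ({r[f'{gb}_iqr']:.4f})"
        star = "*" if r["significant"] else ""
        lines.append(f"| {r['variable']} | {r['family']} | {ca} | {cb} | "
                     f"{r['p_adj']:.3g} | {star} |")
    return "\n".join(lines)
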