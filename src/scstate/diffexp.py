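"""Two-group Wilcoxon rank-sum differential expression with Seurat-style
fold changes and multiple-testing control.

The rank-sum p-value is exact (full enumeration of the rank-sum
distribution) when both groups have at most 8 observations and the data
are tie-free, and otherwise uses the normal approximation with tie and
continuity corrections.  Fold changes are computed on de-logged means with
a pseudocount, matching the convention of mainstream single-cell toolkits,
and the default multiple-testing adjustment is Bonferroni over all genes
tested (Benjamini-Hochberg available by flag).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from scstate.annotate import NormalizedMatrix

EXACT_MAX_N = 8


def rank_sum_test(
    values_a: Sequence[float], values_b: Sequence[float], alternative: str = "two-sided"
) -> float:
    """Wilcoxon rank-sum (Mann-Whitney) p-value, two-sided by default.

    Exact when ``len(a), len(b) <= 8`` and there are no ties; normal
    approximation with tie and continuity corrections otherwise.
    ``alternative`` may be ``"greater"``/``"less"`` for one-sided tests
    (group a stochastically greater / less than group b).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    tie_free = np.unique(combined).size == combined.size
    if a.size <= EXACT_MAX_N and b.size <= EXACT_MAX_N and tie_free:
        method = "exact"
    else:
        method = "asymptotic"
    res = mannwhitneyu(a, b, alternative=alternative, method=method, use_continuity=True)
    # extreme z underflows sf() to 0; floor so p stays in (0, 1]
    return float(min(max(res.pvalue, np.finfo(float).tiny), 1.0))


def log2_avg_fold_change(
    norm_a: Sequence[float], norm_b: Sequence[float], pseudocount: float = 1.0
) -> float:
    """log2 of the ratio of de-logged group means, with a pseudocount.

    Inputs are log1p-scale expression vectors; the value is
    log2((mean(expm1(a)) + c) / (mean(expm1(b)) + c)).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    a = np.expm1(np.asarray(norm_a, dtype=float)).mean()
    b = np.expm1(np.asarray(norm_b, dtype=float)).mean()
    return float(np.log2((a + pseudocount) / (b + pseudocount)))


def adjust_p(p_values: Sequence[float], method: str = "bonferroni") -> np.ndarray:
    """Multiple-testing adjustment: ``bonferroni`` or ``bh`` (step-up FDR)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown adjustment method {method!r}")


def find_markers(
    norm: NormalizedMatrix,
    group1: Sequence[bool],
    group2: Sequence[bool],
    alpha: float = 0.05,
    method: str = "bonferroni",
    pseudocount: float = 1.0,
    min_pct: float = 0.0,
    min_abs_log2fc: float = 0.0,
) -> pd.DataFrame:
    """Per-gene rank-sum DE between two disjoint cell selections.

    Returns a table with log2 average fold change (group1 over group2),
    raw and adjusted p, detection percentages, group sizes and a
    ``significant`` flag (adjusted p < *alpha*).  Optional pre-filters on
    detection fraction and |log2FC| default off; pre-filtered genes are
    excluded before adjustment and marked ``tested = False``.
    """
    g1 = np.asarray(list(group1), dtype=bool)
    g2 = np.asarray(list(group2), dtype=bool)
    if g1.size != norm.n_cells or g2.size != norm.n_cells:
        raise ValueError("group selectors and matrix have different cell counts")
    if np.any(g1 & g2):
        raise ValueError("group selectors overlap")
    if not g1.any() or not g2.any():
        raise ValueError("both groups must select at least one cell")

    x1 = np.asarray(norm.values[:, np.flatnonzero(g1)].todense())
    x2 = np.asarray(norm.values[:, np.flatnonzero(g2)].todense())
    n1, n2 = x1.shape[1], x2.shape[1]
    pct1 = 100.0 * (x1 > 0).mean(axis=1)
    pct2 = 100.0 * (x2 > 0).mean(axis=1)
    fc = np.array(
        [log2_avg_fold_change(x1[i], x2[i], pseudocount) for i in range(len(norm.genes))]
    )
    tested = (np.maximum(pct1, pct2) >= 100.0 * min_pct) & (np.abs(fc) >= min_abs_log2fc)
    pvals = np.full(len(norm.genes), np.nan)
    for i in np.flatnonzero(tested):
        pvals[i] = rank_sum_test(x1[i], x2[i])
    adj = np.full(len(norm.genes), np.nan)
    if tested.any():
        adj[tested] = adjust_p(pvals[tested], method=method)
    out = pd.DataFrame(
        {
            "gene": norm.genes,
            "log2_fc": fc,
            "p_value": pvals,
            "adjusted_p": adj,
            "pct_1": pct1,
            "pct_2": pct2,
            "n1": n1,
            "n2": n2,
            "tested": tested,
        }
    )
    out["significant"] = (out["adjusted_p"] < alpha).fillna(False)
    return out
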