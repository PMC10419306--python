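"""Per-donor cell-type composition analysis across two conditions.

Proportions are computed per donor (optionally within a parent population
for subtypes, e.g. Th17.1 among T cells), screened per (cell type,
condition) with a single-outlier Grubbs test on donor proportions, and
compared with a two-sample pooled-variance Student t test at a 95% level
of confidence.  Results are tiered: "*" for p < 0.05, the trending mark
"‡" for 0.05 <= p < 0.1, "n.s." otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

TIER_SIGNIFICANT = "*"
TIER_TRENDING = "‡"
TIER_NS = "n.s."


class InsufficientDonorsError(ValueError):
    pass


def proportion_table(
    cells: pd.DataFrame,
    level: str = "cell_type",
    parent: str | None = None,
    parent_level: str = "cell_type",
) -> pd.DataFrame:
    """Per-donor cell-type (or subtype) proportions.

    With *parent* set, *level* is interpreted within the parent population:
    rows are per donor with the denominator being that donor's cells whose
    *parent_level* equals *parent* (e.g. subtype flags among T cells).
    Donors with zero cells at the level are excluded with a warning.
    """
    df = cells
    if parent is not None:
        df = df[df[parent_level] == parent]
    rows = []
    for (donor, condition), sub in df.groupby(["donor", "condition"], sort=True):
        total = len(sub)
        if total == 0:
            continue
        counts = sub[level].value_counts()
        for value, n in counts.sort_index().items():
            rows.append(
                {
                    "donor": donor,
                    "condition": condition,
                    "cell_type": value,
                    "n_cells": int(n),
                    "proportion": n / total,
                }
            )
    excluded = set(zip(cells["donor"], cells["condition"])) - {
        (r["donor"], r["condition"]) for r in rows
    }
    for donor, condition in sorted(excluded):
        warnings.warn(f"donor {donor!r} ({condition}) has no cells at level {level!r}; excluded")
    return pd.DataFrame(rows, columns=["donor", "condition", "cell_type", "n_cells", "proportion"])


@dataclass
class TTestResult:
    t: float
    p: float
    zero_variance: bool = False


def student_t_test(
    props_control: Sequence[float], props_disease: Sequence[float], welch: bool = False
) -> TTestResult:
    """Two-sided two-sample Student t test (pooled variance by default).

    Degrees of freedom n1 + n2 - 2.  With zero pooled variance the result
    is the degenerate convention: t = 0, p = 1 for equal means, otherwise
    t = +/-inf, p = 0, flagged ``zero_variance``.  Requires at least two
    donors per condition.
    """
    x = np.asarray(list(props_control), dtype=float)
    y = np.asarray(list(props_disease), dtype=float)
    if x.size < 2 or y.size < 2:
        raise InsufficientDonorsError("insufficient donors: need >= 2 per condition")
    if not welch:
        ss = ((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()
        df = x.size + y.size - 2
        pooled_var = ss / df
        if pooled_var == 0.0:
            if x.mean() == y.mean():
                return TTestResult(t=0.0, p=1.0, zero_variance=True)
            t = np.inf if x.mean() > y.mean() else -np.inf
            return TTestResult(t=float(t), p=0.0, zero_variance=True)
        se = np.sqrt(pooled_var * (1.0 / x.size + 1.0 / y.size))
        t = (x.mean() - y.mean()) / se
        p = 2.0 * stats.t.sf(abs(t), df)
        return TTestResult(t=float(t), p=float(min(p, 1.0)))
    res = stats.ttest_ind(x, y, equal_var=False)
    return TTestResult(t=float(res.statistic), p=float(res.pvalue))


def classify_tier(p: float) -> str:
    """"*" below 0.05, "‡" (trending) below 0.1, "n.s." otherwise."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if p < 0.05:
        return TIER_SIGNIFICANT
    if p < 0.1:
        return TIER_TRENDING
    return TIER_NS


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided single-outlier Grubbs critical value from the t distribution.

    G_crit = ((n-1)/sqrt(n)) * sqrt(t^2 / (n - 2 + t^2)) with
    t = t_{1 - alpha/(2n), n-2}.
    """
    if n < 3:
        raise ValueError("Grubbs test requires n >= 3")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return float((n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t)))


def grubbs_test(values: Sequence[float], alpha: float = 0.05) -> int | None:
    """Single-outlier Grubbs test; returns the outlier index or ``None``.

    G = max_i |x_i - mean| / sd (sd with n-1 denominator); an outlier is
    declared when G exceeds the two-sided critical value at *alpha*.  At
    most one outlier per call.  Location-scale free.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 3:
        raise ValueError("Grubbs test requires n >= 3")
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise ValueError("Grubbs test undefined for zero-variance data")
    dev = np.abs(x - x.mean())
    g = dev.max() / sd
    if g > grubbs_critical_value(x.size, alpha):
        return int(dev.argmax())
    return None


def composition_report(
    pt: pd.DataFrame,
    screen_outliers: bool = True,
    alpha: float = 0.05,
    grubbs_alpha: float = 0.05,
    welch: bool = False,
    nonzero_only: bool = False,
) -> pd.DataFrame:
    """Per-cell-type condition comparison of donor proportions.

    For every cell type: donor proportions per condition (donors in the
    table but lacking the type count as proportion 0), optional Grubbs
    screening per condition (a flagged donor is removed for that cell
    type's test only, and logged), then a Student t test and tier.  Test
    failures (e.g. too few donors after screening) are recorded per cell
    type in the ``note`` column rather than aborting the report.

    ``nonzero_only`` restricts each group's t test to donors that actually
    contain the population (screening still sees every donor); this mirrors
    rare-subtype comparisons where only subtype-containing donors are
    informative, and a group reduced below two donors is reported as
    insufficient rather than tested.
    """
    donors_by_cond = (
        pt[["donor", "condition"]].drop_duplicates().groupby("condition")["donor"].apply(list)
    )
    wide = pt.pivot_table(
        index=["donor", "condition"], columns="cell_type", values="proportion", fill_value=0.0
    )
    rows = []
    for cell_type in sorted(pt["cell_type"].unique()):
        removed: list[str] = []
        group: dict[str, np.ndarray] = {}
        for condition in ("control", "disease"):
            donors = donors_by_cond.get(condition, [])
            props = np.array(
                [
                    wide.loc[(d, condition), cell_type] if (d, condition) in wide.index else 0.0
                    for d in donors
                ]
            )
            if screen_outliers and props.size >= 3 and props.std(ddof=1) > 0:
                idx = grubbs_test(props, alpha=grubbs_alpha)
                if idx is not None:
                    removed.append(f"{donors[idx]} ({condition})")
                    props = np.delete(props, idx)
            if nonzero_only:
                props = props[props > 0]
            group[condition] = props
        row = {
            "cell_type": cell_type,
            "mean_control": float(group["control"].mean()) if group["control"].size else np.nan,
            "mean_disease": float(group["disease"].mean()) if group["disease"].size else np.nan,
            "removed_donors": ";".join(removed),
            "note": "",
        }
        if row["mean_control"] and not np.isnan(row["mean_control"]):
            row["fold_change"] = row["mean_disease"] / row["mean_control"]
        else:
            row["fold_change"] = np.nan
        try:
            res = student_t_test(group["control"], group["disease"], welch=welch)
            row.update(t=res.t, p=res.p, tier=classify_tier(res.p))
            if res.zero_variance:
                row["note"] = "zero variance"
        except InsufficientDonorsError as exc:
            row.update(t=np.nan, p=np.nan, tier="", note=str(exc))
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "cell_type",
            "mean_control",
            "mean_disease",
            "fold_change",
            "t",
            "p",
            "tier",
            "removed_donors",
            "note",
        ],
    )
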