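"""Condition-specific transcription factors.

A TF is condition-specific for a cell type when it is significantly
differentially expressed (cell type vs all other cell types) within the
disease condition but not within the control condition.  The two DE runs
must use the same grouping definition; a TF absent from the control DE
table (e.g. undetected there) counts as not-significant-in-control and is
recorded as "untested".
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd


def condition_specific_tfs(
    de_disease: pd.DataFrame,
    de_control: pd.DataFrame,
    catalog: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Retain catalog TFs significant in disease but not in control.

    Returns one row per retained TF: disease adjusted p and log2FC, and
    the control status (its adjusted p, or "untested" when the TF is
    absent from the control table).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    catalog = frozenset(catalog)
    dis = de_disease.set_index("gene")
    ctl = de_control.set_index("gene")
    rows = []
    for gene in dis.index:
        if gene not in catalog:
            continue
        d = dis.loc[gene]
        d_adj = float(d["adjusted_p"])
        if not d_adj < alpha:
            continue
        if gene in ctl.index and pd.notna(ctl.loc[gene, "adjusted_p"]):
            c_adj = float(ctl.loc[gene, "adjusted_p"])
            if c_adj < alpha:
                continue
            control_status = f"{c_adj:.6g}"
        else:
            control_status = "untested"
        rows.append(
            {
                "tf": gene,
                "disease_adjusted_p": d_adj,
                "disease_log2_fc": float(d["log2_fc"]),
                "control_adjusted_p": control_status,
            }
        )
    return pd.DataFrame(
        rows, columns=["tf", "disease_adjusted_p", "disease_log2_fc", "control_adjusted_p"]
    )
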