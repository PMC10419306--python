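"""Signed, max-normalized gene enrichment score (GES) over directed gene sets.

For a gene set with members g_1..g_G carrying activator/repressor
directions, repressor genes have the sign of their log2 average fold
change inverted, and

    GES = sum_i adjFC_i / max_i |adjFC_i|

over the set genes entering the score.  Positive GES means the set is
upregulated (disease over control, for the usual comparison); |GES| <= G.
By default only genes significant in the DE table (adjusted p < 0.05)
enter, matching the retention rule applied upstream, and the max-abs
normalizer is taken within the entering set genes (a global normalizer
across the whole DE table is available by option).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from scstate.io_formats import DirectedGeneSet


class EnrichmentError(ValueError):
    pass


@dataclass
class GESRecord:
    set_name: str
    g_scored: int
    g_declared: int
    ges: float
    contributions: pd.DataFrame = field(repr=False)
    dropped: list[str] = field(default_factory=list, repr=False)


def adjust_directions(de: pd.DataFrame, gene_set: DirectedGeneSet) -> tuple[pd.DataFrame, list[str]]:
    """Apply repressor sign inversion to the set's genes found in a DE table.

    Returns a per-gene frame (gene, direction, log2_fc, adjusted_fc, and
    any DE columns needed downstream) plus the list of set genes absent
    from the DE table.
    """
    de_idx = de.set_index("gene")
    rows = []
    dropped = []
    for gene, direction in gene_set.members:
        if gene not in de_idx.index:
            dropped.append(gene)
            continue
        rec = de_idx.loc[gene]
        fc = float(rec["log2_fc"])
        rows.append(
            {
                "gene": gene,
                "direction": direction,
                "log2_fc": fc,
                "adjusted_fc": -fc if direction == "repressor" else fc,
                "significant": bool(rec["significant"]) if "significant" in rec else True,
            }
        )
    cols = ["gene", "direction", "log2_fc", "adjusted_fc", "significant"]
    return pd.DataFrame(rows, columns=cols), dropped


def ges(
    de: pd.DataFrame,
    gene_set: DirectedGeneSet,
    significant_only: bool = True,
    normalizer: str = "set",
) -> GESRecord:
    """Compute the GES of one gene set against one DE table.

    ``significant_only`` (default on) restricts to genes flagged
    significant in the DE table.  ``normalizer`` is ``"set"`` (max |adjFC|
    within entering set genes) or ``"global"`` (max |log2FC| over the whole
    DE table).
    """
    adjusted, dropped = adjust_directions(de, gene_set)
    entering = adjusted[adjusted["significant"]] if significant_only else adjusted
    if entering.empty:
        raise EnrichmentError(f"empty gene set after filtering: {gene_set.name!r}")
    if normalizer == "set":
        denom = float(entering["adjusted_fc"].abs().max())
    elif normalizer == "global":
        denom = float(de["log2_fc"].abs().max())
    else:
        raise ValueError(f"unknown normalizer {normalizer!r}")
    if denom == 0.0:
        raise EnrichmentError(f"degenerate normalizer for gene set {gene_set.name!r}")
    contributions = entering.copy()
    contributions["normalized"] = contributions["adjusted_fc"] / denom
    score = float(contributions["normalized"].sum())
    return GESRecord(
        set_name=gene_set.name,
        g_scored=len(entering),
        g_declared=len(gene_set.members),
        ges=score,
        contributions=contributions.reset_index(drop=True),
        dropped=dropped,
    )


def ges_table(
    de_by_comparison: dict[str, pd.DataFrame],
    sets: list[DirectedGeneSet],
    significant_only: bool = True,
    normalizer: str = "set",
) -> pd.DataFrame:
    """GES for every (comparison, set) pair; incomputable pairs keep a reason.

    Rows carry comparison, set, G_scored, G_declared, ges and a status
    column ("ok" or the failure reason); the score is NaN when incomputable.
    """
    rows = []
    for comparison, de in de_by_comparison.items():
        for s in sets:
            try:
                rec = ges(de, s, significant_only=significant_only, normalizer=normalizer)
                rows.append(
                    {
                        "comparison": comparison,
                        "set": s.name,
                        "G_scored": rec.g_scored,
                        "G_declared": rec.g_declared,
                        "ges": rec.ges,
                        "status": "ok",
                    }
                )
            except EnrichmentError as exc:
                rows.append(
                    {
                        "comparison": comparison,
                        "set": s.name,
                        "G_scored": 0,
                        "G_declared": len(s.members),
                        "ges": float("nan"),
                        "status": str(exc),
                    }
                )
    return pd.DataFrame(
        rows, columns=["comparison", "set", "G_scored", "G_declared", "ges", "status"]
    )
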