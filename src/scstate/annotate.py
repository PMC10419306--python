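"""Log-normalization, marker-based cluster annotation, co-expression
subtype gating, and ROC validation of candidate markers.

Clustering itself is upstream and pluggable: annotation consumes per-cell
cluster ids (the simulator's truth, or any external tool's labels) and
assigns each cluster the cell-type label whose marker set has the highest
mean normalized expression — an automatic, auditable stand-in for manual
annotation from violin plots, with per-label scores reported for override.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import rankdata

from scstate.io_formats import CountMatrix


@dataclass
class NormalizedMatrix:
    """Gene-by-cell matrix of log1p-normalized expression values."""

    genes: list[str]
    barcodes: list[str]
    values: sparse.csc_matrix

    def __post_init__(self) -> None:
        self.values = sparse.csc_matrix(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError("values shape does not match genes x barcodes")

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not present in matrix") from None

    def gene_values(self, gene: str) -> np.ndarray:
        return np.asarray(self.values[self.gene_index(gene), :].todense()).ravel()


def log_normalize(m: CountMatrix, scale_factor: float = 1e4) -> NormalizedMatrix:
    """ln(1 + count * scale_factor / cell_total) per entry.

    All-zero cells map to all-zero columns.  Within-cell rank order of
    genes is preserved (the transform is monotone per cell).
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be > 0")
    counts = m.counts.tocsc().astype(float)
    totals = np.asarray(counts.sum(axis=0)).ravel()
    scale = np.where(totals > 0, scale_factor / np.maximum(totals, 1.0), 0.0)
    out = counts.copy()
    # scale column j by scale[j], then log1p the stored entries (zeros stay zero)
    out.data = out.data * np.repeat(scale, np.diff(out.indptr))
    out.data = np.log1p(out.data)
    return NormalizedMatrix(genes=list(m.genes), barcodes=list(m.barcodes), values=out)


def annotate_clusters(
    norm: NormalizedMatrix,
    clusters: Sequence,
    markers: Mapping[str, Sequence[str]],
) -> tuple[dict, pd.DataFrame]:
    """Assign each cluster the label with highest mean marker expression.

    Returns ``(assignment, scores)`` where *scores* has one row per
    (cluster, label) with the mean normalized expression of the label's
    marker genes averaged over the cluster's cells, plus the winner and a
    tie flag.  Exact ties go to the first label in declaration order.
    """
    clusters = np.asarray(list(clusters))
    if clusters.size != norm.n_cells:
        raise ValueError("clusters and matrix have different cell counts")
    if clusters.size == 0:
        raise ValueError("empty cluster assignment")
    gidx = {g: i for i, g in enumerate(norm.genes)}
    marker_rows = {
        label: [gidx[g] for g in genes if g in gidx] for label, genes in markers.items()
    }
    for label, rows in marker_rows.items():
        if not rows:
            raise ValueError(f"no marker of label {label!r} is present in the matrix")
    assignment: dict = {}
    records = []
    for cl in pd.unique(clusters):
        mask = clusters == cl
        if not mask.any():
            raise ValueError(f"cluster {cl!r} has no cells")
        sub = norm.values[:, np.flatnonzero(mask)]
        cell_means = np.asarray(sub.mean(axis=1)).ravel()
        scores = {label: float(cell_means[rows].mean()) for label, rows in marker_rows.items()}
        best = max(scores.values())
        winners = [label for label, s in scores.items() if s == best]
        assignment[cl] = winners[0]
        records.append(
            {
                "cluster": cl,
                "label": winners[0],
                "tie": len(winners) > 1,
                **{f"score_{label}": s for label, s in scores.items()},
            }
        )
    return assignment, pd.DataFrame(records)


def coexpression_gate(
    norm: NormalizedMatrix, gene_a: str, gene_b: str, threshold: float = 0.0
) -> np.ndarray:
    """Flag cells with expression of both genes above *threshold*.

    The default threshold 0 flags any cell with a nonzero count for both
    genes — the weakest defensible co-expression gate in sparse data.
    The result is invariant to log-normalization (positivity is preserved).
    """
    a = norm.gene_values(gene_a)
    b = norm.gene_values(gene_b)
    return (a > threshold) & (b > threshold)


def marker_auc(norm: NormalizedMatrix, positive: Sequence[bool], gene: str) -> float:
    """ROC AUC of one gene for a binary cell partition.

    Mann-Whitney U / (n_pos * n_neg) with ties counted half: the
    probability that a random positive cell out-expresses a random
    negative cell.
    """
    positive = np.asarray(list(positive), dtype=bool)
    if positive.size != norm.n_cells:
        raise ValueError("positive mask and matrix have different cell counts")
    n_pos = int(positive.sum())
    n_neg = int(positive.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("degenerate mask: need at least one positive and one negative cell")
    x = norm.gene_values(gene)
    ranks = rankdata(x)
    u = ranks[positive].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))
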