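"""Per-cell QC metrics, threshold filtering, deferred mitochondrial
filtering, and cell downsampling.

Discard rules use strict inequalities ("less than" / "more than"), so a
cell sitting exactly on a threshold is kept.  The mitochondrial cut can be
deferred to a second pass after annotation, where listed cell-type labels
(cardiomyocytes, which physiologically run high) are exempt.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from scstate.io_formats import CountMatrix

MITO_PREFIX = "MT-"


@dataclass
class QCThresholds:
    """Per-sample-group QC cut-offs; ``None`` disables a rule.

    ``defer_mito`` postpones the mitochondrial cut to
    :func:`deferred_mito_filter`, whose ``mito_exempt_labels`` are never
    filtered on mitochondrial content.
    """

    min_features: float | None = None
    max_features: float | None = None
    max_counts: float | None = None
    max_pct_mito: float | None = None
    defer_mito: bool = False
    mito_exempt_labels: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if (
            self.min_features is not None
            and self.max_features is not None
            and self.min_features > self.max_features
        ):
            raise ValueError("min_features > max_features")
        self.mito_exempt_labels = tuple(self.mito_exempt_labels)


def compute_metrics(m: CountMatrix, mito_prefix: str = MITO_PREFIX) -> pd.DataFrame:
    """Per-cell n_features, n_counts and pct_mito (0 for all-zero cells)."""
    counts = m.counts.tocsc()
    n_counts = np.asarray(counts.sum(axis=0)).ravel()
    n_features = np.diff(counts.indptr)  # nonzeros per column
    mito_rows = [i for i, g in enumerate(m.genes) if g.startswith(mito_prefix)]
    if mito_rows:
        mito_counts = np.asarray(counts[mito_rows, :].sum(axis=0)).ravel()
    else:
        mito_counts = np.zeros_like(n_counts)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(n_counts > 0, 100.0 * mito_counts / np.maximum(n_counts, 1), 0.0)
    return pd.DataFrame(
        {
            "barcode": m.barcodes,
            "sample_id": m.sample_id,
            "n_features": n_features.astype(int),
            "n_counts": n_counts.astype(int),
            "pct_mito": pct,
        }
    )


def apply_thresholds(metrics: pd.DataFrame, t: QCThresholds) -> np.ndarray:
    """Boolean keep mask; boundary cells (metric == threshold) are kept."""
    keep = np.ones(len(metrics), dtype=bool)
    nf = metrics["n_features"].to_numpy()
    nc = metrics["n_counts"].to_numpy()
    pm = metrics["pct_mito"].to_numpy()
    if t.min_features is not None:
        keep &= ~(nf < t.min_features)
    if t.max_features is not None:
        keep &= ~(nf > t.max_features)
    if t.max_counts is not None:
        keep &= ~(nc > t.max_counts)
    if t.max_pct_mito is not None and not t.defer_mito:
        keep &= ~(pm > t.max_pct_mito)
    return keep


def deferred_mito_filter(
    metrics: pd.DataFrame, labels: Sequence[str], t: QCThresholds
) -> np.ndarray:
    """Second-pass mitochondrial cut applied after annotation.

    Cells labelled with an exempt type always pass; all others must have
    pct_mito <= max_pct_mito.  With no cap set, everything passes.
    """
    labels = pd.Series(list(labels))
    if len(labels) != len(metrics):
        raise ValueError("labels and metrics have different lengths")
    if labels.isna().any() or (labels == "").any():
        raise ValueError("every cell needs a label for deferred mitochondrial filtering")
    keep = np.ones(len(metrics), dtype=bool)
    if t.max_pct_mito is None:
        return keep
    exempt = labels.isin(t.mito_exempt_labels).to_numpy()
    pm = metrics["pct_mito"].to_numpy()
    keep = exempt | ~(pm > t.max_pct_mito)
    return keep


def downsample(m: CountMatrix, n_cells: int, seed: int) -> CountMatrix:
    """Uniform random cell subset without replacement, order-preserving.

    Counts are never modified; if ``n_cells`` >= current size the matrix is
    returned unchanged.  Deterministic under a fixed seed.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if n_cells >= m.n_cells:
        return m
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(m.n_cells, size=n_cells, replace=False))
    return m.subset_cells(idx)
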