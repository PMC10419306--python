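"""Negative-binomial simulator for multi-donor two-condition count data.

The generator emulates the structure the downstream analysis assumes:
several donors per condition, a cell-type mixture whose weights shift
multiplicatively in disease, per-donor Dirichlet jitter of mixture weights
(so proportion tests see realistic between-donor variance), log-normal
library sizes, planted differentially expressed genes per cell type and
condition, a rare co-expressing subtype defined by two gating genes,
cell-type-dependent mitochondrial content (high in the cardiomyocyte-like
type, exercising deferred mitochondrial filtering), and an optional outlier
donor.  Every run returns a ground-truth ledger so recovery is checkable.

Counts for gene g in cell i of type t are drawn

    X_gi ~ NB(mean = L_i * f_t[g] * 2^beta, dispersion theta)

where L_i is the cell's library size, f_t is the type's expression profile
(normalized so mitochondrial genes carry the type's expected mitochondrial
share), beta is the planted log2 effect when (t, g, condition) is in the DE
ledger and 0 otherwise, and var = mean + mean^2 / theta.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from scstate.io_formats import CountMatrix

MITO_PREFIX = "MT-"


class ConfigError(ValueError):
    """The simulation configuration violates one of its invariants."""


@dataclass
class DonorSpec:
    donor: str
    condition: str
    n_cells: int


@dataclass
class DEEffect:
    """A planted log2 differential-expression effect."""

    cell_type: str
    gene: str
    condition: str
    beta: float


@dataclass
class SubtypeSpec:
    """Rare co-expressing subtype nested in a parent cell type.

    Subtype cells are ordinary parent-type cells whose two gating genes'
    expected expression is raised from ~0 to ``weight`` x library size.
    """

    parent: str
    gene_a: str
    gene_b: str
    frequency: Mapping[str, float]  # condition -> fraction of parent cells
    weight: float = 0.008


@dataclass
class OutlierSpec:
    """Perturb one donor's mixture weight for a cell type (Grubbs target)."""

    donor: str
    cell_type: str
    weight_multiplier: float = 20.0


@dataclass
class SimulationConfig:
    genes: list[str]
    profiles: dict[str, np.ndarray]  # cell type -> relative expression weights
    markers: dict[str, list[str]]  # cell type -> marker symbols (for annotation)
    mixture_weights: dict[str, float]
    proportion_shift: dict[str, float]  # multiplicative in disease; 1 = no shift
    donors: list[DonorSpec]
    de_effects: list[DEEffect] = field(default_factory=list)
    subtype: SubtypeSpec | None = None
    mito_level: Mapping[str, float] = field(default_factory=dict)
    dispersion: float = 2.0
    library_meanlog: float = 7.6
    library_sdlog: float = 0.35
    donor_concentration: float = 200.0
    outlier: OutlierSpec | None = None
    seed: int = 0

    def validate(self) -> None:
        n = len(self.genes)
        if len(set(self.genes)) != n:
            raise ConfigError("gene symbols are not unique")
        for name, prof in self.profiles.items():
            if len(prof) != n:
                raise ConfigError(f"profile for {name!r} has wrong length")
            if np.any(np.asarray(prof) < 0):
                raise ConfigError(f"profile for {name!r} has negative weights")
        if set(self.mixture_weights) != set(self.profiles):
            raise ConfigError("mixture_weights and profiles name different cell types")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be > 0")
        for d in self.donors:
            if d.n_cells <= 0:
                raise ConfigError(f"donor {d.donor} has n_cells <= 0")
            if d.condition not in ("control", "disease"):
                raise ConfigError(f"donor {d.donor} has unknown condition {d.condition!r}")
        for name, level in self.mito_level.items():
            if not 0 <= level < 1:
                raise ConfigError(f"mito_level for {name!r} outside [0, 1)")
        if self.subtype is not None:
            for f in self.subtype.frequency.values():
                if not 0 <= f <= 1:
                    raise ConfigError("subtype frequency outside [0, 1]")
            for g in (self.subtype.gene_a, self.subtype.gene_b):
                if g not in self.genes:
                    raise ConfigError(f"subtype gating gene {g!r} not in gene list")
                if g.startswith(MITO_PREFIX):
                    raise ConfigError(f"subtype gating gene {g!r} collides with mitochondrial genes")
        for e in self.de_effects:
            if e.gene not in self.genes:
                raise ConfigError(f"planted DE gene {e.gene!r} not in gene list")
            if e.cell_type not in self.profiles:
                raise ConfigError(f"planted DE cell type {e.cell_type!r} unknown")

    @property
    def cell_types(self) -> list[str]:
        return list(self.profiles)


@dataclass
class SimTruth:
    """Ground-truth ledger of a simulation run."""

    cells: pd.DataFrame  # barcode, donor, condition, cell_type, is_subtype
    proportions: pd.DataFrame  # donor, condition, cell_type, n_cells, proportion
    de_ledger: pd.DataFrame  # cell_type, gene, condition, beta
    outlier_donor: str | None = None


def _normalized_profile(config: SimulationConfig, cell_type: str, mito_idx: np.ndarray) -> np.ndarray:
    """Scale a raw profile so mito genes carry the type's mito share."""
    prof = np.asarray(config.profiles[cell_type], dtype=float).copy()
    level = float(config.mito_level.get(cell_type, 0.0))
    out = np.zeros_like(prof)
    non_mito = np.ones(len(prof), dtype=bool)
    non_mito[mito_idx] = False
    nm_sum = prof[non_mito].sum()
    if nm_sum <= 0:
        raise ConfigError(f"profile for {cell_type!r} has no non-mitochondrial expression")
    out[non_mito] = prof[non_mito] / nm_sum * (1.0 - level)
    if mito_idx.size:
        mito_raw = prof[mito_idx]
        if mito_raw.sum() <= 0:
            mito_raw = np.ones(mito_idx.size)
        out[mito_idx] = mito_raw / mito_raw.sum() * level
    return out


def _donor_weights(config: SimulationConfig, donor: DonorSpec, rng: np.random.Generator) -> np.ndarray:
    """Mixture weights for one donor: shift, outlier perturbation, Dirichlet jitter."""
    types = config.cell_types
    w = np.array([config.mixture_weights[t] for t in types], dtype=float)
    if donor.condition == "disease":
        w = w * np.array([config.proportion_shift.get(t, 1.0) for t in types])
    if config.outlier is not None and config.outlier.donor == donor.donor:
        w[types.index(config.outlier.cell_type)] *= config.outlier.weight_multiplier
    w = w / w.sum()
    return rng.dirichlet(w * config.donor_concentration)


def simulate(config: SimulationConfig) -> tuple[list[CountMatrix], pd.DataFrame, SimTruth]:
    """Draw counts for every donor; return matrices, a cell table, and truth.

    The cell table has one row per simulated cell with barcode, sample_id,
    donor, condition, a cluster id (the true type index — clustering proper
    is upstream and pluggable), and the true subtype flag.  Identical seeds
    give bitwise-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = config.genes
    gidx = {g: i for i, g in enumerate(genes)}
    mito_idx = np.array([i for i, g in enumerate(genes) if g.startswith(MITO_PREFIX)], dtype=int)
    types = config.cell_types
    profiles = np.column_stack([_normalized_profile(config, t, mito_idx) for t in types])
    theta = config.dispersion

    effects_by_cond: dict[str, list[tuple[int, int, float]]] = {"control": [], "disease": []}
    for e in config.de_effects:
        effects_by_cond[e.condition].append((types.index(e.cell_type), gidx[e.gene], e.beta))

    matrices: list[CountMatrix] = []
    cell_rows: list[pd.DataFrame] = []
    prop_rows: list[dict] = []
    for donor in config.donors:
        w = _donor_weights(config, donor, rng)
        type_of = rng.choice(len(types), size=donor.n_cells, p=w)
        lib = rng.lognormal(config.library_meanlog, config.library_sdlog, donor.n_cells)
        mu = profiles[:, type_of] * lib[np.newaxis, :]
        for t_i, g_i, beta in effects_by_cond[donor.condition]:
            mask = type_of == t_i
            mu[g_i, mask] *= 2.0**beta
        is_sub = np.zeros(donor.n_cells, dtype=bool)
        st = config.subtype
        if st is not None:
            freq = float(st.frequency.get(donor.condition, 0.0))
            parent_mask = type_of == types.index(st.parent)
            if freq > 0 and parent_mask.any():
                is_sub[parent_mask] = rng.random(parent_mask.sum()) < freq
                for g in (st.gene_a, st.gene_b):
                    mu[gidx[g], is_sub] += st.weight * lib[is_sub]
        counts = rng.negative_binomial(theta, theta / (theta + mu))
        barcodes = [f"{donor.donor}_c{i:05d}" for i in range(donor.n_cells)]
        matrices.append(
            CountMatrix(
                genes=list(genes),
                barcodes=barcodes,
                counts=sparse.csc_matrix(counts),
                sample_id=donor.donor,
            )
        )
        cell_rows.append(
            pd.DataFrame(
                {
                    "barcode": barcodes,
                    "sample_id": donor.donor,
                    "donor": donor.donor,
                    "condition": donor.condition,
                    "cluster": type_of,
                    "cell_type": [types[t] for t in type_of],
                    "is_subtype": is_sub,
                }
            )
        )
        n_by_type = np.bincount(type_of, minlength=len(types))
        for t_i, t in enumerate(types):
            prop_rows.append(
                {
                    "donor": donor.donor,
                    "condition": donor.condition,
                    "cell_type": t,
                    "n_cells": int(n_by_type[t_i]),
                    "proportion": n_by_type[t_i] / donor.n_cells,
                }
            )

    cells = pd.concat(cell_rows, ignore_index=True)
    truth = SimTruth(
        cells=cells[["barcode", "donor", "condition", "cell_type", "is_subtype"]].copy(),
        proportions=pd.DataFrame(prop_rows),
        de_ledger=pd.DataFrame(
            [
                {"cell_type": e.cell_type, "gene": e.gene, "condition": e.condition, "beta": e.beta}
                for e in config.de_effects
            ],
            columns=["cell_type", "gene", "condition", "beta"],
        ),
        outlier_donor=config.outlier.donor if config.outlier is not None else None,
    )
    return matrices, cells, truth


def simulate_composition(config: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw only per-donor cell-type counts (no gene expression).

    Uses the same weight machinery as :func:`simulate`; suited to power and
    type-I-error studies of the composition stage where gene-level counts
    are irrelevant.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    types = config.cell_types
    rows = []
    for donor in config.donors:
        w = _donor_weights(config, donor, rng)
        n = rng.multinomial(donor.n_cells, w)
        for t_i, t in enumerate(types):
            rows.append(
                {
                    "donor": donor.donor,
                    "condition": donor.condition,
                    "cell_type": t,
                    "n_cells": int(n[t_i]),
                    "proportion": n[t_i] / donor.n_cells,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Default fixture


def _default_gene_list(n_genes: int, n_mito: int, marker_map: dict[str, list[str]]) -> list[str]:
    genes = [f"{MITO_PREFIX}{i + 1}" for i in range(n_mito)]
    genes += ["TBX21", "RUNX1"]
    for ms in marker_map.values():
        genes += ms
    n_filler = n_genes - len(genes)
    if n_filler < 0:
        raise ConfigError("n_genes too small for markers + mito + gating genes")
    genes += [f"G{i + 1:03d}" for i in range(n_filler)]
    return genes


DEFAULT_MARKERS: dict[str, list[str]] = {
    "T_cell": ["CD3D", "CD3E", "CD2", "TRAC", "IL7R"],
    "macrophage": ["CD68", "LYZ", "C1QA", "C1QB", "MRC1"],
    "fibroblast": ["DCN", "COL1A1", "PDGFRA", "LUM", "GSN"],
    "endothelial": ["PECAM1", "VWF", "CDH5", "EGFL7", "FLT1"],
    "cardiomyocyte": ["TNNT2", "MYH7", "TTN", "ACTC1", "RYR2"],
}


def default_fixture(
    seed: int = 1,
    n_genes: int = 300,
    n_donors: int = 4,
    n_cells_per_donor: int = 400,
    outlier: bool = False,
    null: bool = False,
) -> SimulationConfig:
    """Small standard configuration exercising the full pipeline.

    ~300 genes (10 mitochondrial), 5 cell types including a high-mito
    cardiomyocyte-like type, 4 donors per condition at ~400 cells each, a
    2x disease shift of the T-cell mixture weight, 20 planted DE genes at
    |beta| >= 1.2 (10 in T cells, 10 in macrophages, disease only), and a
    7% TBX21+RUNX1+ subtype among disease T cells.  With ``null=True`` all
    effects (shift, DE, subtype) are switched off.  With ``outlier=True``
    one control donor's T-cell weight is inflated 20x so Grubbs screening
    has a true positive.
    """
    marker_map = {k: list(v) for k, v in DEFAULT_MARKERS.items()}
    genes = _default_gene_list(n_genes, n_mito=10, marker_map=marker_map)
    gidx = {g: i for i, g in enumerate(genes)}
    prof_rng = np.random.default_rng(777)  # fixed: profiles are part of the fixture
    baseline = prof_rng.lognormal(0.0, 0.5, n_genes)
    baseline[[gidx["TBX21"], gidx["RUNX1"]]] = 0.0  # gate genes silent outside the subtype

    profiles: dict[str, np.ndarray] = {}
    for t, ms in marker_map.items():
        p = baseline.copy()
        for other, oms in marker_map.items():
            for g in oms:
                p[gidx[g]] = 30.0 if other == t else 0.0
        profiles[t] = p

    import re

    filler = [g for g in genes if re.fullmatch(r"G\d+", g)]  # generated filler genes only
    betas = [1.5, -1.5, 2.0, -2.0, 1.2, -1.2, 1.8, -1.8, 1.5, -1.5]
    de_effects = [
        DEEffect("T_cell", filler[i], "disease", betas[i]) for i in range(10)
    ] + [
        DEEffect("macrophage", filler[10 + i], "disease", betas[i]) for i in range(10)
    ]

    cfg = SimulationConfig(
        genes=genes,
        profiles=profiles,
        markers=marker_map,
        mixture_weights={
            "T_cell": 0.20,
            "macrophage": 0.25,
            "fibroblast": 0.15,
            "endothelial": 0.10,
            "cardiomyocyte": 0.30,
        },
        proportion_shift={"T_cell": 2.0},
        donors=[
            DonorSpec(f"ctrl{i + 1}", "control", n_cells_per_donor) for i in range(n_donors)
        ]
        + [DonorSpec(f"dis{i + 1}", "disease", n_cells_per_donor) for i in range(n_donors)],
        de_effects=de_effects,
        subtype=SubtypeSpec(
            parent="T_cell",
            gene_a="TBX21",
            gene_b="RUNX1",
            frequency={"control": 0.0, "disease": 0.07},
            weight=0.008,
        ),
        mito_level={
            "T_cell": 0.03,
            "macrophage": 0.03,
            "fibroblast": 0.03,
            "endothelial": 0.03,
            "cardiomyocyte": 0.40,
        },
        dispersion=2.0,
        library_meanlog=7.6,
        library_sdlog=0.35,
        donor_concentration=200.0,
        outlier=OutlierSpec("ctrl1", "T_cell", 20.0) if outlier else None,
        seed=seed,
    )
    if null:
        cfg = replace(cfg, proportion_shift={}, de_effects=[], subtype=None, outlier=None)
    return cfg


def write_truth(truth: SimTruth, dir_path) -> dict[str, str]:
    """Write the ground-truth ledger as TSVs (cells, proportions, DE)."""
    from pathlib import Path

    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    paths = {
        "cells": dir_path / "truth_cells.tsv",
        "proportions": dir_path / "truth_proportions.tsv",
        "de_ledger": dir_path / "truth_de_ledger.tsv",
    }
    truth.cells.to_csv(paths["cells"], sep="\t", index=False)
    truth.proportions.to_csv(paths["proportions"], sep="\t", index=False)
    truth.de_ledger.to_csv(paths["de_ledger"], sep="\t", index=False)
    if truth.outlier_donor is not None:
        (dir_path / "truth_outlier.txt").write_text(truth.outlier_donor + "\n")
        paths["outlier"] = dir_path / "truth_outlier.txt"
    return {k: str(v) for k, v in paths.items()}
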