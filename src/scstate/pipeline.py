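"""Stage orchestration behind the command-line interface.

Stages run in dependency order (simulate|ingest → qc → annotate → de →
ges → tfs → composition), exchange plain-text artifacts under one output
directory, and record every output in a manifest with content hashes,
seeds and the package version.  All randomness flows from the config seed,
so a rerun with identical config and inputs reproduces identical result
files.  The two-pass QC scheme is expressed as stage ordering: threshold
QC first, then annotation, then the deferred mitochondrial cut.
"""

from __future__ import annotations

import copy
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import scstate
from scstate import composition as comp
from scstate import synthetic
from scstate.annotate import annotate_clusters, coexpression_gate, log_normalize
from scstate.diffexp import find_markers
from scstate.enrichment import ges_table
from scstate.io_formats import (
    CountMatrix,
    read_gene_sets,
    read_marker_map,
    read_mtx_triplet,
    read_sample_sheet,
    read_tf_catalog,
    sha256_file,
    write_gene_sets,
    write_marker_map,
    write_mtx_triplet,
    DirectedGeneSet,
)
from scstate.qc import QCThresholds, apply_thresholds, compute_metrics, deferred_mito_filter, downsample
from scstate.tf_specificity import condition_specific_tfs


class DependencyError(RuntimeError):
    """A requested stage is missing an upstream output."""


STAGES = ("simulate", "qc", "annotate", "de", "ges", "tfs", "composition")

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "simulate": {"n_genes": 300, "n_donors": 4, "n_cells_per_donor": 400, "outlier": False},
    "qc": {
        "mito_prefix": "MT-",
        "thresholds": {
            "control": {"min_features": 100, "max_pct_mito": 5.0, "defer_mito": True},
            "disease": {"min_features": 100, "max_pct_mito": 10.0, "defer_mito": True},
        },
        "mito_exempt_labels": ["cardiomyocyte"],
        "downsample": {},
    },
    "annotate": {
        "marker_map": None,
        "scale_factor": 10000.0,
        "gate": {"gene_a": "TBX21", "gene_b": "RUNX1", "threshold": 0.0, "parent": "T_cell"},
    },
    "de": {"alpha": 0.05, "method": "bonferroni", "pseudocount": 1.0, "min_cells": 10},
    "ges": {"gene_sets": None, "significant_only": True, "normalizer": "set"},
    "tfs": {"catalog": None, "alpha": 0.05},
    "composition": {"alpha": 0.05, "grubbs_alpha": 0.05, "screen_outliers": True},
    "inputs": {"sample_sheet": None, "cells": None},
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


class Pipeline:
    """Run analysis stages against one output directory."""

    def __init__(self, config: dict, outdir: str | Path):
        self.config = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)

    # -- manifest ----------------------------------------------------------

    @property
    def manifest_path(self) -> Path:
        return self.outdir / "manifest.tsv"

    def _record(self, stage: str, paths: list[Path], seed: int | None) -> None:
        import datetime

        rows = [
            {
                "stage": stage,
                "path": str(p.relative_to(self.outdir)),
                "sha256": sha256_file(p),
                "seed": "" if seed is None else seed,
                "version": scstate.__version__,
                "recorded_at": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            }
            for p in paths
        ]
        new = pd.DataFrame(rows)
        if self.manifest_path.exists():
            old = pd.read_csv(self.manifest_path, sep="\t", dtype=str)
            old = old[old["stage"] != stage]
            new = pd.concat([old, new.astype(str)], ignore_index=True)
        new.to_csv(self.manifest_path, sep="\t", index=False)

    def _require(self, stage: str, *paths: Path) -> None:
        missing = [str(p) for p in paths if not p.exists()]
        if missing:
            raise DependencyError(
                f"stage {stage!r} is missing upstream outputs: {missing}; "
                "run the producing stage first"
            )

    # -- stage: simulate ---------------------------------------------------

    def stage_simulate(self) -> None:
        sc = self.config["simulate"]
        cfg = synthetic.default_fixture(
            seed=int(self.config["seed"]),
            n_genes=int(sc["n_genes"]),
            n_donors=int(sc["n_donors"]),
            n_cells_per_donor=int(sc["n_cells_per_donor"]),
            outlier=bool(sc["outlier"]),
        )
        matrices, cells, truth = synthetic.simulate(cfg)
        sim_dir = self.outdir / "sim"
        sim_dir.mkdir(parents=True, exist_ok=True)
        paths: list[Path] = []
        sheet_rows = []
        for m, donor in zip(matrices, cfg.donors):
            triplet = write_mtx_triplet(m, sim_dir / donor.donor)
            paths.extend(triplet.values())
            sheet_rows.append(
                {
                    "sample_id": donor.donor,
                    "condition": donor.condition,
                    "tissue": "synthetic",
                    "path": str((sim_dir / donor.donor).relative_to(self.outdir)),
                }
            )
        sheet = sim_dir / "sample_sheet.tsv"
        pd.DataFrame(sheet_rows).to_csv(sheet, sep="\t", index=False)
        cells_path = sim_dir / "cells.tsv"
        cells.to_csv(cells_path, sep="\t", index=False)
        truth_paths = synthetic.write_truth(truth, sim_dir)
        markers_path = write_marker_map(cfg.markers, sim_dir / "markers.tsv")
        sets_path = write_gene_sets(self._fixture_gene_sets(truth), sim_dir / "gene_sets.gmt")
        catalog_path = sim_dir / "tf_catalog.txt"
        catalog_path.write_text("".join(s + "\n" for s in self._fixture_tf_catalog(cfg, truth)))
        paths += [sheet, cells_path, markers_path, sets_path, catalog_path]
        paths += [Path(p) for p in truth_paths.values()]
        self._record("simulate", paths, seed=int(self.config["seed"]))

    @staticmethod
    def _fixture_gene_sets(truth: synthetic.SimTruth) -> list[DirectedGeneSet]:
        """Directed sets built from the planted-effect ledger.

        For each cell type with planted effects: an "up program" whose
        members are the up genes as activators plus the down genes as
        repressors (expected strongly positive GES), and a "down program"
        listing the down genes as activators (expected negative GES).
        """
        sets = []
        ledger = truth.de_ledger
        for cell_type, sub in ledger.groupby("cell_type"):
            up = sub[sub["beta"] > 0]["gene"].tolist()
            down = sub[sub["beta"] < 0]["gene"].tolist()
            members = [(g, "activator") for g in up] + [(g, "repressor") for g in down]
            if members:
                sets.append(
                    DirectedGeneSet(
                        name=f"{cell_type}_disease_program",
                        members=members,
                        description="planted up-genes as activators, down-genes as repressors",
                    )
                )
            if down:
                sets.append(
                    DirectedGeneSet(
                        name=f"{cell_type}_suppressed_program",
                        members=[(g, "activator") for g in down],
                        description="planted down-genes as activators",
                    )
                )
        return sets

    @staticmethod
    def _fixture_tf_catalog(cfg: synthetic.SimulationConfig, truth: synthetic.SimTruth) -> list[str]:
        """Catalog mixing planted disease-only genes, markers, and inert genes."""
        catalog = list(dict.fromkeys(truth.de_ledger["gene"].tolist()))
        catalog += [ms[0] for ms in cfg.markers.values()]  # significant in both conditions
        import re

        inert = [g for g in cfg.genes if re.fullmatch(r"G\d+", g) and g not in set(catalog)][:5]
        return catalog + inert

    # -- stage: qc ---------------------------------------------------------

    def _sample_sheet(self) -> pd.DataFrame:
        external = self.config["inputs"]["sample_sheet"]
        path = Path(external) if external else self.outdir / "sim" / "sample_sheet.tsv"
        self._require("qc", path)
        return read_sample_sheet(path)

    def _cells_table(self) -> pd.DataFrame:
        external = self.config["inputs"]["cells"]
        path = Path(external) if external else self.outdir / "sim" / "cells.tsv"
        self._require("qc", path)
        return pd.read_csv(path, sep="\t")

    def stage_qc(self) -> None:
        qcfg = self.config["qc"]
        sheet = self._sample_sheet()
        cells = self._cells_table().set_index("barcode")
        seed = int(self.config["seed"])
        kept_matrices: dict[str, list[CountMatrix]] = {"control": [], "disease": []}
        reports = []
        for _, row in sheet.iterrows():
            base = Path(row["path"])
            if not base.is_absolute():
                base = self.outdir / base
            m = read_mtx_triplet(
                base / "matrix.mtx", base / "features.tsv", base / "barcodes.tsv", row["sample_id"]
            )
            metrics = compute_metrics(m, mito_prefix=qcfg["mito_prefix"])
            t = QCThresholds(
                **qcfg["thresholds"].get(row["condition"], {}),
                mito_exempt_labels=tuple(qcfg["mito_exempt_labels"]),
            )
            keep = apply_thresholds(metrics, t)
            metrics["kept"] = keep
            metrics["condition"] = row["condition"]
            reports.append(metrics)
            kept_matrices[row["condition"]].append(m.subset_cells(np.flatnonzero(keep)))
        merged_parts = []
        for condition in ("control", "disease"):
            if not kept_matrices[condition]:
                continue
            merged = CountMatrix.concat(kept_matrices[condition])
            target = qcfg["downsample"].get(condition)
            if target is not None:
                offset = {"control": 101, "disease": 202}[condition]
                merged = downsample(merged, int(target), seed=seed + offset)
            merged_parts.append(merged)
        merged = CountMatrix.concat(merged_parts)
        qc_dir = self.outdir / "qc"
        qc_dir.mkdir(parents=True, exist_ok=True)
        report = pd.concat(reports, ignore_index=True)
        report_path = qc_dir / "qc_report.tsv"
        report.to_csv(report_path, sep="\t", index=False, float_format="%.6g")
        triplet = write_mtx_triplet(merged, qc_dir / "merged")
        kept_cells = cells.loc[merged.barcodes].reset_index()
        metrics_kept = report.set_index("barcode").loc[merged.barcodes]
        for col in ("n_features", "n_counts", "pct_mito"):
            kept_cells[col] = metrics_kept[col].to_numpy()
        cells_path = qc_dir / "cells.tsv"
        kept_cells.to_csv(cells_path, sep="\t", index=False, float_format="%.6g")
        self._record("qc", [report_path, cells_path, *triplet.values()], seed=seed)

    # -- stage: annotate ---------------------------------------------------

    def _read_merged(self) -> CountMatrix:
        base = self.outdir / "qc" / "merged"
        self._require("annotate", base / "matrix.mtx")
        return read_mtx_triplet(base / "matrix.mtx", base / "features.tsv", base / "barcodes.tsv")

    def stage_annotate(self) -> None:
        acfg = self.config["annotate"]
        qcfg = self.config["qc"]
        cells_path = self.outdir / "qc" / "cells.tsv"
        self._require("annotate", cells_path)
        cells = pd.read_csv(cells_path, sep="\t")
        m = self._read_merged()
        norm = log_normalize(m, scale_factor=float(acfg["scale_factor"]))
        marker_path = acfg["marker_map"] or self.outdir / "sim" / "markers.tsv"
        self._require("annotate", Path(marker_path))
        markers = read_marker_map(marker_path)
        assignment, scores = annotate_clusters(norm, cells["cluster"].to_numpy(), markers)
        cells["cell_type"] = [assignment[c] for c in cells["cluster"]]

        # deferred mitochondrial cut, per condition, exempt labels kept
        keep = np.ones(len(cells), dtype=bool)
        for condition in cells["condition"].unique():
            tdict = dict(qcfg["thresholds"].get(condition, {}))
            t = QCThresholds(**tdict, mito_exempt_labels=tuple(qcfg["mito_exempt_labels"]))
            if not t.defer_mito:
                continue
            mask = (cells["condition"] == condition).to_numpy()
            sub = cells.loc[mask]
            keep[mask] = deferred_mito_filter(
                sub[["n_features", "n_counts", "pct_mito"]].assign(barcode=sub["barcode"]),
                sub["cell_type"].tolist(),
                t,
            )
        cells = cells.loc[keep].reset_index(drop=True)
        m2 = m.subset_cells(np.flatnonzero(keep))
        norm2 = log_normalize(m2, scale_factor=float(acfg["scale_factor"]))
        gate = acfg["gate"]
        cells["is_gated_subtype"] = coexpression_gate(
            norm2, gate["gene_a"], gate["gene_b"], threshold=float(gate["threshold"])
        )
        ann_dir = self.outdir / "annotate"
        ann_dir.mkdir(parents=True, exist_ok=True)
        out_cells = ann_dir / "cells.tsv"
        cells.to_csv(out_cells, sep="\t", index=False, float_format="%.6g")
        scores_path = ann_dir / "cluster_scores.tsv"
        scores.to_csv(scores_path, sep="\t", index=False, float_format="%.6g")
        triplet = write_mtx_triplet(m2, ann_dir / "filtered")
        self._record("annotate", [out_cells, scores_path, *triplet.values()], seed=None)

    # -- stage: de ---------------------------------------------------------

    def _annotated(self) -> tuple[CountMatrix, pd.DataFrame]:
        base = self.outdir / "annotate"
        self._require("de", base / "cells.tsv", base / "filtered" / "matrix.mtx")
        cells = pd.read_csv(base / "cells.tsv", sep="\t")
        m = read_mtx_triplet(
            base / "filtered" / "matrix.mtx",
            base / "filtered" / "features.tsv",
            base / "filtered" / "barcodes.tsv",
        )
        return m, cells

    def stage_de(self) -> None:
        dcfg = self.config["de"]
        m, cells = self._annotated()
        norm = log_normalize(m, scale_factor=float(self.config["annotate"]["scale_factor"]))
        de_dir = self.outdir / "de"
        de_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for cell_type in sorted(cells["cell_type"].unique()):
            g_dis = ((cells["cell_type"] == cell_type) & (cells["condition"] == "disease")).to_numpy()
            g_ctl = ((cells["cell_type"] == cell_type) & (cells["condition"] == "control")).to_numpy()
            if g_dis.sum() < int(dcfg["min_cells"]) or g_ctl.sum() < int(dcfg["min_cells"]):
                continue
            de = find_markers(
                norm,
                g_dis,
                g_ctl,
                alpha=float(dcfg["alpha"]),
                method=dcfg["method"],
                pseudocount=float(dcfg["pseudocount"]),
            )
            path = de_dir / f"{cell_type}__disease_vs_control.tsv"
            de.to_csv(path, sep="\t", index=False, float_format="%.6g")
            paths.append(path)
        if not paths:
            raise DependencyError("stage 'de': no cell type has enough cells in both conditions")
        self._record("de", paths, seed=None)

    # -- stage: ges --------------------------------------------------------

    def stage_ges(self) -> None:
        gcfg = self.config["ges"]
        de_dir = self.outdir / "de"
        self._require("ges", de_dir)
        de_paths = sorted(de_dir.glob("*__disease_vs_control.tsv"))
        if not de_paths:
            raise DependencyError("stage 'ges': no DE output present; run 'de' first")
        sets_path = gcfg["gene_sets"] or self.outdir / "sim" / "gene_sets.gmt"
        self._require("ges", Path(sets_path))
        sets = read_gene_sets(sets_path)
        de_by_comp = {p.stem: pd.read_csv(p, sep="\t") for p in de_paths}
        table = ges_table(
            de_by_comp,
            sets,
            significant_only=bool(gcfg["significant_only"]),
            normalizer=gcfg["normalizer"],
        )
        ges_dir = self.outdir / "ges"
        ges_dir.mkdir(parents=True, exist_ok=True)
        path = ges_dir / "ges_table.tsv"
        table.to_csv(path, sep="\t", index=False, float_format="%.6g")
        self._record("ges", [path], seed=None)

    # -- stage: tfs --------------------------------------------------------

    def stage_tfs(self) -> None:
        tcfg = self.config["tfs"]
        m, cells = self._annotated()
        catalog_path = tcfg["catalog"] or self.outdir / "sim" / "tf_catalog.txt"
        self._require("tfs", Path(catalog_path))
        catalog = read_tf_catalog(catalog_path)
        norm = log_normalize(m, scale_factor=float(self.config["annotate"]["scale_factor"]))
        min_cells = int(self.config["de"]["min_cells"])
        rows = []
        for cell_type in sorted(cells["cell_type"].unique()):
            per_condition = {}
            for condition in ("control", "disease"):
                in_cond = (cells["condition"] == condition).to_numpy()
                g1 = in_cond & (cells["cell_type"] == cell_type).to_numpy()
                g2 = in_cond & (cells["cell_type"] != cell_type).to_numpy()
                if g1.sum() < min_cells or g2.sum() < min_cells:
                    per_condition[condition] = None
                    continue
                per_condition[condition] = find_markers(
                    norm, g1, g2, alpha=float(tcfg["alpha"]), method=self.config["de"]["method"]
                )
            if per_condition.get("disease") is None:
                continue
            ctl = per_condition.get("control")
            if ctl is None:
                ctl = pd.DataFrame(columns=["gene", "log2_fc", "adjusted_p"])
            result = condition_specific_tfs(
                per_condition["disease"], ctl, catalog, alpha=float(tcfg["alpha"])
            )
            if not result.empty:
                result.insert(0, "cell_type", cell_type)
                rows.append(result)
        table = (
            pd.concat(rows, ignore_index=True)
            if rows
            else pd.DataFrame(
                columns=["cell_type", "tf", "disease_adjusted_p", "disease_log2_fc", "control_adjusted_p"]
            )
        )
        tf_dir = self.outdir / "tfs"
        tf_dir.mkdir(parents=True, exist_ok=True)
        path = tf_dir / "condition_specific_tfs.tsv"
        table.to_csv(path, sep="\t", index=False, float_format="%.6g")
        self._record("tfs", [path], seed=None)

    # -- stage: composition ------------------------------------------------

    def stage_composition(self) -> None:
        ccfg = self.config["composition"]
        cells_path = self.outdir / "annotate" / "cells.tsv"
        self._require("composition", cells_path)
        cells = pd.read_csv(cells_path, sep="\t")
        out_dir = self.outdir / "composition"
        out_dir.mkdir(parents=True, exist_ok=True)
        pt = comp.proportion_table(cells, level="cell_type")
        report = comp.composition_report(
            pt,
            screen_outliers=bool(ccfg["screen_outliers"]),
            alpha=float(ccfg["alpha"]),
            grubbs_alpha=float(ccfg["grubbs_alpha"]),
        )
        paths = []
        pt_path = out_dir / "proportions.tsv"
        pt.to_csv(pt_path, sep="\t", index=False, float_format="%.6g")
        rp_path = out_dir / "report.tsv"
        report.to_csv(rp_path, sep="\t", index=False, float_format="%.6g")
        paths += [pt_path, rp_path]
        parent = self.config["annotate"]["gate"].get("parent")
        if parent and "is_gated_subtype" in cells.columns:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # donors with no parent cells are expected
                sub_pt = comp.proportion_table(cells, level="is_gated_subtype", parent=parent)
            sub_pt = sub_pt[sub_pt["cell_type"] == True]  # noqa: E712 — gated fraction rows
            sub_path = out_dir / "subtype_proportions.tsv"
            sub_pt.to_csv(sub_path, sep="\t", index=False, float_format="%.6g")
            paths.append(sub_path)
        self._record("composition", paths, seed=None)

    # -- driver ------------------------------------------------------------

    def run(self, stages: list[str] | None = None) -> Path:
        stages = list(stages or STAGES)
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for stage in STAGES:  # dependency order
            if stage in stages:
                getattr(self, f"stage_{stage}")()
        return self.manifest_path


def run(config: dict, outdir: str | Path, stages: list[str] | None = None) -> Path:
    """Run the requested stages; returns the manifest path."""
    return Pipeline(config, outdir).run(stages)
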