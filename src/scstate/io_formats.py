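"""Readers and writers for the plain-text formats the pipeline touches.

Count matrices travel as 10x-style Matrix Market triplets (``matrix.mtx`` +
``features.tsv`` + ``barcodes.tsv``, optionally gzipped), gene sets as GMT
with a ``|rep`` member suffix marking repressors, transcription-factor
catalogs as one symbol per line, and sample sheets as TSV.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

CONDITIONS = ("control", "disease")


class FormatError(ValueError):
    """A file violates its declared format or an invariant of its type."""


@dataclass
class CountMatrix:
    """Sparse gene-by-cell matrix of non-negative integer UMI counts.

    Genes are rows and cells are columns (10x convention).  Gene symbols and
    barcodes are unique and ordered; ``counts`` is stored CSC with int64 data.
    """

    genes: list[str]
    barcodes: list[str]
    counts: sparse.csc_matrix
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.counts = sparse.csc_matrix(self.counts)
        self.validate()

    def validate(self) -> None:
        if self.counts.shape != (len(self.genes), len(self.barcodes)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.barcodes)} barcodes"
            )
        if len(set(self.genes)) != len(self.genes):
            raise FormatError("gene symbols are not unique")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise FormatError("barcodes are not unique")
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                raise FormatError("negative counts")
            if not np.allclose(data, np.round(data)):
                raise FormatError("non-integer counts")
        self.counts = self.counts.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not present in matrix") from None

    def subset_cells(self, indices: Sequence[int]) -> "CountMatrix":
        idx = np.asarray(indices, dtype=int)
        return CountMatrix(
            genes=list(self.genes),
            barcodes=[self.barcodes[i] for i in idx],
            counts=self.counts[:, idx],
            sample_id=self.sample_id,
        )

    @classmethod
    def concat(cls, matrices: Sequence["CountMatrix"]) -> "CountMatrix":
        """Column-concatenate per-sample matrices sharing one gene list."""
        if not matrices:
            raise ValueError("no matrices to concatenate")
        genes = matrices[0].genes
        for m in matrices[1:]:
            if m.genes != genes:
                raise FormatError("cannot concatenate matrices with differing gene lists")
        barcodes = [b for m in matrices for b in m.barcodes]
        counts = sparse.hstack([m.counts for m in matrices], format="csc")
        return cls(genes=list(genes), barcodes=barcodes, counts=counts, sample_id="")


@dataclass
class DirectedGeneSet:
    """Named gene set whose members carry an activator/repressor direction."""

    name: str
    members: list[tuple[str, str]] = field(default_factory=list)
    description: str = ""

    def __post_init__(self) -> None:
        symbols = [g for g, _ in self.members]
        if len(set(symbols)) != len(symbols):
            raise FormatError(f"duplicate member in gene set {self.name!r}")
        for g, d in self.members:
            if d not in ("activator", "repressor"):
                raise FormatError(f"bad direction {d!r} for {g!r} in set {self.name!r}")

    @property
    def symbols(self) -> list[str]:
        return [g for g, _ in self.members]

    def direction(self, gene: str) -> str:
        for g, d in self.members:
            if g == gene:
                return d
        raise KeyError(gene)


def _open_text(path: str | Path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _read_column(path: str | Path) -> list[str]:
    """Read one entry per line; for multi-column 10x features take field 2."""
    out = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            out.append(parts[1] if len(parts) >= 2 else parts[0])
    return out


def read_mtx_triplet(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    sample_id: str = "",
) -> CountMatrix:
    """Read a Matrix Market coordinate triplet into a :class:`CountMatrix`.

    Entries absent from the coordinate section are zero.  Indices are 1-based
    on disk and 0-based in memory.  Gzipped files are accepted transparently.
    """
    with _open_text(matrix_path, "rb") as fh:
        try:
            raw = spio.mmread(fh)
        except Exception as exc:  # scipy raises assorted ValueError subclasses
            raise FormatError(f"cannot parse Matrix Market file {matrix_path}: {exc}") from exc
    mat = sparse.coo_matrix(raw)
    genes = _read_column(features_path)
    barcodes = _read_column(barcodes_path)
    if mat.shape[0] != len(genes):
        raise FormatError(
            f"matrix declares {mat.shape[0]} rows but features file has {len(genes)} entries"
        )
    if mat.shape[1] != len(barcodes):
        raise FormatError(
            f"matrix declares {mat.shape[1]} columns but barcodes file has {len(barcodes)} entries"
        )
    return CountMatrix(genes=genes, barcodes=barcodes, counts=mat.tocsc(), sample_id=sample_id)


def write_mtx_triplet(m: CountMatrix, dir_path: str | Path) -> dict[str, Path]:
    """Write ``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv`` under *dir_path*.

    ``read_mtx_triplet`` on the result reproduces *m* exactly.
    """
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": dir_path / "matrix.mtx",
        "features": dir_path / "features.tsv",
        "barcodes": dir_path / "barcodes.tsv",
    }
    spio.mmwrite(str(paths["matrix"]), m.counts.tocoo(), field="integer")
    paths["features"].write_text("".join(g + "\n" for g in m.genes))
    paths["barcodes"].write_text("".join(b + "\n" for b in m.barcodes))
    return paths


REPRESSOR_SUFFIX = "|rep"


def read_gene_sets(path: str | Path) -> list[DirectedGeneSet]:
    """Parse a GMT file; members suffixed ``|rep`` are repressors.

    Standard GMT layout: name TAB description TAB member [TAB member ...].
    """
    sets: list[DirectedGeneSet] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: gene set with no members")
            name, description = parts[0], parts[1]
            members: list[tuple[str, str]] = []
            for token in parts[2:]:
                if not token:
                    continue
                if token.endswith(REPRESSOR_SUFFIX):
                    members.append((token[: -len(REPRESSOR_SUFFIX)], "repressor"))
                else:
                    members.append((token, "activator"))
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            try:
                sets.append(DirectedGeneSet(name=name, members=members, description=description))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return sets


def write_gene_sets(sets: Iterable[DirectedGeneSet], path: str | Path) -> Path:
    path = Path(path)
    lines = []
    for s in sets:
        tokens = [g + (REPRESSOR_SUFFIX if d == "repressor" else "") for g, d in s.members]
        lines.append("\t".join([s.name, s.description or "."] + tokens))
    path.write_text("".join(line + "\n" for line in lines))
    return path


def read_tf_catalog(path: str | Path) -> frozenset[str]:
    """Read a transcription-factor catalog: one gene symbol per line."""
    symbols = []
    with _open_text(path) as fh:
        for line in fh:
            sym = line.strip()
            if sym:
                symbols.append(sym)
    if not symbols:
        raise FormatError(f"TF catalog {path} is empty")
    if len(set(symbols)) != len(symbols):
        raise FormatError(f"TF catalog {path} contains duplicate symbols")
    return frozenset(symbols)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read the sample sheet TSV: sample_id, condition, tissue, path."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "condition", "tissue", "path"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise FormatError("sample sheet has duplicate sample_ids")
    bad = set(df["condition"]) - set(CONDITIONS)
    if bad:
        raise FormatError(f"sample sheet has unknown conditions: {sorted(bad)}")
    return df


def read_marker_map(path: str | Path) -> dict[str, list[str]]:
    """Read a marker map TSV: cell-type label TAB comma-separated markers."""
    markers: dict[str, list[str]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected label TAB markers")
            label = parts[0]
            genes = [g.strip() for g in parts[1].split(",") if g.strip()]
            if not genes:
                raise FormatError(f"{path}:{lineno}: no markers for label {label!r}")
            if label in markers:
                raise FormatError(f"{path}:{lineno}: duplicate label {label!r}")
            markers[label] = genes
    return markers


def write_marker_map(markers: dict[str, list[str]], path: str | Path) -> Path:
    path = Path(path)
    path.write_text("".join(f"{label}\t{','.join(genes)}\n" for label, genes in markers.items()))
    return path


def sha256_file(path: str | Path) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
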