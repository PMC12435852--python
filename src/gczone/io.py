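"""Shared data model and on-disk formats.

The central container is :class:`CellTable`: one pre-cropped germinal center
(GC) with per-cell x/y positions in micrometers, a cells x genes count
matrix (dense or scipy sparse) and a free-form per-cell metadata frame.
Gene signatures are directed gene lists (DZ-up or LZ-up) read from GMT or
two-column TSV files.  A packaged synthetic stand-in for the published
370-gene DZ/LZ spatial signature (169 dark-zone, 201 light-zone genes) ships
with the library for self-contained runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger(__name__)

__version__ = "0.1.0"

DZ_UP = "DZ_up"
LZ_UP = "LZ_up"
DIRECTIONS = (DZ_UP, LZ_UP)

#: packaged synthetic stand-in signature file (real set sizes, curated +
#: placeholder symbols; see data/dz_lz_signature_synthetic.gmt)
PACKAGED_SIGNATURE_RESOURCE = "dz_lz_signature_synthetic.gmt"


class GCZoneError(ValueError):
    """Base class for input-contract violations."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSignature:
    """A named, directed gene set (DZ-up or LZ-up)."""

    name: str
    genes: tuple[str, ...]
    direction: str

    def __post_init__(self):
        if self.direction not in DIRECTIONS:
            raise GCZoneError(
                f"signature {self.name!r}: direction must be one of {DIRECTIONS}, "
                f"got {self.direction!r}"
            )
        if len(self.genes) == 0:
            raise GCZoneError(f"signature {self.name!r} is empty")
        seen, dups = set(), []
        for g in self.genes:
            if g in seen:
                dups.append(g)
            seen.add(g)
        if dups:
            raise GCZoneError(
                f"signature {self.name!r} contains duplicate genes: {sorted(set(dups))}"
            )

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class CellTable:
    """Positions, counts and metadata for the cells of one tissue/GC.

    ``counts`` is cells x genes, non-negative integers, dense ndarray or any
    scipy sparse matrix.  ``metadata`` is indexed like ``cell_ids`` and may
    carry subtype labels, GC ids, etc.
    """

    cell_ids: np.ndarray
    x: np.ndarray
    y: np.ndarray
    counts: object  # ndarray or scipy.sparse matrix, cells x genes
    gene_ids: np.ndarray
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not sparse.issparse(self.counts):
            self.counts = np.asarray(self.counts)
        n, g = self.counts.shape
        if len(self.cell_ids) != n:
            raise GCZoneError(
                f"{len(self.cell_ids)} cell ids but {n} count-matrix rows"
            )
        if len(self.gene_ids) != g:
            raise GCZoneError(
                f"{len(self.gene_ids)} gene ids but {g} count-matrix columns"
            )
        for label, ids in (("cell", self.cell_ids), ("gene", self.gene_ids)):
            if len(set(ids)) != len(ids):
                raise GCZoneError(f"duplicate {label} ids")
        if self.x.shape != (n,) or self.y.shape != (n,):
            raise GCZoneError("x/y must be one value per cell")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise GCZoneError("non-finite cell coordinates")
        if self.counts_min() < 0:
            raise GCZoneError("negative counts")
        if self.metadata is None or len(self.metadata) == 0:
            self.metadata = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))
        elif len(self.metadata) != n:
            raise GCZoneError("metadata rows do not match cells")

    # -- small helpers -----------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def counts_dense(self) -> np.ndarray:
        if sparse.issparse(self.counts):
            return np.asarray(self.counts.todense())
        return np.asarray(self.counts)

    def counts_min(self) -> float:
        if sparse.issparse(self.counts):
            return self.counts.min() if self.counts.nnz else 0
        return float(self.counts.min()) if self.counts.size else 0.0

    def subset(self, mask: np.ndarray) -> "CellTable":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CellTable(
            cell_ids=self.cell_ids[idx],
            x=self.x[idx],
            y=self.y[idx],
            counts=self.counts[idx],
            gene_ids=self.gene_ids,
            metadata=self.metadata.iloc[idx].copy(),
        )

    def equals(self, other: "CellTable") -> bool:
        return (
            np.array_equal(self.cell_ids, other.cell_ids)
            and np.array_equal(self.gene_ids, other.gene_ids)
            and np.allclose(self.x, other.x)
            and np.allclose(self.y, other.y)
            and np.array_equal(self.counts_dense(), other.counts_dense())
            and self.metadata.reset_index(drop=True).equals(
                other.metadata.reset_index(drop=True)
            )
        )


@dataclass
class ResultReport:
    """Structured, JSON-serializable record of one pipeline run."""

    parameters: dict = field(default_factory=dict)
    seed: int | None = None
    version: str = __version__
    scores: dict = field(default_factory=dict)
    regions: dict = field(default_factory=dict)
    boundary: list = field(default_factory=list)
    profiles: dict = field(default_factory=dict)
    exclusion: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = json.dumps(dataclasses.asdict(self), default=_jsonify, indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "ResultReport":
        text = Path(source).read_text() if isinstance(source, (str, Path)) and "\n" not in str(source) and Path(str(source)).exists() else str(source)
        return cls(**json.loads(text))


def _jsonify(obj):
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_cell_table(matrix_path, cells_path, genes_path=None) -> CellTable:
    """Read a CellTable from an MTX triplet or a dense CSV matrix.

    ``matrix_path`` ending in ``.mtx`` is a MatrixMarket coordinate file with
    cells as rows; ``genes_path`` is then required (one gene id per line, no
    header).  A ``.csv`` matrix is dense with a header row of gene ids and a
    first column of cell ids.  ``cells_path`` is a CSV with at least
    ``cell_id``, ``x`` and ``y`` columns; extra columns become metadata.
    """
    matrix_path, cells_path = Path(matrix_path), Path(cells_path)
    for p in (matrix_path, cells_path):
        if not p.exists():
            raise FileNotFoundError(f"missing input file: {p}")

    # keep empty strings (e.g. "no subtype") instead of coercing them to NaN
    cells_df = pd.read_csv(cells_path, keep_default_na=False, na_values=[])
    for col in ("cell_id", "x", "y"):
        if col not in cells_df.columns:
            raise GCZoneError(f"{cells_path}: missing required column {col!r}")

    if matrix_path.suffix == ".mtx":
        if genes_path is None:
            raise GCZoneError("genes_path is required for MTX input")
        genes_path = Path(genes_path)
        if not genes_path.exists():
            raise FileNotFoundError(f"missing input file: {genes_path}")
        counts = sparse.csr_matrix(spio.mmread(matrix_path))
        gene_ids = [
            ln.split("\t")[0].strip()
            for ln in genes_path.read_text().splitlines()
            if ln.strip()
        ]
        if counts.shape[1] != len(gene_ids):
            raise GCZoneError(
                f"{genes_path}: {len(gene_ids)} genes but matrix has "
                f"{counts.shape[1]} columns ({matrix_path})"
            )
    else:
        dense = pd.read_csv(matrix_path, index_col=0)
        counts = dense.to_numpy()
        gene_ids = list(dense.columns)
        if genes_path is not None:
            listed = [
                ln.split("\t")[0].strip()
                for ln in Path(genes_path).read_text().splitlines()
                if ln.strip()
            ]
            if listed != gene_ids:
                raise GCZoneError(f"{genes_path}: gene list disagrees with {matrix_path} header")

    if counts.shape[0] != len(cells_df):
        raise GCZoneError(
            f"{cells_path}: {len(cells_df)} cells but matrix has "
            f"{counts.shape[0]} rows ({matrix_path})"
        )

    meta_cols = [c for c in cells_df.columns if c not in ("cell_id", "x", "y")]
    metadata = cells_df[meta_cols].copy()
    metadata.index = pd.Index(cells_df["cell_id"], name="cell_id")
    return CellTable(
        cell_ids=cells_df["cell_id"].to_numpy(dtype=object),
        x=cells_df["x"].to_numpy(float),
        y=cells_df["y"].to_numpy(float),
        counts=counts,
        gene_ids=np.asarray(gene_ids, dtype=object),
        metadata=metadata,
    )


def write_cell_table(cells: CellTable, outdir) -> dict:
    """Write ``matrix.mtx`` + ``cells.csv`` + ``genes.tsv`` into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "matrix.mtx",
        "cells": outdir / "cells.csv",
        "genes": outdir / "genes.tsv",
    }
    mat = cells.counts if sparse.issparse(cells.counts) else sparse.coo_matrix(cells.counts)
    spio.mmwrite(paths["matrix"], mat, field="integer")
    df = pd.DataFrame({"cell_id": cells.cell_ids, "x": cells.x, "y": cells.y})
    for col in cells.metadata.columns:
        df[col] = cells.metadata[col].to_numpy()
    df.to_csv(paths["cells"], index=False)
    paths["genes"].write_text("\n".join(map(str, cells.gene_ids)) + "\n")
    return {k: str(v) for k, v in paths.items()}


def _direction_from_token(token: str, context: str) -> str:
    up = token.strip()
    if up in DIRECTIONS:
        return up
    if up.upper().startswith("DZ"):
        return DZ_UP
    if up.upper().startswith("LZ"):
        return LZ_UP
    raise GCZoneError(
        f"{context}: cannot interpret direction token {token!r} "
        f"(expected DZ_up/LZ_up or a DZ*/LZ* set name)"
    )


def read_signatures(path) -> list[GeneSignature]:
    """Read directed gene signatures from a GMT file or a two-column TSV.

    GMT lines are ``name<TAB>description<TAB>gene...``; the set name must
    identify the direction (DZ* or LZ*).  The TSV dialect has two columns,
    ``gene<TAB>direction`` with direction strictly ``DZ_up`` or ``LZ_up``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing signature file: {path}")
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise GCZoneError(f"{path}: empty signature file")

    if path.suffix.lower() == ".gmt" or len(lines[0].split("\t")) > 2:
        sigs = []
        for ln in lines:
            parts = ln.split("\t")
            if len(parts) < 3:
                raise GCZoneError(f"{path}: malformed GMT line {ln[:50]!r}")
            name, genes = parts[0], tuple(g.strip() for g in parts[2:] if g.strip())
            sigs.append(GeneSignature(name, genes, _direction_from_token(name, str(path))))
        return sigs

    by_dir: dict[str, list[str]] = {}
    for ln in lines:
        parts = ln.split("\t")
        if len(parts) != 2:
            raise GCZoneError(f"{path}: expected 'gene<TAB>direction', got {ln!r}")
        gene, token = parts[0].strip(), parts[1].strip()
        if gene.lower() == "gene" and token.lower() == "direction":
            continue  # optional header
        if token not in DIRECTIONS:
            raise GCZoneError(
                f"{path}: direction must be DZ_up or LZ_up, got {token!r}"
            )
        by_dir.setdefault(token, []).append(gene)
    return [
        GeneSignature("DZ" if d == DZ_UP else "LZ", tuple(genes), d)
        for d, genes in by_dir.items()
    ]


def load_packaged_signatures() -> tuple[GeneSignature, GeneSignature]:
    """Return the packaged (DZ, LZ) spatial-signature stand-in.

    This fixture is a *synthetic* transcription: it reproduces the published
    set sizes (169 DZ-up, 201 LZ-up) with curated germinal-center marker
    genes padded by placeholder symbols, and is intended for simulation and
    testing rather than for annotating real tissue.
    """
    ref = resources.files("gczone.data") / PACKAGED_SIGNATURE_RESOURCE
    with resources.as_file(ref) as p:
        sigs = read_signatures(p)
    dz = next(s for s in sigs if s.direction == DZ_UP)
    lz = next(s for s in sigs if s.direction == LZ_UP)
    return dz, lz


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_filter(cells: CellTable, max_features: int = 3000, min_counts: int = 400) -> CellTable:
    """Drop low-quality cells.

    Retains cells with strictly fewer than ``max_features`` detected genes
    and strictly more than ``min_counts`` total counts; both ties are
    excluded.  Cell order is preserved and the removal tally is logged.
    """
    if max_features <= 0 or min_counts <= 0:
        raise GCZoneError("QC thresholds must be positive")
    counts = cells.counts
    if sparse.issparse(counts):
        detected = np.asarray((counts > 0).sum(axis=1)).ravel()
        totals = np.asarray(counts.sum(axis=1)).ravel()
    else:
        detected = (counts > 0).sum(axis=1)
        totals = counts.sum(axis=1)
    keep = (detected < max_features) & (totals > min_counts)
    n_removed = int((~keep).sum())
    if keep.sum() == 0:
        raise GCZoneError(
            f"QC removed all {cells.n_cells} cells; review thresholds "
            f"(max_features={max_features}, min_counts={min_counts})"
        )
    logger.info(
        "QC: removed %d/%d cells (max_features=%d, min_counts=%d)",
        n_removed, cells.n_cells, max_features, min_counts,
    )
    return cells.subset(keep)
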