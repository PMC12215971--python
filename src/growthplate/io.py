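"""Data model and file I/O shared by all pipeline stages.

Count matrices are held genes-in-rows, cells-in-columns as scipy sparse
matrices; tables are pandas DataFrames. On-disk formats are Matrix Market
(``.mtx``) plus one-id-per-line text files for counts, TSV/CSV with header
for tables, and JSON for configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("growthplate")

#: significant digits used for all floating-point table output
FLOAT_FORMAT = "%.9g"

CYLINDER_COLUMNS = ["cell_id", "bin", "pseudotime", "x", "y", "z"]


class DataError(ValueError):
    """Raised when an input file or matrix violates a precondition."""


@dataclass
class CountMatrix:
    """Sparse genes x cells matrix of raw non-negative integer counts.

    Gene and cell identifiers are ordered and unique; duplicate gene rows
    are collapsed at read time (first occurrence kept).
    """

    values: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise DataError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataError("duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise DataError("duplicate cell ids")
        data = self.values.data
        if data.size:
            if data.min() < 0:
                raise DataError("negative counts present")
            if not np.allclose(data, np.round(data)):
                raise DataError("non-integer counts present")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def subset_genes(self, mask: np.ndarray) -> "CountMatrix":
        return CountMatrix(self.values[mask], self.gene_ids[mask], self.cell_ids)

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        return CountMatrix(self.values[:, mask], self.gene_ids, self.cell_ids[mask])


@dataclass
class NormalizedMatrix:
    """Log-normalized expression, same orientation and ids as the source counts."""

    values: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    scale_factor: float

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)


@dataclass
class RunConfig:
    """All tunable parameters of the pipeline, with the published defaults.

    The defaults reproduce the stated settings: scale factor 1e4, 3-MAD
    outlier filters, low-abundance threshold 1e-3, 2000 highly variable
    genes, 50 pseudotime bins and a disk radius of 20.
    """

    scale_factor: float = 1e4
    n_mads: float = 3.0
    qc_log_scale: bool = True
    mito_prefix: str = "mt-"
    low_abundance_threshold: float = 1e-3
    n_hvg: int = 2000
    n_pcs: int = 30
    n_bins: int = 50
    disk_radius: float = 20.0
    perplexity: float = 30.0
    n_iter: int = 1000
    early_exaggeration: float = 12.0
    learning_rate: float | None = None
    init: str = "pca"
    z_mode: str = "pseudotime"
    grid_nx: int = 40
    grid_ny: int = 40
    grid_margin: float = 0.05
    grid_bandwidth: float | None = None
    grid_min_support: float = 1.0
    neutral_eps: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale_factor <= 0 or self.n_mads <= 0:
            raise DataError("scale_factor and n_mads must be positive")
        if self.low_abundance_threshold < 0:
            raise DataError("low_abundance_threshold must be non-negative")
        if self.n_hvg < 1 or self.n_bins < 1:
            raise DataError("n_hvg and n_bins must be positive integers")
        if self.disk_radius <= 0:
            raise DataError("disk_radius must be positive")
        if self.z_mode not in ("pseudotime", "index"):
            raise DataError(f"unknown z_mode {self.z_mode!r}")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _read_ids(path: str | Path) -> np.ndarray:
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    return np.asarray(ids, dtype=object)


def _dedupe_genes(values: sp.spmatrix, gene_ids: np.ndarray) -> tuple[sp.csr_matrix, np.ndarray]:
    seen: dict[str, int] = {}
    keep: list[int] = []
    for i, g in enumerate(gene_ids):
        if g not in seen:
            seen[g] = i
            keep.append(i)
    if len(keep) < len(gene_ids):
        n_dup = len(gene_ids) - len(keep)
        logger.warning("removed %d duplicate gene entries (first occurrence kept)", n_dup)
        values = sp.csr_matrix(values)[keep]
        gene_ids = gene_ids[keep]
    return sp.csr_matrix(values), gene_ids


def read_counts(
    path_matrix: str | Path,
    path_genes: str | Path | None = None,
    path_cells: str | Path | None = None,
) -> CountMatrix:
    """Read a count matrix from Matrix Market + id files or a dense delimited table.

    Orientation is normalized to genes-in-rows; a cells-in-rows layout is
    detected from the lengths of the id files and transposed. Duplicate gene
    entries are removed keeping the first occurrence.
    """
    path_matrix = Path(path_matrix)
    if path_matrix.suffix == ".mtx":
        if path_genes is None or path_cells is None:
            raise DataError("Matrix Market input requires gene and cell id files")
        values = sp.csr_matrix(scipy.io.mmread(path_matrix))
        gene_ids = _read_ids(path_genes)
        cell_ids = _read_ids(path_cells)
        n_rows, n_cols = values.shape
        if (n_rows, n_cols) == (len(gene_ids), len(cell_ids)):
            pass
        elif (n_rows, n_cols) == (len(cell_ids), len(gene_ids)):
            logger.info("cells-in-rows layout detected; transposing to genes x cells")
            values = sp.csr_matrix(values.T)
        else:
            raise DataError(
                f"matrix shape {values.shape} matches neither "
                f"{len(gene_ids)} genes x {len(cell_ids)} cells nor its transpose"
            )
    else:
        sep = "," if path_matrix.suffix == ".csv" else "\t"
        df = pd.read_csv(path_matrix, sep=sep, index_col=0)
        values = sp.csr_matrix(df.to_numpy())
        gene_ids = np.asarray(df.index, dtype=object)
        cell_ids = np.asarray(df.columns, dtype=object)
    values, gene_ids = _dedupe_genes(values, gene_ids)
    return CountMatrix(values, gene_ids, cell_ids)


def write_counts(counts: CountMatrix, path_matrix: str | Path,
                 path_genes: str | Path, path_cells: str | Path) -> None:
    scipy.io.mmwrite(str(path_matrix), sp.coo_matrix(counts.values), field="integer")
    Path(path_genes).write_text("".join(f"{g}\n" for g in counts.gene_ids))
    Path(path_cells).write_text("".join(f"{c}\n" for c in counts.cell_ids))


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read per-cell metadata; requires a ``cell_id`` column."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    if "cell_id" not in df.columns:
        raise DataError("cell table must have a 'cell_id' column")
    if df["cell_id"].duplicated().any():
        raise DataError("duplicate cell_id entries in cell table")
    if "pseudotime" in df.columns:
        pt = df["pseudotime"]
        if np.isinf(pt.to_numpy(dtype=float, na_value=np.nan)).any():
            raise DataError("non-finite pseudotime values")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    df.to_csv(path, sep=sep, index=False, float_format=FLOAT_FORMAT)


def write_cylinder(recon: pd.DataFrame, path: str | Path) -> None:
    """Write cylinder coordinates (cell_id, bin, pseudotime, x, y, z) as a table."""
    missing = [c for c in CYLINDER_COLUMNS if c not in recon.columns]
    if missing:
        raise DataError(f"cylinder table missing columns: {missing}")
    write_table(recon[CYLINDER_COLUMNS], path)


def read_cylinder(path: str | Path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in CYLINDER_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"cylinder table missing columns: {missing}")
    return df.astype({"bin": int, "pseudotime": float, "x": float, "y": float, "z": float})


def log_stage(stage: str, *, cells_in: int | None = None, genes_in: int | None = None,
              cells_out: int | None = None, genes_out: int | None = None,
              **params: object) -> None:
    """One line per pipeline stage on the run log."""
    parts = [f"stage={stage}"]
    parts += [f"{k}={v}" for k, v in params.items()]
    for name, val in (("cells_in", cells_in), ("genes_in", genes_in),
                      ("cells_out", cells_out), ("genes_out", genes_out)):
        if val is not None:
            parts.append(f"{name}={val}")
    logger.info(" ".join(parts))
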