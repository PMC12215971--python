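"""Pseudospatiotemporal reconstruction: bin by pseudotime, embed each bin
into a bounded disk, stack the disks into a cylinder.

Cells are grouped into equal-width pseudotime bins; each non-empty bin is
embedded with disk-constrained t-SNE on a per-bin PCA of the normalized
highly-variable-gene expression; the circular projections are then stacked
in pseudotime order, giving every cell an (x, y, z) coordinate in the
reconstructed cylinder. z is the bin's pseudotime midpoint by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix, DataError, NormalizedMatrix
from .preprocess import pca_scores, scale_matrix
from .tsne import TsneParams, tsne_constrained

logger = logging.getLogger("growthplate")

#: bins smaller than this take the degenerate placement path
MIN_TSNE_CELLS = 4


@dataclass
class PseudotimeBins:
    """Equal-width binning of pseudotime; assignment -1 marks cells without
    a finite pseudotime."""

    n_bins: int
    edges: np.ndarray
    assignment: np.ndarray  # per-cell bin index, -1 = missing
    cell_ids: np.ndarray

    def midpoints(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2.0

    def cells_in(self, b: int) -> np.ndarray:
        return np.where(self.assignment == b)[0]


@dataclass
class DiskEmbedding:
    """Per-bin 2-D coordinates, all within the disk of radius R."""

    bin_index: int
    cell_ids: np.ndarray
    coords: np.ndarray
    kl_trace: np.ndarray


def assign_bins(cells: pd.DataFrame, n_bins: int) -> PseudotimeBins:
    """Assign cells to equal-width pseudotime intervals over [min, max].

    Intervals are right-closed; the lowest interval is closed on both ends
    so the minimum cell is kept. Cells with missing pseudotime get -1.
    """
    if n_bins < 1:
        raise DataError("n_bins must be >= 1")
    if "pseudotime" not in cells.columns:
        raise DataError("cell table has no 'pseudotime' column")
    pt = cells["pseudotime"].to_numpy(dtype=float)
    finite = np.isfinite(pt)
    if not finite.any():
        raise DataError("no cell has a finite pseudotime")
    lo, hi = pt[finite].min(), pt[finite].max()
    if hi <= lo:
        raise DataError("pseudotime range is zero; cannot bin")
    edges = np.linspace(lo, hi, n_bins + 1)
    assignment = np.full(len(pt), -1, dtype=int)
    binned = pd.cut(pt[finite], bins=edges, labels=False, include_lowest=True, right=True)
    assignment[finite] = np.asarray(binned, dtype=int)
    empty = sorted(set(range(n_bins)) - set(assignment[assignment >= 0]))
    if empty:
        logger.info("empty pseudotime bins: %s", empty)
    return PseudotimeBins(n_bins, edges, assignment, cells["cell_id"].to_numpy(dtype=object))


def _degenerate_embedding(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    # uniform inside a disk of radius R/10: no structure fabricated
    r = radius / 10.0 * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def embed_bins(norm: NormalizedMatrix, hvg: pd.DataFrame, bins: PseudotimeBins,
               params: TsneParams, n_pcs: int = 30) -> list[DiskEmbedding]:
    """Constrained t-SNE per non-empty bin.

    Each bin gets its own PCA (min(n_pcs, n-1) components of the bin's cells)
    and its own seed (base seed + bin index) so runs are bit-reproducible and
    independent of cell order within the bin.
    """
    if not np.array_equal(bins.cell_ids, norm.cell_ids):
        raise DataError("bin cell ids do not match the normalized matrix")
    sel = hvg["selected"].to_numpy()
    gene_pos = {g: i for i, g in enumerate(norm.gene_ids)}
    rows = [gene_pos[g] for g in hvg.loc[sel, "gene_id"] if g in gene_pos]
    if not rows:
        raise DataError("no selected HVG present in the normalized matrix")
    expr = norm.values[rows]

    embeddings: list[DiskEmbedding] = []
    for b in range(bins.n_bins):
        idx = bins.cells_in(b)
        if idx.size == 0:
            continue
        order = np.argsort(bins.cell_ids[idx].astype(str))
        idx = idx[order]  # canonical within-bin order: sorted cell id
        bin_seed = params.seed + b
        rng = np.random.default_rng(bin_seed)
        if idx.size < MIN_TSNE_CELLS:
            coords = _degenerate_embedding(idx.size, params.disk_radius, rng)
            kl_trace = np.empty(0)
        else:
            X = expr[:, idx].toarray().T  # cells x genes
            k = min(n_pcs, idx.size - 1)
            feats = pca_scores(scale_matrix(X), k)
            bin_params = TsneParams(
                perplexity=params.perplexity, n_iter=params.n_iter,
                early_exaggeration=params.early_exaggeration,
                exaggeration_iter=params.exaggeration_iter,
                learning_rate=params.learning_rate,
                momentum_early=params.momentum_early,
                momentum_late=params.momentum_late,
                init=params.init, disk_radius=params.disk_radius, seed=bin_seed,
            )
            try:
                coords, kl_trace = tsne_constrained(feats, bin_params)
            except DataError as exc:
                if "perplexity infeasible" in str(exc):
                    coords = _degenerate_embedding(idx.size, params.disk_radius, rng)
                    kl_trace = np.empty(0)
                else:
                    raise DataError(f"bin {b}: {exc}") from exc
        embeddings.append(DiskEmbedding(b, bins.cell_ids[idx], coords, kl_trace))
    return embeddings


def stack_cylinder(embeddings: list[DiskEmbedding], bins: PseudotimeBins,
                   cells: pd.DataFrame, z_mode: str = "pseudotime") -> pd.DataFrame:
    """Stack per-bin disks into cylinder coordinates.

    z is the bin's pseudotime midpoint (or the bin index with
    ``z_mode="index"``); (x, y) are inherited unchanged from the bin's disk
    embedding. Rows sorted by (bin, cell_id).
    """
    have = {e.bin_index for e in embeddings}
    need = {b for b in range(bins.n_bins) if bins.cells_in(b).size}
    if have != need:
        raise DataError(f"embeddings for bins {sorted(have)} do not match "
                        f"non-empty bins {sorted(need)}")
    pt = cells.set_index("cell_id")["pseudotime"]
    mids = bins.midpoints()
    frames = []
    for emb in sorted(embeddings, key=lambda e: e.bin_index):
        z = mids[emb.bin_index] if z_mode == "pseudotime" else float(emb.bin_index)
        frames.append(pd.DataFrame({
            "cell_id": emb.cell_ids,
            "bin": emb.bin_index,
            "pseudotime": pt.loc[emb.cell_ids].to_numpy(),
            "x": emb.coords[:, 0],
            "y": emb.coords[:, 1],
            "z": z,
        }))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["bin", "cell_id"], kind="mergesort", ignore_index=True)


def zone_profile(norm: NormalizedMatrix, recon: pd.DataFrame,
                 genes: list[str]) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Marker-gene expression along the reconstructed cylinder.

    Returns (per-bin mean expression table with bins as rows and genes as
    columns, per-cell long table joined to (x, y, z), and each gene's peak
    bin index; ties break to the lowest bin).
    """
    gene_pos = {g: i for i, g in enumerate(norm.gene_ids)}
    unknown = [g for g in genes if g not in gene_pos]
    if unknown:
        sample = ", ".join(map(str, norm.gene_ids[:5]))
        raise DataError(f"unknown genes {unknown}; valid names look like: {sample} ...")
    cell_pos = {c: i for i, c in enumerate(norm.cell_ids)}
    cols = np.array([cell_pos[c] for c in recon["cell_id"]])
    expr = norm.values[[gene_pos[g] for g in genes]][:, cols].toarray()

    per_cell = pd.concat(
        [recon[["cell_id", "bin", "pseudotime", "x", "y", "z"]].reset_index(drop=True),
         pd.DataFrame(expr.T, columns=genes)],
        axis=1,
    )
    profile = per_cell.groupby("bin")[genes].mean()
    peaks = {g: int(profile[g].idxmax()) for g in genes}  # first max = lowest bin
    return profile, per_cell, peaks
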