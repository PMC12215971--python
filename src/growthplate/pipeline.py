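"""End-to-end orchestration: QC -> normalize -> HVG -> bin -> embed -> stack.

The library entry point is :func:`reconstruct_pipeline`; the CLI ``run``
command wraps it with file I/O and a manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix, DataError, NormalizedMatrix, RunConfig, log_stage
from .preprocess import (
    compute_qc_metrics,
    filter_low_abundance_genes,
    flag_outlier_cells,
    log_normalize,
    select_hvg_vst,
)
from .recon import PseudotimeBins, assign_bins, embed_bins, stack_cylinder
from .tsne import TsneParams

logger = logging.getLogger("growthplate")


@dataclass
class PipelineResult:
    config: RunConfig
    qc_metrics: pd.DataFrame
    qc_flags: pd.DataFrame
    counts: CountMatrix          # QC-passed cells, abundance-filtered genes
    cells: pd.DataFrame          # QC-passed cell table
    norm: NormalizedMatrix
    hvg: pd.DataFrame
    bins: PseudotimeBins
    embeddings: list
    cylinder: pd.DataFrame


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def tsne_params_from_config(config: RunConfig) -> TsneParams:
    return TsneParams(
        perplexity=config.perplexity,
        n_iter=config.n_iter,
        early_exaggeration=config.early_exaggeration,
        learning_rate=config.learning_rate,
        init=config.init,
        disk_radius=config.disk_radius,
        seed=config.seed,
    )


def apply_qc(counts: CountMatrix, cells: pd.DataFrame, config: RunConfig
             ) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """QC metrics, outlier flags and cell/gene filtering in the stated order."""
    metrics = compute_qc_metrics(counts, config.mito_prefix)
    flags = flag_outlier_cells(metrics, config.n_mads, log_scale=config.qc_log_scale)
    keep = flags["pass_qc"].to_numpy()
    filtered = counts.subset_cells(keep)
    filtered = filter_low_abundance_genes(filtered, config.low_abundance_threshold)
    cells_out = cells[cells["cell_id"].isin(set(filtered.cell_ids))].reset_index(drop=True)
    cells_out = cells_out.set_index("cell_id").loc[filtered.cell_ids].reset_index()
    log_stage("qc", cells_in=counts.n_cells, genes_in=counts.n_genes,
              cells_out=filtered.n_cells, genes_out=filtered.n_genes,
              n_mads=config.n_mads, threshold=config.low_abundance_threshold)
    return filtered, cells_out, metrics, flags


def reconstruct_pipeline(counts: CountMatrix, cells: pd.DataFrame,
                         config: RunConfig | None = None) -> PipelineResult:
    """Run the full reconstruction on in-memory inputs."""
    config = config or RunConfig()
    if "pseudotime" not in cells.columns:
        raise DataError("cell table has no 'pseudotime' column")
    if not set(counts.cell_ids) <= set(cells["cell_id"]):
        raise DataError("cell table does not cover all matrix cells")

    filtered, cells_out, metrics, flags = apply_qc(counts, cells, config)
    norm = log_normalize(filtered, config.scale_factor)
    log_stage("normalize", cells_in=filtered.n_cells, scale_factor=config.scale_factor)
    hvg = select_hvg_vst(filtered, config.n_hvg)
    log_stage("hvg", genes_in=filtered.n_genes, genes_out=int(hvg["selected"].sum()))

    bins = assign_bins(cells_out, config.n_bins)
    params = tsne_params_from_config(config)
    embeddings = embed_bins(norm, hvg, bins, params, n_pcs=config.n_pcs)
    cylinder = stack_cylinder(embeddings, bins, cells_out, z_mode=config.z_mode)
    log_stage("reconstruct", cells_in=filtered.n_cells, n_bins=config.n_bins,
              radius=config.disk_radius, cells_out=len(cylinder))
    return PipelineResult(config, metrics, flags, filtered, cells_out, norm,
                          hvg, bins, embeddings, cylinder)


def max_embedding_radius(result: PipelineResult) -> float:
    """Largest distance from the disk center over all cells in all bins."""
    xy = result.cylinder[["x", "y"]].to_numpy(dtype=float)
    return float(np.sqrt((xy**2).sum(axis=1)).max())


@dataclass
class StageRecord:
    stage: str
    config_hash: str
    inputs: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    cells_in: int | None = None
    genes_in: int | None = None
    cells_out: int | None = None
    genes_out: int | None = None
    wall_time_s: float = 0.0


class ManifestWriter:
    """Ordered stage records written as JSON."""

    def __init__(self, config: RunConfig) -> None:
        self.hash = config_hash(config)
        self.records: list[StageRecord] = []

    def record(self, stage: str, t0: float, **kw) -> None:
        self.records.append(
            StageRecord(stage=stage, config_hash=self.hash,
                        wall_time_s=round(time.perf_counter() - t0, 3), **kw)
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump([asdict(r) for r in self.records], fh, indent=2)
            fh.write("\n")
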