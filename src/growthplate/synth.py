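"""Synthetic growth plate with known ground truth.

Cells sit on a latent differentiation axis s in [0, 1] running through four
ordered chondrocyte zones (resting, proliferative, pre-hypertrophic,
hypertrophic). Each zone owns marker genes whose negative-binomial mean
peaks as a Gaussian bump at the zone's center; background genes are flat,
a small mitochondrial gene set is flat, and a fixed fraction of cells is
corrupted (collapsed library, mitochondrial takeover) to exercise QC.
Pseudotime is the latent position plus Gaussian jitter, standing in for an
inferred trajectory ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix, DataError

ZONE_NAMES = ("resting", "proliferative", "pre-hypertrophic", "hypertrophic")


@dataclass
class ZoneSpec:
    name: str
    n_markers: int = 25
    center: float = 0.5
    width: float = 0.1


def _default_zones() -> list[ZoneSpec]:
    centers = (0.125, 0.375, 0.625, 0.875)
    return [ZoneSpec(name, 25, c, 0.1) for name, c in zip(ZONE_NAMES, centers)]


@dataclass
class SynthConfig:
    """Generator settings; defaults give a QC-solvable, zone-ordered plate."""

    n_cells: int = 2000
    n_genes: int = 5000
    zones: list[ZoneSpec] = field(default_factory=_default_zones)
    base_mean: float = 3.0
    marker_amplitude: float = 3.0
    background_lognormal_sigma: float = 1.0
    nb_dispersion: float = 0.2
    libsize_lognormal_sigma: float = 0.35
    mito_gene_count: int = 13
    mito_mean: float = 6.0
    corrupted_fraction: float = 0.05
    corrupted_library_factor: float = 0.05
    corrupted_mito_fraction: float = 0.6
    pseudotime_jitter: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_genes < 1:
            raise DataError("n_cells and n_genes must be positive")
        centers = [z.center for z in self.zones]
        if sorted(centers) != centers or len(set(centers)) != len(centers):
            raise DataError("zone peak centers must be strictly increasing")
        if not all(0.0 <= c <= 1.0 for c in centers):
            raise DataError("zone peak centers must lie in [0, 1]")
        if not 0.0 <= self.corrupted_fraction <= 1.0:
            raise DataError("corrupted_fraction must be in [0, 1]")
        n_marker = sum(z.n_markers for z in self.zones)
        if n_marker + self.mito_gene_count > self.n_genes:
            raise DataError("markers + mito genes exceed n_genes")


@dataclass
class GroundTruth:
    """Per-cell and per-gene generative truth, joinable by id."""

    cells: pd.DataFrame  # cell_id, s, zone, corrupted, library_factor
    genes: pd.DataFrame  # gene_id, role, peak_center


def _zone_of(s: np.ndarray, zones: list[ZoneSpec]) -> np.ndarray:
    centers = np.array([z.center for z in zones])
    bounds = (centers[:-1] + centers[1:]) / 2.0
    idx = np.searchsorted(bounds, s)
    return np.array([zones[i].name for i in idx], dtype=object)


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    # var = mean + dispersion * mean^2; size r = 1/dispersion
    r = 1.0 / dispersion
    p = r / (r + np.maximum(mean, 1e-12))
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    out[pos] = rng.negative_binomial(r, p[pos])
    return out


def simulate_growth_plate(config: SynthConfig | None = None
                          ) -> tuple[CountMatrix, pd.DataFrame, GroundTruth]:
    """Generate (counts, cell table, ground truth), reproducible from the seed."""
    cfg = config or SynthConfig()
    rng = np.random.default_rng(cfg.seed)

    s = rng.uniform(size=cfg.n_cells)
    zone = _zone_of(s, cfg.zones)
    lib_factor = rng.lognormal(
        mean=-cfg.libsize_lognormal_sigma**2 / 2.0,
        sigma=cfg.libsize_lognormal_sigma, size=cfg.n_cells,
    )
    n_corrupt = int(round(cfg.corrupted_fraction * cfg.n_cells))
    corrupt_idx = rng.choice(cfg.n_cells, size=n_corrupt, replace=False)
    corrupted = np.zeros(cfg.n_cells, dtype=bool)
    corrupted[corrupt_idx] = True
    lib_factor = np.where(corrupted, lib_factor * cfg.corrupted_library_factor, lib_factor)

    # gene roster: zone markers, mitochondrial set, flat background
    gene_ids: list[str] = []
    roles: list[str] = []
    peak_centers: list[float] = []
    marker_center: list[float] = []
    marker_width: list[float] = []
    for z in cfg.zones:
        for i in range(z.n_markers):
            gene_ids.append(f"Mkr-{z.name}-{i:02d}")
            roles.append(z.name)
            peak_centers.append(z.center)
            marker_center.append(z.center)
            marker_width.append(z.width)
    for i in range(cfg.mito_gene_count):
        gene_ids.append(f"mt-Gene{i:02d}")
        roles.append("mito")
        peak_centers.append(np.nan)
    n_marker = len(marker_center)
    n_background = cfg.n_genes - n_marker - cfg.mito_gene_count
    for i in range(n_background):
        gene_ids.append(f"Gene{i:05d}")
        roles.append("background")
        peak_centers.append(np.nan)

    floor = 0.1
    # background genes are flat along s but span a realistic abundance
    # spectrum (lognormal per-gene baseline), giving the mean-variance trend
    # fit a continuum of means to anchor on
    background_mean = cfg.base_mean * floor * np.exp(
        rng.normal(0.0, cfg.background_lognormal_sigma, size=n_background)
    )
    centers = np.asarray(marker_center)
    widths = np.asarray(marker_width)
    bump = np.exp(-((s[None, :] - centers[:, None]) ** 2) / (2.0 * widths[:, None] ** 2))
    mean = np.empty((cfg.n_genes, cfg.n_cells))
    mean[:n_marker] = cfg.base_mean * (floor + cfg.marker_amplitude * bump)
    mean[n_marker:n_marker + cfg.mito_gene_count] = cfg.mito_mean
    mean[n_marker + cfg.mito_gene_count:] = background_mean[:, None]
    mean *= lib_factor[None, :]

    counts = _nb_sample(rng, mean, cfg.nb_dispersion)

    # corrupted cells: mitochondrial reads dominate (~corrupted_mito_fraction
    # of the cell total), emulating damaged/dying cells
    mito_rows = slice(n_marker, n_marker + cfg.mito_gene_count)
    for c in np.sort(corrupt_idx):
        non_mito = counts[:, c].sum() - counts[mito_rows, c].sum()
        f = cfg.corrupted_mito_fraction
        target = int(round(non_mito * f / (1.0 - f)))
        counts[mito_rows, c] = rng.multinomial(
            target, np.full(cfg.mito_gene_count, 1.0 / cfg.mito_gene_count)
        )

    pseudotime = np.clip(s + rng.normal(0.0, cfg.pseudotime_jitter, cfg.n_cells), 0.0, None)
    cell_ids = np.array([f"cell{i:05d}" for i in range(cfg.n_cells)], dtype=object)

    cm = CountMatrix(sp.csr_matrix(counts), np.array(gene_ids, dtype=object), cell_ids)
    cell_table = pd.DataFrame(
        {"cell_id": cell_ids, "pseudotime": pseudotime, "label": zone}
    )
    truth = GroundTruth(
        cells=pd.DataFrame({
            "cell_id": cell_ids, "s": s, "zone": zone,
            "corrupted": corrupted, "library_factor": lib_factor,
        }),
        genes=pd.DataFrame({
            "gene_id": gene_ids, "role": roles, "peak_center": peak_centers,
        }),
    )
    return cm, cell_table, truth


def simulate_perturbation_field(embedding: pd.DataFrame, ground_truth: GroundTruth,
                                target_zone: str | None = None, scale: float = 1.0,
                                nx: int = 40, ny: int = 40) -> pd.DataFrame:
    """Per-cell displacement field for a virtual knockout fixture.

    Baseline vectors follow the local pseudotime-gradient direction; inside
    ``target_zone`` they are reversed, creating a known inaccessible region.
    ``embedding`` needs columns cell_id, x, y, pseudotime.
    """
    from .fields import interpolate_grid_vectors, pseudotime_gradient_grid

    zones = set(ground_truth.cells["zone"])
    if target_zone is not None and target_zone not in zones:
        raise DataError(f"unknown zone {target_zone!r}; valid: {sorted(zones)}")
    xy = embedding[["x", "y"]].to_numpy(dtype=float)
    pt = embedding["pseudotime"].to_numpy(dtype=float)
    grid = pseudotime_gradient_grid(xy, pt, nx=nx, ny=ny)
    vec = interpolate_grid_vectors(grid, xy)
    norms = np.linalg.norm(vec, axis=1)
    vec = np.where(norms[:, None] > 0, vec / np.maximum(norms, 1e-300)[:, None] * scale, 0.0)
    if target_zone is not None:
        zone_by_cell = ground_truth.cells.set_index("cell_id")["zone"]
        in_zone = zone_by_cell.loc[embedding["cell_id"]].to_numpy() == target_zone
        vec[in_zone] *= -1.0
    return pd.DataFrame({
        "cell_id": embedding["cell_id"].to_numpy(),
        "dx": vec[:, 0], "dy": vec[:, 1],
    })
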