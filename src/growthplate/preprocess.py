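"""Quality control, normalization, highly-variable-gene selection and PCA.

Per-cell QC follows the MAD-outlier tradition: library size and detected-gene
counts are tested two-sided on a log1p scale, mitochondrial fraction one-sided
(above the median only), each at ``n_mads`` median absolute deviations with
the 1.4826 normal-consistency constant. Normalization is the log1p
counts-per-scale-factor transform; variable genes are ranked by the variance
of clipped standardized counts after a local-regression mean-variance trend
fit (the "vst" ranking).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import CountMatrix, DataError, NormalizedMatrix

logger = logging.getLogger("growthplate")

MAD_CONSTANT = 1.4826  # consistency with the normal distribution


def compute_qc_metrics(counts: CountMatrix, mito_prefix: str) -> pd.DataFrame:
    """Per-cell library size, detected-gene count and mitochondrial fraction.

    Returns a DataFrame indexed like ``counts.cell_ids`` with columns
    ``library_size``, ``n_genes_detected``, ``mito_fraction``. Cells with
    zero counts get a mitochondrial fraction of 0.
    """
    if counts.n_cells == 0 or counts.n_genes == 0:
        raise DataError("empty count matrix")
    csc = counts.values.tocsc()
    library = np.asarray(csc.sum(axis=0)).ravel()
    detected = np.asarray((csc > 0).sum(axis=0)).ravel()
    mito_mask = np.array([str(g).startswith(mito_prefix) for g in counts.gene_ids])
    if not mito_mask.any():
        logger.warning("no gene matches mitochondrial prefix %r; mito_fraction set to 0",
                       mito_prefix)
        mito = np.zeros_like(library, dtype=float)
    else:
        mito = np.asarray(csc[mito_mask.nonzero()[0]].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(library > 0, mito / np.maximum(library, 1), 0.0)
    return pd.DataFrame(
        {
            "cell_id": counts.cell_ids,
            "library_size": library,
            "n_genes_detected": detected,
            "mito_fraction": mito_frac,
        }
    )


def _mad_flags(values: np.ndarray, n_mads: float, one_sided: bool) -> np.ndarray:
    med = np.median(values)
    mad = MAD_CONSTANT * np.median(np.abs(values - med))
    dev = values - med
    if mad == 0:
        # all-identical metric: only cells actually differing from the median flag
        return (dev > 0) if one_sided else (dev != 0)
    if one_sided:
        return dev > n_mads * mad
    return np.abs(dev) > n_mads * mad


def flag_outlier_cells(metrics: pd.DataFrame, n_mads: float = 3.0,
                       log_scale: bool = True) -> pd.DataFrame:
    """MAD-based outlier flags per cell.

    Library size and detected genes are tested two-sided (on log1p scale by
    default); the mitochondrial fraction is tested one-sided, flagging only
    cells above the median, on the raw scale.
    """
    if len(metrics) < 2:
        raise DataError("need at least 2 cells to flag outliers")
    lib = metrics["library_size"].to_numpy(dtype=float)
    ngenes = metrics["n_genes_detected"].to_numpy(dtype=float)
    if log_scale:
        lib, ngenes = np.log1p(lib), np.log1p(ngenes)
    flags = pd.DataFrame({"cell_id": metrics["cell_id"].to_numpy()})
    flags["fail_library"] = _mad_flags(lib, n_mads, one_sided=False)
    flags["fail_ngenes"] = _mad_flags(ngenes, n_mads, one_sided=False)
    flags["fail_mito"] = _mad_flags(
        metrics["mito_fraction"].to_numpy(dtype=float), n_mads, one_sided=True
    )
    flags["pass_qc"] = ~(flags["fail_library"] | flags["fail_ngenes"] | flags["fail_mito"])
    return flags


def filter_low_abundance_genes(counts: CountMatrix, threshold: float = 1e-3) -> CountMatrix:
    """Drop genes whose mean raw count per cell is below ``threshold``.

    Survivor order is preserved. Raises if no gene survives.
    """
    means = np.asarray(counts.values.mean(axis=1)).ravel()
    keep = means >= threshold
    if not keep.any():
        raise DataError("low-abundance filter removed every gene")
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("low-abundance filter removed %d/%d genes", n_removed, counts.n_genes)
    return counts.subset_genes(keep)


def log_normalize(counts: CountMatrix, scale_factor: float = 1e4) -> NormalizedMatrix:
    """log1p counts-per-scale-factor: v = ln(1 + scale_factor * x / library).

    For every cell the back-transformed total sum(expm1(v)) equals the scale
    factor exactly. Cells with zero library size are a hard error; QC must
    remove them first.
    """
    csc = counts.values.tocsc().astype(float)
    library = np.asarray(csc.sum(axis=0)).ravel()
    zero = np.where(library == 0)[0]
    if zero.size:
        names = ", ".join(str(counts.cell_ids[i]) for i in zero[:5])
        raise DataError(f"cells with zero library size: {names}"
                        + (" ..." if zero.size > 5 else ""))
    # scale column-wise, sparsity pattern preserved
    csc = csc @ sp.diags(scale_factor / library)
    csc.data = np.log1p(csc.data)
    return NormalizedMatrix(csc.tocsr(), counts.gene_ids, counts.cell_ids, scale_factor)


def select_hvg_vst(counts: CountMatrix, n_hvg: int = 2000, span: float = 0.3) -> pd.DataFrame:
    """Rank genes by variance of clipped standardized raw counts ("vst").

    A local regression of log10 variance on log10 mean (span 0.3) over genes
    with positive mean and variance yields each gene's expected standard
    deviation; counts standardized with it are clipped at sqrt(n_cells) and
    the variance of the clipped values is the ranking statistic. Ties break
    lexicographically on gene id. Returns a DataFrame with columns
    ``gene_id, mean, variance, variance_standardized, selected``.
    """
    if counts.n_cells < 2:
        raise DataError("vst ranking needs at least 2 cells")
    n = counts.n_cells
    csr = counts.values.tocsr().astype(float)
    mean = np.asarray(csr.mean(axis=1)).ravel()
    sq = csr.copy()
    sq.data **= 2
    ex2 = np.asarray(sq.mean(axis=1)).ravel()
    var = (ex2 - mean**2) * n / (n - 1)
    var = np.maximum(var, 0.0)

    std_var = np.zeros(counts.n_genes)
    fit_mask = (mean > 0) & (var > 0)
    if fit_mask.sum() >= 2:
        x = np.log10(mean[fit_mask])
        y = np.log10(var[fit_mask])
        fitted = lowess(y, x, frac=span, it=0, return_sorted=False)
        sd_exp = np.sqrt(10.0**fitted)
        clip = np.sqrt(n)
        idx = np.where(fit_mask)[0]
        mu, sd = mean[fit_mask], sd_exp
        # closed-form sum of squared standardized values, then correct the
        # (rare) entries exceeding the clip; zeros standardize negative and
        # never clip since counts are non-negative
        sum_x = np.asarray(csr[idx].sum(axis=1)).ravel()
        sum_x2 = ex2[idx] * n
        ss = (sum_x2 - 2 * mu * sum_x + n * mu**2) / sd**2
        indptr = csr.indptr
        for k, g in enumerate(idx):
            row = csr.data[indptr[g]:indptr[g + 1]]
            z = (row - mu[k]) / sd[k]
            over = z > clip
            if over.any():
                ss[k] += (clip**2 * over.sum()) - (z[over] ** 2).sum()
        std_var[idx] = ss / (n - 1)

    df = pd.DataFrame(
        {
            "gene_id": counts.gene_ids,
            "mean": mean,
            "variance": var,
            "variance_standardized": std_var,
        }
    )
    if n_hvg > counts.n_genes:
        logger.warning("n_hvg=%d exceeds %d genes; selecting all", n_hvg, counts.n_genes)
        n_hvg = counts.n_genes
    order = df.sort_values(
        ["variance_standardized", "gene_id"], ascending=[False, True], kind="mergesort"
    ).index.to_numpy()
    selected = np.zeros(counts.n_genes, dtype=bool)
    selected[order[:n_hvg]] = True
    df["selected"] = selected
    return df


def scale_matrix(values: np.ndarray, clip: float = 10.0) -> np.ndarray:
    """Center and unit-scale columns (genes), clipping scaled values at +/- clip."""
    mu = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return np.clip((values - mu) / sd, -clip, clip)


def run_pca(norm: NormalizedMatrix, hvg: pd.DataFrame, n_components: int = 30,
            clip: float = 10.0) -> np.ndarray:
    """Cell x component PCA scores of scaled, clipped HVG expression.

    Sign convention: the largest-magnitude gene loading of each component is
    positive, making repeated runs bit-identical.
    """
    sel = hvg["selected"].to_numpy()
    gene_pos = {g: i for i, g in enumerate(norm.gene_ids)}
    rows = [gene_pos[g] for g in hvg.loc[sel, "gene_id"] if g in gene_pos]
    if not rows:
        raise DataError("no selected HVG present in the normalized matrix")
    X = norm.values[rows].toarray().T  # cells x genes
    return pca_scores(scale_matrix(X, clip=clip), n_components)


def pca_scores(X: np.ndarray, n_components: int) -> np.ndarray:
    """Deterministic PCA scores of a centered matrix via SVD (sign-fixed)."""
    if n_components > min(X.shape):
        raise DataError(
            f"n_components={n_components} exceeds min(shape)={min(X.shape)}"
        )
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    for k in range(n_components):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] = -Vt[k]
            U[:, k] = -U[:, k]
    return U[:, :n_components] * S[:n_components]
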