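"""t-SNE with a circular boundary condition on gradient descent.

Exact (dense) t-SNE: per-point Gaussian bandwidths from a binary search on
perplexity, symmetrized joint affinities, Student-t low-dimensional kernel,
early exaggeration, momentum with adaptive gains. The constraint is enforced
by projected gradient descent — after every position update any point outside
the disk of radius R is pulled back radially onto the boundary — so the
radius bound holds exactly at every iteration. R = inf recovers standard
(unconstrained) t-SNE on the identical trajectory.

Bin sizes here are tens-to-hundreds of cells, so the O(n^2) exact gradient
is the right tool; no Barnes-Hut approximation is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .io import DataError

_EPS = 1e-12


@dataclass
class TsneParams:
    """Hyperparameters of the constrained t-SNE.

    ``perplexity`` is auto-capped at floor((n-1)/3); ``learning_rate`` of
    None means the max(n/12, 50) heuristic. ``disk_radius`` is the boundary
    circle radius R; use ``math.inf`` to disable the constraint.
    """

    perplexity: float = 30.0
    n_iter: int = 1000
    early_exaggeration: float = 12.0
    exaggeration_iter: int = 250
    learning_rate: float | None = None
    momentum_early: float = 0.5
    momentum_late: float = 0.8
    init: str = "pca"
    disk_radius: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.disk_radius <= 0:
            raise DataError("disk_radius must be positive")
        if self.init not in ("pca", "random"):
            raise DataError(f"unknown init {self.init!r}")


def conditional_bandwidths(d2: np.ndarray, perplexity: float,
                           tol: float = 1e-5, max_iter: int = 64) -> np.ndarray:
    """Binary-search precisions beta_i so 2^H(p_.|i) equals the perplexity.

    ``d2`` is the squared-distance matrix with an arbitrary diagonal (ignored).
    Returns the conditional affinity matrix P (rows i give p_{j|i}).
    """
    n = d2.shape[0]
    target = math.log(perplexity)
    P = np.zeros_like(d2)
    for i in range(n):
        di = np.delete(d2[i], i)
        beta, lo, hi = 1.0, 0.0, math.inf
        for _ in range(max_iter):
            w = np.exp(-di * beta)
            sw = w.sum()
            if sw <= 0:
                H, p = 0.0, w
            else:
                p = w / sw
                H = math.log(sw) + beta * float((di * w).sum()) / sw
            diff = H - target
            if abs(diff) < tol:
                break
            if diff > 0:
                lo = beta
                beta = beta * 2 if hi == math.inf else (beta + hi) / 2
            else:
                hi = beta
                beta = (beta + lo) / 2
        row = np.insert(p if sw > 0 else np.full(n - 1, 1.0 / (n - 1)), i, 0.0)
        P[i] = row
    return P


def joint_affinities(features: np.ndarray, perplexity: float) -> np.ndarray:
    """Symmetrized joint probabilities p_ij = (p_{j|i} + p_{i|j}) / (2n)."""
    d2 = squareform(pdist(features, metric="sqeuclidean"))
    Pc = conditional_bandwidths(d2, perplexity)
    P = (Pc + Pc.T) / (2.0 * d2.shape[0])
    return np.maximum(P, _EPS)


def kl_gradient(P: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact t-SNE gradient and KL divergence at configuration Y.

    grad_i = 4 * sum_j (p_ij - q_ij) (y_i - y_j) / (1 + |y_i - y_j|^2).
    """
    d2 = squareform(pdist(Y, metric="sqeuclidean"))
    num = 1.0 / (1.0 + d2)
    np.fill_diagonal(num, 0.0)
    Z = num.sum()
    Q = np.maximum(num / Z, _EPS)
    PQ = (P - Q) * num
    grad = 4.0 * ((np.diag(PQ.sum(axis=1)) - PQ) @ Y)
    mask = ~np.eye(P.shape[0], dtype=bool)
    kl = float(np.sum(P[mask] * np.log(P[mask] / Q[mask])))
    return grad, kl


def project_to_disk(Y: np.ndarray, radius: float) -> np.ndarray:
    """Radially pull every point with |y| > radius back onto the circle."""
    if not math.isfinite(radius):
        return Y
    # rescaling can overshoot by an ulp; repeat until the bound holds exactly
    for _ in range(8):
        r = np.sqrt((Y**2).sum(axis=1))
        out = r > radius
        if not out.any():
            return Y
        Y = Y.copy()
        Y[out] *= (radius / r[out])[:, None]
    r = np.sqrt((Y**2).sum(axis=1))
    out = r > radius
    if out.any():
        Y[out] *= (np.nextafter(radius, 0.0) / r[out])[:, None]
    return Y


def initial_embedding(features: np.ndarray, params: TsneParams,
                      rng: np.random.Generator) -> np.ndarray:
    """Strictly feasible start: PCA init rescaled to max radius R/4, or
    Gaussian noise with sigma 1e-4."""
    n = features.shape[0]
    if params.init == "pca" and features.shape[1] >= 2:
        Xc = features - features.mean(axis=0)
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        for k in range(2):
            j = np.argmax(np.abs(Vt[k]))
            if Vt[k, j] < 0:
                U[:, k] = -U[:, k]
        Y = U[:, :2] * S[:2]
        rmax = np.sqrt((Y**2).sum(axis=1)).max()
        if rmax > 0 and math.isfinite(params.disk_radius):
            Y = Y * (params.disk_radius / 4.0 / rmax)
        elif rmax > 0:
            Y = Y / rmax
        return Y
    return rng.normal(scale=1e-4, size=(n, 2))


def effective_perplexity(n: int, perplexity: float) -> float:
    return min(perplexity, (n - 1) // 3)


def tsne_constrained(features: np.ndarray, params: TsneParams) -> tuple[np.ndarray, np.ndarray]:
    """Embed ``features`` (cells x dims) into the disk of radius R.

    Returns (coordinates (n, 2), per-iteration KL trace). The KL trace is
    always computed against the unexaggerated affinities, so the final value
    is comparable with the value at the end of early exaggeration.
    """
    features = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(features)):
        raise DataError("non-finite values in t-SNE input features")
    n = features.shape[0]
    perp = effective_perplexity(n, params.perplexity)
    if perp < 2:
        raise DataError(f"perplexity infeasible for n={n} (needs n >= 7)")

    P = joint_affinities(features, perp)
    rng = np.random.default_rng(params.seed)
    Y = initial_embedding(features, params, rng)
    Y = project_to_disk(Y, params.disk_radius)

    lr = params.learning_rate if params.learning_rate is not None else max(n / 12.0, 50.0)
    velocity = np.zeros_like(Y)
    gains = np.ones_like(Y)
    kl_trace = np.empty(params.n_iter)

    for it in range(params.n_iter):
        exaggerate = it < params.exaggeration_iter
        if exaggerate:
            grad_e, _ = kl_gradient(P * params.early_exaggeration, Y)
            _, kl = kl_gradient(P, Y)
        else:
            grad_e, kl = kl_gradient(P, Y)
        kl_trace[it] = kl

        momentum = params.momentum_early if exaggerate else params.momentum_late
        inc = np.sign(grad_e) != np.sign(velocity)
        gains[inc] += 0.2
        gains[~inc] *= 0.8
        np.clip(gains, 0.01, None, out=gains)
        velocity = momentum * velocity - lr * gains * grad_e
        Y = project_to_disk(Y + velocity, params.disk_radius)

    return Y, kl_trace
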