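"""Pseudotime estimation and sliding-window smoothing.

Cells are assigned a scalar pseudotime (native PCA or diffusion-map
backends, or a precomputed table imported from an external trajectory
tool), sorted, and averaged over a sliding window of consecutive cells
to form denoised profiles that act as the method's time points.
"""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .io import ExpressionMatrix

logger = logging.getLogger("pseudogrn")


@dataclass
class PseudotimeVector:
    """Per-cell pseudotime; the designated root attains the minimum."""

    cell_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != len(self.cell_ids):
            raise ValueError("pseudotime length must equal the number of cells")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("pseudotime values must be finite")


@dataclass
class SmoothedTrajectory:
    """Genes × windows matrix of window-averaged expression profiles.

    ``window_centers`` holds the mean pseudotime of each window's member
    cells and is non-decreasing by construction.
    """

    values: np.ndarray
    gene_ids: list[str]
    window_centers: np.ndarray

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]

    def gene_profile(self, gene: str) -> np.ndarray:
        try:
            return self.values[self.gene_ids.index(gene)]
        except ValueError:
            raise KeyError(f"gene {gene!r} not in trajectory") from None


def preprocess(expr: ExpressionMatrix, do_normalize: bool = True) -> ExpressionMatrix:
    """Median-library-size scaling followed by log1p, per cell.

    Each cell's column is scaled so its sum equals the median column
    sum, then ``log(1 + value)`` is applied. Disabled → identity.
    """
    if not do_normalize:
        return expr
    colsums = expr.values.sum(axis=0)
    if np.any(colsums == 0):
        j = int(np.argmin(colsums))
        raise ValueError(f"cell {expr.cell_ids[j]!r} has zero total expression")
    scale = np.median(colsums) / colsums
    vals = np.log1p(expr.values * scale)
    return ExpressionMatrix(vals, expr.gene_ids, expr.cell_ids)


def _root_index(expr: ExpressionMatrix, root_cell: str | None, coord: np.ndarray) -> int:
    if root_cell is None:
        return int(np.argmin(coord))
    try:
        return expr.cell_ids.index(root_cell)
    except ValueError:
        raise KeyError(f"root cell {root_cell!r} not in matrix") from None


def pca_pseudotime(expr: ExpressionMatrix, root_cell: str | None = None) -> PseudotimeVector:
    """Pseudotime from the first principal component of the cells.

    Each cell's coordinate on PC1 of the gene-centered matrix, oriented
    so the root cell sits at the low end (sign is flipped when the root
    ranks in the upper half) and shifted so the minimum is 0. Without a
    root, the cell with the smallest PC1 coordinate is taken as root.
    """
    X = expr.values - expr.values.mean(axis=1, keepdims=True)
    if not np.any(np.abs(X) > 1e-12):
        raise ValueError("expression matrix is constant; PCA pseudotime undefined")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    coord = s[0] * Vt[0]
    # deterministic sign: the dominant gene loading is positive
    j = int(np.argmax(np.abs(U[:, 0])))
    if U[j, 0] < 0:
        coord = -coord
    if root_cell is not None:
        i = _root_index(expr, root_cell, coord)
        if (coord < coord[i]).sum() > (len(coord) - 1) / 2:
            coord = -coord
    else:
        i = int(np.argmin(coord))
    pt = coord - coord.min()
    if pt[i] > 1e-9 * max(pt.max(), 1.0):
        logger.warning("root cell %r is not at the extreme of PC1; its pseudotime is %g",
                       expr.cell_ids[i], pt[i])
    return PseudotimeVector(list(expr.cell_ids), pt)


def diffusion_pseudotime(
    expr: ExpressionMatrix,
    root_cell: str | None = None,
    n_neighbors: int = 15,
    n_comps: int = 10,
) -> PseudotimeVector:
    """Pseudotime as diffusion-map distance from a root cell.

    A symmetric Gaussian-kernel affinity is built on the k-nearest-
    neighbor graph with per-cell adaptive bandwidth (distance to the
    k-th neighbor), row-normalized to a transition operator; cells are
    embedded with the top ``n_comps`` non-trivial eigenpairs, each
    eigenvector weighted by ``lambda/(1 - lambda)`` (that mode's
    accumulated weight over all diffusion times), and pseudotime is the
    Euclidean distance from the root in that embedding.
    """
    n = expr.n_cells
    if n_neighbors >= n:
        raise ValueError("n_neighbors must be smaller than the number of cells")
    Y = expr.values.T  # cells x genes
    dist = squareform(pdist(Y))
    # adaptive bandwidth: distance to the k-th neighbor (self excluded)
    sigma = np.partition(dist, n_neighbors, axis=1)[:, n_neighbors].copy()
    positive = sigma[sigma > 0]
    floor = positive.min() * 1e-6 if positive.size else 1.0
    sigma[sigma == 0] = floor
    # tie-inclusive kNN mask: duplicates at the boundary radius all join,
    # which keeps identical cells indistinguishable in the graph; the
    # unit self-affinity of the Gaussian kernel is kept for the same
    # reason (duplicate rows stay exactly equal)
    mask = dist <= sigma[:, None] * (1 + 1e-12)
    mask |= mask.T
    W = np.where(mask, np.exp(-(dist**2) / np.outer(sigma, sigma)), 0.0)
    W = scipy.sparse.csr_matrix(W)

    n_comp_graph, _ = connected_components(W, directed=False)
    if n_comp_graph > 1:
        raise ValueError(
            f"kNN graph has {n_comp_graph} components; increase n_neighbors"
        )

    d = np.asarray(W.sum(axis=1)).ravel()
    inv_sqrt = 1.0 / np.sqrt(d)
    S = W.toarray() * inv_sqrt[:, None] * inv_sqrt[None, :]
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    n_comps = min(n_comps, n - 1)
    take = order[1 : n_comps + 1]  # skip the trivial stationary eigenpair
    # right eigenvectors of the row-normalized operator, scaled by the
    # mode weight accumulated over all diffusion times (capped near 1)
    lam = np.clip(evals[take], None, 1.0 - 1e-10)
    weight = lam / (1.0 - lam)
    embed = (evecs[:, take] * inv_sqrt[:, None]) * weight[None, :]

    c1 = embed[:, 0]
    j = int(np.argmax(np.abs(c1)))
    if c1[j] < 0:
        c1 = -c1
    i = _root_index(expr, root_cell, c1)
    pt = np.linalg.norm(embed - embed[i], axis=1)
    return PseudotimeVector(list(expr.cell_ids), pt)


def load_precomputed_pseudotime(path: str | Path, expr: ExpressionMatrix) -> PseudotimeVector:
    """Import a two-column (cell, pseudotime) table, e.g. a Slingshot run.

    The table is re-aligned to the matrix cell order; missing cells,
    duplicates and non-numeric values are hard errors. A header line
    ``cell<TAB>pseudotime`` is accepted.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (cell, pseudotime)")
    first_val = str(df.iloc[0, 1])
    try:
        float(first_val)
    except ValueError:
        df = df.iloc[1:]  # header line
    cells = df.iloc[:, 0].astype(str).tolist()
    dup = None
    seen: set = set()
    for c in cells:
        if c in seen:
            dup = c
            break
        seen.add(c)
    if dup is not None:
        raise ValueError(f"{path}: duplicate cell {dup!r}")
    try:
        vals = df.iloc[:, 1].astype(float).to_numpy()
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric pseudotime value ({exc})") from None
    table = dict(zip(cells, vals))
    missing = [c for c in expr.cell_ids if c not in table]
    if missing:
        raise ValueError(f"{path}: pseudotime missing for cell {missing[0]!r}")
    pt = np.array([table[c] for c in expr.cell_ids], dtype=float)
    return PseudotimeVector(list(expr.cell_ids), pt)


def order_and_smooth(
    expr: ExpressionMatrix,
    pt: PseudotimeVector,
    width: int = 5,
    step: int = 1,
) -> SmoothedTrajectory:
    """Sort cells by pseudotime and average over a sliding window.

    Window ``j`` covers sorted cells ``[j*step, j*step + width)``; the
    window count is ``floor((n - width)/step) + 1`` (trailing partial
    windows are dropped so every window averages exactly ``width``
    cells). Pseudotime ties are broken lexicographically by cell id.
    """
    n = expr.n_cells
    if width > n:
        raise ValueError(f"window width {width} exceeds cell count {n}")
    if list(pt.cell_ids) != list(expr.cell_ids):
        raise ValueError("pseudotime cell order does not match the matrix")
    start = time.perf_counter()
    order = np.lexsort((np.asarray(expr.cell_ids, dtype=object), pt.values))
    sorted_vals = expr.values[:, order]
    sorted_pt = pt.values[order]
    T = (n - width) // step + 1
    starts = np.arange(T) * step
    windows = np.stack(
        [sorted_vals[:, s : s + width].mean(axis=1) for s in starts], axis=1
    )
    centers = np.array([sorted_pt[s : s + width].mean() for s in starts])
    logger.info(
        "smoothed %d cells into %d windows (width=%d, step=%d) in %.3fs",
        n, T, width, step, time.perf_counter() - start,
    )
    return SmoothedTrajectory(windows, list(expr.gene_ids), centers)
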