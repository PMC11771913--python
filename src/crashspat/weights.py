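"""Spatial weight matrices linking crash observations.

The spatial lag probit couples observations through an n x n proximity
matrix W with zero diagonal.  Two point-data rules are provided: k nearest
neighbours (binary, possibly asymmetric) and a distance band (w_ij = 1 iff
0 < d(i, j) < threshold, symmetric, strict inequality matching the
eps-neighbourhood convention).  Row-standardization rescales each nonzero
row to sum to 1 so that W y* is a weighted average of neighbouring latent
values; the dependence parameter rho then lives on (1/lambda_min, 1), where
lambda_min is the smallest real eigenvalue of the standardized matrix.
Eigenvalues are computed once (dense) and cached — adequate at desk scale
(n up to a few thousand), which is the intended operating range.
"""

from __future__ import annotations

import logging

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

_ROW_SUM_TOL = 1e-12


class WeightMatrix:
    """Sparse n x n spatial proximity structure.

    Parameters
    ----------
    w : scipy sparse or dense array, zero diagonal, non-negative.
    standardized : whether rows have been rescaled to sum to 1.
    isolated : indices of observations with no neighbour (zero rows);
        their spatial lag is identically 0.
    """

    def __init__(self, w, standardized: bool = False, isolated=None):
        w = sp.csr_matrix(w)
        if w.shape[0] != w.shape[1]:
            raise ValueError("W must be square")
        if w.diagonal().any():
            raise ValueError("W must have a zero diagonal")
        if (w.data < 0).any():
            raise ValueError("W entries must be non-negative")
        self.w = w
        self.standardized = standardized
        if isolated is None:
            isolated = np.flatnonzero(np.asarray(w.sum(axis=1)).ravel() == 0)
        self.isolated = np.asarray(isolated, dtype=int)
        self._eigenvalues: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.w.shape[0]

    @property
    def eigenvalues(self) -> np.ndarray:
        """All eigenvalues (possibly complex) of the dense matrix; cached."""
        if self._eigenvalues is None:
            self._eigenvalues = np.linalg.eigvals(self.w.toarray())
        return self._eigenvalues

    @property
    def eigen_support(self) -> tuple[float, float]:
        """Interval (1/lambda_min, 1) on which rho keeps I - rho*W invertible.

        Only meaningful for the row-standardized form, whose largest real
        eigenvalue is 1 (row-stochastic); the lower end uses the most
        negative real eigenvalue.
        """
        if not self.standardized:
            raise ValueError("eigen_support is defined for the standardized matrix")
        re = self.eigenvalues.real
        lam_min = re.min()
        lo = 1.0 / lam_min if lam_min < 0 else -1.0
        return (float(lo), 1.0)

    def toarray(self) -> np.ndarray:
        return self.w.toarray()


def knn_weights(coords, k: int) -> WeightMatrix:
    """Binary k-nearest-neighbour weights.

    w_ij = 1 when j is among the k nearest neighbours of i (the matrix may
    be asymmetric).  Distance ties are broken by ascending index, so the
    result is fully deterministic.  Brute-force all-pairs distances; fine at
    desk scale.
    """
    coords = np.asarray(getattr(coords, "coords", coords), dtype=float)
    n = len(coords)
    if k >= n:
        raise ValueError(f"k ({k}) must be < number of observations ({n})")
    if k < 1:
        raise ValueError("k must be >= 1")
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    idx = np.arange(n)
    rows, cols = [], []
    for i in range(n):
        order = np.lexsort((idx, d2[i]))  # distance, then index
        rows.extend([i] * k)
        cols.extend(order[:k])
    w = sp.csr_matrix((np.ones(n * k), (rows, cols)), shape=(n, n))
    return WeightMatrix(w, standardized=False, isolated=np.array([], dtype=int))


def distance_band_weights(coords, threshold: float) -> WeightMatrix:
    """Symmetric contiguity weights: w_ij = 1 iff 0 < d(i, j) < threshold."""
    if not (threshold > 0):
        raise ValueError("threshold must be > 0")
    coords = np.asarray(getattr(coords, "coords", coords), dtype=float)
    n = len(coords)
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
    adj = (d2 < threshold * threshold) & (d2 > 0)
    np.fill_diagonal(adj, False)
    wm = WeightMatrix(sp.csr_matrix(adj.astype(float)), standardized=False)
    if len(wm.isolated):
        logger.warning("distance_band_weights: %d isolated observation(s) "
                       "(no neighbour within %g)", len(wm.isolated), threshold)
    return wm


def row_standardize(W: WeightMatrix) -> WeightMatrix:
    """Rescale each nonzero row to sum to 1; zero rows stay zero.

    The returned matrix carries the eigenvalue cache needed by the spatial
    sampler's log-determinant term and the rho support interval.
    """
    if W.standardized:
        raise ValueError("W is already row-standardized")
    a = W.w.tocoo()
    row_sums = np.asarray(W.w.sum(axis=1)).ravel()
    scale = np.where(row_sums > 0, row_sums, 1.0)
    data = a.data / scale[a.row]
    ws = sp.csr_matrix((data, (a.row, a.col)), shape=W.w.shape)
    out = WeightMatrix(ws, standardized=True, isolated=W.isolated)
    if len(out.isolated):
        logger.warning("row_standardize: %d zero row(s) left unscaled", len(out.isolated))
    # eagerly compute eigenvalues so the support is cached with the matrix
    _ = out.eigenvalues
    return out


def write_weights(W: WeightMatrix, path) -> None:
    """Sparse triplet text format: header then 'i j w' lines (0-based)."""
    coo = W.w.tocoo()
    with open(path, "w") as fh:
        fh.write(f"# n={W.n} standardized={int(W.standardized)}\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i} {j} {v:.17g}\n")


def read_weights(path) -> WeightMatrix:
    with open(path) as fh:
        header = fh.readline()
        parts = dict(tok.split("=") for tok in header.lstrip("# ").split())
        n = int(parts["n"])
        standardized = bool(int(parts["standardized"]))
        rows, cols, vals = [], [], []
        for line in fh:
            i, j, v = line.split()
            rows.append(int(i)); cols.append(int(j)); vals.append(float(v))
    w = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return WeightMatrix(w, standardized=standardized)
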