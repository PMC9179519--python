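"""Laplacian-eigenmaps reduction of the radiomic feature matrix.

The 354-dimensional conventional radiomic vectors are embedded into a
12-dimensional space (a >= 29x reduction): features are z-scored, a
k-nearest-neighbor graph with Gaussian edge weights is built, and the
generalized eigenproblem L v = lambda D v of the graph Laplacian is solved.
The eigenvectors with the smallest nontrivial eigenvalues form the
embedding.  An elbow criterion on the eigenvalue spectrum suggests the
component count.

Out-of-sample (e.g., the held-out case of a leave-one-out fold) points are
placed by a Nystrom-style extension: the affinity-weighted average of the
training embeddings.  Transductive embedding of train and test together is
available but is not the default, to avoid information leakage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import eigsh


class SpectralError(ValueError):
    """Raised for invalid graph or embedding requests."""


@dataclass
class EmbeddedFeatures:
    """Spectral embedding of a cohort's feature matrix."""

    embedding: np.ndarray     # cases x n_components
    eigenvalues: np.ndarray   # ascending, includes the trivial ~0 first value
    graph: dict               # {"k": ..., "kernel_width": ...}


def standardize(X: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column z-score; constant columns map to zero.  Returns (Z, mean, std)."""
    X = np.asarray(X, dtype=np.float64)
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    safe = np.where(std > 0, std, 1.0)
    return (X - mean) / safe, mean, safe


def build_affinity(X: np.ndarray, k_neighbors: int = 10,
                   kernel_width: Union[str, float] = "auto",
                   standardized: bool = False) -> np.ndarray:
    """Symmetric k-NN Gaussian affinity matrix of the rows of X.

    W[i, j] = exp(-d_ij^2 / width^2) when j is among i's k nearest neighbors
    or vice versa, 0 otherwise; zero diagonal.  ``kernel_width="auto"`` uses
    the median distance over the retained edges (scale-free default).
    """
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    if k_neighbors >= n:
        raise SpectralError(f"k_neighbors={k_neighbors} must be < n_cases={n}")
    if not standardized:
        X, _, _ = standardize(X)
    sq = (X ** 2).sum(axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (X @ X.T), 0.0)
    np.fill_diagonal(d2, np.inf)
    nn = np.argsort(d2, axis=1, kind="stable")[:, :k_neighbors]
    adj = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), k_neighbors)
    adj[rows, nn.ravel()] = True
    adj |= adj.T
    edge_d2 = d2[adj]
    if kernel_width == "auto":
        width = float(np.sqrt(np.median(edge_d2))) if edge_d2.size else 1.0
        if width == 0.0:
            width = 1.0
    else:
        width = float(kernel_width)
        if width <= 0:
            raise SpectralError("kernel_width must be positive")
    W = np.zeros((n, n))
    W[adj] = np.exp(-d2[adj] / width ** 2)
    W = np.maximum(W, W.T)  # exact symmetry
    np.fill_diagonal(W, 0.0)
    return W


def laplacian_eigenmaps(affinity: np.ndarray, n_components: int = 12,
                        graph_info: Optional[dict] = None) -> EmbeddedFeatures:
    """Solve L v = lambda D v on the affinity graph and return the embedding.

    The eigenvectors belonging to the ``n_components`` smallest nontrivial
    eigenvalues (the trivial constant eigenvector is dropped) form the
    columns of the embedding, D-orthonormal, each with its largest-magnitude
    entry made positive.  A disconnected graph is regularized by adding a
    tiny uniform affinity (1e-8) with a warning.
    """
    W = np.asarray(affinity, dtype=np.float64)
    n = W.shape[0]
    if W.shape != (n, n):
        raise SpectralError("affinity must be square")
    if n_components < 1 or n_components >= n - 1:
        raise SpectralError(
            f"n_components={n_components} must be in [1, n_cases-2]")
    n_comp_graph = connected_components(sparse.csr_matrix(W > 0),
                                        directed=False)[0]
    if n_comp_graph > 1:
        warnings.warn(
            f"affinity graph has {n_comp_graph} connected components; "
            "adding 1e-8 uniform regularization", stacklevel=2)
        W = W + 1e-8
        np.fill_diagonal(W, 0.0)
    d = W.sum(axis=1)
    L = sparse.csr_matrix(np.diag(d) - W)
    D = sparse.csr_matrix(np.diag(d))
    k = n_components + 1
    # shift-invert about a slightly negative sigma: L + |sigma| D is PD
    vals, vecs = eigsh(L, k=k, M=D, sigma=-1e-5, which="LM")
    order = np.argsort(vals)
    vals = vals[order]
    vecs = vecs[:, order]
    emb = vecs[:, 1:k]
    # fixed sign convention
    for j in range(emb.shape[1]):
        i_max = int(np.argmax(np.abs(emb[:, j])))
        if emb[i_max, j] < 0:
            emb[:, j] = -emb[:, j]
    return EmbeddedFeatures(embedding=emb, eigenvalues=vals,
                            graph=dict(graph_info or {}))


def embed_radiomics(X: np.ndarray, n_components: int = 12,
                    k_neighbors: int = 10,
                    kernel_width: Union[str, float] = "auto") -> EmbeddedFeatures:
    """Standardize -> affinity graph -> eigenmap embedding, in one call."""
    Z, _, _ = standardize(X)
    W = build_affinity(Z, k_neighbors=k_neighbors, kernel_width=kernel_width,
                       standardized=True)
    info = {"k": k_neighbors, "kernel_width": kernel_width}
    return laplacian_eigenmaps(W, n_components=n_components, graph_info=info)


def elbow_select(eigenvalues: np.ndarray) -> int:
    """Component count at the elbow of the (ascending) eigenvalue curve.

    Returns the index (1-based) maximizing the perpendicular distance from
    the curve to the chord joining its endpoints; ties break toward the
    smaller count.
    """
    lam = np.asarray(eigenvalues, dtype=np.float64)
    if lam.size < 3:
        raise SpectralError("elbow selection needs at least 3 eigenvalues")
    m = lam.size
    x = np.arange(1, m + 1, dtype=np.float64)
    p1 = np.array([x[0], lam[0]])
    p2 = np.array([x[-1], lam[-1]])
    chord = p2 - p1
    norm = np.hypot(*chord)
    if norm == 0:
        return 1
    # |cross product| / chord length = perpendicular distance
    d = np.abs(chord[0] * (lam - p1[1]) - chord[1] * (x - p1[0])) / norm
    tol = 1e-9 * (abs(lam[-1] - lam[0]) + 1.0)
    if d.max() <= tol:
        return 1  # no elbow (chord coincides with curve); smallest count wins
    return int(np.argmax(d >= d.max() - tol)) + 1  # ties -> smaller count


class NystromEmbedder:
    """Inductive embedding: fit on a training matrix, extend to new cases.

    The extension places a new case at the affinity-weighted average of the
    training embeddings, with affinities computed against the new case's
    k nearest training rows using the fitted kernel width.  This is a
    pragmatic out-of-sample remedy; an exact eigenfunction extension is not
    defined for test cases the graph has never seen.
    """

    def __init__(self, n_components: int = 12, k_neighbors: int = 10,
                 kernel_width: Union[str, float] = "auto") -> None:
        self.n_components = n_components
        self.k_neighbors = k_neighbors
        self.kernel_width = kernel_width

    def fit(self, X: np.ndarray) -> "NystromEmbedder":
        Z, self._mean, self._std = standardize(X)
        self._Z = Z
        W = build_affinity(Z, self.k_neighbors, self.kernel_width,
                           standardized=True)
        # recover the width actually used (needed for extension)
        if self.kernel_width == "auto":
            sq = (Z ** 2).sum(axis=1)
            d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (Z @ Z.T), 0.0)
            edge_d2 = d2[W > 0]
            self._width = float(np.sqrt(np.median(edge_d2))) if edge_d2.size else 1.0
        else:
            self._width = float(self.kernel_width)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.result_ = laplacian_eigenmaps(
                W, self.n_components,
                graph_info={"k": self.k_neighbors, "kernel_width": self._width})
        return self

    @property
    def embedding_(self) -> np.ndarray:
        return self.result_.embedding

    def transform(self, X_new: np.ndarray) -> np.ndarray:
        X_new = np.atleast_2d(np.asarray(X_new, dtype=np.float64))
        Z_new = (X_new - self._mean) / self._std
        out = np.empty((Z_new.shape[0], self.n_components))
        for r, z in enumerate(Z_new):
            d2 = ((self._Z - z) ** 2).sum(axis=1)
            nn = np.argsort(d2, kind="stable")[:self.k_neighbors]
            w = np.exp(-d2[nn] / self._width ** 2)
            if w.sum() == 0:
                w = np.ones_like(w)
            out[r] = (w[:, None] * self.embedding_[nn]).sum(axis=0) / w.sum()
        return out
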