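"""Cell embeddings, the mutual-kNN similarity graph and its Laplacian.

Cells are embedded with latent semantic indexing (TF-IDF followed by
truncated SVD), the standard scATAC-seq reduction.  A directed kNN graph on
Euclidean distances is symmetrized by keeping only mutual edges
(A = G_hat * G_hat^T elementwise), and the symmetric normalized Laplacian
G_L = I - D^{-1/2} A D^{-1/2} supplies the smoothness penalty
beta^T G_L beta used during model training.  Isolated cells contribute a
zero diagonal (no penalty).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.spatial.distance import cdist

from .io_harmonize import CellPeakMatrix


@dataclass
class CellEmbedding:
    coords: np.ndarray  # cells x components
    method: str = "lsi"

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]


@dataclass
class CellGraph:
    """Mutual-kNN adjacency with degrees and normalized Laplacian."""

    adjacency: sparse.csr_matrix  # binary, symmetric, zero diagonal
    degrees: np.ndarray
    k: int
    laplacian: sparse.csr_matrix

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]

    def propagation_matrix(self) -> sparse.csr_matrix:
        """Row-normalized adjacency D^{-1} A (zero rows for isolated cells)."""
        inv = np.zeros_like(self.degrees, dtype=float)
        nz = self.degrees > 0
        inv[nz] = 1.0 / self.degrees[nz]
        return sparse.diags(inv) @ self.adjacency


def tfidf(matrix: sparse.spmatrix) -> sparse.csr_matrix:
    """Term-frequency / inverse-document-frequency weighting of counts.

    tf = counts scaled by per-cell total; idf = log(1 + n_cells / (1 + df))
    with df the number of cells in which the peak is open.
    """
    X = sparse.csr_matrix(matrix, dtype=float)
    rs = np.asarray(X.sum(axis=1)).ravel()
    rs[rs == 0] = 1.0
    tf = sparse.diags(1.0 / rs) @ X
    df = np.asarray((X > 0).sum(axis=0)).ravel()
    idf = np.log1p(X.shape[0] / (1.0 + df))
    return sparse.csr_matrix(tf @ sparse.diags(idf))


def lsi_embed(cpm: CellPeakMatrix, n_components: int = 15,
              drop_first: bool = True, seed: int = 0) -> CellEmbedding:
    """LSI cell embedding: TF-IDF then truncated SVD.

    The first component, typically dominated by sequencing depth, is dropped
    by default.  Component signs are fixed (largest-magnitude loading
    positive) so the embedding is deterministic.
    """
    from sklearn.decomposition import TruncatedSVD

    n_cells, n_peaks = cpm.matrix.shape
    if n_components >= min(n_cells, n_peaks):
        raise ValueError(
            f"n_components={n_components} must be < min(cells, peaks)="
            f"{min(n_cells, n_peaks)}")
    X = tfidf(cpm.matrix)
    svd = TruncatedSVD(n_components=n_components, algorithm="arpack",
                       random_state=seed)
    emb = svd.fit_transform(X)
    # deterministic sign convention per component
    for c in range(emb.shape[1]):
        load = svd.components_[c]
        if load[np.argmax(np.abs(load))] < 0:
            emb[:, c] *= -1
    if drop_first:
        emb = emb[:, 1:]
    if emb.shape[1] < 2:
        raise ValueError("fewer than 2 components remain after dropping "
                         "the first; increase n_components")
    return CellEmbedding(coords=emb, method="lsi")


def knn_graph(e: CellEmbedding, k: int) -> sparse.csr_matrix:
    """Directed kNN adjacency on Euclidean distances (self excluded).

    Each row has exactly k ones.  Distance ties are broken by ascending cell
    index, so the graph is deterministic even for duplicated points.
    """
    m = e.n_cells
    if k >= m:
        raise ValueError(f"k={k} must be < number of cells ({m})")
    d = cdist(e.coords, e.coords)
    np.fill_diagonal(d, np.inf)
    # lexsort: primary key distance, secondary key column index
    idx = np.arange(m)
    order = np.argsort(d, axis=1, kind="stable")  # stable => index tiebreak
    nbrs = order[:, :k]
    rows = np.repeat(idx, k)
    data = np.ones(m * k)
    return sparse.csr_matrix((data, (rows, nbrs.ravel())), shape=(m, m))


def mutual_knn(g_hat: sparse.spmatrix) -> sparse.csr_matrix:
    """Keep edges present in both directions: A = G_hat o G_hat^T."""
    a = sparse.csr_matrix(g_hat).multiply(sparse.csr_matrix(g_hat).T)
    a = sparse.csr_matrix(a)
    a.data[:] = 1.0
    a.setdiag(0)
    a.eliminate_zeros()
    return a


def norm_laplacian(a: sparse.spmatrix) -> tuple[sparse.csr_matrix, np.ndarray]:
    """Symmetric normalized Laplacian I - D^{-1/2} A D^{-1/2}.

    Isolated nodes receive a zero diagonal entry so they add nothing to the
    quadratic penalty.  Returns (L, degrees).
    """
    a = sparse.csr_matrix(a)
    deg = np.asarray(a.sum(axis=1)).ravel()
    inv_sqrt = np.zeros_like(deg)
    nz = deg > 0
    inv_sqrt[nz] = 1.0 / np.sqrt(deg[nz])
    dinv = sparse.diags(inv_sqrt)
    lap = sparse.diags(nz.astype(float)) - dinv @ a @ dinv
    return sparse.csr_matrix(lap), deg


def build_cell_graph(e: CellEmbedding, k: int = 25) -> CellGraph:
    """kNN -> mutual-kNN -> normalized Laplacian in one call."""
    g_hat = knn_graph(e, k)
    a = mutual_knn(g_hat)
    lap, deg = norm_laplacian(a)
    return CellGraph(adjacency=a, degrees=deg, k=k, laplacian=lap)


def laplacian_quadratic(lap: sparse.spmatrix, beta: np.ndarray) -> float:
    """beta^T G_L beta, the graph-smoothness penalty."""
    return float(beta @ (sparse.csr_matrix(lap) @ beta))
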