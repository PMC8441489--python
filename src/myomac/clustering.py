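"""PCA embedding, kNN graph, shared-nearest-neighbor weighting and
modularity community detection.

Cells are embedded on the top principal components of the standardized
highly-variable-gene expression, connected to their k nearest Euclidean
neighbors, re-weighted by the Jaccard overlap of neighbor sets (the SNN
graph), and partitioned by greedy Louvain-style optimization of the
resolution-parametrized weighted modularity

    Q(gamma) = sum_c [ w_c / W  -  gamma * (s_c / 2W)^2 ]

with w_c the intra-community edge weight, s_c the community strength sum
and W the total edge weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

DEFAULT_K = 20
DEFAULT_PRUNE = 1.0 / 15.0
DEFAULT_RESOLUTION = 0.8


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    coords: np.ndarray            # cells x PCs
    components: np.ndarray        # PCs x genes (loadings)
    explained_variance_ratio: np.ndarray
    mean: np.ndarray              # per-gene centering
    scale: np.ndarray             # per-gene scaling
    genes: list[str]


def pca_embed(expr, hvg: list[str] | None = None, n_pcs: int = 20,
              unit_scale: bool = True) -> PcaResult:
    """Embed cells on principal components of standardized expression.

    Genes are centered and (by default) unit-scaled before decomposition.
    Columns are ordered by decreasing explained variance with a
    deterministic sign convention: the largest-magnitude loading of each
    component is positive (ties broken toward the lower gene index).

    ``expr`` is an ExpressionMatrix or a bare genes x cells array.
    """
    if hasattr(expr, "gene_index"):
        genes = list(hvg) if hvg is not None else list(expr.gene_ids)
        idx = expr.gene_index(genes)
        X = expr.values[idx].T.astype(float)  # cells x genes
    else:
        arr = np.asarray(expr, dtype=float)
        genes = [f"g{i}" for i in range(arr.shape[0])]
        X = arr.T.copy()
    n_cells, n_genes = X.shape
    if n_pcs > min(n_genes, n_cells):
        raise ValueError(f"n_pcs={n_pcs} exceeds min(n_genes, n_cells)")
    mean = X.mean(axis=0)
    Xc = X - mean
    std = Xc.std(axis=0, ddof=0)
    if np.all(std == 0):
        raise ValueError("degenerate input: all genes constant")
    scale = np.where(std > 0, std, 1.0) if unit_scale else np.ones(n_genes)
    Xs = Xc / scale
    # full SVD: deterministic up to sign, which the convention below fixes
    U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
    U, S, Vt = U[:, :n_pcs], S[:n_pcs], Vt[:n_pcs]
    for j in range(n_pcs):
        lead = np.argmax(np.abs(Vt[j]))
        if Vt[j, lead] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    total_var = (Xs ** 2).sum()
    evr = (S ** 2) / total_var if total_var > 0 else np.zeros(n_pcs)
    return PcaResult(U * S, Vt, evr, mean, scale, genes)


# ---------------------------------------------------------------------------
# kNN / SNN graph
# ---------------------------------------------------------------------------

def knn_graph(embedding: np.ndarray, k: int = DEFAULT_K) -> np.ndarray:
    """k nearest Euclidean neighbors per cell (self excluded).

    Exact all-pairs distances; ties broken by cell index (stable sort).
    Returns an (n, k) integer array of neighbor indices.
    """
    X = np.asarray(embedding, dtype=float)
    n = X.shape[0]
    if not 0 < k < n:
        raise ValueError(f"need 0 < k < n_cells, got k={k}, n={n}")
    sq = (X ** 2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.fill_diagonal(d2, np.inf)
    d2 = np.maximum(d2, 0.0)
    np.fill_diagonal(d2, np.inf)
    order = np.argsort(d2, axis=1, kind="stable")  # stable => index tie-break
    return order[:, :k].astype(np.int64)


@dataclass
class SnnGraph:
    """Undirected cell-cell graph weighted by Jaccard neighbor overlap."""

    weights: sp.csr_matrix  # symmetric, zero diagonal, weights in (0, 1]
    prune: float
    k: int

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def snn_from_knn(knn: np.ndarray, prune: float = DEFAULT_PRUNE) -> SnnGraph:
    """Jaccard SNN weights from kNN lists.

    Neighbor sets include the cell itself, so every set has size k+1;
    weight(i,j) = |N(i) & N(j)| / |N(i) | N(j)|. Edges below ``prune``
    are dropped; self-loops removed.
    """
    knn = np.asarray(knn, dtype=np.int64)
    n, k = knn.shape
    rows = np.repeat(np.arange(n), k + 1)
    cols = np.concatenate([knn, np.arange(n)[:, None]], axis=1).ravel()
    B = sp.csr_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
    inter = (B @ B.T).tocoo()
    union = 2.0 * (k + 1) - inter.data
    w = inter.data / union
    keep = (w >= prune) & (inter.row != inter.col)
    W = sp.csr_matrix((w[keep], (inter.row[keep], inter.col[keep])), shape=(n, n))
    W = W.maximum(W.T)  # numerically symmetric by construction; enforce exactly
    return SnnGraph(W, prune=prune, k=k)


# ---------------------------------------------------------------------------
# Modularity / Louvain
# ---------------------------------------------------------------------------

def modularity(weights: sp.spmatrix, labels: np.ndarray, resolution: float = 1.0) -> float:
    """Q(gamma) of a partition, computed from scratch.

    ``weights`` is a symmetric adjacency with the convention that a
    self-loop of weight l appears as a diagonal entry 2*l.
    """
    A = sp.csr_matrix(weights)
    labels = np.asarray(labels)
    W = A.sum() / 2.0
    if W == 0:
        return 0.0
    strength = np.asarray(A.sum(axis=1)).ravel()
    n_com = labels.max() + 1
    s_c = np.bincount(labels, weights=strength, minlength=n_com)
    coo = A.tocoo()
    same = labels[coo.row] == labels[coo.col]
    w_c = coo.data[same].sum() / 2.0
    return float(w_c / W - resolution * ((s_c / (2.0 * W)) ** 2).sum())


@dataclass
class ClusterAssignment:
    labels: np.ndarray      # cell -> cluster, contiguous 0..K-1
    resolution: float
    modularity: float       # Q recomputed from scratch on the final partition
    modularity_incremental: float  # Q tracked move-by-move during optimization

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


def _one_level(A: sp.csr_matrix, gamma: float, rng: np.random.Generator,
               q_state: list[float]) -> np.ndarray:
    """One Louvain level: greedy node moves until no move improves Q.

    Mutates ``q_state[0]`` by the accumulated Q gain. Returns community
    labels (contiguous).
    """
    n = A.shape[0]
    indptr, indices, data = A.indptr, A.indices, A.data
    W = A.sum() / 2.0
    strength = np.asarray(A.sum(axis=1)).ravel()
    com = np.arange(n)
    s_tot = strength.copy()
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            lo, hi = indptr[i], indptr[i + 1]
            nbr, wts = indices[lo:hi], data[lo:hi]
            mask = nbr != i
            nbr, wts = nbr[mask], wts[mask]
            ci = com[i]
            s_tot[ci] -= strength[i]
            # links from i to each neighboring community
            if nbr.size:
                ncom = com[nbr]
                uniq, inv = np.unique(ncom, return_inverse=True)
                links = np.bincount(inv, weights=wts)
            else:
                uniq = np.array([ci])
                links = np.array([0.0])
            if ci not in uniq:
                uniq = np.append(uniq, ci)
                links = np.append(links, 0.0)
            gains = links / W - gamma * s_tot[uniq] * strength[i] / (2.0 * W * W)
            best = np.argmax(gains)
            # deterministic tie-break: keep current community if tied,
            # else lowest community id
            top = gains.max()
            tied = np.flatnonzero(gains >= top - 1e-15)
            if ci in uniq[tied]:
                best = int(np.flatnonzero(uniq == ci)[0])
            else:
                best = int(tied[np.argmin(uniq[tied])])
            new = uniq[best]
            cur = int(np.flatnonzero(uniq == ci)[0])
            if new != ci:
                q_state[0] += gains[best] - gains[cur]
                com[i] = new
                improved = True
            s_tot[com[i]] += strength[i]
    # contiguous relabel preserving first-occurrence order
    _, com = np.unique(com, return_inverse=True)
    return com


def modularity_cluster(snn: SnnGraph, resolution: float = DEFAULT_RESOLUTION,
                       seed: int = 0) -> ClusterAssignment:
    """Louvain-style modularity clustering of the SNN graph.

    Deterministic given the seed (node visiting order is the only
    stochastic element). A graph with no edges yields singleton clusters.
    """
    A = snn.weights.tocsr().astype(float)
    n = A.shape[0]
    if n == 0:
        raise ValueError("empty graph")
    if A.nnz == 0:
        labels = np.arange(n)
        return ClusterAssignment(labels, resolution, 0.0, 0.0)
    rng = np.random.default_rng(seed)
    W = A.sum() / 2.0
    strength = np.asarray(A.sum(axis=1)).ravel()
    # Q of the singleton partition (diagonal convention: A_ii = 2 * loop)
    q0 = float(A.diagonal().sum() / 2.0 / W
               - resolution * ((strength / (2.0 * W)) ** 2).sum())
    q_state = [q0]
    mapping = np.arange(n)
    level_A = A
    while True:
        labels = _one_level(level_A, resolution, rng, q_state)
        n_com = labels.max() + 1
        if n_com == level_A.shape[0]:
            break
        mapping = labels[mapping]
        C = sp.csr_matrix((np.ones(level_A.shape[0]), (np.arange(level_A.shape[0]), labels)),
                          shape=(level_A.shape[0], n_com))
        level_A = (C.T @ level_A @ C).tocsr()
    # relabel by first occurrence in cell order
    _, labels = np.unique(mapping, return_inverse=True)
    first_seen = {}
    out = np.empty_like(labels)
    nxt = 0
    for i, lab in enumerate(labels):
        if lab not in first_seen:
            first_seen[lab] = nxt
            nxt += 1
        out[i] = first_seen[lab]
    q_scratch = modularity(A, out, resolution)
    return ClusterAssignment(out, resolution, q_scratch, q_state[0])
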