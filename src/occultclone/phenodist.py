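"""Phenotypic distances between samples in rescaled diffusion space.

To quantify transcriptional similarity between samples, all cells are
pooled, QC-filtered (mitochondrial fraction), normalized and reduced by
PCA; a kNN graph (k = 30) with an adaptive Gaussian kernel produces an
affinity matrix which, after symmetrization and row normalization, is a
Markov transition matrix over cells. Its top right eigenvectors are the
diffusion coordinates; each coordinate is rescaled by lambda / (1 -
lambda), which sums the geometric series of multi-step transitions so
distances in the embedding approximate multiscale diffusion distances.
The phenotypic distance between two samples is the mean Euclidean
distance over all cross-sample cell pairs in this space, summarized as an
average-linkage (UPGMA) cladogram. A plain 1 - Pearson distance on
per-sample mean expression serves as a simpler cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.neighbors import NearestNeighbors

from .io_formats import CountMatrix

KNN_K = 30
N_PCS = 30
MITO_MAX = 0.20
N_COMPONENTS = 10


@dataclass
class DiffusionOperator:
    markov: sp.csr_matrix  # cells x cells, row-stochastic
    affinity: sp.csr_matrix  # symmetric kernel before normalization
    k: int
    ka: int
    sigma: np.ndarray


@dataclass
class RescaledEmbedding:
    coords: np.ndarray  # cells x m
    eigenvalues: np.ndarray  # lambda_2 .. lambda_{m+1}
    rescale: np.ndarray


@dataclass
class Cladogram:
    linkage: np.ndarray  # scipy linkage matrix
    names: list[str]

    def newick(self) -> str:
        n = len(self.names)
        heights = {i: 0.0 for i in range(n)}

        def node(i: int) -> str:
            if i < n:
                return self.names[i]
            a, b, h, _ = self.linkage[i - n]
            a, b = int(a), int(b)
            return (
                f"({node(a)}:{h - heights[a]:.6g},{node(b)}:{h - heights[b]:.6g})"
            )

        for row in range(len(self.linkage)):
            heights[n + row] = self.linkage[row, 2]
        return node(n + len(self.linkage) - 1) + ";"

    def merge_order(self) -> list[frozenset]:
        """Leaf sets of the internal nodes in merge order (topology summary)."""
        n = len(self.names)
        sets: dict[int, frozenset] = {i: frozenset([self.names[i]]) for i in range(n)}
        out = []
        for row in range(len(self.linkage)):
            a, b = int(self.linkage[row, 0]), int(self.linkage[row, 1])
            sets[n + row] = sets[a] | sets[b]
            out.append(sets[n + row])
        return out


def embed_cells(
    counts_by_sample: dict[str, CountMatrix],
    n_pcs: int = N_PCS,
    mito_threshold: float = MITO_MAX,
) -> tuple[np.ndarray, np.ndarray]:
    """Pool samples, QC on mitochondrial fraction, normalize, and run PCA.

    Cells with mitochondrial fraction (genes named ``MT-*``) at or above
    ``mito_threshold`` are dropped; counts are library-size normalized,
    log1p-transformed, per-gene standardized, and reduced to ``n_pcs``
    principal components on the pooled matrix.

    Returns (coords, sample_labels).
    """
    import scanpy as sc
    from anndata import AnnData

    samples = sorted(counts_by_sample)
    ref = counts_by_sample[samples[0]]
    gene_names = ref.gene_names if ref.gene_names is not None else ref.gene_ids
    blocks, labels = [], []
    for name in samples:
        cm = counts_by_sample[name]
        if list(cm.gene_ids) != list(ref.gene_ids):
            raise ValueError("samples must share an identical gene space")
        blocks.append(cm.matrix.T)  # cells x genes
        labels.extend([name] * cm.n_cells)
    X = sp.vstack(blocks).tocsr().astype(float)
    labels = np.array(labels, dtype=object)

    if n_pcs >= min(X.shape):
        raise ValueError("n_pcs must be smaller than both n_cells and n_genes")

    mito = np.array([str(g).upper().startswith("MT-") for g in gene_names])
    totals = np.asarray(X.sum(axis=1)).ravel()
    mito_frac = np.zeros(len(totals))
    nz = totals > 0
    if mito.any():
        mito_frac[nz] = np.asarray(X[:, mito].sum(axis=1)).ravel()[nz] / totals[nz]
    keep = mito_frac < mito_threshold
    X, labels = X[keep], labels[keep]

    adata = AnnData(X)
    sc.pp.normalize_total(adata, target_sum=1e4)
    sc.pp.log1p(adata)
    sc.pp.scale(adata, zero_center=True)
    sc.tl.pca(adata, n_comps=n_pcs, svd_solver="arpack", random_state=0)
    return adata.obsm["X_pca"].copy(), labels


def diffusion_operator(
    coords: np.ndarray, k: int = KNN_K, ka: int | None = None
) -> DiffusionOperator:
    """Adaptive-Gaussian-kernel Markov matrix on the Euclidean kNN graph.

    Affinity a_ij = exp(-d_ij^2 / (sigma_i sigma_j)) with sigma_i the
    distance to cell i's ka-th neighbor (default ceil(k/3)); self loops are
    excluded before normalization; the affinity is symmetrized as
    (A + A^T)/2 on the union sparsity pattern and rows normalized to 1.
    """
    n = coords.shape[0]
    if not 1 <= k < n:
        raise ValueError("k must satisfy 1 <= k < n_cells")
    if ka is None:
        ka = ceil(k / 3)
    if not 1 <= ka <= k:
        raise ValueError("ka must satisfy 1 <= ka <= k")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    dist, idx = nn.kneighbors(coords)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self

    sigma = dist[:, ka - 1].astype(float)
    floor = np.where(dist > 0, dist, np.inf).min(axis=1)
    if not np.isfinite(floor).any() and np.all(sigma == 0):
        raise ValueError("all points identical: kernel bandwidth undefined")
    zero = sigma == 0
    sigma[zero] = floor[zero]
    if np.any(~np.isfinite(sigma)) or np.any(sigma == 0):
        raise ValueError("degenerate bandwidth: too many duplicate points")

    rows = np.repeat(np.arange(n), k)
    cols = idx.ravel()
    vals = np.exp(-(dist.ravel() ** 2) / (sigma[rows] * sigma[cols]))
    A = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    A = (A + A.T) / 2.0
    A.setdiag(0.0)
    A.eliminate_zeros()
    d = np.asarray(A.sum(axis=1)).ravel()
    if np.any(d <= 0):
        raise ValueError("isolated cell in the affinity graph")
    markov = sp.diags(1.0 / d) @ A
    return DiffusionOperator(markov.tocsr(), A.tocsr(), k, ka, sigma)


def rescaled_coords(op: DiffusionOperator, m: int = N_COMPONENTS) -> RescaledEmbedding:
    """Top diffusion coordinates rescaled by lambda / (1 - lambda).

    The Markov matrix is diagonalized through its symmetric conjugate
    D^{1/2} P D^{-1/2} (real spectrum, stable eigensolve); the stationary
    lambda = 1 component is dropped and each remaining right eigenvector
    is multiplied by lambda_i / (1 - lambda_i).
    """
    n = op.markov.shape[0]
    if m + 1 >= n:
        raise ValueError("m + 1 eigenpairs exceed the available spectrum")
    d = np.asarray(op.affinity.sum(axis=1)).ravel()
    rootd = np.sqrt(d)
    S = sp.diags(1.0 / rootd) @ op.affinity @ sp.diags(1.0 / rootd)
    v0 = np.full(n, 1.0 / np.sqrt(n))
    vals, vecs = spla.eigsh(S, k=m + 1, which="LA", v0=v0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    # drop the stationary component
    lam = vals[1:]
    psi = vecs[:, 1:] / rootd[:, None]  # right eigenvectors of the Markov matrix
    psi /= np.linalg.norm(psi, axis=0, keepdims=True)
    # deterministic sign: largest-magnitude entry positive
    for j in range(psi.shape[1]):
        i = np.argmax(np.abs(psi[:, j]))
        if psi[i, j] < 0:
            psi[:, j] = -psi[:, j]
    lam = np.clip(lam, -1.0 + 1e-12, 1.0 - 1e-12)
    rescale = lam / (1.0 - lam)
    return RescaledEmbedding(psi * rescale[None, :], lam, rescale)


def sample_distance_matrix(
    embedding: RescaledEmbedding | np.ndarray,
    sample_labels: np.ndarray,
    subsample_n: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean pairwise Euclidean distance between (and within) samples.

    Off-diagonal entries average over all cross-sample cell pairs; the
    diagonal averages distinct within-sample pairs (reported, but excluded
    from the cladogram). An optional seeded per-sample subsample caps the
    pair count.
    """
    coords = embedding.coords if isinstance(embedding, RescaledEmbedding) else embedding
    labels = np.asarray(sample_labels)
    samples = sorted(set(labels))
    rng = np.random.default_rng(seed)
    groups = {}
    for s in samples:
        idx = np.where(labels == s)[0]
        if len(idx) < 1:
            raise ValueError(f"sample {s!r} has no cells")
        if subsample_n is not None and len(idx) > subsample_n:
            idx = np.sort(rng.choice(idx, size=subsample_n, replace=False))
        groups[s] = coords[idx]
    D = pd.DataFrame(0.0, index=samples, columns=samples)
    for i, a in enumerate(samples):
        within = pdist(groups[a])
        D.loc[a, a] = float(within.mean()) if len(within) else 0.0
        for b in samples[i + 1 :]:
            d = float(cdist(groups[a], groups[b]).mean())
            D.loc[a, b] = D.loc[b, a] = d
    return D


def build_cladogram(distances: pd.DataFrame) -> Cladogram:
    """Average-linkage (UPGMA-style) cladogram over the off-diagonal distances."""
    if list(distances.index) != list(distances.columns):
        raise ValueError("distance matrix index and columns must match")
    vals = distances.to_numpy(float)
    if not np.allclose(vals, vals.T):
        raise ValueError("distance matrix must be symmetric")
    names = sorted(distances.index)  # lexicographic order fixes tie-breaks
    vals = distances.loc[names, names].to_numpy(float).copy()
    np.fill_diagonal(vals, 0.0)
    Z = linkage(squareform(vals, checks=False), method="average")
    return Cladogram(Z, names)


def pearson_distance(counts_by_sample: dict[str, CountMatrix]) -> pd.DataFrame:
    """1 - Pearson correlation of per-sample mean log-normalized expression."""
    samples = sorted(counts_by_sample)
    ref = counts_by_sample[samples[0]]
    means = []
    for name in samples:
        cm = counts_by_sample[name]
        if list(cm.gene_ids) != list(ref.gene_ids):
            raise ValueError("samples must share an identical gene space")
        X = cm.matrix.T.astype(float).toarray()
        totals = X.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        mean = np.log1p(X / totals * 1e4).mean(axis=0)
        if mean.std() == 0:
            raise ValueError(f"zero-variance expression vector for sample {name!r}")
        means.append(mean)
    corr = np.corrcoef(np.vstack(means))
    return pd.DataFrame(1.0 - corr, index=samples, columns=samples)
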