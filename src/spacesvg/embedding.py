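"""Spatial embeddings per gene cluster and spot clustering into domains.

Each SVG cluster carries one spatial expression program; a
low-dimensional spatially aware embedding is computed per cluster and
the blocks are concatenated into the final spot embedding.  Spots are
then clustered on a shared-nearest-neighbor graph of that embedding.

The per-cluster embedding is a smoothed PCA: expression is first
averaged over spots with row-stochastic Gaussian weights (a spatial
low-pass that suppresses spot-level noise while keeping the spatial
program), then the top principal-component scores of the smoothed,
gene-centered submatrix are retained.  The smoothing bandwidth and the
number of retained components are exposed so a different spatially
aware embedding can be substituted.

The pooled baseline — one embedding from the top SVGs ranked by
combined p-value, no gene clustering — is the standard workflow this
package improves on, and is included for comparison.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Optional, Sequence

import igraph as ig
import leidenalg
import numpy as np
from sklearn.neighbors import NearestNeighbors

from .containers import ExpressionMatrix
from .dependency import GeneClusters
from .detection import SVGTestResult
from .geometry import SpotSet, pairwise_distances

__all__ = [
    "EmbeddingBlock",
    "spatial_smooth",
    "cluster_embedding",
    "aggregate",
    "detect_domains",
    "space_domains",
    "pooled_baseline",
    "default_bandwidth",
]


@dataclass
class EmbeddingBlock:
    """Per-cluster spot embedding: ``(n_spots, d)`` score matrix."""

    cluster_id: int
    scores: np.ndarray

    @property
    def d(self) -> int:
        return self.scores.shape[1]


def default_bandwidth(spots: SpotSet, knn: int = 10) -> float:
    """Median distance to the ``knn``-th nearest neighbor.

    A local length scale: smoothing then averages over a spot's
    immediate neighborhood, suppressing spot-level noise without
    blurring domains together.  (A global scale such as the median of
    all pairwise distances over-smooths — on typical slides it spans a
    large fraction of the tissue and collapses the embedding onto one
    smooth gradient.)
    """
    n = spots.n_spots
    k = int(min(knn, n - 1))
    nn = NearestNeighbors(n_neighbors=k + 1).fit(spots.coords)
    dist, _ = nn.kneighbors(spots.coords)
    scale = float(np.median(dist[:, k]))
    if scale <= 0:
        raise ValueError("all spots coincide; no usable bandwidth")
    return scale


def _smoother(spots: SpotSet, bandwidth: float) -> np.ndarray:
    if not np.isfinite(bandwidth) or bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    d = pairwise_distances(spots)
    W = np.exp(-(d ** 2) / (2.0 * bandwidth ** 2))
    W /= W.sum(axis=1, keepdims=True)
    return W


def spatial_smooth(
    block_expr: np.ndarray, spots: SpotSet, bandwidth: Optional[float] = None
) -> np.ndarray:
    """Row-stochastic Gaussian-kernel average of each gene over spots.

    Constant genes are preserved exactly; as ``bandwidth -> 0`` the
    output approaches the input.
    """
    X = np.atleast_2d(np.asarray(block_expr, dtype=float))
    if X.shape[1] != spots.n_spots:
        raise ValueError("expression block and SpotSet disagree on spots")
    if bandwidth is None:
        bandwidth = default_bandwidth(spots)
    W = _smoother(spots, bandwidth)
    return X @ W.T


def cluster_embedding(
    cluster_expr: np.ndarray,
    spots: SpotSet,
    d: int = 20,
    bandwidth: Optional[float] = None,
) -> np.ndarray:
    """Top-``d`` principal scores of the smoothed, centered cluster block.

    ``d`` is truncated to ``n_genes - 1`` (a centered rank bound) for
    multi-gene clusters; a single-gene cluster yields its smoothed,
    centered profile as a one-column block.
    """
    X = np.atleast_2d(np.asarray(cluster_expr, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("empty cluster")
    S = spatial_smooth(X, spots, bandwidth)
    S = S - S.mean(axis=1, keepdims=True)
    if X.shape[0] == 1:
        return S.T
    d_eff = int(min(d, X.shape[0] - 1, spots.n_spots - 1))
    M = S.T  # spots x genes
    M = M - M.mean(axis=0, keepdims=True)
    U, sv, _ = np.linalg.svd(M, full_matrices=False)
    return U[:, :d_eff] * sv[:d_eff]


def aggregate(blocks: Sequence[np.ndarray], standardize: bool = False) -> np.ndarray:
    """Concatenate per-cluster embedding blocks column-wise."""
    blocks = [np.atleast_2d(np.asarray(b, dtype=float)) for b in blocks]
    if not blocks:
        raise ValueError("no embedding blocks to aggregate")
    n = blocks[0].shape[0]
    if any(b.shape[0] != n for b in blocks):
        raise ValueError("embedding blocks disagree on the number of spots")
    if standardize:
        blocks = [b / max(np.linalg.norm(b), 1e-12) for b in blocks]
    return np.hstack(blocks)


def _snn_graph(embedding: np.ndarray, knn: int) -> ig.Graph:
    n = embedding.shape[0]
    k = int(min(knn, n - 1))
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    neigh = [set(row[1:]) for row in idx]
    edges, weights = [], []
    seen = set()
    for i in range(n):
        for j in idx[i, 1:]:
            j = int(j)
            a, b = (i, j) if i < j else (j, i)
            if (a, b) in seen:
                continue
            seen.add((a, b))
            shared = len(neigh[a] & neigh[b])
            w = shared / len(neigh[a] | neigh[b])
            edges.append((a, b))
            weights.append(max(w, 1e-6))
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    comps = g.connected_components()
    if len(comps) > 1:
        # bridge components through their closest point pairs so that
        # dendrogram-based methods can always reach the requested count
        w_min = min(weights) if weights else 1e-6
        reps = [list(c) for c in comps]
        base = reps[0]
        base_pts = embedding[base]
        for other in reps[1:]:
            d2 = ((embedding[other][:, None, :] - base_pts[None, :, :]) ** 2).sum(-1)
            i, j = np.unravel_index(np.argmin(d2), d2.shape)
            g.add_edge(other[i], base[j], weight=w_min)
    return g


def detect_domains(
    embedding: np.ndarray,
    method: str = "leiden",
    k_domains: Optional[int] = None,
    resolution: float = 1.0,
    knn: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Cluster spots on a shared-nearest-neighbor graph of the embedding.

    ``leiden``/``louvain`` operate at the given resolution when the
    number of domains is unknown; ``walktrap`` cuts its dendrogram at
    ``k_domains`` when that is given.  Returns contiguous integer
    labels per spot.
    """
    E = np.atleast_2d(np.asarray(embedding, dtype=float))
    n = E.shape[0]
    if k_domains is not None:
        if not (1 <= k_domains <= n):
            raise ValueError("k_domains must lie in [1, n_spots]")
        if k_domains == 1:
            return np.zeros(n, dtype=int)
    if knn < 1:
        raise ValueError("knn must be at least 1")
    g = _snn_graph(E, knn)
    if method == "leiden":
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            weights="weight",
            resolution_parameter=resolution,
            seed=seed,
        )
        labels = np.asarray(part.membership)
    elif method == "louvain":
        ig.set_random_number_generator(random.Random(seed))
        part = g.community_multilevel(weights="weight")
        labels = np.asarray(part.membership)
    elif method == "walktrap":
        dend = g.community_walktrap(weights="weight")
        k = k_domains if k_domains is not None else dend.optimal_count
        try:
            part = dend.as_clustering(k)
        except Exception:
            part = dend.as_clustering()
        labels = np.asarray(part.membership)
    else:
        raise ValueError(f"unknown domain method {method!r}")
    # relabel contiguously by first appearance
    _, labels = np.unique(labels, return_inverse=True)
    return labels


def refine_labels(labels: np.ndarray, spots: SpotSet, knn: int = 10) -> np.ndarray:
    """Optional majority-vote smoothing over spatial nearest neighbors."""
    n = spots.n_spots
    k = int(min(knn, n - 1))
    nn = NearestNeighbors(n_neighbors=k + 1).fit(spots.coords)
    _, idx = nn.kneighbors(spots.coords)
    out = labels.copy()
    for i in range(n):
        votes = np.bincount(labels[idx[i, 1:]])
        top = int(np.argmax(votes))
        if votes[top] > k / 2:
            out[i] = top
    return out


def space_domains(
    expr: ExpressionMatrix,
    spots: SpotSet,
    clusters: GeneClusters,
    d: int = 20,
    bandwidth: Optional[float] = None,
    method: str = "walktrap",
    k_domains: Optional[int] = None,
    resolution: float = 1.0,
    knn: int = 10,
    seed: int = 0,
    refine: bool = False,
    standardize: bool = True,
    min_cluster_size: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Domain labels from aggregated per-gene-cluster embeddings.

    Returns ``(labels, embedding)``.  By default blocks are
    standardized to equal total scale before concatenation — the point
    of per-cluster embeddings is that every spatial program gets equal
    footing, so a 30-gene cluster should not be drowned out by an
    800-gene one — and clusters below ``min_cluster_size`` genes
    (singletons) are excluded: a lone gene's embedding is its own noisy
    profile, unvalidated by any correlated peer, and standardization
    would inflate it to the scale of a whole cluster.  Set
    ``min_cluster_size=1`` and/or ``standardize=False`` to include
    everything at raw scale.  Falls back to including singletons when
    no larger cluster exists.
    """
    if not clusters.labels:
        raise ValueError("no gene clusters; nothing to embed")
    if bandwidth is None:
        bandwidth = default_bandwidth(spots)
    by_cluster: dict[int, list] = {}
    for gene, lab in clusters.labels.items():
        by_cluster.setdefault(lab, []).append(gene)
    kept = {lab: genes for lab, genes in by_cluster.items() if len(genes) >= min_cluster_size}
    if not kept:
        kept = by_cluster
    blocks = []
    for lab in sorted(kept):
        genes = sorted(kept[lab], key=list(expr.gene_ids).index)
        block = expr.subset(genes).values
        blocks.append(cluster_embedding(block, spots, d=d, bandwidth=bandwidth))
    E = aggregate(blocks, standardize=standardize)
    labels = detect_domains(
        E, method=method, k_domains=k_domains, resolution=resolution, knn=knn, seed=seed
    )
    if refine:
        labels = refine_labels(labels, spots)
    return labels, E


def pooled_baseline(
    expr: ExpressionMatrix,
    spots: SpotSet,
    svg_result: SVGTestResult,
    n_top: int = 3000,
    d: int = 20,
    bandwidth: Optional[float] = None,
    method: str = "walktrap",
    k_domains: Optional[int] = None,
    resolution: float = 1.0,
    knn: int = 10,
    seed: int = 0,
    refine: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Domains from one embedding of the pooled top SVGs (no gene clusters).

    SVGs are ranked by combined p-value; the top ``n_top`` (capped at
    the number detected) form a single block of ``d`` spatial principal
    components, clustered exactly as in :func:`space_domains`.
    """
    tab = svg_result.table
    svgs = tab.loc[tab["is_svg"]].sort_values("p_combined", kind="stable")
    if len(svgs) == 0:
        raise ValueError("no SVGs detected; cannot build the pooled embedding")
    top = tuple(svgs["gene_id"].head(int(n_top)))
    block = expr.subset(top).values
    E = cluster_embedding(block, spots, d=d, bandwidth=bandwidth)
    labels = detect_domains(
        E, method=method, k_domains=k_domains, resolution=resolution, knn=knn, seed=seed
    )
    if refine:
        labels = refine_labels(labels, spots)
    return labels, E
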