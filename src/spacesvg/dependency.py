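"""SVG classification by covariate-adjusted retesting and graph clustering.

The intuition: two spatially variable genes sharing a spatial pattern
are correlated, so regressing one on the other (or on principal
components of its correlated set) absorbs the shared spatial signal.
For each detected SVG ``j`` the pipeline

1. selects the set ``S_j`` of other SVGs whose absolute correlation
   with ``j`` reaches a threshold;
2. builds adjustment covariates — the member genes themselves when
   ``|S_j| <= 3``, otherwise the top principal components explaining at
   least 80 % of the set's variance;
3. reruns the multi-kernel score test with those covariates in the
   design.  A gene that stays significant has a spatial pattern its
   correlated peers cannot explain — a *unique* gene;
4. connects non-unique SVGs whose correlation reaches the threshold
   into a weighted graph and partitions it with Leiden community
   detection.  Unique genes become singleton clusters.

Since many SVGs are cell-type markers with strongly correlated
expression, the adjustment also absorbs shared cell-type composition
effects without requiring cell-type annotations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import ExpressionMatrix
from .detection import SVGTestEngine, SVGTestResult, cauchy_combine, detect_svgs
from .geometry import KernelBank, SpotSet

__all__ = [
    "DependencyRecord",
    "GeneGraph",
    "GeneClusters",
    "SpaceConfig",
    "correlated_set",
    "adjustment_covariates",
    "adjusted_test",
    "build_graph",
    "cluster_genes",
    "space_pipeline",
    "SpaceResult",
]


@dataclass
class DependencyRecord:
    """Adjusted-retest outcome for one SVG."""

    gene_id: str
    correlated_set: tuple
    n_covariates: int
    p_adjusted: float
    unique: bool
    fully_explained: bool = False


@dataclass
class GeneGraph:
    """Weighted undirected graph over detected SVGs.

    Edges join non-unique SVG pairs whose absolute correlation reaches
    the threshold; the weight is that absolute correlation.
    """

    nodes: tuple
    edges: list  # (id_i, id_j, weight)

    def subgraph_igraph(self) -> ig.Graph:
        index = {g: i for i, g in enumerate(self.nodes)}
        g = ig.Graph(n=len(self.nodes))
        g.vs["name"] = list(self.nodes)
        if self.edges:
            g.add_edges([(index[a], index[b]) for a, b, _ in self.edges])
            g.es["weight"] = [w for _, _, w in self.edges]
        return g


@dataclass
class GeneClusters:
    """Partition of detected SVGs into pattern clusters and singletons."""

    labels: dict  # gene_id -> cluster label (contiguous ints)
    singletons: tuple
    n_clusters: int

    def label_array(self, gene_ids) -> np.ndarray:
        return np.array([self.labels[g] for g in gene_ids])


def _correlation_matrix(values: np.ndarray, method: str) -> np.ndarray:
    if method == "pearson":
        data = values
    elif method == "spearman":
        data = np.apply_along_axis(rankdata, 1, values)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    sd = data.std(axis=1)
    ok = sd > 0
    corr = np.zeros((data.shape[0], data.shape[0]))
    if ok.sum() >= 2:
        corr[np.ix_(ok, ok)] = np.corrcoef(data[ok])
    np.fill_diagonal(corr, 1.0)
    return corr


def correlated_set(
    expr: ExpressionMatrix,
    gene_j: str,
    svg_ids,
    method: str = "pearson",
    threshold: float = 0.5,
) -> tuple:
    """SVGs (other than ``gene_j``) correlated with it at ``threshold``."""
    svg_ids = tuple(svg_ids)
    if gene_j not in svg_ids:
        raise ValueError(f"{gene_j!r} is not among the SVG ids")
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    sub = expr.subset(svg_ids)
    corr = _correlation_matrix(sub.values, method)
    j = svg_ids.index(gene_j)
    keep = np.abs(corr[j]) >= threshold
    keep[j] = False
    return tuple(g for g, k in zip(svg_ids, keep) if k)


def adjustment_covariates(
    expr: ExpressionMatrix, correlated: tuple, variance_target: float = 0.8
) -> np.ndarray:
    """Covariate block for the adjusted retest of one gene.

    With three or fewer correlated genes the (centered) genes
    themselves are the covariates; with more, the top principal
    components of the correlated submatrix are used, keeping the
    smallest number of components whose cumulative explained variance
    reaches ``variance_target``.  Returns an ``(n_spots, k)`` block.
    """
    if len(correlated) == 0:
        raise ValueError("empty correlated set: test the gene unadjusted instead")
    block = expr.subset(correlated).values  # (|S_j|, n_spots)
    block = block - block.mean(axis=1, keepdims=True)
    if len(correlated) <= 3:
        return block.T
    # PCA over spots: spots are observations, member genes are features
    _, s, vt = np.linalg.svd(block, full_matrices=False)
    var = s ** 2
    ratio = np.cumsum(var) / var.sum()
    k = int(np.searchsorted(ratio, variance_target - 1e-12) + 1)
    scores = vt[:k].T * s[:k]  # (n_spots, k) principal-component scores
    return scores


def adjusted_test(
    y: np.ndarray,
    covariates: Optional[np.ndarray],
    spots: SpotSet,
    bank: Optional[KernelBank] = None,
    engine: Optional[SVGTestEngine] = None,
) -> tuple[float, bool]:
    """Cauchy-combined score-test p-value under a covariate-adjusted design.

    Returns ``(p_combined, fully_explained)``; ``fully_explained`` is
    True when the covariates span the gene (zero residual variance), in
    which case the p-value is 1.
    """
    if engine is None:
        engine = SVGTestEngine(spots, bank)
    _, pvals, fully = engine.adjusted_pvalues(y, covariates)
    if fully:
        return 1.0, True
    return cauchy_combine(pvals), False


def build_graph(svg_ids, correlations: np.ndarray, threshold: float, unique_flags) -> GeneGraph:
    """Dependency graph over SVGs; unique-flagged genes stay isolated."""
    svg_ids = tuple(svg_ids)
    corr = np.asarray(correlations, dtype=float)
    if corr.shape != (len(svg_ids), len(svg_ids)):
        raise ValueError("correlation matrix does not match svg_ids")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    unique = dict(zip(svg_ids, unique_flags))
    edges = []
    for i in range(len(svg_ids)):
        if unique[svg_ids[i]]:
            continue
        for j in range(i + 1, len(svg_ids)):
            if unique[svg_ids[j]]:
                continue
            w = abs(corr[i, j])
            if w >= threshold:
                edges.append((svg_ids[i], svg_ids[j], float(min(w, 1.0))))
    return GeneGraph(svg_ids, edges)


def cluster_genes(graph: GeneGraph, resolution: float = 1.0, seed: int = 0) -> GeneClusters:
    """Leiden communities on the dependency graph; isolates become singletons.

    Modularity-type objective (RB configuration null model) at the
    given resolution, with a fixed seed for reproducibility.  Nodes
    without edges — unique genes and unconnected SVGs — each form a
    cluster of size one.
    """
    if len(graph.nodes) == 0:
        return GeneClusters({}, (), 0)
    g = graph.subgraph_igraph()
    degrees = np.array(g.degree())
    connected = np.nonzero(degrees > 0)[0]
    labels = {}
    next_label = 0
    if connected.size:
        sub = g.subgraph(connected)
        part = leidenalg.find_partition(
            sub,
            leidenalg.RBConfigurationVertexPartition,
            weights="weight",
            resolution_parameter=resolution,
            seed=seed,
        )
        for local, comm in enumerate(part.membership):
            labels[sub.vs[local]["name"]] = comm
        next_label = max(part.membership) + 1
    singletons = []
    for v in np.nonzero(degrees == 0)[0]:
        name = g.vs[int(v)]["name"]
        labels[name] = next_label
        next_label += 1
        singletons.append(name)
    return GeneClusters(labels, tuple(singletons), next_label)


@dataclass(frozen=True)
class SpaceConfig:
    """Tunable parameters of the full SVG-clustering pipeline."""

    fdr: float = 0.05
    corr_method: str = "pearson"
    corr_threshold: float = 0.5
    variance_target: float = 0.8
    resolution: float = 1.0
    seed: int = 0
    singleton_rule: str = "unconnected"


@dataclass
class SpaceResult:
    """All artifacts of the two-step pipeline."""

    svg_result: SVGTestResult
    dependencies: list  # DependencyRecord per SVG
    graph: GeneGraph
    clusters: GeneClusters

    def dependency_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [d.gene_id for d in self.dependencies],
                "n_correlated": [len(d.correlated_set) for d in self.dependencies],
                "n_covariates": [d.n_covariates for d in self.dependencies],
                "p_adjusted": [d.p_adjusted for d in self.dependencies],
                "unique": [d.unique for d in self.dependencies],
            }
        )

    def cluster_frame(self) -> pd.DataFrame:
        genes = sorted(self.clusters.labels, key=lambda g: self.clusters.labels[g])
        singles = set(self.clusters.singletons)
        return pd.DataFrame(
            {
                "gene_id": genes,
                "cluster_label": [self.clusters.labels[g] for g in genes],
                "is_singleton": [g in singles for g in genes],
            }
        )


def _bh_cutoff(pvalues: np.ndarray, alpha: float) -> float:
    """Benjamini-Hochberg data-driven p-value cutoff for a p-value set."""
    p = np.sort(np.asarray(pvalues, dtype=float))
    m = p.size
    if m == 0:
        return alpha
    crit = alpha * np.arange(1, m + 1) / m
    passing = p <= crit
    if not passing.any():
        return alpha / m
    return float(p[np.nonzero(passing)[0].max()])


def space_pipeline(
    expr: ExpressionMatrix,
    spots: SpotSet,
    config: SpaceConfig = SpaceConfig(),
    bank: Optional[KernelBank] = None,
    engine: Optional[SVGTestEngine] = None,
) -> SpaceResult:
    """Detection, adjusted retesting, graph construction and clustering.

    A gene counts as *still significant* when its adjusted combined
    p-value stays at or below the BH cutoff recomputed over the
    detected SVGs' combined p-values.  SVGs with an empty correlated
    set keep their unadjusted p-value (there is nothing to adjust for).

    How significance translates into singleton status is set by
    ``config.singleton_rule``:

    * ``"unconnected"`` (default) — a gene is unique only when it is
      still significant *and* has no correlated SVG peers at the
      threshold.  Genes whose shared pattern is imperfectly absorbed by
      noisy covariates (adjustment against noisy peers always leaks
      some signal, which a score test over thousands of spots can
      detect) remain in the graph and cluster with their group.
    * ``"significant"`` — every still-significant gene is isolated
      before clustering, regardless of its correlations.
    """
    expr.check_aligned(spots)
    if engine is None:
        engine = SVGTestEngine(spots, bank)
    svg_result = detect_svgs(expr, spots, alpha=config.fdr, engine=engine)
    svg_ids = svg_result.svg_ids
    if len(svg_ids) == 0:
        return SpaceResult(svg_result, [], GeneGraph((), []), GeneClusters({}, (), 0))

    sub = expr.subset(svg_ids)
    corr = _correlation_matrix(sub.values, config.corr_method)
    svg_p = svg_result.table.set_index("gene_id").loc[list(svg_ids), "p_combined"]
    cutoff = _bh_cutoff(svg_p.to_numpy(), config.fdr)

    # one gene-space Gram of the centered SVG block serves every
    # per-gene PCA below (PCA of a row subset only needs the
    # corresponding Gram submatrix); scores match adjustment_covariates
    # up to column sign, which the regression span ignores
    centered = sub.values - sub.values.mean(axis=1, keepdims=True)
    gram = centered @ centered.T

    def _covariates(member_idx: np.ndarray) -> np.ndarray:
        if member_idx.size <= 3:
            return centered[member_idx].T
        G = gram[np.ix_(member_idx, member_idx)]
        evals, evecs = np.linalg.eigh(G)
        evals, evecs = evals[::-1], evecs[:, ::-1]
        ratio = np.cumsum(evals) / max(evals.sum(), 1e-300)
        k = int(np.searchsorted(ratio, config.variance_target - 1e-12) + 1)
        return centered[member_idx].T @ evecs[:, :k]

    records = []
    for idx, gene in enumerate(svg_ids):
        mask = np.abs(corr[idx]) >= config.corr_threshold
        mask[idx] = False
        s_j = tuple(g for g, keep in zip(svg_ids, mask) if keep)
        if s_j:
            covs = _covariates(np.nonzero(mask)[0])
            p_adj, fully = adjusted_test(sub.values[idx], covs, spots, engine=engine)
            k_j = covs.shape[1]
        else:
            p_adj = float(svg_p.iloc[idx])
            fully = False
            k_j = 0
        significant = p_adj <= cutoff
        if config.singleton_rule == "unconnected":
            unique = significant and len(s_j) == 0
        elif config.singleton_rule == "significant":
            unique = significant
        else:
            raise ValueError(f"unknown singleton_rule {config.singleton_rule!r}")
        records.append(
            DependencyRecord(gene, s_j, k_j, p_adj, unique=unique, fully_explained=fully)
        )

    unique_flags = [r.unique for r in records]
    graph = build_graph(svg_ids, corr, config.corr_threshold, unique_flags)
    clusters = cluster_genes(graph, config.resolution, config.seed)
    return SpaceResult(svg_result, records, graph, clusters)
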