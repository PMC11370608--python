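"""Evaluation metrics: ARI, PAS, empirical power and clustering FDR."""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import NearestNeighbors

from .dependency import GeneClusters
from .geometry import SpotSet

__all__ = ["adjusted_rand_index", "pas", "empirical_power", "empirical_fdr"]


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected partition agreement in [-1, 1]."""
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if a.size != b.size:
        raise ValueError("label vectors must have equal length")
    if a.size < 2:
        raise ValueError("need at least two items")
    return float(adjusted_rand_score(a, b))


def pas(labels, spots: SpotSet, n_neighbors: int = 10, frac: float = 0.6) -> float:
    """Percentage of abnormal spots.

    A spot is abnormal when its label differs from at least
    ``ceil(frac * k)`` of its ``k`` Euclidean nearest neighbors
    (``k = 10``, or all other spots when fewer are available; distance
    ties broken by spot index).  Lower is better: smooth, contiguous
    domain maps have PAS near 0.
    """
    lab = np.asarray(labels).ravel()
    n = spots.n_spots
    if lab.size != n:
        raise ValueError("labels and SpotSet disagree on the number of spots")
    k = int(min(n_neighbors, n - 1))
    threshold = int(np.ceil(frac * k))
    nn = NearestNeighbors(n_neighbors=k + 1).fit(spots.coords)
    _, idx = nn.kneighbors(spots.coords)
    abnormal = 0
    for i in range(n):
        neigh = idx[i][idx[i] != i][:k]
        if np.sum(lab[neigh] != lab[i]) >= threshold:
            abnormal += 1
    return abnormal / n


def empirical_power(is_svg_replicates: Sequence[np.ndarray]) -> np.ndarray:
    """Per-gene detection frequency across replicates.

    ``is_svg_replicates`` holds one boolean vector per replicate, all
    over the same gene layout.
    """
    mat = np.asarray([np.asarray(r, dtype=bool) for r in is_svg_replicates])
    if mat.ndim != 2:
        raise ValueError("replicates must share the gene layout")
    return mat.mean(axis=0)


def empirical_fdr(clusters: GeneClusters, nonspatial_ids) -> float:
    """Fraction of the clustering output occupied by non-spatial genes.

    Every gene in the final output — member of any cluster or a
    singleton — counts as a discovery; a non-spatial gene among them is
    a false discovery.  Returns 0 when there are no discoveries.
    """
    out_genes = list(clusters.labels)
    if not out_genes:
        return 0.0
    bad = set(nonspatial_ids)
    false = sum(1 for g in out_genes if g in bad)
    return false / len(out_genes)
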