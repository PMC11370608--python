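"""Spot geometry and the spatial kernel bank.

Spatial similarity between capture spots is encoded by kernel matrices
built from pairwise Euclidean distances.  Two kernel families are used:

* Gaussian, ``exp(-d^2 / (2 l^2))`` with bandwidth ``l`` — smooth,
  monotonically decaying similarity;
* Cosine, ``cos(2 pi d / phi)`` with period ``phi`` — oscillatory
  similarity that captures periodic expression patterns.

The default bank holds five kernels of each family with scales set to
the {0.1, 0.3, 0.5, 0.7, 0.9} quantiles of the nonzero pairwise-distance
distribution, so the bank spans coarse to fine spatial structure and is
reproducible from the coordinates alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "SpotSet",
    "KernelSpec",
    "KernelBank",
    "pairwise_distances",
    "build_kernel",
    "default_kernel_bank",
    "DEFAULT_SCALE_QUANTILES",
]

DEFAULT_SCALE_QUANTILES = (0.1, 0.3, 0.5, 0.7, 0.9)


@dataclass(frozen=True)
class SpotSet:
    """An ordered set of capture spots with Euclidean coordinates.

    Parameters
    ----------
    spot_ids
        Unique identifiers, one per spot.  Order is significant: it
        defines spot order in every downstream matrix.
    coords
        ``(n_spots, n_dims)`` array of coordinates, finite, usually 2-D.
    """

    spot_ids: tuple
    coords: np.ndarray

    def __post_init__(self):
        ids = tuple(self.spot_ids)
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim == 1:
            coords = coords[:, None]
        if coords.ndim != 2:
            raise ValueError("coords must be a 2-D array of shape (n_spots, n_dims)")
        if len(ids) != coords.shape[0]:
            raise ValueError("spot_ids and coords disagree on the number of spots")
        if len(ids) < 2:
            raise ValueError("a SpotSet needs at least two spots")
        if len(set(ids)) != len(ids):
            raise ValueError("spot ids must be unique")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "spot_ids", ids)
        object.__setattr__(self, "coords", coords)

    @property
    def n_spots(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class KernelSpec:
    """One kernel: a family and a positive length scale.

    ``scale`` is the Gaussian bandwidth ``l`` or the Cosine period
    ``phi``, in the same length units as the spot coordinates.
    """

    family: Literal["gaussian", "cosine"]
    scale: float

    def __post_init__(self):
        if self.family not in ("gaussian", "cosine"):
            raise ValueError(f"unknown kernel family {self.family!r}")
        if not np.isfinite(self.scale) or self.scale <= 0:
            raise ValueError("kernel scale must be a positive finite number")


@dataclass
class KernelBank:
    """An ordered collection of kernel specifications."""

    specs: Sequence[KernelSpec] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.specs)

    def __iter__(self):
        return iter(self.specs)

    def __getitem__(self, i):
        return self.specs[i]


def pairwise_distances(spots: SpotSet) -> np.ndarray:
    """Dense symmetric matrix of Euclidean distances between spots."""
    return squareform(pdist(spots.coords))


def build_kernel(distances: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Evaluate one kernel on a distance matrix.

    Gaussian: ``exp(-d^2/(2 l^2))``; Cosine: ``cos(2 pi d / phi)``.
    Both give exactly 1 at zero distance, so the result has a unit
    diagonal.
    """
    d = np.asarray(distances, dtype=float)
    if spec.family == "gaussian":
        return np.exp(-(d ** 2) / (2.0 * spec.scale ** 2))
    return np.cos(2.0 * np.pi * d / spec.scale)


def default_kernel_bank(
    distances: np.ndarray,
    quantiles: Sequence[float] = DEFAULT_SCALE_QUANTILES,
) -> KernelBank:
    """Data-adaptive bank of 5 Gaussian + 5 Cosine kernels.

    Scales are the given quantiles of the nonzero pairwise-distance
    distribution, shared by both families, strictly increasing within
    each family.  Raises if all spots coincide (no nonzero distance).
    """
    d = np.asarray(distances, dtype=float)
    iu = np.triu_indices_from(d, k=1)
    nz = d[iu]
    nz = nz[nz > 0]
    if nz.size == 0:
        raise ValueError("all pairwise distances are zero; cannot scale kernels")
    scales = np.quantile(nz, np.asarray(quantiles, dtype=float))
    if np.any(np.diff(scales) <= 0):
        # degenerate geometries can collapse adjacent quantiles
        scales = np.maximum.accumulate(scales + 1e-12 * np.arange(len(scales)))
    specs = [KernelSpec("gaussian", float(s)) for s in scales]
    specs += [KernelSpec("cosine", float(s)) for s in scales]
    return KernelBank(specs)
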