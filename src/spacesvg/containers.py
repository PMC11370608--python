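"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import SpotSet

__all__ = ["ExpressionMatrix"]


@dataclass
class ExpressionMatrix:
    """Normalized expression values for ``m`` genes over ``N`` spots.

    ``values`` has genes in rows (matching ``gene_ids``) and spots in
    columns (matching ``spot_ids``).  Values are assumed already
    normalized; see :func:`spacesvg.io.normalize_and_filter` for raw
    counts.
    """

    gene_ids: tuple
    spot_ids: tuple
    values: np.ndarray

    def __post_init__(self):
        self.gene_ids = tuple(self.gene_ids)
        self.spot_ids = tuple(self.spot_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (genes x spots)")
        if self.values.shape != (len(self.gene_ids), len(self.spot_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.spot_ids)} spots"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_spots(self) -> int:
        return self.values.shape[1]

    def check_aligned(self, spots: SpotSet) -> None:
        """Raise unless spot order matches the given :class:`SpotSet`."""
        if self.spot_ids != spots.spot_ids:
            raise ValueError("expression spot order does not match the SpotSet")

    def gene(self, gene_id) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def subset(self, gene_ids) -> "ExpressionMatrix":
        idx = [self.gene_ids.index(g) for g in gene_ids]
        return ExpressionMatrix(tuple(gene_ids), self.spot_ids, self.values[idx])
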