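"""Synthetic spatial transcriptomics generators.

Three generators cover the study conditions used throughout the test
suite and the acceptance runs:

* :func:`scenario_one` — a 53-gene benchmark on 2000 uniformly placed
  spots: independent noise genes, a correlated non-spatial gene group,
  three correlated spatial-pattern groups whose effect strength grows
  with gene index, and three single genes with unique patterns.
  Within-group correlation is compound symmetry (``rho_ij = rho``) or
  AR(1) (``rho_ij = rho**|i-j|``).
* :func:`layered_synthetic` — a laminar-cortex-like design: five curved
  layers (four cortex-like strata and a white-matter-like band), three
  domain-specific SVG clusters with an uneven 800/150/1050 split, and
  log-normal per-gene means and variances for the noise background.
* :func:`null_dataset` — i.i.d. standard normal expression for type-I
  error calibration.

All generators are deterministic functions of their configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .containers import ExpressionMatrix
from .geometry import SpotSet

__all__ = [
    "ScenarioOneConfig",
    "LayeredConfig",
    "SimulationTruth",
    "scenario_one",
    "layered_synthetic",
    "null_dataset",
    "pattern_surfaces",
    "PATTERN_NAMES",
]

PATTERN_NAMES = (
    "hotspot",
    "gradient",
    "streak",
    "annulus",
    "twin_hotspots",
    "stripes",
)


def _bump(x, y, cx, cy, width):
    return np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2.0 * width ** 2))


def pattern_surfaces(coords: np.ndarray) -> np.ndarray:
    """Six spatial pattern surfaces evaluated at given 2-D coordinates.

    Surfaces span the regimes the kernel bank targets — localized
    (hotspot, twin hotspots), smooth monotone (gradient), ridge-like
    (diagonal streak), ring-shaped (annulus) and periodic (stripes).
    Each surface is standardized to zero mean and unit variance over
    the given spots.
    """
    x, y = coords[:, 0], coords[:, 1]
    f = np.empty((6, coords.shape[0]))
    f[0] = _bump(x, y, 0.3, 0.3, 0.15)
    f[1] = x
    f[2] = np.exp(-((x - y) ** 2 / 2.0) / (2.0 * 0.12 ** 2))
    f[3] = np.exp(-((np.hypot(x - 0.5, y - 0.5) - 0.3) ** 2) / (2.0 * 0.08 ** 2))
    f[4] = _bump(x, y, 0.5, 0.85, 0.12) - _bump(x, y, 0.5, 0.15, 0.12)
    f[5] = np.cos(2.0 * np.pi * y / 0.5)
    f -= f.mean(axis=1, keepdims=True)
    f /= f.std(axis=1, keepdims=True)
    return f


def _group_correlation(size: int, structure: str, rho: float) -> np.ndarray:
    if not (0.0 <= rho < 1.0):
        raise ValueError("rho must lie in [0, 1)")
    structure = structure.lower()
    idx = np.arange(size)
    if structure == "cs":
        C = np.full((size, size), rho)
        np.fill_diagonal(C, 1.0)
    elif structure == "ar1":
        C = rho ** np.abs(idx[:, None] - idx[None, :])
    else:
        raise ValueError(f"unknown correlation structure {structure!r}")
    return C


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth attached to a simulated dataset.

    ``roles`` names each gene's generating mechanism; ``gene_group``
    holds the true cluster label of each true SVG (-1 for non-spatial
    genes); ``domain_labels`` is the per-spot domain partition for the
    layered design (None otherwise).
    """

    roles: tuple
    gene_group: np.ndarray
    domain_labels: Optional[np.ndarray] = None
    pattern_names: tuple = PATTERN_NAMES

    @property
    def is_svg(self) -> np.ndarray:
        return self.gene_group >= 0


@dataclass(frozen=True)
class ScenarioOneConfig:
    """Conditions of the 53-gene correlated-pattern benchmark.

    ``strength_grid`` spans signal standard deviations from 0.25 to
    1.5 times the unit noise standard deviation across each pattern
    group's ten members; ``unique_strength`` is the signal level of the
    three unique-pattern genes.  ``coords_seed`` fixes the spot layout
    independently of the expression noise so replicates can share
    coordinates (and hence kernel eigendecompositions).
    """

    seed: int = 0
    n_spots: int = 2000
    structure: str = "cs"
    rho: float = 0.6
    strength_min: float = 0.25
    strength_max: float = 1.5
    unique_strength: float = 1.0
    coords_seed: Optional[int] = None


def _scenario_one_coords(config: ScenarioOneConfig) -> np.ndarray:
    cseed = config.seed if config.coords_seed is None else config.coords_seed
    rng = np.random.default_rng(cseed)
    return rng.uniform(size=(config.n_spots, 2))


def scenario_one(config: ScenarioOneConfig = ScenarioOneConfig()):
    """Generate one scenario-I replicate.

    Returns ``(expr, spots, truth)`` with 53 genes over
    ``config.n_spots`` spots: g1-g10 independent noise, g11-g20
    correlated non-spatial, g21-g30/g31-g40/g41-g50 three correlated
    pattern groups with linearly increasing effect strength, g51-g53
    unique-pattern singles.  All genes are standardized.
    """
    if config.n_spots < 100:
        raise ValueError("scenario one needs at least 100 spots")
    coords = _scenario_one_coords(config)
    n = config.n_spots
    rng = np.random.default_rng(config.seed)
    f = pattern_surfaces(coords)
    C = _group_correlation(10, config.structure, config.rho)
    L = np.linalg.cholesky(C)
    strengths = np.linspace(config.strength_min, config.strength_max, 10)

    Y = np.empty((53, n))
    roles = []
    group = np.full(53, -1)
    Y[0:10] = rng.standard_normal((10, n))
    roles += ["noise_independent"] * 10
    Y[10:20] = L @ rng.standard_normal((10, n))
    roles += ["noise_correlated"] * 10
    for g_idx in range(3):
        rows = slice(20 + 10 * g_idx, 30 + 10 * g_idx)
        noise = L @ rng.standard_normal((10, n))
        Y[rows] = strengths[:, None] * f[g_idx][None, :] + noise
        roles += [f"pattern_{g_idx + 1}"] * 10
        group[rows] = g_idx
    for u_idx in range(3):
        row = 50 + u_idx
        Y[row] = config.unique_strength * f[3 + u_idx] + rng.standard_normal(n)
        roles.append(f"pattern_{4 + u_idx}")
        group[row] = 3 + u_idx

    Y -= Y.mean(axis=1, keepdims=True)
    Y /= Y.std(axis=1, keepdims=True)
    gene_ids = tuple(f"g{i + 1}" for i in range(53))
    spot_ids = tuple(f"spot_{i + 1}" for i in range(n))
    expr = ExpressionMatrix(gene_ids, spot_ids, Y)
    spots = SpotSet(spot_ids, coords)
    return expr, spots, SimulationTruth(tuple(roles), group)


@dataclass(frozen=True)
class LayeredConfig:
    """Conditions of the layered (laminar-cortex-like) design.

    Five parallel curved strata partition the unit square with
    fractional widths ``band_widths``; boundaries are sinusoidally
    perturbed for a curved laminar morphology.  ``svg_counts`` splits
    the SVGs into three domain-specific clusters (layer-1, layers-2-4,
    white-matter band).  Per-gene baseline means and variances are
    log-normal so the noise background has realistic heterogeneous
    scales; marker effect sizes ``a ~ U(effect_min, effect_max)`` (in
    units of the gene's noise SD) give within-cluster correlations of
    about 0.5-0.8.
    """

    seed: int = 0
    n_genes: int = 4865
    n_spots: int = 3484
    svg_counts: tuple = (800, 150, 1050)
    band_widths: tuple = (0.25, 0.15, 0.15, 0.15, 0.30)
    wave_amplitude: float = 0.04
    wave_frequency: float = 1.5
    effect_min: float = 1.0
    effect_max: float = 2.0
    mean_log_mu: float = 0.0
    mean_log_sigma: float = 0.4
    var_log_mu: float = -0.5
    var_log_sigma: float = 0.6


def _layer_labels(coords: np.ndarray, config: LayeredConfig, phase: float) -> np.ndarray:
    widths = np.asarray(config.band_widths, dtype=float)
    edges = np.cumsum(widths / widths.sum())[:-1]
    wave = config.wave_amplitude * np.sin(
        2.0 * np.pi * config.wave_frequency * coords[:, 0] + phase
    )
    depth = np.clip(coords[:, 1] - wave, 0.0, 1.0 - 1e-12)
    return np.searchsorted(edges, depth, side="right")


def layered_synthetic(config: LayeredConfig = LayeredConfig()):
    """Generate one layered-cortex replicate.

    Returns ``(expr, spots, truth)``; ``truth.domain_labels`` holds the
    five-layer partition of the spots, ``truth.gene_group`` the SVG
    cluster of each gene (-1 for noise genes).
    """
    n_svg = int(np.sum(config.svg_counts))
    if n_svg > config.n_genes:
        raise ValueError("svg_counts exceed n_genes")
    if len(config.svg_counts) != 3:
        raise ValueError("expected three SVG cluster counts")
    rng = np.random.default_rng(config.seed)
    n = config.n_spots
    nx = int(np.ceil(np.sqrt(n)))
    ny = int(np.ceil(n / nx))
    gx, gy = np.meshgrid(np.linspace(0, 1, nx), np.linspace(0, 1, ny))
    coords = np.column_stack([gx.ravel(), gy.ravel()])[:n]
    phase = rng.uniform(0.0, 2.0 * np.pi)
    layers = _layer_labels(coords, config, phase)

    # domain-specific standardized signatures.  Cluster 1 marks layer 1
    # and cluster 3 the white-matter band; each cluster-2 gene
    # overexpresses in one of the middle cortex layers (2, 3 or 4), so
    # the middle layers carry distinguishable signatures.
    def _signature(mask):
        z = mask.astype(float)
        return (z - z.mean()) / z.std()

    Z = np.stack([
        _signature(layers == 0),
        _signature(layers == 1),
        _signature(layers == 2),
        _signature(layers == 3),
        _signature(layers == 4),
    ])
    signature_of_cluster = {0: (0,), 1: (1, 2, 3), 2: (4,)}

    means = rng.lognormal(config.mean_log_mu, config.mean_log_sigma, config.n_genes)
    sds = np.sqrt(rng.lognormal(config.var_log_mu, config.var_log_sigma, config.n_genes))
    svg_idx = rng.choice(config.n_genes, size=n_svg, replace=False)
    cluster_of = np.full(config.n_genes, -1)
    offset = 0
    for c, count in enumerate(config.svg_counts):
        cluster_of[svg_idx[offset:offset + count]] = c
        offset += count

    Y = np.empty((config.n_genes, n))
    noise = rng.standard_normal((config.n_genes, n))
    effects = rng.uniform(config.effect_min, config.effect_max, config.n_genes)
    target_layer = np.full(config.n_genes, -1)
    for g in range(config.n_genes):
        c = cluster_of[g]
        if c < 0:
            Y[g] = means[g] + sds[g] * noise[g]
        else:
            choices = signature_of_cluster[c]
            sig = choices[rng.integers(len(choices))] if len(choices) > 1 else choices[0]
            target_layer[g] = sig
            a = effects[g]
            unit = (a * Z[sig] + noise[g]) / np.sqrt(a ** 2 + 1.0)
            Y[g] = means[g] + sds[g] * unit

    roles = tuple(
        "noise" if cluster_of[g] < 0 else f"svg_cluster_{cluster_of[g] + 1}"
        for g in range(config.n_genes)
    )
    gene_ids = tuple(f"g{i + 1}" for i in range(config.n_genes))
    spot_ids = tuple(f"spot_{i + 1}" for i in range(n))
    expr = ExpressionMatrix(gene_ids, spot_ids, Y)
    spots = SpotSet(spot_ids, coords)
    return expr, spots, SimulationTruth(tuple(roles), cluster_of, domain_labels=layers)


def null_dataset(seed: int = 0, n_genes: int = 500, n_spots: int = 400):
    """I.i.d. standard-normal expression with no spatial structure."""
    if n_genes < 2 or n_spots < 2:
        raise ValueError("need at least 2 genes and 2 spots")
    rng = np.random.default_rng(seed)
    coords = rng.uniform(size=(n_spots, 2))
    Y = rng.standard_normal((n_genes, n_spots))
    gene_ids = tuple(f"g{i + 1}" for i in range(n_genes))
    spot_ids = tuple(f"spot_{i + 1}" for i in range(n_spots))
    return (
        ExpressionMatrix(gene_ids, spot_ids, Y),
        SpotSet(spot_ids, coords),
        SimulationTruth(("noise_independent",) * n_genes, np.full(n_genes, -1)),
    )
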