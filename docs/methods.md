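# Methods

## Model and detection step

Per gene, normalized expression `y` over `N` spots is modeled as a
Gaussian process

    y ~ MVN(Xβ, σs² K + δ I)

where `K` is a spot-similarity kernel built from the coordinates, `σs²`
the spatial variance component, `δ` the non-spatial noise variance, and
`X` the covariate design (the intercept alone unless covariates are
supplied).  A gene is spatially variable (an SVG) when `σs² > 0`, so
detection tests `H0: σs² = 0`.

We use the standard variance-component score test.  With `r` the
residuals of the null least-squares fit and `δ̂ = r'r/(N−k)` (unbiased
divisor, so the identity-kernel case is exact), the statistic

    T = r' K r / δ̂

follows under H0 the law of `Σᵢ λᵢ χ²₁` with `λᵢ` the eigenvalues of
`P₀KP₀`, `P₀` the projection off the design column space, when `δ̂` is
treated as known (the plug-in convention of `score_test`).  The
pipeline goes one step further and uses the *exact* finite-sample
null of the ratio: `T > q` iff `r'(K − q/(N−k)·I)r > 0`, a weighted-χ²
sign probability in which the variance estimate cancels, so under
Gaussian errors every per-kernel p-value is exactly uniform rather
than approximately so.  Tail probabilities come from numerical
inversion of the characteristic function (Imhof's formula); see
*Numerical choices*.

### Kernel bank

Ten kernels: five Gaussian `exp(−d²/2l²)` and five Cosine
`cos(2πd/φ)`.  The scale parameters (bandwidth `l`, period `φ`) are the
{0.1, 0.3, 0.5, 0.7, 0.9} quantiles of the nonzero pairwise-distance
distribution, shared by both families — a data-adaptive ladder from
smooth to fine spatial structure, reproducible from the coordinates
alone.  Cosine kernels are indefinite; the score test accepts them
because the weighted-χ² tail is defined for negative weights.

### Combination and selection

Per gene the ten kernel p-values are combined with the equal-weight
Cauchy (tangent-average) combination, which is valid under arbitrary
dependence.  Combined p-values are Benjamini–Hochberg-adjusted across
genes; genes with q ≤ α (default 0.05) are the detected SVGs (`m1`).

One pitfall: when a strong spatial gene *anti*-matches an indefinite
kernel its statistic is negative and the per-kernel p-value is
numerically 1; the naive clipped tangent transform then contributes
−3.2·10¹⁴, which can exactly cancel the +3.2·10¹⁴ of a clipped tiny
p-value and yield a combined p near 0.5 for an overwhelmingly
significant gene.  Components numerically equal to 1 are therefore set
to `1 − 1/d` (d = number of kernels) before the transform, the standard
remedy in Cauchy-combination software.

## Classification step

For each detected SVG `j`:

1. **Correlated set** `S_j`: all other SVGs with `|corr| ≥ 0.5`
   (Pearson by default; Spearman available).
2. **Adjustment covariates**: the member genes themselves when
   `|S_j| ≤ 3`; otherwise the top principal components of the `S_j`
   submatrix covering ≥ 80 % of its variance.
3. **Adjusted retest**: the score test is rerun with the covariates in
   the design (spectra recomputed for the enlarged projection) and the
   kernel p-values Cauchy-combined.  A gene whose residual variance
   vanishes is *fully explained* (p = 1).
4. **Graph and clustering**: non-unique SVG pairs with `|corr| ≥ 0.5`
   are joined by edges weighted by `|corr|`; Leiden community
   detection (modularity objective, resolution 1, fixed seed)
   partitions the graph; unique genes and unconnected nodes become
   singleton clusters.

Because many SVGs are cell-type markers with strongly correlated
expression, regressing on correlated peers also absorbs shared
cell-type composition effects without any cell-type annotation.

### What "unique" means, and why

A gene still significant after adjustment (at the BH cutoff recomputed
over the `m1` detected SVGs' combined p-values) carries spatial signal
its peers cannot explain.  Two readings are implemented
(`SpaceConfig.singleton_rule`):

* `"unconnected"` (default): a gene is a singleton iff it is still
  significant **and** has no correlated SVG peer at the threshold.
* `"significant"`: every still-significant gene is isolated before
  clustering.

The default is deliberate.  Adjusting a gene by principal components of
*noisy* peer genes is an errors-in-variables regression: when the peer
group shares a common noise factor (compound-symmetric correlation),
the best linear combination of peers has a bounded signal-to-noise
ratio, so a fixed fraction (roughly `1/(1 + s'Σ⁻¹s)`, ~20 % in the
53-gene benchmark) of the shared pattern always survives in the
residual.  A score test over thousands of spots detects that leak, so
under the `"significant"` rule the strongest and weakest members of
every pattern group are torn out of their clusters as spurious
singletons.  Under the default rule singletons are genes whose pattern
is both unexplained *and* uncorrelated with every other SVG — in the
benchmark, exactly the three unique-pattern genes.

## Spatial domains

Each gene cluster contributes one embedding block: expression is
smoothed over spots with a row-stochastic Gaussian kernel, genes are
centered, and the top `d = 20` principal-component score vectors are
retained (bounded by cluster size).  Defaults, each a deliberate
choice:

* **Smoothing bandwidth** — the median 10-nearest-neighbor distance, a
  *local* scale.  A global scale such as the median of all pairwise
  distances spans a large fraction of the tissue, collapses the
  embedding onto one smooth gradient and merges thin domains.
* **Block standardization ON** — the point of per-cluster embeddings
  is that every spatial program gets equal footing; without rescaling,
  an 800-gene cluster numerically drowns a 150-gene one and the
  aggregated embedding degenerates toward the pooled baseline.
* **Singletons excluded** (`min_cluster_size = 2`) — a singleton block
  is a single smoothed gene, unvalidated by any peer; standardization
  would inflate it to the scale of a whole cluster.  If no multi-gene
  cluster exists the singletons are used after all.

Blocks are concatenated and spots are clustered on a shared-nearest-
neighbor graph (10 nearest neighbors in embedding space, Jaccard
weights; disconnected components are bridged through their closest
point pairs so dendrogram cuts always reach the requested count).
Leiden or Louvain at resolution 1 serve when the number of domains is
unknown; Walktrap cut at `kd` when it is known.  Optional
majority-vote label refinement over the 10 spatial nearest neighbors
is off by default.

The comparison baseline is the standard workflow: one embedding block
from the pooled top 3000 SVGs (capped at the number detected, ranked
by combined p-value), `d = 20`, identical spot clustering.

## Synthetic data

**53-gene benchmark** (default 2000 spots uniform on the unit square):
g1–g10 independent noise; g11–g20 correlated noise; g21–g30, g31–g40,
g41–g50 three pattern groups whose members share a spatial surface
with effect strength rising linearly from 0.25 to 1.5 noise-SD; g51–g53
unique patterns at strength 1.0.  Within-group noise is
compound-symmetric (`ρ = 0.6`) or AR(1) (`ρ^{|i−j|}`).  The six
surfaces — Gaussian hotspot, linear gradient, diagonal streak, annulus,
opposed-sign hotspot pair, periodic stripes — are standardized and
pairwise correlate below 0.5 in magnitude, spanning the localized,
smooth, ridge-like and periodic regimes the kernel bank targets.
Coordinates can be fixed independently of expression noise
(`coords_seed`) so replicates share kernel eigendecompositions.

**Layered design** (default 4865 genes × 3484 spots): a grid
partitioned into five parallel strata with sinusoidally perturbed
boundaries and fractional widths (0.25, 0.15, 0.15, 0.15, 0.30) — four
cortex-like layers and a white-matter-like band.  2000 SVGs split
800/150/1050: cluster 1 marks layer 1, cluster 3 the white-matter
band, and each cluster-2 gene overexpresses in *one* of layers 2–4
(so the middle layers carry distinguishable signatures — had all 150
genes marked the union, layers 2–4 would be information-theoretically
indistinguishable for every method).  Marker effect sizes are
`a ~ U(1, 2)` noise-SD, giving within-cluster correlations of
0.5–0.8; baseline means and variances are log-normal so the noise
background has realistic heterogeneous scales.

**Null generator**: i.i.d. standard normal expression, for type-I
error calibration.

What the generators do *not* emulate: count noise (everything is
Gaussian on the normalized scale), spot-level library-size artifacts,
hexagonal capture geometry, segmentation errors, and spatial
covariance *within* a domain beyond the shared signature.  Passing
tests therefore show correct behavior of the statistics and the
pipeline under the stated model, not robustness to count overdispersion
or platform artifacts.

## Numerical choices

* **Tail probabilities.**  `davies_tail` splits Imhof's inversion
  integral at an adaptive point: the head is integrated by vectorized
  composite Gauss–Legendre panels (panel count proportional to the
  oscillation count `q·split/4π`), the split is doubled until an
  envelope bound shows the remaining tail is below 1e−10, and only
  when that fails (very short weight lists) is the oscillatory tail
  integrated by Fourier-weighted quadrature.  The envelope's decay
  exponent counts only *activated* weights (`|w|·u > 1`) — counting
  all weights overstates decay badly when a few large eigenvalues sit
  atop a near-zero bulk.  Equal positive weights short-circuit to the
  exact scaled-χ² form.
* **The ratio null** (`ratio_tail_zero`) evaluates
  `P(Σ wᵢ χ²₁ + b·χ²ₘ > 0)`, with the thousands of beyond-basis
  eigenvalues entering as one weight of multiplicity `m`.  Far tails
  are gated by a rigorous Chernoff bound — the four-moment Liu
  approximation alone can be off by orders of magnitude for heavily
  skewed forms, so it supplies only the magnitude once the bound
  certifies the tail is below 1e−9.  Probabilities near 1 are computed
  through the complement tail so the float precision of `1 − p`
  survives (a value saturating to exactly 1.0 would otherwise be
  distorted by the combination step).  Every path is validated against
  Monte-Carlo and brute-force eigendecomposition oracles in the tests.
* **Cauchy combination under dependence** is exact in the tails but
  mildly non-uniform in the bulk (mass compressed toward mid-range
  p).  Detection decisions (BH at small p) are unaffected; bulk
  summaries of combined p-values inherit a few-percent conservatism
  whose size depends on the spot geometry.
* **Shared eigenbases.**  One symmetric eigendecomposition per kernel
  (on the intercept-centered kernel) serves every gene.  Spectra for
  covariate-adjusted designs come from an exact rank-`k` projection
  update in the truncated eigenbasis (retained eigenvalue mass
  1 − 1e−12, discarded mass < 1e−8 absolute), verified against the
  direct per-design eigendecomposition in tests.
* **Degenerate inputs.**  Constant genes are flagged and given p = 1;
  rank-deficient designs raise; genes inside their covariate span are
  reported fully explained; duplicate-coordinate spot sets are
  rejected when a kernel scale cannot be formed.
* **Ties.**  PAS breaks neighbor-distance ties by spot index; with 10
  or fewer spots it uses all others with threshold ⌈0.6·(N−1)⌉.
  Leiden and Louvain take explicit seeds; Walktrap is deterministic.

## Problem sizes used in the shipped studies

The acceptance script runs 50 replicates of the 53-gene benchmark at
its full 2000 spots with shared coordinates.  The layered comparison
in the test suite uses 10 replicates at 1500 spots × 1200 genes with
SVG counts (200, 40, 260), preserving the 800:150:1050 ratio and the
SVG fraction of the full design.  Null calibration uses 500 genes ×
400 spots.

## Known limitations

* The adjusted retest cannot fully absorb a shared pattern observed
  through noisy peers (see *What "unique" means*); its p-values
  measure *unexplained* signal, not evidence of a *novel* pattern.
* Walktrap cuts of chain-like SNN graphs can land off-boundary when
  the embedding is a smooth gradient; a denser graph (larger `knn`)
  stabilizes small slides.
* The per-cluster embedding is a smoothed PCA, not a probabilistic
  spatial factor model; it is exposed behind a small interface
  (`cluster_embedding`) so a heavier spatially aware embedding can be
  substituted.
* Leiden/Louvain at resolution 1 typically over-partition spot graphs
  of small slides; prefer Walktrap with a known domain count when one
  is available.
* Penalized-regression selection of correlated sets (LASSO, elastic
  net, MCP, SIS) and distance/kernel correlation are not implemented;
  the correlation `method` argument is the extension point.
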