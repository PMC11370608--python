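"""Spatially variable gene detection by a multi-kernel score test.

Per gene the normalized expression ``y`` is modeled as a Gaussian
process over spots,

    y ~ MVN(X beta, sigma_s^2 K + delta I),

where ``K`` is a spot-similarity kernel, ``sigma_s^2`` the spatial
variance component and ``delta`` the non-spatial noise variance.  A gene
is spatially variable when ``sigma_s^2 > 0``; the test of
``H0: sigma_s^2 = 0`` is the variance-component score test: with
residuals ``r`` from the null least-squares fit and
``delta_hat = r'r/(N-k)``, the statistic ``T = r'Kr/delta_hat`` follows,
under H0, the law of ``sum_i lambda_i chi2_1`` with ``lambda_i`` the
eigenvalues of ``P0 K P0`` (``P0`` projects off the design columns).
Per-kernel p-values over the 10-kernel bank are aggregated by the Cauchy
combination and genes are selected by Benjamini–Hochberg at FDR
``alpha``.

:class:`SVGTestEngine` precomputes one eigendecomposition per kernel for
a fixed geometry and serves every gene — and, via an exact low-rank
projection update, every covariate-adjusted redesign — from that cache.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix
from .geometry import KernelBank, SpotSet, build_kernel, default_kernel_bank, pairwise_distances
from .quadform import davies_tail, ratio_tail_zero

__all__ = [
    "NullFit",
    "fit_null",
    "kernel_spectrum",
    "score_test",
    "cauchy_combine",
    "SVGTestEngine",
    "SVGTestResult",
    "detect_svgs",
]

# p-values are clipped away from 0/1 before the tangent transform
_CAUCHY_CLIP = 1e-15
# relative |eigenvalue| mass retained in the truncated kernel eigenbasis
_SPECTRUM_MASS_RTOL = 1e-12


@dataclass
class NullFit:
    """Least-squares fit of a gene under the no-spatial-variance null."""

    design: np.ndarray
    coefficients: np.ndarray
    residuals: np.ndarray
    residual_variance: float
    degenerate: bool = False


def fit_null(y: np.ndarray, design: np.ndarray) -> NullFit:
    """OLS fit of ``y`` on ``design``; the null model of the score test.

    ``residual_variance`` is the unbiased ``r'r/(N-k)``.  A gene whose
    residual variance vanishes (``y`` in the design span) is flagged
    degenerate and is assigned p = 1 downstream.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if y.size != n:
        raise ValueError("y and design disagree on the number of spots")
    if n <= k:
        raise ValueError("need more spots than design columns")
    q, r_tri = np.linalg.qr(X)
    if np.min(np.abs(np.diag(r_tri))) < 1e-10 * max(1.0, np.max(np.abs(r_tri))):
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    coef = np.linalg.solve(r_tri, q.T @ y)
    resid = y - X @ coef
    rss = float(resid @ resid)
    scale = float(y @ y) + 1.0
    dvar = rss / (n - k)
    degenerate = rss <= 1e-12 * scale
    return NullFit(X, coef, resid, dvar, degenerate)


def kernel_spectrum(K: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Eigenvalues of ``P0 K P0``, descending, for a kernel and design.

    ``P0 = I - Q Q'`` with ``Q`` an orthonormal basis of the design
    column space.  At least ``k`` eigenvalues are (numerically) zero.
    """
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("K must be square")
    if not np.allclose(K, K.T, atol=1e-8 * max(1.0, np.max(np.abs(K)))):
        raise ValueError("K must be symmetric")
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    q, _ = np.linalg.qr(X)
    KQ = K @ q
    QtKQ = q.T @ KQ
    Kc = K - q @ KQ.T - KQ @ q.T + q @ QtKQ @ q.T
    w = np.linalg.eigvalsh(0.5 * (Kc + Kc.T))
    return w[::-1]


def score_test(
    y: np.ndarray,
    nullfit: NullFit,
    K: np.ndarray,
    spectrum: np.ndarray,
) -> tuple[float, float]:
    """Score statistic and p-value for one gene and one kernel.

    ``T = r'Kr / delta_hat``; ``p`` is the weighted-chi-square upper
    tail at ``T`` with the spectrum of ``P0 K P0`` as weights.  A
    degenerate null fit yields ``(0, 1)``.
    """
    if nullfit.degenerate or nullfit.residual_variance <= 0:
        return 0.0, 1.0
    r = nullfit.residuals
    T = float(r @ (np.asarray(K, dtype=float) @ r)) / nullfit.residual_variance
    return T, davies_tail(T, spectrum)


def cauchy_combine(p_list: Sequence[float], weights: Optional[Sequence[float]] = None) -> float:
    """Cauchy (ACAT) combination of dependent p-values.

    ``T = sum_i w_i tan((0.5 - p_i) pi)`` with weights summing to one;
    the combined p-value is ``0.5 - arctan(T)/pi``.  Valid under
    arbitrary dependence of the components.
    """
    p = np.asarray(p_list, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("cannot combine an empty list of p-values")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if weights is None:
        w = np.full(p.size, 1.0 / p.size)
    else:
        w = np.asarray(weights, dtype=float).ravel()
        if w.size != p.size or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be nonnegative and match p_list")
        w = w / w.sum()
    if p.size > 1:
        # components numerically equal to 1 would contribute a huge
        # negative tangent that can cancel genuinely tiny p-values;
        # following ACAT practice they are set to 1 - 1/d instead
        p = np.where(p > 1.0 - 1e-12, 1.0 - 1.0 / p.size, p)
    p = np.clip(p, _CAUCHY_CLIP, 1.0 - _CAUCHY_CLIP)
    stat = float(np.sum(w * np.tan((0.5 - p) * np.pi)))
    return float(0.5 - np.arctan(stat) / np.pi)


class SVGTestEngine:
    """Cached multi-kernel score-test machinery for one geometry.

    One symmetric eigendecomposition per kernel is done at construction
    on the intercept-centered kernel; every gene (and every
    covariate-adjusted redesign sharing the geometry) is then tested
    from the cached truncated eigenbasis.  The truncation keeps all
    eigenvalues up to a relative absolute-mass tolerance of ``1e-12``,
    which matches the direct per-design eigendecomposition to better
    than ``1e-8``.
    """

    def __init__(self, spots: SpotSet, bank: Optional[KernelBank] = None):
        self.spots = spots
        n = spots.n_spots
        dist = pairwise_distances(spots)
        self.bank = bank if bank is not None else default_kernel_bank(dist)
        ones = np.full((n, 1), 1.0 / np.sqrt(n))
        self._basis = []  # per kernel: (U_r, w_r)
        self._base_spectra = []  # spectrum of P0 K P0, intercept design
        for spec in self.bank:
            K = build_kernel(dist, spec)
            KQ = K @ ones
            Kc = K - ones @ KQ.T - KQ @ ones.T + ones @ (ones.T @ KQ) @ ones.T
            w, U = np.linalg.eigh(0.5 * (Kc + Kc.T))
            order = np.argsort(-np.abs(w))
            w, U = w[order], U[:, order]
            mass = np.cumsum(np.abs(w))
            total = mass[-1]
            r = int(np.searchsorted(mass, (1.0 - _SPECTRUM_MASS_RTOL) * total)) + 1
            self._basis.append((np.ascontiguousarray(U[:, :r]), w[:r].copy()))
            self._base_spectra.append(np.sort(w)[::-1])

    @property
    def n_kernels(self) -> int:
        return len(self.bank)

    def base_spectrum(self, kernel_index: int) -> np.ndarray:
        return self._base_spectra[kernel_index]

    # -- intercept-only testing (vectorized over genes) ---------------

    def test_genes(self, values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-gene, per-kernel statistics and p-values, intercept design.

        Parameters
        ----------
        values
            ``(n_genes, n_spots)`` expression block.

        Returns
        -------
        T, P, degenerate
            ``(n_genes, n_kernels)`` statistic and p-value arrays and a
            boolean mask of degenerate (constant) genes.
        """
        Y = np.asarray(values, dtype=float)
        n = self.spots.n_spots
        if Y.shape[1] != n:
            raise ValueError("expression and SpotSet disagree on spot count")
        R = Y - Y.mean(axis=1, keepdims=True)
        rss = np.einsum("ij,ij->i", R, R)
        dvar = rss / (n - 1)
        scale = np.einsum("ij,ij->i", Y, Y) + 1.0
        degenerate = rss <= 1e-12 * scale
        ngenes = Y.shape[0]
        T = np.zeros((ngenes, self.n_kernels))
        P = np.ones((ngenes, self.n_kernels))
        ok = ~degenerate
        for ki, (U, w) in enumerate(self._basis):
            proj = R @ U  # (genes, r)
            quad = np.einsum("gr,r,gr->g", proj, w, proj)
            T[ok, ki] = quad[ok] / dvar[ok]
            P[ok, ki] = self._ratio_pvalues(T[ok, ki], w, n - 1)
        return T, P, degenerate

    @staticmethod
    def _ratio_pvalues(stats_: np.ndarray, spectrum: np.ndarray, dof: int) -> np.ndarray:
        """Exact finite-sample p-values of the ratio statistic.

        ``T = r'Kr/(r'r/dof) > q`` iff ``sum (lambda_i - q/dof) chi2_1``
        is positive over the ``dof``-dimensional design complement, so
        the noise-variance estimate cancels exactly and, under Gaussian
        errors, the p-value is exact rather than plug-in.  Eigenvalues
        beyond the truncated basis enter as ``-q/dof`` with the
        remaining multiplicity.
        """
        r = spectrum.size
        out = np.empty(stats_.size)
        for i, q in enumerate(stats_):
            c = q / dof
            out[i] = ratio_tail_zero(spectrum - c, -c, max(dof - r, 0))
        return out

    # -- covariate-adjusted testing (per gene) ------------------------

    def adjusted_pvalues(
        self, y: np.ndarray, covariates: Optional[np.ndarray]
    ) -> tuple[np.ndarray, np.ndarray, bool]:
        """Score test of one gene under design ``[intercept | covariates]``.

        The spectra of ``P K P`` for the enlarged projection ``P`` are
        obtained from the cached eigenbasis by an exact rank-``k``
        update.  Returns per-kernel ``(T, p)`` and a flag that is True
        when the covariates absorb the gene entirely (zero residual
        variance; the gene is "fully explained" and p = 1).
        """
        y = np.asarray(y, dtype=float).ravel()
        n = self.spots.n_spots
        ones = np.full((n, 1), 1.0 / np.sqrt(n))
        if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
            X = ones
        else:
            C = np.asarray(covariates, dtype=float)
            if C.ndim == 1:
                C = C[:, None]
            X = np.hstack([ones, C])
        Q, r_tri = np.linalg.qr(X)
        keep = np.abs(np.diag(r_tri)) > 1e-10 * max(1.0, np.max(np.abs(r_tri)))
        Q = Q[:, keep]
        k = Q.shape[1]
        resid = y - Q @ (Q.T @ y)
        rss = float(resid @ resid)
        dvar = rss / (n - k)
        if rss <= 1e-12 * (float(y @ y) + 1.0):
            nk = self.n_kernels
            return np.zeros(nk), np.ones(nk), True
        # covariate part orthogonal to the intercept (the cached basis
        # already lives in the intercept complement)
        Qc = Q - ones @ (ones.T @ Q)
        qn = np.linalg.norm(Qc, axis=0)
        Qc = Qc[:, qn > 1e-10] / qn[qn > 1e-10]
        T = np.zeros(self.n_kernels)
        P = np.ones(self.n_kernels)
        for ki, (U, w) in enumerate(self._basis):
            proj = U.T @ resid
            T[ki] = float(np.sum(w * proj ** 2)) / dvar
            spec_adj = self._adjusted_spectrum(ki, Qc)
            # the update basis can exceed the adjusted complement
            # dimension by up to k numerical zeros; the total weight
            # count must equal n - k exactly
            extra = spec_adj.size - (n - k)
            if extra > 0:
                keep = np.sort(np.argsort(np.abs(spec_adj))[extra:])
                spec_adj = spec_adj[keep]
            c = T[ki] / (n - k)
            P[ki] = ratio_tail_zero(spec_adj - c, -c, (n - k) - spec_adj.size)
        return T, P, False

    def _adjusted_spectrum(self, kernel_index: int, Qc: np.ndarray) -> np.ndarray:
        """Eigenvalues of ``P K P`` via the truncated-basis update.

        With ``K ~ U diag(w) U'`` in the intercept complement and
        ``P = P0 - Qc Qc'``, the nonzero eigenvalues of ``P K P`` equal
        those of ``S diag(w) S`` where ``S = (I - V V')^{1/2}`` and
        ``V = U' Qc``.
        """
        U, w = self._basis[kernel_index]
        if Qc.shape[1] == 0:
            return w
        V = U.T @ Qc  # (r, k)
        Pv, sv, _ = np.linalg.svd(V, full_matrices=False)
        sv = np.clip(sv, 0.0, 1.0)
        d = 1.0 - np.sqrt(1.0 - sv ** 2)  # S = I - Pv diag(d) Pv'
        A = Pv * d  # Pv diag(d)
        Pw = Pv * w[:, None]  # diag(w) Pv
        H = Pv.T @ Pw  # Pv' diag(w) Pv  (k x k)
        M = np.diag(w) - A @ Pw.T - Pw @ A.T + A @ H @ A.T
        return np.linalg.eigvalsh(0.5 * (M + M.T))[::-1]


@dataclass
class SVGTestResult:
    """Outcome of the detection step over all tested genes."""

    table: pd.DataFrame
    alpha: float
    n_kernels: int = 10
    statistics: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def m1(self) -> int:
        return int(self.table["is_svg"].sum())

    @property
    def svg_ids(self) -> tuple:
        return tuple(self.table.loc[self.table["is_svg"], "gene_id"])

    @property
    def combined_p(self) -> np.ndarray:
        return self.table["p_combined"].to_numpy()


def detect_svgs(
    expr: ExpressionMatrix,
    spots: SpotSet,
    bank: Optional[KernelBank] = None,
    alpha: float = 0.05,
    engine: Optional[SVGTestEngine] = None,
) -> SVGTestResult:
    """Run the multi-kernel score test over every gene and select SVGs.

    Per gene the 10 kernel p-values are Cauchy-combined; combined
    p-values are BH-adjusted across genes and genes with q <= ``alpha``
    are flagged as SVGs.  Pass a prebuilt ``engine`` to reuse kernel
    eigendecompositions across datasets sharing the same coordinates.
    """
    expr.check_aligned(spots)
    if expr.n_genes == 0:
        raise ValueError("no genes to test")
    if engine is None:
        engine = SVGTestEngine(spots, bank)
    T, P, degenerate = engine.test_genes(expr.values)
    combined = np.array(
        [1.0 if degenerate[g] else cauchy_combine(P[g]) for g in range(expr.n_genes)]
    )
    _, qvals, _, _ = multipletests(combined, alpha=alpha, method="fdr_bh")
    qvals = np.maximum(qvals, combined)
    is_svg = qvals <= alpha
    cols = {"gene_id": list(expr.gene_ids)}
    for ki in range(engine.n_kernels):
        cols[f"p_kernel_{ki + 1}"] = P[:, ki]
    cols["p_combined"] = combined
    cols["q_value"] = qvals
    cols["is_svg"] = is_svg
    return SVGTestResult(pd.DataFrame(cols), alpha, engine.n_kernels, statistics=T)
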