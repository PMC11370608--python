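import numpy as np
import pytest
from scipy.stats import chi2, kstest

from spacesvg.containers import ExpressionMatrix
from spacesvg.detection import (
    SVGTestEngine,
    cauchy_combine,
    detect_svgs,
    fit_null,
    kernel_spectrum,
    score_test,
)
from spacesvg.geometry import build_kernel, pairwise_distances
from spacesvg.quadform import davies_tail
from spacesvg.simulate import null_dataset


class TestFitNull:
    def test_intercept_only_identities(self, rng):
        y = rng.normal(size=50)
        fit = fit_null(y, np.ones((50, 1)))
        assert fit.coefficients[0] == pytest.approx(y.mean())
        assert fit.residuals.sum() == pytest.approx(0.0, abs=1e-10)
        assert fit.residual_variance == pytest.approx(y.var(ddof=1))

    def test_constant_gene_degenerate(self):
        fit = fit_null(np.full(30, 2.5), np.ones((30, 1)))
        assert fit.degenerate

    def test_matches_normal_equations(self, rng):
        X = np.column_stack([np.ones(40), rng.normal(size=(40, 2))])
        y = rng.normal(size=40)
        fit = fit_null(y, X)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(fit.coefficients, beta, atol=1e-10)
        # residuals orthogonal to the design
        assert np.max(np.abs(X.T @ fit.residuals)) < 1e-8 * len(y)

    def test_rank_deficient_design_rejected(self, rng):
        x = rng.normal(size=30)
        X = np.column_stack([np.ones(30), x, 2 * x])
        with pytest.raises(np.linalg.LinAlgError):
            fit_null(rng.normal(size=30), X)


class TestKernelSpectrum:
    def test_identity_kernel_projection_spectrum(self):
        n = 25
        spec = kernel_spectrum(np.eye(n), np.ones((n, 1)))
        np.testing.assert_allclose(spec[: n - 1], 1.0, atol=1e-10)
        assert abs(spec[-1]) < 1e-10

    def test_kernel_in_design_span_vanishes(self):
        n = 20
        K = np.ones((n, n))
        spec = kernel_spectrum(K, np.ones((n, 1)))
        np.testing.assert_allclose(spec, 0.0, atol=1e-9)

    def test_trace_identity(self, rng):
        n = 30
        A = rng.normal(size=(n, n))
        K = A @ A.T
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        spec = kernel_spectrum(K, X)
        q, _ = np.linalg.qr(X)
        P0 = np.eye(n) - q @ q.T
        assert spec.sum() == pytest.approx(np.trace(P0 @ K), rel=1e-8)

    def test_asymmetric_kernel_rejected(self, rng):
        with pytest.raises(ValueError, match="symmetric"):
            kernel_spectrum(rng.normal(size=(10, 10)), np.ones((10, 1)))


class TestScoreTest:
    def test_identity_kernel_closed_form(self, rng):
        n = 100
        y = rng.normal(size=n)
        fit = fit_null(y, np.ones((n, 1)))
        spec = kernel_spectrum(np.eye(n), np.ones((n, 1)))
        T, p = score_test(y, fit, np.eye(n), spec)
        assert T == pytest.approx(n - 1, rel=1e-10)
        assert p == pytest.approx(chi2.sf(n - 1, n - 1), abs=1e-6)

    def test_degenerate_fit_gives_p_one(self):
        n = 40
        fit = fit_null(np.full(n, 1.0), np.ones((n, 1)))
        T, p = score_test(np.full(n, 1.0), fit, np.eye(n), np.ones(n))
        assert (T, p) == (0.0, 1.0)

    def test_null_pvalues_uniform(self, small_spots, small_bank):
        """Monte-Carlo null: per-kernel p-values are uniform."""
        d = pairwise_distances(small_spots)
        K = build_kernel(d, small_bank[2])
        n = small_spots.n_spots
        X = np.ones((n, 1))
        spec = kernel_spectrum(K, X)
        gen = np.random.default_rng(7)
        pvals = []
        for _ in range(400):
            y = gen.normal(size=n)
            fit = fit_null(y, X)
            _, p = score_test(y, fit, K, spec)
            pvals.append(p)
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestCauchyCombine:
    def test_single_p_identity(self):
        assert cauchy_combine([0.01]) == pytest.approx(0.01, abs=1e-12)

    def test_equal_p_fixed_point(self):
        assert cauchy_combine([0.2] * 5) == pytest.approx(0.2, abs=1e-12)

    def test_formula_oracle(self):
        # direct evaluation of the tangent-average formula
        p = np.array([0.01, 0.5])
        stat = 0.5 * np.tan((0.5 - p) * np.pi).sum()
        expected = 0.5 - np.arctan(stat) / np.pi
        assert cauchy_combine(p) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.02, abs=0.002)

    def test_dominated_by_smallest_component(self):
        assert cauchy_combine([1e-10, 0.4, 0.6]) < 1e-9

    def test_component_at_one_does_not_cancel_tiny_p(self):
        # a numerically-1 component must not neutralize strong evidence
        assert cauchy_combine([1e-300, 1.0]) < 1e-3

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            cauchy_combine([])
        with pytest.raises(ValueError):
            cauchy_combine([0.5, 1.2])


class TestEngineAgainstDirectPath:
    """The cached-eigenbasis engine must reproduce the direct computation."""

    def test_base_statistics_and_spectra(self, small_spots, small_bank, rng):
        eng = SVGTestEngine(small_spots, small_bank)
        d = pairwise_distances(small_spots)
        n = small_spots.n_spots
        Y = rng.normal(size=(4, n))
        T, P, _ = eng.test_genes(Y)
        ki = 6
        K = build_kernel(d, small_bank[ki])
        spec_direct = kernel_spectrum(K, np.ones((n, 1)))
        np.testing.assert_allclose(
            np.sort(eng.base_spectrum(ki))[-30:], np.sort(spec_direct)[-30:], atol=1e-8
        )
        ones_q, _ = np.linalg.qr(np.ones((n, 1)))
        P0 = np.eye(n) - ones_q @ ones_q.T
        for g in range(4):
            fit = fit_null(Y[g], np.ones((n, 1)))
            T_dir, _ = score_test(Y[g], fit, K, spec_direct)
            assert T[g, ki] == pytest.approx(T_dir, abs=1e-6)
            # the engine p-value is the exact null of the *ratio*
            # statistic: P(T > q) = P(r'(K - q/(n-1) I)r > 0)
            c = T_dir / (n - 1)
            shifted = np.linalg.eigvalsh(P0 @ (K - c * np.eye(n)) @ P0)
            oracle = davies_tail(0.0, shifted)
            assert P[g, ki] == pytest.approx(oracle, abs=2e-6)

    def test_adjusted_path_matches_direct(self, small_spots, small_bank, rng):
        eng = SVGTestEngine(small_spots, small_bank)
        d = pairwise_distances(small_spots)
        n = small_spots.n_spots
        y = rng.normal(size=n)
        C = rng.normal(size=(n, 3))
        T, P, fully = eng.adjusted_pvalues(y, C)
        assert not fully
        X = np.column_stack([np.ones(n), C])
        fit = fit_null(y, X)
        ones = np.full((n, 1), 1.0 / np.sqrt(n))
        Q, _ = np.linalg.qr(X)
        Qc = Q - ones @ (ones.T @ Q)
        norms = np.linalg.norm(Qc, axis=0)
        Qc = Qc[:, norms > 1e-10] / norms[norms > 1e-10]
        for ki in (0, 7):
            K = build_kernel(d, small_bank[ki])
            spec = kernel_spectrum(K, X)
            # low-rank update spectrum agrees with the direct
            # eigendecomposition to 1e-8
            spec_eng = eng._adjusted_spectrum(ki, Qc)
            # both lists are descending: large positive eigenvalues at
            # the front, large negative ones (indefinite cosine kernels)
            # at the back, numerical zeros interleaving in the middle —
            # compare both informative ends
            np.testing.assert_allclose(spec_eng[:15], spec[:15], atol=1e-8)
            np.testing.assert_allclose(spec_eng[-10:], spec[-10:], atol=1e-8)
            T_dir, _ = score_test(y, fit, K, spec)
            assert T[ki] == pytest.approx(T_dir, rel=1e-8)
            # exact ratio-null oracle via the direct projection
            Qd, _ = np.linalg.qr(X)
            Pd = np.eye(n) - Qd @ Qd.T
            c = T_dir / (n - X.shape[1])
            shifted = np.linalg.eigvalsh(Pd @ (K - c * np.eye(n)) @ Pd)
            oracle = davies_tail(0.0, shifted)
            assert P[ki] == pytest.approx(oracle, abs=2e-6)

    def test_gene_in_covariate_span_fully_explained(self, small_spots, small_bank, rng):
        eng = SVGTestEngine(small_spots, small_bank)
        c = rng.normal(size=small_spots.n_spots)
        y = 2.0 + 3.0 * c
        _, P, fully = eng.adjusted_pvalues(y, c[:, None])
        assert fully
        np.testing.assert_allclose(P, 1.0)


class TestDetectSvgs:
    def test_strong_signal_detected(self, small_spots):
        n = small_spots.n_spots
        gen = np.random.default_rng(3)
        bump = np.exp(
            -((small_spots.coords - 0.4) ** 2).sum(axis=1) / (2 * 0.15 ** 2)
        )
        Y = gen.normal(size=(20, n))
        Y[0] = 5 * (bump - bump.mean()) / bump.std() + 0.1 * gen.normal(size=n)
        expr = ExpressionMatrix(tuple(f"g{i}" for i in range(20)), small_spots.spot_ids, Y)
        res = detect_svgs(expr, small_spots)
        tab = res.table.set_index("gene_id")
        assert tab.loc["g0", "q_value"] < 1e-6
        assert tab.loc["g0", "is_svg"]

    def test_result_invariants(self, small_spots, rng):
        Y = rng.normal(size=(15, small_spots.n_spots))
        expr = ExpressionMatrix(tuple(f"g{i}" for i in range(15)), small_spots.spot_ids, Y)
        res = detect_svgs(expr, small_spots)
        t = res.table
        assert ((t["p_combined"] >= 0) & (t["p_combined"] <= 1)).all()
        assert (t["q_value"] >= t["p_combined"] - 1e-12).all()
        assert res.m1 == int((t["q_value"] <= res.alpha).sum())

    def test_null_data_rarely_detects(self):
        expr, spots, _ = null_dataset(11, n_genes=60, n_spots=150)
        res = detect_svgs(expr, spots)
        assert res.m1 <= 2

    def test_empty_expression_rejected(self, small_spots):
        expr = ExpressionMatrix((), small_spots.spot_ids, np.empty((0, small_spots.n_spots)))
        with pytest.raises(ValueError):
            detect_svgs(expr, small_spots)
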