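"""System matrices, SVD solutions, regularization and diagnostics."""

import numpy as np
import pytest

import perfkit as pk
from perfkit.deconv import SVDFactorization, picard_diagnostic

from conftest import random_deconv_problem


class TestBuildSystemMatrix:
    def test_toeplitz_layout(self):
        grid = pk.TimeGrid(1.0, 3)
        aif = pk.ConcentrationCurve(grid, [1.0, 2.0, 3.0], "arterial")
        A = pk.build_system_matrix(aif, "toeplitz")
        np.testing.assert_array_equal(A.matrix, [[1, 0, 0], [2, 1, 0], [3, 2, 1]])

    def test_leading_zeros_bound_the_rank(self):
        grid = pk.TimeGrid(1.0, 8)
        vals = np.array([0.0, 0.0, 1.0, 2.0, 1.0, 0.5, 0.2, 0.1])
        A = pk.build_system_matrix(pk.ConcentrationCurve(grid, vals, "arterial"))
        assert A.n_lz == 2
        assert A.svd.rank <= A.n - A.n_lz

    def test_circulant_product_is_circular_convolution(self):
        grid = pk.TimeGrid(1.0, 3)
        aif = pk.ConcentrationCurve(grid, [1.0, 0.0, 0.0], "arterial")
        A = pk.build_system_matrix(aif, "circulant")
        assert A.dim == 6
        rng = np.random.default_rng(0)
        x = rng.normal(size=6)
        col = A.matrix[:, 0]
        brute = np.array(
            [sum(col[(j - i) % 6] * x[i] for i in range(6)) for j in range(6)]
        )
        np.testing.assert_allclose(A.matrix @ x, brute, rtol=1e-12)

    def test_all_zero_aif_rejected(self):
        grid = pk.TimeGrid(1.0, 4)
        with pytest.raises(ValueError, match="all-zero"):
            pk.build_system_matrix(pk.ConcentrationCurve(grid, np.zeros(4), "arterial"))

    def test_svd_reconstructs_matrix(self, aif40):
        A = pk.build_system_matrix(aif40)
        svd = A.svd
        recon = svd.u @ np.diag(svd.s) @ svd.vt
        assert np.linalg.norm(A.matrix - recon) <= 1e-10 * svd.s[0]
        np.testing.assert_allclose(svd.u.T @ svd.u, np.eye(svd.rank), atol=1e-10)


class TestSolutions:
    def test_least_squares_recovers_exact_data(self):
        # well-conditioned full-rank A (rough AIF, nonzero first sample):
        # exact data invert exactly
        grid = pk.TimeGrid(1.0, 40)
        rng = np.random.default_rng(2)
        aif = pk.ConcentrationCurve(grid, rng.uniform(0.5, 1.5, grid.n), "arterial")
        k_true = 0.01 * np.exp(-grid.times / rng.uniform(2, 6))
        c = pk.forward_convolve(aif, pk.FlowScaledResidue(grid, k_true))
        sol = pk.least_squares_solution(pk.build_system_matrix(aif), c)
        np.testing.assert_allclose(sol.values, k_true, rtol=1e-8, atol=1e-10 * k_true.max())

    def test_zero_rhs_gives_zero_solution(self, aif40, grid40):
        A = pk.build_system_matrix(aif40)
        c = pk.ConcentrationCurve(grid40, np.zeros(grid40.n), "tissue")
        sol = pk.least_squares_solution(A, c)
        np.testing.assert_allclose(sol.values, 0.0, atol=1e-12)

    def test_noisy_least_squares_oscillates(self, single_voxel_problem):
        aif, _, c = single_voxel_problem
        rng = np.random.default_rng(3)
        noisy = pk.ConcentrationCurve(
            c.grid, c.values + rng.normal(0, 0.01 * c.values.max(), c.grid.n), "tissue"
        )
        A = pk.build_system_matrix(aif)
        sol = pk.least_squares_solution(A, noisy)
        reg = pk.regularized_solution(
            A, noisy, pk.RegularizationSpec(method="tikhonov", lambda_rel=0.3)
        )
        # strong oscillation and amplitude growth vs the regularized solution
        assert sol.diagnostics["oscillation_index"] > 10 * reg.diagnostics["oscillation_index"]
        assert np.abs(sol.values).max() > 3 * np.abs(reg.values).max()

    def test_tikhonov_at_tiny_lambda_equals_least_squares(self):
        # full-rank A so the lambda -> 0 limit is well conditioned
        grid = pk.TimeGrid(1.0, 30)
        vals = pk.make_aif(pk.AIFSpec.with_peak(100.0, onset=0.0), grid).values + 1.0
        aif = pk.ConcentrationCurve(grid, vals, "arterial")
        c = pk.forward_convolve(
            aif, pk.FlowScaledResidue(grid, 0.01 * np.exp(-grid.times / 4.0))
        )
        A = pk.build_system_matrix(aif)
        ls = pk.least_squares_solution(A, c)
        tik = pk.regularized_solution(
            A, c, pk.RegularizationSpec(method="tikhonov", lambda_rel=1e-9)
        )
        assert np.linalg.norm(tik.values - ls.values) <= 1e-6 * np.linalg.norm(ls.values)

    def test_tikhonov_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(16, 65))
            aif, _, c = random_deconv_problem(rng, n)
            A = pk.build_system_matrix(aif)
            lam_rel = float(rng.uniform(0.01, 0.5))
            mine = pk.regularized_solution(
                A, c, pk.RegularizationSpec(method="tikhonov", lambda_rel=lam_rel)
            ).values
            lam = lam_rel * A.svd.s[0]
            oracle = np.linalg.solve(
                A.matrix.T @ A.matrix + lam**2 * np.eye(n), A.matrix.T @ c.values
            )
            assert np.linalg.norm(mine - oracle) <= 1e-8 * np.linalg.norm(oracle)

    def test_tsvd_just_below_smallest_sigma_is_least_squares(self, single_voxel_problem):
        aif, _, c = single_voxel_problem
        A = pk.build_system_matrix(aif)
        lam_rel = 0.999 * A.svd.s[-1] / A.svd.s[0]
        tsvd = pk.regularized_solution(
            A, c, pk.RegularizationSpec(method="tsvd", lambda_rel=lam_rel)
        )
        ls = pk.least_squares_solution(A, c)
        np.testing.assert_allclose(tsvd.values, ls.values, rtol=1e-10, atol=1e-14)

    def test_invalid_lambda_rejected(self, single_voxel_problem):
        aif, _, c = single_voxel_problem
        A = pk.build_system_matrix(aif)
        with pytest.raises(ValueError, match="lambda_rel"):
            pk.regularized_solution(A, c, pk.RegularizationSpec(lambda_rel=1.5))

    def test_norm_monotonicity_in_lambda(self):
        rng = np.random.default_rng(11)
        lams = np.logspace(-4, 0, 50)
        for _ in range(5):
            aif, _, c = random_deconv_problem(rng, 40)
            A = pk.build_system_matrix(aif)
            sols = [
                pk.regularized_solution(
                    A, c, pk.RegularizationSpec(method="tikhonov", lambda_rel=l)
                )
                for l in lams
            ]
            sn = np.array([s.diagnostics["solution_norm"] for s in sols])
            rn = np.array([s.diagnostics["residual_norm"] for s in sols])
            assert np.all(np.diff(sn) <= 1e-10 * sn[0])
            assert np.all(np.diff(rn) >= -1e-10 * rn[-1])


class TestFftPath:
    def test_matches_circulant_svd_tikhonov(self, single_voxel_problem):
        aif, _, c = single_voxel_problem
        A = pk.build_system_matrix(aif, "circulant")
        for lam_rel in (0.01, 0.1, 0.3):
            spec = pk.RegularizationSpec(method="tikhonov", lambda_rel=lam_rel)
            svd_sol = pk.regularized_solution(A, c, spec)
            fft_sol = pk.fft_deconvolve(aif, c, spec)
            assert (
                np.linalg.norm(svd_sol.values - fft_sol.values)
                <= 1e-6 * np.linalg.norm(svd_sol.values)
            )

    def test_recovers_truth_at_tiny_lambda(self):
        # curves with compact support: the linear convolution decays well
        # inside the padded window, so circular deconvolution is exact
        grid = pk.TimeGrid(1.0, 40)
        aif = pk.make_aif(
            pk.AIFSpec.with_peak(100.0, onset=2.0, shape=2.0, timescale=0.8), grid
        )
        k_true = 0.01 * np.exp(-grid.times / 1.5)
        c = pk.forward_convolve(aif, pk.FlowScaledResidue(grid, k_true))
        sol = pk.fft_deconvolve(
            aif, c, pk.RegularizationSpec(method="tikhonov", lambda_rel=1e-8)
        )
        np.testing.assert_allclose(sol.values, k_true, atol=1e-6 * k_true.max())

    def test_impulse_aif_rescales_curve(self, grid40, grey_kinetics):
        imp = np.zeros(grid40.n)
        imp[0] = 2.0
        aif = pk.ConcentrationCurve(grid40, imp, "arterial")
        k_true = pk.flow_scaled_residue(grey_kinetics, grid40)
        c = pk.forward_convolve(aif, k_true)
        sol = pk.fft_deconvolve(aif, c, pk.RegularizationSpec(lambda_rel=1e-10))
        np.testing.assert_allclose(sol.values, c.values / (grid40.dt * 2.0), rtol=1e-6)


class TestDelayInsensitivity:
    def test_circulant_stable_toeplitz_drops_under_delay(self, single_voxel_problem):
        aif, _, c = single_voxel_problem
        d = 3
        delayed = pk.ConcentrationCurve(
            c.grid, np.concatenate([np.zeros(d), c.values[:-d]]), "tissue"
        )
        spec = pk.RegularizationSpec(method="tikhonov", lambda_rel=0.2)
        for kind, check in (("circulant", "stable"), ("toeplitz", "drops")):
            A = pk.build_system_matrix(aif, kind)
            m0 = pk.regularized_solution(A, c, spec).values.max()
            md = pk.regularized_solution(A, delayed, spec).values.max()
            if check == "stable":
                assert abs(md - m0) / m0 < 0.02
            else:
                assert md < m0

    def test_circulant_tmax_shifts_by_delay(self, single_voxel_problem):
        aif, _, c = single_voxel_problem
        d = 3
        delayed = pk.ConcentrationCurve(
            c.grid, np.concatenate([np.zeros(d), c.values[:-d]]), "tissue"
        )
        A = pk.build_system_matrix(aif, "circulant")
        spec = pk.RegularizationSpec(method="tikhonov", lambda_rel=0.2)
        t0 = pk.tmax_of_k(pk.regularized_solution(A, c, spec))
        td = pk.tmax_of_k(pk.regularized_solution(A, delayed, spec))
        assert td - t0 == pytest.approx(d * c.grid.dt)


class TestModelFit:
    def test_exponential_truth_recovered(self, single_voxel_problem):
        aif, k_true, c = single_voxel_problem
        a, b = pk.model_fit_deconvolve(aif, c)
        assert a == pytest.approx(k_true.values.max(), rel=0.01)
        assert b == pytest.approx(4.0, rel=0.01)

    def test_gamma_residue_preserves_cbv_product(self, aif40, grid40):
        tk = pk.TissueKinetics(cbf=60.0, cbv=4.0, rho_voi=1.04, residue_family="gamma")
        k = pk.flow_scaled_residue(tk, grid40)
        c = pk.forward_convolve(aif40, k)
        a, b = pk.model_fit_deconvolve(aif40, c)
        cbv_model = a * b / 1.04 * 100.0
        assert cbv_model == pytest.approx(4.0, rel=0.05)

    def test_zero_curve_gives_zero_amplitude(self, aif40, grid40):
        c = pk.ConcentrationCurve(grid40, np.zeros(grid40.n), "tissue")
        a, _ = pk.model_fit_deconvolve(aif40, c)
        assert a == 0.0


class TestDiagnostics:
    def test_picard_not_raised_for_consistent_data(self, single_voxel_problem):
        aif, _, c = single_voxel_problem
        A = pk.build_system_matrix(aif)
        _, violated = picard_diagnostic(A.svd, c.values)
        assert not violated

    def test_picard_raised_for_white_noise(self, aif40, grid40):
        rng = np.random.default_rng(5)
        A = pk.build_system_matrix(aif40)
        _, violated = picard_diagnostic(A.svd, rng.normal(size=grid40.n))
        assert violated

    def test_picard_table_columns(self, single_voxel_problem):
        aif, _, c = single_voxel_problem
        A = pk.build_system_matrix(aif)
        table, _ = picard_diagnostic(A.svd, c.values)
        assert list(table.columns) == ["index", "sigma", "utc", "ratio"]
        assert len(table) == A.svd.rank
        np.testing.assert_allclose(table["ratio"], table["utc"] / table["sigma"])

    def test_rhs_in_first_singular_vector_collapses_ratios(self, aif40):
        A = pk.build_system_matrix(aif40)
        c = pk.ConcentrationCurve(aif40.grid, A.svd.u[:, 0], "tissue")
        table, violated = picard_diagnostic(A.svd, c.values)
        assert not violated
        assert np.all(table["utc"].to_numpy()[1:] < 1e-10)


class TestOscillationIndex:
    @pytest.mark.parametrize(
        "values", [np.ones(20), np.linspace(0.1, 2.0, 20)], ids=["constant", "ramp"]
    )
    def test_affine_sequences_have_zero_oi(self, values):
        k = pk.FlowScaledResidue(pk.TimeGrid(1.0, values.size), values)
        assert pk.oscillation_index(k) == pytest.approx(0.0, abs=1e-12)

    def test_alternating_sequence_closed_form(self):
        L = 24
        vals = np.resize([1.0, -1.0], L)
        k = pk.FlowScaledResidue(pk.TimeGrid(1.0, L), vals)
        assert pk.oscillation_index(k) == pytest.approx((L - 2) * 2.0 / L)

    def test_nonpositive_k_gives_nan(self):
        k = pk.FlowScaledResidue(pk.TimeGrid(1.0, 10), -np.ones(10))
        assert np.isnan(pk.oscillation_index(k))


class TestLambdaSelection:
    def test_oi_smallest_grid_value_for_clean_data(self, single_voxel_problem):
        aif, _, c = single_voxel_problem
        A = pk.build_system_matrix(aif)
        spec = pk.RegularizationSpec(selection="oi")
        lam = pk.select_lambda_oi(A, c, spec)
        assert lam == pytest.approx(spec.lambda_grid()[0])

    def test_oi_larger_lambda_under_noise(self, single_voxel_problem):
        aif, _, c = single_voxel_problem
        rng = np.random.default_rng(13)
        noisy = pk.ConcentrationCurve(
            c.grid, c.values + rng.normal(0, 0.02 * c.values.max(), c.grid.n), "tissue"
        )
        A = pk.build_system_matrix(aif)
        spec = pk.RegularizationSpec(selection="oi")
        assert pk.select_lambda_oi(A, noisy, spec) > pk.select_lambda_oi(A, c, spec)

    def test_oi_infinite_threshold_gives_grid_minimum(self, single_voxel_problem):
        aif, _, c = single_voxel_problem
        A = pk.build_system_matrix(aif)
        spec = pk.RegularizationSpec(selection="oi", oi_threshold=np.inf)
        assert pk.select_lambda_oi(A, c, spec) == pytest.approx(spec.lambda_grid()[0])

    def test_lcurve_matches_brute_force_curvature_scan(self, single_voxel_problem):
        aif, _, c = single_voxel_problem
        rng = np.random.default_rng(17)
        noisy = pk.ConcentrationCurve(
            c.grid, c.values + rng.normal(0, 0.02 * c.values.max(), c.grid.n), "tissue"
        )
        A = pk.build_system_matrix(aif)
        spec = pk.RegularizationSpec(selection="lcurve")
        lam = pk.select_lambda_lcurve(A, noisy, spec)
        # independent exhaustive scan over the same grid
        grid = spec.lambda_grid()
        pts = []
        for l in grid:
            s = pk.regularized_solution(A, noisy, pk.RegularizationSpec(lambda_rel=l))
            pts.append(
                (np.log(s.diagnostics["residual_norm"] ** 2),
                 np.log(s.diagnostics["solution_norm"] ** 2))
            )
        best, best_c = None, -1.0
        for i in range(1, len(grid) - 1):
            (x0, y0), (x1, y1), (x2, y2) = pts[i - 1], pts[i], pts[i + 1]
            area2 = abs((x1 - x0) * (y2 - y0) - (y1 - y0) * (x2 - x0))
            d = (np.hypot(x1 - x0, y1 - y0) * np.hypot(x2 - x1, y2 - y1)
                 * np.hypot(x2 - x0, y2 - y0))
            curv = 2 * area2 / d if d else 0.0
            if curv > best_c:
                best, best_c = i, curv
        # within one grid step of the exhaustively found corner
        idx = int(np.argmin(np.abs(grid - lam)))
        assert abs(idx - best) <= 1

    def test_lcurve_two_point_grid_rejected(self, single_voxel_problem):
        aif, _, c = single_voxel_problem
        A = pk.build_system_matrix(aif)
        with pytest.raises(ValueError, match="grid points"):
            pk.select_lambda_lcurve(A, c, pk.RegularizationSpec(lcurve_grid=2))
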