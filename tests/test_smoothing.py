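import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tmmp import smoothing as sm


class TestAutocovariance:
    @pytest.mark.parametrize(
        "kernel, lag, expected",
        [
            (sm.KernelSpec("ar1", kappa=2, rho=0.5), 0, 4.0),
            (sm.KernelSpec("ar1", kappa=2, rho=0.5), 3, 4.0 * 0.5**3),
            (sm.KernelSpec("matern", kappa=1, ell=1, nu=0.5), 1, np.exp(-1)),
            (sm.KernelSpec("squared_exponential", kappa=1, ell=1), 1,
             np.exp(-0.5)),
            (sm.KernelSpec("iid", sigma=1.5), 0, 2.25),
            (sm.KernelSpec("iid", sigma=1.5), 1, 0.0),
            (sm.KernelSpec("arma11", sigma=1.2, rho=0.6, theta=-0.3), 0,
             1.44),
        ],
    )
    def test_point_values(self, kernel, lag, expected):
        assert sm.autocovariance(kernel, lag) == pytest.approx(expected,
                                                               abs=1e-12)

    def test_matern_half_is_exponential(self):
        k = sm.KernelSpec("matern", kappa=1.3, ell=2.0, nu=0.5)
        h = np.arange(21)
        expected = 1.3**2 * np.exp(-h / 2.0)
        assert np.allclose(sm.autocovariance(k, h), expected, atol=1e-10)

    def test_matern_three_halves_closed_form(self):
        k = sm.KernelSpec("matern", kappa=0.8, ell=1.7, nu=1.5)
        h = np.arange(21)
        s3 = np.sqrt(3.0) * h / 1.7
        expected = 0.8**2 * (1 + s3) * np.exp(-s3)
        assert np.allclose(sm.autocovariance(k, h), expected, atol=1e-10)

    def test_matern_general_nu_matches_bessel_limit(self):
        # general Bessel branch evaluated just off nu=1/2 agrees with the
        # exponential kernel
        k = sm.KernelSpec("matern", kappa=1.0, ell=1.0, nu=0.5 + 1e-9)
        assert sm.autocovariance(k, 1) == pytest.approx(np.exp(-1), rel=1e-6)

    @pytest.mark.parametrize("kernel", [
        sm.KernelSpec("ar1", kappa=1, rho=0.9),
        sm.KernelSpec("squared_exponential", kappa=1, ell=3.0),
        sm.KernelSpec("matern", kappa=1, ell=3.0, nu=1.5),
        sm.KernelSpec("arma11", sigma=1, rho=0.9, theta=-0.5),
    ])
    def test_decay_to_zero(self, kernel):
        s0 = sm.autocovariance(kernel, 0)
        assert abs(sm.autocovariance(kernel, 1000)) / s0 < 1e-6

    def test_hyperparameter_validation(self):
        with pytest.raises(ValueError):
            sm.KernelSpec("ar1", kappa=-1, rho=0.5)
        with pytest.raises(ValueError):
            sm.KernelSpec("ar1", kappa=1, rho=1.0)
        with pytest.raises(ValueError):
            sm.KernelSpec("arma11", sigma=1, rho=0.5, theta=0.5)
        with pytest.raises(ValueError, match="missing"):
            sm.KernelSpec("matern", kappa=1, ell=1)

    def test_unknown_family(self):
        with pytest.raises(ValueError, match="unknown kernel"):
            sm.KernelSpec("brownian", sigma=1)


class TestCovariance:
    def test_iid_identity(self):
        k = sm.KernelSpec("iid", sigma=1.0)
        assert np.allclose(sm.build_covariance(k, 3), np.eye(3), atol=1e-9)

    def test_ar1_entry(self):
        k = sm.KernelSpec("ar1", kappa=1.7, rho=0.4)
        S = sm.build_covariance(k, 5)
        assert S[0, 3] == pytest.approx(1.7**2 * 0.4**3)
        assert np.allclose(S, S.T)

    def test_arma11_matches_simulation(self):
        """Stationary ARMA(1,1) autocovariance vs a brute-force simulation
        of the recursion (scaled-down version of the full oracle)."""
        sigma, rho, theta = 1.0, 0.6, -0.3
        k = sm.KernelSpec("arma11", sigma=sigma, rho=rho, theta=theta)
        rng = np.random.default_rng(0)
        paths, n, burn = 40000, 400, 200
        ve = sigma**2 * (1 - rho**2) / (1 + 2 * rho * theta + theta**2)
        e = rng.normal(0, np.sqrt(ve), (paths, n))
        x = np.zeros((paths, n))
        for t in range(1, n):
            x[:, t] = rho * x[:, t - 1] + e[:, t] + theta * e[:, t - 1]
        x = x[:, burn:]
        S = sm.build_covariance(k, 6)
        for lag in range(6):
            emp = float(np.mean(x[:, : x.shape[1] - lag] * x[:, lag:]))
            assert emp == pytest.approx(S[0, lag], rel=0.03, abs=0.01)

    def test_psd_after_jitter(self):
        k = sm.KernelSpec("squared_exponential", kappa=1, ell=10.0)
        S = sm.build_covariance(k, 40)
        assert np.linalg.eigvalsh(S).min() > -1e-9


class TestDifferencing:
    def test_first_difference_entries(self):
        D = sm.difference_matrix(3, 1)
        assert np.array_equal(D, [[-1, 1, 0], [0, -1, 1]])

    def test_second_difference_is_composition(self):
        D = sm.difference_matrix(4, 2)
        assert np.array_equal(D, [[1, -2, 1, 0], [0, 1, -2, 1]])

    def test_r0_identity(self):
        assert np.array_equal(sm.difference_matrix(4, 0), np.eye(4))

    def test_dimension_error(self):
        with pytest.raises(ValueError):
            sm.difference_matrix(3, 3)

    def test_minimum_norm_hand_example(self):
        # K=3, r=1, gamma=[1,1]: D D' = [[2,-1],[-1,2]]
        delta = sm.recover_levels(np.array([1.0, 1.0]), 1, "minimum_norm")
        assert np.allclose(delta, [-1.0, 0.0, 1.0], atol=1e-12)
        assert abs(delta.sum()) < 1e-12

    def test_zero_gamma_gives_zero_delta(self):
        assert np.allclose(
            sm.recover_levels(np.zeros(5), 2, "minimum_norm"), 0.0
        )

    @settings(max_examples=200, deadline=None)
    @given(
        st.integers(min_value=3, max_value=30),
        st.integers(min_value=1, max_value=2),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_difference_of_recovery_is_identity(self, K, r, seed):
        gamma = np.random.default_rng(seed).normal(size=K - r)
        D = sm.difference_matrix(K, r)
        for mode, anchors in [
            ("minimum_norm", None),
            ("anchored", {d: list(range(K - d)) for d in range(r)}),
        ]:
            delta = sm.recover_levels(gamma, r, mode, anchors)
            assert np.allclose(D @ delta, gamma, atol=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(
        st.integers(min_value=4, max_value=25),
        st.integers(min_value=1, max_value=2),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_minimum_norm_orthogonal_to_nullspace(self, K, r, seed):
        gamma = np.random.default_rng(seed).normal(size=K - r)
        delta = sm.recover_levels(gamma, r, "minimum_norm")
        # null(D) is spanned by polynomials of degree < r
        for d in range(r):
            basis = np.arange(K, dtype=float) ** d
            assert abs(delta @ basis) < 1e-8 * max(1, np.abs(delta).max())

    def test_anchored_satisfies_declared_constraints(self):
        # the sum-to-zero and reference-coefficient anchorings used by the
        # mortality models hold exactly in the recovered levels
        K, r = 12, 2
        anchors = {0: [5], 1: list(range(K - 1))}
        gamma = np.random.default_rng(1).normal(size=K - r)
        delta = sm.recover_levels(gamma, r, "anchored", anchors)
        assert abs(delta[5]) < 1e-10
        assert abs(delta[-1] - delta[0]) < 1e-10  # sum of first differences

    def test_anchored_requires_all_orders(self):
        with pytest.raises(ValueError, match="index set"):
            sm.recover_levels(np.ones(3), 2, "anchored", {0: [0]})


class TestBasis:
    def test_identity(self):
        b = sm.BasisSpec("identity")
        assert np.array_equal(sm.build_basis(b, np.arange(1, 11)), np.eye(10))

    def test_bspline_count(self):
        # 25 grid units at spacing 2.5 -> 10 intervals -> K = 10 + 3
        b = sm.BasisSpec("bspline", degree=3, knot_spacing=2.5)
        B = sm.build_basis(b, np.arange(0.0, 25.01, 1.0), span=(0.0, 25.0))
        assert B.shape[1] == 13

    def test_partition_of_unity(self):
        b = sm.BasisSpec("bspline", degree=3, knot_spacing=2.5)
        times = np.arange(1.0, 21.0)
        B = sm.build_basis(b, times)
        assert np.allclose(B.sum(axis=1), 1.0, atol=1e-10)

    def test_full_column_rank(self):
        b = sm.BasisSpec("bspline", degree=3, knot_spacing=2.5)
        B = sm.build_basis(b, np.arange(1.0, 31.0))
        assert np.linalg.matrix_rank(B) == B.shape[1]

    def test_span_extension_preserves_columns(self):
        b = sm.BasisSpec("bspline", degree=3, knot_spacing=2.5)
        times = np.arange(1.0, 21.0)
        B1 = sm.build_basis(b, times, span=(1.0, 20.0))
        B2 = sm.build_basis(b, times, span=(1.0, 40.0))
        assert np.allclose(B2[:, : B1.shape[1]], B1, atol=1e-12)

    def test_short_span_error(self):
        b = sm.BasisSpec("bspline", degree=3, knot_spacing=5.0)
        with pytest.raises(ValueError, match="span"):
            sm.build_basis(b, np.arange(1.0, 4.0), span=(1.0, 3.0))


class TestSampling:
    def test_zero_draws(self):
        spec = sm.SmoothingSpec(
            basis=sm.BasisSpec("identity"),
            kernel=sm.KernelSpec("iid", sigma=1.0), r=0,
        )
        eps = sm.sample_smoothing(spec, np.arange(1, 6), 0, seed=0)
        assert eps.shape == (0, 5)

    def test_iid_marginal_variance(self):
        spec = sm.SmoothingSpec(
            basis=sm.BasisSpec("identity"),
            kernel=sm.KernelSpec("iid", sigma=0.7), r=0,
        )
        eps = sm.sample_smoothing(spec, np.arange(1, 11), 20000, seed=1)
        mc_se = 0.7**2 * np.sqrt(2 / 20000)
        assert np.all(np.abs(eps.var(axis=0) - 0.49) < 4 * mc_se)

    def test_anchoring_holds_in_every_draw(self):
        K = sm.basis_size(sm.BasisSpec("bspline", knot_spacing=2.5),
                          (1.0, 20.0))
        anchors = {0: [K // 2], 1: list(range(K - 1))}
        spec = sm.SmoothingSpec(
            basis=sm.BasisSpec("bspline", knot_spacing=2.5),
            kernel=sm.KernelSpec("iid", sigma=0.3), r=2,
            constraint_mode="anchored", anchors=anchors,
        )
        rng = np.random.default_rng(2)
        B = sm.build_basis(sm.BasisSpec("bspline", knot_spacing=2.5),
                           np.arange(1.0, 21.0))
        eps = sm.sample_smoothing(spec, np.arange(1.0, 21.0), 50, rng)
        delta = np.linalg.lstsq(B, eps.T, rcond=None)[0].T
        assert np.abs(delta[:, K // 2]).max() < 1e-8
        assert np.abs(delta[:, -1] - delta[:, 0]).max() < 1e-8

    def test_seed_reproducibility(self):
        spec = sm.SmoothingSpec(
            basis=sm.BasisSpec("identity"),
            kernel=sm.KernelSpec("ar1", kappa=1.0, rho=0.6), r=0,
        )
        a = sm.sample_smoothing(spec, np.arange(1, 8), 5, seed=42)
        b = sm.sample_smoothing(spec, np.arange(1, 8), 5, seed=42)
        assert np.array_equal(a, b)


class TestConditioning:
    def test_ar1_closed_form(self):
        kappa, rho = 1.5, 0.7
        k = sm.KernelSpec("ar1", kappa=kappa, rho=rho)
        eps_obs = np.array([0.2, -0.1, 0.9])
        cond = sm.condition_projection(k, eps_obs, 4)
        for h in range(1, 5):
            assert cond.mean[h - 1] == pytest.approx(
                rho**h * eps_obs[-1], abs=1e-8
            )
            assert cond.cov[h - 1, h - 1] == pytest.approx(
                kappa**2 * (1 - rho ** (2 * h)), abs=1e-8
            )

    def test_iid_unconditional(self):
        k = sm.KernelSpec("iid", sigma=0.5)
        cond = sm.condition_projection(k, np.array([1.0, 2.0]), 1)
        assert cond.mean[0] == pytest.approx(0.0, abs=1e-12)
        assert cond.cov[0, 0] == pytest.approx(0.25, rel=1e-6)

    def test_against_brute_force_conditional(self):
        """Generic conditioning agrees with an explicit partitioned
        inverse of the full joint covariance on a small instance."""
        k = sm.KernelSpec("squared_exponential", kappa=1.1, ell=2.0)
        m, K_add = 8, 4
        obs = np.random.default_rng(5).normal(size=m)
        cond = sm.condition_projection(k, obs, K_add)
        S = sm.build_covariance(k, m + K_add)
        S11, S12, S22 = S[:m, :m], S[:m, m:], S[m:, m:]
        mean_bf = S12.T @ np.linalg.solve(S11, obs)
        cov_bf = S22 - S12.T @ np.linalg.solve(S11, S12)
        assert np.allclose(cond.mean, mean_bf, atol=1e-9)
        assert np.allclose(cond.cov, cov_bf, atol=1e-9)

    def test_extend_levels_rw2_linear_trend(self):
        delta = np.array([0.0, 1.0, 2.0])
        out = sm.extend_levels(delta, np.zeros(4), 2)
        assert np.allclose(out, np.arange(7.0))
        assert np.allclose(np.diff(out, n=2), 0.0, atol=1e-12)
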