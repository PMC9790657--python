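import numpy as np
import pytest

from tmmp import ModelConfig, TimeGrid, TMMPModel
from tmmp import smoothing as sm
from tmmp.inference import PosteriorSamples
from tmmp.projection import (
    compute_pooling_targets,
    extended_basis,
    pool_second_differences,
    project_default,
    project_log_pooling,
)


def _ar1_model(T, T_star, kappa=0.8, rho=0.7):
    cfg = ModelConfig({
        "transform": "identity",
        "smoothing": {"basis": "identity", "kernel": "ar1",
                      "kernel_params": {"kappa": kappa, "rho": rho},
                      "r": 0, "constraint": "none"},
        "data_model": {"family": "normal", "variance": "fixed"},
        "hierarchy": {"kernel_scale": {"strategy": "fixed"}},
    })
    return TMMPModel(cfg, TimeGrid(T=T, T_star=T_star), ["A"])


def _b3_model(T, T_star, sigma=0.05):
    from tmmp.zoo import zoo

    entry = zoo("b3_u5mr")
    entry.config.doc["smoothing"]["kernel_params"]["sigma"] = sigma
    entry.config.doc["hierarchy"]["kernel_scale"] = {"strategy": "fixed"}
    return entry.build_model(TimeGrid(T=T, T_star=T_star), ["A"])


def _posterior(model, draws_dict, n_draws):
    """Fake posterior with every draw identical; per-population arrays
    (gamma, eta) gain their population axis here."""
    draws = {}
    for k, v in draws_dict.items():
        v = np.asarray(v, dtype=float)
        if k in ("gamma", "eta") and v.ndim == 1:
            v = v[None, :]  # single population
        draws[k] = np.broadcast_to(v, (1, n_draws) + v.shape).copy()
    return PosteriorSamples(draws=draws, populations=model.populations,
                            grid=model.grid, seed=0, fingerprint="test",
                            model=model)


class TestDefaultProjection:
    def test_empty_projection_when_Tstar_equals_T(self):
        model = _ar1_model(6, 6)
        post = _posterior(model, {
            "gamma": np.zeros((1, 6)), "eta": np.zeros((1, 6)),
        }, 50)
        out = project_default(post, model, seed=0)
        assert out.shape == (50, 1, 0)

    def test_ar1_projection_matches_closed_form(self):
        T, T_star, kappa, rho = 8, 14, 0.8, 0.7
        model = _ar1_model(T, T_star, kappa, rho)
        eps = np.zeros(T)
        eps[-1] = 1.3  # condition on the last deviation
        post = _posterior(model, {"gamma": eps, "eta": eps}, 4000)
        out = project_default(post, model, seed=1)  # identity transform
        H = T_star - T
        for h in range(1, H + 1):
            vals = out[:, 0, h - 1]
            mean_cf = rho**h * 1.3
            var_cf = kappa**2 * (1 - rho ** (2 * h))
            assert vals.mean() == pytest.approx(
                mean_cf, abs=4 * np.sqrt(var_cf / 4000))
            assert vals.var() == pytest.approx(var_cf, rel=0.15)

    def test_rw2_spline_mean_path_continues_linear_trend(self):
        """With an IID RW(2) spline smoother the conditional-mean
        projection extrapolates the last linear trend: second differences
        of the mean path vanish once the path is supported by extended
        coefficients only."""
        T, T_star = 20, 45
        model = _b3_model(T, T_star)
        spec = model.smoothing_spec()
        B_star, K, K_star = extended_basis(model)
        rng = np.random.default_rng(3)
        gamma = rng.normal(0, 0.05, K - 2)
        R = sm.recovery_matrix(K, 2, spec.constraint_mode, spec.anchors)
        delta = R @ gamma
        # conditional mean of future IID second differences is zero
        delta_star = sm.extend_levels(delta, np.zeros(K_star - K), 2)
        mean_path = B_star @ delta_star
        # restrict to times supported only by the linearly extended
        # coefficients
        supported = np.where(np.abs(B_star[:, : K - 1]).sum(axis=1) < 1e-12)[0]
        assert supported.size >= 5
        d2 = np.diff(mean_path[supported], n=2)
        assert np.abs(d2).max() < 1e-8

    def test_spline_extension_preserves_estimation_columns(self):
        model = _b3_model(20, 35)
        B_star, K, K_star = extended_basis(model)
        spec = model.smoothing_spec()
        B = sm.build_basis(spec.basis, model.grid.times.astype(float),
                           span=(1.0, 20.0))
        assert K_star > K
        assert np.allclose(B_star[:20, :K], B, atol=1e-12)


class TestLogPooling:
    def test_w_one_collapses_to_global_moments(self):
        rng = np.random.default_rng(0)
        G, V = -0.004, 0.0009
        draws = np.array([
            pool_second_differences(np.array([1.0, 1.1, 1.3]), 0.04**2,
                                    1.0, G, V, 6, rng)
            for _ in range(4000)
        ])
        assert np.allclose(draws.mean(axis=0), G, atol=4 * np.sqrt(V / 4000))
        assert np.allclose(draws.var(axis=0), V, rtol=0.15)

    def test_w_zero_collapses_to_own_extrapolation(self):
        rng = np.random.default_rng(0)
        delta = np.array([1.0, 1.2, 1.5])  # last second difference = 0.1
        sig2 = 0.03**2
        draws = np.array([
            pool_second_differences(delta, sig2, 0.0, 5.0, 9.0, 4, rng)
            for _ in range(4000)
        ])
        # first projected difference centred at the last estimated one,
        # constant variance sigma^2 at every step (Theta recursion collapses)
        assert draws[:, 0].mean() == pytest.approx(0.1, abs=4 * 0.03 / 63)
        assert draws[:, 0].var() == pytest.approx(sig2, rel=0.15)
        assert draws[:, -1].var() == pytest.approx(4 * sig2, rel=0.2)

    def test_w_zero_first_step_matches_default_law_at_zero_trendchange(self):
        """When the last estimated second difference is zero, the first
        pooled step has the same N(0, sigma^2) law as the default RW(2)
        projection (beyond the first step the pooling recursion
        deliberately random-walks the second differences)."""
        rng = np.random.default_rng(1)
        delta = np.array([0.5, 0.7, 0.9])  # linear: last 2nd difference 0
        sig2 = 0.05**2
        draws = np.array([
            pool_second_differences(delta, sig2, 0.0, 5.0, 9.0, 1, rng)[0]
            for _ in range(6000)
        ])
        assert draws.mean() == pytest.approx(0.0, abs=4 * 0.05 / 77)
        assert draws.var() == pytest.approx(sig2, rel=0.12)

    def test_project_log_pooling_end_to_end(self):
        T, T_star = 20, 30
        model = _b3_model(T, T_star)
        spec = model.smoothing_spec()
        B_star, K, K_star = extended_basis(model)
        rng = np.random.default_rng(5)
        gamma = rng.normal(0, 0.04, K - 2)
        post = _posterior(model, {
            "gamma": gamma,
            "alpha0": np.array([4.0]), "alpha1": np.array([-0.02]),
            "eta": np.exp(np.full(T, 4.0)),
            "kernel_scale": np.array([0.04]),
        }, 200)
        out = project_log_pooling(post, model, W=0.5, G=0.0, V=0.001, seed=2)
        assert out.shape == (200, 1, T_star - T)
        assert np.all(out > 0)

    def test_w_out_of_range(self):
        model = _b3_model(10, 12)
        with pytest.raises(ValueError, match="W"):
            project_log_pooling(None, model, W=1.2, G=0.0, V=1.0)


class TestPoolingTargets:
    def _post(self, gamma):
        model = _b3_model(10, 12)
        return _posterior(model, {"gamma": gamma,
                                  "eta": np.zeros(10)}, 30)

    def test_identical_values(self):
        post = self._post(np.full(5, 0.2))
        G, V = compute_pooling_targets(post)
        assert G == pytest.approx(0.2)
        assert V == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_median_zero(self):
        post = self._post(np.array([-1.0, 0.0, 1.0]))
        G, _ = compute_pooling_targets(post)
        assert G == 0.0

    def test_matches_sort_based_median(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=1000)
        post = self._post(vals)
        G, V = compute_pooling_targets(post)
        assert G == pytest.approx(float(np.sort(vals)[499:501].mean()))
        assert V == pytest.approx(float(vals.var()))

    def test_too_few_values(self):
        post = self._post(np.array([0.3]))
        with pytest.raises(ValueError, match="at least 2"):
            compute_pooling_targets(post)


class TestStationaryVarianceLimits:
    def test_r0_projection_variance_approaches_stationary(self):
        kappa, rho = 0.9, 0.8
        k = sm.KernelSpec("ar1", kappa=kappa, rho=rho)
        cond = sm.condition_projection(k, np.array([1.0]), 40)
        var_h = np.diag(cond.cov)
        assert var_h[-1] == pytest.approx(kappa**2, rel=1e-6)
        assert np.all(np.diff(var_h) >= -1e-10)

    def test_rw_projection_variance_nondecreasing(self):
        rng = np.random.default_rng(0)
        sig2 = 0.04**2
        n, H = 3000, 8
        delta = np.array([0.0, 0.0, 0.0])
        paths = np.array([
            sm.extend_levels(delta, rng.normal(0, 0.04, H), 2)[3:]
            for _ in range(n)
        ])
        v = paths.var(axis=0)
        assert np.all(np.diff(v) > 0)


class TestJointVersusConditional:
    def test_joint_estimation_matches_conditional_projection(self):
        """On a linear-Gaussian toy with no data after T, fitting the
        latent field jointly to T* gives the same projection law as
        conditional projection from a fit to T (moment comparison)."""
        import pandas as pd

        from tmmp import ObservationTable
        from tmmp.inference import fit

        kappa, rho = 0.8, 0.6
        rows = [{"population": "A", "time": t, "value": v,
                 "sampling_sd": 0.2, "source": "s"}
                for t, v in [(1, 0.5), (2, 0.3), (4, 0.1)]]

        def make(T, T_star):
            cfg = ModelConfig({
                "transform": "identity",
                "smoothing": {"basis": "identity", "kernel": "ar1",
                              "kernel_params": {"kappa": kappa, "rho": rho},
                              "r": 0, "constraint": "none"},
                "data_model": {"family": "normal", "variance": "fixed"},
                "hierarchy": {"kernel_scale": {"strategy": "fixed"}},
            })
            return TMMPModel(cfg, TimeGrid(T=T, T_star=T_star), ["A"])

        opts = {"chains": 2, "draws": 3000, "warmup": 100, "seed": 4}
        # joint: latent field estimated straight to T* = 7
        joint_model = make(7, 7)
        joint = fit(joint_model,
                    ObservationTable(pd.DataFrame(rows), joint_model.grid),
                    options=opts)
        eta_joint = joint.get("eta")[:, 0, 4:]
        # conditional: estimate to T = 4, project 3 steps
        cond_model = make(4, 7)
        post = fit(cond_model,
                   ObservationTable(pd.DataFrame(rows), cond_model.grid),
                   options=opts)
        eta_cond = project_default(post, cond_model, seed=8)[:, 0, :]
        n = eta_joint.shape[0]
        for h in range(3):
            se = np.sqrt(eta_joint[:, h].var() / n) * 4 + 0.01
            assert eta_cond[:, h].mean() == pytest.approx(
                eta_joint[:, h].mean(), abs=4 * se)
            assert eta_cond[:, h].var() == pytest.approx(
                eta_joint[:, h].var(), rel=0.15)
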