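"""Projections of the latent field beyond the last estimation year.

The default projection extends each posterior draw with the estimation
process model itself: the basis is extended over the projection period
(for B-splines, extra knots at the same spacing; existing columns are
unchanged), the new r-th order differenced coefficients are drawn from
their closed-form Gaussian conditional given the estimated ones, levels
are rebuilt by undifferencing, and the non-stochastic components are
evaluated out to T*.

The logarithmic-pooling variant (used for under-five mortality
projections with a spline RW(2) smoother) replaces the conditional draw
of second differences with a mixture of the country's own extrapolated
differences and a global median/variance of past differences:

    Gamma_{c,k} = W G + (1 - W) diff2(delta)_{c,k-1},
    Theta_{c,k} = W V + (1 - W) Theta_{c,k-1},   Theta_{c,K-1} = sigma_c^2.
"""

from __future__ import annotations

import numpy as np

from . import smoothing as sm
from .model import TMMPModel
from .process import TransformSpec, inverse_transform, systematic_logistic_step

__all__ = [
    "project_default",
    "pool_second_differences",
    "project_log_pooling",
    "compute_pooling_targets",
    "extended_basis",
]


def extended_basis(model: TMMPModel):
    """(B_star, K, K_star): basis over 1..T*, original columns unchanged."""
    spec = model.smoothing_spec()
    grid = model.grid
    times_star = grid.times_star.astype(float)
    if spec.basis.kind == "identity":
        B = np.eye(grid.T_star)
        return B, grid.T, grid.T_star
    span0 = (1.0, float(grid.T))
    K = sm.basis_size(spec.basis, span0)
    span_star = (1.0, float(grid.T_star))
    B_star = sm.build_basis(spec.basis, times_star, span=span_star)
    K_star = B_star.shape[1]
    if K_star <= K:
        # projection span still covered by the estimation-period knots
        B_star = sm.build_basis(spec.basis, times_star, span=span0)
        K_star = K
    return B_star, K, K_star


def _draw_params(posterior, model: TMMPModel, i: int) -> dict:
    """Component parameters of stacked posterior draw i."""
    d = posterior.draws
    pops = posterior.populations
    params = {}

    def g(name):
        return posterior.get(name)[i]

    if "alpha0" in d:
        a0, a1 = g("alpha0"), g("alpha1")
        params["alpha"] = {p: (a0[c], a1[c]) for c, p in enumerate(pops)}
        params["t_star"] = model.config["systematic_component"].get(
            "t_star", (1 + model.grid.T) // 2
        )
    if "beta0" in d:
        params["beta0"] = {p: g("beta0")[c] for c, p in enumerate(pops)}
    if "beta" in d:
        params["beta"] = g("beta")
    fixed = model.config["priors"].get("fixed", {})
    if model.config["covariate_component"]["kind"] == "gbd_nonlinear":
        params["beta_gbd"] = fixed["beta_gbd"]
    if model.config["covariate_component"]["kind"] == "piecewise_nmr":
        params["beta1"] = float(g("beta")[0])
        params["beta2"] = float(
            fixed.get("beta2", model.config["covariate_component"].get("beta2", 1.0))
        )
    if "P_tilde" in d:
        params["logistic"] = {
            p: (g("P_tilde")[c], g("omega")[c], g("Omega")[c])
            for c, p in enumerate(pops)
        }
        params["t_star"] = model.config["systematic_component"].get(
            "t_star", (1 + model.grid.T) // 2
        )
    return params


def _deterministic_mean(model, params, covariates, population, times):
    """Covariate + non-recursive systematic + offset terms over `times`."""
    out = np.zeros(times.size)
    cov_kind = model.config["covariate_component"]["kind"]
    if cov_kind not in ("none", "pca_linear"):
        # piecewise slope lives in params["beta1"]; linear slopes in "beta"
        p = dict(params)
        if cov_kind == "piecewise_nmr" and "beta1" not in p:
            p["beta1"] = float(np.atleast_1d(p.get("beta", [0.0]))[0])
        out += model.covariate_term(population, covariates, p, times=times)
    sys_kind = model.config["systematic_component"]["kind"]
    if sys_kind in ("linear_trend", "trapezoid"):
        out += model.systematic_term(population, params, times=times)
    ci = model.pop_index(population)
    out += model.offsets[ci, times - 1]
    return out


def _kernel_for_draw(posterior, model, i, c) -> sm.KernelSpec:
    spec = model.smoothing_spec().kernel
    overrides = {}
    scale_param = "sigma" if spec.family in ("arma11", "iid") else "kappa"
    if "kernel_scale" in posterior.draws:
        overrides[scale_param] = float(posterior.get("kernel_scale")[i, c])
    for p in ("rho", "theta", "ell"):
        if p in posterior.draws:
            overrides[p] = float(posterior.get(p)[i])
    return spec.replace(**overrides)


def _projected_epsilon_default(posterior, model, i, c, rng):
    spec = model.smoothing_spec()
    B_star, K, K_star = extended_basis(model)
    gamma = posterior.get("gamma")[i, c]
    r = spec.r
    if r > 0:
        R = sm.recovery_matrix(K, r, spec.constraint_mode, spec.anchors)
        delta = R @ gamma
    else:
        delta = gamma
    kernel = _kernel_for_draw(posterior, model, i, c)
    K_added = K_star - K
    if K_added == 0:
        return B_star @ delta
    cond = sm.condition_projection(kernel, gamma, K_added)
    gamma_new = cond.sample(rng)[0]
    delta_star = sm.extend_levels(delta, gamma_new, r)
    return B_star @ delta_star


def project_default(
    posterior,
    model: TMMPModel,
    covariates=None,
    seed: int = 0,
) -> np.ndarray:
    """Projection-period eta draws, shape (n_draws, C, T* - T).

    T* = T returns an empty array (identity on the posterior).
    """
    grid = model.grid
    H = grid.T_star - grid.T
    n = posterior.get("eta").shape[0]
    C = len(posterior.populations)
    if H == 0:
        return np.empty((n, C, 0))
    rng = np.random.default_rng(seed)
    tf = TransformSpec(model.config["transform"])
    times_proj = np.arange(grid.T + 1, grid.T_star + 1)
    recursive = model.is_recursive()
    include = model.config["systematic_component"].get(
        "include_eps_in_recursion", True
    )
    out = np.empty((n, C, H))
    eta_all = posterior.get("eta")
    for i in range(n):
        params = _draw_params(posterior, model, i)
        for c, p in enumerate(posterior.populations):
            eps_star = _projected_epsilon_default(posterior, model, i, c, rng)
            if recursive:
                P_t, w_t, _ = params["logistic"][p]
                eta_T = float(eta_all[i, c, grid.T - 1])
                if include:
                    # deviations feed back into the transition
                    eta_prev = eta_T
                    for h in range(H):
                        f = systematic_logistic_step(eta_prev, P_t, w_t) + (
                            eps_star[grid.T + h] - eps_star[grid.T + h - 1]
                            if h > 0 else eps_star[grid.T] - eps_star[grid.T - 1]
                        )
                        eta_prev = float(inverse_transform(f, tf))
                        out[i, c, h] = eta_prev
                else:
                    from .process import logistic_path

                    path = logistic_path(
                        grid.T_star, int(params["t_star"]),
                        params["logistic"][p][2], P_t, w_t,
                        include_eps_in_recursion=False,
                    )
                    f = path[grid.T:] + eps_star[grid.T:]
                    out[i, c] = inverse_transform(f, tf)
            else:
                mean = _deterministic_mean(model, params, covariates, p, times_proj)
                f = mean + eps_star[grid.T:]
                out[i, c] = inverse_transform(f, tf)
    return out


def project_log_pooling(
    posterior,
    model: TMMPModel,
    W: float,
    G: float | None = None,
    V: float | None = None,
    covariates=None,
    seed: int = 0,
) -> np.ndarray:
    """Log-pooling projection for spline RW(2) smoothers.

    With W = 1 every projected second difference is drawn from the global
    N(G, V); with W = 0 the projection reduces to the default RW(2) law
    seeded at the country's own last difference.
    """
    if not 0.0 <= W <= 1.0:
        raise ValueError("pooling weight W must lie in [0, 1]")
    spec = model.smoothing_spec()
    if spec.r != 2:
        raise ValueError("log-pooling projection requires an RW(2) smoother (r=2)")
    if G is None or V is None:
        G_auto, V_auto = compute_pooling_targets(posterior)
        G = G_auto if G is None else G
        V = V_auto if V is None else V
    grid = model.grid
    H = grid.T_star - grid.T
    n = posterior.get("eta").shape[0]
    C = len(posterior.populations)
    if H == 0:
        return np.empty((n, C, 0))
    rng = np.random.default_rng(seed)
    tf = TransformSpec(model.config["transform"])
    times_proj = np.arange(grid.T + 1, grid.T_star + 1)
    B_star, K, K_star = extended_basis(model)
    R = sm.recovery_matrix(K, 2, spec.constraint_mode, spec.anchors)
    out = np.empty((n, C, H))
    sigma_all = posterior.get("kernel_scale") if "kernel_scale" in posterior.draws \
        else None
    for i in range(n):
        params = _draw_params(posterior, model, i)
        for c, p in enumerate(posterior.populations):
            gamma = posterior.get("gamma")[i, c]
            delta = R @ gamma
            if sigma_all is not None:
                sig2 = float(sigma_all[i, c]) ** 2
            else:
                sig2 = float(getattr(spec.kernel, "sigma")) ** 2
            gam_new = pool_second_differences(
                delta, sig2, W, G, V, K_star - K, rng
            )
            delta_star = sm.extend_levels(delta, gam_new, 2)
            eps_star = B_star @ delta_star
            mean = _deterministic_mean(model, params, covariates, p, times_proj)
            f = mean + eps_star[grid.T:]
            out[i, c] = inverse_transform(f, tf)
    return out


def pool_second_differences(delta, sigma2, W, G, V, K_added, rng):
    """Sample projected second differences by the pooling recursion.

    Gamma_k = W G + (1 - W) * (previous realized second difference);
    Theta_k = W V + (1 - W) Theta_{k-1}, started at the country's own
    smoothing variance sigma2.  With W = 1 every draw is N(G, V); with
    W = 0 the second differences follow a random walk started at the last
    estimated difference with constant variance sigma2.
    """
    delta = np.asarray(delta, dtype=float)
    d2_prev = (delta[-1] - 2 * delta[-2] + delta[-3]) if delta.size >= 3 \
        else 0.0
    theta = float(sigma2)
    out = np.empty(K_added)
    for j in range(K_added):
        Gamma = W * G + (1 - W) * d2_prev
        theta = W * V + (1 - W) * theta
        out[j] = rng.normal(Gamma, np.sqrt(max(theta, 0.0)))
        d2_prev = out[j]
    return out


def compute_pooling_targets(posterior) -> tuple[float, float]:
    """(G, V): median and variance of posterior-median past second
    differences of the smoothing coefficients, pooled over populations."""
    gamma = posterior.get("gamma")  # (n, C, m); gamma are r-th differences
    med = np.median(gamma, axis=0)  # (C, m)
    pooled = med.reshape(-1)
    if pooled.size < 2:
        raise ValueError("need at least 2 pooled second differences")
    return float(np.median(pooled)), float(np.var(pooled))
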