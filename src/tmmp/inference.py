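"""Posterior sampling for TMMP models.

The sampler is a blocked Metropolis-within-Gibbs scheme built around the
conditional structure of the model class:

- Coefficient blocks with Gaussian priors (systematic-trend coefficients,
  covariate intercepts/slopes, differenced smoothing coefficients gamma)
  are updated with Gauss-Newton Laplace *independence* proposals: a few
  Newton steps locate the conditional mode and curvature, a Gaussian
  proposal is drawn there, and a Metropolis correction makes the update
  exact.  When the data model is Gaussian on the transformed scale the
  proposal coincides with the full conditional and the acceptance
  probability is one, so the update degenerates to exact Gibbs.
- Kernel scales and shapes (and other hyperparameters the coefficient
  priors depend on) use adaptive random-walk Metropolis moves that
  jointly refresh the affected coefficient blocks from their Laplace
  conditionals under the proposed value.  In the Gaussian case this is
  exact marginal MH (the coefficients are integrated out), which removes
  the funnel coupling between a scale and its coefficients.
- Hierarchy group means are conjugate normal draws; hierarchy scales and
  data-model sigmas use plain adaptive random-walk Metropolis.

The latent coefficient vector delta is parametrized through the free
differenced coefficients gamma = diff^r(delta) plus the constraint-mode
recovery map, so anchoring constraints hold exactly in every draw.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats
from scipy.special import expit, gammaln, logit

from . import smoothing as sm
from .hierarchy import bounded_transform
from .model import TMMPModel

__all__ = ["PosteriorSamples", "Diagnostics", "fit", "diagnose", "FitProblem"]

_LN10 = np.log(10.0)
_LOG2PI = np.log(2 * np.pi)


# light-weight log-density helpers (scipy.stats objects are too slow for
# per-iteration scalar use)

def _lp_norm(x, mean, sd):
    if sd <= 0:
        return -np.inf
    z = (np.asarray(x) - mean) / sd
    return float(np.sum(-0.5 * z * z - np.log(sd) - 0.5 * _LOG2PI))


def _lp_halfnorm(x, scale):
    x = np.asarray(x)
    if np.any(x < 0):
        return -np.inf
    z = x / scale
    return float(np.sum(
        0.5 * np.log(2.0 / np.pi) - np.log(scale) - 0.5 * z * z
    ))


def _lp_truncnorm(x, lo, hi, mean, sd):
    from scipy.special import ndtr

    x = np.asarray(x)
    if np.any((x <= lo) | (x >= hi)) or sd <= 0:
        return -np.inf
    zlo, zhi = (lo - mean) / sd, (hi - mean) / sd
    lognorm = np.log(ndtr(zhi) - ndtr(zlo))
    z = (x - mean) / sd
    return float(np.sum(-0.5 * z * z - np.log(sd) - 0.5 * _LOG2PI - lognorm))


def _chol(a):
    return np.linalg.cholesky(a)  # raises np.linalg.LinAlgError if not PD


def _solve_lower(L, b):
    """Solve L x = b for lower-triangular L."""
    return linalg.solve_triangular(L, b, lower=True, check_finite=False)


def _solve_upper(L, b):
    """Solve L' x = b for lower-triangular L."""
    return linalg.solve_triangular(L, b, lower=True, trans=1,
                                   check_finite=False)


def _cho_solve(L, b):
    """Solve (L L') x = b."""
    return linalg.cho_solve((L, True), b, check_finite=False)


# ---------------------------------------------------------------------------
# likelihood derivatives on the transformed scale
# ---------------------------------------------------------------------------

def _mu_dmu(f: np.ndarray, transform: str):
    if transform == "identity":
        return f, np.ones_like(f)
    if transform == "log":
        mu = np.exp(f)
        return mu, mu
    if transform == "log10":
        mu = np.power(10.0, f)
        return mu, mu * _LN10
    if transform == "logit":
        mu = expit(f)
        return mu, mu * (1.0 - mu)
    raise ValueError(transform)


def loglik_terms(y, f, sd, n, family, transform, phi=None, want_derivs=True):
    """Per-record (loglik, d loglik/df, Fisher weight) on the f-scale."""
    f = np.asarray(f, dtype=float)
    mu, dmu = _mu_dmu(f, transform)
    if family == "normal":
        resid = y - mu
        ll = -0.5 * ((resid / sd) ** 2) - np.log(sd) - 0.5 * np.log(2 * np.pi)
        if not want_derivs:
            return ll, None, None
        return ll, resid / sd**2 * dmu, (dmu / sd) ** 2
    if family == "logit_normal":
        z = logit(y)
        if transform == "logit":
            psi, dpsi = f, np.ones_like(f)
        else:
            psi = logit(mu)
            dpsi = dmu / (mu * (1.0 - mu))
        core = -0.5 * ((z - psi) / sd) ** 2 - np.log(sd) - 0.5 * np.log(2 * np.pi)
        ll = core - np.log(y * (1.0 - y))
        if not want_derivs:
            return ll, None, None
        return ll, (z - psi) / sd**2 * dpsi, (dpsi / sd) ** 2
    if family == "binomial":
        if transform == "logit":
            psi, dpsi = f, np.ones_like(f)
        else:
            psi = logit(np.clip(mu, 1e-12, 1 - 1e-12))
            dpsi = dmu / (mu * (1.0 - mu))
        p = expit(psi)
        ll = (
            gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
            + y * psi - n * np.logaddexp(0.0, psi)
        )
        if not want_derivs:
            return ll, None, None
        return ll, (y - n * p) * dpsi, n * p * (1 - p) * dpsi**2
    if family == "negative_binomial":
        m = n * mu
        dm = n * dmu
        ll = (
            gammaln(y + phi) - gammaln(phi) - gammaln(y + 1)
            + phi * np.log(phi / (phi + m)) + y * np.log(m / (phi + m))
        )
        if not want_derivs:
            return ll, None, None
        grad_m = y / m - (y + phi) / (m + phi)
        fisher_m = phi / (m * (m + phi))
        return ll, grad_m * dm, fisher_m * dm**2
    raise ValueError(family)


# ---------------------------------------------------------------------------
# adaptive random walk helper
# ---------------------------------------------------------------------------

class AdaptiveRW:
    """Scalar/vector random-walk Metropolis with Robbins-Monro step tuning."""

    def __init__(self, dim: int = 1, step: float = 0.5, target: float = 0.44):
        self.dim = dim
        self.log_step = np.log(step)
        self.target = target if dim == 1 else 0.25
        self.count = 0

    def propose(self, x, rng):
        return x + np.exp(self.log_step) * rng.standard_normal(np.shape(x))

    def adapt(self, accepted: bool):
        self.count += 1
        rate = 1.0 if accepted else 0.0
        self.log_step += (rate - self.target) / max(10, self.count) ** 0.6
        self.log_step = float(np.clip(self.log_step, -8, 1.5))


def _slice_scalar(x0, logpost, rng, w=1.0, max_steps=30):
    """Univariate slice sampler (stepping out + shrinkage)."""
    lp0 = logpost(x0)
    if not np.isfinite(lp0):
        return x0
    level = lp0 + np.log(rng.uniform())
    u = rng.uniform()
    L, R = x0 - w * u, x0 + w * (1.0 - u)
    for _ in range(max_steps):
        if logpost(L) <= level:
            break
        L -= w
    for _ in range(max_steps):
        if logpost(R) <= level:
            break
        R += w
    for _ in range(max_steps + 20):
        x1 = rng.uniform(L, R)
        if logpost(x1) > level:
            return x1
        if x1 < x0:
            L = x1
        else:
            R = x1
    return x0


class AdaptiveCovRW:
    """Random-walk proposal with covariance learned from the warmup
    trajectory (Haario-style) and frozen afterwards, plus scalar step
    tuning toward a multivariate acceptance target."""

    def __init__(self, dim: int, step: float = 0.6):
        self.dim = dim
        self.log_step = np.log(step)
        self.count = 0
        self.mean = np.zeros(dim)
        self.M2 = np.eye(dim) * 1e-12
        self.n_obs = 0
        self.frozen = None

    def observe(self, x):
        x = np.asarray(x, dtype=float)
        self.n_obs += 1
        d = x - self.mean
        self.mean += d / self.n_obs
        self.M2 += np.outer(d, x - self.mean)

    def _chol(self):
        if self.frozen is not None:
            return self.frozen
        if self.n_obs < max(20, 2 * self.dim):
            return None
        cov = self.M2 / max(self.n_obs - 1, 1)
        cov = cov + 1e-10 * np.eye(self.dim) * max(np.trace(cov), 1e-6)
        try:
            return np.linalg.cholesky(cov * (2.38**2 / self.dim))
        except np.linalg.LinAlgError:
            return None

    def freeze(self):
        if self.frozen is None:
            L = self._chol()
            self.frozen = L if L is not None else np.eye(self.dim) * 0.1

    def propose(self, x, rng):
        L = self._chol()
        z = rng.standard_normal(self.dim) * np.exp(self.log_step)
        if L is None:
            return x + 0.1 * z
        return x + L @ z

    def adapt(self, accepted: bool):
        self.count += 1
        rate = 1.0 if accepted else 0.0
        self.log_step += (rate - 0.25) / max(10, self.count) ** 0.6
        self.log_step = float(np.clip(self.log_step, -6, 3))


def _mh_scalar(key, state, logpost, rng, rws, adapting, vector=False):
    """Generic MH step on state[key] with the given conditional logpost."""
    x = state[key]
    rw = rws.setdefault(key, AdaptiveRW(dim=np.size(x)))
    lp0 = logpost(x)
    x1 = rw.propose(x, rng)
    lp1 = logpost(x1)
    accept = bool(np.isfinite(lp1) and np.log(rng.uniform()) < lp1 - lp0)
    if accept:
        state[key] = x1
    if adapting:
        rw.adapt(accept)
    return accept


# ---------------------------------------------------------------------------
# hierarchical normal manager
# ---------------------------------------------------------------------------

class HierNormal:
    """Nested normal hierarchy over population-level values.

    x_c ~ N(mu^{(1)}_{g1[c]}, s_1^2), mu^{(1)}_g ~ N(mu^{(2)}_{g2[g]}, s_2^2),
    ... with a N(0, 10^2) prior on the top-level means and Half-Normal(5)
    priors on the level sds.  Group means are updated by conjugate Gibbs
    draws; sds by adaptive random-walk Metropolis.
    """

    def __init__(self, name: str, populations: list[str], level_maps: list[dict]):
        self.name = name
        if not level_maps:
            level_maps = [{p: "world" for p in populations}]
        # make sure the hierarchy terminates in a single world unit
        top_units = sorted(set(level_maps[-1].values()))
        if len(top_units) > 1:
            level_maps = level_maps + [{u: "world" for u in top_units}]
        self.level_maps = level_maps
        self.units = [list(populations)]
        for m in level_maps:
            self.units.append(sorted(set(m[u] for u in self.units[-1])))
        self.L = len(level_maps)
        # child indices: for level l (1..L), for each unit, indices into level l-1
        self.children = []
        for l in range(1, self.L + 1):
            mapping = level_maps[l - 1]
            idx = {u: i for i, u in enumerate(self.units[l])}
            ch = [[] for _ in self.units[l]]
            for i, u in enumerate(self.units[l - 1]):
                ch[idx[mapping[u]]].append(i)
            self.children.append(ch)

    def key_mu(self, l):
        return f"{self.name}::mu{l}"

    def key_s(self, l):
        return f"{self.name}::s{l}"

    def init_state(self, state, x0):
        x = np.asarray(x0, dtype=float)
        for l in range(1, self.L + 1):
            vals = np.array([np.mean(x[self.children[l - 1][i]]) if l == 1 else 0.0
                             for i in range(len(self.units[l]))])
            if l > 1:
                prev = state[self.key_mu(l - 1)]
                vals = np.array(
                    [np.mean(prev[self.children[l - 1][i]])
                     for i in range(len(self.units[l]))]
                )
            state[self.key_mu(l)] = vals
            state[self.key_s(l)] = 0.5

    def mean_sd_for_pops(self, state):
        mu1 = state[self.key_mu(1)]
        mapping = self.level_maps[0]
        idx = {u: i for i, u in enumerate(self.units[1])}
        means = np.array([mu1[idx[mapping[p]]] for p in self.units[0]])
        return means, float(state[self.key_s(1)])

    def logpdf_children(self, state, x) -> float:
        means, s1 = self.mean_sd_for_pops(state)
        if s1 <= 0:
            return -np.inf
        return _lp_norm(np.asarray(x), means, s1)

    def _level_values(self, state, l, x):
        return np.asarray(x) if l == 0 else state[self.key_mu(l)]

    def update(self, state, x, rng, rws, adapting):
        # conjugate means, bottom level up
        for l in range(1, self.L + 1):
            child_vals = self._level_values(state, l - 1, x)
            s_l = float(state[self.key_s(l)])
            if l < self.L:
                parent_vals = state[self.key_mu(l + 1)]
                mapping = self.level_maps[l]
                pidx = {u: i for i, u in enumerate(self.units[l + 1])}
                prior_means = np.array(
                    [parent_vals[pidx[mapping[u]]] for u in self.units[l]]
                )
                prior_sd = float(state[self.key_s(l + 1)])
            else:
                prior_means = np.zeros(len(self.units[l]))
                prior_sd = 10.0
            new_mu = np.empty(len(self.units[l]))
            for i, ch in enumerate(self.children[l - 1]):
                n = len(ch)
                prec = n / s_l**2 + 1.0 / prior_sd**2
                mean = (np.sum(child_vals[ch]) / s_l**2
                        + prior_means[i] / prior_sd**2) / prec
                new_mu[i] = mean + rng.standard_normal() / np.sqrt(prec)
            state[self.key_mu(l)] = new_mu
        # scales by slice sampling on log s (tuning-free; the conditional
        # can be wide when the children are weakly informed)
        for l in range(1, self.L + 1):
            child_vals = self._level_values(state, l - 1, x)
            mu_l = state[self.key_mu(l)]
            mapping = self.level_maps[l - 1]
            idx = {u: i for i, u in enumerate(self.units[l])}
            means = np.array(
                [mu_l[idx[mapping[u]]] for u in self.units[l - 1]]
            )

            def lp(logs):
                s = np.exp(logs)
                return (
                    _lp_norm(child_vals, means, s)
                    + _lp_halfnorm(s, 5.0)
                    + logs  # Jacobian of the log parametrization
                )

            logs_new = _slice_scalar(
                float(np.log(state[self.key_s(l)])), lp, rng
            )
            state[self.key_s(l)] = float(np.exp(logs_new))


# ---------------------------------------------------------------------------
# problem construction
# ---------------------------------------------------------------------------

@dataclass
class PopObs:
    t_idx: np.ndarray
    y: np.ndarray
    sd_fixed: np.ndarray
    src_idx: np.ndarray
    n: np.ndarray


@dataclass
class LinearBlockSpec:
    """A Gaussian-prior coefficient block entering f linearly."""

    name: str
    members: list[int]
    designs: dict  # pop index -> (T, p)
    size: int
    slices: dict = field(default_factory=dict)  # component name -> slice


class FitProblem:
    """Internal fitting representation of a TMMPModel plus data."""

    def __init__(self, model: TMMPModel, data, covariates=None):
        self.model = model
        grid = model.grid
        self.T = grid.T
        self.times = grid.times
        self.C = len(model.populations)
        self.transform = model.config["transform"]
        dm = model.config["data_model"]
        self.family = dm["family"]
        self.variance_mode = dm["variance"]
        self.phi = dm.get("phi")
        self.covariates = covariates

        # ---- observations per population, mapped to estimation grid
        self.sources: list[str] = []
        src_map: dict[str, int] = {}
        self.pops: list[PopObs] = []
        frame = data.frame
        for p in model.populations:
            sub = frame[frame["population"] == p]
            sub = sub[sub["time"] <= self.T]
            t_idx = sub["time"].to_numpy(int) - 1
            y = sub["value"].to_numpy(float)
            sd = sub["sampling_sd"].to_numpy(float) if len(sub) else np.empty(0)
            srcs = sub["source"].astype(str).tolist() if len(sub) else []
            for s in srcs:
                if s not in src_map:
                    src_map[s] = len(self.sources)
                    self.sources.append(s)
            src_idx = np.array([src_map[s] for s in srcs], dtype=int)
            n = sub["denominator"].to_numpy(float) if len(sub) else np.empty(0)
            self.pops.append(PopObs(t_idx, y, sd, src_idx, n))
        self.estimate_sigma = self.variance_mode != "fixed"

        # ---- smoothing structure
        spec = model.smoothing_spec()
        self.smooth_spec = spec
        B = sm.build_basis(spec.basis, self.times.astype(float))
        K = B.shape[1]
        self.m_gamma = K - spec.r
        if spec.r > 0:
            R = sm.recovery_matrix(K, spec.r, spec.constraint_mode, spec.anchors)
        else:
            R = np.eye(K)
        self.B, self.R = B, R
        self.A_smooth = B @ R  # (T, m_gamma)

        # kernel: which hyperparameters are free
        hier = model.config["hierarchy"]
        ks = dict(hier.get("kernel_scale", {"strategy": "prior"}))
        if ks.get("strategy") == "global":
            # one scale shared by every population: a single-group version
            # of the grouped strategy
            ks = {"strategy": "grouped", "group_by": "_all"}
            model.groupings = dict(model.groupings)
            model.groupings["_all"] = {p: "all" for p in model.populations}
        self.kscale_strategy = ks.get("strategy", "prior")
        self.kscale_cfg = ks
        self.scale_param = (
            "sigma" if spec.kernel.family in ("arma11", "iid") else "kappa"
        )
        shape_cfg = hier.get("kernel_shape", {})
        self.free_shapes = [
            p for p, v in shape_cfg.items()
            if v.get("strategy", "fixed") != "fixed"
        ]
        self.hier_kscale = None
        if self.kscale_strategy == "hierarchical":
            self.hier_kscale = HierNormal(
                "kernel_scale", model.populations,
                self._level_maps(ks.get("levels", ["world"])),
            )
        self.kscale_groups = None
        if self.kscale_strategy == "grouped":
            gkey = ks["group_by"]
            gmap = model.groupings[gkey]
            self.kscale_group_labels = sorted(set(gmap.values()))
            self.kscale_groups = np.array(
                [self.kscale_group_labels.index(gmap[p]) for p in model.populations]
            )

        # ---- per-population linear block layout
        self.comp_layout: list[tuple[str, int]] = []
        sysc = model.config["systematic_component"]
        cov = model.config["covariate_component"]
        self.fpem = sysc["kind"] == "logistic_transition"
        self.pca = cov["kind"] == "pca_linear"
        if sysc["kind"] == "linear_trend":
            self.t_star = float(sysc.get("t_star", (1 + self.T) // 2))
            self.comp_layout += [("alpha0", 1), ("alpha1", 1)]
        hier_beta0 = None
        self.shared_cols: list[str] = []
        if cov["kind"] in ("linear", "piecewise_nmr"):
            self.comp_layout.append(("beta0", 1))
            b0 = hier.get("beta0", {"strategy": "prior"})
            if b0.get("strategy") == "hierarchical":
                hier_beta0 = HierNormal(
                    "beta0", model.populations,
                    self._level_maps(b0.get("levels", ["world"])),
                )
            if cov["kind"] == "linear":
                self.shared_cols = list(cov.get("covariates", []))
            else:
                self.shared_cols = ["_piecewise"]
        self.hier_beta0 = hier_beta0
        self.comp_layout.append(("gamma", self.m_gamma))
        self.p_u = sum(s for _, s in self.comp_layout)
        self.slices = {}
        off = 0
        for nm, sz in self.comp_layout:
            self.slices[nm] = slice(off, off + sz)
            off += sz

        # fast path: identity basis, iid kernel, no regression columns --
        # the conditional precision of u_c is diagonal
        self.diag_u = (
            self.comp_layout == [("gamma", self.m_gamma)]
            and spec.basis.kind == "identity"
            and spec.kernel.family == "iid"
            and spec.r == 0
        )

        # number of sweeps of the scalar hyperparameter moves per
        # iteration (weakly identified scales mix faster with several
        # cheap marginal moves per sweep of the coefficient blocks)
        self.sweeps = 2

        # per-pop design matrices (T, p_u)
        self.A_u: list[np.ndarray] = []
        self.X_shared: list[np.ndarray] = []  # (T, q) per pop
        self.M_base = np.zeros((self.C, self.T))
        fixed = model.config["priors"].get("fixed", {})
        for ci, p in enumerate(model.populations):
            A = np.zeros((self.T, self.p_u))
            if "alpha0" in self.slices:
                A[:, self.slices["alpha0"]] = 1.0
                A[:, self.slices["alpha1"]] = (
                    self.times.astype(float) - self.t_star
                )[:, None]
            if "beta0" in self.slices:
                A[:, self.slices["beta0"]] = 1.0
            A[:, self.slices["gamma"]] = self.A_smooth
            self.A_u.append(A)
            # shared covariate columns
            if self.shared_cols:
                cols = cov.get("covariates", [])
                X = covariates.matrix(p, cols)[: self.T]
                if cov["kind"] == "piecewise_nmr":
                    b2 = float(fixed.get("beta2", cov.get("beta2", 1.0)))
                    x = X[:, 0]
                    z = (np.log(x) - np.log(b2)) * (x > b2)
                    X = z[:, None]
                self.X_shared.append(X)
            # fixed covariate contributions -> base mean
            if cov["kind"] == "gbd_nonlinear":
                beta = np.asarray(fixed["beta_gbd"], dtype=float)
                self.M_base[ci] += model.covariate_term(
                    p, covariates, {"beta_gbd": beta}, times=self.times
                )
            self.M_base[ci] += model.offsets[ci, : self.T]
        self.q_shared = (
            self.X_shared[0].shape[1] if self.shared_cols else 0
        )
        # centre shared covariate columns by their global mean: shared
        # slopes and intercepts are otherwise nearly collinear and the
        # blocked sampler would mix poorly.  A single shift for all
        # populations is an exact reparametrization (it is absorbed by the
        # estimated intercept level); the intercepts reported in the draws
        # are transformed back to the uncentred parametrization.
        self.X_shared_mean = None
        if self.q_shared and "beta0" in self.slices:
            self.X_shared_mean = np.mean(
                [X.mean(axis=0) for X in self.X_shared], axis=0
            )  # (q,)
            self.X_shared = [X - self.X_shared_mean for X in self.X_shared]

        # ---- FPEM structures
        if self.fpem:
            self.fpem_t_star = int(sysc.get("t_star", (1 + self.T) // 2))
            self.fpem_bounds = {
                "P_tilde": tuple(hier.get("P_tilde", {}).get("bounds", (0.5, 1.0))),
                "omega": tuple(hier.get("omega", {}).get("bounds", (0.01, 0.5))),
            }
            self.hier_fpem = {}
            for comp in ("P_tilde", "omega", "Omega"):
                cfgc = hier.get(comp, {"strategy": "prior"})
                if cfgc.get("strategy") == "hierarchical":
                    self.hier_fpem[comp] = HierNormal(
                        comp, model.populations,
                        self._level_maps(cfgc.get("levels", ["world"])),
                    )

        # ---- PCA (subnational) structures
        if self.pca:
            gmap = model.groupings["county"]
            self.counties = sorted(set(gmap.values()))
            self.county_of = np.array(
                [self.counties.index(gmap[p]) for p in model.populations]
            )
            cols = cov.get("covariates", [])
            self.P_pca = len(cols)
            self.X_pca = np.stack(
                [covariates.matrix(p, cols)[: self.T] for p in model.populations]
            )  # (C, T, P)
            D2 = sm.difference_matrix(self.T, 2)
            self.Q_rw2_base = D2.T @ D2

    def _level_maps(self, level_names):
        maps = []
        units = list(self.model.populations)
        for name in level_names:
            if name == "world":
                maps.append({u: "world" for u in units})
            else:
                gmap = self.model.groupings[name]
                maps.append({u: gmap[u] for u in units})
            units = sorted(set(maps[-1].values()))
        return maps

    # ------------------------------------------------------------------
    # state
    # ------------------------------------------------------------------
    def init_state(self, rng) -> dict:
        state = {}
        state["u"] = [np.zeros(self.p_u) for _ in range(self.C)]
        if self.q_shared:
            state["shared"] = np.zeros(self.q_shared)
        spec = self.smooth_spec
        scale0 = float(getattr(spec.kernel, self.scale_param))
        if self.kscale_strategy == "grouped":
            state["log_kscale_groups"] = np.full(
                len(self.kscale_group_labels), np.log(scale0)
            )
        else:
            state["log_kscale"] = np.full(self.C, np.log(scale0))
        for p in self.free_shapes:
            state[f"kshape_{p}"] = float(getattr(spec.kernel, p))
        if self.estimate_sigma:
            state["log_data_sigma"] = np.full(
                max(len(self.sources), 1), np.log(0.1)
            )
        if self.hier_kscale:
            self.hier_kscale.init_state(state, state["log_kscale"])
        if self.hier_beta0:
            self.hier_beta0.init_state(state, np.zeros(self.C))
        if self.kscale_strategy == "bmat":
            state["bmat_lambda"] = np.zeros(self.C)
            state["log_sigma_w"] = np.log(scale0)
            state["log_sigma_lambda"] = np.log(0.25)
        if self.fpem:
            th = np.zeros((self.C, 3))
            for ci, pop in enumerate(self.pops):
                if len(pop.y):
                    ybar = float(np.clip(np.mean(pop.y), 1e-3, 1 - 1e-3))
                    th[ci, 2] = logit(ybar)
            state["fpem_theta"] = th  # columns: P_tilde*, omega*, Omega
            for comp, mgr in self.hier_fpem.items():
                j = ("P_tilde", "omega", "Omega").index(comp)
                mgr.init_state(state, th[:, j])
        if self.pca:
            state["pca_beta"] = [
                np.zeros((self.T, self.P_pca)) for _ in self.counties
            ]
            state["pca_mu"] = np.zeros((self.P_pca, self.T))
            state["log_pca_sigma_p"] = np.full(self.P_pca, np.log(0.5))
            state["log_pca_sigma_mu"] = np.log(0.1)
        # small chain-specific jitter for overdispersed starts
        for key in list(state):
            v = state[key]
            if isinstance(v, np.ndarray) and v.dtype.kind == "f":
                state[key] = v + 0.05 * rng.standard_normal(v.shape)
        return state

    # ------------------------------------------------------------------
    # kernels, priors
    # ------------------------------------------------------------------
    def kernel_for(self, state, c) -> sm.KernelSpec:
        spec = self.smooth_spec.kernel
        overrides = {}
        if self.kscale_strategy == "fixed":
            for p in self.free_shapes:
                overrides[p] = float(state[f"kshape_{p}"])
            return spec.replace(**overrides) if overrides else spec
        if self.kscale_strategy == "grouped":
            overrides[self.scale_param] = float(
                np.exp(state["log_kscale_groups"][self.kscale_groups[c]])
            )
        elif self.kscale_strategy == "bmat":
            sw = np.exp(state["log_sigma_w"])
            overrides[self.scale_param] = float(
                sw * (1.0 + state["bmat_lambda"][c])
            )
        else:
            overrides[self.scale_param] = float(np.exp(state["log_kscale"][c]))
        for p in self.free_shapes:
            overrides[p] = float(state[f"kshape_{p}"])
        return spec.replace(**overrides)

    def _gamma_block(self, state, c):
        """(chol Sigma, precision Q_gamma, logdet Q_gamma), cached on the
        kernel hyperparameter values."""
        kernel = self.kernel_for(state, c)
        key = (kernel.kappa, kernel.sigma, kernel.rho, kernel.ell,
               kernel.theta, kernel.nu)
        cache = getattr(self, "_gb_cache", None)
        if cache is None:
            cache = self._gb_cache = {}
        hit = cache.get(key)
        if hit is not None:
            return hit
        sigma = sm.build_covariance(kernel, self.m_gamma)
        L = _chol(sigma)
        Qg = _cho_solve(L, np.eye(self.m_gamma))
        logdet_Q = -2.0 * float(np.sum(np.log(np.diag(L))))
        if len(cache) > 4096:
            cache.clear()
        cache[key] = (L, Qg, logdet_Q)
        return cache[key]

    def gamma_prior_chol(self, state, c):
        return self._gamma_block(state, c)[0]

    def gamma_logprior(self, state, c, gamma) -> float:
        try:
            L = self.gamma_prior_chol(state, c)
        except (linalg.LinAlgError, np.linalg.LinAlgError):
            return -np.inf
        z = _solve_lower(L, gamma)
        return float(
            -0.5 * z @ z - np.sum(np.log(np.diag(L)))
            - 0.5 * self.m_gamma * np.log(2 * np.pi)
        )

    def u_prior(self, state, c):
        """(mean, precision, logdet precision) of the prior on u_c."""
        m0 = np.zeros(self.p_u)
        Q = np.zeros((self.p_u, self.p_u))
        logdet = 0.0
        pri = self.model.config["priors"]
        for nm in ("alpha0", "alpha1"):
            if nm in self.slices:
                sd = float(pri.get(nm, {}).get("sd", 10.0))
                mean = float(pri.get(nm, {}).get("mean", 0.0))
                i = self.slices[nm].start
                m0[i] = mean
                Q[i, i] = 1.0 / sd**2
                logdet += np.log(Q[i, i])
        if "beta0" in self.slices:
            i = self.slices["beta0"].start
            if self.hier_beta0:
                means, s1 = self.hier_beta0.mean_sd_for_pops(state)
                m0[i] = means[c]
                Q[i, i] = 1.0 / max(s1, 1e-8) ** 2
            else:
                sd = float(pri.get("beta0", {}).get("sd", 10.0))
                Q[i, i] = 1.0 / sd**2
            logdet += np.log(Q[i, i])
        sl = self.slices["gamma"]
        _, Qg, logdet_Qg = self._gamma_block(state, c)
        Q[sl, sl] = Qg
        logdet += logdet_Qg
        return m0, Q, logdet

    # ------------------------------------------------------------------
    # means and likelihood
    # ------------------------------------------------------------------
    def base_mean(self, state, c) -> np.ndarray:
        """Transformed-scale mean contribution outside the linear blocks."""
        M = self.M_base[c].copy()
        if self.fpem:
            from .process import logistic_path

            th = state["fpem_theta"][c]
            P = bounded_transform(th[0], *self.fpem_bounds["P_tilde"])
            w = bounded_transform(th[1], *self.fpem_bounds["omega"])
            M += logistic_path(
                self.T, self.fpem_t_star, th[2], P, w,
                include_eps_in_recursion=False,
            )
        if self.pca:
            beta = state["pca_beta"][self.county_of[c]]  # (T, P)
            M += np.einsum("tp,tp->t", self.X_pca[c], beta)
        return M

    def full_f(self, state, c) -> np.ndarray:
        f = self.base_mean(state, c) + self.A_u[c] @ state["u"][c]
        if self.q_shared:
            f += self.X_shared[c] @ state["shared"]
        return f

    def _sd_for(self, state, pop: PopObs) -> np.ndarray:
        if self.family in ("binomial", "negative_binomial"):
            return np.ones(len(pop.y))
        sd = pop.sd_fixed.copy()
        if self.estimate_sigma:
            sig = np.exp(state["log_data_sigma"])
            missing = ~np.isfinite(sd)
            if self.variance_mode == "global":
                sd[missing] = sig[0]
            else:
                sd[missing] = sig[pop.src_idx[missing]]
        if np.any(~np.isfinite(sd)):
            raise ValueError(
                "variance='fixed' requires sampling_sd on every record"
            )
        return sd

    def pop_loglik(self, state, c, f_obs=None) -> float:
        pop = self.pops[c]
        if len(pop.y) == 0:
            return 0.0
        if f_obs is None:
            f_obs = self.full_f(state, c)[pop.t_idx]
        sd = self._sd_for(state, pop)
        ll, _, _ = loglik_terms(
            pop.y, f_obs, sd, pop.n, self.family, self.transform,
            self.phi, want_derivs=False,
        )
        return float(np.sum(ll))

    def total_loglik(self, state) -> float:
        return sum(self.pop_loglik(state, c) for c in range(self.C))

    def log_density(self, state) -> float:
        """Joint log density: likelihood plus all priors (cross-check hook)."""
        total = self.total_loglik(state)
        for c in range(self.C):
            m0, Q, logdetQ = self.u_prior(state, c)
            d = state["u"][c] - m0
            total += float(
                -0.5 * d @ Q @ d + 0.5 * logdetQ
                - 0.5 * self.p_u * np.log(2 * np.pi)
            )
        total += self._hyper_logprior(state)
        return total

    def _hyper_logprior(self, state) -> float:
        total = 0.0
        if self.kscale_strategy == "prior":
            sigma = np.exp(state["log_kscale"])
            total += float(
                _lp_halfnorm(sigma, 5.0)
                + np.sum(state["log_kscale"])
            )
        elif self.kscale_strategy == "hierarchical":
            total += self.hier_kscale.logpdf_children(state, state["log_kscale"])
        if self.q_shared:
            total += _lp_norm(state["shared"], 0.0, 10.0)
        return total


# ---------------------------------------------------------------------------
# block updates
# ---------------------------------------------------------------------------

def _laplace_for(prob, state, c):
    if prob.diag_u:
        return _LaplaceUDiag(prob, state, c)
    return _LaplaceU(prob, state, c)


class _LaplaceUDiag:
    """Diagonal-precision Laplace machinery for identity-basis iid
    smoothers (the conditional factorizes over time points)."""

    def __init__(self, prob, state, c, n_newton=6):
        self.prob, self.c = prob, c
        kernel = prob.kernel_for(state, c)
        sig = float(kernel.sigma)
        if not (np.isfinite(sig) and sig > 0):
            raise np.linalg.LinAlgError("degenerate kernel scale")
        self.p = prob.p_u
        self.qdiag = np.full(self.p, 1.0 / sig**2)
        self.logdetQ = float(np.sum(np.log(self.qdiag)))
        pop = prob.pops[c]
        self.has_data = len(pop.y) > 0
        base = prob.base_mean(state, c)
        if prob.q_shared:
            base = base + prob.X_shared[c] @ state["shared"]
        self.t = pop.t_idx
        self.f0 = base[pop.t_idx]
        self.y, self.n = pop.y, pop.n
        self.sd = prob._sd_for(state, pop) if self.has_data else None
        self._newton(n_newton)

    def loglik(self, v) -> float:
        if not self.has_data:
            return 0.0
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            ll, _, _ = loglik_terms(
                self.y, self.f0 + v[self.t], self.sd, self.n,
                self.prob.family, self.prob.transform, self.prob.phi,
                want_derivs=False,
            )
        t = np.sum(ll)
        return float(t) if np.isfinite(t) else -np.inf

    def logprior(self, v) -> float:
        return float(
            -0.5 * np.sum(self.qdiag * v * v) + 0.5 * self.logdetQ
            - 0.5 * self.p * _LOG2PI
        )

    def logpost(self, v) -> float:
        return self.loglik(v) + self.logprior(v)

    def _start(self):
        tf, fam = self.prob.transform, self.prob.family
        if fam == "normal" and tf in ("log", "log10") and np.all(self.y > 0):
            b = np.e if tf == "log" else 10.0
            z = np.log(self.y) / np.log(b)
            w = (self.y * np.log(b) / self.sd) ** 2
        elif fam == "logit_normal" and tf == "logit":
            z = logit(self.y)
            w = 1.0 / self.sd**2
        elif fam == "normal" and tf == "identity":
            z = self.y
            w = 1.0 / self.sd**2
        else:
            return np.zeros(self.p)
        num = np.zeros(self.p)
        den = self.qdiag.copy()
        np.add.at(num, self.t, w * (z - self.f0))
        np.add.at(den, self.t, w)
        return num / den

    def _newton(self, n_newton):
        v = np.zeros(self.p)
        hdiag = self.qdiag.copy()
        if self.has_data:
            v = self._start()
            obj = self.logpost(v)
            if not np.isfinite(obj):
                v = np.zeros(self.p)
                obj = self.logpost(v)
            for _ in range(n_newton):
                with np.errstate(over="ignore", invalid="ignore",
                                 divide="ignore"):
                    _, grad, w = loglik_terms(
                        self.y, self.f0 + v[self.t], self.sd, self.n,
                        self.prob.family, self.prob.transform, self.prob.phi,
                    )
                if not (np.all(np.isfinite(grad)) and np.all(np.isfinite(w))):
                    break
                g = np.zeros(self.p)
                np.add.at(g, self.t, grad)
                g -= self.qdiag * v
                hdiag = self.qdiag.copy()
                np.add.at(hdiag, self.t, np.maximum(w, 0.0))
                step = g / hdiag
                lam, obj_new, v_new = 1.0, -np.inf, v
                for _ in range(8):
                    v_try = v + lam * step
                    obj_try = self.logpost(v_try)
                    if np.isfinite(obj_try) and obj_try >= obj - 1e-12:
                        v_new, obj_new = v_try, obj_try
                        break
                    lam *= 0.5
                if not np.isfinite(obj_new):
                    break
                moved = float(np.max(np.abs(v_new - v)))
                v, obj = v_new, obj_new
                if moved < 1e-6:
                    break
        self.vhat = v
        self.hdiag = hdiag
        self.logdet_half = float(0.5 * np.sum(np.log(hdiag)))

    def sample(self, rng):
        return self.vhat + rng.standard_normal(self.p) / np.sqrt(self.hdiag)

    def logq(self, v) -> float:
        d = v - self.vhat
        return float(
            -0.5 * np.sum(self.hdiag * d * d) + self.logdet_half
            - 0.5 * self.p * _LOG2PI
        )


class _LaplaceU:
    """Gauss-Newton Laplace approximation of the full conditional of u_c.

    The Newton iteration starts from a deterministic point (a Gaussianized
    pseudo-data solve where available, else the prior mean), so the
    resulting Gaussian depends only on the data and the current
    hyperparameters -- making it usable both as an independence proposal
    for u_c and as the refresh distribution inside joint hyperparameter
    moves.  ``logpost`` includes the full prior normalization, which is
    required when comparing states with different hyperparameters.
    """

    def __init__(self, prob: FitProblem, state, c, n_newton=6):
        self.prob, self.c = prob, c
        self.m0, self.Q0, self.logdetQ = prob.u_prior(state, c)
        if not np.isfinite(self.logdetQ):
            raise linalg.LinAlgError("prior precision not positive definite")
        pop = prob.pops[c]
        self.has_data = len(pop.y) > 0
        A = prob.A_u[c]
        base = prob.base_mean(state, c)
        if prob.q_shared:
            base = base + prob.X_shared[c] @ state["shared"]
        self.Aobs = A[pop.t_idx]
        self.f0 = base[pop.t_idx]
        self.y, self.n = pop.y, pop.n
        self.sd = prob._sd_for(state, pop) if self.has_data else None
        self.p = prob.p_u
        self._newton(n_newton)

    # -- likelihood pieces -------------------------------------------------
    def _derivs(self, v):
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            return loglik_terms(
                self.y, self.f0 + self.Aobs @ v, self.sd, self.n,
                self.prob.family, self.prob.transform, self.prob.phi,
            )

    def loglik(self, v) -> float:
        if not self.has_data:
            return 0.0
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            ll, _, _ = loglik_terms(
                self.y, self.f0 + self.Aobs @ v, self.sd, self.n,
                self.prob.family, self.prob.transform, self.prob.phi,
                want_derivs=False,
            )
        s = np.sum(ll)
        return float(s) if np.isfinite(s) else -np.inf

    def logprior(self, v) -> float:
        d = v - self.m0
        return float(
            -0.5 * d @ self.Q0 @ d + 0.5 * self.logdetQ
            - 0.5 * self.p * np.log(2 * np.pi)
        )

    def logpost(self, v) -> float:
        return self.loglik(v) + self.logprior(v)

    # -- Newton ------------------------------------------------------------
    def _start(self):
        """Deterministic warm start: Gaussianized pseudo-data solve."""
        if not self.has_data:
            return self.m0.copy()
        tf, fam = self.prob.transform, self.prob.family
        if fam == "normal" and tf in ("log", "log10") and np.all(self.y > 0):
            b = np.e if tf == "log" else 10.0
            z = np.log(self.y) / np.log(b)
            sd_z = self.sd / (self.y * np.log(b))
            w = 1.0 / sd_z**2
        elif fam == "logit_normal" and tf == "logit":
            z = logit(self.y)
            w = 1.0 / self.sd**2
        elif fam == "normal" and tf == "identity":
            z = self.y
            w = 1.0 / self.sd**2
        else:
            return self.m0.copy()
        H = self.Aobs.T @ (w[:, None] * self.Aobs) + self.Q0
        g = self.Aobs.T @ (w * (z - self.f0)) + self.Q0 @ self.m0
        try:
            return _cho_solve(_chol(H), g)
        except linalg.LinAlgError:
            return self.m0.copy()

    def _newton(self, n_newton):
        v = self._start()
        obj = self.logpost(v)
        if not np.isfinite(obj):
            v = self.m0.copy()
            obj = self.logpost(v)
        H = self.Q0
        if self.has_data:
            for _ in range(n_newton):
                _, grad, w = self._derivs(v)
                if not (np.all(np.isfinite(grad)) and np.all(np.isfinite(w))):
                    break
                w = np.maximum(w, 0.0)
                g = self.Aobs.T @ grad - self.Q0 @ (v - self.m0)
                H = self.Aobs.T @ (w[:, None] * self.Aobs) + self.Q0
                try:
                    step = _cho_solve(_chol(H), g)
                except linalg.LinAlgError:
                    step = linalg.solve(H + 1e-8 * np.eye(self.p), g)
                lam, obj_new, v_new = 1.0, -np.inf, v
                for _ in range(8):
                    v_try = v + lam * step
                    obj_try = self.logpost(v_try)
                    if np.isfinite(obj_try) and obj_try >= obj - 1e-12:
                        v_new, obj_new = v_try, obj_try
                        break
                    lam *= 0.5
                if not np.isfinite(obj_new):
                    break
                moved = float(np.max(np.abs(v_new - v)))
                v, obj = v_new, obj_new
                if moved < 1e-6:
                    break
            _, _, w = self._derivs(v)
            if np.all(np.isfinite(w)):
                H = self.Aobs.T @ (
                    np.maximum(w, 0.0)[:, None] * self.Aobs) + self.Q0
        self.vhat = v
        try:
            self.Lh = _chol(H)
        except np.linalg.LinAlgError:
            self.Lh = _chol(H + 1e-8 * np.eye(self.p))
        self.logdet_half = float(np.sum(np.log(np.diag(self.Lh))))

    # -- proposal ----------------------------------------------------------
    def sample(self, rng) -> np.ndarray:
        z = rng.standard_normal(self.p)
        return self.vhat + _solve_upper(self.Lh, z)

    def logq(self, v) -> float:
        z = self.Lh.T @ (v - self.vhat)
        return float(
            -0.5 * z @ z + self.logdet_half - 0.5 * self.p * np.log(2 * np.pi)
        )


def _get_mac(cache, prob, state, c):
    """Laplace machinery for u_c, cached until a dependency changes."""
    if cache is None:
        return _laplace_for(prob, state, c)
    mac = cache.get(c)
    if mac is None:
        mac = cache[c] = _laplace_for(prob, state, c)
    return mac


def _update_u(prob: FitProblem, state, c, rng, force=False, cache=None):
    """Independence-MH update of u_c from its Laplace conditional.

    Exact Gibbs (acceptance one) when the data model is Gaussian on the
    transformed scale.  ``force`` accepts unconditionally (used once at
    initialization to start the chain inside the posterior bulk).
    """
    mac = _get_mac(cache, prob, state, c)
    prop = mac.sample(rng)
    if force:
        state["u"][c] = prop
        return True
    cur = state["u"][c]
    log_alpha = mac.logpost(prop) - mac.logpost(cur) \
        + mac.logq(cur) - mac.logq(prop)
    if np.log(rng.uniform()) < log_alpha:
        state["u"][c] = prop
        return True
    return False


def _joint_hyper_mh(
    prob, state, rng, rws, adapting, key, x0, members, make_trial, prior_fn,
    dim=1, step=0.4, cache=None,
):
    """MH on a hyperparameter with a Laplace refresh of the member u-blocks.

    The proposal draws x' from a random walk and u'_c from the Laplace
    conditional under x'; the acceptance ratio
    sum_c [logpost(u'_c | x') - logq(u'_c | x')] + logprior(x') minus the
    same at the current state targets (approximately exactly, with MH
    correction) the *marginal* posterior of x -- removing the funnel
    coupling between scales and their coefficients.
    """
    rw = rws.setdefault(key, AdaptiveRW(dim=dim, step=step))
    x1 = rw.propose(x0, rng)
    lp_prior0 = prior_fn(state, x0)
    lp_prior1 = prior_fn(state, x1)
    accept = False
    if np.isfinite(lp_prior1):
        trial = make_trial(x1)
        try:
            score0, score1 = lp_prior0, lp_prior1
            new_us = {}
            new_macs = {}
            for c in members:
                mac0 = _get_mac(cache, prob, state, c)
                u_c = state["u"][c]
                score0 += mac0.logpost(u_c) - mac0.logq(u_c)
                mac1 = _laplace_for(prob, trial, c)
                new_macs[c] = mac1
                u_new = mac1.sample(rng)
                new_us[c] = u_new
                score1 += mac1.logpost(u_new) - mac1.logq(u_new)
            if np.isfinite(score1) and np.log(rng.uniform()) < score1 - score0:
                accept = True
                for c, u_new in new_us.items():
                    state["u"][c] = u_new
                    if cache is not None:
                        cache[c] = new_macs[c]
        except (linalg.LinAlgError, np.linalg.LinAlgError,
                sm.NumericalError, OverflowError):
            accept = False
    if adapting:
        rw.adapt(accept)
    return accept, (x1 if accept else x0)


def _laplace_update_shared(prob: FitProblem, state, rng, n_newton=8,
                           force=False):
    """Update the globally shared covariate slopes (Laplace independence MH)."""
    q = prob.q_shared
    m0 = np.zeros(q)
    Q0 = np.eye(q) / 100.0
    rows_A, rows_y, rows_sd, rows_n, rows_f0 = [], [], [], [], []
    for c in range(prob.C):
        pop = prob.pops[c]
        if len(pop.y) == 0:
            continue
        base = prob.base_mean(state, c) + prob.A_u[c] @ state["u"][c]
        rows_A.append(prob.X_shared[c][pop.t_idx])
        rows_f0.append(base[pop.t_idx])
        rows_y.append(pop.y)
        rows_sd.append(prob._sd_for(state, pop))
        rows_n.append(pop.n)
    if not rows_A:
        return
    Aobs = np.vstack(rows_A)
    f0 = np.concatenate(rows_f0)
    y = np.concatenate(rows_y)
    sd = np.concatenate(rows_sd)
    n = np.concatenate(rows_n) if len(rows_n[0]) else None

    def ll_and_derivs(v, want=True):
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            return loglik_terms(
                y, f0 + Aobs @ v, sd, n, prob.family, prob.transform,
                prob.phi, want_derivs=want,
            )

    def logpost(v):
        ll, _, _ = ll_and_derivs(v, want=False)
        s = np.sum(ll)
        d = v - m0
        return (float(s) if np.isfinite(s) else -np.inf) \
            - 0.5 * float(d @ Q0 @ d)

    v = m0.copy()
    obj = logpost(v)
    for _ in range(n_newton):
        _, grad, w = ll_and_derivs(v)
        if not (np.all(np.isfinite(grad)) and np.all(np.isfinite(w))):
            break
        g = Aobs.T @ grad - Q0 @ (v - m0)
        H = Aobs.T @ (np.maximum(w, 0)[:, None] * Aobs) + Q0
        step = linalg.solve(H, g)
        lam, obj_new, v_new = 1.0, -np.inf, v
        for _ in range(8):
            v_try = v + lam * step
            obj_try = logpost(v_try)
            if np.isfinite(obj_try) and obj_try >= obj - 1e-12:
                v_new, obj_new = v_try, obj_try
                break
            lam *= 0.5
        if not np.isfinite(obj_new):
            break
        moved = np.max(np.abs(v_new - v))
        v, obj = v_new, obj_new
        if moved < 1e-9:
            break
    _, _, w = ll_and_derivs(v)
    H = Aobs.T @ (np.maximum(w, 0)[:, None] * Aobs) + Q0
    Lh = _chol(H + 1e-10 * np.eye(q))
    logdet_half = float(np.sum(np.log(np.diag(Lh))))

    def logq(x):
        zz = Lh.T @ (x - v)
        return -0.5 * float(zz @ zz) + logdet_half

    prop = v + _solve_upper(Lh, rng.standard_normal(q))
    if force:
        state["shared"] = prop
        return
    cur = state["shared"]
    if np.log(rng.uniform()) < logpost(prop) - logpost(cur) \
            + logq(cur) - logq(prop):
        state["shared"] = prop


def _shared_joint_move(prob, state, rng, rws, adapting, cache=None):
    """Random-walk move on the shared slopes, with proposal covariance
    adapted from the warmup trajectory and a Laplace refresh of all
    per-population blocks; decouples global slopes from intercepts and
    smoothing terms."""
    q = prob.q_shared
    rw = rws.setdefault("shared_joint", AdaptiveCovRW(dim=q))
    x0 = state["shared"]
    if adapting:
        rw.observe(x0)
    else:
        rw.freeze()
    x1 = rw.propose(x0, rng)
    trial = dict(state)
    trial["shared"] = x1
    score0 = _lp_norm(x0, 0.0, 10.0)
    score1 = _lp_norm(x1, 0.0, 10.0)
    accept = False
    try:
        new_us = {}
        new_macs = {}
        for c in range(prob.C):
            mac0 = _get_mac(cache, prob, state, c)
            u_c = state["u"][c]
            score0 += mac0.logpost(u_c) - mac0.logq(u_c)
            mac1 = _laplace_for(prob, trial, c)
            new_macs[c] = mac1
            u_new = mac1.sample(rng)
            new_us[c] = u_new
            score1 += mac1.logpost(u_new) - mac1.logq(u_new)
        if np.isfinite(score1) and np.log(rng.uniform()) < score1 - score0:
            accept = True
            state["shared"] = x1
            for c, u_new in new_us.items():
                state["u"][c] = u_new
                if cache is not None:
                    cache[c] = new_macs[c]
    except (linalg.LinAlgError, np.linalg.LinAlgError,
            sm.NumericalError, OverflowError):
        accept = False
    if adapting:
        rw.adapt(accept)


def _kscale_prior(prob: FitProblem, state, c, logs: float) -> float:
    """Log prior of one population's log kernel scale in the given state."""
    if prob.hier_kscale:
        means, s1 = prob.hier_kscale.mean_sd_for_pops(state)
        return _lp_norm(logs, means[c], max(s1, 1e-8))
    return _lp_halfnorm(np.exp(logs), 5.0) + logs


def _update_kernel_scales(prob: FitProblem, state, rng, rws, adapting,
                          cache=None):
    strat = prob.kscale_strategy
    if strat == "fixed":
        return
    if strat == "grouped":
        for gi in list(range(len(prob.kscale_group_labels))) * 3:
            members = list(np.where(prob.kscale_groups == gi)[0])

            def make_trial(x, gi=gi):
                trial = dict(state)
                arr = state["log_kscale_groups"].copy()
                arr[gi] = x
                trial["log_kscale_groups"] = arr
                return trial

            def prior(st, x):
                return _lp_halfnorm(np.exp(x), 5.0) + x

            _, x = _joint_hyper_mh(
                prob, state, rng, rws, adapting,
                f"log_kscale_groups::{gi}",
                float(state["log_kscale_groups"][gi]),
                members, make_trial, prior, cache=cache,
            )
            state["log_kscale_groups"][gi] = x
        # interweaved rescaling + conditional slice (ancillarity /
        # sufficiency pair) for each group scale
        sl = prob.slices["gamma"]
        for gi in range(len(prob.kscale_group_labels)):
            members = list(np.where(prob.kscale_groups == gi)[0])
            rw = rws.setdefault(f"kscale_groups_iw::{gi}",
                                AdaptiveRW(step=0.3))
            x0 = float(state["log_kscale_groups"][gi])
            x1 = float(rw.propose(x0, rng))
            ratio = np.exp(x1 - x0)
            trial_us = {c: state["u"][c].copy() for c in members}
            for c in members:
                trial_us[c][sl] = trial_us[c][sl] * ratio
            lp0 = _lp_halfnorm(np.exp(x0), 5.0) + x0
            lp1 = _lp_halfnorm(np.exp(x1), 5.0) + x1
            for c in members:
                lp0 += prob.pop_loglik(state, c)
                base = prob.base_mean(state, c)
                if prob.q_shared:
                    base = base + prob.X_shared[c] @ state["shared"]
                f1 = base + prob.A_u[c] @ trial_us[c]
                pop = prob.pops[c]
                lp1 += prob.pop_loglik(state, c, f_obs=f1[pop.t_idx]) \
                    if len(pop.y) else 0.0
            accept = np.isfinite(lp1) and np.log(rng.uniform()) < lp1 - lp0
            if accept:
                state["log_kscale_groups"][gi] = x1
                for c in members:
                    state["u"][c] = trial_us[c]
                    if cache is not None:
                        cache.pop(c, None)
            if adapting:
                rw.adapt(bool(accept))
            # conditional slice given the current coefficients
            gammas = [state["u"][c][sl] for c in members]

            def lp_cond(logs, gi=gi, gammas=gammas):
                trial = dict(state)
                arr = state["log_kscale_groups"].copy()
                arr[gi] = logs
                trial["log_kscale_groups"] = arr
                total = _lp_halfnorm(np.exp(logs), 5.0) + logs
                for c, g in zip(members, gammas):
                    total += prob.gamma_logprior(trial, c, g)
                return total

            new_logs = _slice_scalar(
                float(state["log_kscale_groups"][gi]), lp_cond, rng, w=0.5)
            if new_logs != state["log_kscale_groups"][gi]:
                state["log_kscale_groups"][gi] = new_logs
                if cache is not None:
                    for c in members:
                        cache.pop(c, None)
        return
    if strat == "bmat":
        _update_bmat_scales(prob, state, rng, rws, adapting, cache=cache)
        return
    for c in range(prob.C):
        # no data: the joint (scale, gamma) conditional is exactly the
        # prior, so draw the scale from its prior and the coefficients
        # from their prior under it, in one exact blocked draw
        if len(prob.pops[c].y) == 0:
            if prob.hier_kscale:
                means, s1 = prob.hier_kscale.mean_sd_for_pops(state)
                state["log_kscale"][c] = rng.normal(means[c], max(s1, 1e-8))
            else:
                state["log_kscale"][c] = np.log(
                    abs(rng.normal(0.0, 5.0)) + 1e-12)
            if cache is not None:
                cache.pop(c, None)
            _update_u(prob, state, c, rng, force=True, cache=cache)
    for c in list(range(prob.C)) * prob.sweeps:
        if len(prob.pops[c].y) == 0:
            continue

        def make_trial(x, c=c):
            trial = dict(state)
            arr = state["log_kscale"].copy()
            arr[c] = x
            trial["log_kscale"] = arr
            return trial

        def prior(st, x, c=c):
            return _kscale_prior(prob, st, c, float(x))

        _, x = _joint_hyper_mh(
            prob, state, rng, rws, adapting, f"log_kscale::{c}",
            float(state["log_kscale"][c]), [c], make_trial, prior,
            cache=cache,
        )
        state["log_kscale"][c] = x
    if prob.hier_kscale:
        prob.hier_kscale.update(state, state["log_kscale"], rng, rws, adapting)
        _kscale_hier_expansion(prob, state, rng, rws, adapting, cache)


def _kscale_hier_expansion(prob, state, rng, rws, adapting, cache=None):
    """Scale-expansion move on the kernel-scale hierarchy.

    Proposes s1' and rescales every population's log-scale about the group
    mean by s1'/s1 (holding the standardized deviations fixed), refreshing
    the coefficient blocks; this breaks the funnel between the hierarchy
    scale and its children when the data say little about the individual
    scales."""
    mgr = prob.hier_kscale
    s1 = float(state[mgr.key_s(1)])
    means, _ = mgr.mean_sd_for_pops(state)
    rw = rws.setdefault("kscale_hier_expand", AdaptiveRW(step=0.3))
    x0 = np.log(s1)
    x1 = float(rw.propose(x0, rng))
    ratio = np.exp(x1 - x0)
    children = state["log_kscale"]
    children_new = means + (children - means) * ratio
    if np.max(np.abs(children_new)) > 40.0:  # exp() would overflow
        if adapting:
            rw.adapt(False)
        return
    trial = dict(state)
    trial["log_kscale"] = children_new
    trial[mgr.key_s(1)] = float(np.exp(x1))
    # priors: half-normal on s1 (log parametrization Jacobian included);
    # the standardized children prior is invariant under the move
    score0 = _lp_halfnorm(s1, 5.0) + x0
    score1 = _lp_halfnorm(np.exp(x1), 5.0) + x1
    accept = False
    try:
        new_us = {}
        new_macs = {}
        for c in range(prob.C):
            mac0 = _get_mac(cache, prob, state, c)
            u_c = state["u"][c]
            score0 += mac0.logpost(u_c) - mac0.logq(u_c)
            mac1 = _laplace_for(prob, trial, c)
            new_macs[c] = mac1
            u_new = mac1.sample(rng)
            new_us[c] = u_new
            score1 += mac1.logpost(u_new) - mac1.logq(u_new)
        if np.isfinite(score1) and np.log(rng.uniform()) < score1 - score0:
            accept = True
            state["log_kscale"] = children_new
            state[mgr.key_s(1)] = float(np.exp(x1))
            for c, u_new in new_us.items():
                state["u"][c] = u_new
                if cache is not None:
                    cache[c] = new_macs[c]
    except (np.linalg.LinAlgError, sm.NumericalError, OverflowError):
        accept = False
    if adapting:
        rw.adapt(accept)


def _update_bmat_scales(prob: FitProblem, state, rng, rws, adapting,
                        cache=None):
    s_lam = float(np.exp(state["log_sigma_lambda"]))
    a, b = -1.0 / s_lam, 2.0 / s_lam
    for c in list(range(prob.C)) * prob.sweeps:

        def make_trial(x, c=c):
            trial = dict(state)
            arr = state["bmat_lambda"].copy()
            arr[c] = x
            trial["bmat_lambda"] = arr
            return trial

        def prior(st, x):
            if not (-1.0 < x < 2.0):
                return -np.inf
            return _lp_truncnorm(x, -1.0, 2.0, 0.0, s_lam)

        _, x = _joint_hyper_mh(
            prob, state, rng, rws, adapting, f"bmat_lambda::{c}",
            float(state["bmat_lambda"][c]), [c], make_trial, prior,
            cache=cache,
        )
        state["bmat_lambda"][c] = x

    def make_trial_w(x):
        trial = dict(state)
        trial["log_sigma_w"] = x
        return trial

    def prior_w(st, x):
        return _lp_halfnorm(np.exp(x), 5.0) + x

    _, x = _joint_hyper_mh(
        prob, state, rng, rws, adapting, "log_sigma_w",
        float(state["log_sigma_w"]), list(range(prob.C)), make_trial_w,
        prior_w, cache=cache,
    )
    state["log_sigma_w"] = x

    def lp_sl(logsl):
        s = np.exp(logsl)
        aa, bb = -1.0 / s, 2.0 / s
        return (
            _lp_truncnorm(state["bmat_lambda"], -1.0, 2.0, 0.0, s)
            + _lp_halfnorm(s, 5.0) + logsl
        )

    _mh_scalar("log_sigma_lambda", state, lp_sl, rng, rws, adapting)


def _update_kernel_shapes(prob: FitProblem, state, rng, rws, adapting,
                          cache=None):
    """Global kernel shape parameters, random-walked on unconstrained
    scales (logit for rho and theta, log for ell) so the moves are not
    throttled near the boundaries of their uniform priors."""

    def to_unconstrained(pname, v):
        if pname == "rho":
            return float(logit(np.clip(v, 1e-6, 0.999)))
        if pname == "theta":
            return float(logit(np.clip(v + 1.0, 1e-6, 1 - 1e-6)))
        return float(np.log(v))  # ell

    def to_natural(pname, x):
        if pname == "rho":
            return float(expit(x)) * 0.999
        if pname == "theta":
            return float(expit(x)) - 1.0
        return float(np.exp(x))

    for pname in prob.free_shapes:
        key = f"kshape_{pname}"

        def make_trial(x, key=key, pname=pname):
            trial = dict(state)
            trial[key] = to_natural(pname, float(x))
            return trial

        def prior(st, x, pname=pname):
            # uniform prior on the natural scale (half-normal for ell)
            # plus the Jacobian of the unconstrained parametrization
            x = float(x)
            if pname in ("rho", "theta"):
                return float(x - 2.0 * np.logaddexp(0.0, x))
            return _lp_halfnorm(np.exp(x), 10.0) + x

        _, x = _joint_hyper_mh(
            prob, state, rng, rws, adapting, key,
            to_unconstrained(pname, float(state[key])),
            list(range(prob.C)), make_trial, prior, step=0.3, cache=cache,
        )
        state[key] = to_natural(pname, float(x))


def _update_data_sigma(prob: FitProblem, state, rng, rws, adapting):
    """Returns True if any sigma changed (machinery caches must be dropped)."""
    if not prob.estimate_sigma:
        return False
    n_sig = len(state["log_data_sigma"])
    changed = False
    for si in range(n_sig):

        def lp(logs, si=si):
            trial = dict(state)
            arr = state["log_data_sigma"].copy()
            arr[si] = logs
            trial["log_data_sigma"] = arr
            total = _lp_halfnorm(np.exp(logs), 5.0) + logs
            for c in range(prob.C):
                total += prob.pop_loglik(trial, c)
            return total

        key = f"log_data_sigma::{si}"
        state.setdefault(key, float(state["log_data_sigma"][si]))
        state[key] = float(state["log_data_sigma"][si])
        changed = _mh_scalar(key, state, lp, rng, rws, adapting) or changed
        state["log_data_sigma"][si] = state[key]
    return changed


def _update_fpem(prob: FitProblem, state, rng, rws, adapting, cache=None):
    """Componentwise (theta_cj, u_c) joint moves for the logistic
    transition: each of asymptote, rate and level gets its own tuned
    random-walk scale, with the AR deviations refreshed under the
    proposal."""
    comps = ("P_tilde", "omega", "Omega")
    # populations without data: the conditional of theta_c is its prior
    for c in range(prob.C):
        if len(prob.pops[c].y):
            continue
        mat = state["fpem_theta"].copy()
        for j, comp in enumerate(comps):
            if comp in prob.hier_fpem:
                means, s1 = prob.hier_fpem[comp].mean_sd_for_pops(state)
                mat[c, j] = rng.normal(means[c], max(s1, 1e-8))
            else:
                mat[c, j] = rng.normal(0.0, 10.0)
        state["fpem_theta"] = mat
    for c in list(range(prob.C)) * prob.sweeps:
        if len(prob.pops[c].y) == 0:
            continue
        for j, comp in enumerate(comps):

            def make_trial(x, c=c, j=j):
                trial = dict(state)
                mat = state["fpem_theta"].copy()
                mat[c, j] = float(x)
                trial["fpem_theta"] = mat
                return trial

            def prior(st, x, c=c, comp=comp):
                if comp in prob.hier_fpem:
                    means, s1 = prob.hier_fpem[comp].mean_sd_for_pops(st)
                    return _lp_norm(float(x), means[c], max(s1, 1e-8))
                return _lp_norm(float(x), 0.0, 10.0)

            _, x = _joint_hyper_mh(
                prob, state, rng, rws, adapting, f"fpem_{comp}::{c}",
                float(state["fpem_theta"][c, j]), [c], make_trial, prior,
                step=0.3, cache=cache,
            )
            mat = state["fpem_theta"].copy()
            mat[c, j] = x
            state["fpem_theta"] = mat
    # joint 3-parameter move per population with covariance adapted from
    # the warmup trajectory (follows the asymptote/level ridge that the
    # componentwise moves cannot)
    for c in range(prob.C):
        if len(prob.pops[c].y) == 0:
            continue
        rw = rws.setdefault(f"fpem_joint::{c}", AdaptiveCovRW(dim=3))
        th0 = state["fpem_theta"][c].copy()
        if adapting:
            rw.observe(th0)
        else:
            rw.freeze()
        th1 = rw.propose(th0, rng)

        def make_trial(th, c=c):
            trial = dict(state)
            mat = state["fpem_theta"].copy()
            mat[c] = th
            trial["fpem_theta"] = mat
            return trial

        def prior(st, th, c=c):
            total = 0.0
            for j, comp in enumerate(comps):
                if comp in prob.hier_fpem:
                    means, s1 = prob.hier_fpem[comp].mean_sd_for_pops(st)
                    total += _lp_norm(float(th[j]), means[c], max(s1, 1e-8))
                else:
                    total += _lp_norm(float(th[j]), 0.0, 10.0)
            return total

        accept = False
        try:
            trial = make_trial(th1)
            mac0 = _get_mac(cache, prob, state, c)
            u_c = state["u"][c]
            score0 = prior(state, th0) + mac0.logpost(u_c) - mac0.logq(u_c)
            mac1 = _laplace_for(prob, trial, c)
            u_new = mac1.sample(rng)
            score1 = prior(state, th1) + mac1.logpost(u_new) - mac1.logq(u_new)
            if np.isfinite(score1) and np.log(rng.uniform()) < score1 - score0:
                accept = True
                mat = state["fpem_theta"].copy()
                mat[c] = th1
                state["fpem_theta"] = mat
                state["u"][c] = u_new
                if cache is not None:
                    cache[c] = mac1
        except (linalg.LinAlgError, np.linalg.LinAlgError,
                sm.NumericalError, OverflowError):
            accept = False
        if adapting:
            rw.adapt(accept)

    for comp, mgr in prob.hier_fpem.items():
        j = comps.index(comp)
        mgr.update(state, state["fpem_theta"][:, j], rng, rws, adapting)


class _GaussBlockPCA:
    """Laplace machinery for one county's (T x P) coefficient block.

    Each observation involves the coefficients of a single year, so the
    conditional precision is block-diagonal by time; all factorizations
    are batched (T, P, P) operations.
    """

    def __init__(self, prob, state, gi):
        T, P = prob.T, prob.P_pca
        self.T, self.P = T, P
        self.dim = T * P
        sig_p = np.exp(state["log_pca_sigma_p"])
        self.m0 = state["pca_mu"].T.copy()  # (T, P)
        self.qdiag = 1.0 / sig_p**2  # (P,)
        self.logdetQ = float(T * np.sum(np.log(self.qdiag)))
        ts, Xr, ys, sds, f0s = [], [], [], [], []
        for c in np.where(prob.county_of == gi)[0]:
            pop = prob.pops[c]
            if len(pop.y) == 0:
                continue
            base = prob.M_base[c] + prob.A_u[c] @ state["u"][c]
            ts.append(pop.t_idx)
            Xr.append(prob.X_pca[c][pop.t_idx])
            ys.append(pop.y)
            sds.append(prob._sd_for(state, pop))
            f0s.append(base[pop.t_idx])
        self.has_data = bool(ts)
        if self.has_data:
            self.t_idx = np.concatenate(ts)
            self.X = np.vstack(Xr)  # (n, P)
            self.y = np.concatenate(ys)
            self.sd = np.concatenate(sds)
            self.f0 = np.concatenate(f0s)
        self.prob = prob
        self._newton()

    def _f(self, v):
        return self.f0 + np.einsum("np,np->n", self.X, v[self.t_idx])

    def loglik(self, v) -> float:
        v = v.reshape(self.T, self.P)
        if not self.has_data:
            return 0.0
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            ll, _, _ = loglik_terms(
                self.y, self._f(v), self.sd, None, self.prob.family,
                self.prob.transform, want_derivs=False,
            )
        t = np.sum(ll)
        return float(t) if np.isfinite(t) else -np.inf

    def logprior(self, v) -> float:
        d = (v.reshape(self.T, self.P) - self.m0)
        return float(
            -0.5 * np.sum(d * d * self.qdiag) + 0.5 * self.logdetQ
            - 0.5 * self.dim * _LOG2PI
        )

    def logpost(self, v) -> float:
        return self.loglik(v) + self.logprior(v)

    def _hess(self, v):
        """Per-time (P, P) precision blocks and gradient at v (T, P)."""
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            _, grad, w = loglik_terms(
                self.y, self._f(v), self.sd, None, self.prob.family,
                self.prob.transform,
            )
        if not (np.all(np.isfinite(grad)) and np.all(np.isfinite(w))):
            return None, None
        w = np.maximum(w, 0.0)
        g = np.zeros((self.T, self.P))
        np.add.at(g, self.t_idx, grad[:, None] * self.X)
        H = np.zeros((self.T, self.P, self.P))
        outer = (w[:, None, None]
                 * self.X[:, :, None] * self.X[:, None, :])
        np.add.at(H, self.t_idx, outer)
        H += np.diag(self.qdiag)
        return g, H

    def _newton(self):
        v = self.m0.copy()
        H = np.broadcast_to(
            np.diag(self.qdiag), (self.T, self.P, self.P)
        ).copy()
        if self.has_data:
            obj = self.logpost(v.reshape(-1))
            for _ in range(6):
                g, H_new = self._hess(v)
                if g is None:
                    break
                H = H_new
                g = g - (v - self.m0) * self.qdiag
                step = np.linalg.solve(H, g[..., None])[..., 0]
                lam, obj_new, v_new = 1.0, -np.inf, v
                for _ in range(8):
                    v_try = v + lam * step
                    obj_try = self.logpost(v_try.reshape(-1))
                    if np.isfinite(obj_try) and obj_try >= obj - 1e-12:
                        v_new, obj_new = v_try, obj_try
                        break
                    lam *= 0.5
                if not np.isfinite(obj_new):
                    break
                moved = float(np.max(np.abs(v_new - v)))
                v, obj = v_new, obj_new
                if moved < 1e-6:
                    break
            g, H_new = self._hess(v)
            if g is not None:
                H = H_new
        self.vhat = v  # (T, P)
        self.Lh = np.linalg.cholesky(H)  # (T, P, P)
        diag = self.Lh[:, np.arange(self.P), np.arange(self.P)]
        self.logdet_half = float(np.sum(np.log(diag)))

    def sample(self, rng):
        z = rng.standard_normal((self.T, self.P, 1))
        LhT = np.swapaxes(self.Lh, 1, 2)
        x = self.vhat + np.linalg.solve(LhT, z)[..., 0]
        return x.reshape(-1)

    def logq(self, v) -> float:
        d = (v.reshape(self.T, self.P) - self.vhat)[..., None]
        z = np.swapaxes(self.Lh, 1, 2) @ d
        return float(
            -0.5 * np.sum(z * z) + self.logdet_half
            - 0.5 * self.dim * _LOG2PI
        )


def _pca_mu_conditional(prob, state, p):
    """Exact Gaussian conditional of mu_p given the county coefficients."""
    T = prob.T
    sig_p = float(np.exp(state["log_pca_sigma_p"][p]))
    sig_mu = float(np.exp(state["log_pca_sigma_mu"]))
    nG = len(prob.counties)
    betas = np.stack(state["pca_beta"])  # (G, T, P)
    Q_pr = prob.Q_rw2_base / sig_mu**2 + np.eye(T) / 100.0
    Q = Q_pr + nG / sig_p**2 * np.eye(T)
    b = betas[:, :, p].sum(axis=0) / sig_p**2
    L = _chol(Q)
    mean = _cho_solve(L, b)
    return mean, L, Q_pr


def _pca_mu_prior_logpdf(prob, state, p, mu_p):
    T = prob.T
    sig_mu = float(np.exp(state["log_pca_sigma_mu"]))
    Q_pr = prob.Q_rw2_base / sig_mu**2 + np.eye(T) / 100.0
    sign, logdet = np.linalg.slogdet(Q_pr)
    return float(-0.5 * mu_p @ Q_pr @ mu_p + 0.5 * logdet
                 - 0.5 * T * _LOG2PI)


def _update_pca(prob: FitProblem, state, rng, rws, adapting, force=False):
    """Subnational model updates.

    County coefficient blocks beta_{c,t,p} get Laplace independence-MH
    updates; the component mean paths mu_p are exact Gaussian draws; the
    variance parameters sigma_p and sigma_mu get random-walk moves that
    jointly refresh the blocks whose priors they control (marginal-style
    MH, avoiding the scale/coefficient funnel)."""
    T, P = prob.T, prob.P_pca
    nG = len(prob.counties)

    # 1. county blocks
    for gi in range(nG):
        mac = _GaussBlockPCA(prob, state, gi)
        prop = mac.sample(rng)
        cur = state["pca_beta"][gi].reshape(-1)
        if force or np.log(rng.uniform()) < (
            mac.logpost(prop) - mac.logpost(cur)
            + mac.logq(cur) - mac.logq(prop)
        ):
            state["pca_beta"][gi] = prop.reshape(T, P)

    # 2. mu_p: exact conditional draws
    for p in range(P):
        mean, L, _ = _pca_mu_conditional(prob, state, p)
        state["pca_mu"][p] = mean + _solve_upper(L, rng.standard_normal(T))

    # 3. sigma_p: joint moves over the vector of component sds,
    # refreshing all county blocks under the proposal (two sweeps)
    for _sweep in range(2):
      rw = rws.setdefault("log_pca_sigma_p", AdaptiveRW(dim=P, step=0.2))
      x0 = state["log_pca_sigma_p"]
      x1 = rw.propose(x0, rng)
      trial = dict(state)
      trial["log_pca_sigma_p"] = x1
      score0 = _lp_halfnorm(np.exp(x0), 5.0) + float(np.sum(x0))
      score1 = _lp_halfnorm(np.exp(x1), 5.0) + float(np.sum(x1))
      new_betas = []
      ok = True
      try:
          for gi in range(nG):
              mac0 = _GaussBlockPCA(prob, state, gi)
              cur = state["pca_beta"][gi].reshape(-1)
              score0 += mac0.logpost(cur) - mac0.logq(cur)
              mac1 = _GaussBlockPCA(prob, trial, gi)
              newv = mac1.sample(rng)
              new_betas.append(newv.reshape(T, P))
              score1 += mac1.logpost(newv) - mac1.logq(newv)
      except np.linalg.LinAlgError:
          ok = False
      accept = ok and np.isfinite(score1) and \
          np.log(rng.uniform()) < score1 - score0
      if accept:
          state["log_pca_sigma_p"] = x1
          state["pca_beta"] = new_betas
      if adapting:
          rw.adapt(bool(accept))

    # 3b. interweaved rescaling (ancillarity) moves: rescale each
    # component's county deviations about their mean together with its sd;
    # the standardized-deviation prior is invariant, so the move costs only
    # likelihood evaluations and traverses the weakly identified sds
    for p_i in range(P):
        rw = rws.setdefault(f"pca_sigma_iw::{p_i}", AdaptiveRW(step=0.3))
        x0 = float(state["log_pca_sigma_p"][p_i])
        x1 = float(rw.propose(x0, rng))
        ratio = np.exp(x1 - x0)
        mu_p = state["pca_mu"][p_i]
        new_betas = [b.copy() for b in state["pca_beta"]]
        for b in new_betas:
            b[:, p_i] = mu_p + (b[:, p_i] - mu_p) * ratio
        trial = dict(state)
        trial["pca_beta"] = new_betas
        lp0 = _lp_halfnorm(np.exp(x0), 5.0) + x0
        lp1 = _lp_halfnorm(np.exp(x1), 5.0) + x1
        for c in range(prob.C):
            lp0 += prob.pop_loglik(state, c)
            lp1 += prob.pop_loglik(trial, c)
        accept = np.isfinite(lp1) and np.log(rng.uniform()) < lp1 - lp0
        if accept:
            arr = state["log_pca_sigma_p"].copy()
            arr[p_i] = x1
            state["log_pca_sigma_p"] = arr
            state["pca_beta"] = new_betas
        if adapting:
            rw.adapt(bool(accept))

    # 3c. conditional slice update of each sigma_p given the deviations
    # (the sufficient-parametrization half of the interweaving pair)
    betas_cur = np.stack(state["pca_beta"])
    for p_i in range(P):
        resid = betas_cur[:, :, p_i] - state["pca_mu"][p_i]

        def lp_cond(logs, resid=resid):
            sd = np.exp(logs)
            return (_lp_norm(resid, 0.0, sd)
                    + _lp_halfnorm(sd, 5.0) + logs)

        arr = state["log_pca_sigma_p"].copy()
        arr[p_i] = _slice_scalar(float(arr[p_i]), lp_cond, rng, w=0.5)
        state["log_pca_sigma_p"] = arr

    # 4. sigma_mu: joint move refreshing the mu_p fields exactly
    def prior_smu(x):
        return _lp_halfnorm(np.exp(x), 5.0) + x

    rw = rws.setdefault("log_pca_sigma_mu", AdaptiveRW(step=0.3))
    x0 = float(state["log_pca_sigma_mu"])
    x1 = float(rw.propose(x0, rng))
    trial = dict(state)
    trial["log_pca_sigma_mu"] = x1
    score0, score1 = prior_smu(x0), prior_smu(x1)
    new_mu = np.empty_like(state["pca_mu"])
    sig_p = np.exp(state["log_pca_sigma_p"])
    betas = np.stack(state["pca_beta"])
    if not (-15.0 < x1 < 5.0):
        if adapting:
            rw.adapt(False)
        return
    try:
      for p in range(P):
        mean0, L0, _ = _pca_mu_conditional(prob, state, p)
        mu0 = state["pca_mu"][p]

        def lq(mu, mean, L):
            z = L.T @ (mu - mean)
            return float(-0.5 * z @ z + np.sum(np.log(np.diag(L)))
                         - 0.5 * T * _LOG2PI)

        lik0 = _lp_norm(betas[:, :, p] - mu0, 0.0, float(sig_p[p]))
        score0 += _pca_mu_prior_logpdf(prob, state, p, mu0) + lik0 \
            - lq(mu0, mean0, L0)
        mean1, L1, _ = _pca_mu_conditional(prob, trial, p)
        mu1 = mean1 + _solve_upper(L1, rng.standard_normal(T))
        new_mu[p] = mu1
        lik1 = _lp_norm(betas[:, :, p] - mu1, 0.0, float(sig_p[p]))
        score1 += _pca_mu_prior_logpdf(prob, trial, p, mu1) + lik1 \
            - lq(mu1, mean1, L1)
    except np.linalg.LinAlgError:
        score1 = -np.inf
    accept = np.isfinite(score1) and np.log(rng.uniform()) < score1 - score0
    if accept:
        state["log_pca_sigma_mu"] = x1
        state["pca_mu"] = new_mu
    if adapting:
        rw.adapt(bool(accept))


# ---------------------------------------------------------------------------
# posterior container and diagnostics
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSamples:
    """Joint posterior draws, shaped (chains, draws, ...) per variable."""

    draws: dict
    populations: list[str]
    grid: object
    seed: int
    fingerprint: str
    model: TMMPModel = None
    warnings: list = field(default_factory=list)

    def get(self, name: str) -> np.ndarray:
        """Draws stacked over chains: (chains*draws, ...)."""
        arr = self.draws[name]
        return arr.reshape((-1,) + arr.shape[2:])

    def eta_draws(self) -> np.ndarray:
        return self.get("eta")

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    def to_arviz(self):
        import arviz as az

        data = {}
        for name, arr in self.draws.items():
            data[name.replace("::", "_")] = arr
        return az.from_dict(posterior=data)


@dataclass
class Diagnostics:
    rhat: dict
    ess: dict
    notes: list = field(default_factory=list)

    @property
    def max_rhat(self) -> float:
        vals = [v for v in self.rhat.values() if np.isfinite(v)]
        return max(vals) if vals else np.nan


def diagnose(posterior: PosteriorSamples) -> Diagnostics:
    """Split-Rhat and bulk ESS per parameter (via ArviZ)."""
    import arviz as az

    notes = []
    rhat, ess = {}, {}
    single = posterior.n_chains < 2
    if single:
        notes.append("single chain: split-Rhat omitted")
    for name, arr in posterior.draws.items():
        if name == "eta":
            continue
        flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
        for j in range(flat.shape[2]):
            x = flat[:, :, j]
            label = name if flat.shape[2] == 1 else f"{name}[{j}]"
            if np.allclose(x, x.flat[0]):
                rhat[label] = 1.0
                ess[label] = float(x.size)
                continue
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                ds = az.convert_to_dataset(np.ascontiguousarray(x))
                if not single:
                    rhat[label] = float(np.asarray(az.rhat(ds)["x"].values))
                ess[label] = float(np.asarray(az.ess(ds)["x"].values))
    return Diagnostics(rhat, ess, notes)


# ---------------------------------------------------------------------------
# main fitting loop
# ---------------------------------------------------------------------------

def _record(prob: FitProblem, state) -> dict:
    out = {}
    sl = prob.slices
    u = np.stack(state["u"])  # (C, p_u)
    if "alpha0" in sl:
        out["alpha0"] = u[:, sl["alpha0"].start]
        out["alpha1"] = u[:, sl["alpha1"].start]
    if "beta0" in sl:
        out["beta0"] = u[:, sl["beta0"].start]
        if prob.X_shared_mean is not None:
            out["beta0"] = out["beta0"] - float(
                prob.X_shared_mean @ state["shared"]
            )
    out["gamma"] = u[:, sl["gamma"]]
    if prob.q_shared:
        out["beta"] = state["shared"].copy()
    if prob.kscale_strategy == "grouped":
        out["kernel_scale"] = np.exp(
            state["log_kscale_groups"][prob.kscale_groups]
        )
    elif prob.kscale_strategy == "bmat":
        out["kernel_scale"] = np.exp(state["log_sigma_w"]) * (
            1.0 + state["bmat_lambda"]
        )
        out["bmat_lambda"] = state["bmat_lambda"].copy()
        out["sigma_w"] = np.exp(state["log_sigma_w"])
    elif prob.kscale_strategy != "fixed":
        out["kernel_scale"] = np.exp(state["log_kscale"])
    for p in prob.free_shapes:
        out[p] = float(state[f"kshape_{p}"])
    if prob.estimate_sigma:
        out["data_sigma"] = np.exp(state["log_data_sigma"])
    if prob.fpem:
        th = state["fpem_theta"]
        out["P_tilde"] = bounded_transform(th[:, 0], *prob.fpem_bounds["P_tilde"])
        out["omega"] = bounded_transform(th[:, 1], *prob.fpem_bounds["omega"])
        out["Omega"] = th[:, 2].copy()
    if prob.pca:
        out["beta_pca"] = np.stack(state["pca_beta"])
        out["pca_mu"] = state["pca_mu"].copy()
        out["pca_sigma_p"] = np.exp(state["log_pca_sigma_p"])
    for mgr in filter(None, [prob.hier_kscale, prob.hier_beta0]):
        out[mgr.key_mu(mgr.L)] = state[mgr.key_mu(mgr.L)].copy()
        out[mgr.key_s(1)] = float(state[mgr.key_s(1)])
    # latent field on the natural scale
    from .process import inverse_transform, TransformSpec

    f = np.stack([prob.full_f(state, c) for c in range(prob.C)])
    out["eta"] = inverse_transform(f, TransformSpec(prob.transform))
    return out


def _run_chain(prob: FitProblem, seed, warmup, draws):
    rng = np.random.default_rng(seed)
    state = prob.init_state(rng)
    rws: dict = {}
    # sanity check the initial log density
    lp0 = prob.total_loglik(state)
    if not np.isfinite(lp0):
        raise RuntimeError(
            "non-finite log-likelihood at initialization; check data/model "
            "support (e.g. transform domain)"
        )
    # start every Gaussian block at a draw from its Laplace conditional so
    # the independence proposals begin inside the posterior bulk
    if prob.pca:
        _update_pca(prob, state, rng, {}, adapting=False, force=True)
    for c in range(prob.C):
        _update_u(prob, state, c, rng, force=True)
    if prob.q_shared:
        _laplace_update_shared(prob, state, rng, force=True)
    stored = []
    # cache of per-population Laplace machinery; entries are dropped the
    # moment any quantity they depend on (hypers, shared slopes, data
    # sigmas, hierarchy means, pca coefficients) changes
    cache: dict = {}
    for it in range(warmup + draws):
        adapting = it < warmup
        for c in range(prob.C):
            _update_u(prob, state, c, rng, cache=cache)
        if prob.q_shared:
            _laplace_update_shared(prob, state, rng)
            cache.clear()
            for _ in range(prob.sweeps):
                _shared_joint_move(prob, state, rng, rws, adapting, cache)
        _update_kernel_scales(prob, state, rng, rws, adapting, cache=cache)
        _update_kernel_shapes(prob, state, rng, rws, adapting, cache=cache)
        if _update_data_sigma(prob, state, rng, rws, adapting):
            cache.clear()
        if prob.fpem:
            _update_fpem(prob, state, rng, rws, adapting, cache=cache)
        if prob.pca:
            _update_pca(prob, state, rng, rws, adapting)
            cache.clear()
        if prob.hier_beta0 is not None:
            i = prob.slices["beta0"].start
            b0 = np.array([state["u"][c][i] for c in range(prob.C)])
            prob.hier_beta0.update(state, b0, rng, rws, adapting)
            cache.clear()
        if not adapting:
            stored.append(_record(prob, state))
    return stored


def fit(
    model: TMMPModel,
    data,
    covariates=None,
    options: dict | None = None,
) -> PosteriorSamples:
    """Sample the joint posterior of a TMMPModel given observations.

    ``options``: chains (default 4), draws (1000), warmup (1000), seed (0).
    Populations with no observations receive prior-predictive draws of the
    latent field.  An Rhat above 1.05 on any recorded parameter attaches a
    warning to the returned object (never silently).
    """
    options = dict(options or {})
    inf = model.config["inference"]
    chains = int(options.get("chains", inf["chains"]))
    draws = int(options.get("draws", inf["draws"]))
    warmup = int(options.get("warmup", inf["warmup"]))
    seed = int(options.get("seed", inf["seed"]))
    prob = FitProblem(model, data, covariates)
    prob.sweeps = int(options.get("sweeps", 2))
    seeds = np.random.SeedSequence(seed).spawn(chains)
    all_chains = [
        _run_chain(prob, s, warmup, draws) for s in seeds
    ]
    names = all_chains[0][0].keys()
    stacked = {}
    for name in names:
        stacked[name] = np.stack(
            [np.stack([np.asarray(d[name]) for d in ch]) for ch in all_chains]
        )
    post = PosteriorSamples(
        draws=stacked,
        populations=list(model.populations),
        grid=model.grid,
        seed=seed,
        fingerprint=model.fingerprint(seed),
        model=model,
    )
    if chains >= 2:
        diag = diagnose(post)
        bad = {k: v for k, v in diag.rhat.items() if v > 1.05}
        if bad:
            worst = max(bad, key=bad.get)
            post.warnings.append(
                f"Rhat > 1.05 on {len(bad)} parameter(s); worst {worst} = "
                f"{bad[worst]:.3f}"
            )
    return post
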