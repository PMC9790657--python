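"""Synthetic multi-population datasets from a fully specified model.

The generator draws the latent field through the process model and then
observations through the data model, retaining the ground truth for
recovery scoring.  It emulates the data situation the model class is
designed for: many populations observed sparsely and irregularly, with
several data sources of differing sampling error, and possibly whole
populations with no observations at all.

The generator samples directly from the model's own generative form
(basis/kernel sampling plus elementwise noise); it never calls the
posterior-sampling code, so recovery experiments are not circular.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import smoothing as sm
from .io_config import ObservationTable, TimeGrid
from .model import TMMPModel

__all__ = [
    "MissingnessPattern",
    "SyntheticTruth",
    "RecoveryReport",
    "generate",
    "random_pattern",
    "recovery_experiment",
]


@dataclass
class MissingnessPattern:
    """Observation design: which (population, time) cells are observed,
    by which sources, and with what relative sampling error.

    ``sources`` maps a source label to its relative sampling sd (sd as a
    fraction of the true level for normal data; absolute transformed-scale
    sd for logit-normal).  ``times`` maps population -> list of observed
    times (possibly empty); each listed time is observed once per source
    in ``sources_at`` (default: all sources).
    """

    times: dict
    sources: dict
    sources_at: dict = field(default_factory=dict)
    denominators: dict = field(default_factory=dict)

    def validate(self, grid: TimeGrid):
        for p, ts in self.times.items():
            for t in ts:
                if not 1 <= t <= grid.T:
                    raise ValueError(
                        f"pattern time {t} for population {p!r} off the "
                        f"estimation grid 1..{grid.T}"
                    )


def random_pattern(
    populations: list[str],
    T: int,
    frac_observed: float = 0.4,
    source_rel_sd: dict | None = None,
    n_unobserved: int = 1,
    seed: int = 0,
) -> MissingnessPattern:
    """Irregular design: a fraction of population-years observed, the
    first ``n_unobserved`` populations left entirely without data."""
    rng = np.random.default_rng(seed)
    if source_rel_sd is None:
        source_rel_sd = {"survey": 0.09, "vr": 0.03}
    times = {}
    labels = sorted(source_rel_sd)
    for i, p in enumerate(populations):
        if i < n_unobserved:
            times[p] = []
            continue
        n_obs = max(2, int(round(frac_observed * T)))
        ts = np.sort(rng.choice(np.arange(1, T + 1), size=n_obs, replace=False))
        times[p] = [int(t) for t in ts]
    sources_at = {
        p: {t: [labels[int(rng.integers(len(labels)))]] for t in times[p]}
        for p in populations
    }
    return MissingnessPattern(times=times, sources=dict(source_rel_sd),
                              sources_at=sources_at)


@dataclass
class SyntheticTruth:
    """Ground truth retained for recovery scoring."""

    model: TMMPModel
    params: dict
    eta: np.ndarray  # (C, T*)
    epsilon: np.ndarray  # (C, T*)
    seed: int


def _true_field(model: TMMPModel, params: dict, seed: int):
    """Latent field over 1..T* and the epsilon paths that produced it."""
    grid = model.grid
    C = len(model.populations)
    spec = model.smoothing_spec()
    times_star = grid.times_star.astype(float)
    eps = np.empty((C, grid.T_star))
    for ci, p in enumerate(model.populations):
        kernel = spec.kernel
        if "kernel_scale" in params:
            scale = params["kernel_scale"][p] if isinstance(
                params["kernel_scale"], dict) else params["kernel_scale"]
            name = "sigma" if kernel.family in ("arma11", "iid") else "kappa"
            kernel = kernel.replace(**{name: float(scale)})
        pop_spec = sm.SmoothingSpec(
            basis=spec.basis, kernel=kernel, r=spec.r,
            constraint_mode=spec.constraint_mode, anchors=spec.anchors,
        )
        # per-population stream keyed by (seed, population index):
        # results do not depend on the order populations are processed in
        rng = np.random.default_rng(np.random.SeedSequence([seed, 7, ci]))
        eps[ci] = sample_one = sm.sample_smoothing(
            pop_spec, times_star, 1, rng, span=(1.0, float(grid.T_star))
        )[0]
    from .process import TransformSpec, inverse_transform

    tf = TransformSpec(model.config["transform"])
    eta = np.empty((C, grid.T_star))
    for ci, p in enumerate(model.populations):
        f = model.offsets[ci].copy()
        if model.config["covariate_component"]["kind"] != "none":
            f = f + model.covariate_term(p, params.get("_covariates"), params)
        if model.is_recursive():
            f = f + model.systematic_term(p, params, epsilon=eps[ci])
        else:
            f = f + model.systematic_term(p, params) + eps[ci]
        eta[ci] = inverse_transform(f, tf)
    return eta, eps


def generate(
    model: TMMPModel,
    truth_params: dict,
    pattern: MissingnessPattern,
    seed: int = 0,
    covariates=None,
) -> tuple[ObservationTable, SyntheticTruth]:
    """Draw a synthetic ObservationTable and retain the SyntheticTruth.

    The master seed is split into independent truth and noise streams, so
    the same latent truth can be re-observed under fresh noise by reusing
    the truth seed.
    """
    pattern.validate(model.grid)
    params = dict(truth_params)
    if covariates is not None:
        params["_covariates"] = covariates
    ss = np.random.SeedSequence(seed)
    truth_seed, noise_seed = [int(s.generate_state(1)[0]) % 2**31 for s in ss.spawn(2)]
    eta, eps = _true_field(model, params, truth_seed)
    family = model.config["data_model"]["family"]
    rows = []
    rng = np.random.default_rng(noise_seed)
    for ci, p in enumerate(model.populations):
        for t in pattern.times.get(p, []):
            srcs = pattern.sources_at.get(p, {}).get(t, sorted(pattern.sources))
            for s in srcs:
                rel = pattern.sources[s]
                true = eta[ci, t - 1]
                denom = pattern.denominators.get(p, {}).get(t)
                if family == "normal":
                    sd = rel * abs(true)
                    y = rng.normal(true, sd)
                    rows.append((p, t, y, sd, s, np.nan))
                elif family == "logit_normal":
                    sd = rel  # absolute sd on the logit scale
                    y = float(expit(rng.normal(logit(true), sd)))
                    rows.append((p, t, y, sd, s, np.nan))
                elif family == "binomial":
                    n = int(denom or 1000)
                    y = int(rng.binomial(n, true))
                    rows.append((p, t, y, np.nan, s, n))
                elif family == "negative_binomial":
                    n = int(denom or 1000)
                    phi = float(model.config["data_model"].get("phi") or 10.0)
                    m = n * true
                    y = int(rng.negative_binomial(phi, phi / (phi + m)))
                    rows.append((p, t, y, np.nan, s, n))
                else:
                    raise ValueError(family)
    df = pd.DataFrame(
        rows,
        columns=["population", "time", "value", "sampling_sd", "source",
                 "denominator"],
    )
    table = ObservationTable(df, model.grid)
    params.pop("_covariates", None)
    truth = SyntheticTruth(model=model, params=params, eta=eta, epsilon=eps,
                           seed=seed)
    return table, truth


# ---------------------------------------------------------------------------
# recovery experiments
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    """Per-parameter recovery scores aggregated over simulations."""

    scores: dict  # name -> dict(bias, rmse, coverage, n, mc_se_coverage)
    n_sims: int
    n_flagged: int  # fits with max Rhat > 1.1
    mean_posterior_sd: dict = field(default_factory=dict)

    def __str__(self):
        lines = [f"recovery over {self.n_sims} simulations "
                 f"({self.n_flagged} flagged fits)"]
        for k, v in self.scores.items():
            lines.append(
                f"  {k:14s} bias {v['bias']:+.4f}  rmse {v['rmse']:.4f}  "
                f"95% coverage {v['coverage']:.3f} (n={v['n']})"
            )
        return "\n".join(lines)


_SCOREABLE = ("alpha0", "alpha1", "beta0", "kernel_scale", "P_tilde",
              "omega", "Omega", "rho", "theta", "data_sigma")


def _truth_vector(name: str, truth_params: dict, populations) -> np.ndarray | None:
    if name == "alpha0" and "alpha" in truth_params:
        return np.array([truth_params["alpha"][p][0] for p in populations])
    if name == "alpha1" and "alpha" in truth_params:
        return np.array([truth_params["alpha"][p][1] for p in populations])
    if name == "beta0" and "beta0" in truth_params:
        return np.array([truth_params["beta0"][p] for p in populations])
    if name == "kernel_scale" and "kernel_scale" in truth_params:
        ks = truth_params["kernel_scale"]
        if isinstance(ks, dict):
            return np.array([ks[p] for p in populations])
        return np.full(len(populations), float(ks))
    if name in ("P_tilde", "omega", "Omega") and "logistic" in truth_params:
        j = ("P_tilde", "omega", "Omega").index(name)
        return np.array([truth_params["logistic"][p][j] for p in populations])
    if name in ("rho", "theta") and name in truth_params:
        return np.atleast_1d(float(truth_params[name]))
    return None


def recovery_experiment(
    model: TMMPModel,
    truth_params: dict,
    pattern: MissingnessPattern,
    n_sims: int,
    seed: int = 0,
    covariates=None,
    fit_options: dict | None = None,
) -> RecoveryReport:
    """Generate -> fit -> score, n_sims times.

    Scores bias, RMSE and empirical coverage of central 95% credible
    intervals for every truth parameter the posterior reports.  Fits whose
    worst split-Rhat exceeds 1.1 are counted (never silently dropped).
    """
    from .inference import diagnose, fit

    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    fit_options = dict(fit_options or {})
    errors: dict[str, list] = {}
    covered: dict[str, list] = {}
    post_sds: dict[str, list] = {}
    n_flagged = 0
    sim_seeds = np.random.SeedSequence(seed).spawn(n_sims)
    for si, s in enumerate(sim_seeds):
        data_seed, fit_seed = [int(x.generate_state(1)[0]) % 2**31
                               for x in s.spawn(2)]
        table, truth = generate(model, truth_params, pattern, seed=data_seed,
                                covariates=covariates)
        opts = dict(fit_options)
        opts["seed"] = fit_seed
        post = fit(model, table, covariates=covariates, options=opts)
        if post.n_chains >= 2:
            diag = diagnose(post)
            if diag.max_rhat > 1.1:
                n_flagged += 1
        for name in _SCOREABLE:
            tv = _truth_vector(name, truth_params, model.populations)
            if tv is None or name not in post.draws:
                continue
            draws = post.get(name)
            draws = draws.reshape(draws.shape[0], -1)
            mean = draws.mean(axis=0)
            lo = np.quantile(draws, 0.025, axis=0)
            hi = np.quantile(draws, 0.975, axis=0)
            m = min(len(tv), draws.shape[1])
            errors.setdefault(name, []).extend((mean[:m] - tv[:m]).tolist())
            covered.setdefault(name, []).extend(
                ((lo[:m] <= tv[:m]) & (tv[:m] <= hi[:m])).tolist()
            )
            post_sds.setdefault(name, []).extend(draws.std(axis=0)[:m].tolist())
    scores = {}
    mean_sd = {}
    for name, errs in errors.items():
        errs = np.asarray(errs)
        cov = np.asarray(covered[name], dtype=float)
        n = len(errs)
        scores[name] = {
            "bias": float(errs.mean()),
            "rmse": float(np.sqrt(np.mean(errs**2))),
            "coverage": float(cov.mean()),
            "n": n,
            "mc_se_coverage": float(np.sqrt(cov.mean() * (1 - cov.mean()) / n))
            if n else np.nan,
        }
        mean_sd[name] = float(np.mean(post_sds[name]))
    return RecoveryReport(scores=scores, n_sims=n_sims, n_flagged=n_flagged,
                          mean_posterior_sd=mean_sd)
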