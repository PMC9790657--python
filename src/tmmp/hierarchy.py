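"""Parameter-estimation strategies: fixed values, priors, hierarchies.

A population-level parameter gamma_c can be

- fixed to a known value (with a provenance note),
- given a prior distribution directly, or
- modelled hierarchically: gamma_c ~ pi(gamma_c | gamma_{group}, sigma^2),
  recursively up to a world level, so information is shared between
  populations through group means.

An optional bounding transform maps an unconstrained parameter into
(lo, hi) via a scaled inverse-logit before the hierarchy applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import expit, logit

__all__ = [
    "bounded_transform",
    "inverse_bounded_transform",
    "HierarchySpec",
    "build_hierarchy",
    "default_prior_logpdf",
]


def bounded_transform(x_star, lo: float, hi: float):
    """lo + (hi - lo) * expit(x*); strictly monotone onto (lo, hi)."""
    if not lo < hi:
        raise ValueError("require lo < hi")
    out = lo + (hi - lo) * expit(np.asarray(x_star, dtype=float))
    return float(out) if np.ndim(x_star) == 0 else out


def inverse_bounded_transform(x, lo: float, hi: float):
    if not lo < hi:
        raise ValueError("require lo < hi")
    out = logit((np.asarray(x, dtype=float) - lo) / (hi - lo))
    return float(out) if np.ndim(x) == 0 else out


def default_prior_logpdf(kind: str, value, scale: float | None = None) -> float:
    """Default vague priors used when a configuration does not override them.

    Locations (transformed scale): Normal(0, 10^2).  Scales: Half-Normal
    with sd 5.  Correlations rho: Uniform(0, 1).  Moving-average theta:
    Uniform(-1, 0).
    """
    value = np.asarray(value, dtype=float)
    if kind == "location":
        s = 10.0 if scale is None else scale
        return float(np.sum(stats.norm.logpdf(value, 0.0, s)))
    if kind == "scale":
        s = 5.0 if scale is None else scale
        if np.any(value <= 0):
            return -np.inf
        return float(np.sum(stats.halfnorm.logpdf(value, scale=s)))
    if kind == "rho":
        return 0.0 if np.all((0 <= value) & (value < 1)) else -np.inf
    if kind == "theta":
        return 0.0 if np.all((-1 <= value) & (value <= 0)) else -np.inf
    raise ValueError(f"unknown default prior kind {kind!r}")


@dataclass(frozen=True)
class HierarchySpec:
    """Estimation strategy for one named parameter.

    ``strategy``: 'fixed', 'prior' or 'hierarchical'.

    - fixed: ``value`` (and optional ``source_note`` recording provenance).
    - prior: ``distribution`` ('normal', 'halfnormal', 'uniform',
      'truncated_normal') with ``params``.
    - hierarchical: ``levels`` grouping maps, population -> group label,
      ordered from the finest level upward (the last level groups into a
      single world unit); ``pi`` is the level distribution ('normal' or
      'truncated_normal' with ``truncation`` bounds); per-level scale
      priors default to Half-Normal(5).
    """

    name: str
    strategy: str
    value: float | None = None
    source_note: str | None = None
    distribution: str = "normal"
    params: dict = field(default_factory=dict)
    levels: tuple = ()  # tuple of dicts: unit -> parent label
    pi: str = "normal"
    truncation: tuple | None = None
    bounds: tuple | None = None  # (lo, hi) bounding transform

    def __post_init__(self):
        if self.strategy not in ("fixed", "prior", "hierarchical"):
            raise ValueError("strategy must be fixed, prior or hierarchical")
        if self.strategy == "fixed" and self.value is None:
            raise ValueError("fixed strategy requires a value")
        if self.strategy == "hierarchical" and len(self.levels) < 1:
            raise ValueError("hierarchical strategy requires >= 1 level")
        if self.bounds is not None and not self.bounds[0] < self.bounds[1]:
            raise ValueError("bounds must satisfy lo < hi")


def _level_logpdf(pi: str, x, mean, sd, truncation=None) -> float:
    x = np.asarray(x, dtype=float)
    if sd <= 0:
        return -np.inf
    if pi == "normal":
        return float(np.sum(stats.norm.logpdf(x, mean, sd)))
    if pi == "truncated_normal":
        lo, hi = truncation
        a, b = (lo - mean) / sd, (hi - mean) / sd
        return float(np.sum(stats.truncnorm.logpdf(x, a, b, loc=mean, scale=sd)))
    raise ValueError(f"unknown hierarchy distribution {pi!r}")


def build_hierarchy(spec: HierarchySpec, populations: list[str]):
    """Return a log-density function for the hierarchy's contribution.

    The returned callable takes a dict of arrays keyed by level:
    ``values[0]`` are the population-level parameters ordered like
    ``populations``; ``values[l]`` (l >= 1) the group-level means for
    level l (ordered by sorted group label); ``scales[l]`` the level-l
    sd.  The top-level mean gets the default vague location prior and each
    scale the default half-normal prior (overridable via spec.params).

    With one level and a normal pi, this reduces to
    gamma_c ~ N(gamma_world, sigma^2) for every population.
    """
    if spec.strategy != "hierarchical":
        raise ValueError("build_hierarchy applies to hierarchical strategies")

    # resolve the chain of group labels per level
    level_units: list[list[str]] = [list(populations)]
    for lvl, mapping in enumerate(spec.levels):
        units = level_units[-1]
        missing = [u for u in units if u not in mapping]
        if missing:
            raise ValueError(
                f"grouping map for level {lvl + 1} of {spec.name!r} is missing "
                f"unit {missing[0]!r}"
            )
        parents = sorted(set(mapping[u] for u in units))
        level_units.append(parents)

    n_levels = len(spec.levels)

    def logpdf(values: dict, scales: dict) -> float:
        total = 0.0
        for lvl in range(n_levels):
            mapping = spec.levels[lvl]
            units = level_units[lvl]
            parents = level_units[lvl + 1]
            parent_idx = {p: i for i, p in enumerate(parents)}
            x = np.asarray(values[lvl], dtype=float)
            mu_parent = np.asarray(values[lvl + 1], dtype=float)
            if len(x) != len(units):
                raise ValueError(
                    f"level {lvl} of {spec.name!r} expects {len(units)} values"
                )
            means = mu_parent[[parent_idx[mapping[u]] for u in units]]
            sd = float(scales[lvl + 1])
            for xi, mi in zip(x, means):
                total += _level_logpdf(spec.pi, xi, mi, sd, spec.truncation)
            total += default_prior_logpdf(
                "scale", sd, spec.params.get("scale_sd")
            )
        # vague prior on the top-level mean(s)
        total += default_prior_logpdf(
            "location",
            np.asarray(values[n_levels], dtype=float),
            spec.params.get("location_sd"),
        )
        return total

    logpdf.level_units = level_units
    return logpdf
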