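"""Data models: per-record log-likelihood contributions pi(y | eta, theta_d).

Observations are conditionally independent given the latent field.  Four
families are supported:

- ``normal``: y_i ~ N(eta_{c,t}, s_i^2) on the indicator's natural scale;
- ``logit_normal``: logit(y_i) ~ N(logit(eta_{c,t}), s_i^2), y_i in (0,1);
- ``binomial``: y_i ~ Binom(n_i, eta_{c,t});
- ``negative_binomial``: mean n_i * eta_{c,t}, overdispersion phi with
  variance mean * (1 + mean / phi)  (NB2 parametrization; the variance
  collapses to the Poisson limit as phi -> infinity).

Variances may come from a per-record ``sampling_sd`` column (fixed s_i),
or be estimated -- one sigma per source label or one global sigma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import logit

__all__ = ["DataModelSpec", "loglik", "total_loglik", "FAMILIES"]

FAMILIES = ("normal", "logit_normal", "binomial", "negative_binomial")


class SupportError(ValueError):
    """Observation or latent value outside the family's support."""


@dataclass(frozen=True)
class DataModelSpec:
    """Family plus variance/overdispersion handling.

    ``variance``: 'fixed' (use each record's sampling_sd), 'per_source'
    (one estimated sigma per source label) or 'global'.  ``sigma`` maps a
    source label (or '_global') to its sd -- during inference these are
    free parameters; for likelihood evaluation they must be supplied.
    ``phi`` is the negative-binomial overdispersion.
    """

    family: str
    variance: str = "fixed"
    sigma: dict = field(default_factory=dict)
    phi: float | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown data model {self.family!r}; choose from {FAMILIES}"
            )
        if self.variance not in ("fixed", "per_source", "global"):
            raise ValueError("variance must be fixed, per_source or global")

    def record_sd(self, sampling_sd, source) -> float:
        if self.variance == "fixed":
            if sampling_sd is None or not np.isfinite(sampling_sd):
                raise ValueError(
                    "variance='fixed' requires a sampling_sd on every record"
                )
            return float(sampling_sd)
        if self.variance == "per_source":
            if sampling_sd is not None and np.isfinite(sampling_sd or np.nan):
                return float(sampling_sd)
            try:
                return float(self.sigma[source])
            except KeyError:
                raise ValueError(f"no sigma supplied for source {source!r}")
        return float(self.sigma["_global"])


def _check_unit_interval(x, what):
    if not (0.0 < x < 1.0):
        raise SupportError(f"{what} = {x} outside (0, 1)")


def loglik(
    y: float,
    eta_ct: float,
    spec: DataModelSpec,
    sampling_sd: float | None = None,
    source: str | None = None,
    n: int | None = None,
) -> float:
    """Exact log-density / log-mass of one observation given eta_{c,t}."""
    f = spec.family
    if f == "normal":
        sd = spec.record_sd(sampling_sd, source)
        return float(stats.norm.logpdf(y, loc=eta_ct, scale=sd))
    if f == "logit_normal":
        _check_unit_interval(y, "observation")
        _check_unit_interval(eta_ct, "eta")
        sd = spec.record_sd(sampling_sd, source)
        core = stats.norm.logpdf(logit(y), loc=logit(eta_ct), scale=sd)
        jacobian = -np.log(y * (1.0 - y))
        return float(core + jacobian)
    if f == "binomial":
        _check_unit_interval(eta_ct, "eta")
        if n is None:
            raise ValueError("binomial data model requires a denominator n")
        return float(stats.binom.logpmf(y, n, eta_ct))
    # negative binomial: mean m = n * eta, var m (1 + m / phi)
    if n is None:
        raise ValueError("negative binomial data model requires a denominator n")
    if spec.phi is None or spec.phi <= 0:
        raise ValueError("negative binomial requires overdispersion phi > 0")
    if eta_ct <= 0:
        raise SupportError(f"eta = {eta_ct} must be > 0 for negative binomial")
    m = n * eta_ct
    # scipy's nbinom(r, p): mean r(1-p)/p -> r = phi, p = phi/(phi+m)
    return float(stats.nbinom.logpmf(y, spec.phi, spec.phi / (spec.phi + m)))


def total_loglik(table, eta: np.ndarray, spec: DataModelSpec) -> float:
    """Sum of per-record contributions over an ObservationTable.

    ``eta`` is the latent field, shape (C, T), with rows ordered like
    ``table.populations``.
    """
    df = table.frame
    pop_index = {p: i for i, p in enumerate(table.populations)}
    total = 0.0
    for row in df.itertuples(index=False):
        c = pop_index[row.population]
        t = int(row.time) - 1
        sd = getattr(row, "sampling_sd", None)
        if sd is not None and not np.isfinite(sd):
            sd = None
        nn = getattr(row, "denominator", None)
        if nn is not None and (nn is np.nan or not np.isfinite(nn)):
            nn = None
        total += loglik(
            row.value,
            float(eta[c, t]),
            spec,
            sampling_sd=sd,
            source=getattr(row, "source", None),
            n=None if nn is None else int(nn),
        )
    return total
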