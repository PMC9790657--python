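"""Process-model components.

The process model for the latent indicator eta_{c,t} is additive on a
transformed scale:

    g1(eta_{c,t}) = g2(X_{c,t}, beta) + g3(t, eta, alpha) + a_{c,t} + eps_{c,t}

with a transformation g1, a covariate component g2, a parametric
systematic component g3, a fixed offset a and the stochastic smoothing
deviation eps.  All components here are pure functions; assembly inverts
g1 elementwise, except for recursive systematic components (the logistic
transition), which are propagated outward from a reference year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

__all__ = [
    "TransformSpec",
    "TRANSFORMS",
    "transform",
    "inverse_transform",
    "covariate_linear",
    "covariate_gbd",
    "covariate_piecewise_nmr",
    "systematic_linear",
    "systematic_logistic_step",
    "systematic_logistic_back_step",
    "logistic_path",
    "systematic_trapezoid",
    "assemble_eta",
]


class DomainError(ValueError):
    """Argument outside the mathematical domain of a component."""


@dataclass(frozen=True)
class TransformSpec:
    name: str

    def __post_init__(self):
        if self.name not in TRANSFORMS:
            raise ValueError(
                f"unknown transform {self.name!r}; choose from {sorted(TRANSFORMS)}"
            )

    def forward(self, x):
        return transform(x, self)

    def inverse(self, z):
        return inverse_transform(z, self)


_LN10 = np.log(10.0)

TRANSFORMS = {
    "identity": (lambda x: x, lambda z: z, (-np.inf, np.inf)),
    "log": (np.log, np.exp, (0.0, np.inf)),
    "log10": (np.log10, lambda z: np.power(10.0, z), (0.0, np.inf)),
    "logit": (logit, expit, (0.0, 1.0)),
}


def _check_domain(x, name):
    lo, hi = TRANSFORMS[name][2]
    x = np.asarray(x, dtype=float)
    if np.any(x <= lo) or np.any(x >= hi):
        raise DomainError(
            f"value outside the open domain ({lo}, {hi}) of transform {name!r}"
        )


def transform(x, spec: TransformSpec):
    """Apply g1; raises DomainError outside the open domain (no clamping)."""
    _check_domain(x, spec.name)
    out = TRANSFORMS[spec.name][0](np.asarray(x, dtype=float))
    return float(out) if np.ndim(x) == 0 else out


def inverse_transform(z, spec: TransformSpec):
    # overflow to inf is deliberate here: extreme prior-predictive values
    # are representable and handled by downstream domain checks
    with np.errstate(over="ignore"):
        out = TRANSFORMS[spec.name][1](np.asarray(z, dtype=float))
    return float(out) if np.ndim(z) == 0 else out


# ---------------------------------------------------------------------------
# covariate components
# ---------------------------------------------------------------------------

def covariate_linear(X_row, beta0: float, beta) -> float:
    """beta_{c,0} + sum_k X_k beta_k."""
    X_row = np.atleast_1d(np.asarray(X_row, dtype=float))
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    if X_row.shape[-1] != beta.shape[-1]:
        raise ValueError(
            f"covariate row has {X_row.shape[-1]} columns but "
            f"{beta.shape[-1]} slopes were given"
        )
    return beta0 + X_row @ beta


def covariate_gbd(LDI, EDU, HIV, beta) -> float:
    """log10(exp[b1 log(LDI) + b2 EDU + b3] + b4 HIV)."""
    b1, b2, b3, b4 = np.asarray(beta, dtype=float)
    LDI = np.asarray(LDI, dtype=float)
    if np.any(LDI <= 0):
        raise DomainError("LDI must be > 0")
    inner = np.exp(b1 * np.log(LDI) + b2 * np.asarray(EDU, float) + b3)
    total = inner + b4 * np.asarray(HIV, float)
    if np.any(total <= 0):
        raise DomainError("argument of log10 in the GBD covariate function is <= 0")
    out = np.log10(total)
    return float(out) if np.ndim(out) == 0 else out


def covariate_piecewise_nmr(U5MR, beta0_c: float, beta1: float, beta2: float):
    """beta_{c,0} + beta1 (log U5MR - log beta2) 1[U5MR > beta2].

    Continuous at the change point beta2; constant below it.
    """
    if beta2 <= 0:
        raise DomainError("beta2 (the U5MR cut-off) must be > 0")
    U5MR = np.asarray(U5MR, dtype=float)
    if np.any(U5MR <= 0):
        raise DomainError("U5MR must be > 0")
    out = beta0_c + beta1 * (np.log(U5MR) - np.log(beta2)) * (U5MR > beta2)
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# systematic components
# ---------------------------------------------------------------------------

def systematic_linear(t, alpha0: float, alpha1: float, t_star: float):
    """Population-specific line alpha0 + alpha1 (t - t*)."""
    out = alpha0 + alpha1 * (np.asarray(t, dtype=float) - t_star)
    return float(out) if np.ndim(t) == 0 else out


def systematic_logistic_step(eta_prev: float, P_tilde: float, omega: float) -> float:
    """One forward step of the logistic transition, on the logit scale.

    While eta_{t-1} < P_tilde the indicator moves along a logistic curve
    with asymptote P_tilde: eta_t = P_tilde * expit(logit(eta_{t-1} /
    P_tilde) + omega).  Once at or above the asymptote, the level is
    carried over unchanged.  Returns logit(eta_t).
    """
    if not (0.0 < P_tilde <= 1.0):
        raise DomainError("P_tilde must lie in (0, 1]")
    if not (0.0 < eta_prev < 1.0):
        raise DomainError("eta_prev must lie in (0, 1)")
    if eta_prev >= P_tilde:
        return float(logit(eta_prev))
    z = logit(eta_prev / P_tilde)
    return float(logit(P_tilde * expit(z + omega)))


def systematic_logistic_back_step(eta_next: float, P_tilde: float, omega: float) -> float:
    """Exact inverse of the forward logistic step: logit(eta_{t-1}) given eta_t."""
    if not (0.0 < P_tilde <= 1.0):
        raise DomainError("P_tilde must lie in (0, 1]")
    if not (0.0 < eta_next < 1.0):
        raise DomainError("eta_next must lie in (0, 1)")
    if eta_next >= P_tilde:
        return float(logit(eta_next))
    z = logit(eta_next / P_tilde)
    return float(logit(P_tilde * expit(z - omega)))


def logistic_path(
    T: int,
    t_star: int,
    Omega: float,
    P_tilde: float,
    omega: float,
    eps: np.ndarray | None = None,
    include_eps_in_recursion: bool = True,
) -> np.ndarray:
    """Transformed-scale path of the logistic transition over t = 1..T.

    The level at the reference year t* is Omega (on the logit scale); the
    transition is propagated forward and backward from t*.  If ``eps`` is
    given, deviations are added at every step; by default the recursion
    sees the previous step's level including its deviation, so the
    smoothing terms act on the rate of change and accumulate over time.
    Returns the logit-scale path (g3 + eps).
    """
    if not 1 <= t_star <= T:
        raise ValueError("t_star must lie on the grid 1..T")
    if eps is None:
        eps = np.zeros(T)
    eps = np.asarray(eps, dtype=float)
    path = np.empty(T)
    i_star = t_star - 1
    path[i_star] = Omega + eps[i_star]
    g3_prev = Omega
    for i in range(i_star + 1, T):
        prev = path[i - 1] if include_eps_in_recursion else g3_prev
        g3 = systematic_logistic_step(float(expit(prev)), P_tilde, omega)
        path[i] = g3 + eps[i]
        g3_prev = g3
    g3_next = Omega
    for i in range(i_star - 1, -1, -1):
        nxt = path[i + 1] if include_eps_in_recursion else g3_next
        g3 = systematic_logistic_back_step(float(expit(nxt)), P_tilde, omega)
        path[i] = g3 + eps[i]
        g3_next = g3
    return path


def systematic_trapezoid(
    t, xi: float, gamma0: float, lambda1: float, lambda2: float, lambda3: float
):
    """Trapezoid: rise 0 -> xi over (g0, g1), plateau, fall back to 0.

    Change points are g1 = g0 + lambda1, g2 = g1 + lambda2,
    g3 = g2 + lambda3; zero outside (g0, g3).
    """
    if min(lambda1, lambda2, lambda3) <= 0:
        raise DomainError("trapezoid durations lambda_j must be > 0")
    g1 = gamma0 + lambda1
    g2 = g1 + lambda2
    g3 = g2 + lambda3
    t = np.asarray(t, dtype=float)
    out = np.select(
        [
            (t > gamma0) & (t < g1),
            (t >= g1) & (t <= g2),
            (t > g2) & (t < g3),
        ],
        [
            xi * (t - gamma0) / lambda1,
            np.full_like(t, xi, dtype=float),
            xi - xi * (t - g2) / lambda3,
        ],
        default=0.0,
    )
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def assemble_eta(
    transform_spec: TransformSpec,
    covariate_term: np.ndarray | float = 0.0,
    systematic_term: np.ndarray | float = 0.0,
    offset_term: np.ndarray | float = 0.0,
    epsilon: np.ndarray | float = 0.0,
) -> np.ndarray:
    """eta = g1^{-1}(g2 + g3 + a + eps), elementwise.

    All terms live on the transformed scale and broadcasting applies.  For
    the recursive logistic component use :func:`logistic_path` to produce
    the combined (g3 + eps) path and pass it as ``systematic_term`` with
    ``epsilon=0``.
    """
    z = (
        np.asarray(covariate_term, dtype=float)
        + np.asarray(systematic_term, dtype=float)
        + np.asarray(offset_term, dtype=float)
        + np.asarray(epsilon, dtype=float)
    )
    if not np.all(np.isfinite(z)):
        bad = np.argwhere(~np.isfinite(np.atleast_1d(z)))
        raise DomainError(f"non-finite transformed value at index {bad[0]}")
    return inverse_transform(z, transform_spec)
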