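"""Stochastic smoothing components: epsilon_c = B_c delta_c.

The smoothing model places a zero-mean multivariate normal distribution on
the r-th order differences of the coefficient vector delta_c,

    diff^r(delta_c) ~ N(0, Sigma_c),

where Sigma_c is a stationary covariance built from an autocovariance
kernel s(|t1 - t2|, kappa).  For r > 0 the model is made generative by
anchoring constraints that pin down the null space of the differencing
operator (e.g. a sum-to-zero constraint on the coefficients, or a
reference coefficient fixed at zero).

Bases B_c are either the identity (the deviations live directly on the
time grid) or cubic B-splines on an evenly spaced knot grid, in which case
delta_c are spline coefficients and the kernel distance is measured in
coefficient-index units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, special
from scipy.interpolate import BSpline

__all__ = [
    "KernelSpec",
    "BasisSpec",
    "SmoothingSpec",
    "GaussianConditional",
    "autocovariance",
    "build_covariance",
    "difference_matrix",
    "recover_levels",
    "recovery_matrix",
    "build_basis",
    "basis_size",
    "sample_smoothing",
    "condition_projection",
    "extend_levels",
]

KERNEL_FAMILIES = ("ar1", "squared_exponential", "matern", "arma11", "iid")


class NumericalError(RuntimeError):
    """A covariance factorization failed beyond the jitter policy."""


@dataclass(frozen=True)
class KernelSpec:
    """Stationary autocovariance kernel s(h, kappa).

    Hyperparameters by family:

    - ``ar1``: ``kappa`` (marginal sd), ``rho`` in [0, 1)
    - ``squared_exponential``: ``kappa`` (marginal sd), ``ell`` > 0
    - ``matern``: ``kappa``, ``ell`` > 0, ``nu`` > 0
    - ``arma11``: ``sigma`` (stationary sd), ``rho`` in [0, 1],
      ``theta`` in [-1, 0]
    - ``iid``: ``sigma`` > 0
    """

    family: str
    kappa: float | None = None
    rho: float | None = None
    ell: float | None = None
    nu: float | None = None
    theta: float | None = None
    sigma: float | None = None

    def __post_init__(self):
        if self.family not in KERNEL_FAMILIES:
            raise ValueError(
                f"unknown kernel family {self.family!r}; "
                f"choose one of {KERNEL_FAMILIES}"
            )
        required = {
            "ar1": ("kappa", "rho"),
            "squared_exponential": ("kappa", "ell"),
            "matern": ("kappa", "ell", "nu"),
            "arma11": ("sigma", "rho", "theta"),
            "iid": ("sigma",),
        }[self.family]
        missing = [p for p in required if getattr(self, p) is None]
        if missing:
            raise ValueError(
                f"kernel {self.family!r} requires hyperparameters {required}; "
                f"missing {missing}"
            )
        self._validate()

    def _validate(self):
        f = self.family
        if f == "ar1":
            if self.kappa <= 0:
                raise ValueError("ar1: kappa must be > 0")
            if not (0 <= self.rho < 1):
                raise ValueError("ar1: rho must be in [0, 1)")
        elif f == "squared_exponential":
            if self.kappa <= 0 or self.ell <= 0:
                raise ValueError("squared_exponential: kappa, ell must be > 0")
        elif f == "matern":
            if self.kappa <= 0 or self.ell <= 0 or self.nu <= 0:
                raise ValueError("matern: kappa, ell, nu must be > 0")
        elif f == "arma11":
            if self.sigma <= 0:
                raise ValueError("arma11: sigma must be > 0")
            if not (0 <= self.rho <= 1):
                raise ValueError("arma11: rho must be in [0, 1]")
            if not (-1 <= self.theta <= 0):
                raise ValueError("arma11: theta must be in [-1, 0]")
        elif f == "iid":
            if self.sigma <= 0:
                raise ValueError("iid: sigma must be > 0")

    def replace(self, **kwargs) -> "KernelSpec":
        from dataclasses import replace as _replace

        return _replace(self, **kwargs)


def _matern(h: np.ndarray, kappa: float, ell: float, nu: float) -> np.ndarray:
    h = np.asarray(h, dtype=float)
    out = np.full(h.shape, float(kappa) ** 2)
    pos = h > 0
    if not np.any(pos):
        return out
    x = np.sqrt(2.0 * nu) * h[pos] / ell
    if nu == 0.5:
        out[pos] = kappa**2 * np.exp(-h[pos] / ell)
    elif nu == 1.5:
        s3 = np.sqrt(3.0) * h[pos] / ell
        out[pos] = kappa**2 * (1.0 + s3) * np.exp(-s3)
    elif nu == 2.5:
        s5 = np.sqrt(5.0) * h[pos] / ell
        out[pos] = kappa**2 * (1.0 + s5 + s5**2 / 3.0) * np.exp(-s5)
    else:
        out[pos] = (
            kappa**2
            * (2.0 ** (1.0 - nu) / special.gamma(nu))
            * x**nu
            * special.kv(nu, x)
        )
    return out


def _arma11(h: np.ndarray, sigma: float, rho: float, theta: float) -> np.ndarray:
    # Stationary ARMA(1,1) autocovariance, scaled so that s(0) = sigma^2.
    # With innovation variance v: gamma0 = v (1 + 2 rho theta + theta^2)/(1-rho^2)
    # and gamma(h) = rho^(h-1) * v (1 + rho theta)(rho + theta)/(1-rho^2), h >= 1.
    h = np.asarray(h, dtype=float)
    out = np.full(h.shape, float(sigma) ** 2)
    pos = h > 0
    if np.any(pos):
        denom = 1.0 + 2.0 * rho * theta + theta**2
        if denom <= 0:  # rho=0, theta=-1 degenerate corner
            out[pos] = 0.0
        else:
            c1 = (1.0 + rho * theta) * (rho + theta) / denom
            out[pos] = sigma**2 * c1 * rho ** (h[pos] - 1.0)
    return out


def autocovariance(kernel: KernelSpec, lag) -> np.ndarray | float:
    """Evaluate s(|lag|, kappa) for the kernel; accepts scalars or arrays."""
    h = np.abs(np.asarray(lag, dtype=float))
    f = kernel.family
    if f == "ar1":
        out = kernel.kappa**2 * kernel.rho**h
    elif f == "squared_exponential":
        out = kernel.kappa**2 * np.exp(-(h**2) / (2.0 * kernel.ell**2))
    elif f == "matern":
        out = _matern(h, kernel.kappa, kernel.ell, kernel.nu)
    elif f == "arma11":
        out = _arma11(h, kernel.sigma, kernel.rho, kernel.theta)
    elif f == "iid":
        out = np.where(h == 0, kernel.sigma**2, 0.0)
    if np.isscalar(lag) or np.ndim(lag) == 0:
        return float(out)
    return out


def build_covariance(kernel: KernelSpec, n: int) -> np.ndarray:
    """Toeplitz covariance Sigma[i, j] = s(|i - j|, kappa), shape (n, n).

    A single jitter of 1e-10 * s(0) is added to the diagonal before any
    factorization downstream; the returned matrix includes the jitter.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    acf = np.asarray(autocovariance(kernel, np.arange(n)), dtype=float)
    if n == 1:
        acf = np.atleast_1d(acf)
    sigma = linalg.toeplitz(acf)
    sigma[np.diag_indices_from(sigma)] += 1e-10 * acf.flat[0]
    return sigma


def _chol(sigma: np.ndarray) -> np.ndarray:
    try:
        return linalg.cholesky(sigma, lower=True)
    except linalg.LinAlgError:
        w = linalg.eigvalsh(sigma)
        raise NumericalError(
            f"covariance not positive definite after jitter; "
            f"smallest eigenvalue {w.min():.3e}"
        )


def difference_matrix(K: int, r: int) -> np.ndarray:
    """(K - r) x K matrix D with D @ delta = diff^r(delta).

    Built as the composition of r first-difference matrices; r = 0 gives
    the K x K identity.
    """
    if not 0 <= r < K:
        raise ValueError(f"require 0 <= r < K, got r={r}, K={K}")
    D = np.eye(K)
    for m in range(K, K - r, -1):
        D1 = np.zeros((m - 1, m))
        idx = np.arange(m - 1)
        D1[idx, idx] = -1.0
        D1[idx, idx + 1] = 1.0
        D = D1 @ D
    return D


def _anchor_vectors(K: int, r: int, anchors: dict[int, list[int]]) -> np.ndarray:
    """Rows c_d with c_d @ delta = sum over K_d of diff^d(delta)."""
    rows = []
    for d in range(r):
        if d not in anchors:
            raise ValueError(f"anchored mode requires an index set for order d={d}")
        Dd = difference_matrix(K, d)
        idx = np.asarray(anchors[d], dtype=int)
        if idx.size == 0:
            raise ValueError(f"anchor set for d={d} is empty")
        if idx.min() < 0 or idx.max() >= K - d:
            raise ValueError(f"anchor indices for d={d} out of range [0, {K - d})")
        rows.append(Dd[idx].sum(axis=0))
    return np.asarray(rows)


def recovery_matrix(
    K: int,
    r: int,
    constraint_mode: str = "minimum_norm",
    anchors: dict[int, list[int]] | None = None,
) -> np.ndarray:
    """Linear map R (K x (K - r)) with delta = R @ gamma.

    ``minimum_norm`` returns the pseudoinverse map D'(DD')^{-1}, whose image
    is orthogonal to the null space of D.  ``anchored`` returns the unique
    solution of D delta = gamma satisfying the anchoring equations
    sum_{k in K_d} diff^d(delta)_k = 0 for 0 <= d <= r - 1, where the index
    sets are 0-based positions into the length-(K - d) differenced vector.
    """
    if r == 0:
        return np.eye(K)
    D = difference_matrix(K, r)
    Rmin = D.T @ linalg.solve(D @ D.T, np.eye(K - r), assume_a="pos")
    if constraint_mode == "minimum_norm":
        return Rmin
    if constraint_mode != "anchored":
        raise ValueError(f"unknown constraint mode {constraint_mode!r}")
    if anchors is None:
        raise ValueError("anchored mode requires anchor index sets")
    # null(D) is spanned by polynomials of degree < r in the index
    k = np.arange(K, dtype=float)
    N = np.vander(k, r, increasing=True)  # K x r
    C = _anchor_vectors(K, r, anchors)  # r x K
    CN = C @ N
    if np.linalg.matrix_rank(CN) < r:
        raise np.linalg.LinAlgError(
            "anchoring constraints do not pin down the null space of D "
            "(rank deficient)"
        )
    # delta = Rmin gamma + N z with C delta = 0  =>  z = -(CN)^{-1} C Rmin gamma
    correction = N @ np.linalg.solve(CN, C @ Rmin)
    return Rmin - correction


def recover_levels(
    gamma: np.ndarray,
    r: int,
    constraint_mode: str = "minimum_norm",
    anchors: dict[int, list[int]] | None = None,
) -> np.ndarray:
    """Recover delta (length K = len(gamma) + r) from gamma = diff^r(delta)."""
    gamma = np.asarray(gamma, dtype=float)
    K = gamma.shape[-1] + r
    R = recovery_matrix(K, r, constraint_mode, anchors)
    return gamma @ R.T


@dataclass(frozen=True)
class BasisSpec:
    """Basis for the deviations: identity or cubic B-splines.

    ``knot_spacing`` is in grid (time) units; exterior knots continue the
    uniform spacing ``degree`` intervals beyond each end of the span, so
    extending the span appends columns without altering existing ones.
    """

    kind: str = "identity"
    degree: int = 3
    knot_spacing: float = 2.5

    def __post_init__(self):
        if self.kind not in ("identity", "bspline"):
            raise ValueError(f"unknown basis kind {self.kind!r}")
        if self.kind == "bspline" and self.knot_spacing <= 0:
            raise ValueError("knot_spacing must be > 0")


def _bspline_knots(span: tuple[float, float], spacing: float, degree: int):
    first, last = float(span[0]), float(span[1])
    if last - first < spacing:
        raise ValueError(
            f"span {span} shorter than one knot interval ({spacing})"
        )
    n_int = int(np.ceil((last - first) / spacing - 1e-9))
    # uniform knots from first - degree*spacing to first + (n_int+degree)*spacing
    return first + spacing * np.arange(-degree, n_int + degree + 1)


def basis_size(basis: BasisSpec, span: tuple[float, float], T: int | None = None) -> int:
    if basis.kind == "identity":
        if T is None:
            raise ValueError("identity basis needs T")
        return T
    knots = _bspline_knots(span, basis.knot_spacing, basis.degree)
    return len(knots) - basis.degree - 1


def build_basis(
    basis: BasisSpec,
    times: np.ndarray,
    span: tuple[float, float] | None = None,
) -> np.ndarray:
    """Basis matrix B (T x K) evaluated at the given grid times.

    For B-splines the knots cover ``span`` (default: the range of
    ``times``); rows at times inside the span sum to one.  Times outside
    the span get zero rows (no deviations are modelled there).
    """
    times = np.asarray(times, dtype=float)
    T = times.size
    if basis.kind == "identity":
        return np.eye(T)
    if span is None:
        span = (times.min(), times.max())
    knots = _bspline_knots(span, basis.knot_spacing, basis.degree)
    K = len(knots) - basis.degree - 1
    lo, hi = knots[basis.degree], knots[-basis.degree - 1]
    inside = (times >= lo - 1e-12) & (times <= hi + 1e-12)
    B = np.zeros((T, K))
    if np.any(inside):
        t_in = np.clip(times[inside], lo, hi)
        B[inside] = BSpline.design_matrix(
            t_in, knots, basis.degree
        ).toarray()
    return B


@dataclass(frozen=True)
class SmoothingSpec:
    """Complete smoothing-component specification.

    ``r`` is the differencing order (0, 1 or 2); for r > 0 a constraint
    mode is required to anchor the level (``minimum_norm`` or ``anchored``
    with explicit index sets per difference order).
    """

    basis: BasisSpec
    kernel: KernelSpec
    r: int = 0
    constraint_mode: str = "none"
    anchors: dict | None = None

    def __post_init__(self):
        if self.r not in (0, 1, 2):
            raise ValueError("r must be 0, 1 or 2")
        if self.r == 0 and self.constraint_mode != "none":
            raise ValueError("r = 0 admits no constraints (mode must be 'none')")
        if self.r > 0 and self.constraint_mode not in ("minimum_norm", "anchored"):
            raise ValueError(
                "r > 0 requires constraint_mode 'minimum_norm' or 'anchored'"
            )
        if self.constraint_mode == "anchored" and not self.anchors:
            raise ValueError("anchored mode requires anchor index sets")


def sample_smoothing(
    spec: SmoothingSpec,
    times: np.ndarray,
    n_draws: int,
    seed: int | np.random.Generator,
    span: tuple[float, float] | None = None,
) -> np.ndarray:
    """Draw epsilon paths (n_draws x T) from the smoothing model.

    gamma = diff^r(delta) is drawn from N(0, Sigma) and levels are
    recovered through the declared constraint mode, so every draw satisfies
    the anchoring constraints exactly.
    """
    times = np.asarray(times, dtype=float)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    B = build_basis(spec.basis, times, span=span)
    K = B.shape[1]
    m = K - spec.r
    if m < 1:
        raise ValueError("differencing order leaves no free coefficients")
    if n_draws == 0:
        return np.empty((0, times.size))
    sigma = build_covariance(spec.kernel, m)
    L = _chol(sigma)
    gamma = rng.standard_normal((n_draws, m)) @ L.T
    if spec.r == 0:
        delta = gamma
    else:
        R = recovery_matrix(K, spec.r, spec.constraint_mode, spec.anchors)
        delta = gamma @ R.T
    return delta @ B.T


@dataclass
class GaussianConditional:
    """Gaussian conditional law N(mean, cov) with a sampling helper."""

    mean: np.ndarray
    cov: np.ndarray
    _chol: np.ndarray = field(default=None, repr=False)

    def sample(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        if self._chol is None:
            cov = self.cov + 1e-12 * np.eye(len(self.mean)) * max(
                np.trace(self.cov) / max(len(self.mean), 1), 1.0
            )
            self._chol = _chol(cov)
        z = rng.standard_normal((n, len(self.mean)))
        return self.mean + z @ self._chol.T


def condition_projection(
    kernel: KernelSpec,
    gamma_obs: np.ndarray,
    K_added: int,
) -> GaussianConditional:
    """Conditional law of the next K_added differenced coefficients.

    The joint vector (gamma_obs, gamma_new) is N(0, Sigma*) with Sigma*
    built from the kernel; the returned law is gamma_new | gamma_obs by
    standard Gaussian conditioning.
    """
    gamma_obs = np.asarray(gamma_obs, dtype=float)
    m = gamma_obs.size
    if K_added < 1:
        raise ValueError("K_added must be >= 1")
    n = m + K_added
    sigma = build_covariance(kernel, n)
    s11 = sigma[:m, :m]
    s12 = sigma[:m, m:]
    s22 = sigma[m:, m:]
    if m == 0:
        return GaussianConditional(np.zeros(K_added), s22)
    try:
        sol = linalg.solve(s11, s12, assume_a="pos")
    except linalg.LinAlgError as e:
        raise NumericalError(f"singular conditioning block: {e}")
    mean = gamma_obs @ sol
    cov = s22 - s12.T @ sol
    return GaussianConditional(mean, cov)


def extend_levels(delta: np.ndarray, gamma_new: np.ndarray, r: int) -> np.ndarray:
    """Append new levels implied by new r-th order differences.

    r = 0 appends gamma_new directly; r = 1 cumulates; r = 2 continues the
    local linear trend plus the new second differences.
    """
    delta = np.asarray(delta, dtype=float)
    gamma_new = np.atleast_1d(np.asarray(gamma_new, dtype=float))
    if r == 0:
        return np.concatenate([delta, gamma_new])
    if delta.size < r:
        raise ValueError(f"need at least r={r} existing levels")
    out = list(delta)
    for g in gamma_new:
        if r == 1:
            out.append(out[-1] + g)
        elif r == 2:
            out.append(2.0 * out[-1] - out[-2] + g)
        else:
            raise ValueError("r must be 0, 1 or 2")
    return np.asarray(out)
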