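"""Tables and model configuration.

Observation, covariate, offset and estimate tables are plain CSV
(comma-separated, UTF-8, '.' decimal, header required).  The time grid is
integer, 1-based and contiguous; calendar years are labels only and are
mapped onto the grid when a table is read.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TimeGrid",
    "ObservationTable",
    "CovariateTable",
    "ModelConfig",
    "SchemaError",
    "read_observations",
    "read_covariates",
    "read_offsets",
    "write_estimates",
    "parse_config",
    "save_config",
]


class SchemaError(ValueError):
    """A table or configuration violates its schema."""


@dataclass(frozen=True)
class TimeGrid:
    """1-based contiguous integer grid: estimation to T, projection to T*."""

    T: int
    T_star: int | None = None
    year_start: int | None = None

    def __post_init__(self):
        object.__setattr__(
            self, "T_star", self.T if self.T_star is None else self.T_star
        )
        if not (1 <= self.T <= self.T_star):
            raise ValueError("require 1 <= T <= T_star")

    @property
    def times(self) -> np.ndarray:
        return np.arange(1, self.T + 1)

    @property
    def times_star(self) -> np.ndarray:
        return np.arange(1, self.T_star + 1)

    def to_index(self, time_value) -> int:
        """Map a calendar year (if the grid is anchored) or index to 1..T*."""
        t = int(time_value)
        if self.year_start is not None and t >= self.year_start:
            t = t - self.year_start + 1
        return t

    def year_label(self, index: int):
        if self.year_start is None:
            return index
        return self.year_start + index - 1


@dataclass
class ObservationTable:
    """Long-format observations with columns population, time, value,
    sampling_sd, source, denominator (the latter three optional)."""

    frame: pd.DataFrame
    grid: TimeGrid

    def __post_init__(self):
        for col in ("sampling_sd", "source", "denominator"):
            if col not in self.frame.columns:
                self.frame[col] = (
                    np.nan if col != "source" else "unknown"
                )
        self.frame["source"] = self.frame["source"].fillna("unknown")

    @property
    def populations(self) -> list[str]:
        return sorted(self.frame["population"].astype(str).unique())

    def __len__(self) -> int:
        return len(self.frame)

    def for_population(self, population: str) -> pd.DataFrame:
        return self.frame[self.frame["population"] == population]


@dataclass
class CovariateTable:
    frame: pd.DataFrame
    grid: TimeGrid

    @property
    def columns(self) -> list[str]:
        return [
            c for c in self.frame.columns if c not in ("population", "time")
        ]

    def matrix(self, population: str, columns: list[str]) -> np.ndarray:
        """(T*, k) covariate values for one population, time-ordered 1..T*."""
        sub = self.frame[self.frame["population"] == population]
        sub = sub.set_index("time").sort_index()
        missing = [t for t in range(1, self.grid.T_star + 1) if t not in sub.index]
        if missing:
            raise SchemaError(
                f"covariates for population {population!r} missing at times "
                f"{missing[:5]} (need complete coverage to T* for projection)"
            )
        return sub.loc[list(range(1, self.grid.T_star + 1)), columns].to_numpy(float)


def read_observations(
    path, grid: TimeGrid, data_model: str | None = None
) -> ObservationTable:
    """Read and validate an observations CSV against the grid.

    Times are mapped to grid indices (calendar years are accepted when the
    grid is anchored); off-grid rows raise.  An empty data section yields
    an empty table -- populations may legitimately have no observations.
    """
    df = pd.read_csv(path)
    required = {"population", "time", "value"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"observations file missing columns {sorted(missing)}")
    if len(df) == 0:
        df = df.reindex(columns=list(df.columns))
        return ObservationTable(df, grid)
    bad = df[~np.isfinite(pd.to_numeric(df["value"], errors="coerce"))]
    if len(bad):
        raise SchemaError(
            f"non-numeric value at row {bad.index[0] + 2} of {path}"
        )
    df["value"] = df["value"].astype(float)
    df["time"] = [grid.to_index(t) for t in df["time"]]
    off = df[(df["time"] < 1) | (df["time"] > grid.T_star)]
    if len(off):
        raise SchemaError(
            f"observation at row {off.index[0] + 2} lies off the grid "
            f"1..{grid.T_star}"
        )
    if data_model in ("logit_normal", "binomial"):
        if data_model == "logit_normal" and (
            (df["value"] <= 0) | (df["value"] >= 1)
        ).any():
            raise SchemaError(
                "logit-normal data model declared but a value lies outside (0, 1)"
            )
    df["population"] = df["population"].astype(str)
    return ObservationTable(df, grid)


def read_covariates(path, grid: TimeGrid) -> CovariateTable:
    df = pd.read_csv(path)
    if not {"population", "time"} <= set(df.columns):
        raise SchemaError("covariates file needs population and time columns")
    df["time"] = [grid.to_index(t) for t in df["time"]]
    df["population"] = df["population"].astype(str)
    return CovariateTable(df, grid)


def read_offsets(path, grid: TimeGrid) -> pd.DataFrame:
    """Offsets a_{c,t} on the transformed scale; columns population,time,offset."""
    df = pd.read_csv(path)
    if not {"population", "time", "offset"} <= set(df.columns):
        raise SchemaError("offsets file needs population, time, offset columns")
    df["time"] = [grid.to_index(t) for t in df["time"]]
    df["population"] = df["population"].astype(str)
    return df


def write_estimates(posterior, path) -> Path:
    """Write population,time,q025,median,q975 of eta on the natural scale."""
    eta = posterior.eta_draws()  # (n_draws, C, T)
    qs = np.quantile(eta, [0.025, 0.5, 0.975], axis=0)
    rows = []
    for ci, pop in enumerate(posterior.populations):
        for ti in range(eta.shape[2]):
            rows.append(
                {
                    "population": pop,
                    "time": ti + 1,
                    "q025": qs[0, ci, ti],
                    "median": qs[1, ci, ti],
                    "q975": qs[2, ci, ti],
                }
            )
    out = pd.DataFrame(rows)
    path = Path(path)
    out.to_csv(path, index=False, float_format="%.12g")
    return path


# ---------------------------------------------------------------------------
# model configuration
# ---------------------------------------------------------------------------

_KERNEL_REQUIRED = {
    "ar1": ["kappa", "rho"],
    "squared_exponential": ["kappa", "ell"],
    "matern": ["kappa", "ell", "nu"],
    "arma11": ["sigma", "rho", "theta"],
    "iid": ["sigma"],
}

_COVARIATE_KINDS = ("none", "linear", "gbd_nonlinear", "piecewise_nmr", "pca_linear")
_SYSTEMATIC_KINDS = ("none", "linear_trend", "logistic_transition", "trapezoid")
_DATA_MODELS = ("normal", "logit_normal", "binomial", "negative_binomial")
_TRANSFORMS = ("identity", "log", "log10", "logit")

_DEFAULTS = {
    "indicator": "indicator",
    "transform": "identity",
    "covariate_component": {"kind": "none", "covariates": []},
    "systematic_component": {"kind": "none"},
    "offset": None,
    "smoothing": {
        "basis": "identity",
        "degree": 3,
        "knot_spacing": 2.5,
        "kernel": "iid",
        "kernel_params": {"sigma": 0.1},
        "r": 0,
        "constraint": "none",
        "anchors": None,
    },
    "data_model": {"family": "normal", "variance": "fixed", "phi": None},
    "hierarchy": {},
    "projection": {"method": "default_conditional", "W": None, "G": None, "V": None},
    "priors": {},
    "inference": {"seed": 0, "chains": 4, "draws": 1000, "warmup": 1000},
}


def _merge_defaults(defaults, given):
    if not isinstance(defaults, dict):
        return copy.deepcopy(defaults) if given is None else given
    out = {}
    given = given or {}
    unknown = set(given) - set(defaults)
    if unknown and defaults is not _DEFAULTS.get("hierarchy"):
        # hierarchy and priors blocks are free-form per parameter name
        pass
    for k, v in defaults.items():
        out[k] = _merge_defaults(v, given.get(k))
    for k in given:
        if k not in out:
            out[k] = copy.deepcopy(given[k])
    return out


@dataclass
class ModelConfig:
    """Fully resolved model configuration (defaults filled).

    The document round-trips losslessly through YAML serialization.
    """

    doc: dict = field(default_factory=dict)

    def __post_init__(self):
        self.doc = _merge_defaults(_DEFAULTS, self.doc)
        self.validate()

    def validate(self):
        d = self.doc
        if d["transform"] not in _TRANSFORMS:
            raise SchemaError(
                f"unknown transform {d['transform']!r}; choose from {_TRANSFORMS}"
            )
        cov = d["covariate_component"]
        if cov["kind"] not in _COVARIATE_KINDS:
            raise SchemaError(
                f"unknown covariate component {cov['kind']!r}; "
                f"choose from {_COVARIATE_KINDS}"
            )
        sysc = d["systematic_component"]
        if sysc["kind"] not in _SYSTEMATIC_KINDS:
            raise SchemaError(
                f"unknown systematic component {sysc['kind']!r}; "
                f"choose from {_SYSTEMATIC_KINDS}"
            )
        sm = d["smoothing"]
        if sm["kernel"] not in _KERNEL_REQUIRED:
            raise SchemaError(
                f"unknown kernel {sm['kernel']!r}; "
                f"choose from {sorted(_KERNEL_REQUIRED)}"
            )
        missing = [
            p for p in _KERNEL_REQUIRED[sm["kernel"]]
            if p not in (sm.get("kernel_params") or {})
        ]
        if missing:
            raise SchemaError(
                f"kernel {sm['kernel']!r} requires hyperparameters "
                f"{_KERNEL_REQUIRED[sm['kernel']]}; missing {missing}"
            )
        if sm["basis"] not in ("identity", "bspline"):
            raise SchemaError(f"unknown basis {sm['basis']!r}")
        if sm["r"] not in (0, 1, 2):
            raise SchemaError("smoothing r must be 0, 1 or 2")
        if d["data_model"]["family"] not in _DATA_MODELS:
            raise SchemaError(
                f"unknown data model {d['data_model']['family']!r}; "
                f"choose from {_DATA_MODELS}"
            )
        pm = d["projection"]["method"]
        if pm not in ("joint", "default_conditional", "log_pooling"):
            raise SchemaError(f"unknown projection method {pm!r}")

    def __getitem__(self, key):
        return self.doc[key]

    def to_dict(self) -> dict:
        return copy.deepcopy(self.doc)

    def __eq__(self, other):
        return isinstance(other, ModelConfig) and self.doc == other.doc

    # smoothing-spec helper ------------------------------------------------
    def smoothing_spec(self):
        from . import smoothing as sm

        blk = self.doc["smoothing"]
        kernel = sm.KernelSpec(blk["kernel"], **blk["kernel_params"])
        basis = sm.BasisSpec(
            blk["basis"], degree=blk["degree"], knot_spacing=blk["knot_spacing"]
        )
        anchors = blk.get("anchors")
        if anchors is not None:
            anchors = {int(k): list(v) for k, v in anchors.items()}
        return sm.SmoothingSpec(
            basis=basis,
            kernel=kernel,
            r=blk["r"],
            constraint_mode=blk["constraint"],
            anchors=anchors,
        )


def parse_config(path) -> ModelConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return ModelConfig(doc)


def save_config(config: ModelConfig, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return path
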