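"""TMMPModel: a fully specified temporal model for multiple populations.

Binds the transformation, covariate component, systematic component,
offsets, smoothing specification, data model, parameter-estimation
strategies and projection settings to a time grid and a set of
populations.  The same object drives synthetic generation, posterior
fitting and projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodels import DataModelSpec
from .io_config import CovariateTable, ModelConfig, TimeGrid
from .process import (
    TransformSpec,
    covariate_gbd,
    covariate_linear,
    covariate_piecewise_nmr,
    logistic_path,
    systematic_linear,
    systematic_trapezoid,
)
from .smoothing import SmoothingSpec

__all__ = ["TMMPModel"]


@dataclass
class TMMPModel:
    config: ModelConfig
    grid: TimeGrid
    populations: list[str]
    offsets: np.ndarray | None = None  # (C, T*) on the transformed scale
    groupings: dict = field(default_factory=dict)  # level name -> {pop: group}

    def __post_init__(self):
        if self.offsets is None:
            self.offsets = np.zeros((len(self.populations), self.grid.T_star))
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.offsets.shape != (len(self.populations), self.grid.T_star):
            raise ValueError(
                f"offsets must have shape (C, T*) = "
                f"({len(self.populations)}, {self.grid.T_star})"
            )

    # ------------------------------------------------------------------
    @property
    def transform(self) -> TransformSpec:
        return TransformSpec(self.config["transform"])

    @property
    def data_model(self) -> DataModelSpec:
        blk = self.config["data_model"]
        return DataModelSpec(
            family=blk["family"],
            variance=blk["variance"],
            phi=blk.get("phi"),
            sigma=dict(blk.get("sigma") or {}),
        )

    def smoothing_spec(self) -> SmoothingSpec:
        return self.config.smoothing_spec()

    def pop_index(self, population: str) -> int:
        return self.populations.index(population)

    # ------------------------------------------------------------------
    def covariate_term(
        self,
        population: str,
        covariates: CovariateTable | None,
        params: dict,
        times: np.ndarray | None = None,
    ) -> np.ndarray:
        """g2 evaluated on the transformed scale over the requested times."""
        blk = self.config["covariate_component"]
        kind = blk["kind"]
        times = self.grid.times_star if times is None else np.asarray(times)
        if kind == "none":
            return np.zeros(times.size)
        if covariates is None:
            raise ValueError(f"covariate component {kind!r} requires a covariate table")
        cols = blk.get("covariates") or []
        X = covariates.matrix(population, cols)[times - 1]
        if kind == "linear" or kind == "pca_linear":
            beta0 = params.get("beta0", {}).get(population, params.get("beta0_global", 0.0))
            if kind == "pca_linear":
                beta = np.asarray(params["beta_pca"][population], dtype=float)
                if beta.ndim == 2:  # time-varying coefficients (T*, P)
                    return np.einsum("tk,tk->t", X, beta[times - 1])
                return covariate_linear(X, 0.0, beta)
            beta = np.asarray(params.get("beta", np.zeros(X.shape[1])), dtype=float)
            return covariate_linear(X, float(beta0), beta)
        if kind == "gbd_nonlinear":
            beta = np.asarray(params["beta_gbd"], dtype=float)
            ldi, edu, hiv = X[:, 0], X[:, 1], X[:, 2]
            return covariate_gbd(ldi, edu, hiv, beta)
        if kind == "piecewise_nmr":
            beta0 = params["beta0"][population]
            return covariate_piecewise_nmr(
                X[:, 0], float(beta0), float(params["beta1"]), float(params["beta2"])
            )
        raise ValueError(f"unknown covariate kind {kind!r}")

    def systematic_term(
        self,
        population: str,
        params: dict,
        times: np.ndarray | None = None,
        epsilon: np.ndarray | None = None,
    ) -> np.ndarray:
        """g3 on the transformed scale.

        For the recursive logistic transition the returned path already
        includes epsilon (the recursion consumes it), so the caller must
        not add epsilon again.
        """
        blk = self.config["systematic_component"]
        kind = blk["kind"]
        times = self.grid.times_star if times is None else np.asarray(times)
        if kind == "none":
            return np.zeros(times.size)
        if kind == "linear_trend":
            a0, a1 = params["alpha"][population]
            t_star = params.get("t_star", blk.get("t_star", (1 + self.grid.T) // 2))
            return systematic_linear(times.astype(float), a0, a1, float(t_star))
        if kind == "logistic_transition":
            P_tilde, omega, Omega = params["logistic"][population]
            t_star = int(params.get("t_star", blk.get("t_star", (1 + self.grid.T) // 2)))
            include = blk.get("include_eps_in_recursion", True)
            T_eval = int(times.max())
            path = logistic_path(
                T_eval, t_star, Omega, P_tilde, omega,
                eps=None if epsilon is None else np.asarray(epsilon)[:T_eval],
                include_eps_in_recursion=include,
            )
            return path[times - 1]
        if kind == "trapezoid":
            xi, g0, l1, l2, l3 = params["trapezoid"][population]
            return systematic_trapezoid(times.astype(float), xi, g0, l1, l2, l3)
        raise ValueError(f"unknown systematic kind {kind!r}")

    def is_recursive(self) -> bool:
        return self.config["systematic_component"]["kind"] == "logistic_transition"

    def fingerprint(self, seed: int | None = None) -> str:
        import hashlib
        import json

        doc = self.config.to_dict()
        doc["_grid"] = [self.grid.T, self.grid.T_star, self.grid.year_start]
        doc["_populations"] = self.populations
        if seed is not None:
            doc["_seed"] = seed
        blob = json.dumps(doc, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
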