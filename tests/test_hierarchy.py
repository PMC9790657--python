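import numpy as np
import pytest
from scipy import stats

from tmmp.hierarchy import (
    HierarchySpec,
    bounded_transform,
    build_hierarchy,
    inverse_bounded_transform,
)


class TestBoundedTransform:
    def test_midpoint(self):
        assert bounded_transform(0.0, 0.5, 1.0) == pytest.approx(0.75)

    def test_limits(self):
        assert bounded_transform(40.0, 0.5, 1.0) == pytest.approx(1.0,
                                                                  abs=1e-12)
        assert bounded_transform(-40.0, 0.5, 1.0) == pytest.approx(0.5,
                                                                   abs=1e-12)

    def test_round_trip(self):
        x = 1.3
        y = bounded_transform(x, 0.01, 0.5)
        assert inverse_bounded_transform(y, 0.01, 0.5) == pytest.approx(
            x, abs=1e-10
        )

    def test_monotone(self):
        xs = np.linspace(-5, 5, 50)
        ys = bounded_transform(xs, -2.0, 3.0)
        assert np.all(np.diff(ys) > 0)
        assert ys.min() > -2.0 and ys.max() < 3.0

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            bounded_transform(0.0, 1.0, 0.5)


class TestBuildHierarchy:
    def test_one_level_reduces_to_plain_normal(self):
        spec = HierarchySpec(
            name="gamma", strategy="hierarchical",
            levels=({"A": "world", "B": "world"},),
        )
        lp = build_hierarchy(spec, ["A", "B"])
        values = {0: np.array([0.3, -0.2]), 1: np.array([0.1])}
        scales = {1: 0.7}
        got = lp(values, scales)
        expected = (
            stats.norm.logpdf(0.3, 0.1, 0.7)
            + stats.norm.logpdf(-0.2, 0.1, 0.7)
            + stats.halfnorm.logpdf(0.7, scale=5.0)
            + stats.norm.logpdf(0.1, 0, 10.0)
        )
        assert got == pytest.approx(expected, abs=1e-10)

    def test_three_level_structure(self):
        # rate parameters pooled country < subregion < region < world
        pops = ["C1", "C2", "C3", "C4"]
        spec = HierarchySpec(
            name="omega", strategy="hierarchical",
            levels=(
                {"C1": "S1", "C2": "S1", "C3": "S2", "C4": "S2"},
                {"S1": "R1", "S2": "R2"},
                {"R1": "world", "R2": "world"},
            ),
        )
        lp = build_hierarchy(spec, pops)
        assert lp.level_units == [
            pops, ["S1", "S2"], ["R1", "R2"], ["world"]
        ]
        values = {
            0: np.zeros(4), 1: np.zeros(2), 2: np.zeros(2), 3: np.zeros(1),
        }
        scales = {1: 0.5, 2: 0.5, 3: 0.5}
        assert np.isfinite(lp(values, scales))

    def test_missing_population_named(self):
        spec = HierarchySpec(
            name="gamma", strategy="hierarchical",
            levels=({"A": "world"},),
        )
        with pytest.raises(ValueError, match="'B'"):
            build_hierarchy(spec, ["A", "B"])

    def test_truncated_normal_level(self):
        spec = HierarchySpec(
            name="lambda", strategy="hierarchical",
            levels=({"A": "world"},), pi="truncated_normal",
            truncation=(-1.0, 2.0),
        )
        lp = build_hierarchy(spec, ["A"])
        inside = lp({0: np.array([0.5]), 1: np.array([0.0])}, {1: 0.4})
        outside = lp({0: np.array([2.5]), 1: np.array([0.0])}, {1: 0.4})
        assert np.isfinite(inside)
        assert outside == -np.inf

    def test_bmat_scale_structure_stays_in_range(self):
        # sigma_c = sigma_w (1 + lambda_c) with lambda_c in (-1, 2) keeps
        # every country sd in (0, 3 sigma_w)
        rng = np.random.default_rng(0)
        sigma_w = 0.08
        lam = stats.truncnorm.rvs(-1 / 0.4, 2 / 0.4, scale=0.4, size=1000,
                                  random_state=rng)
        sig = sigma_w * (1 + lam)
        assert sig.min() > 0.0
        assert sig.max() < 3 * sigma_w

    def test_fixed_strategy_requires_value(self):
        with pytest.raises(ValueError):
            HierarchySpec(name="x", strategy="fixed")
        spec = HierarchySpec(name="x", strategy="fixed", value=2.0,
                             source_note="from a separate regression fit")
        assert spec.value == 2.0
        assert "regression" in spec.source_note


class TestShrinkage:
    def test_hierarchical_shrinkage_two_populations(self):
        """A data-poor population's posterior mean lies between its own
        flat-prior estimate and the pooled mean (normal-normal argument on
        the fitted hierarchy)."""
        import pandas as pd

        from tmmp import ModelConfig, ObservationTable, TimeGrid, TMMPModel
        from tmmp.inference import fit

        grid = TimeGrid(T=8)
        cfg = ModelConfig({
            "transform": "identity",
            "covariate_component": {"kind": "linear", "covariates": ["x"]},
            "smoothing": {"basis": "identity", "kernel": "iid",
                          "kernel_params": {"sigma": 0.05}, "r": 0,
                          "constraint": "none"},
            "data_model": {"family": "normal", "variance": "fixed"},
            "hierarchy": {
                "beta0": {"strategy": "hierarchical", "levels": ["world"]},
                "kernel_scale": {"strategy": "fixed"},
            },
        })
        rng = np.random.default_rng(7)
        rows, cov_rows = [], []
        truth = {"A": 1.0, "B": 2.0}
        for p, n_obs in [("A", 8), ("B", 2)]:
            for t in range(1, 9):
                cov_rows.append({"population": p, "time": t, "x": 0.0})
            for t in range(1, n_obs + 1):
                rows.append({"population": p, "time": t,
                             "value": rng.normal(truth[p], 0.3),
                             "sampling_sd": 0.3, "source": "s"})
        from tmmp.io_config import CovariateTable

        data = ObservationTable(pd.DataFrame(rows), grid)
        covs = CovariateTable(pd.DataFrame(cov_rows), grid)
        model = TMMPModel(cfg, grid, ["A", "B"])
        post = fit(model, data, covariates=covs,
                   options={"chains": 2, "draws": 400, "warmup": 400,
                            "seed": 1})
        b0 = post.get("beta0")
        mle_B = np.mean([r["value"] for r in rows if r["population"] == "B"])
        mle_A = np.mean([r["value"] for r in rows if r["population"] == "A"])
        post_B = b0[:, 1].mean()
        lo, hi = sorted([mle_B, (mle_A + mle_B) / 2])
        assert lo - 0.1 < post_B < hi + 0.1
        # shrinkage pulls B toward A
        assert abs(post_B - mle_A) < abs(mle_B - mle_A) + 0.05


class TestConcentrationLimit:
    def test_vanishing_scale_pins_children_to_group_mean(self):
        """As the level sd goes to zero the hierarchy density concentrates
        on children equal to the group mean: any spread is exponentially
        penalized relative to the pinned configuration."""
        spec = HierarchySpec(
            name="gamma", strategy="hierarchical",
            levels=({"A": "world", "B": "world"},),
        )
        lp = build_hierarchy(spec, ["A", "B"])
        scales = {1: 1e-6}
        mean = np.array([0.4])
        pinned = lp({0: np.array([0.4, 0.4]), 1: mean}, scales)
        spread = lp({0: np.array([0.4, 0.4001]), 1: mean}, scales)
        assert pinned - spread > 1e3  # log-density gap
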