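import numpy as np
import pandas as pd
import pytest

from tmmp import TimeGrid
from tmmp.io_config import CovariateTable
from tmmp.zoo import (
    ZOO_NAMES,
    gbd_offsets_simplified,
    parse_template_config,
    render_template,
    zoo,
    zoo_scenario,
)


class TestZooEntries:
    def test_unknown_name_enumerates(self):
        with pytest.raises(ValueError, match="b3_u5mr"):
            zoo("igme_u5mr")

    def test_b3_structure(self):
        e = zoo("b3_u5mr")
        cfg = e.config
        assert cfg["transform"] == "log"
        assert cfg["smoothing"]["r"] == 2
        assert cfg["smoothing"]["basis"] == "bspline"
        assert cfg["smoothing"]["knot_spacing"] == 2.5
        assert cfg["projection"]["method"] == "log_pooling"
        assert cfg["hierarchy"]["kernel_scale"]["strategy"] == "hierarchical"

    def test_gbd_structure(self):
        cfg = zoo("gbd_u5mr").config
        assert cfg["transform"] == "log10"
        assert cfg["smoothing"]["kernel"] == "matern"
        assert cfg["smoothing"]["r"] == 0
        assert cfg["hierarchy"]["kernel_scale"]["strategy"] == "fixed"
        assert cfg["covariate_component"]["kind"] == "gbd_nonlinear"

    def test_fpem_structure(self):
        cfg = zoo("fpem_total_use").config
        assert cfg["transform"] == "logit"
        assert cfg["systematic_component"]["kind"] == "logistic_transition"
        assert cfg["smoothing"]["kernel"] == "ar1"
        assert cfg["hierarchy"]["omega"]["levels"] == \
            ["subregion", "region", "world"]
        assert cfg["hierarchy"]["P_tilde"]["bounds"] == [0.5, 1.0]

    def test_nmr_structure(self):
        cfg = zoo("igme_nmr").config
        assert cfg["covariate_component"]["kind"] == "piecewise_nmr"
        assert cfg["smoothing"]["r"] == 1
        assert cfg["smoothing"]["anchor_policy"] == "sum_to_zero"

    def test_bmat_anchors_at_1990(self):
        e = zoo("bmat_mmr")
        assert e.config["smoothing"]["anchor_policy"] == "reference_year:1990"
        model = e.build_model(TimeGrid(T=20, year_start=1986),
                              ["C1"], groupings={"region": {"C1": "R"}})
        anchors = model.smoothing_spec().anchors
        assert anchors == {0: [4]}  # 1990 is the 5th grid year
        assert e.config["smoothing"]["kernel"] == "arma11"

    def test_subnational_structure(self):
        cfg = zoo("subnational_mortality").config
        assert cfg["covariate_component"]["kind"] == "pca_linear"
        assert cfg["hierarchy"]["kernel_scale"]["strategy"] == "grouped"


class TestTemplates:
    @pytest.mark.parametrize("name", ZOO_NAMES)
    def test_render_is_total_and_round_trips(self, name):
        entry = zoo(name)
        text = render_template(entry)
        # every template field present
        for field in ["eta_ct", "g1", "Covariate component",
                      "Systematic component", "Offsets", "Smoothing basis",
                      "Smoothing kernel", "| r |", "K_dc", "Projections",
                      "Fixed parameters", "Vague priors"]:
            assert field in text, field
        # machine-readable appendix reproduces the configuration
        assert parse_template_config(text) == entry.config

    def test_b3_template_mentions_log_and_r2(self):
        text = render_template(zoo("b3_u5mr"))
        assert "| g1 | log |" in text
        assert "| r | 2 |" in text

    def test_gbd_template_marks_unused_hierarchy(self):
        text = render_template(zoo("gbd_u5mr"))
        assert "Hierarchical distribution | ·" in text


class TestGbdOffsets:
    def _setup(self, values_shift=0.0):
        grid = TimeGrid(T=3)
        pops = ["A", "B"]
        beta = [0.0, 0.0, np.log(50.0), 0.0]  # constant prediction of 50
        cov = CovariateTable(pd.DataFrame([
            {"population": p, "time": t, "ldi": 1.0, "edu": 0.0, "hiv": 0.0}
            for p in pops for t in (1, 2, 3)
        ]), grid)
        return grid, pops, beta, cov

    def _obs(self, rows, grid):
        from tmmp.io_config import ObservationTable

        return ObservationTable(pd.DataFrame(rows), grid)

    def test_zero_residuals_zero_offsets(self):
        grid, pops, beta, cov = self._setup()
        rows = [{"population": p, "time": t, "value": 50.0}
                for p in pops for t in (1, 2, 3)]
        offsets = gbd_offsets_simplified(self._obs(rows, grid), cov, beta,
                                         grid, pops)
        assert np.allclose(offsets, 0.0, atol=1e-12)

    def test_single_country_constant_residual(self):
        grid, pops, beta, cov = self._setup()
        rows = [{"population": "A", "time": t, "value": 55.0}
                for t in (1, 2, 3)]
        offsets = gbd_offsets_simplified(
            self._obs(rows, grid), cov, beta, grid, ["A"],
            region_map={"A": "r"},
        )
        expected = np.log10(55.0) - np.log10(50.0)
        assert np.allclose(offsets, expected, atol=1e-12)

    def test_two_country_weighted_average(self):
        """Hand-computed 0.99/0.01 spatial weighting with a Gaussian
        temporal kernel on a 2-population, 3-year toy."""
        grid, pops, beta, cov = self._setup()
        rows = [
            {"population": "A", "time": 1, "value": 52.0},
            {"population": "B", "time": 1, "value": 46.0},
        ]
        bw = 2.0
        offsets = gbd_offsets_simplified(
            self._obs(rows, grid), cov, beta, grid, pops,
            region_map={"A": "r", "B": "r"}, temporal_bandwidth=bw,
        )
        # cell (A, t=2): both residuals at time 1, same temporal weight
        w_a, w_b = 0.99, 0.01
        r_hat = (w_a * 2.0 + w_b * (-4.0)) / (w_a + w_b)
        expected = np.log10(50.0 + r_hat) - np.log10(50.0)
        assert offsets[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_floor_warns(self):
        grid, pops, beta, cov = self._setup()
        rows = [{"population": "A", "time": t, "value": -60.0}
                for t in (1, 2, 3)]
        with pytest.warns(UserWarning, match="floored"):
            offsets = gbd_offsets_simplified(
                self._obs(rows, grid), cov, beta, grid, ["A"],
                region_map={"A": "r"},
            )
        assert np.allclose(offsets, -2.0)  # floored at 1% of prediction


class TestScenarios:
    @pytest.mark.parametrize("name", ZOO_NAMES)
    def test_scenario_generates_valid_data(self, name):
        from tmmp.synthetic import generate

        sc = zoo_scenario(name, C=4, T=15, seed=1)
        table, truth = generate(sc["model"], sc["truth_params"],
                                sc["pattern"], seed=2,
                                covariates=sc["covariates"])
        assert len(table) > 0
        assert np.all(np.isfinite(truth.eta))
        assert np.all(np.isfinite(table.frame["value"]))
        tf = sc["model"].config["transform"]
        if tf in ("log", "log10"):
            assert np.all(truth.eta > 0)
        elif tf == "logit":
            assert np.all((truth.eta > 0) & (truth.eta < 1))
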