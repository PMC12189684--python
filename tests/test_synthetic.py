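"""Synthetic world: grids, niches, surveys, and paired climate layers."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from loligosdm import (
    GridSpec,
    NicheSpec,
    ScenarioDelta,
    generate_env_stack,
    generate_scenario_layers,
    simulate_survey,
)
from loligosdm.synthetic import PLAUSIBLE_RANGES, GaussianResponse


class TestGridSpec:
    def test_default_grid_is_18_by_15(self):
        spec = GridSpec()
        assert (spec.n_lat, spec.n_lon) == (18, 15)
        assert spec.lats[0] == 26.5 and spec.lats[-1] == 35.0
        assert spec.lons[0] == 120.0 and spec.lons[-1] == 127.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(lat_min=30, lat_max=30),
            dict(lon_min=127, lon_max=120),
            dict(cell_size=0.0),
            dict(cell_size=-1.0),
        ],
    )
    def test_degenerate_grids_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GridSpec(**kwargs)


class TestGenerateEnvStack:
    def test_deterministic_under_seed(self):
        a = generate_env_stack(seed=1)
        b = generate_env_stack(seed=1)
        for name in a.layers:
            np.testing.assert_array_equal(a.layers[name], b.layers[name])

    def test_different_seeds_differ_per_layer(self):
        a = generate_env_stack(seed=1)
        b = generate_env_stack(seed=2)
        for name in a.layers:
            sea = a.sea_mask
            assert np.any(a.layers[name][sea] != b.layers[name][sea]), name

    @pytest.mark.parametrize("season", ["spring", "summer", "autumn", "winter"])
    def test_values_in_plausible_ranges(self, season):
        stack = generate_env_stack(season=season, seed=3)
        for name, arr in stack.layers.items():
            lo, hi = PLAUSIBLE_RANGES[name]
            vals = arr[np.isfinite(arr)]
            assert vals.min() >= lo and vals.max() <= hi, name

    def test_land_mask_consistent_across_layers(self, default_stack):
        masks = [np.isfinite(a) for a in default_stack.layers.values()]
        for m in masks[1:]:
            np.testing.assert_array_equal(m, masks[0])
        assert 0 < default_stack.n_sea < default_stack.lat.size * default_stack.lon.size

    def test_unknown_season_rejected(self):
        with pytest.raises(ValueError):
            generate_env_stack(season="monsoon", seed=0)


class TestNiche:
    @given(
        opt=st.floats(10, 28),
        breadth=st.floats(0.5, 5),
        x=st.floats(-50, 50),
    )
    def test_suitability_bounded(self, opt, breadth, x):
        niche = NicheSpec(responses={"sbt": GaussianResponse(opt, breadth)})
        s = niche.suitability({"sbt": np.array([x])})
        assert 0.0 <= s[0] <= 1.0

    def test_presence_probability_monotone_in_suitability(self, default_stack, sbt_niche):
        # empirical presence rate rises with true suitability bins
        tbl = simulate_survey(default_stack, sbt_niche, n_stations=200, seed=11)
        lo = tbl[tbl["true_suitability"] < 0.2]
        hi = tbl[tbl["true_suitability"] > 0.8]
        assert (hi["count"] > 0).mean() > (lo["count"] > 0).mean()


class TestSimulateSurvey:
    def test_zero_detection_scale_all_absent(self, default_stack):
        niche = NicheSpec(detection_scale=0.0)
        tbl = simulate_survey(default_stack, niche, n_stations=50, seed=0)
        assert (tbl["count"] == 0).all()
        assert (tbl["weight"] == 0).all()

    def test_deterministic_under_seed(self, default_stack, sbt_niche):
        a = simulate_survey(default_stack, sbt_niche, n_stations=100, seed=5)
        b = simulate_survey(default_stack, sbt_niche, n_stations=100, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_stations_on_distinct_sea_cells(self, default_stack, sbt_niche):
        tbl = simulate_survey(default_stack, sbt_niche, n_stations=120, seed=2)
        cells = set(zip(tbl["lat"], tbl["lon"]))
        assert len(cells) == len(tbl)
        assert tbl[["sst", "sbt", "sss", "sbs"]].notna().all().all()

    def test_too_many_stations_rejected(self, default_stack, sbt_niche):
        with pytest.raises(ValueError):
            simulate_survey(default_stack, sbt_niche,
                            n_stations=default_stack.n_sea + 1, seed=0)

    def test_presence_rate_tracks_thermal_optimum(self):
        # Monte-Carlo check against the generating probabilities: stations
        # near the 20 C optimum must be occupied far more often than
        # stations >5 C away (fine grid so 500 distinct cells exist).
        spec = GridSpec(cell_size=0.25)
        stack = generate_env_stack(spec, season="autumn", seed=4)
        niche = NicheSpec(responses={"sbt": GaussianResponse(20.0, 2.0)})
        tbl = simulate_survey(stack, niche, n_stations=500, seed=4)
        near = tbl[np.abs(tbl["sbt"] - 20) < 1]
        far = tbl[np.abs(tbl["sbt"] - 20) > 5]
        assert len(near) > 10 and len(far) > 10
        assert (near["count"] > 0).mean() > (far["count"] > 0).mean() + 0.3

    def test_poisson_limit_counts_match_mean(self, default_stack):
        niche = NicheSpec(
            responses={}, detection_scale=6.0, dispersion=math.inf
        )
        tbl = simulate_survey(default_stack, niche, n_stations=200, seed=9)
        assert abs(tbl["count"].mean() - 6.0) < 0.5

    def test_weight_zero_iff_count_zero(self, survey_table):
        zero = survey_table["count"] == 0
        assert (survey_table.loc[zero, "weight"] == 0).all()
        assert (survey_table.loc[~zero, "weight"] > 0).all()


class TestScenarioLayers:
    def test_zero_shift_zero_bias_identity(self, default_stack):
        delta = ScenarioDelta()
        gb, gf, tf = generate_scenario_layers(default_stack, delta, seed=0)
        for name in default_stack.layers:
            np.testing.assert_array_equal(gb.layers[name], default_stack.layers[name])
            np.testing.assert_array_equal(gf.layers[name], default_stack.layers[name])
            np.testing.assert_array_equal(tf.layers[name], default_stack.layers[name])

    def test_bias_cancels_in_model_anomaly(self, default_stack):
        delta = ScenarioDelta(shift={"sbt": 2.0}, gcm_bias={"sbt": 1.0}, noise_sd=0.0)
        gb, gf, tf = generate_scenario_layers(default_stack, delta, seed=0)
        sea = default_stack.sea_mask
        anomaly = gf.layers["sbt"][sea] - gb.layers["sbt"][sea]
        np.testing.assert_allclose(anomaly, 2.0)
        np.testing.assert_allclose(
            tf.layers["sbt"][sea] - default_stack.layers["sbt"][sea], 2.0
        )

    def test_mean_bias_recovered_within_noise(self, default_stack):
        delta = ScenarioDelta(gcm_bias={"sbt": 1.0}, noise_sd=0.2)
        gb, _, _ = generate_scenario_layers(default_stack, delta, seed=3)
        sea = default_stack.sea_mask
        diff = gb.layers["sbt"][sea] - default_stack.layers["sbt"][sea]
        assert abs(diff.mean() - 1.0) < 0.05

    def test_grids_stay_aligned_and_masked(self, default_stack):
        delta = ScenarioDelta(shift={"sst": 1.0}, gcm_bias={"sst": 0.5}, noise_sd=0.1)
        gb, gf, tf = generate_scenario_layers(default_stack, delta, seed=1)
        for s in (gb, gf, tf):
            assert s.aligned_with(default_stack)
            np.testing.assert_array_equal(s.sea_mask, default_stack.sea_mask)
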