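"""Synthetic generators: determinism, construction invariants, mechanisms."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import binyield as by
from binyield.regions import classify_counties


class TestWeatherGenerator:
    def test_seeded_determinism(self):
        cfg = by.ClimateGenConfig(grid_rows=3, grid_cols=3, years=2, seed=5)
        a = by.gen_weather(cfg)
        b = by.gen_weather(cfg)
        for v in ("tmin", "tmax", "precip"):
            np.testing.assert_array_equal(a.data[v].values, b.data[v].values)

    def test_tmax_at_least_tmin_and_precip_nonneg(self, grid_small):
        assert np.all(grid_small.data["tmax"].values >= grid_small.data["tmin"].values)
        assert np.all(grid_small.data["precip"].values >= 0)

    def test_warming_offset_shifts_tmean_exactly(self):
        cfg = by.ClimateGenConfig(grid_rows=3, grid_cols=3, years=2, seed=9)
        base = by.gen_weather(cfg)
        warm = by.gen_weather(replace(cfg, warming_offset=3.0))
        tm0 = (base.data["tmin"] + base.data["tmax"]).values / 2
        tm1 = (warm.data["tmin"] + warm.data["tmax"]).values / 2
        np.testing.assert_allclose(tm1 - tm0, 3.0, atol=1e-12)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            by.ClimateGenConfig(grid_rows=0)
        with pytest.raises(ValueError):
            by.ClimateGenConfig(years=-1)
        with pytest.raises(ValueError):
            by.ClimateGenConfig(anomaly_ar1=1.0)
        with pytest.raises(ValueError):
            by.ClimateGenConfig(diurnal_range_mean=0.0)


class TestRegionGenerator:
    def test_weights_sum_to_one_and_partition_disjoint(self, regions_small):
        sums = regions_small.cells.groupby("county_id")["weight"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)
        assert not regions_small.cells["cell_id"].duplicated().any()

    def test_single_cell_county_weight_one(self, grid_small):
        r = by.gen_regions(
            by.RegionGenConfig(n_counties=6, cells_per_county=1, n_states=2, seed=0),
            grid_small,
        )
        np.testing.assert_allclose(r.cells["weight"], 1.0)

    def test_single_state(self, grid_small):
        r = by.gen_regions(
            by.RegionGenConfig(n_counties=5, cells_per_county=2, n_states=1, seed=0),
            grid_small,
        )
        assert r.counties["state_id"].nunique() == 1

    def test_infeasible_partition(self, grid_small):
        with pytest.raises(ValueError, match="cells"):
            by.gen_regions(
                by.RegionGenConfig(n_counties=40, cells_per_county=4, n_states=2),
                grid_small,
            )

    def test_centroid_is_weighted_mean(self, regions_small):
        c0 = regions_small.cells[regions_small.cells["county_id"] == 0]
        want = (c0["lat"] * c0["weight"]).sum()
        got = regions_small.centroids().loc[0, "lat"]
        assert got == pytest.approx(want, abs=1e-12)

    def test_share_mixture_yields_both_regimes(self, regions_mc):
        regime = classify_counties(regions_mc)
        assert (regime == "rainfed").sum() > 0
        assert (regime == "irrigated").sum() > 0


class TestStatisticalYieldGenerator:
    def test_noiseless_panel_is_exact_equation(self, county_exposure_small, regions_small):
        truth = by.default_true_model(
            regions_small, seed=3, error_sd=0.0,
            gamma={b: 0.0 for b in county_exposure_small.bin_labels},
            delta_precip_lin=0.0, delta_precip_quad=0.0,
            state_trend_lin={}, state_trend_quad={},
        )
        panel = by.gen_yields_statistical(county_exposure_small, truth, regions_small)
        logy = np.log(panel["yield"].to_numpy())
        want = truth.alpha0 + panel["county_id"].map(truth.county_effects).to_numpy()
        np.testing.assert_allclose(logy, want, atol=1e-12)

    def test_bin_mismatch_rejected(self, county_exposure_small, regions_small):
        truth = by.default_true_model(regions_small, gamma={"bin_0_3": 0.1})
        with pytest.raises(ValueError, match="gamma"):
            by.gen_yields_statistical(county_exposure_small, truth, regions_small)

    def test_zero_range_residuals_uncorrelated(self, county_exposure_small, regions_small):
        """With spatial range 0, cross-county residual correlation -> 0."""
        truth = by.default_true_model(
            regions_small, seed=3, error_sd=0.2, error_spatial_range=0.0
        )
        reps = 400
        pairs = []
        base = by.gen_yields_statistical(
            county_exposure_small, replace(truth, error_sd=0.0), regions_small
        )
        for r in range(reps):
            panel = by.gen_yields_statistical(
                county_exposure_small, replace(truth, seed=10_000 + r), regions_small
            )
            eps = np.log(panel["yield"].to_numpy()) - np.log(base["yield"].to_numpy())
            frame = panel[["county_id", "year"]].assign(eps=eps)
            wide = frame.pivot(index="year", columns="county_id", values="eps")
            pairs.append(wide.iloc[:, 0].corr(wide.iloc[:, 1]))
        assert abs(np.nanmean(pairs)) < 0.05

    def test_positive_range_residuals_correlated_nearby(self, county_exposure_mc, regions_mc):
        truth = by.default_true_model(
            regions_mc, seed=3, error_sd=0.2, error_spatial_range=2.0
        )
        panel = by.gen_yields_statistical(county_exposure_mc, truth, regions_mc)
        base = by.gen_yields_statistical(
            county_exposure_mc, replace(truth, error_sd=0.0), regions_mc
        )
        eps = np.log(panel["yield"].to_numpy()) - np.log(base["yield"].to_numpy())
        wide = panel[["county_id", "year"]].assign(eps=eps).pivot(
            index="year", columns="county_id", values="eps"
        )
        cent = regions_mc.centroids()
        corr = wide.corr().to_numpy()
        d = np.sqrt(((cent.to_numpy()[:, None, :] - cent.to_numpy()[None, :, :]) ** 2).sum(-1))
        off = ~np.eye(len(cent), dtype=bool)
        near = corr[(d < 1.0) & off].mean()
        far = corr[(d > 6.0) & off].mean()
        assert near > far + 0.2


class TestSurrogate:
    def test_irrigated_yields_potential_everywhere(self, grid_small, regions_small):
        params = by.SurrogateCropParams(irrigated=True)
        panel = by.gen_yields_surrogate(
            grid_small, regions_small, params, by.default_season("maize")
        )
        np.testing.assert_allclose(
            np.log(panel["yield"].to_numpy()), params.potential_log_yield, atol=1e-12
        )

    def test_daily_rain_at_capacity_equals_irrigated(self, grid_small, regions_small):
        flooded = grid_small.data.copy()
        flooded["precip"] = flooded["precip"] * 0 + 120.0
        wet = by.DailyWeatherGrid(flooded)
        params = by.SurrogateCropParams(irrigated=False, bucket_capacity=120.0)
        panel = by.gen_yields_surrogate(wet, regions_small, params, by.default_season("maize"))
        np.testing.assert_allclose(
            np.log(panel["yield"].to_numpy()), params.potential_log_yield, atol=1e-12
        )

    def test_hot_dry_year_yields_less_than_cool_dry(self, grid_small, regions_small):
        """Same rainfall, +5 degC -> more evaporative demand -> lower yield."""
        hot = grid_small.data.copy()
        hot["tmin"] = hot["tmin"] + 5.0
        hot["tmax"] = hot["tmax"] + 5.0
        params = by.SurrogateCropParams(irrigated=False)
        season = by.default_season("maize")
        cool_p = by.gen_yields_surrogate(grid_small, regions_small, params, season)
        hot_p = by.gen_yields_surrogate(
            by.DailyWeatherGrid(hot), regions_small, params, season
        )
        assert np.all(hot_p["yield"].to_numpy() <= cool_p["yield"].to_numpy())
        assert hot_p["yield"].mean() < cool_p["yield"].mean()
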