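"""Panel estimator: absorption equivalence, spatial HAC, divergence, median."""

import numpy as np
import pandas as pd
import pytest

import binyield as by
from binyield.bins import BinScheme
from binyield.exposure import ExposurePanel
from binyield.panel import (
    BinnedYieldModel,
    RegressionSpec,
    build_design,
    ci_overlap_divergence,
    conley_vcov,
    ensemble_median,
)


def _random_panel(n_counties=5, n_years=6, n_states=2, seed=0, gamma_scale=0.01):
    """Hand-rolled exposure + yield panel with known random structure."""
    rng = np.random.default_rng(seed)
    scheme = BinScheme()
    rows = []
    for c in range(n_counties):
        for y in range(2000, 2000 + n_years):
            row = {"county_id": c, "year": y}
            expo = rng.dirichlet(np.ones(14)) * rng.uniform(150, 184)
            for lab, v in zip(scheme.pooled_labels, expo):
                row[lab] = v
            row["time_below_0"] = 184 - expo.sum() + rng.uniform(0, 5)
            row["season_precip"] = rng.uniform(200, 600)
            row["season_length"] = 184.0
            rows.append(row)
    exposures = ExposurePanel(pd.DataFrame(rows), scheme)
    gamma = rng.normal(0, gamma_scale, 14)
    df = exposures.frame
    logy = (
        1.5
        + df[list(scheme.pooled_labels)].to_numpy() @ gamma
        + 5e-4 * df["season_precip"].to_numpy()
        + rng.normal(0, 0.05, len(df))
    )
    yields = pd.DataFrame(
        {
            "county_id": df["county_id"],
            "state_id": df["county_id"] % n_states,
            "year": df["year"],
            "yield": np.exp(logy),
        }
    )
    centroids = pd.DataFrame(
        {
            "lat": 40 + rng.uniform(0, 8, n_counties),
            "lon": -100 + rng.uniform(0, 8, n_counties),
        },
        index=pd.Index(range(n_counties), name="county_id"),
    )
    return exposures, yields, centroids


class TestDesign:
    def test_step_form_column_count(self, county_exposure_mc, regions_mc):
        """14 bins + 2 precip + 2 trends per state; ~80 total at 30 states."""
        truth = by.default_true_model(regions_mc, seed=0)
        yields = by.gen_yields_statistical(county_exposure_mc, truth, regions_mc)
        d = build_design(county_exposure_mc, yields)
        n_states = regions_mc.counties["state_id"].nunique()
        assert d.X.shape[1] == 14 + 2 + 2 * n_states
        # the published-scale panel has ~30 states: 14 + 2 + 60 + intercept ~ 80
        assert 14 + 2 + 2 * 30 + 1 == 77

    def test_piecewise_form_two_temperature_columns(self, county_exposure_mc, regions_mc):
        truth = by.default_true_model(regions_mc, seed=0)
        yields = by.gen_yields_statistical(county_exposure_mc, truth, regions_mc)
        d = build_design(
            county_exposure_mc, yields, RegressionSpec(response_form="piecewise_linear")
        )
        assert d.temp_cols == ["gdd_below_knot", "gdd_above_knot"]

    def test_nonpositive_yields_dropped(self):
        exposures, yields, _ = _random_panel()
        yields.loc[0, "yield"] = -1.0
        yields.loc[1, "yield"] = np.nan
        d = build_design(exposures, yields)
        assert d.n_dropped == 2
        assert d.nobs == len(yields) - 2

    def test_empty_panel_errors(self):
        exposures, yields, _ = _random_panel()
        with pytest.raises(ValueError, match="empty"):
            build_design(exposures, yields.assign(year=yields["year"] + 1000))

    def test_duplicate_sources_rejected(self):
        exposures, yields, _ = _random_panel()
        with pytest.raises(ValueError, match="duplicate"):
            build_design(exposures, pd.concat([yields, yields]))

    def test_collinear_zero_exposure_named(self):
        exposures, yields, _ = _random_panel()
        exposures.frame["bin_39_42"] = 0.0
        with pytest.raises(ValueError, match="bin_39_42"):
            BinnedYieldModel(exposures, yields)


class TestFit:
    def test_within_equals_explicit_dummies(self):
        """Absorbed county effects match the brute-force dummy regression."""
        import statsmodels.api as sm

        exposures, yields, _ = _random_panel(n_counties=5, n_years=6, seed=1)
        model = BinnedYieldModel(exposures, yields)
        res = model.fit(cov_type="hc0")
        d = model.design
        dummies = pd.get_dummies(pd.Series(d.county), prefix="c", dtype=float)
        Xfull = pd.concat([d.X.reset_index(drop=True), dummies], axis=1)
        ols = sm.OLS(d.y.to_numpy(), Xfull.to_numpy()).fit()
        np.testing.assert_allclose(
            res.params.to_numpy(), ols.params[: d.X.shape[1]], atol=1e-8
        )
        # absorbed county effects + intercept equal the dummy coefficients
        absorbed = res.alpha0 + res.county_effects.to_numpy()
        np.testing.assert_allclose(absorbed, ols.params[d.X.shape[1]:], atol=1e-8)

    def test_row_permutation_invariance(self):
        exposures, yields, cent = _random_panel(seed=2)
        res_a = BinnedYieldModel(exposures, yields, centroids=cent).fit()
        perm = yields.sample(frac=1.0, random_state=0)
        res_b = BinnedYieldModel(exposures, perm, centroids=cent).fit()
        np.testing.assert_allclose(res_a.params, res_b.params, atol=1e-10)

    def test_yield_rescaling_moves_only_intercept(self):
        exposures, yields, cent = _random_panel(seed=3)
        res_a = BinnedYieldModel(exposures, yields, centroids=cent).fit()
        scaled = yields.assign(**{"yield": yields["yield"] * 7.5})
        res_b = BinnedYieldModel(exposures, scaled, centroids=cent).fit()
        np.testing.assert_allclose(res_a.params, res_b.params, atol=1e-10)
        assert res_b.alpha0 - res_a.alpha0 == pytest.approx(np.log(7.5), abs=1e-10)

    def test_noiseless_recovery(self, county_exposure_small, regions_small):
        truth = by.default_true_model(regions_small, seed=4, error_sd=0.0)
        yields = by.gen_yields_statistical(county_exposure_small, truth, regions_small)
        res = BinnedYieldModel(
            county_exposure_small, yields, centroids=regions_small.centroids()
        ).fit()
        for b, g in truth.gamma.items():
            assert res.params[b] == pytest.approx(g, abs=1e-8)
        assert res.params["precip"] == pytest.approx(truth.delta_precip_lin, abs=1e-8)
        assert res.params["precip_sq"] == pytest.approx(truth.delta_precip_quad, abs=1e-8)


def _brute_force_conley(X, e, county, year, centroids, cutoff):
    """O(n^2) double loop over observation pairs (independent oracle)."""
    X = np.asarray(X, float)
    n, k = X.shape
    omega = np.zeros((k, k))
    coords = centroids.loc[county, ["lat", "lon"]].to_numpy(float)
    for i in range(n):
        for j in range(n):
            if year[i] != year[j]:
                continue
            d = np.hypot(*(coords[i] - coords[j]))
            if d <= cutoff:
                omega += np.outer(X[i] * e[i], X[j] * e[j])
    bread = np.linalg.inv(X.T @ X)
    return bread @ omega @ bread


def _toy_obs(n_counties=6, n_years=3, k=4, seed=5):
    """Small observation set (X, resid, county, year, centroids) for vcov oracles."""
    rng = np.random.default_rng(seed)
    county = np.repeat(np.arange(n_counties), n_years)
    year = np.tile(np.arange(2000, 2000 + n_years), n_counties)
    X = rng.normal(size=(n_counties * n_years, k))
    e = rng.normal(size=n_counties * n_years)
    cent = pd.DataFrame(
        {"lat": 40 + rng.uniform(0, 6, n_counties), "lon": -100 + rng.uniform(0, 6, n_counties)},
        index=pd.Index(range(n_counties), name="county_id"),
    )
    return X, e, county, year, cent


class TestConley:
    def test_matches_brute_force_pairwise_oracle(self):
        X, e, county, year, cent = _toy_obs(n_counties=6, n_years=3, seed=5)
        for cutoff in (0.5, 3.0, 20.0):
            got = conley_vcov(X, e, county, year, cent, cutoff)
            want = _brute_force_conley(X, e, county, year, cent, cutoff)
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_collapses_to_hc0_below_min_distance(self):
        exposures, yields, cent = _random_panel(n_counties=6, n_years=8, seed=6)
        model = BinnedYieldModel(exposures, yields, centroids=cent)
        hc0 = model.fit(cov_type="hc0")
        tiny = model.fit(cov_type="conley", cutoff=1e-9)
        np.testing.assert_allclose(tiny.vcov, hc0.vcov, atol=1e-14)

    def test_negative_cutoff_rejected(self):
        exposures, yields, cent = _random_panel(seed=7)
        model = BinnedYieldModel(exposures, yields, centroids=cent)
        with pytest.raises(ValueError, match="cutoff"):
            model.fit(cov_type="conley", cutoff=-1.0)

    def test_spatially_correlated_errors_inflate_conley_se(
        self, county_exposure_mc, regions_mc
    ):
        """With strong spatial error correlation, Conley SEs exceed HC0."""
        from dataclasses import replace

        truth = by.default_true_model(
            regions_mc, seed=8, error_sd=0.15, error_spatial_range=3.0
        )
        ratios = []
        for r in range(5):
            yields = by.gen_yields_statistical(
                county_exposure_mc, replace(truth, seed=500 + r), regions_mc
            )
            model = BinnedYieldModel(
                county_exposure_mc, yields, centroids=regions_mc.centroids()
            )
            conley = model.fit(cov_type="conley")
            hc0 = model.fit(cov_type="hc0")
            ratios.append(
                (conley.gamma["se"] / hc0.gamma["se"]).mean()
            )
        assert np.mean(ratios) > 1.1


class TestDivergence:
    def test_identical_fits_no_divergence(self):
        exposures, yields, cent = _random_panel(seed=9)
        res = BinnedYieldModel(exposures, yields, centroids=cent).fit()
        flags, count = ci_overlap_divergence(res, res)
        assert count == 0 and not flags.any()

    def test_interval_conventions(self):
        # disjoint -> divergent; shared endpoint -> overlapping
        a = pd.DataFrame({"lower": [0.1], "upper": [0.2]}, index=["bin_0_3"])
        b = pd.DataFrame({"lower": [0.3], "upper": [0.4]}, index=["bin_0_3"])
        c = pd.DataFrame({"lower": [0.1], "upper": [0.3]}, index=["bin_0_3"])

        class Fake:
            def __init__(self, ci):
                self._ci = ci
                self.temp_cols = list(ci.index)

            def conf_int(self, level=None):
                return self._ci

        assert ci_overlap_divergence(Fake(a), Fake(b))[1] == 1
        assert ci_overlap_divergence(Fake(c), Fake(b))[1] == 0  # shared endpoint
        # symmetry
        assert ci_overlap_divergence(Fake(b), Fake(a))[1] == 1

    def test_large_true_difference_flagged(self, county_exposure_small, regions_small):
        truth = by.default_true_model(regions_small, seed=10, error_sd=0.02)
        shifted_gamma = dict(truth.gamma)
        shifted_gamma["bin_24_27"] += 0.05  # far beyond a few SEs
        from dataclasses import replace

        truth_b = replace(truth, gamma=shifted_gamma, seed=11)
        ya = by.gen_yields_statistical(county_exposure_small, truth, regions_small)
        yb = by.gen_yields_statistical(county_exposure_small, truth_b, regions_small)
        cent = regions_small.centroids()
        ra = BinnedYieldModel(county_exposure_small, ya, centroids=cent).fit()
        rb = BinnedYieldModel(county_exposure_small, yb, centroids=cent).fit()
        flags, _ = ci_overlap_divergence(ra, rb)
        assert flags["bin_24_27"]


class TestEnsembleMedian:
    def _panel(self, yields, source):
        return pd.DataFrame(
            {
                "county_id": [0] * len(yields),
                "state_id": [0] * len(yields),
                "year": range(2000, 2000 + len(yields)),
                "yield": yields,
                "source": source,
            }
        )

    def test_odd_count_median(self):
        panels = [self._panel([2.0], "a"), self._panel([3.0], "b"), self._panel([10.0], "c")]
        med = ensemble_median(panels)
        assert med["yield"].iloc[0] == 3.0
        assert (med["source"] == "ensemble-median").all()

    def test_even_count_mean_of_middle(self):
        panels = [self._panel([v], s) for v, s in zip([1.0, 2.0, 3.0, 4.0], "abcd")]
        assert ensemble_median(panels)["yield"].iloc[0] == 2.5

    def test_single_source_identity(self):
        p = self._panel([5.0, 6.0], "only")
        med = ensemble_median([p])
        np.testing.assert_allclose(med["yield"], p["yield"])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ensemble_median([])
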