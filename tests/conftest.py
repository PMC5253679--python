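"""Shared synthetic fixtures: weather grids, regions, exposures, panels."""

import numpy as np
import pandas as pd
import pytest

import binyield as by


@pytest.fixture(scope="session")
def grid_small():
    return by.gen_weather(by.ClimateGenConfig(grid_rows=6, grid_cols=6, years=8, seed=7))


@pytest.fixture(scope="session")
def regions_small(grid_small):
    return by.gen_regions(
        by.RegionGenConfig(n_counties=9, cells_per_county=4, n_states=3, seed=1),
        grid_small,
    )


@pytest.fixture(scope="session")
def county_exposure_small(grid_small, regions_small):
    cells = by.season_exposure(grid_small, by.default_season("maize"))
    return by.aggregate_to_counties(cells, regions_small)


@pytest.fixture(scope="session")
def grid_mc():
    """Corn-belt-like grid backing the 200-county, 31-year study panels."""
    return by.gen_weather(by.ClimateGenConfig(grid_rows=20, grid_cols=20, years=31, seed=11))


@pytest.fixture(scope="session")
def regions_mc(grid_mc):
    return by.gen_regions(
        by.RegionGenConfig(n_counties=200, cells_per_county=2, n_states=10, seed=2),
        grid_mc,
    )


@pytest.fixture(scope="session")
def county_exposure_mc(grid_mc, regions_mc):
    cells = by.season_exposure(grid_mc, by.default_season("maize"))
    panel = by.aggregate_to_counties(cells, regions_mc)
    panel.check_conservation()
    return panel


@pytest.fixture(scope="session")
def sin_samples():
    """Sorted dense samples of sin(2*pi*t) over one day: the quadrature oracle.

    The empirical distribution of the sampled sinusoid gives the oracle
    fraction of the day above any threshold without using the closed form.
    """
    n = 4_000_000
    t = (np.arange(n) + 0.5) / n
    return np.sort(np.sin(2 * np.pi * t))


def oracle_fraction_above(tmin, tmax, threshold, samples):
    """Brute-force time-above-threshold from sampled diurnal temperatures."""
    mid = (tmax + tmin) / 2.0
    amp = (tmax - tmin) / 2.0
    if amp == 0:
        return float(tmin > threshold)
    z = (threshold - mid) / amp
    return 1.0 - np.searchsorted(samples, z, side="right") / len(samples)
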