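"""Region map: grid cells -> counties -> states, with crop-area weights."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["RegionMap", "classify_counties"]

# county classification thresholds (crop-area shares)
RAINFED_MIN_SHARE = 0.90
IRRIGATED_MIN_SHARE = 0.75


class RegionMap:
    """Links grid cells to counties and counties to states.

    ``cells``: DataFrame with columns ``cell_id, lat, lon, county_id, weight``
    (optionally ``weight_rainfed``/``weight_irrigated`` for regime-specific
    crop-area weighting).  Weights are nonnegative crop-area weights; they are
    renormalized to sum to one within each county on construction, so any
    positive rescaling of a county's weights leaves aggregation unchanged.

    ``counties``: DataFrame with columns ``county_id, state_id,
    rainfed_share``; centroids (``lat``/``lon``) are the weight-weighted mean
    cell coordinates and are computed here.
    """

    def __init__(self, cells: pd.DataFrame, counties: pd.DataFrame):
        cells = cells.copy()
        counties = counties.copy()
        for col in ("cell_id", "lat", "lon", "county_id", "weight"):
            if col not in cells.columns:
                raise ValueError(f"cells table missing column {col!r}")
        for col in ("county_id", "state_id", "rainfed_share"):
            if col not in counties.columns:
                raise ValueError(f"counties table missing column {col!r}")
        if cells["cell_id"].duplicated().any():
            raise ValueError("a cell is assigned to more than one county")
        shares = counties["rainfed_share"].to_numpy(float)
        if np.any((shares < 0) | (shares > 1)):
            raise ValueError("rainfed_share outside [0, 1]")
        for wcol in self._weight_cols(cells):
            if (cells[wcol] < 0).any():
                raise ValueError(f"negative {wcol} in cells table")
            tot = cells.groupby("county_id")[wcol].transform("sum")
            cells[wcol] = np.where(tot > 0, cells[wcol] / tot.replace(0, np.nan), 0.0)
        self.cells = cells.reset_index(drop=True)
        cent = (
            cells.assign(
                wlat=cells["lat"] * cells["weight"], wlon=cells["lon"] * cells["weight"]
            )
            .groupby("county_id")[["wlat", "wlon"]]
            .sum()
            .rename(columns={"wlat": "lat", "wlon": "lon"})
        )
        counties = counties.set_index("county_id")
        counties["lat"] = cent["lat"]
        counties["lon"] = cent["lon"]
        self.counties = counties.reset_index()

    @staticmethod
    def _weight_cols(cells: pd.DataFrame) -> list[str]:
        return [
            c for c in ("weight", "weight_rainfed", "weight_irrigated") if c in cells.columns
        ]

    @property
    def county_ids(self) -> np.ndarray:
        return self.counties["county_id"].to_numpy()

    def centroids(self) -> pd.DataFrame:
        """County centroids (lat, lon in degrees), indexed by county_id."""
        return self.counties.set_index("county_id")[["lat", "lon"]]

    def states(self) -> pd.Series:
        return self.counties.set_index("county_id")["state_id"]

    def cell_weights(self, regime: str = "rainfed") -> pd.DataFrame:
        """Per-cell weights for a water regime, renormalized within county.

        Uses a regime-specific column when present, else the common crop-area
        ``weight``.  Counties whose total weight for the regime is zero are
        dropped with a logged warning.
        """
        col = f"weight_{regime}"
        if col not in self.cells.columns:
            col = "weight"
        w = self.cells[["cell_id", "county_id", col]].rename(columns={col: "weight"})
        tot = w.groupby("county_id")["weight"].transform("sum")
        dropped = w.loc[tot <= 0, "county_id"].unique()
        if len(dropped):
            logger.warning(
                "dropping %d counties with zero %s weight: %s",
                len(dropped), regime, list(dropped[:10]),
            )
            w = w[tot > 0]
            tot = tot[tot > 0]
        w = w.assign(weight=w["weight"] / tot)
        return w.reset_index(drop=True)

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path) -> None:
        """Single flat CSV: one row per cell with county attributes merged."""
        merged = self.cells.merge(
            self.counties[["county_id", "state_id", "rainfed_share"]], on="county_id"
        )
        merged.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RegionMap":
        df = pd.read_csv(path)
        county_cols = ["county_id", "state_id", "rainfed_share"]
        missing = set(county_cols) - set(df.columns)
        if missing:
            raise ValueError(f"region CSV missing columns: {sorted(missing)}")
        counties = df[county_cols].drop_duplicates("county_id")
        cells = df.drop(columns=["state_id", "rainfed_share"])
        return cls(cells, counties)

    def __repr__(self) -> str:
        return (
            f"<RegionMap {len(self.cells)} cells, {len(self.counties)} counties, "
            f"{self.counties['state_id'].nunique()} states>"
        )


def classify_counties(
    regions: RegionMap,
    rainfed_min: float = RAINFED_MIN_SHARE,
    irrigated_min: float = IRRIGATED_MIN_SHARE,
) -> pd.Series:
    """Classify counties as ``rainfed``, ``irrigated`` or ``excluded``.

    A county is rainfed when its crop-area rainfed share is at least 90%,
    irrigated when the irrigated share (1 - rainfed share) is at least 75%;
    mixed counties (rainfed share between 25% and 90%) are excluded.
    """
    shares = regions.counties.set_index("county_id")["rainfed_share"]
    if ((shares < 0) | (shares > 1)).any():
        raise ValueError("rainfed_share outside [0, 1]")
    out = pd.Series("excluded", index=shares.index, name="regime")
    out[shares >= rainfed_min] = "rainfed"
    out[(1.0 - shares) >= irrigated_min] = "irrigated"
    return out
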