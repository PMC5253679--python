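"""Readers, writers and run manifests for the pipeline's file formats.

CSV dialect throughout: UTF-8, comma-separated, header row, ISO dates.
Weather additionally round-trips through NetCDF (via xarray's scipy
backend) when the filename ends in ``.nc``.
"""

from __future__ import annotations

import importlib.resources
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .decomposition import ChangeFactors
from .weather import DailyWeatherGrid

__all__ = [
    "read_weather",
    "write_weather",
    "read_yield_panel",
    "write_yield_panel",
    "write_fit_result",
    "read_fit_csv",
    "write_manifest",
    "load_reference_change_factors",
    "read_change_factors",
]

YIELD_COLS = ("county_id", "state_id", "year", "yield")


def read_weather(path) -> DailyWeatherGrid:
    path = Path(path)
    if path.suffix == ".nc":
        return DailyWeatherGrid.from_netcdf(path)
    return DailyWeatherGrid.from_csv(path)


def write_weather(grid: DailyWeatherGrid, path) -> None:
    path = Path(path)
    if path.suffix == ".nc":
        grid.to_netcdf(path)
    else:
        grid.to_csv(path)


def read_yield_panel(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(YIELD_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"yield panel {path}: missing columns {sorted(missing)}")
    keys = ["county_id", "year"] + (["source"] if "source" in df.columns else [])
    if df.duplicated(keys).any():
        dup = df[df.duplicated(keys, keep=False)].head(3)
        raise ValueError(f"yield panel {path}: duplicated county-year rows, e.g.\n{dup}")
    return df


def write_yield_panel(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_fit_result(res, out_dir, stem: str = "fit", extra: dict | None = None) -> None:
    """Coefficient CSV plus a JSON sidecar with sample sizes and the spec."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    res.to_csv(out_dir / f"{stem}_coefficients.csv")
    spec = res.spec
    sidecar = {
        "n_obs": int(res.nobs),
        "n_counties": int(res.n_counties),
        "n_params": int(res.n_params),
        "cov_type": res.cov_type,
        "alpha0": float(res.alpha0),
        "spec": {
            "response_form": spec.response_form,
            "knot": spec.knot,
            "ci_level": spec.ci_level,
            "spatial_cutoff": spec.spatial_cutoff,
            "distance_metric": spec.distance_metric,
            "spatial_kernel": spec.spatial_kernel,
        },
    }
    if extra:
        sidecar.update(extra)
    (out_dir / f"{stem}_meta.json").write_text(json.dumps(sidecar, indent=2))


def read_fit_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"name", "estimate", "se", "lower", "upper"} - set(df.columns)
    if missing:
        raise ValueError(f"fit CSV {path}: missing columns {sorted(missing)}")
    return df.set_index("name")


def write_manifest(out_dir, config: dict, seeds: dict | None = None) -> Path:
    """Provenance record written beside every run's outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "binyield",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": config,
        "seeds": seeds or {},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


def read_change_factors(path) -> list[tuple[ChangeFactors, ChangeFactors]]:
    """(historical, future) factor pairs per crop from a factors CSV.

    Columns: crop, period (historical|future), below30, f30_36, above36.
    """
    df = pd.read_csv(path)
    missing = {"crop", "period", "below30", "f30_36", "above36"} - set(df.columns)
    if missing:
        raise ValueError(f"factors CSV {path}: missing columns {sorted(missing)}")
    pairs = []
    for crop, grp in df.groupby("crop", sort=False):
        by_period = {}
        for _, row in grp.iterrows():
            by_period[row["period"]] = ChangeFactors(
                crop=crop,
                period=row["period"],
                factor_below30=float(row["below30"]),
                factor_30_36=float(row["f30_36"]),
                factor_above36=float(row["above36"]),
            )
        if set(by_period) != {"historical", "future"}:
            raise ValueError(f"factors CSV: crop {crop!r} needs historical and future rows")
        pairs.append((by_period["historical"], by_period["future"]))
    return pairs


def load_reference_change_factors() -> list[tuple[ChangeFactors, ChangeFactors]]:
    """Packaged reference change factors for US maize, soybean and wheat.

    Published end-of-century (RCP8.5) temperature-range yield change factors
    estimated from observed US county yields; used as the worked input of
    the decomposition report.
    """
    ref = importlib.resources.files("binyield.data") / "reference_change_factors.csv"
    with importlib.resources.as_file(ref) as path:
        return read_change_factors(path)
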