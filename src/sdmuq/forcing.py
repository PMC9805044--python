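"""Synthetic gridded environmental forcing from divergent pseudo earth-system models.

Generates annual spring-mean fields of seven ocean covariates over the study
domain for three stylised "pseudo-ESM" futures under a high-emissions
trajectory.  Each variable is a static spatial base field plus a linear
secular trend, an optional decadal sinusoid, and spatially correlated AR(1)
interannual noise, clipped to physical bounds.  The three default styles
share the base climatology but diverge in their trends — most strongly for
bottom oxygen and zooplankton — with divergence amplified nearshore.

A NetCDF ingest path is provided for real downscaled forcing; monthly inputs
are reduced to the March-May (spring) mean per year.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xarray as xr
from scipy import ndimage

from ._rng import child_rng
from .grids import GridSpec, make_grid

__all__ = [
    "VARIABLES",
    "EsmStyle",
    "default_styles",
    "generate_forcing",
    "write_forcing",
    "read_forcing",
    "env_to_frame",
]

#: covariates carried by every environmental field, with units
VARIABLES = {
    "SST": "degC",          # sea surface temperature
    "BT": "degC",           # bottom temperature
    "BO": "mmol m-3",       # bottom oxygen
    "MLD": "m",             # mixed layer depth
    "CHL": "mg m-3",        # surface chlorophyll-a
    "ZOO50": "mmol N m-2",  # zooplankton integrated over 50 m
    "ZOO200": "mmol N m-2", # zooplankton integrated over 200 m
}

# lower physical bounds applied after noise
_LOWER_BOUND = {"BO": 0.0, "CHL": 0.0, "ZOO50": 0.0, "ZOO200": 0.0, "MLD": 1.0}

SPRING_MONTHS = (3, 4, 5)


@dataclass(frozen=True)
class EsmStyle:
    """Statistical recipe of one pseudo-ESM.

    Parameters
    ----------
    esm_id:
        Label of the pseudo-ESM (e.g. ``"pseudo-HAD"``).
    trend_per_decade:
        Linear trend of each variable, units per decade.  Signs follow the
        expected high-emissions behaviour: temperatures warm; mixed layer
        depth, bottom oxygen and zooplankton decline.
    decadal_amplitude / decadal_period / decadal_phase:
        Amplitude (variable units), period (years) and phase (radians) of a
        low-frequency sinusoid; by default only MLD, CHL and zooplankton carry
        decadal variability.
    noise_sd:
        Standard deviation of the interannual anomaly of each variable.
    ar1_phi:
        Lag-1 autocorrelation of the interannual anomaly.
    noise_length:
        e-folding length (grid cells) of the spatial smoothing applied to the
        noise, making anomalies spatially coherent.
    nearshore_amplification:
        Multiplier applied to trends at the coast (decaying offshore), so the
        pseudo-ESMs diverge most in coastal waters.
    """

    esm_id: str
    trend_per_decade: dict[str, float]
    decadal_amplitude: dict[str, float] = field(default_factory=dict)
    decadal_period: float = 30.0
    decadal_phase: float = 0.0
    noise_sd: dict[str, float] = field(default_factory=dict)
    ar1_phi: float = 0.5
    noise_length: float = 3.0
    nearshore_amplification: float = 1.6


_BASE_NOISE = {
    "SST": 0.25, "BT": 0.10, "BO": 3.0, "MLD": 1.5,
    "CHL": 0.15, "ZOO50": 0.4, "ZOO200": 0.7,
}
_BASE_DECADAL = {"MLD": 4.0, "CHL": 0.25, "ZOO50": 0.7, "ZOO200": 1.3}


def default_styles() -> list[EsmStyle]:
    """The three default divergent pseudo-ESM recipes.

    Trends emulate a strong-forcing scenario: all styles warm and lose
    oxygen and zooplankton, but at different rates (pseudo-HAD warmest and
    most productivity loss, pseudo-GFDL mildest), with decadal cycles in MLD
    and zooplankton offset in phase between styles.
    """
    return [
        EsmStyle(
            esm_id="pseudo-GFDL",
            trend_per_decade={"SST": 0.22, "BT": 0.05, "BO": -0.8, "MLD": -0.4,
                              "CHL": -0.012, "ZOO50": -0.08, "ZOO200": -0.15},
            decadal_amplitude=dict(_BASE_DECADAL),
            decadal_phase=0.0,
            noise_sd=dict(_BASE_NOISE),
        ),
        EsmStyle(
            esm_id="pseudo-HAD",
            trend_per_decade={"SST": 0.45, "BT": 0.10, "BO": -1.8, "MLD": -0.8,
                              "CHL": -0.030, "ZOO50": -0.20, "ZOO200": -0.35},
            decadal_amplitude=dict(_BASE_DECADAL),
            decadal_phase=2.0,
            noise_sd=dict(_BASE_NOISE),
        ),
        EsmStyle(
            esm_id="pseudo-IPSL",
            trend_per_decade={"SST": 0.33, "BT": 0.07, "BO": -1.2, "MLD": -0.6,
                              "CHL": -0.020, "ZOO50": -0.14, "ZOO200": -0.25},
            decadal_amplitude=dict(_BASE_DECADAL),
            decadal_phase=4.0,
            noise_sd=dict(_BASE_NOISE),
        ),
    ]


def _base_field(var: str, grid: xr.Dataset) -> np.ndarray:
    """Static spring climatology of one variable, shape (nlat, nlon).

    Idealised but oceanographically plausible structure: SST decreases
    poleward; bottom temperature and oxygen follow bathymetry (cold, hypoxic
    at mid-slope depths); MLD deepens offshore; chlorophyll and zooplankton
    are concentrated in the coastal upwelling band.
    """
    lat = grid["lat"].values[:, None]
    lon = grid["lon"].values[None, :]
    depth = grid["bathymetry"].values
    dist = lon.max() - lon  # deg offshore of easternmost cell centers

    if var == "SST":
        return 21.0 - 0.45 * (lat - 30.0) + 0.06 * dist + 0.0 * depth
    if var == "BT":
        return 4.0 + 9.0 * np.exp(-depth / 350.0) - 0.05 * (lat - 30.0)
    if var == "BO":
        # oxygen minimum at mid-slope depths, ventilated shelf and abyss
        omz = 110.0 * np.exp(-0.5 * ((depth - 700.0) / 450.0) ** 2)
        return 180.0 - omz - 1.2 * (lat - 30.0)
    if var == "MLD":
        return 14.0 + 22.0 * np.tanh(dist / 7.0) + 0.25 * (lat - 30.0)
    if var == "CHL":
        return 0.4 + 4.5 * np.exp(-dist / 2.5) + 0.015 * (lat - 30.0)
    if var == "ZOO50":
        return 2.0 + 9.0 * np.exp(-dist / 3.0) + 0.05 * (lat - 30.0)
    if var == "ZOO200":
        return 5.0 + 11.0 * np.exp(-dist / 5.0) + 0.12 * (lat - 30.0)
    raise KeyError(f"unknown variable {var!r}")


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int],
                  length: float) -> np.ndarray:
    """Unit-variance white noise smoothed to correlation length ``length``."""
    w = rng.standard_normal(shape)
    if length > 0:
        w = ndimage.gaussian_filter(w, sigma=length, mode="nearest")
        sd = w.std()
        if sd > 0:
            w = w / sd
    return w


def generate_forcing(spec: GridSpec, style: EsmStyle, seed: int = 0) -> xr.Dataset:
    """Generate annual spring-mean forcing for one pseudo-ESM.

    Returns an ``xarray.Dataset`` with one ``(year, lat, lon)`` variable per
    covariate plus static ``bathymetry``, and ``esm_id`` in ``attrs``.
    Identical ``(spec, style, seed)`` yields bit-identical output.
    """
    grid = make_grid(spec)
    years = spec.years
    t = (years - years[0]).astype(float)  # years since start
    nlat, nlon = len(spec.lats), len(spec.lons)

    dist = grid["lon"].values.max() + spec.resolution / 2.0 - grid["lon"].values
    nearshore = 1.0 + (style.nearshore_amplification - 1.0) * np.exp(-dist / 4.0)

    data = {}
    for var in VARIABLES:
        rng = child_rng(seed, "forcing", style.esm_id, var)
        base = _base_field(var, grid)
        trend = style.trend_per_decade.get(var, 0.0) / 10.0
        trend_field = trend * nearshore[None, :] * np.ones((nlat, 1))

        amp = style.decadal_amplitude.get(var, 0.0)
        decadal = amp * np.sin(2.0 * np.pi * t / style.decadal_period
                               + style.decadal_phase)

        sd = style.noise_sd.get(var, 0.0)
        arr = np.empty((len(years), nlat, nlon))
        eps_prev = np.zeros((nlat, nlon))
        innov_sd = np.sqrt(max(1.0 - style.ar1_phi**2, 0.0))
        for i in range(len(years)):
            if sd > 0:
                w = _smooth_noise(rng, (nlat, nlon), style.noise_length)
                eps_prev = style.ar1_phi * eps_prev + innov_sd * w
            arr[i] = base + trend_field * t[i] + decadal[i] + sd * eps_prev
        if var in _LOWER_BOUND:
            arr = np.maximum(arr, _LOWER_BOUND[var])
        data[var] = (("year", "lat", "lon"), arr)

    data["bathymetry"] = (("lat", "lon"), grid["bathymetry"].values)
    ds = xr.Dataset(data, coords={"year": years, "lat": spec.lats, "lon": spec.lons})
    ds.attrs["esm_id"] = style.esm_id
    for var, units in VARIABLES.items():
        ds[var].attrs["units"] = units
    ds["bathymetry"].attrs["units"] = "m"
    return ds


def write_forcing(env: xr.Dataset, path) -> None:
    """Write a forcing dataset to NetCDF (classic format)."""
    env.to_netcdf(path, engine="scipy")


def read_forcing(path, variable_map: dict[str, str] | None = None) -> xr.Dataset:
    """Read gridded forcing from NetCDF, reducing monthly data to spring means.

    Parameters
    ----------
    variable_map:
        Optional mapping from canonical names (keys of :data:`VARIABLES`,
        plus ``bathymetry``) to the names used in the file.

    Files with a ``year`` axis are taken as annual spring means already; files
    with a datetime ``time`` axis are averaged over March-May within each year.
    """
    variable_map = variable_map or {}
    with xr.open_dataset(path, engine="scipy") as raw:
        raw = raw.load()

    rename = {v: k for k, v in variable_map.items() if v in raw}
    raw = raw.rename(rename)

    missing = [v for v in VARIABLES if v not in raw]
    if missing:
        raise KeyError(
            "forcing file is missing required variable(s): " + ", ".join(missing)
        )

    if "time" in raw.dims:
        times = pd.DatetimeIndex(raw["time"].values)
        if not times.is_monotonic_increasing:
            raise ValueError("time axis is not monotonically increasing")
        spring = raw.sel(time=times.month.isin(SPRING_MONTHS))
        env = spring.groupby("time.year").mean("time")
    elif "year" in raw.dims:
        if not np.all(np.diff(raw["year"].values) > 0):
            raise ValueError("year axis is not monotonically increasing")
        env = raw
    else:
        raise ValueError("forcing file must have a 'time' or 'year' axis")

    if "bathymetry" not in env:
        raise KeyError("forcing file is missing required variable(s): bathymetry")
    if "time" in env["bathymetry"].dims or "year" in env["bathymetry"].dims:
        env["bathymetry"] = env["bathymetry"].isel(
            {d: 0 for d in env["bathymetry"].dims if d in ("time", "year")}
        )
    return env


def env_to_frame(env: xr.Dataset, years=None) -> pd.DataFrame:
    """Flatten a forcing dataset to one row per (year, cell).

    Columns: year, cell, lat, lon, the seven covariates, bathymetry.
    Cell ids number lat-major over the grid, matching :func:`grids.cell_table`.
    """
    sub = env if years is None else env.sel(year=years)
    nlat, nlon = sub.sizes["lat"], sub.sizes["lon"]
    df = (
        sub[list(VARIABLES)]
        .to_dataframe()
        .reset_index()
    )
    # lat-major cell index within each year
    lat_idx = df["lat"].map({v: i for i, v in enumerate(sub["lat"].values)})
    lon_idx = df["lon"].map({v: i for i, v in enumerate(sub["lon"].values)})
    df["cell"] = lat_idx * nlon + lon_idx
    bathy = sub["bathymetry"].values.reshape(-1)
    df["bathymetry"] = bathy[df["cell"].values]
    cols = ["year", "cell", "lat", "lon"] + list(VARIABLES) + ["bathymetry"]
    return df[cols].sort_values(["year", "cell"]).reset_index(drop=True)
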