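"""Grid geometry and synthetic bathymetry.

The study domain is a rectangular latitude/longitude box emulating the
California Current System (30-48 degN, coast to 134 degW).  The coastline is
idealised as the eastern boundary of the box; bathymetry deepens monotonically
westward through a shelf, a slope and an abyssal plain, so that inshore
(shelf + slope) habitat masks can be defined by a single depth threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

__all__ = ["GridSpec", "make_grid", "inshore_mask"]

# depth profile versus distance (degrees of longitude) from the eastern
# boundary: shelf to ~1250 m at 8.5 deg offshore, slope to the abyssal plain
_PROFILE_DIST = np.array([0.0, 8.5, 13.0, 30.0])
_PROFILE_DEPTH = np.array([10.0, 1250.0, 4200.0, 4600.0])

#: depth threshold (m) delimiting the inshore shelf/slope habitat
INSHORE_MAX_DEPTH = 1200.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry and time axis of the simulation domain.

    Coordinates refer to cell centers.  The default box spans 30-48 degN and
    134-116 degW at 0.5 deg resolution over 1985-2100.
    """

    lat_min: float = 30.0
    lat_max: float = 48.0
    lon_min: float = -134.0
    lon_max: float = -116.0
    resolution: float = 0.5
    year_start: int = 1985
    year_end: int = 2100

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError(f"resolution must be positive, got {self.resolution}")
        if not (self.lat_min < self.lat_max and self.lon_min < self.lon_max):
            raise ValueError("grid bounds must satisfy min < max")
        if self.year_start > self.year_end:
            raise ValueError("year_start must not exceed year_end")

    @property
    def lats(self) -> np.ndarray:
        n = int(round((self.lat_max - self.lat_min) / self.resolution))
        return self.lat_min + (np.arange(n) + 0.5) * self.resolution

    @property
    def lons(self) -> np.ndarray:
        n = int(round((self.lon_max - self.lon_min) / self.resolution))
        return self.lon_min + (np.arange(n) + 0.5) * self.resolution

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    @property
    def n_cells(self) -> int:
        return len(self.lats) * len(self.lons)


def _bathymetry(spec: GridSpec) -> np.ndarray:
    """Static depth field (m, positive down), shape (nlat, nlon).

    Depth increases strictly from the eastern (coastal) column westward,
    with a small smooth along-shore modulation so the field is genuinely
    two-dimensional.  The modulation is multiplicative and positive, so the
    west-over-east monotonicity is preserved in every row.
    """
    lats, lons = spec.lats, spec.lons
    dist = lons.max() + spec.resolution / 2.0 - lons  # deg offshore, > 0
    profile = np.interp(dist, _PROFILE_DIST, _PROFILE_DEPTH)
    alongshore = 1.0 + 0.04 * np.sin(2.0 * np.pi * (lats - spec.lat_min) / 12.0)
    return alongshore[:, None] * profile[None, :]


def make_grid(spec: GridSpec) -> xr.Dataset:
    """Build the static grid: cell-center coordinates and bathymetry."""
    return xr.Dataset(
        {"bathymetry": (("lat", "lon"), _bathymetry(spec))},
        coords={"lat": spec.lats, "lon": spec.lons},
        attrs={"resolution": spec.resolution},
    )


def inshore_mask(grid: xr.Dataset, max_depth: float = INSHORE_MAX_DEPTH) -> xr.DataArray:
    """Boolean mask of shelf/slope cells (depth <= ``max_depth``)."""
    return grid["bathymetry"] <= max_depth


def cell_table(grid: xr.Dataset) -> pd.DataFrame:
    """Flatten the grid to one row per cell: (cell, lat, lon, bathymetry)."""
    df = grid["bathymetry"].to_dataframe().reset_index()
    df.insert(0, "cell", np.arange(len(df)))
    return df
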