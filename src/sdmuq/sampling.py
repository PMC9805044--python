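"""Observation design: random cell samples joined with truth and covariates.

The estimation models never see the full grid.  Training uses 500 random
cells per year over 1985-2010 (n = 13,000) and testing 500 random cells per
year over 2011-2100 (n = 45,000), drawn without replacement within each year
from the archetype's domain.  The SDM-facing covariates substitute surface
chlorophyll-a for the zooplankton fields that actually drive the simulation,
mimicking the imperfect prey information available in practice.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import xarray as xr

from ._rng import child_rng
from .forcing import VARIABLES, env_to_frame
from .operating_model import ArchetypeSpec

__all__ = [
    "SDM_COVARIATES",
    "TEMP_COVARIATE",
    "sample_cells",
    "attach_proxy_covariates",
]

log = logging.getLogger(__name__)

#: SDM-facing covariates per archetype (chlorophyll replaces zooplankton)
SDM_COVARIATES = {
    "HMS": ["SST", "MLD", "CHL"],
    "CPS": ["SST", "CHL", "bathymetry"],
    "GFS": ["BT", "BO", "bathymetry"],
}

#: the single covariate of the temperature-only parameterization
TEMP_COVARIATE = {"HMS": "SST", "CPS": "SST", "GFS": "BT"}

DEFAULT_N_PER_YEAR = 500
TRAIN_YEARS = (1985, 2010)
TEST_YEARS = (2011, 2100)


def sample_cells(truth: xr.Dataset, env: xr.Dataset, years,
                 n_per_year: int = DEFAULT_N_PER_YEAR, seed: int = 0,
                 role: str = "train") -> pd.DataFrame:
    """Draw the annual random-cell observation design.

    Each year, ``n_per_year`` distinct cells are drawn uniformly from the
    archetype's domain (all cells if fewer are available, with a warning).
    Rows carry cell geometry, all environmental covariates, and the truth
    columns (suitability, presence, biomass).  Reproducible under ``seed``.
    """
    if n_per_year < 1:
        raise ValueError("n_per_year must be >= 1")
    years = np.asarray(years)
    env_df = env_to_frame(env, years=years)

    mask = truth["mask"].values.reshape(-1)
    domain_cells = np.flatnonzero(mask)
    if n_per_year > len(domain_cells):
        log.warning(
            "requested %d cells/year but domain has only %d; sampling all cells",
            n_per_year, len(domain_cells),
        )

    rng = child_rng(seed, "sampling", role, truth.attrs.get("archetype", ""))
    take = min(n_per_year, len(domain_cells))
    picks = {
        int(yr): np.sort(rng.choice(domain_cells, size=take, replace=False))
        for yr in years
    }

    ncell = mask.size
    frames = []
    for yr in years:
        cells = picks[int(yr)]
        sub = env_df[env_df["year"] == yr].set_index("cell").loc[cells].reset_index()
        iy = int(np.flatnonzero(truth["year"].values == yr)[0])
        for col in ("suitability", "presence", "biomass"):
            sub[col] = truth[col].values[iy].reshape(ncell)[cells]
        frames.append(sub)
    out = pd.concat(frames, ignore_index=True)
    out.attrs["role"] = role
    out.attrs["seed"] = int(seed)
    out.attrs["archetype"] = truth.attrs.get("archetype", "")
    return out


def attach_proxy_covariates(samples: pd.DataFrame,
                            spec: ArchetypeSpec | str) -> pd.DataFrame:
    """Designate the SDM-facing covariate set for a sample table.

    Replaces the zooplankton drivers with the chlorophyll proxy in the list
    of covariates the estimation models are allowed to use; truth columns are
    untouched.  Idempotent.
    """
    name = spec if isinstance(spec, str) else spec.name
    covs = SDM_COVARIATES[name]
    missing = [c for c in covs if c not in samples.columns]
    if missing:
        raise KeyError(f"samples lack SDM covariate(s): {', '.join(missing)}")
    out = samples.copy()
    out.attrs = dict(samples.attrs)
    out.attrs["sdm_covariates"] = list(covs)
    out.attrs["temp_covariate"] = TEMP_COVARIATE[name]
    return out
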