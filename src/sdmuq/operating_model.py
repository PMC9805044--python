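"""Virtual-species operating models: the simulated "truth".

Each of three marine archetypes — a highly migratory species (HMS, albacore
style), a coastal pelagic species (CPS, anchovy style) and a groundfish
(GFS, sablefish style) — is defined by environmental response curves, a
suitability-to-presence logistic conversion, a lognormal biomass draw scaled
by suitability, and an optional population-level biomass multiplier
(boom-bust regimes for CPS, 20-year recruitment phases for GFS).

Suitability is the product of per-driver responses rescaled by the field
maximum, so the best cell-year in a simulation scores 1.  Where the species
is absent, biomass is exactly zero (hurdle structure).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xarray as xr

from ._rng import child_rng
from .grids import INSHORE_MAX_DEPTH

__all__ = [
    "ResponseCurve",
    "ArchetypeSpec",
    "default_archetypes",
    "eval_response",
    "combine_suitability",
    "presence_probability",
    "population_multiplier",
    "draw_truth",
]


@dataclass(frozen=True)
class ResponseCurve:
    """Suitability response of one environmental driver.

    Forms:

    - ``gaussian``: exp(-((x - optimum) / breadth)^2 / 2); peaks at 1.
    - ``logistic``: 1 / (1 + exp(-(x - midpoint)/slope)); monotone
      (increasing for slope > 0, decreasing for slope < 0).
    - ``linear-ramp``: 0 below ``low``, 1 above ``high``, linear between.
    """

    variable: str
    form: str
    params: dict[str, float]

    def __post_init__(self):
        allowed = {"gaussian", "logistic", "linear-ramp"}
        if self.form not in allowed:
            raise ValueError(f"unknown response form {self.form!r}")

    def __call__(self, x):
        return eval_response(self, x)


def eval_response(curve: ResponseCurve, x):
    """Evaluate a response curve; result is in [0, 1] for finite input."""
    x = np.asarray(x, dtype=float)
    p = curve.params
    if curve.form == "gaussian":
        z = (x - p["optimum"]) / p["breadth"]
        return np.exp(-0.5 * z * z)
    if curve.form == "logistic":
        return 1.0 / (1.0 + np.exp(-(x - p["midpoint"]) / p["slope"]))
    # linear-ramp
    lo, hi = p["low"], p["high"]
    return np.clip((x - lo) / (hi - lo), 0.0, 1.0)


def combine_suitability(parts: list[np.ndarray], rescale: bool = True) -> np.ndarray:
    """Combine per-driver suitabilities into total suitability.

    The combiner is the product of the components, rescaled by the maximum
    over the whole field so the best cell-year scores 1 (if the field is all
    zero the rescaling is skipped).
    """
    total = parts[0].astype(float).copy()
    for part in parts[1:]:
        total = total * part
    if rescale:
        m = np.nanmax(total)
        if m > 0:
            total = total / m
    return total


def presence_probability(suitability, beta: float, alpha: float):
    """Logistic conversion of suitability to presence probability.

    p = 1 / (1 + exp((s - beta) / alpha)) with alpha < 0, so probability
    increases with suitability; beta is the suitability at which p = 0.5 and
    |alpha| controls the sharpness of the conversion.
    """
    if alpha == 0:
        raise ValueError("alpha must be negative (nonzero)")
    if alpha > 0:
        raise ValueError("alpha must be negative so presence rises with suitability")
    s = np.asarray(suitability, dtype=float)
    return 1.0 / (1.0 + np.exp((s - beta) / alpha))


@dataclass(frozen=True)
class ArchetypeSpec:
    """Full definition of one virtual species archetype."""

    name: str
    curves: tuple[ResponseCurve, ...]
    presence_beta: float = 0.3
    presence_alpha: float = -0.05
    biomass_meanlog: float = 2.0
    biomass_sdlog: float = 0.3
    multiplier_kind: str = "none"  # none | boom-bust | recruitment-phase
    multiplier_params: dict[str, float] = field(default_factory=dict)
    domain: str = "full"  # full | inshore
    inshore_max_depth: float = INSHORE_MAX_DEPTH

    @property
    def driver_variables(self) -> list[str]:
        return [c.variable for c in self.curves]

    def domain_mask(self, env: xr.Dataset) -> np.ndarray:
        """Boolean (lat, lon) mask of the archetype's habitat domain."""
        if self.domain == "inshore":
            return (env["bathymetry"].values <= self.inshore_max_depth)
        return np.ones(env["bathymetry"].shape, dtype=bool)


def default_archetypes() -> dict[str, ArchetypeSpec]:
    """Default archetype parameterisations.

    Response optima sit in the upper-mid historical range of each driver so
    that historical suitability is strongly structured in space while
    end-of-century warming pushes a substantial fraction of the domain
    outside the historical niche.  The CPS and GFS domains are restricted to
    shelf/slope waters (depth <= 1200 m).
    """
    return {
        "HMS": ArchetypeSpec(
            name="HMS",
            curves=(
                ResponseCurve("SST", "gaussian", {"optimum": 16.0, "breadth": 3.0}),
                ResponseCurve("MLD", "gaussian", {"optimum": 32.0, "breadth": 12.0}),
                ResponseCurve("ZOO200", "logistic", {"midpoint": 8.0, "slope": 2.0}),
            ),
            domain="full",
            multiplier_kind="none",
        ),
        "CPS": ArchetypeSpec(
            name="CPS",
            curves=(
                ResponseCurve("SST", "gaussian", {"optimum": 14.5, "breadth": 3.5}),
                ResponseCurve("ZOO50", "logistic", {"midpoint": 5.0, "slope": 0.7}),
                ResponseCurve("bathymetry", "logistic", {"midpoint": 700.0, "slope": -180.0}),
            ),
            domain="inshore",
            multiplier_kind="boom-bust",
            multiplier_params={
                "p_stay_high": 0.8, "p_stay_low": 0.8,
                "high": 2.0, "low": 0.25, "jitter_sd": 0.2,
            },
        ),
        "GFS": ArchetypeSpec(
            name="GFS",
            curves=(
                ResponseCurve("BT", "gaussian", {"optimum": 6.0, "breadth": 2.0}),
                ResponseCurve("BO", "logistic", {"midpoint": 70.0, "slope": 25.0}),
                ResponseCurve("bathymetry", "gaussian", {"optimum": 500.0, "breadth": 350.0}),
            ),
            domain="inshore",
            multiplier_kind="recruitment-phase",
            multiplier_params={"low": 0.5, "high": 1.5, "phase_years": 20.0,
                               "ramp_years": 4.0},
        ),
    }


def population_multiplier(kind: str, years: np.ndarray,
                          params: dict[str, float] | None = None,
                          seed: int = 0) -> np.ndarray:
    """Annual population-level biomass multiplier M_t > 0.

    - ``none``: constant 1.
    - ``recruitment-phase``: alternates between a low and a high recruitment
      level every ``phase_years`` (default 20), i.e. a 40-year full cycle,
      with a smooth logistic ramp of width ``ramp_years`` at each transition.
      The first phase (from the first simulated year) is the low phase.
    - ``boom-bust``: a two-state (high/low) Markov regime series with
      multiplicative lognormal jitter, reproducible under ``seed``.
    """
    years = np.asarray(years)
    params = dict(params or {})
    if kind == "none":
        return np.ones(len(years))
    if kind == "recruitment-phase":
        low = params.get("low", 0.5)
        high = params.get("high", 1.5)
        phase = params.get("phase_years", 20.0)
        ramp = max(params.get("ramp_years", 4.0), 1e-6)
        t = (years - years[0]).astype(float)
        # smooth square wave: sum of logistic steps at each phase boundary
        m = np.full(len(years), low, dtype=float)
        n_bound = int(np.ceil((t.max() + 1) / phase)) + 1
        for k in range(n_bound):
            b = (k + 1) * phase
            sign = 1.0 if k % 2 == 0 else -1.0
            m += sign * (high - low) / (1.0 + np.exp(-(t - b) / (ramp / 4.0)))
        return np.clip(m, min(low, high), max(low, high))
    if kind == "boom-bust":
        p_hh = params.get("p_stay_high", 0.8)
        p_ll = params.get("p_stay_low", 0.8)
        high = params.get("high", 2.0)
        low = params.get("low", 0.25)
        jitter = params.get("jitter_sd", 0.2)
        rng = child_rng(seed, "boom-bust")
        state = rng.random() < 0.5  # True = high
        m = np.empty(len(years))
        for i in range(len(years)):
            level = high if state else low
            m[i] = level * np.exp(rng.normal(0.0, jitter) - 0.5 * jitter**2)
            stay = p_hh if state else p_ll
            if rng.random() > stay:
                state = not state
        return m
    raise ValueError(f"unknown multiplier kind {kind!r}")


def suitability_field(env: xr.Dataset, spec: ArchetypeSpec) -> np.ndarray:
    """Total habitat suitability, shape (nyear, nlat, nlon), max 1 on domain."""
    missing = [v for v in spec.driver_variables
               if v not in env.data_vars]
    if missing:
        raise KeyError(
            f"environmental field lacks driver variable(s) {missing} "
            f"required by archetype {spec.name}"
        )
    parts = []
    for curve in spec.curves:
        arr = env[curve.variable].values
        if curve.variable == "bathymetry":
            arr = np.broadcast_to(arr, (env.sizes["year"],) + arr.shape)
        parts.append(eval_response(curve, arr))
    total = combine_suitability(parts, rescale=False)
    mask = spec.domain_mask(env)
    total = total * mask[None, :, :]
    m = total.max()
    if m > 0:
        total = total / m
    return total


def draw_truth(env: xr.Dataset, spec: ArchetypeSpec, seed: int = 0) -> xr.Dataset:
    """Simulate "observed" presence and biomass for one archetype.

    Presence is Bernoulli in the logistic presence probability; where present,
    biomass = LogNormal(meanlog, sdlog) x suitability x M_t; elsewhere zero.
    Returns a Dataset with ``suitability``, ``presence``, ``biomass`` on
    (year, lat, lon), the annual ``multiplier`` and the domain ``mask``.
    """
    suit = suitability_field(env, spec)
    p = presence_probability(suit, spec.presence_beta, spec.presence_alpha)
    mask = spec.domain_mask(env)
    p = p * mask[None, :, :]

    years = env["year"].values
    mult = population_multiplier(
        spec.multiplier_kind, years, spec.multiplier_params, seed=seed
    )

    rng = child_rng(seed, "truth", spec.name, env.attrs.get("esm_id", ""))
    presence = (rng.random(p.shape) < p).astype(np.int8)
    lognorm = rng.lognormal(spec.biomass_meanlog, spec.biomass_sdlog, size=p.shape)
    biomass = presence * lognorm * suit * mult[:, None, None]

    ds = xr.Dataset(
        {
            "suitability": (("year", "lat", "lon"), suit),
            "presence": (("year", "lat", "lon"), presence),
            "biomass": (("year", "lat", "lon"), biomass),
            "multiplier": (("year",), mult),
            "mask": (("lat", "lon"), mask),
        },
        coords={"year": years, "lat": env["lat"].values, "lon": env["lon"].values},
        attrs={"archetype": spec.name, "esm_id": env.attrs.get("esm_id", "")},
    )
    return ds
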