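"""Environmental novelty relative to the historical reference niche.

Implements the ExDet two-part extrapolation metric.  For each projection
point, NT1 measures univariate range exceedance (sum of normalized distances
beyond each covariate's reference min/max; 0 when all covariates are within
range, negative otherwise) and NT2 measures combinatorial novelty inside the
univariate envelope (Mahalanobis distance to the reference mean, scaled by
the most extreme reference point).  A cell-year is novel when NT1 < 0
(univariate extrapolation) or NT2 > 1 (combinatorial extrapolation).

The reference niche is built from every grid cell of the archetype's domain
over the historical fitting period, not just the sampled cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "ReferenceNiche",
    "build_reference",
    "nt1",
    "nt2",
    "classify",
    "percent_novel",
]

ANALOG = "analog"
UNIVARIATE = "univariate-extrapolation"
COMBINATORIAL = "combinatorial-extrapolation"


@dataclass(frozen=True)
class ReferenceNiche:
    """Summary of the historical multivariate niche used for novelty scoring."""

    covariates: tuple[str, ...]
    mins: np.ndarray
    maxs: np.ndarray
    mean: np.ndarray
    cov_inv: np.ndarray | None   # None in the single-covariate fallback
    max_d2: float | None

    @property
    def n_covariates(self) -> int:
        return len(self.covariates)


def build_reference(points: pd.DataFrame | np.ndarray,
                    covariates: list[str] | None = None) -> ReferenceNiche:
    """Build the reference niche from historical cell-year covariate values.

    The covariance is ridge-regularized (1e-8 x trace added to the diagonal)
    before inversion; with a single covariate NT2 is undefined and
    classification falls back to NT1 only.
    """
    if isinstance(points, pd.DataFrame):
        covariates = list(covariates or points.columns)
        arr = points[covariates].to_numpy(dtype=float)
    else:
        arr = np.asarray(points, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        covariates = list(covariates or [f"x{i}" for i in range(arr.shape[1])])
    n, p = arr.shape
    if n < 2:
        raise ValueError("need at least 2 reference points")

    mins, maxs = arr.min(axis=0), arr.max(axis=0)
    mean = arr.mean(axis=0)
    if p == 1:
        return ReferenceNiche(tuple(covariates), mins, maxs, mean, None, None)

    cov = np.cov(arr, rowvar=False)
    cov = cov + 1e-8 * np.trace(cov) * np.eye(p)
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError as err:
        raise ValueError("reference covariance singular after regularization") from err
    centered = arr - mean
    d2 = np.einsum("ij,jk,ik->i", centered, cov_inv, centered)
    return ReferenceNiche(tuple(covariates), mins, maxs, mean, cov_inv,
                          float(d2.max()))


def _as_matrix(points, ref: ReferenceNiche) -> np.ndarray:
    if isinstance(points, pd.DataFrame):
        return points[list(ref.covariates)].to_numpy(dtype=float)
    arr = np.asarray(points, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :] if arr.shape[0] == ref.n_covariates else arr[:, None]
    return arr


def nt1(points, ref: ReferenceNiche) -> np.ndarray:
    """Univariate extrapolation score, <= 0 (0 iff all covariates in range).

    NT1 = sum over covariates of min{(x - min)/range, (max - x)/range, 0}.
    A zero-range covariate counts as in-range only where the point equals
    the reference value.
    """
    arr = _as_matrix(points, ref)
    rng = ref.maxs - ref.mins
    out = np.zeros(len(arr))
    for j in range(arr.shape[1]):
        x = arr[:, j]
        if rng[j] == 0:
            off = x != ref.mins[j]
            if np.any(off):
                raise ValueError(
                    f"covariate {ref.covariates[j]!r} has zero reference range "
                    "and out-of-range projection values"
                )
            continue
        ud = np.minimum.reduce([
            (x - ref.mins[j]) / rng[j],
            (ref.maxs[j] - x) / rng[j],
            np.zeros_like(x),
        ])
        out += ud
    return out


def nt2(points, ref: ReferenceNiche) -> np.ndarray:
    """Combinatorial novelty score, >= 0, for points inside the NT1 envelope.

    NT2 = Mahalanobis D^2 to the reference mean divided by the largest D^2
    of any reference point; > 1 means combinatorially novel.  Raises if
    called on points with NT1 < 0 (the metric is defined only inside the
    univariate envelope) or with a single covariate.
    """
    if ref.cov_inv is None:
        raise ValueError("NT2 undefined with a single covariate")
    if np.any(nt1(points, ref) < 0):
        raise ValueError("nt2 called on point(s) with NT1 < 0")
    arr = _as_matrix(points, ref)
    centered = arr - ref.mean
    d2 = np.einsum("ij,jk,ik->i", centered, ref.cov_inv, centered)
    return d2 / ref.max_d2


def classify(points, ref: ReferenceNiche) -> pd.DataFrame:
    """Per-point NT1, NT2 and novelty class.

    NT2 is reported only for points with NT1 = 0 (NaN otherwise).  Classes:
    ``univariate-extrapolation`` when NT1 < 0, ``combinatorial-extrapolation``
    when NT1 = 0 and NT2 > 1, else ``analog``.
    """
    arr = _as_matrix(points, ref)
    v1 = nt1(arr, ref)
    v2 = np.full(len(arr), np.nan)
    inside = v1 == 0
    if ref.cov_inv is not None and inside.any():
        v2[inside] = nt2(arr[inside], ref)
    cls = np.where(
        v1 < 0, UNIVARIATE,
        np.where(np.nan_to_num(v2, nan=0.0) > 1.0, COMBINATORIAL, ANALOG),
    )
    novel = (v1 < 0) | (np.nan_to_num(v2, nan=0.0) > 1.0)
    return pd.DataFrame({"nt1": v1, "nt2": v2, "novel": novel, "class": cls})


def percent_novel(env: xr.Dataset, ref: ReferenceNiche,
                  covariates: list[str], years=None,
                  mask: np.ndarray | None = None) -> pd.Series:
    """Percent of domain cells per year that are environmentally novel."""
    years = env["year"].values if years is None else np.asarray(years)
    flat_mask = (np.ones(env["bathymetry"].shape, bool) if mask is None
                 else np.asarray(mask)).reshape(-1)
    out = {}
    bathy = env["bathymetry"].values.reshape(-1)[flat_mask]
    for yr in years:
        cols = {}
        for c in covariates:
            if c == "bathymetry":
                cols[c] = bathy
            else:
                cols[c] = env[c].sel(year=yr).values.reshape(-1)[flat_mask]
        res = classify(pd.DataFrame(cols), ref)
        out[int(yr)] = 100.0 * res["novel"].mean()
    return pd.Series(out, name="percent_novel").rename_axis("year")


def reference_from_env(env: xr.Dataset, covariates: list[str],
                       years, mask: np.ndarray | None = None) -> ReferenceNiche:
    """Convenience: build the niche from every domain cell over given years."""
    flat_mask = (np.ones(env["bathymetry"].shape, bool) if mask is None
                 else np.asarray(mask)).reshape(-1)
    years = np.asarray(years)
    cols = {}
    for c in covariates:
        if c == "bathymetry":
            b = env["bathymetry"].values.reshape(-1)[flat_mask]
            cols[c] = np.tile(b, len(years))
        else:
            vals = env[c].sel(year=years).values.reshape(len(years), -1)
            cols[c] = vals[:, flat_mask].reshape(-1)
    return build_reference(pd.DataFrame(cols), covariates)
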