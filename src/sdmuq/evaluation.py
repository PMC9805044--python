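"""Scoring projections against the simulated truth.

Annual pooled Spearman rank correlation between true and predicted biomass
(zeros tie heavily; average ranks handle them), occurrence AUC by the
Mann-Whitney formulation, an 11-year centered running mean for time-series
display, latitude-band regional tags, and ensemble min/mean/max spread.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.metrics import roc_auc_score

__all__ = [
    "spearman_by_year",
    "auc_by_year",
    "running_mean",
    "regional_tag",
    "ensemble_spread",
]

REGIONS = ("north", "central", "south")


def spearman_by_year(truth: pd.DataFrame, pred: pd.DataFrame,
                     truth_col: str = "biomass",
                     pred_col: str = "biomass_pred") -> pd.Series:
    """Pooled annual Spearman rho between observed and estimated biomass.

    Rows are matched on (year, cell).  Years where either side is constant
    have no defined rank correlation and are recorded as NaN.
    """
    merged = truth[["year", "cell", truth_col]].merge(
        pred[["year", "cell", pred_col]], on=["year", "cell"], validate="one_to_one"
    )
    out = {}
    for yr, grp in merged.groupby("year"):
        a, b = grp[truth_col].values, grp[pred_col].values
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            out[int(yr)] = np.nan
        else:
            out[int(yr)] = float(spearmanr(a, b).statistic)
    return pd.Series(out, name="rho").rename_axis("year")


def auc_by_year(truth: pd.DataFrame, pred: pd.DataFrame,
                presence_col: str = "presence",
                score_col: str = "p_occ") -> pd.Series:
    """Annual occurrence AUC (Mann-Whitney, ties half-credited).

    Years with a single presence class have no defined AUC -> NaN.
    """
    merged = truth[["year", "cell", presence_col]].merge(
        pred[["year", "cell", score_col]], on=["year", "cell"], validate="one_to_one"
    )
    out = {}
    for yr, grp in merged.groupby("year"):
        y = grp[presence_col].values
        if y.min() == y.max():
            out[int(yr)] = np.nan
        else:
            out[int(yr)] = float(roc_auc_score(y, grp[score_col].values))
    return pd.Series(out, name="auc").rename_axis("year")


def running_mean(series: pd.Series, window: int = 11) -> pd.Series:
    """Centered running mean; edge windows shrink to the available points."""
    if window % 2 == 0:
        raise ValueError("running-mean window must be odd")
    return series.rolling(window, center=True, min_periods=1).mean()


def regional_tag(lat) -> np.ndarray:
    """Latitude-band region: north (> 40), central (34.5-40), south (< 34.5).

    Both boundary latitudes belong to the central band.
    """
    lat = np.asarray(lat, dtype=float)
    out = np.where(lat > 40.0, "north", np.where(lat < 34.5, "south", "central"))
    return out if out.ndim else out.item()


def ensemble_spread(member_series: dict[str, pd.Series]) -> pd.DataFrame:
    """Per-year min/mean/max/range across ensemble members.

    ``member_series`` maps member id to a year-indexed series (e.g. annual
    rho or aggregate biomass).  Requires at least two members.
    """
    if len(member_series) < 2:
        raise ValueError("ensemble spread requires at least 2 members")
    wide = pd.DataFrame(member_series)
    out = pd.DataFrame({
        "min": wide.min(axis=1),
        "mean": wide.mean(axis=1),
        "max": wide.max(axis=1),
    })
    out["range"] = out["max"] - out["min"]
    return out
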