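"""Variance partitioning of ensemble projections by dominance analysis.

For each year and region, the aggregate predicted biomass of every ensemble
member is regressed on three categorical factors — forcing pseudo-ESM (3
levels), SDM family (4 levels) and covariate parameterization (up to 6
levels).  General dominance assigns each factor its average incremental R^2
over all subsets of the other factors (exhaustively enumerated: with three
groups there are only 2^3 subsets), a quantity whose group-wise sum equals
the full model R^2.  Relative uncertainty shares are the general dominance
weights renormalized over the three factors.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .evaluation import regional_tag, running_mean

__all__ = [
    "aggregate_predictions",
    "r_squared",
    "general_dominance",
    "relative_shares",
    "shares_by_year",
]

FACTORS = ("esm", "family", "parameterization")


def aggregate_predictions(predictions: pd.DataFrame,
                          by_region: bool = True) -> pd.DataFrame:
    """Sum member predictions per (year, region).

    ``predictions`` is the long table of test-cell predictions with columns
    (archetype, esm, family, parameterization, year, lat, biomass_pred).
    Returns one row per (member, year, region) — region ``all`` when
    ``by_region`` is false — with the regional biomass aggregate.
    """
    df = predictions.copy()
    df["region"] = regional_tag(df["lat"]) if by_region else "all"
    keys = ["archetype", "esm", "family", "parameterization", "year", "region"]
    out = df.groupby(keys, as_index=False)["biomass_pred"].sum()
    return out.rename(columns={"biomass_pred": "biomass"})


def _dummies(values: pd.Series) -> np.ndarray:
    """Full-rank dummy coding (first level dropped)."""
    d = pd.get_dummies(values.astype(str), drop_first=True)
    return d.to_numpy(dtype=float)


def r_squared(y: np.ndarray, blocks: list[np.ndarray]) -> float:
    """R^2 of an OLS fit of y on an intercept plus the given dummy blocks."""
    n = len(y)
    X = np.hstack([np.ones((n, 1))] + blocks) if blocks else np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        return 0.0
    return 1.0 - float((resid**2).sum()) / tss


def general_dominance(rows: pd.DataFrame, response: str = "biomass",
                      factors: tuple[str, ...] = FACTORS) -> dict[str, float]:
    """General dominance weights of factor groups for one cross-section.

    Each factor enters and leaves the model as its whole dummy block.  The
    weight of factor g is the mean over subset sizes k of the average
    incremental R^2 of adding g to each size-k subset of the other factors.
    Weights sum to the full-model R^2.  Factors with a single observed level
    explain nothing and receive weight 0.
    """
    y = rows[response].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        return {g: 0.0 for g in factors}
    blocks = {g: _dummies(rows[g]) for g in factors}

    cache: dict[frozenset, float] = {}

    def r2(subset: frozenset) -> float:
        if subset not in cache:
            cache[subset] = r_squared(y, [blocks[g] for g in factors if g in subset])
        return cache[subset]

    weights = {}
    for g in factors:
        others = [f for f in factors if f != g]
        level_means = []
        for k in range(len(others) + 1):
            incs = [
                r2(frozenset(sub) | {g}) - r2(frozenset(sub))
                for sub in combinations(others, k)
            ]
            level_means.append(float(np.mean(incs)))
        weights[g] = float(np.mean(level_means))
    return weights


def relative_shares(weights: dict[str, float]) -> dict[str, float]:
    """Normalize dominance weights to shares summing to 1.

    Tiny negative weights from numerical noise are clipped to zero; if all
    weights are zero the shares are undefined (NaN).
    """
    vals = {g: (0.0 if -1e-10 < w < 0 else w) for g, w in weights.items()}
    if any(w < 0 for w in vals.values()):
        raise ValueError(f"negative dominance weight beyond numerical noise: {vals}")
    total = sum(vals.values())
    if total <= 0:
        return {g: float("nan") for g in vals}
    return {g: w / total for g, w in vals.items()}


def shares_by_year(agg: pd.DataFrame, smooth_window: int = 11,
                   factors: tuple[str, ...] = FACTORS) -> pd.DataFrame:
    """Uncertainty-share time series per (archetype, region).

    Dominance analysis is run on each (archetype, region, year) cross-section
    of member aggregates; the resulting share series are smoothed with a
    centered running mean before reporting.  Also records the full-model R^2.
    """
    recs = []
    for (arch, region, year), grp in agg.groupby(["archetype", "region", "year"]):
        w = general_dominance(grp, factors=factors)
        shares = relative_shares(w)
        recs.append({
            "archetype": arch, "region": region, "year": int(year),
            "r2": sum(w.values()),
            **{f"share_{g}": shares[g] for g in factors},
        })
    out = pd.DataFrame(recs).sort_values(["archetype", "region", "year"])
    if smooth_window and smooth_window > 1:
        share_cols = [f"share_{g}" for g in factors]
        out[share_cols] = (
            out.groupby(["archetype", "region"], group_keys=False)[share_cols]
            .apply(lambda d: d.apply(lambda s: running_mean(s, smooth_window)))
        )
    return out.reset_index(drop=True)
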