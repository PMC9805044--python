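"""Hurdle (delta) species distribution models and the projection ensemble.

Every estimation model is a two-part hurdle: a binary occurrence submodel and
a lognormal positive-biomass submodel fitted to log biomass on presence rows
only.  Combined predictions are p_occ x exp(mu_log + s^2/2), the
bias-corrected lognormal mean, with s^2 the training residual variance of the
log-biomass submodel.

Four model families are provided:

- ``GAM``  — penalized regression splines (per-covariate cubic B-spline
  bases, a tensor-product surface for the spatial term, an unconstrained
  spline in year for the temporal term).
- ``GLMM`` — linear fixed effects plus a low-rank Gaussian radial-basis
  spatial surface, a cheap surrogate for a mixed-model spatial random effect.
- ``BRT``  — stochastic gradient-boosted regression trees.
- ``MLP``  — a single-hidden-layer feedforward network on standardized inputs.

Covariate parameterizations combine environmental (E), spatial (S) and
temporal (T) terms, plus a deliberately under-specified temperature-only
(Temp) variant.  Models are never clipped to the training covariate range:
they extrapolate natively, and extrapolation is measured separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier, LGBMRegressor
from scipy.interpolate import BSpline
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.preprocessing import StandardScaler

from ._rng import child_seed
from .sampling import SDM_COVARIATES, TEMP_COVARIATE

__all__ = [
    "SdmConfig",
    "FittedSdm",
    "EnsembleMember",
    "DEFAULT_ROSTER",
    "DEFAULT_EXCLUSIONS",
    "build_design",
    "fit_hurdle",
    "project",
    "enumerate_ensemble",
]

FAMILIES = ("GAM", "GLMM", "BRT", "MLP")
PARAMETERIZATIONS = ("E", "S", "ES", "ST", "EST", "Temp")

#: the 15 model types of the full roster.  BRT_ST fills the roster's spare
#: slot (a spatiotemporal machine-learning variant with no environmental
#: covariates); the roster is configuration, not a hard-coded constant.
DEFAULT_ROSTER: tuple[tuple[str, str], ...] = (
    ("GAM", "E"), ("GAM", "S"), ("GAM", "ES"), ("GAM", "EST"),
    ("GLMM", "E"), ("GLMM", "ES"), ("GLMM", "ST"), ("GLMM", "EST"),
    ("BRT", "E"), ("BRT", "ES"), ("BRT", "ST"), ("BRT", "EST"),
    ("MLP", "E"), ("MLP", "ES"), ("MLP", "EST"),
)

#: model types dropped from the retained ensemble for poor projection-period
#: behaviour (spatial-only smoothers and the year-smooth additive model)
DEFAULT_EXCLUSIONS: frozenset[str] = frozenset({"GAM_S", "GAM_EST", "GLMM_ST"})

MIN_POSITIVE_ROWS = 30


@dataclass(frozen=True)
class SdmConfig:
    """One ensemble member's family and covariate parameterization."""

    family: str
    parameterization: str
    archetype: str
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.parameterization not in PARAMETERIZATIONS:
            raise ValueError(f"unknown parameterization {self.parameterization!r}")

    @property
    def sdm_id(self) -> str:
        return f"{self.family}_{self.parameterization}"


def build_design(samples: pd.DataFrame, config: SdmConfig) -> pd.DataFrame:
    """Assemble the feature table for one configuration.

    E contributes the archetype's SDM-facing covariates, S the (lat, lon)
    coordinates, T the year, and Temp a single temperature column.  Column
    order is deterministic: environmental, spatial, temporal.
    """
    param = config.parameterization
    cols: list[str] = []
    if param == "Temp":
        cols.append(TEMP_COVARIATE[config.archetype])
    elif "E" in param:
        cols.extend(SDM_COVARIATES[config.archetype])
    if "S" in param:
        cols.extend(["lat", "lon"])
    if "T" in param and param != "Temp":
        cols.append("year")
    missing = [c for c in cols if c not in samples.columns]
    if missing:
        raise KeyError(f"samples lack required covariate(s): {', '.join(missing)}")
    X = samples[cols].copy()
    X.attrs["env_cols"] = [c for c in cols if c not in ("lat", "lon", "year")]
    X.attrs["has_spatial"] = "S" in param
    X.attrs["has_temporal"] = "T" in param and param != "Temp"
    return X


# ---------------------------------------------------------------------------
# basis expansions for the semi-parametric families

class _SplineBasis:
    """Cubic B-spline basis for one covariate, knots at training quantiles.

    Outside the training range the basis extrapolates polynomially, so a
    spline in an always-increasing covariate (e.g. a year smooth) can and
    will run away over a long projection — that hazard is the point.
    """

    def __init__(self, df: int = 8, degree: int = 3):
        self.df = df
        self.degree = degree
        self.knots_: np.ndarray | None = None

    def fit(self, x: np.ndarray) -> "_SplineBasis":
        n_interior = self.df - self.degree - 1
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        # inverted-CDF quantiles depend only on the empirical distribution,
        # so knot placement is invariant to duplicated rows
        interior = (np.quantile(x, qs, method="inverted_cdf")
                    if n_interior > 0 else np.array([]))
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi <= lo:
            hi = lo + 1.0
        self.knots_ = np.concatenate([
            np.repeat(lo, self.degree + 1), interior, np.repeat(hi, self.degree + 1)
        ])
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        dm = BSpline.design_matrix(
            np.asarray(x, dtype=float), self.knots_, self.degree, extrapolate=True
        )
        return dm.toarray()


class _GamFeatures:
    """Additive spline features: one basis per covariate, tensor surface for S."""

    def __init__(self, env_cols, has_spatial, has_temporal,
                 df: int = 8, spatial_df: int = 5):
        self.env_cols = list(env_cols)
        self.has_spatial = has_spatial
        self.has_temporal = has_temporal
        self.df = df
        self.spatial_df = spatial_df

    def fit(self, X: pd.DataFrame) -> "_GamFeatures":
        self.bases_ = {c: _SplineBasis(self.df).fit(X[c].values)
                       for c in self.env_cols}
        if self.has_spatial:
            self.lat_basis_ = _SplineBasis(self.spatial_df + 3).fit(X["lat"].values)
            self.lon_basis_ = _SplineBasis(self.spatial_df + 3).fit(X["lon"].values)
        if self.has_temporal:
            self.year_basis_ = _SplineBasis(self.df).fit(X["year"].values)
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        blocks = [self.bases_[c].transform(X[c].values) for c in self.env_cols]
        if self.has_spatial:
            a = self.lat_basis_.transform(X["lat"].values)
            b = self.lon_basis_.transform(X["lon"].values)
            blocks.append(np.einsum("ni,nj->nij", a, b).reshape(len(X), -1))
        if self.has_temporal:
            blocks.append(self.year_basis_.transform(X["year"].values))
        return np.hstack(blocks) if blocks else np.empty((len(X), 0))


class _GlmmFeatures:
    """Polynomial fixed effects plus a low-rank RBF spatial surface.

    Environmental covariates enter as standardized linear + quadratic terms
    (the usual way GLM-type SDMs accommodate unimodal niche responses); the
    Gaussian radial basis at a coarse knot grid stands in for a spatial
    random effect; the year term enters linearly.
    """

    def __init__(self, env_cols, has_spatial, has_temporal, n_knots: int = 6):
        self.env_cols = list(env_cols)
        self.has_spatial = has_spatial
        self.has_temporal = has_temporal
        self.n_knots = n_knots

    def _raw(self, X: pd.DataFrame) -> np.ndarray:
        cols = [X[c].values for c in self.env_cols]
        cols += [X[c].values ** 2 for c in self.env_cols]
        if self.has_temporal:
            cols.append(X["year"].values)
        return np.column_stack(cols) if cols else np.empty((len(X), 0))

    def fit(self, X: pd.DataFrame) -> "_GlmmFeatures":
        lin_cols = self.env_cols + (["year"] if self.has_temporal else [])
        self.lin_cols_ = lin_cols
        if lin_cols:
            self.scaler_ = StandardScaler().fit(self._raw(X))
        if self.has_spatial:
            la = np.linspace(X["lat"].min(), X["lat"].max(), self.n_knots)
            lo = np.linspace(X["lon"].min(), X["lon"].max(), self.n_knots)
            ka, ko = np.meshgrid(la, lo, indexing="ij")
            self.knots_ = np.column_stack([ka.ravel(), ko.ravel()])
            spacing = max(la[1] - la[0], lo[1] - lo[0]) if self.n_knots > 1 else 1.0
            self.bandwidth_ = 1.5 * spacing
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        blocks = []
        if self.lin_cols_:
            blocks.append(self.scaler_.transform(self._raw(X)))
        if self.has_spatial:
            pts = X[["lat", "lon"]].values
            d2 = ((pts[:, None, :] - self.knots_[None, :, :]) ** 2).sum(axis=2)
            blocks.append(np.exp(-0.5 * d2 / self.bandwidth_**2))
        return np.hstack(blocks) if blocks else np.empty((len(X), 0))


class _BasisGlm:
    """Penalized GLM on an explicit basis expansion (occurrence or biomass).

    The penalty is expressed per training row, so the fit is invariant to
    duplicating the training data (a sanity property of deterministic
    likelihood-based fits).
    """

    # ridge weight per training row (Ridge's alpha scales with n, and
    # sklearn's logistic C multiplies the summed loss, so C scales with 1/n:
    # both choices keep the fit invariant to duplicated data).  The logistic
    # weight corresponds to a light penalty (C ~ 13) at the 13,000-row
    # annual-sampling training design.
    LOGISTIC_WEIGHT = 1.7e5
    RIDGE_ALPHA_PER_ROW = 1e-3

    def __init__(self, features, binary: bool):
        self.features = features
        self.binary = binary

    def fit(self, X: pd.DataFrame, y: np.ndarray) -> "_BasisGlm":
        F = self.features.fit(X).transform(X)
        n = len(F)
        if self.binary:
            self.model_ = LogisticRegression(
                C=self.LOGISTIC_WEIGHT / n, max_iter=200,
                solver="newton-cholesky", tol=1e-10,
            ).fit(F, y)
        else:
            self.model_ = Ridge(alpha=self.RIDGE_ALPHA_PER_ROW * n).fit(F, y)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        F = self.features.transform(X)
        if self.binary:
            # linear predictor -> probability by hand so that polynomial
            # basis extrapolation saturates instead of overflowing
            z = F @ self.model_.coef_.ravel() + self.model_.intercept_[0]
            return 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))
        return self.model_.predict(F)


class _Brt:
    def __init__(self, binary: bool, seed: int):
        kw = dict(
            n_estimators=500, learning_rate=0.05, max_depth=3, num_leaves=8,
            subsample=0.5, subsample_freq=1, random_state=seed,
            n_jobs=1, verbose=-1, min_child_samples=10,
        )
        self.binary = binary
        self.model_ = LGBMClassifier(**kw) if binary else LGBMRegressor(**kw)

    def fit(self, X, y):
        self.cols_ = list(X.columns)
        self.model_.fit(X[self.cols_], y)
        return self

    def predict(self, X):
        v = X[self.cols_]
        if self.binary:
            return self.model_.predict_proba(v)[:, 1]
        return self.model_.predict(v)


class _Mlp:
    def __init__(self, binary: bool, seed: int):
        kw = dict(hidden_layer_sizes=(16,), solver="lbfgs", max_iter=500,
                  random_state=seed)
        self.binary = binary
        self.model_ = MLPClassifier(**kw) if binary else MLPRegressor(**kw)
        self.scaler_ = StandardScaler()

    def fit(self, X, y):
        self.cols_ = list(X.columns)
        F = self.scaler_.fit_transform(X.values)
        self.model_.fit(F, y)
        return self

    def predict(self, X):
        F = self.scaler_.transform(X[self.cols_].values)
        if self.binary:
            return self.model_.predict_proba(F)[:, 1]
        return self.model_.predict(F)


def _make_submodel(config: SdmConfig, X: pd.DataFrame, binary: bool, seed: int):
    env_cols = X.attrs["env_cols"]
    has_s, has_t = X.attrs["has_spatial"], X.attrs["has_temporal"]
    if config.family == "GAM":
        return _BasisGlm(_GamFeatures(env_cols, has_s, has_t), binary)
    if config.family == "GLMM":
        return _BasisGlm(_GlmmFeatures(env_cols, has_s, has_t), binary)
    if config.family == "BRT":
        return _Brt(binary, seed)
    return _Mlp(binary, seed)


@dataclass
class FittedSdm:
    """A fitted hurdle model plus the metadata needed to project it."""

    config: SdmConfig
    occurrence: object
    positive: object
    resid_var: float
    train_ranges: pd.DataFrame  # per design column: min, max
    n_train: int
    n_positive: int

    @property
    def sdm_id(self) -> str:
        return self.config.sdm_id


def fit_hurdle(samples: pd.DataFrame, config: SdmConfig,
               seed: int | None = None) -> FittedSdm:
    """Fit the two-part hurdle model for one configuration.

    The occurrence submodel is fitted to presence/absence on all training
    rows; the biomass submodel to log biomass on presence rows only.  Raises
    if the training data contain a single class or too few positive rows.
    """
    seed = config.seed if seed is None else seed
    X = build_design(samples, config)
    y_pres = samples["presence"].values.astype(int)
    if y_pres.min() == y_pres.max():
        raise ValueError(
            "training data contain a single presence class; hurdle model unfittable"
        )
    pos = y_pres == 1
    if pos.sum() < MIN_POSITIVE_ROWS:
        raise ValueError(
            f"only {int(pos.sum())} positive rows (< {MIN_POSITIVE_ROWS}); "
            "biomass submodel unfittable"
        )

    occ = _make_submodel(config, X, binary=True, seed=child_seed(seed, "occ"))
    occ.fit(X, y_pres)

    Xp = X.loc[pos]
    Xp.attrs = dict(X.attrs)
    ylog = np.log(samples.loc[pos, "biomass"].values)
    bio = _make_submodel(config, Xp, binary=False, seed=child_seed(seed, "pos"))
    bio.fit(Xp, ylog)
    resid = ylog - bio.predict(Xp)
    resid_var = float(np.var(resid, ddof=1)) if len(resid) > 1 else 0.0

    ranges = pd.DataFrame({"min": X.min(axis=0), "max": X.max(axis=0)})
    return FittedSdm(
        config=config, occurrence=occ, positive=bio, resid_var=resid_var,
        train_ranges=ranges, n_train=len(X), n_positive=int(pos.sum()),
    )


_LOG_CLIP = 300.0  # cap on the log-scale prediction to keep exp() finite


def project(fitted: FittedSdm, data: pd.DataFrame) -> pd.DataFrame:
    """Predict combined biomass for new cell-years.

    combined = p_occ x exp(mu_log + s^2/2).  Covariates are not clipped to
    the training range; the log-scale mean is capped far outside any
    plausible value purely to keep the arithmetic finite.
    """
    X = build_design(data, fitted.config)
    p = np.asarray(fitted.occurrence.predict(X), dtype=float)
    p = np.clip(p, 0.0, 1.0)
    mu = np.asarray(fitted.positive.predict(X), dtype=float)
    mu = np.clip(np.nan_to_num(mu, nan=0.0), -_LOG_CLIP, _LOG_CLIP)
    pos_mean = np.exp(mu + 0.5 * fitted.resid_var)
    out = pd.DataFrame({
        "year": data["year"].values,
        "cell": data["cell"].values if "cell" in data else np.arange(len(data)),
        "p_occ": p,
        "pos_mean": pos_mean,
        "biomass_pred": p * pos_mean,
    })
    out.attrs["sdm_id"] = fitted.sdm_id
    return out


@dataclass(frozen=True)
class EnsembleMember:
    archetype: str
    esm_id: str
    config: SdmConfig

    @property
    def member_id(self) -> str:
        return f"{self.archetype}:{self.esm_id}:{self.config.sdm_id}"


def enumerate_ensemble(archetypes, esms, roster=DEFAULT_ROSTER,
                       exclusions=DEFAULT_EXCLUSIONS,
                       master_seed: int = 0) -> list[EnsembleMember]:
    """Full factorial of (model type x archetype x ESM) minus exclusions.

    Ordering is stable: archetype-major, then ESM, then roster order.  Each
    member receives a deterministic child seed so stochastic families are
    reproducible member by member.
    """
    members = []
    for arch in archetypes:
        for esm in esms:
            for fam, param in roster:
                sdm_id = f"{fam}_{param}"
                if sdm_id in exclusions:
                    continue
                cfg = SdmConfig(
                    family=fam, parameterization=param, archetype=arch,
                    seed=child_seed(master_seed, "sdm", arch, esm, sdm_id),
                )
                members.append(EnsembleMember(arch, esm, cfg))
    return members
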