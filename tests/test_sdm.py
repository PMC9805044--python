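import numpy as np
import pandas as pd
import pytest

from sdmuq.sampling import attach_proxy_covariates, sample_cells
from sdmuq.sdm import (
    DEFAULT_EXCLUSIONS,
    DEFAULT_ROSTER,
    FittedSdm,
    SdmConfig,
    build_design,
    enumerate_ensemble,
    fit_hurdle,
    project,
)
from scipy.stats import spearmanr


def monotone_toy(n=600, seed=0) -> pd.DataFrame:
    """Noiseless monotone world: present iff SST > 8, biomass 2*SST there."""
    rng = np.random.default_rng(seed)
    sst = rng.uniform(5, 25, n)
    presence = (sst > 8).astype(int)
    df = pd.DataFrame({
        "year": rng.integers(1985, 2011, n),
        "cell": np.arange(n),
        "lat": rng.uniform(30, 48, n),
        "lon": rng.uniform(-134, -116, n),
        "SST": sst,
        "presence": presence,
        "biomass": presence * 2.0 * sst,
    })
    return df


class TestBuildDesign:
    def test_environment_spatial_columns(self, hms_truth, default_env):
        samples = attach_proxy_covariates(
            sample_cells(hms_truth, default_env, [1990], 50, seed=1), "CPS")
        X = build_design(samples, SdmConfig("BRT", "ES", "CPS"))
        assert list(X.columns) == ["SST", "CHL", "bathymetry", "lat", "lon"]

    def test_temperature_only_single_column(self, hms_truth, default_env):
        samples = attach_proxy_covariates(
            sample_cells(hms_truth, default_env, [1990], 50, seed=1), "GFS")
        X = build_design(samples, SdmConfig("GAM", "Temp", "GFS"))
        assert list(X.columns) == ["BT"]

    def test_deterministic(self, hms_truth, default_env):
        samples = attach_proxy_covariates(
            sample_cells(hms_truth, default_env, [1990], 50, seed=1), "HMS")
        cfg = SdmConfig("MLP", "EST", "HMS")
        assert build_design(samples, cfg).equals(build_design(samples, cfg))

    def test_missing_covariate_named_in_error(self):
        df = monotone_toy()
        with pytest.raises(KeyError, match="MLD"):
            build_design(df, SdmConfig("GAM", "E", "HMS"))


@pytest.mark.parametrize("family", ["GAM", "GLMM", "BRT", "MLP"])
def test_every_family_recovers_noiseless_monotone_truth(family):
    """On a deterministic monotone toy, in-sample rank skill is near-perfect."""
    toy = monotone_toy()
    fitted = fit_hurdle(toy, SdmConfig(family, "Temp", "HMS", seed=1))
    pred = project(fitted, toy)
    rho = spearmanr(toy["biomass"], pred["biomass_pred"]).statistic
    assert rho >= 0.99, family


@pytest.mark.parametrize("family", ["GAM", "GLMM"])
def test_duplicating_training_rows_leaves_fit_unchanged(family):
    # likelihood-based deterministic fits are invariant to doubled data;
    # overlapping classes keep the occurrence likelihood strongly convex so
    # the optimizer reaches the unique optimum to tight tolerance
    rng = np.random.default_rng(5)
    toy = monotone_toy()
    p = 1.0 / (1.0 + np.exp(-(toy["SST"] - 12.0)))
    toy["presence"] = (rng.random(len(toy)) < p).astype(int)
    toy["biomass"] = toy["presence"] * 2.0 * toy["SST"]
    doubled = pd.concat([toy, toy], ignore_index=True)
    doubled.attrs = dict(toy.attrs)
    cfg = SdmConfig(family, "Temp", "HMS", seed=1)
    p1 = project(fit_hurdle(toy, cfg), toy)
    p2 = project(fit_hurdle(doubled, cfg), toy)
    np.testing.assert_allclose(p1["biomass_pred"], p2["biomass_pred"],
                               rtol=1e-6, atol=1e-9)


def test_single_class_training_rejected():
    toy = monotone_toy()
    toy["presence"] = 1
    toy["biomass"] = 2.0 * toy["SST"]
    with pytest.raises(ValueError, match="single presence class"):
        fit_hurdle(toy, SdmConfig("GAM", "Temp", "HMS"))


def test_too_few_positives_rejected():
    toy = monotone_toy(n=200)
    toy["presence"] = (toy["SST"] > 24.5).astype(int)
    toy["biomass"] = toy["presence"] * toy["SST"]
    with pytest.raises(ValueError, match="positive rows"):
        fit_hurdle(toy, SdmConfig("GAM", "Temp", "HMS"))


class _Const:
    def __init__(self, value):
        self.value = value

    def predict(self, X):
        return np.full(len(X), self.value)


def test_project_applies_lognormal_bias_correction():
    """Constant submodels reproduce r * exp(m + s^2/2) at every cell."""
    r, m, s2 = 0.37, 1.4, 0.25
    fitted = FittedSdm(
        config=SdmConfig("GLMM", "Temp", "HMS"),
        occurrence=_Const(r), positive=_Const(m), resid_var=s2,
        train_ranges=pd.DataFrame(), n_train=10, n_positive=5)
    data = monotone_toy(n=20)
    out = project(fitted, data)
    np.testing.assert_allclose(out["biomass_pred"],
                               r * np.exp(m + s2 / 2.0))
    # degenerate correction: s -> 0 gives r * exp(m)
    fitted.resid_var = 0.0
    out0 = project(fitted, data)
    np.testing.assert_allclose(out0["biomass_pred"], r * np.exp(m))


def test_zero_occurrence_annihilates_biomass():
    fitted = FittedSdm(
        config=SdmConfig("GLMM", "Temp", "HMS"),
        occurrence=_Const(0.0), positive=_Const(5.0), resid_var=0.1,
        train_ranges=pd.DataFrame(), n_train=10, n_positive=5)
    out = project(fitted, monotone_toy(n=10))
    assert (out["biomass_pred"] == 0).all()


def test_predictions_stay_finite_under_wild_extrapolation():
    # a year-spline pushed 90 years past its training range explodes on the
    # log scale; the combined prediction must still be finite
    toy = monotone_toy()
    toy["year"] = np.random.default_rng(0).integers(1985, 2011, len(toy))
    fitted = fit_hurdle(toy, SdmConfig("GAM", "ST", "HMS", seed=1))
    far = monotone_toy(n=50, seed=3)
    far["year"] = 2100
    out = project(fitted, far)
    assert np.isfinite(out["biomass_pred"]).all()


class TestEnumerateEnsemble:
    ARCHS = ["HMS", "CPS", "GFS"]
    ESMS = ["pseudo-GFDL", "pseudo-HAD", "pseudo-IPSL"]

    def test_retained_roster_size(self):
        members = enumerate_ensemble(self.ARCHS, self.ESMS)
        assert len(members) == 12 * 3 * 3 == 108

    def test_temperature_only_addition(self):
        temp = [("GAM", "Temp"), ("GLMM", "Temp"), ("BRT", "Temp"),
                ("MLP", "Temp")]
        members = enumerate_ensemble(self.ARCHS, self.ESMS, roster=temp,
                                     exclusions=frozenset())
        assert len(members) == 36

    def test_no_exclusions_gives_full_roster(self):
        members = enumerate_ensemble(self.ARCHS, self.ESMS,
                                     exclusions=frozenset())
        assert len(DEFAULT_ROSTER) == 15
        assert len(members) == 15 * 9 == 135

    def test_excluded_ids_absent(self):
        ids = {m.config.sdm_id for m in enumerate_ensemble(self.ARCHS, self.ESMS)}
        assert ids.isdisjoint(DEFAULT_EXCLUSIONS)

    def test_stable_ordering_and_per_member_seeds(self):
        a = enumerate_ensemble(self.ARCHS, self.ESMS, master_seed=1)
        b = enumerate_ensemble(self.ARCHS, self.ESMS, master_seed=1)
        assert a == b
        seeds = [m.config.seed for m in a]
        assert len(set(seeds)) == len(seeds)


def test_environmental_beats_spatial_only_in_sample(hms_truth, default_env):
    """The spatial-only additive model underfits the training data relative
    to its environmental sibling (the reason it is excluded downstream)."""
    train = attach_proxy_covariates(
        sample_cells(hms_truth, default_env, np.arange(1985, 2011), 500,
                     seed=2), "HMS")
    rhos = {}
    for param in ["E", "S"]:
        fitted = fit_hurdle(train, SdmConfig("GAM", param, "HMS", seed=2))
        pred = project(fitted, train)
        rhos[param] = spearmanr(train["biomass"], pred["biomass_pred"]).statistic
    assert rhos["E"] > rhos["S"]


def test_year_smooth_extrapolation_hazard(hms_truth, default_env):
    """Among spline configs the unconstrained year smooth (EST) degrades the
    most by late century, as spline extrapolation runs away."""
    train = attach_proxy_covariates(
        sample_cells(hms_truth, default_env, np.arange(1985, 2011), 500,
                     seed=2), "HMS")
    test = attach_proxy_covariates(
        sample_cells(hms_truth, default_env, np.arange(2071, 2101), 500,
                     seed=3, role="test"), "HMS")
    late = {}
    for param in ["E", "ES", "EST"]:
        fitted = fit_hurdle(train, SdmConfig("GAM", param, "HMS", seed=2))
        pred = project(fitted, test)
        late[param] = spearmanr(test["biomass"], pred["biomass_pred"]).statistic
    assert late["EST"] <= min(late["E"], late["ES"])
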