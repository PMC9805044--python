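import numpy as np
import pytest
from dataclasses import replace

from sdmuq.forcing import EsmStyle, generate_forcing
from sdmuq.grids import GridSpec
from sdmuq.operating_model import (
    ArchetypeSpec,
    ResponseCurve,
    combine_suitability,
    default_archetypes,
    draw_truth,
    eval_response,
    population_multiplier,
    presence_probability,
)


class TestResponseCurves:
    def test_gaussian_peaks_at_optimum(self):
        g = ResponseCurve("SST", "gaussian", {"optimum": 18.0, "breadth": 2.0})
        assert eval_response(g, 18.0) == pytest.approx(1.0)
        # closed form one breadth away: exp(-1/2)
        assert eval_response(g, 20.0) == pytest.approx(np.exp(-0.5))
        # symmetry about the optimum
        assert eval_response(g, 16.0) == pytest.approx(eval_response(g, 20.0))

    def test_logistic_midpoint_and_monotonicity(self):
        lo = ResponseCurve("ZOO50", "logistic", {"midpoint": 5.0, "slope": 1.5})
        assert eval_response(lo, 5.0) == pytest.approx(0.5)
        x = np.linspace(-10, 20, 200)
        assert (np.diff(eval_response(lo, x)) > 0).all()

    def test_curves_bounded_in_unit_interval(self):
        curves = [
            ResponseCurve("a", "gaussian", {"optimum": 0.0, "breadth": 1.0}),
            ResponseCurve("a", "logistic", {"midpoint": 0.0, "slope": -2.0}),
            ResponseCurve("a", "linear-ramp", {"low": 0.0, "high": 1.0}),
        ]
        x = np.linspace(-50, 50, 401)
        for c in curves:
            v = eval_response(c, x)
            assert (v >= 0).all() and (v <= 1).all()

    def test_unknown_form_rejected(self):
        with pytest.raises(ValueError, match="form"):
            ResponseCurve("a", "quadratic", {})


class TestCombiner:
    def test_identity_and_annihilator(self):
        assert combine_suitability([np.array([1.0]), np.array([1.0])])[0] == 1.0
        out = combine_suitability([np.array([0.0, 0.5]), np.array([0.9, 0.8])])
        assert out[0] == 0.0

    def test_field_max_rescaling(self):
        # two-cell field: products (0.4, 0.1); best cell rescales to 1
        out = combine_suitability([np.array([0.5, 0.5]), np.array([0.8, 0.2])])
        assert out[0] == pytest.approx(1.0)
        assert out[1] == pytest.approx(0.25)

    def test_all_zero_field_stays_zero(self):
        out = combine_suitability([np.zeros(3), np.zeros(3)])
        assert (out == 0).all()


class TestPresenceConversion:
    def test_midpoint_gives_half(self):
        assert presence_probability(0.3, 0.3, -0.05) == pytest.approx(0.5)

    def test_closed_form_value(self):
        # beta=0.5, alpha=-0.05, s=0.6 -> 1/(1+exp(-2))
        assert presence_probability(0.6, 0.5, -0.05) == pytest.approx(
            1.0 / (1.0 + np.exp(-2.0)))

    def test_sharp_limit_approaches_step(self):
        p = presence_probability(np.array([0.49, 0.51]), 0.5, -1e-4)
        assert p[0] < 1e-6 and p[1] > 1 - 1e-6

    def test_increasing_in_suitability(self):
        s = np.linspace(0, 1, 50)
        assert (np.diff(presence_probability(s, 0.4, -0.1)) > 0).all()

    @pytest.mark.parametrize("alpha", [0.0, 0.05])
    def test_invalid_alpha_rejected(self, alpha):
        with pytest.raises(ValueError):
            presence_probability(0.5, 0.3, alpha)


class TestPopulationMultiplier:
    years = np.arange(1985, 2185)

    def test_none_is_identity(self):
        assert (population_multiplier("none", self.years) == 1.0).all()

    def test_recruitment_phase_levels_and_period(self):
        m = population_multiplier(
            "recruitment-phase", self.years,
            {"low": 0.5, "high": 1.5, "phase_years": 20.0, "ramp_years": 4.0})
        # the first two 20-year phases sit at distinct levels
        assert abs(m[:20].mean() - m[20:40].mean()) > 0.5
        # autocorrelation of the cycle peaks at the 40-year full period
        x = m - m.mean()
        acf = np.array([np.corrcoef(x[:-k], x[k:])[0, 1] for k in range(1, 81)])
        assert np.argmax(acf) + 1 == 40

    def test_boom_bust_stationary_occupancy(self):
        # symmetric two-state chain: stationary P(high) = 0.5; jittered
        # levels 2.0 / 0.25 separate cleanly at their geometric midpoint
        years = np.arange(0, 10_000)
        m = population_multiplier(
            "boom-bust", years,
            {"p_stay_high": 0.8, "p_stay_low": 0.8, "high": 2.0, "low": 0.25,
             "jitter_sd": 0.2}, seed=42)
        occupancy = (m > np.sqrt(2.0 * 0.25)).mean()
        assert occupancy == pytest.approx(0.5, abs=0.03)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            population_multiplier("cyclic", self.years)


SMALL = GridSpec(resolution=2.0, year_end=2000)
QUIET = EsmStyle(esm_id="quiet", trend_per_decade={}, noise_sd={},
                 nearshore_amplification=1.0)


class TestDrawTruth:
    def test_hurdle_consistency(self, default_env):
        truth = draw_truth(default_env, default_archetypes()["CPS"], seed=3)
        b = truth["biomass"].values
        p = truth["presence"].values
        assert ((b > 0) == (p == 1)).all()
        assert (b[p == 0] == 0).all()

    def test_inshore_archetype_zero_offshore(self, default_env):
        truth = draw_truth(default_env, default_archetypes()["GFS"], seed=3)
        outside = ~truth["mask"].values
        assert (truth["biomass"].values[:, outside] == 0).all()
        assert (truth["presence"].values[:, outside] == 0).all()

    def test_degenerate_lognormal_gives_exact_biomass(self):
        env = generate_forcing(SMALL, QUIET, seed=0)
        spec = replace(default_archetypes()["HMS"], biomass_sdlog=1e-12,
                       multiplier_kind="none")
        truth = draw_truth(env, spec, seed=0)
        present = truth["presence"].values == 1
        expected = (np.exp(spec.biomass_meanlog)
                    * truth["suitability"].values[present])
        np.testing.assert_allclose(truth["biomass"].values[present], expected,
                                   rtol=1e-6)

    def test_lognormal_mean_matches_closed_form(self):
        # spatially flat environment -> suitability 1 everywhere; the mean
        # positive-cell biomass over ~1e5 draws matches exp(mu + sigma^2/2)
        # within 1%
        import xarray as xr

        years = np.arange(1985, 2235)
        nlat = nlon = 20
        flat = {"SST": 16.0, "MLD": 32.0, "ZOO200": 20.0}
        data = {
            var: (("year", "lat", "lon"),
                  np.full((len(years), nlat, nlon), val))
            for var, val in flat.items()
        }
        data["bathymetry"] = (("lat", "lon"), np.full((nlat, nlon), 100.0))
        env = xr.Dataset(data, coords={
            "year": years,
            "lat": np.linspace(31, 47, nlat),
            "lon": np.linspace(-133, -117, nlon)})
        spec = replace(default_archetypes()["HMS"], multiplier_kind="none")
        truth = draw_truth(env, spec, seed=1)
        b = truth["biomass"].values
        s = truth["suitability"].values
        present = truth["presence"].values == 1
        assert present.sum() > 50_000
        np.testing.assert_allclose(s, 1.0)
        expected = np.exp(spec.biomass_meanlog + spec.biomass_sdlog**2 / 2)
        assert b[present].mean() == pytest.approx(expected, rel=0.01)

    def test_missing_driver_raises(self, default_env):
        spec = default_archetypes()["HMS"]
        with pytest.raises(KeyError, match="ZOO200"):
            draw_truth(default_env.drop_vars("ZOO200"), spec, seed=0)

    def test_reproducible_under_seed(self, default_env):
        spec = default_archetypes()["CPS"]
        a = draw_truth(default_env, spec, seed=9)
        b = draw_truth(default_env, spec, seed=9)
        assert a.identical(b)

    def test_suitability_monotone_toward_optimum(self):
        # raising SST toward the optimum (others fixed) never lowers the
        # unrescaled response product
        spec = default_archetypes()["HMS"]
        sst_curve = spec.curves[0]
        opt = sst_curve.params["optimum"]
        x = np.linspace(opt - 8, opt, 100)
        assert (np.diff(eval_response(sst_curve, x)) >= 0).all()

    def test_poleward_shift_under_warming(self, default_env):
        # under trend forcing the biomass-weighted mean latitude of the two
        # pelagic archetypes moves north between the first and last decades
        lat = default_env["lat"].values
        for name in ["HMS", "CPS"]:
            truth = draw_truth(default_env, default_archetypes()[name], seed=3)
            w = truth["biomass"].values
            latgrid = np.broadcast_to(lat[:, None], w.shape[1:])
            early = (w[:26] * latgrid).sum() / w[:26].sum()
            late = (w[-26:] * latgrid).sum() / w[-26:].sum()
            assert late > early, name
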