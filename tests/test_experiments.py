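"""Experiment protocol: spinup, evaluation windows, sensitivity sweeps,
climate swaps, and observed-growth correlation."""

import numpy as np
import pandas as pd
import pytest

import nscsim as ns
from nscsim import experiments as ex


class TestSpinup:
    def test_deterministic(self, met50):
        a, _ = ex.spinup(ns.LOW_SITE, met50, years=10)
        b, _ = ex.spinup(ns.LOW_SITE, met50, years=10)
        assert a.__dict__ == b.__dict__

    def test_stabilizes_within_tolerance(self, spinup_diags):
        for name, diag in spinup_diags.items():
            assert diag["stabilization_rel_change_20yr"] < 0.05, name

    def test_biomass_ordered_along_gradient(self, spinup_states):
        b = {k: v.structural for k, v in spinup_states.items()}
        assert b["high"] >= b["mid"] >= b["low"]

    def test_lai_ordered_along_gradient(self, spinup_states):
        lai = {k: ns.lai_of(v.leafC) for k, v in spinup_states.items()}
        assert lai["high"] >= lai["mid"] >= lai["low"]

    def test_requires_full_year(self):
        short = ns.generate_synthetic_forcing(1, seed=1).iloc[:100]
        with pytest.raises(ns.forcing.ConfigurationError):
            ex.spinup(ns.LOW_SITE, short, years=2)


class TestRunWindow:
    def test_degenerate_single_year_window(self, spinup_states):
        met = ns.generate_synthetic_forcing(1, seed=4, site=ns.MID_SITE)
        _, annual, cell = ns.run_window(ns.MID_SITE,
                                        spinup_states["mid"].copy(), met,
                                        ns.NSCParams(), lead_in_years=0)
        assert len(annual) == 1
        assert cell["min_nsc"] == pytest.approx(annual["min_nsc"].iloc[0])

    def test_window_min_bounds_annual_minima(self, spinup_states, drought23):
        met = ns.adjust_to_site(drought23, 2262.0, ns.HIGH_SITE)
        _, annual, cell = ns.run_window(ns.HIGH_SITE,
                                        spinup_states["high"].copy(), met,
                                        ns.NSCParams(), lead_in_years=7)
        window_annual = annual.iloc[7:]
        assert (cell["min_nsc"] <= window_annual["min_nsc"] + 1e-12).all()

    def test_window_not_covered_raises(self, spinup_states):
        met = ns.generate_synthetic_forcing(3, seed=4, site=ns.MID_SITE)
        with pytest.raises(ns.forcing.ConfigurationError):
            ns.run_window(ns.MID_SITE, spinup_states["mid"].copy(), met,
                          ns.NSCParams(), lead_in_years=7)

    def test_benign_forcing_low_risk(self, spinup_states):
        met = ns.generate_synthetic_forcing(10, seed=6, site=ns.HIGH_SITE)
        _, _, cell = ns.run_window(ns.HIGH_SITE,
                                   spinup_states["high"].copy(), met,
                                   ns.NSCParams(nsc_npp_frac=0.3,
                                                minl_agc=0.05),
                                   lead_in_years=2)
        assert cell["risk"] == "low"


class TestSensitivityGrid:
    def test_degenerate_grid_equals_run_window(self, spinup_states,
                                               drought23):
        params = ns.NSCParams(nsc_npp_frac=0.3, minl_agc=0.05)
        grid = ns.sensitivity_grid([ns.HIGH_SITE], spinup_states, drought23,
                                   [0.3], [0.05])
        met = ns.adjust_to_site(drought23, 2262.0, ns.HIGH_SITE)
        _, _, cell = ns.run_window(ns.HIGH_SITE,
                                   spinup_states["high"].copy(), met, params)
        assert len(grid) == 1
        row = grid.iloc[0].to_dict()
        for k in ("min_nsc", "min_nsc_frac", "min_lai", "risk"):
            assert row[k] == cell[k]

    def test_stand_high_not_riskier_than_tree_at_upper_fraction(
            self, spinup_states, drought23):
        """With ample storage allocation, the spun-up high-elevation stand
        (greater biomass) keeps at least as small a biomass-normalised NSC
        minimum as a mid-sized tree under the same climate."""
        met = ns.adjust_to_site(drought23, 2262.0, ns.HIGH_SITE)
        p = ns.NSCParams(nsc_npp_frac=0.35, minl_agc=0.05)
        _, _, stand = ns.run_window(ns.HIGH_SITE,
                                    spinup_states["high"].copy(), met, p,
                                    mode="stand")
        _, _, tree = ns.run_window(ns.HIGH_SITE,
                                   spinup_states["mid"].copy(), met, p,
                                   mode="tree")
        stand_norm = stand["min_nsc"] / spinup_states["high"].structural
        tree_norm = tree["min_nsc"] / spinup_states["mid"].structural
        assert stand_norm <= tree_norm


class TestClimateSwap:
    def test_both_swapped_uses_other_site_forcing(self, spinup_states,
                                                  drought23):
        params = ns.NSCParams(nsc_npp_frac=0.25, minl_agc=0.05)
        swapped = ns.climate_swap(ns.HIGH_SITE, ns.LOW_SITE, drought23,
                                  "both_swapped", spinup_states, params,
                                  mode="tree")
        met_low = ns.adjust_to_site(drought23, 2262.0, ns.LOW_SITE)
        _, annual, _ = ns.run_window(ns.HIGH_SITE,
                                     spinup_states["mid"].copy(), met_low,
                                     params, mode="tree")
        direct = float(annual["npp"].iloc[7:].mean())
        assert swapped["high"]["mean_npp"] == pytest.approx(direct, rel=1e-12)

    def test_swap_is_involution(self, spinup_states, drought23):
        """Swapping (a,b) then reading site b equals swapping (b,a) and
        reading site b's counterpart: double swap recovers baseline."""
        params = ns.NSCParams(nsc_npp_frac=0.25, minl_agc=0.05)
        base = ns.climate_swap(ns.HIGH_SITE, ns.LOW_SITE, drought23,
                               "baseline", spinup_states, params, mode="tree")
        ab = ns.climate_swap(ns.HIGH_SITE, ns.LOW_SITE, drought23,
                             "both_swapped", spinup_states, params,
                             mode="tree")
        ba = ns.climate_swap(ns.LOW_SITE, ns.HIGH_SITE, drought23,
                             "both_swapped", spinup_states, params,
                             mode="tree")
        # site high under (a<->b) swap == site high under (b<->a) swap's
        # counterpart == low-site forcing; re-swapping restores baseline
        assert ab["high"]["mean_npp"] == pytest.approx(
            ba["high"]["mean_npp"], rel=1e-12)
        assert base["high"]["mean_npp"] != ab["high"]["mean_npp"]

    def test_all_rain_eliminates_snowpack(self, spinup_states, drought23):
        params = ns.NSCParams(nsc_npp_frac=0.25, minl_agc=0.05)
        out = ns.climate_swap(ns.HIGH_SITE, ns.LOW_SITE, drought23,
                              "all_rain", spinup_states, params, mode="tree")
        for site in ("high", "low"):
            assert np.all(out[site]["swe_daily"] == 0.0)

    def test_unknown_scenario_rejected(self, spinup_states, drought23):
        with pytest.raises(ValueError):
            ns.climate_swap(ns.HIGH_SITE, ns.LOW_SITE, drought23,
                            "nonsense", spinup_states, ns.NSCParams())


class TestGrowthCorrelation:
    def _summaries(self):
        rng = np.random.default_rng(3)
        growth = rng.uniform(100, 300, size=10)
        return pd.DataFrame({"water_year": np.arange(1992, 2002),
                             "npp": growth, "growth": growth,
                             "min_nsc": 0.0, "min_lai": 1.0})

    def test_affine_transform_perfect_correlation(self):
        s = self._summaries()
        obs = pd.DataFrame({"water_year": s["water_year"],
                            "bai": 0.1 * s["growth"] + 5.0})
        r, p = ns.growth_correlation(s, obs)
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_negated_deviations_anticorrelate(self):
        s = self._summaries()
        g = s["growth"]
        obs = pd.DataFrame({"water_year": s["water_year"],
                            "bai": 2 * g.mean() - g})
        r, _ = ns.growth_correlation(s, obs)
        assert r == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        s = self._summaries()
        rng = np.random.default_rng(9)
        obs = pd.DataFrame({"water_year": s["water_year"],
                            "bai": rng.uniform(10, 40, size=10)})
        r, _ = ns.growth_correlation(s, obs)
        g, b = s["growth"].to_numpy(), obs["bai"].to_numpy()
        gd, bd = g - g.mean(), b - b.mean()
        expected = (gd * bd).sum() / np.sqrt((gd ** 2).sum() * (bd ** 2).sum())
        assert r == pytest.approx(expected, abs=1e-12)

    def test_insufficient_overlap_rejected(self):
        s = self._summaries().iloc[:2]
        obs = pd.DataFrame({"water_year": [1992, 1993], "bai": [1.0, 2.0]})
        with pytest.raises(ValueError):
            ns.growth_correlation(s, obs)

    def test_zero_variance_rejected(self):
        s = self._summaries()
        obs = pd.DataFrame({"water_year": s["water_year"], "bai": 7.0})
        with pytest.raises(ValueError):
            ns.growth_correlation(s, obs)


class TestConstantForcingPlateau:
    def test_lai_plateaus_without_oscillation(self):
        """Steady favourable forcing (weekly rain pulses, fixed temps)
        drives LAI to a plateau; annual means stop drifting."""
        dates = pd.date_range("1980-10-01", periods=60 * 365, freq="D")
        precip = np.where(np.arange(len(dates)) % 7 == 0, 14.0, 0.0)
        met = pd.DataFrame({"date": dates, "tmax_c": 22.0, "tmin_c": 8.0,
                            "precip_mm": precip})
        d = ns.derive_met_series(met, ns.HIGH_SITE)
        res = ns.simulate(ns.HIGH_SITE, d, ns.initial_water(ns.HIGH_SITE),
                          ns.seedling_state(), ns.NSCParams())
        lai = res.daily["lai"]
        yr = np.arange(len(lai)) // 365
        annual = np.array([lai[yr == y].mean() for y in range(60)])
        assert annual[5] > annual[0]            # grows from seedling
        last10 = annual[-10:]
        assert (last10.max() - last10.min()) / last10.mean() < 0.01
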