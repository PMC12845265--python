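"""Whole-body ODE system: structure, conservation, linearity, GI chain."""

import numpy as np
import pytest

from digoxin_pbpk import DoseEvent, Regimen, build_model, simulate
from digoxin_pbpk.engine import SYSTEMIC_ORGANS


def _bolus(amount=0.5, route="iv_bolus"):
    return Regimen(events=(DoseEvent(route, amount, 0.0),))


class TestStructure:
    def test_state_count_matches_declared_layout(self, adult_model):
        # 2 blood + 14 organs × (fast, deep) + lung × 2 + 14 bound pools
        # + stomach lumen (solid, dissolved) + 8 segments × 3 + 3 ledger states
        expected = 2 + 28 + 2 + 14 + 2 + 24 + 3
        assert adult_model.n_states == expected
        assert len(adult_model.state_labels) == expected

    def test_build_is_deterministic(self, adult_drug, adult_profile):
        m1 = build_model(adult_drug, adult_profile)
        m2 = build_model(adult_drug, adult_profile)
        assert np.array_equal(m1.ps_fu, m2.ps_fu)
        assert np.array_equal(m1.kp_ic, m2.kp_ic)
        assert m1.state_labels == m2.state_labels

    def test_zero_cellular_permeability_decouples_deep_spaces(
        self, adult_drug, adult_profile
    ):
        drug = adult_drug.with_overrides(cellular_permeability=0.0)
        model = build_model(drug, adult_profile)
        res = simulate(model, _bolus(), t_end=24.0)
        for organ in SYSTEMIC_ORGANS:
            assert np.all(np.abs(res.state(f"{organ}_intracellular")) < 1e-9)
            assert np.all(np.abs(res.state(f"{organ}_bound")) < 1e-9)

    def test_simulation_deterministic(self, adult_model):
        r1 = simulate(adult_model, _bolus(), t_end=24.0)
        r2 = simulate(adult_model, _bolus(), t_end=24.0)
        assert np.array_equal(r1.plasma_concentration, r2.plasma_concentration)


class TestConservation:
    def test_zero_clearance_conserves_dose(self, adult_drug, adult_profile):
        from dataclasses import replace

        profile = replace(adult_profile, gfr=0.0)
        model = build_model(adult_drug, profile)
        res = simulate(model, _bolus(), t_end=48.0, rel_tol=1e-8, abs_tol=1e-10)
        in_body = res.ledger["in_body"]
        assert in_body == pytest.approx(500.0, rel=1e-6)
        assert res.ledger["eliminated"] == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("route, amount", [("iv_bolus", 0.5), ("oral", 0.25)])
    def test_mass_balance_below_1e6(self, adult_model, route, amount):
        res = simulate(adult_model, _bolus(amount, route), t_end=48.0,
                       rel_tol=1e-8, abs_tol=1e-10)
        assert res.mass_balance_error < 1e-6

    def test_no_negative_state_excursions(self, adult_model):
        res = simulate(adult_model, _bolus(), t_end=96.0,
                       rel_tol=1e-8, abs_tol=1e-10)
        assert not res.warnings
        assert np.all(res.plasma_concentration >= 0)


class TestLinearity:
    def test_dose_doubling_doubles_auc_without_pgp(self, adult_drug,
                                                   adult_profile):
        from digoxin_pbpk.analysis import auc_0t

        drug = adult_drug.with_overrides(pgp_vmax=0.0)
        model = build_model(drug, adult_profile)
        res1 = simulate(model, _bolus(0.25, "oral"), t_end=48.0,
                        rel_tol=1e-8, abs_tol=1e-10)
        res2 = simulate(model, _bolus(0.5, "oral"), t_end=48.0,
                        rel_tol=1e-8, abs_tol=1e-10)
        assert auc_0t(res2, 48.0) == pytest.approx(2 * auc_0t(res1, 48.0),
                                                   rel=5e-3)

    def test_superposition_of_multiple_doses(self, adult_drug, adult_profile):
        drug = adult_drug.with_overrides(pgp_vmax=0.0)
        model = build_model(drug, adult_profile)
        tau = 24.0
        multi = Regimen(events=(DoseEvent("iv_bolus", 0.5, 0.0),
                                DoseEvent("iv_bolus", 0.5, tau)))
        res_m = simulate(model, multi, t_end=72.0, rel_tol=1e-9, abs_tol=1e-11)
        res_s = simulate(model, _bolus(0.5), t_end=72.0,
                         rel_tol=1e-9, abs_tol=1e-11)
        grid = np.arange(tau + 0.5, 72.0, 0.5)
        c_multi = np.interp(grid, res_m.time, res_m.plasma_concentration)
        c_sum = (np.interp(grid, res_s.time, res_s.plasma_concentration)
                 + np.interp(grid - tau, res_s.time, res_s.plasma_concentration))
        assert np.allclose(c_multi, c_sum, rtol=5e-3)

    def test_short_infusion_converges_to_bolus(self, adult_model):
        res_b = simulate(adult_model, _bolus(0.5), t_end=24.0,
                         rel_tol=1e-8, abs_tol=1e-10)
        inf = Regimen(events=(DoseEvent("iv_infusion", 0.5, 0.0, 1.0 / 60),))
        res_i = simulate(adult_model, inf, t_end=24.0,
                         rel_tol=1e-8, abs_tol=1e-10)
        grid = np.arange(1.0, 24.0, 0.5)
        cb = np.interp(grid, res_b.time, res_b.plasma_concentration)
        ci = np.interp(grid, res_i.time, res_i.plasma_concentration)
        assert np.allclose(cb, ci, rtol=0.02)


class TestClearanceOracle:
    def test_iv_auc_inf_equals_dose_over_filtration_clearance(
        self, adult_drug, adult_profile
    ):
        from digoxin_pbpk.analysis import auc_inf

        model = build_model(adult_drug, adult_profile)
        res = simulate(model, _bolus(0.5), t_end=5000.0,
                       rel_tol=1e-9, abs_tol=1e-11)
        cl_ml_per_min = adult_drug.gfr_fraction * adult_drug.fu * adult_profile.gfr
        expected = 500.0 * 1000.0 / (cl_ml_per_min * 60.0)  # ng·h/mL
        assert auc_inf(res) == pytest.approx(expected, rel=0.01)


class TestGIChain:
    def test_fraction_absorbed_approaches_one_in_permissive_limit(
        self, adult_drug, adult_profile
    ):
        drug = adult_drug.with_overrides(
            solubility=1e3, pgp_vmax=0.0, intestinal_permeability=1e-2
        )
        model = build_model(drug, adult_profile)
        res = simulate(model, _bolus(0.25, "oral"), t_end=48.0)
        assert res.ledger["absorbed"] / res.ledger["dosed"] > 0.95

    def test_pgp_efflux_reduces_oral_exposure(self, adult_drug, adult_profile):
        from digoxin_pbpk.analysis import auc_0t

        with_pgp = build_model(adult_drug, adult_profile)
        without = build_model(adult_drug.with_overrides(pgp_vmax=0.0),
                              adult_profile)
        auc_with = auc_0t(simulate(with_pgp, _bolus(0.25, "oral"), 48.0), 48.0)
        auc_without = auc_0t(simulate(without, _bolus(0.25, "oral"), 48.0), 48.0)
        assert auc_without > auc_with

    def test_solid_dose_below_solubility_cap_fully_dissolves(
        self, adult_model
    ):
        res = simulate(adult_model, _bolus(0.25, "oral"), t_end=48.0,
                       rel_tol=1e-8, abs_tol=1e-10)
        solid_left = sum(
            res.state(lab)[-1] for lab in res.state_labels if "solid" in lab
        )
        assert solid_left < 0.25  # µg, of a 250 µg dose
        assert res.mass_balance_error < 1e-6

    def test_nonpositive_transit_time_rejected(self, adult_drug, adult_profile):
        from digoxin_pbpk.engine import gi_chain

        with pytest.raises(ValueError, match="transit"):
            gi_chain(adult_drug, adult_profile,
                     transit_times_h={"colon": 0.0})


class TestDosing:
    def test_events_must_be_sorted(self):
        with pytest.raises(ValueError):
            Regimen(events=(DoseEvent("iv_bolus", 1.0, 10.0),
                            DoseEvent("iv_bolus", 1.0, 5.0)))

    def test_bolus_duration_must_be_zero(self):
        with pytest.raises(ValueError):
            DoseEvent("iv_bolus", 1.0, 0.0, duration=1.0)

    def test_per_kg_resolution_and_repeats(self):
        reg = Regimen.from_spec(
            {"route": "oral", "amount": 0.01, "unit": "mg_per_kg",
             "start": 0.0, "repeat_every": 12.0, "count": 3},
            body_weight_kg=10.0,
        )
        assert len(reg.events) == 3
        assert all(e.amount == pytest.approx(0.1) for e in reg.events)
        assert [e.start_time for e in reg.events] == [0.0, 12.0, 24.0]

    def test_t_end_before_last_dose_rejected(self, adult_model):
        reg = Regimen(events=(DoseEvent("iv_bolus", 0.5, 48.0),))
        with pytest.raises(ValueError, match="t_end"):
            simulate(adult_model, reg, t_end=24.0)

    def test_result_export(self, adult_model, tmp_path):
        import json

        import pandas as pd

        res = simulate(adult_model, _bolus(), t_end=24.0)
        res.to_csv(tmp_path / "profile.csv")
        df = pd.read_csv(tmp_path / "profile.csv")
        assert list(df.columns) == ["time_h", "conc_ng_per_ml"]
        res.ledger_to_json(tmp_path / "ledger.json")
        ledger = json.loads((tmp_path / "ledger.json").read_text())
        assert ledger["dosed"] == pytest.approx(500.0)
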