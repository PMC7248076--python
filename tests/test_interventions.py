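"""Scenario inputs, instantaneous transforms and preset library."""

import numpy as np
import pytest
from scipy.integrate import quad

from ferropoiesis.interventions import (IvIronDose, OralIronCourse, Phlebotomy,
                                        Scenario, ScenarioError,
                                        apply_phlebotomy, iv_iron_input,
                                        oral_iron_input, presets,
                                        scenario_modifiers)
from ferropoiesis.iron_metabolism import observables
from ferropoiesis.state import layout_for, reference_state


class TestIvIronInput:
    TINF = 15.0 / 1440.0

    def test_zero_outside_windows(self):
        sc = Scenario(label="iv", horizon=10.0, iron_iv=(IvIronDose(1.0, 100.0),))
        assert iv_iron_input(0.5, sc, self.TINF) == 0.0
        assert iv_iron_input(1.0 + self.TINF, sc, self.TINF) == 0.0

    def test_rectangle_height_is_dose_over_duration(self):
        sc = Scenario(label="iv", horizon=10.0, iron_iv=(IvIronDose(1.0, 100.0),))
        assert iv_iron_input(1.0, sc, self.TINF) == pytest.approx(100.0 / self.TINF)

    def test_pulse_integral_equals_dose(self):
        sc = Scenario(label="iv", horizon=10.0, iron_iv=(IvIronDose(2.0, 250.0),))
        total, _ = quad(lambda t: iv_iron_input(t, sc, self.TINF), 2.0,
                        2.0 + self.TINF, limit=200)
        assert total == pytest.approx(250.0, rel=1e-9)

    def test_nonpositive_duration_rejected(self):
        sc = Scenario(label="iv", horizon=10.0)
        with pytest.raises(ScenarioError):
            iv_iron_input(0.0, sc, 0.0)


class TestOralIronInput:
    def test_diet_only(self, params):
        sc = Scenario(label="diet", horizon=10.0)
        assert oral_iron_input(3.3, sc, params) == pytest.approx(
            params.iron.FeDiet_nor)

    def test_malnutrition_halves_diet(self, params):
        sc = Scenario(label="half", horizon=10.0, diet_factor=0.5)
        assert oral_iron_input(3.3, sc, params) == pytest.approx(
            0.5 * params.iron.FeDiet_nor)

    def test_twice_daily_course_pulses_only_inside_window(self, params):
        sc = Scenario(label="bid", horizon=20.0,
                      iron_oral=(OralIronCourse(0.0, 10.0, 300.0, 2),))
        width = sc.oral_pulse_width
        diet = params.iron.FeDiet_nor
        pulse = 300.0 / width / params.sigmoids.zferro.v_min
        # inside a pulse at the scheduled clock times
        assert oral_iron_input(0.0, sc, params) == pytest.approx(diet + pulse)
        assert oral_iron_input(0.5 + width / 2, sc, params) == pytest.approx(
            diet + pulse)
        # between pulses and after the course only diet remains
        assert oral_iron_input(0.25, sc, params) == pytest.approx(diet)
        assert oral_iron_input(10.0, sc, params) == pytest.approx(diet)
        assert oral_iron_input(12.3, sc, params) == pytest.approx(diet)

    def test_daily_integral_recovers_scaled_doses(self, params):
        sc = Scenario(label="bid", horizon=4.0,
                      iron_oral=(OralIronCourse(0.0, 4.0, 150.0, 2),))
        total, _ = quad(lambda t: oral_iron_input(t, sc, params)
                        - params.iron.FeDiet_nor, 0.0, 1.0,
                        points=[0, sc.oral_pulse_width, 0.5,
                                0.5 + sc.oral_pulse_width], limit=400)
        assert total == pytest.approx(
            2 * 150.0 / params.sigmoids.zferro.v_min, rel=1e-6)


class TestPhlebotomy:
    def test_zero_fraction_is_identity(self, params):
        y = reference_state(params)
        np.testing.assert_array_equal(
            apply_phlebotomy(y, 0.0, layout_for(params)), y)

    def test_circulating_cells_and_iron_scaled_marrow_untouched(self, params):
        lay = layout_for(params)
        y = reference_state(params)
        out = apply_phlebotomy(y, 0.1, lay)
        for idx in (lay.RET, lay.ERY_rand, lay.Fe_RET, lay.Fe_ERY_rand):
            assert out[idx] == pytest.approx(0.9)
        np.testing.assert_allclose(out[lay.ERY], 0.9)
        np.testing.assert_allclose(out[lay.Fe_ERY], 0.9)
        for idx in (lay.S, lay.MEB, lay.Fe_MEB, lay.NTBI, lay.TRFl, lay.F_S):
            assert out[idx] == pytest.approx(1.0)

    def test_hb_commutes_with_bleed_fraction(self, params):
        # HB right after a fraction-f bleed is (1-f) times HB before
        y = reference_state(params)
        before = observables(y, params)["HB"]
        after = observables(apply_phlebotomy(y, 0.1, layout_for(params)),
                            params)["HB"]
        assert after == pytest.approx(0.9 * before)

    def test_two_bleeds_compose_multiplicatively(self, params):
        lay = layout_for(params)
        y = reference_state(params)
        twice = apply_phlebotomy(apply_phlebotomy(y, 0.1, lay), 0.1, lay)
        assert twice[lay.RET] == pytest.approx(0.81)

    def test_out_of_range_fraction_rejected(self, params):
        with pytest.raises(ValueError):
            apply_phlebotomy(reference_state(params), 1.0, layout_for(params))


class TestScenarioModifiers:
    def test_defaults_leave_parameters_unchanged(self, params):
        sc = Scenario(label="plain", horizon=10.0)
        out = scenario_modifiers(params, sc)
        assert out.iron == params.iron
        assert out.derived == params.derived

    def test_inflammation_raises_steady_hepcidin(self, params, scenario_lib):
        from ferropoiesis import simulate

        traj = simulate(scenario_lib["inflammation"], params, grid=1.0,
                        rtol=1e-6, atol=1e-9)
        assert traj.series("HEP")[-1] > 1.1

    def test_haemochromatosis_lowers_hepcidin_and_raises_ferroportin(
            self, params, scenario_lib):
        from ferropoiesis import simulate

        traj = simulate(scenario_lib["haemochromatosis"], params, grid=2.0,
                        rtol=1e-6, atol=1e-9)
        assert traj.series("HEP")[-1] < 0.9
        assert traj.series("Zferro")[-1] > 1.0

    def test_invalid_scenarios_rejected(self):
        with pytest.raises(ScenarioError):
            Scenario(label="bad", horizon=10.0,
                     phlebotomies=(Phlebotomy(0.0, 1.2),))
        with pytest.raises(ScenarioError):
            Scenario(label="bad", horizon=10.0,
                     iron_iv=(IvIronDose(20.0, 100.0),))  # beyond horizon
        with pytest.raises(ScenarioError):
            Scenario(label="bad", horizon=10.0, diet_factor=-0.5)


class TestPresets:
    def test_library_contains_the_documented_scenarios(self, scenario_lib):
        for name in ("oral_iron_150bid_50d", "epo_iv_plus_oral_iron",
                     "iron_deficiency_50pct", "iv_iron_100mg",
                     "phlebotomy_10pct", "inflammation", "haemochromatosis",
                     "souillard_epo", "rutherford_g1", "rutherford_g2",
                     "rutherford_g3", "kiss_donation", "kiss_donation_iron",
                     "chop14", "chop14_epo_iron"):
            assert name in scenario_lib

    def test_chop14_has_six_fortnightly_cycles(self, scenario_lib):
        chemo = scenario_lib["chop14"].chemo
        assert chemo.times == (0.0, 14.0, 28.0, 42.0, 56.0, 70.0)

    def test_souillard_schedule_matches_study(self, scenario_lib):
        doses = scenario_lib["souillard_epo"].epo
        assert [d.time for d in doses] == [0.0, 2.0, 4.0, 7.0, 10.0]
        assert all(d.dose == 200.0 and d.unit == "iu_per_kg" and d.route == "sc"
                   for d in doses)
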