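"""Velocity law, Dixon / Cornish-Bowden geometry, inhibition classification,
pre-incubation testing and fractional-inhibition prediction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrkinetics import (DesignError, KineticParams, ValidationError,
                        classify_inhibition, fit_cornish_bowden, fit_dixon,
                        fit_velocity_law, fractional_inhibition,
                        mg_per_l_to_um, preincubation_test, velocity)
from mrkinetics.kinetics import PARALLEL
from mrkinetics.simulate import generate_kinetic_dataset

S2 = [25.0, 100.0]
I_SMALL = [0.0, 10.0, 20.0, 40.0]
I_WIDE = [0.0, 50.0, 150.0, 300.0]

COMPETITIVE = KineticParams.competitive(vmax=1.0, km=50.0, ki=20.0)
UNCOMPETITIVE = KineticParams.uncompetitive(vmax=1.0, km=50.0, ki=30.0)
NONCOMPETITIVE = KineticParams.noncompetitive(vmax=1.0, km=50.0, ki=25.0)
MIXED = KineticParams.mixed(vmax=1.0, km=50.0, ki_c=21.0, ki_u=60.0)


def _exact(params, substrate=S2, inhibitors=I_SMALL):
    return generate_kinetic_dataset(params, substrate, inhibitors, cv=0.0, replicates=1)


class TestKineticParams:
    @pytest.mark.parametrize("kwargs", [
        dict(vmax=0, km=50),
        dict(vmax=1, km=-1),
        dict(vmax=1, km=50, ki_c=0.0),
        dict(vmax=1, km=50, model="competitive"),          # ki_c must be finite
        dict(vmax=1, km=50, ki_c=20.0, ki_u=30.0, model="noncompetitive"),
        dict(vmax=1, km=50, ki_c=20.0, ki_u=20.0, model="mixed"),
    ])
    def test_inconsistent_parameterizations_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            KineticParams(**kwargs)


class TestVelocity:
    def test_no_inhibitor_is_michaelis_menten(self):
        assert velocity(50.0, 0.0, COMPETITIVE) == pytest.approx(1.0 * 50 / (50 + 50))

    def test_hand_computed_competitive_point(self):
        # vmax=1, km=50, ki_c=20: v = 50 / (50·(1+1) + 50) = 1/3
        assert velocity(50.0, 20.0, COMPETITIVE) == pytest.approx(1 / 3)

    def test_competitive_inhibition_is_surmountable(self):
        assert velocity(1e9, 500.0, COMPETITIVE) == pytest.approx(1.0, rel=1e-5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(1, 500), st.floats(0, 400), st.floats(1, 400))
    def test_monotone_decreasing_in_inhibitor_increasing_in_substrate(self, s, i, di):
        for params in (COMPETITIVE, UNCOMPETITIVE, NONCOMPETITIVE, MIXED):
            assert velocity(s, i + di, params) < velocity(s, i, params)
            assert velocity(s + di, i, params) > velocity(s, i, params)

    def test_invalid_concentrations_rejected(self):
        with pytest.raises(ValidationError):
            velocity(0.0, 1.0, COMPETITIVE)
        with pytest.raises(ValidationError):
            velocity(10.0, -1.0, COMPETITIVE)


class TestExactGeometry:
    """Noise-free Dixon/CB intersections match the closed forms to 1e-9."""

    def test_competitive_dixon_intersects_at_minus_ki_and_inverse_vmax(self):
        fit = fit_dixon(_exact(COMPETITIVE))
        I, y = fit.intersection
        assert I == pytest.approx(-20.0, rel=1e-9)
        assert y == pytest.approx(1.0, rel=1e-9)
        assert fit.ki == pytest.approx(20.0, rel=1e-9)

    def test_competitive_cornish_bowden_is_parallel(self):
        assert fit_cornish_bowden(_exact(COMPETITIVE)).intersection == PARALLEL

    def test_uncompetitive_dixon_is_parallel(self):
        assert fit_dixon(_exact(UNCOMPETITIVE)).intersection == PARALLEL

    def test_uncompetitive_cb_intersects_at_minus_kiu(self):
        fit = fit_cornish_bowden(_exact(UNCOMPETITIVE))
        I, y = fit.intersection
        assert I == pytest.approx(-30.0, rel=1e-9)
        assert y == pytest.approx(50.0, rel=1e-9)  # km/vmax when ki_c infinite

    def test_noncompetitive_cb_intersects_on_axis(self):
        fit = fit_cornish_bowden(_exact(NONCOMPETITIVE))
        I, y = fit.intersection
        assert I == pytest.approx(-25.0, rel=1e-9)
        assert abs(y) < 1e-9

    def test_mixed_closed_forms_both_plots(self):
        dixon = fit_dixon(_exact(MIXED))
        cb = fit_cornish_bowden(_exact(MIXED))
        assert dixon.intersection[0] == pytest.approx(-21.0, rel=1e-9)
        assert dixon.intersection[1] == pytest.approx((1 - 21.0 / 60.0) / 1.0, rel=1e-9)
        assert cb.intersection[0] == pytest.approx(-60.0, rel=1e-9)
        assert cb.intersection[1] == pytest.approx(50.0 * (1 - 60.0 / 21.0), rel=1e-9)

    def test_design_errors(self):
        with pytest.raises(DesignError, match="substrate"):
            fit_dixon(_exact(COMPETITIVE, substrate=[50.0]))
        with pytest.raises(DesignError, match="inhibitor"):
            fit_dixon(_exact(COMPETITIVE, inhibitors=[0.0, 10.0]))


class TestClassification:
    @pytest.mark.parametrize("params,expected", [
        (COMPETITIVE, "competitive"),
        (UNCOMPETITIVE, "uncompetitive"),
        (NONCOMPETITIVE, "noncompetitive"),
        (MIXED, "mixed"),
    ])
    def test_noise_free_round_trip(self, params, expected):
        fit = classify_inhibition(_exact(params))
        assert fit.inferred_type == expected
        if expected in ("competitive", "noncompetitive", "mixed"):
            assert fit.ki == pytest.approx(params.ki_c, rel=1e-6)
        else:
            assert fit.ki == pytest.approx(params.ki_u, rel=1e-6)

    def test_noisy_dataset_still_classified(self):
        ds = generate_kinetic_dataset(MIXED, [25.0, 50.0, 100.0, 200.0], I_WIDE,
                                      cv=0.05, replicates=3, seed=4)
        assert classify_inhibition(ds).inferred_type in (
            "competitive", "uncompetitive", "noncompetitive", "mixed")


class TestNonlinearCrossCheck:
    def test_direct_fit_recovers_competitive_parameters(self):
        ds = _exact(COMPETITIVE, inhibitors=I_SMALL)
        fit = fit_velocity_law(ds, "competitive")
        assert fit.vmax == pytest.approx(1.0, rel=1e-6)
        assert fit.km == pytest.approx(50.0, rel=1e-6)
        assert fit.ki_c == pytest.approx(20.0, rel=1e-6)

    def test_direct_fit_agrees_with_dixon_on_noisy_data(self):
        params = KineticParams.competitive(1.0, 50.0, 152.0)
        ds = generate_kinetic_dataset(params, S2, I_WIDE, cv=0.05,
                                      replicates=3, seed=9)
        dixon_ki = fit_dixon(ds).ki
        direct_ki = fit_velocity_law(ds, "competitive").ki_c
        assert dixon_ki == pytest.approx(direct_ki, rel=0.25)


class TestPreincubation:
    def test_identical_arms_not_mechanism_based(self):
        ds = generate_kinetic_dataset(COMPETITIVE, S2, I_WIDE, cv=0.0,
                                      replicates=2, include_preincubated=True)
        res = preincubation_test(ds.arm(False), ds.arm(True))
        assert res.verdict == "not-mechanism-based"
        assert res.mean_difference == pytest.approx(0.0)

    def test_vmax_loss_flags_mechanism_based_candidate(self):
        ds = generate_kinetic_dataset(COMPETITIVE, S2, I_WIDE, cv=0.05,
                                      replicates=3, preincubation_effect=0.6,
                                      include_preincubated=True, seed=7)
        res = preincubation_test(ds.arm(False), ds.arm(True))
        assert res.verdict == "mechanism-based-candidate"
        assert res.mean_difference < 0

    def test_direction_contract_higher_preincubated_not_flagged(self):
        control = generate_kinetic_dataset(COMPETITIVE, S2, I_WIDE, cv=0.0,
                                           replicates=2)
        params_hi = KineticParams.competitive(1.0, 50.0, ki=40.0)  # weaker inhibition
        higher = generate_kinetic_dataset(params_hi, S2, I_WIDE, cv=0.0, replicates=2)
        higher.observations["preincubated"] = True
        res = preincubation_test(control, higher)
        assert res.verdict == "not-mechanism-based"

    def test_mismatched_grids_rejected(self):
        a = generate_kinetic_dataset(COMPETITIVE, S2, I_WIDE, cv=0.0, replicates=1)
        b = generate_kinetic_dataset(COMPETITIVE, S2, I_SMALL, cv=0.0, replicates=1)
        with pytest.raises(DesignError):
            preincubation_test(a, b)


class TestFractionalInhibition:
    def test_plasma_caffeic_acid_predictions(self):
        assert fractional_inhibition(6.16, 156.0) == pytest.approx(0.038, abs=5e-4)
        assert fractional_inhibition(7.12, 156.0) == pytest.approx(0.044, abs=5e-4)

    def test_zero_inhibitor_gives_zero(self):
        assert fractional_inhibition(0.0, 156.0) == 0.0

    def test_substrate_form_approaches_low_substrate_limit(self):
        km = 50.0
        low_s = fractional_inhibition(6.16, 156.0, substrate_uM=km * 1e-6, km_uM=km)
        assert low_s == pytest.approx(fractional_inhibition(6.16, 156.0), abs=1e-6)

    def test_substrate_form_weaker_at_high_substrate(self):
        # competitive inhibition is surmountable: more substrate, less inhibition
        high = fractional_inhibition(100.0, 156.0, substrate_uM=500.0, km_uM=50.0)
        low = fractional_inhibition(100.0, 156.0)
        assert high < low

    def test_invalid_ki_rejected(self):
        with pytest.raises(ValidationError):
            fractional_inhibition(1.0, 0.0)


class TestUnitConversion:
    def test_caffeic_acid_plasma_concentration(self):
        assert mg_per_l_to_um(1.11, 180.16) == pytest.approx(6.16, abs=0.005)

    def test_higher_intake_concentration(self):
        # 1.28 mg/l at MW 180.16 is 7.10 μM by direct arithmetic
        assert mg_per_l_to_um(1.28, 180.16) == pytest.approx(7.10, abs=0.005)

    def test_zero_concentration(self):
        assert mg_per_l_to_um(0.0, 180.16) == 0.0

    def test_invalid_molecular_weight(self):
        with pytest.raises(ValidationError):
            mg_per_l_to_um(1.0, 0.0)
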