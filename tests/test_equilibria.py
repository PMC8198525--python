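"""Saturation, eutectic and DRH solving."""

import math

import numpy as np
import pytest
from scipy import optimize

from deliq.equilibria import (ANHYDRATE, HYDRATE, R_GAS, SolidFormChoice,
                              ard, hydrate_solubility_product,
                              ideal_solubility_activity, parse_solid,
                              predict_drh, predict_drh_mixture,
                              solid_solid_transition_rh, solve_saturation)
from deliq.maps import saturation_with_background

T0 = 298.15


def eq1(dh_kJ, Tm, dcp, T):
    """Direct evaluation of the melting-properties solubility exponent."""
    return math.exp(-dh_kJ * 1000 / (R_GAS * T) * (1 - T / Tm)
                    - dcp / R_GAS * (math.log(Tm / T) - Tm / T + 1))


class TestIdealSolubilityActivity:
    def test_unity_at_melting_point(self, cs):
        f = cs["fructose"]
        assert ideal_solubility_activity(f, f.melting_T) == pytest.approx(
            1.0, abs=1e-14)

    def test_fructose_matches_direct_formula(self, cs):
        assert ideal_solubility_activity(cs["fructose"], T0) \
            == pytest.approx(eq1(32.4, 353.2, 0.0, T0), rel=1e-14)

    def test_heat_capacity_term_raises_activity_below_melting(self, cs):
        """ln(Tm/T) - Tm/T + 1 <= 0 for any T, so a positive melting-cp
        change increases the saturation activity (citric acid check)."""
        ca = cs["citric acid"]
        with_cp = ideal_solubility_activity(ca, T0)
        without_cp = eq1(41.84, 428.55, 0.0, T0)
        assert with_cp > without_cp

    def test_missing_melting_data_rejected(self, cs):
        with pytest.raises(ValueError):
            ideal_solubility_activity(cs["water"], T0)


class TestHydrateSolubilityProduct:
    def test_at_transition_temperature(self, cs):
        """The dehydration exponential drops out at T_trans."""
        spec = cs.hydrate("citric acid")
        ca = cs["citric acid"]
        Ks = hydrate_solubility_product(spec, ca, spec.transition_T)
        assert Ks == pytest.approx(
            ideal_solubility_activity(ca, spec.transition_T)
            * spec.water_activity_at_transition, rel=1e-12)

    def test_unit_transition_activity_recovers_simple_form(self, cs):
        spec = cs.hydrate("citric acid")
        simple = spec.__class__(
            anhydrate_name=spec.anhydrate_name,
            stoich_solute=spec.stoich_solute,
            stoich_water=spec.stoich_water,
            transition_enthalpy=spec.transition_enthalpy,
            transition_T=spec.transition_T,
            water_activity_at_transition=1.0)
        ca = cs["citric acid"]
        ratio = (hydrate_solubility_product(spec, ca, T0)
                 / hydrate_solubility_product(simple, ca, T0))
        assert ratio == pytest.approx(0.725, rel=1e-12)

    def test_citric_acid_value_from_printed_inputs(self, cs):
        spec = cs.hydrate("citric acid")
        ca = cs["citric acid"]
        expected = (eq1(41.84, 428.55, 159.46, T0) * 0.725
                    * math.exp(-10850 / (R_GAS * T0) * (1 - T0 / 309.45)))
        assert hydrate_solubility_product(spec, ca, T0) == pytest.approx(
            expected, rel=1e-12)


class TestSolveSaturation:
    def test_fructose_saturated_mass_fraction(self, cs):
        st = solve_saturation([SolidFormChoice("fructose")], T0, cs)
        w = st.mass_fractions(cs)["fructose"]
        assert w == pytest.approx(0.78, abs=0.01)

    def test_saturation_condition_satisfied(self, cs):
        st = solve_saturation([SolidFormChoice("fructose")], T0, cs)
        a_target = ideal_solubility_activity(cs["fructose"], T0)
        assert st.x_of("fructose") * st.gamma_of("fructose") \
            == pytest.approx(a_target, rel=1e-9)

    def test_hydrate_residual_satisfied(self, cs):
        st = solve_saturation([SolidFormChoice("citric acid", HYDRATE)],
                              T0, cs)
        spec = cs.hydrate("citric acid")
        Ks = hydrate_solubility_product(spec, cs["citric acid"], T0)
        lhs = ((st.x_of("citric acid") * st.gamma_of("citric acid"))
               ** spec.stoich_solute
               * (st.x_of("water") * st.gamma_of("water"))
               ** spec.stoich_water)
        assert lhs == pytest.approx(Ks, rel=1e-9)

    def test_ideal_gamma_reduces_to_closed_form(self, cs):
        st = solve_saturation([SolidFormChoice("fructose")], T0, cs,
                              activity_model="ideal")
        assert st.x_of("fructose") == pytest.approx(
            ideal_solubility_activity(cs["fructose"], T0), rel=1e-9)

    def test_eutectic_dry_basis_composition(self, cs):
        st = solve_saturation([SolidFormChoice("fructose"),
                               SolidFormChoice("glucose")], T0, cs)
        xf, xg = st.x_of("fructose"), st.x_of("glucose")
        wf = xf * 180.16 / (xf * 180.16 + xg * 180.16)
        assert wf == pytest.approx(0.85, abs=0.02)

    def test_above_melting_rejected(self, cs):
        with pytest.raises(ValueError, match="melting"):
            solve_saturation([SolidFormChoice("fructose")], 360.0, cs)

    def test_duplicate_solids_rejected(self, cs):
        with pytest.raises(ValueError):
            solve_saturation([SolidFormChoice("fructose"),
                              SolidFormChoice("fructose")], T0, cs)

    def test_eutectic_matches_traced_solubility_curve_intersection(self, cs):
        """Brute-force oracle: the eutectic equals the intersection of the
        two independently traced single-solute solubility curves."""
        sa, sb = SolidFormChoice("fructose"), SolidFormChoice("glucose")

        def xa_sat(xb):
            x, _ = saturation_with_background(sa, T0, cs, {"glucose": xb})
            return float(x[1])

        def xb_sat(xa):
            x, _ = saturation_with_background(sb, T0, cs, {"fructose": xa})
            return float(x[1])

        xb_root = optimize.brentq(lambda xb: xb_sat(xa_sat(xb)) - xb,
                                  1e-4, 0.09, xtol=1e-12)
        xa_root = xa_sat(xb_root)
        st = solve_saturation([sa, sb], T0, cs)
        assert st.x_of("fructose") == pytest.approx(xa_root, abs=1e-6)
        assert st.x_of("glucose") == pytest.approx(xb_root, abs=1e-6)


class TestPredictDrh:
    def test_raoult_to_pcsaft_ratio_is_inverse_gamma_water(self, cs):
        """DRH_raoult / DRH_pcsaft = 1/gamma_water at the same saturated
        composition (sign of the difference follows gamma_water - 1)."""
        for name in ("fructose", "nicotinamide"):
            p = predict_drh([SolidFormChoice(name)], T0, cs, "pcsaft")
            r = predict_drh([SolidFormChoice(name)], T0, cs, "raoult")
            gw = p.saturation.gamma_of("water")
            assert r.drh / p.drh == pytest.approx(1.0 / gw, rel=1e-9)
        # nicotinamide has gamma_water > 1: Raoult below PC-SAFT
        assert predict_drh([SolidFormChoice("nicotinamide")], T0, cs,
                           "raoult").drh < \
            predict_drh([SolidFormChoice("nicotinamide")], T0, cs,
                        "pcsaft").drh

    def test_single_element_mixture_equals_single(self, cs):
        one = predict_drh([SolidFormChoice("fructose")], T0, cs)
        mix = predict_drh_mixture([SolidFormChoice("fructose")], T0, cs)
        assert mix.drh == pytest.approx(one.drh, rel=1e-12)

    def test_mixture_drh_below_each_single(self, cs):
        singles = [predict_drh([SolidFormChoice(n)], T0, cs).drh
                   for n in ("fructose", "glucose")]
        mix = predict_drh_mixture([SolidFormChoice("fructose"),
                                   SolidFormChoice("glucose")], T0, cs).drh
        assert mix <= min(singles)

    def test_mixture_invariant_to_dry_basis(self, cs):
        solids = [SolidFormChoice("fructose"), SolidFormChoice("glucose")]
        a = predict_drh_mixture(solids, T0, cs,
                                dry_basis={"fructose": 0.3, "glucose": 0.7})
        b = predict_drh_mixture(solids, T0, cs,
                                dry_basis={"fructose": 0.9, "glucose": 0.1})
        assert a.drh == pytest.approx(b.drh, abs=1e-8)

    def test_unknown_method_rejected(self, cs):
        with pytest.raises(ValueError):
            predict_drh([SolidFormChoice("fructose")], T0, cs, "unifac")

    def test_adding_a_solute_never_raises_water_activity(self, cs):
        base = predict_drh([SolidFormChoice("citric acid")], T0, cs).drh
        for other in ("fructose", "glucose", "sucrose"):
            mix = predict_drh_mixture(
                [SolidFormChoice("citric acid"), SolidFormChoice(other)],
                T0, cs).drh
            assert mix <= base + 1e-9


class TestSolidSolidTransition:
    def test_at_transition_temperature(self, cs):
        spec = cs.hydrate("citric acid")
        rh = solid_solid_transition_rh("citric acid", spec.transition_T, cs)
        assert rh == pytest.approx(100.0 * 0.725, rel=1e-12)

    def test_room_temperature_near_experiment(self, cs):
        # experimental solid-solid transition: 60.3 % RH; prediction
        # agrees within a few % RH
        rh = solid_solid_transition_rh("citric acid", T0, cs)
        assert rh == pytest.approx(60.3, abs=3.0)

    def test_no_stable_hydrate_above_transition(self, cs):
        assert solid_solid_transition_rh("citric acid", 320.0, cs) is None

    def test_deliquescence_lines_cross_at_transition_temperature(self, cs):
        """The anhydrate and hydrate deliquescence lines intersect at
        T_trans (within 0.1 K) where the two solids are equally stable."""
        def gap(T):
            anh = predict_drh([SolidFormChoice("citric acid")], T, cs).drh
            hyd = predict_drh([SolidFormChoice("citric acid", HYDRATE)],
                              T, cs).drh
            return anh - hyd

        Tcross = optimize.brentq(gap, 305.0, 314.0, xtol=1e-3)
        assert Tcross == pytest.approx(309.45, abs=0.1)


class TestArd:
    def test_identical_vectors(self):
        assert ard([61.5, 89.4], [61.5, 89.4]) == 0.0

    def test_hand_value(self):
        assert ard([50.0], [100.0]) == pytest.approx(50.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ard([1.0, 2.0], [1.0])

    def test_nonpositive_experimental(self):
        with pytest.raises(ValueError):
            ard([1.0], [0.0])


class TestParseSolid:
    def test_plain_and_hydrate(self):
        assert parse_solid("fructose") == SolidFormChoice("fructose",
                                                          ANHYDRATE)
        assert parse_solid("citric acid:hydrate") == SolidFormChoice(
            "citric acid", HYDRATE)

    def test_bad_form(self):
        with pytest.raises(ValueError):
            parse_solid("citric acid:pentahydrate")
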