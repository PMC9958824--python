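"""Work of mixing, osmotic work and the pressure/stoichiometry conversions."""
import math

import numpy as np
import pytest

from isoswell import (
    ModelError,
    PhysicalConstants,
    TransportPlan,
    VolumeChange,
    find_equal_work_volume,
    isochoric_complete_mixing,
    isotonic_work,
    mixing_work_closed,
    mixing_work_numeric,
    osmotic_work,
    path_state,
    solve_full_equilibrium,
    validity_range,
    vant_hoff_pressure,
    water_per_ion,
    work_to_donnan,
)
from isoswell.energetics import chemical_energy_decrease
from isoswell.isotonic_path import PathCoefficients

PRINTED_ISOTONIC = {"Na+": 138.5, "K+": 8.6, "Cl-": 109.4, "A-": 0.0, "HCO3-": 13.3}
PRINTED_ISOCHORIC = {"Na+": 80.3, "K+": 66.8, "Cl-": 64.4, "A-": 53.1, "HCO3-": 5.1}


@pytest.fixture(scope="module")
def omega(table1_state):
    return solve_full_equilibrium(table1_state).omega


class TestMixingWorkClosed:
    def test_printed_per_ion_values(self, table1_coeffs, omega):
        bd = isotonic_work(table1_coeffs, omega)
        for name, value in PRINTED_ISOTONIC.items():
            assert round(bd.mixing[name], 1) == value
        assert round(bd.total_mixing, 1) == 269.8

    def test_no_work_without_change(self, table1_coeffs, table1_state):
        for s in table1_state.species:
            w = mixing_work_closed(
                s.name, table1_coeffs, 1.0, 1.0, s.conc_out, s.conc_in
            )
            assert w == pytest.approx(0.0, abs=1e-12)

    def test_impermeants_do_no_mixing_work(self, table1_coeffs):
        grid = np.linspace(table1_coeffs.omega, 0.25, 20)
        for at in grid:
            bd = isotonic_work(table1_coeffs, float(at))
            assert bd.mixing["A-"] == pytest.approx(0.0, abs=1e-10)

    def test_negative_final_concentration_rejected(self, table1_coeffs):
        with pytest.raises(ModelError):
            mixing_work_closed("Na+", table1_coeffs, 0.5, 7 / 6, -1.0, 50.0)

    def test_agrees_with_quadrature_everywhere(self, table1_coeffs, omega):
        """Independent oracle: trapezoid quadrature of the path integral."""
        for at in (omega, 0.1, 0.2):
            bd = isotonic_work(table1_coeffs, at)
            for s in table1_coeffs.initial.species:
                numeric = mixing_work_numeric(s.name, table1_coeffs, at, 100_000)
                assert numeric == pytest.approx(
                    bd.mixing[s.name], rel=1e-6, abs=1e-6
                )

    def test_quadrature_converges_to_closed_form(self, table1_coeffs, omega):
        closed = isotonic_work(table1_coeffs, 0.1).mixing["Na+"]
        errors = [
            abs(mixing_work_numeric("Na+", table1_coeffs, 0.1, n) - closed)
            for n in (1000, 2000, 4000, 8000)
        ]
        assert all(e2 < e1 for e1, e2 in zip(errors, errors[1:]))

    def test_zero_gradient_species_does_no_work(self):
        from isoswell import IonSpec, TissueState
        from isoswell.isotonic_path import path_coefficients

        species = (
            IonSpec("C1", 1, True, 100.0, 20.0),
            IonSpec("C2", 1, True, 24.0, 104.0),
            IonSpec("F", -1, True, 50.0, 50.0),
            IonSpec("X", -1, True, 64.0, 40.0),
            IonSpec("A", -1, False, 10.0, 34.0),
        )
        state = TissueState.from_specs(species, 0.25)
        coeffs = path_coefficients(state)
        eq = solve_full_equilibrium(state)
        # F has no gradient, so it is co-transported exactly at 50 mM and
        # ln(Ko/Ki) vanishes along the whole path
        assert coeffs.plan.c["F"] == pytest.approx(50.0, rel=1e-12)
        assert mixing_work_numeric("F", coeffs, eq.omega) == pytest.approx(
            0.0, abs=1e-9
        )


class TestOsmoticWork:
    def test_zero_at_constant_volume(self, table1_coeffs, table1_state):
        for s in table1_state.species:
            assert osmotic_work(s.name, table1_coeffs, 1.0, 1.0) == 0.0

    def test_total_vanishes_along_isotonic_path(self, table1_coeffs):
        """Water movement is paid for by the co-transported ions, not by an
        osmotic imbalance: the species-summed osmotic work is identically 0."""
        for at in np.linspace(table1_coeffs.omega, 0.25, 50):
            bd = isotonic_work(table1_coeffs, float(at))
            assert bd.total_osmotic == pytest.approx(0.0, abs=1e-9)

    def test_sign_pattern(self, table1_coeffs):
        """Na+ and Cl- receive osmotic work (their high-concentration
        compartment shrinks); K+ and A- deliver it."""
        for at in np.linspace(table1_coeffs.omega, 0.249, 25):
            bd = isotonic_work(table1_coeffs, float(at))
            assert bd.osmotic["Na+"] <= 1e-12
            assert bd.osmotic["Cl-"] <= 1e-12
            assert bd.osmotic["K+"] >= -1e-12
            assert bd.osmotic["A-"] >= -1e-12

    def test_energy_identity(self, table1_coeffs, omega):
        """work of mixing = decrease in chemical potential energy - osmotic
        work done, per species and at every volume."""
        for at in (omega, 0.08, 0.15, 0.22):
            vol = VolumeChange.from_alpha(0.25, at)
            final = path_state(table1_coeffs, at, warn_super_equilibrium=False)
            for s in table1_coeffs.initial.species:
                args = (
                    s.name,
                    table1_coeffs,
                    vol.w,
                    vol.y,
                    final.conc_out[s.name],
                    final.conc_in[s.name],
                )
                mixing = mixing_work_closed(*args)
                chem = chemical_energy_decrease(*args)
                osm = osmotic_work(s.name, table1_coeffs, vol.w, vol.y)
                assert mixing == pytest.approx(chem - osm, abs=1e-9)

    def test_impermeant_work_is_purely_osmotic(self, table1_coeffs, omega):
        """A- does no mixing work; its full chemical-energy decrease is spent
        as osmotic work (the closed-form terms cancel)."""
        vol = VolumeChange.from_alpha(0.25, omega)
        final = path_state(table1_coeffs, omega)
        chem = chemical_energy_decrease(
            "A-", table1_coeffs, vol.w, vol.y, final.conc_out["A-"], final.conc_in["A-"]
        )
        osm = osmotic_work("A-", table1_coeffs, vol.w, vol.y)
        assert chem == pytest.approx(osm, abs=1e-9)
        assert osm > 0

    def test_total_mixing_work_grows_during_shrinkage(self, table1_coeffs):
        grid = np.linspace(0.25, table1_coeffs.omega, 40)
        totals = [isotonic_work(table1_coeffs, float(a)).total_mixing for a in grid]
        assert np.all(np.diff(totals) > 0)


class TestIsochoricMixing:
    def test_printed_per_ion_values(self, table1_state):
        bd = isochoric_complete_mixing(table1_state)
        for name, value in PRINTED_ISOCHORIC.items():
            assert round(bd.mixing[name], 1) == value
        assert round(bd.total_mixing, 1) == 269.8

    def test_equals_isotonic_total(self, table1_state, table1_coeffs, omega):
        """Same endpoints, different membrane position: identical total work."""
        isochoric = isochoric_complete_mixing(table1_state).total_mixing
        isotonic = isotonic_work(table1_coeffs, omega).total_mixing
        assert isochoric == pytest.approx(isotonic, abs=1e-9)

    def test_fully_mixed_input_does_no_work(self):
        from isoswell import IonSpec, TissueState

        species = (
            IonSpec("C", 1, True, 60.0, 60.0),
            IonSpec("X", -1, True, 40.0, 40.0),
            IonSpec("A", -1, False, 20.0, 20.0),
        )
        bd = isochoric_complete_mixing(TissueState.from_specs(species, 0.25))
        assert bd.total_mixing == pytest.approx(0.0, abs=1e-12)


class TestWorkToDonnan:
    def test_isochoric_donnan_work(self, table1_state):
        bd = work_to_donnan(table1_state, 0.25)
        assert round(bd.total_mixing) == 197
        assert bd.total_osmotic == pytest.approx(0.0, abs=1e-12)

    def test_at_omega_equals_isotonic_breakdown(self, table1_state, table1_coeffs, omega):
        don = work_to_donnan(table1_state, omega)
        iso = isotonic_work(table1_coeffs, omega)
        for name in table1_state.names:
            assert don.mixing[name] == pytest.approx(iso.mixing[name], abs=1e-6)
            assert don.osmotic[name] == pytest.approx(iso.osmotic[name], abs=1e-6)
        assert don.total_osmotic == pytest.approx(0.0, abs=1e-6)

    def test_osmotic_work_positive_between_endpoints(self, table1_state, omega):
        for at in np.linspace(omega * 1.1, 0.24, 15):
            bd = work_to_donnan(table1_state, float(at))
            assert bd.total_osmotic > 0

    def test_out_of_range_volume_rejected(self, table1_state):
        with pytest.raises(ModelError):
            work_to_donnan(table1_state, 0.3)


class TestEqualWorkVolume:
    def test_printed_value(self, table1_state):
        at = find_equal_work_volume(table1_state)
        assert at == pytest.approx(0.115, abs=0.001)

    def test_residual_vanishes_at_solution(self, table1_state, table1_coeffs):
        at = find_equal_work_volume(table1_state)
        w_iso = isotonic_work(table1_coeffs, at).total_mixing
        w_ref = work_to_donnan(table1_state, 0.25).total_mixing
        assert abs(w_iso - w_ref) < 1e-9


class TestAlternativePlansDoLessWork:
    def test_enhanced_sodium_variant(self, table1_state):
        """An isotonic electro-neutral plan with c_Na raised to 179 mM (and
        c_K lowered to -27 mM) depletes extracellular Na+ early and retrieves
        less work than the full-equilibrium plan."""
        eq = solve_full_equilibrium(table1_state)
        c = dict(eq.transport_plan.c)
        c["Na+"], c["K+"] = 179.0, -27.0
        plan = TransportPlan(species=table1_state.species, c=c)
        plan.audit(expected_total=304.0, tol=0.2)  # rounded baseline c values
        coeffs = PathCoefficients(initial=table1_state, plan=plan, omega=eq.omega)
        endpoint = max(validity_range(coeffs).alpha_min, eq.omega)
        total = isotonic_work(coeffs, endpoint).total_mixing
        baseline = isochoric_complete_mixing(table1_state).total_mixing
        assert total < baseline
        assert total == pytest.approx(263, abs=5)  # not a hard pin: endpoint ambiguity

    @pytest.mark.parametrize("delta", [5.0, 10.0, 20.0])
    def test_balanced_perturbations_reduce_work(self, table1_state, delta):
        eq = solve_full_equilibrium(table1_state)
        c = dict(eq.transport_plan.c)
        c["Na+"] += delta
        c["K+"] -= delta
        coeffs = PathCoefficients(
            initial=table1_state,
            plan=TransportPlan(species=table1_state.species, c=c),
            omega=eq.omega,
        )
        endpoint = max(validity_range(coeffs).alpha_min, eq.omega)
        total = isotonic_work(coeffs, endpoint).total_mixing
        assert total < isochoric_complete_mixing(table1_state).total_mixing


class TestVantHoff:
    def test_one_millimolar(self):
        pa, mmhg = vant_hoff_pressure(1.0)
        assert pa == pytest.approx(2576.0, rel=1e-3)
        assert mmhg == pytest.approx(19.3, abs=0.05)  # printed to one decimal

    def test_zero(self):
        assert vant_hoff_pressure(0.0) == (0.0, 0.0)

    def test_linearity(self):
        pa1, _ = vant_hoff_pressure(1.0)
        pa171, _ = vant_hoff_pressure(171.0)
        assert pa171 == pytest.approx(171 * pa1, rel=1e-12)


class TestWaterStoichiometry:
    def test_overall_ratio(self, table1_state):
        plan = solve_full_equilibrium(table1_state).transport_plan
        ws = water_per_ion(plan)
        assert ws.overall == pytest.approx(183, abs=0.5)

    def test_all_water_through_chloride(self, table1_state):
        plan = solve_full_equilibrium(table1_state).transport_plan
        ws = water_per_ion(plan)
        assert ws.per_species["Cl-"] == pytest.approx(458, abs=0.5)

    def test_impermeant_ratio_is_flagged_undefined(self, table1_state):
        plan = solve_full_equilibrium(table1_state).transport_plan
        assert water_per_ion(plan).per_species["A-"] is None

    def test_transport_at_water_molarity_gives_unity(self, table1_state):
        plan = TransportPlan(
            species=table1_state.species[:1], c={"Na+": 55.6e3}
        )
        assert water_per_ion(plan).per_species["Na+"] == pytest.approx(1.0)


class TestEnergyBreakdownStructure:
    def test_totals_are_sums(self, table1_coeffs, omega):
        bd = isotonic_work(table1_coeffs, omega)
        assert bd.total_mixing == pytest.approx(sum(bd.mixing.values()))
        assert bd.total_osmotic == pytest.approx(sum(bd.osmotic.values()))
        assert bd.scenario == "isotonic"
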