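"""Gas physics: solubility, equilibrium, headspace partition, flux."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from n2ofix.gases import (
    GasRangeError,
    GasSpec,
    VialGeometry,
    air_water_flux,
    equilibrium_concentration,
    expected_headspace_ratio,
    headspace_partition,
    ostwald_coefficient,
)

# Ostwald coefficients at 22 degC evaluated by hand from the published
# solubility functions (Hamme-Emerson / Weiss-Price polynomials evaluated
# outside the package, converted via ideal-gas concentration of moist air).
HAND_OSTWALD_22C = {"N2": 0.01650, "Ar": 0.03566, "N2O": 0.65306}


class TestOstwald:
    @pytest.mark.parametrize("gas_name", ["N2", "Ar", "O2", "N2O"])
    def test_monotone_decreasing_with_temperature(self, gases, gas_name):
        temps = np.linspace(0.0, 35.0, 36)
        ks = [ostwald_coefficient(gases[gas_name], t) for t in temps]
        assert all(k > 0 for k in ks)
        assert all(a > b for a, b in zip(ks, ks[1:]))

    @pytest.mark.parametrize("gas_name,expected", sorted(HAND_OSTWALD_22C.items()))
    def test_matches_hand_evaluation_at_22C(self, gases, gas_name, expected):
        assert ostwald_coefficient(gases[gas_name], 22.0) == pytest.approx(
            expected, rel=1e-3
        )

    def test_out_of_range_names_gas_and_interval(self, gases):
        with pytest.raises(GasRangeError, match=r"0\.0, 35\.0.*N2O"):
            ostwald_coefficient(gases["N2O"], 50.0)


class TestEquilibriumConcentration:
    def test_zero_mole_fraction_gives_zero(self):
        gas = GasSpec.from_constants("N2", mole_fraction=0.0)
        assert equilibrium_concentration(gas, 20.0) == 0.0

    def test_n2_near_ambient_background(self, gases):
        # the ~487 uM ambient N2 pool corresponds to summer field temperature
        assert equilibrium_concentration(gases["N2"], 25.0) == pytest.approx(
            487.0, rel=0.05
        )

    def test_n2o_equilibrium_order_of_magnitude(self, gases):
        # ~9.2 nM at atmospheric equilibration (332 ppb, ~20 degC)
        eq_nM = equilibrium_concentration(gases["N2O"], 20.0) * 1000.0
        assert 5.0 < eq_nM < 20.0
        assert eq_nM == pytest.approx(9.2, rel=0.05)

    def test_linear_in_mole_fraction_and_pressure(self):
        base = GasSpec.from_constants("N2O")
        double_x = GasSpec.from_constants(
            "N2O", mole_fraction=2 * base.atmospheric_mole_fraction
        )
        c1 = equilibrium_concentration(base, 15.0, 1.0)
        assert equilibrium_concentration(double_x, 15.0, 1.0) == pytest.approx(2 * c1)
        assert equilibrium_concentration(base, 15.0, 2.0) == pytest.approx(2 * c1)


class TestHeadspacePartition:
    def test_no_headspace_all_aqueous(self):
        geom = VialGeometry(0.0, 10.0, 15.0)
        c_hs, c_aq = headspace_partition(50.0, geom, 0.5)
        assert c_hs == 0.0
        assert c_aq == pytest.approx(5.0)

    def test_symbolic_solution(self):
        # c_hs*V_hs + K*c_hs*V_aq = total  =>  c_hs = 100/(2 + 0.7*10)
        geom = VialGeometry(2.0, 10.0, 15.0)
        c_hs, c_aq = headspace_partition(100.0, geom, 0.7)
        assert c_hs == pytest.approx(100.0 / 9.0, rel=1e-12)
        assert c_aq == pytest.approx(0.7 * 100.0 / 9.0, rel=1e-12)

    def test_degenerate_geometry_raises(self):
        geom = VialGeometry(0.0, 0.0, 15.0)
        with pytest.raises(ValueError, match="degenerate"):
            headspace_partition(1.0, geom, 0.5)

    @settings(max_examples=200, deadline=None)
    @given(
        total=st.floats(0.0, 1e6),
        v_hs=st.floats(0.1, 11.0),
        v_aq=st.floats(0.1, 50.0),
        k=st.floats(0.001, 5.0),
    )
    def test_mole_conservation_property(self, total, v_hs, v_aq, k):
        geom = VialGeometry(v_hs, v_aq, 15.0)
        c_hs, c_aq = headspace_partition(total, geom, k)
        recovered = c_hs * v_hs + c_aq * v_aq
        assert recovered == pytest.approx(total, rel=1e-9, abs=1e-12)
        assert c_aq == pytest.approx(k * c_hs, rel=1e-12, abs=1e-15)


class TestExpectedHeadspaceRatio:
    def test_equal_temperatures_consistent_with_independent_partition(self, gases):
        geom = VialGeometry(2.0, 10.0, 22.0, 22.0)
        ratio = expected_headspace_ratio((gases["N2"], gases["Ar"]), geom)
        parts = []
        for g in (gases["N2"], gases["Ar"]):
            c = equilibrium_concentration(g, 22.0)
            k = ostwald_coefficient(g, 22.0)
            parts.append(headspace_partition(c * 10.0, geom, k)[0])
        assert ratio == pytest.approx(parts[0] / parts[1], rel=1e-12)

    def test_identical_solubility_gives_atmospheric_ratio(self):
        a = GasSpec.from_constants("N2")
        b = GasSpec(
            name="N2",
            atmospheric_mole_fraction=a.atmospheric_mole_fraction / 3.0,
            solubility_form=a.solubility_form,
            solubility_params=a.solubility_params,
        )
        geom = VialGeometry(2.0, 10.0, 8.0, 22.0)
        assert expected_headspace_ratio((a, b), geom) == pytest.approx(3.0, rel=1e-12)

    def test_matches_brute_force_mole_balance(self, gases, rng):
        # oracle: root-find the mole balance per gas instead of the closed form
        for _ in range(100):
            v_hs = rng.uniform(0.5, 5.0)
            v_aq = rng.uniform(2.0, 20.0)
            t_field = rng.uniform(1.0, 30.0)
            geom = VialGeometry(v_hs, v_aq, t_field, 22.0)
            brute = []
            for g in (gases["N2"], gases["Ar"]):
                total = equilibrium_concentration(g, t_field) * v_aq
                k = ostwald_coefficient(g, 22.0)
                f = lambda c_hs: c_hs * v_hs + k * c_hs * v_aq - total
                brute.append(brentq(f, 0.0, 1e9))
            expected = brute[0] / brute[1]
            got = expected_headspace_ratio((gases["N2"], gases["Ar"]), geom)
            assert got == pytest.approx(expected, rel=1e-9)


class TestAirWaterFlux:
    def test_zero_at_saturation(self):
        assert air_water_flux(10.0, 10.0, 1.5) == 0.0

    def test_unit_algebra(self):
        # 1 uM deficit at k = 1 m/d -> -1000 umol m^-2 d^-1
        assert air_water_flux(9.0, 10.0, 1.0) == pytest.approx(-1000.0)

    def test_sign_follows_deficit(self):
        assert air_water_flux(12.0, 10.0, 0.5) > 0
        assert air_water_flux(8.0, 10.0, 0.5) < 0

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError, match="transfer velocity"):
            air_water_flux(1.0, 1.0, -0.5)


class TestVialGeometry:
    def test_negative_volume_rejected(self):
        with pytest.raises(ValueError):
            VialGeometry(-1.0, 10.0, 15.0)

    def test_nominal_volume_mismatch_rejected(self):
        with pytest.raises(ValueError, match="nominal"):
            VialGeometry(2.0, 8.0, 15.0, nominal_volume_mL=12.0)

    def test_temperature_bounds(self):
        with pytest.raises(ValueError):
            VialGeometry(2.0, 10.0, 45.0)
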