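"""Signal processing: drift correction, GC inversion, Eq.-style double ratio."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from n2ofix.gases import GasSpec, VialGeometry, ostwald_coefficient
from n2ofix.saturation import (
    GcCalibration,
    IrmsReading,
    drift_correct,
    expected_vial_ratio,
    gc_n2o_concentration,
    n2_saturation,
    n2o_saturation,
)


def _sequence(signals, roles):
    return [
        IrmsReading(signals={"m28": s, "m40": s / 10.0}, run_index=i, role=r)
        for i, (s, r) in enumerate(zip(signals, roles))
    ]


class TestDriftCorrect:
    def test_identical_standards_constant_rescale(self):
        seq = _sequence([50.0, 80.0, 50.0], ["air_standard", "sample", "air_standard"])
        out = drift_correct(seq, {"m28": 100.0})
        # nominal/observed = 2 everywhere
        assert out[1].signals["m28"] == pytest.approx(160.0)
        assert out[0].signals["m28"] == pytest.approx(100.0)
        # untouched channel passes through
        assert out[1].signals["m40"] == pytest.approx(8.0)

    def test_linear_drift_interpolated_at_midpoint(self):
        # standards drift +10% across the run; the mid-run sample is scaled
        # down by ~5%
        seq = _sequence([100.0, 70.0, 110.0], ["air_standard", "sample", "air_standard"])
        out = drift_correct(seq, {"m28": 100.0})
        assert out[1].signals["m28"] == pytest.approx(70.0 / 1.05)

    def test_missing_bracket_falls_back_to_nearest(self):
        seq = _sequence(
            [100.0, 100.0, 80.0], ["air_standard", "air_standard", "sample"]
        )
        with pytest.warns(UserWarning, match="nearest-standard"):
            out = drift_correct(seq, {"m28": 100.0})
        assert out[2].signals["m28"] == pytest.approx(80.0)

    def test_needs_two_standards(self):
        seq = _sequence([100.0, 80.0], ["air_standard", "sample"])
        with pytest.raises(ValueError, match="at least 2"):
            drift_correct(seq, {"m28": 100.0})


class TestGcCalibration:
    def test_roundtrip_is_exact_inverse_on_range(self):
        amounts = np.geomspace(0.02, 2.0, 6)
        cal = GcCalibration(amounts, 5e4 * amounts)
        for a in np.geomspace(0.02, 2.0, 17):
            inv, extrapolated = cal.invert(float(cal.forward(a)))
            assert inv == pytest.approx(a, rel=1e-12)
            assert not extrapolated

    def test_quadratic_roundtrip(self):
        amounts = np.geomspace(0.02, 2.0, 8)
        resp = 5e4 * amounts + 3e3 * amounts**2
        cal = GcCalibration(amounts, resp, quadratic=True)
        inv, _ = cal.invert(float(cal.forward(0.7)))
        assert inv == pytest.approx(0.7, rel=1e-9)

    def test_below_blank_clips_and_flags(self):
        cal = GcCalibration(np.array([0.1, 1.0]), np.array([1e3, 1e4]))
        inv, flagged = cal.invert(-5.0)
        assert inv == 0.0 and flagged

    def test_extrapolation_flagged(self):
        cal = GcCalibration(np.array([0.1, 1.0]), np.array([1e3, 1e4]))
        _, flagged = cal.invert(5e4)
        assert flagged

    def test_unsorted_amounts_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            GcCalibration(np.array([1.0, 0.1]), np.array([1e4, 1e3]))


class TestGcN2oConcentration:
    def test_zero_response_zero_concentration(self):
        cal = GcCalibration(np.array([0.1, 1.0]), np.array([1e3, 1e4]))
        geom = VialGeometry(2.0, 10.0, 15.0)
        conc, _ = gc_n2o_concentration(0.0, cal, geom)
        assert conc == 0.0

    def test_forward_simulated_vial_roundtrip(self):
        # a 10 nM water sample, equilibrated, measured, inverted -> 10 nM
        n2o = GasSpec.from_constants("N2O")
        geom = VialGeometry(2.0, 10.0, 15.0, 22.0)
        k = ostwald_coefficient(n2o, 22.0)
        true_nM = 10.0
        total_nmol = true_nM / 1000.0 * geom.v_water_mL
        c_hs = total_nmol / (geom.v_headspace_mL + k * geom.v_water_mL)
        amount = c_hs * 0.1
        cal = GcCalibration(np.geomspace(1e-4, 2.0, 6),
                            5e4 * np.geomspace(1e-4, 2.0, 6))
        response = float(cal.forward(amount))
        conc, flags = gc_n2o_concentration(response, cal, geom, n2o=n2o)
        assert conc == pytest.approx(true_nM, rel=1e-6)
        assert flags == []


class TestN2Saturation:
    def _reading(self, n2, ar, idx=0, role="sample"):
        return IrmsReading(signals={"m28": n2, "m40": ar}, run_index=idx, role=role)

    def test_sample_equal_to_reference_is_100(self, gases):
        geom = VialGeometry(2.0, 10.0, 22.0, 22.0)
        exp = expected_vial_ratio(geom)
        sample = self._reading(40.0, 1.0)
        ref = self._reading(40.0, 1.0, role="reference_water")
        res = n2_saturation(sample, ref, exp, exp)
        assert res.saturation_percent == pytest.approx(100.0)

    def test_two_percent_excess_n2_gives_102(self):
        geom = VialGeometry(2.0, 10.0, 22.0, 22.0)
        exp = expected_vial_ratio(geom)
        res = n2_saturation(
            self._reading(40.0 * 1.02, 1.0),
            self._reading(40.0, 1.0, role="reference_water"),
            exp, exp,
        )
        assert res.saturation_percent == pytest.approx(102.0)

    @settings(max_examples=100, deadline=None)
    @given(gain=st.floats(0.01, 100.0))
    def test_invariant_to_common_detector_gain(self, gain):
        geom = VialGeometry(2.0, 10.0, 18.0, 22.0)
        exp_s = expected_vial_ratio(geom)
        geom_r = VialGeometry(2.0, 10.0, 22.0, 22.0)
        exp_r = expected_vial_ratio(geom_r)
        base_s = self._reading(37.0, 1.1)
        base_r = self._reading(40.0, 1.0, role="reference_water")
        scaled_s = self._reading(37.0 * gain, 1.1 * gain)
        scaled_r = self._reading(40.0 * gain, 1.0 * gain, role="reference_water")
        a = n2_saturation(base_s, base_r, exp_s, exp_r).saturation_percent
        b = n2_saturation(scaled_s, scaled_r, exp_s, exp_r).saturation_percent
        assert b == pytest.approx(a, rel=1e-12)

    def test_zero_ar_signal_raises(self):
        geom = VialGeometry(2.0, 10.0, 22.0, 22.0)
        exp = expected_vial_ratio(geom)
        with pytest.raises(ZeroDivisionError, match="m40"):
            n2_saturation(
                self._reading(40.0, 0.0),
                self._reading(40.0, 1.0, role="reference_water"),
                exp, exp,
            )


class TestN2oSaturation:
    def test_equilibrium_is_100(self, gases):
        from n2ofix.gases import equilibrium_concentration

        eq_nM = equilibrium_concentration(gases["N2O"], 12.0) * 1000.0
        res = n2o_saturation(eq_nM, 12.0)
        assert res.saturation_percent == pytest.approx(100.0)

    def test_zero_concentration_is_zero(self):
        assert n2o_saturation(0.0, 12.0).saturation_percent == 0.0
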