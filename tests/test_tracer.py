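"""15N bookkeeping: labelling fractions, rates, fixation partition,
direct-vs-indirect discrimination."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from n2ofix.tracer import (
    IncubationVial,
    LabellingScheme,
    assimilation_rate,
    classify_direct,
    delta_15n2,
    discrimination_report,
    enrichment,
    fixation_partition,
    indirect_upper_threshold,
    labelling_fraction,
    n2o_15n_concentration,
    total_reduction_rate,
    trimmed_mean,
)


def _vial(dw=0.5, dt=1.0, vol=0.012):
    return IncubationVial(
        treatment="tracer_N2O", biomass_type="benthic", dry_weight_g=dw,
        incubation_time_d=dt, temperature_C=15.0, water_volume_L=vol,
    )


class TestLabellingFraction:
    @pytest.mark.parametrize(
        "added,ambient,expected,sig",
        [
            (9.0, 487.0, 0.018, 2),     # N2 pool after tracer addition
            (9.0, 0.01, 0.98, 2),       # N2O pool
            (0.63, 487.0, 0.0013, 2),   # indirect-scenario N2 pool
        ],
    )
    def test_pond_scheme_values(self, added, ambient, expected, sig):
        f = labelling_fraction(added, 0.98, ambient)
        rounded = float(f"{f:.{sig}g}")
        assert rounded == expected

    def test_table_literal_mode_matches_printed_formulas(self):
        assert labelling_fraction(9.0, 0.98, 487.0, table_literal=True) == (
            pytest.approx(9.0 / 496.0)
        )

    def test_no_tracer_returns_natural_abundance_floor(self):
        assert labelling_fraction(0.0, 0.98, 100.0) == pytest.approx(0.00366)

    def test_empty_pool_undefined(self):
        with pytest.raises(ZeroDivisionError):
            labelling_fraction(0.0, 0.98, 0.0)

    @settings(max_examples=200, deadline=None)
    @given(
        added=st.floats(0.01, 100.0),
        ambient=st.floats(0.01, 1000.0),
        bump=st.floats(0.01, 10.0),
    )
    def test_monotonicity_property(self, added, ambient, bump):
        f = labelling_fraction(added, 0.98, ambient)
        assert labelling_fraction(added + bump, 0.98, ambient) > f
        assert labelling_fraction(added, 0.98, ambient + bump) < f


class TestDiscrimination:
    def test_threshold_from_printed_inputs(self):
        assert indirect_upper_threshold(0.0013, 0.018, 11.5) == pytest.approx(
            0.8306, abs=5e-4
        )
        assert round(indirect_upper_threshold(0.0013, 0.018, 11.5), 1) == 0.8

    def test_zero_indirect_labelling_zero_threshold(self):
        assert indirect_upper_threshold(0.0, 0.018, 11.5) == 0.0

    def test_fourteen_fold_suppression(self):
        thr = indirect_upper_threshold(0.0013, 0.018, 11.5)
        assert 11.5 / thr == pytest.approx(14.0, abs=0.5)

    def test_measured_far_above_threshold_is_direct(self):
        v = classify_direct(5.3, 0.8)
        assert v.verdict == "direct-dominant"
        assert v.fold_ratio == pytest.approx(5.3 / 0.8)

    def test_boundary_is_indistinguishable(self):
        assert classify_direct(0.8, 0.8).verdict == "indistinguishable"

    @settings(max_examples=100, deadline=None)
    @given(scale=st.floats(0.001, 1000.0))
    def test_verdict_invariant_to_common_rescaling(self, scale):
        a = classify_direct(5.3, 0.8)
        b = classify_direct(5.3 * scale, 0.8 * scale)
        assert a.verdict == b.verdict
        assert b.fold_ratio == pytest.approx(a.fold_ratio, rel=1e-9)

    def test_report_reproduces_scheme_table(self):
        rep = discrimination_report(LabellingScheme(), 11.5, 5.3)
        assert round(rep["F_N2"], 3) == 0.018
        assert round(rep["F_N2O"], 2) == 0.98
        assert float(f"{rep['F_N2_prime']:.2g}") == 0.0013
        assert round(rep["indirect_upper_threshold"], 1) == 0.8
        assert rep["verdict"] == "direct-dominant"
        assert rep["suppression_factor"] == pytest.approx(14.0, abs=0.5)


class TestIsotopologueConcentrations:
    @pytest.mark.parametrize(
        "m45,m46,expected", [(0.0, 0.0, 0.0), (0.1, 1.0, 2.1), (0.0, 9.0, 18.0)]
    )
    def test_15n2o_formula(self, m45, m46, expected):
        assert n2o_15n_concentration(m45, m46) == pytest.approx(expected)

    def test_delta15n2_below_lod_flagged_and_zeroed(self):
        d = delta_15n2(0.05, 0.02)
        assert d.value_uM == pytest.approx(0.09)
        assert d.below_lod
        assert d.budget_value_uM == 0.0

    def test_delta15n2_above_lod_retained(self):
        d = delta_15n2(0.1, 0.2)
        assert d.value_uM == pytest.approx(0.5)
        assert not d.below_lod
        assert d.budget_value_uM == pytest.approx(0.5)

    def test_delta15n2_half_lod_policy(self):
        d = delta_15n2(0.01, 0.01, below_lod="half")
        assert d.budget_value_uM == pytest.approx(0.07)


class TestRates:
    def test_no_change_zero_rate(self):
        assert total_reduction_rate(9.0, 9.0, _vial()) == 0.0

    def test_reduction_hand_arithmetic(self):
        # (9.0 - 8.82) uM * 0.012 L * 1000 / (1 d * 0.5 g) = 4.32
        assert total_reduction_rate(9.0, 8.82, _vial()) == pytest.approx(4.32)

    def test_negative_rate_retained(self):
        assert total_reduction_rate(8.0, 9.0, _vial()) < 0

    def test_enrichment_trivial_and_formula(self):
        assert enrichment(0.366, 0.466, 0.366, 0.376) == pytest.approx(0.0009)
        assert enrichment(0.4, 0.5, 0.4, 0.5) == 0.0

    def test_assimilation_hand_arithmetic(self):
        # 5000 nmol * 0.001 / (1 d * 0.5 g) = 10
        assert assimilation_rate(5000.0, 0.001, _vial()) == pytest.approx(10.0)

    def test_assimilation_zero_enrichment(self):
        assert assimilation_rate(5000.0, 0.0, _vial()) == 0.0


class TestFixationPartition:
    def test_no_n2_production_fixation_equals_reduction(self):
        p = fixation_partition(100.0, 0.0, 40.0)
        assert p.total_fixation == 100.0
        assert p.din_production == 60.0

    def test_worked_arithmetic(self):
        p = fixation_partition(100.0, 20.0, 50.0)
        assert p.total_fixation == 80.0
        assert p.din_production == 30.0

    def test_nox_fraction(self):
        p = fixation_partition(100.0, 10.0, 40.0, nox_production=11.7)
        assert p.nox_fraction == pytest.approx(0.117)

    def test_inconsistent_vial_flagged(self):
        p = fixation_partition(10.0, 20.0, 1.0)
        assert "n2_production_exceeds_reduction" in p.flags

    @settings(max_examples=200, deadline=None)
    @given(
        red=st.floats(0.0, 1000.0),
        n2frac=st.floats(0.0, 1.0),
        assim=st.floats(0.0, 100.0),
    )
    def test_closure_property(self, red, n2frac, assim):
        n2p = red * n2frac
        p = fixation_partition(red, n2p, assim)
        assert p.total_fixation == pytest.approx(red - n2p, rel=1e-12, abs=1e-9)
        assert p.total_fixation == pytest.approx(
            p.assimilation + p.din_production, rel=1e-12, abs=1e-9
        )


class TestCohortStatistics:
    def test_trimmed_mean_drops_tails(self):
        x = np.concatenate([np.ones(98), [1000.0, -1000.0]])
        assert trimmed_mean(x) == pytest.approx(1.0)

    def test_trimmed_mean_empty(self):
        assert math.isnan(trimmed_mean([]))
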