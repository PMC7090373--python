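"""Core calculator: COHb lookups, loss models, STPD, tHb-mass formula."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ocor import core
from ocor.core import CorrectionParams
from ocor.errors import (
    ConfigurationError,
    InfeasibleSessionError,
    InvalidRiseError,
    MissingTimepointError,
)
from ocor.session import COSample, OcorSession


def make_session(baseline_readings, timed, dose=50.0, **kw):
    return OcorSession(
        subject_id="t",
        dose_co_ml=dose,
        baseline=[COSample(-1.0, r) for r in baseline_readings],
        timed=[COSample(t, r) for t, r in timed],
        **kw,
    )


class TestBaselineAndLookup:
    @pytest.mark.parametrize(
        "baselines, expected",
        [
            ([[1.62]], 1.62),
            ([[1.5, 1.7]], 1.6),
            ([[1.0], [2.0]], 1.5),
        ],
    )
    def test_baseline_mean(self, baselines, expected):
        s = make_session(baselines, [(6.0, [6.0]), (8.0, [6.0])])
        assert core.baseline_cohb(s) == pytest.approx(expected)

    def test_lookup_single_and_replicates(self):
        s = make_session([[1.0]], [(6.0, [6.33]), (8.0, [6.2, 6.4])])
        assert core.cohb_at(s, 6.0) == pytest.approx(6.33)
        assert core.cohb_at(s, 8.0) == pytest.approx(6.3)

    def test_lookup_outside_tolerance_raises(self):
        s = make_session([[1.0]], [(8.4, [6.0])])
        with pytest.raises(MissingTimepointError):
            core.cohb_at(s, 8.0 - 0.5)  # 8.4 is 0.9 away from 7.5
        with pytest.raises(MissingTimepointError):
            core.cohb_at(s, 6.0)

    def test_lookup_tie_prefers_earlier(self):
        s = make_session([[1.0]], [(6.5, [5.0]), (7.5, [6.0])])
        assert core.cohb_at(s, 7.0) == pytest.approx(5.0)

    @pytest.mark.parametrize(
        "c6, c8, expected",
        [(6.0, 6.2, 6.1), (6.30, 6.30, 6.30), (6.33, 6.30, 6.315)],
    )
    def test_seven_min_value(self, c6, c8, expected):
        s = make_session([[1.0]], [(6.0, [c6]), (8.0, [c8])])
        assert core.seven_min_cohb(s) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "base, post, expected", [(1.62, 6.88, 5.26), (2.0, 2.0, 0.0), (1.0, 5.0, 4.0)]
    )
    def test_delta_cohb(self, base, post, expected):
        s = make_session([[base]], [(6.0, [post]), (8.0, [post])])
        assert core.delta_cohb(s, core.SEVEN_MIN) == pytest.approx(expected)


class TestLossModels:
    @pytest.mark.parametrize(
        "dose, t, expected", [(40.0, 20.0, 1.4), (55.0, 0.0, 0.0), (72.0, 20.0, 2.52)]
    )
    def test_myoglobin_linear(self, dose, t, expected, params):
        assert core.co_loss_myoglobin(dose, t, params) == pytest.approx(expected)

    def test_myoglobin_negative_time_raises(self, params):
        with pytest.raises(ValueError):
            core.co_loss_myoglobin(50.0, -1.0, params)

    def test_exhaled_zero_during_rebreathing(self, params):
        s = make_session([[1.0]], [(6.0, [6.0])])
        assert core.co_loss_exhaled(s, 2.0, params) == 0.0
        assert core.co_loss_exhaled(s, 1.0, params) == 0.0

    @pytest.mark.parametrize("rate, expected", [(0.15, 2.7), (0.28, 5.04)])
    def test_exhaled_rate_after_disconnect(self, rate, expected):
        s = make_session([[1.0]], [(6.0, [6.0])], exhale_rate_ml_per_min=rate)
        assert core.co_loss_exhaled(s, 20.0, CorrectionParams()) == pytest.approx(expected)

    def test_absorbed_subtraction(self):
        params = CorrectionParams(k_myo_per_min=1.5 / (50 * 20), exhale_rate_ml_per_min=2.0 / 18)
        s = make_session([[1.0]], [(6.0, [6.0])], dose=50.0, residual_system_co_ml=5.0)
        assert core.absorbed_co(s, 20.0, params) == pytest.approx(50 - 5 - 2 - 1.5)

    def test_absorbed_equals_dose_without_losses(self):
        params = CorrectionParams(k_myo_per_min=0.0, exhale_rate_ml_per_min=0.0)
        s = make_session([[1.0]], [(6.0, [6.0])], dose=50.0)
        assert core.absorbed_co(s, 20.0, params) == pytest.approx(50.0)

    def test_losses_exceeding_dose_raise(self):
        s = make_session([[1.0]], [(6.0, [6.0])], dose=1.0, residual_system_co_ml=0.9)
        params = CorrectionParams(exhale_rate_ml_per_min=1.0)
        with pytest.raises(InfeasibleSessionError):
            core.absorbed_co(s, 20.0, params)

    @settings(max_examples=50, derandomize=True)
    @given(
        dose=st.floats(30, 80),
        residual=st.floats(0, 5),
        t=st.floats(0, 20),
        rate=st.floats(0.0, 0.3),
        k=st.floats(0.0, 0.003),
    )
    def test_conservation_and_monotonicity(self, dose, residual, t, rate, k):
        """Absorbed + exhaled + myoglobin + residual == dose; absorbed non-increasing."""
        params = CorrectionParams(k_myo_per_min=k, exhale_rate_ml_per_min=rate)
        s = make_session(
            [[1.0]], [(6.0, [6.0])], dose=dose, residual_system_co_ml=residual
        )
        try:
            absorbed = core.absorbed_co(s, t, params)
        except InfeasibleSessionError:
            return
        total = (
            absorbed
            + core.co_loss_exhaled(s, t, params)
            + core.co_loss_myoglobin(dose, t, params)
            + residual
        )
        assert total == pytest.approx(dose, rel=1e-12)
        if t + 1 <= 20:
            try:
                later = core.absorbed_co(s, t + 1.0, params)
                assert later <= absorbed + 1e-12
            except InfeasibleSessionError:
                pass


class TestSTPD:
    def test_identity_when_disabled(self, params):
        assert core.stpd(50.0, None, None, params) == 50.0

    def test_definitional_point(self):
        params = CorrectionParams(apply_stpd=True, vapor_table_mmhg={0.0: 0.0})
        assert core.stpd(100.0, 0.0, 760.0, params) == pytest.approx(100.0)

    def test_room_conditions(self):
        params = CorrectionParams(apply_stpd=True, vapor_table_mmhg={20.0: 17.5})
        assert core.stpd(50.0, 20.0, 760.0, params) == pytest.approx(45.52, abs=0.01)

    def test_missing_ambient_raises(self):
        params = CorrectionParams(apply_stpd=True)
        with pytest.raises(ConfigurationError):
            core.stpd(50.0, None, 760.0, params)


class TestTHbMass:
    def test_worked_value(self):
        # M_CO 50 ml at ΔCOHb 5.0% -> 50*100/(5*1.39) g
        params = CorrectionParams(k_myo_per_min=0.0, exhale_rate_ml_per_min=0.0)
        s = make_session([[1.0]], [(6.0, [6.0]), (8.0, [6.0])], dose=50.0)
        res = core.thb_mass_at(s, core.SEVEN_MIN, params)
        assert res.thb_mass_g == pytest.approx(719.42, abs=0.01)

    def test_linearity_in_dose(self):
        params = CorrectionParams(k_myo_per_min=0.0, exhale_rate_ml_per_min=0.0)
        s1 = make_session([[1.0]], [(6.0, [6.0]), (8.0, [6.0])], dose=50.0)
        s2 = make_session([[1.0]], [(6.0, [6.0]), (8.0, [6.0])], dose=100.0)
        r1 = core.thb_mass_at(s1, 7.0, params)
        r2 = core.thb_mass_at(s2, 7.0, params)
        assert r2.thb_mass_g == pytest.approx(2 * r1.thb_mass_g)

    def test_inverse_consistency(self):
        # tHb 396 g at ΔCOHb 7.2% implies M_CO = 39.63 ml
        m_co = 396.0 * 7.2 * 1.39 / 100.0
        assert m_co == pytest.approx(39.63, abs=0.01)

    def test_negative_rise_raises(self):
        s = make_session([[5.0]], [(6.0, [4.0]), (8.0, [4.0])])
        with pytest.raises(InvalidRiseError):
            core.thb_mass_at(s, 7.0)

    @settings(max_examples=40, derandomize=True)
    @given(delta=st.floats(1.0, 9.0), delta2=st.floats(1.0, 9.0))
    def test_strictly_decreasing_in_delta(self, delta, delta2):
        if abs(delta - delta2) < 1e-6:
            return
        params = CorrectionParams(k_myo_per_min=0.0, exhale_rate_ml_per_min=0.0)
        lo, hi = sorted([delta, delta2])
        s_lo = make_session([[1.0]], [(6.0, [1.0 + lo]), (8.0, [1.0 + lo])])
        s_hi = make_session([[1.0]], [(6.0, [1.0 + hi]), (8.0, [1.0 + hi])])
        assert (
            core.thb_mass_at(s_hi, 7.0, params).thb_mass_g
            < core.thb_mass_at(s_lo, 7.0, params).thb_mass_g
        )

    def test_unit_invariance_of_pipeline(self, session, params):
        """tHb-mass depends on COHb percentages only; downstream volume
        conversion happens at one boundary (checked in volumes tests)."""
        res = core.thb_mass_at(session, 7.0, params)
        assert res.thb_mass_g > 0
        assert res.absorbed_co_ml <= session.dose_co_ml
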