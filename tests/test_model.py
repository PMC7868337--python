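"""Unit and property tests for the dynamic creatinine model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neocrea import (
    ModelParameters,
    NeonateProfile,
    TreatmentCourse,
    ValidationError,
    apply_ibuprofen_effect,
    distribution_volume,
    elimination_rate,
    maturation_clearance,
    simulate_concentration,
)
from neocrea.model import CLEARANCE_FLOOR

from conftest import euler_reference


def params(**kw):
    defaults = dict(emax=0.4, t50=10.0, hill=2.0, production_rate=2.5)
    defaults.update(kw)
    return ModelParameters(**defaults)


def profile(**kw):
    defaults = dict(id="n1", gestational_age=27, birth_weight=779.0,
                    initial_creatinine=0.462)
    defaults.update(kw)
    return NeonateProfile(**defaults)


class TestMaturationClearance:
    def test_baseline_at_birth(self):
        # at t = 0 the Hill term vanishes: CL(0) = 0.075 * 3.55 = 0.26625
        assert maturation_clearance(0.0, params()) == pytest.approx(0.26625)

    def test_half_maximum_at_t50(self):
        p = params()
        assert maturation_clearance(p.t50, p) == pytest.approx(p.cl_bl_eff + p.emax / 2)

    def test_hand_computed_value(self):
        # emax 0.4, t50 10, hill 2, t 5: 0.26625 + 0.4 * 25 / 125
        assert maturation_clearance(5.0, params()) == pytest.approx(0.34625)

    def test_negative_age_rejected(self):
        with pytest.raises(ValidationError):
            maturation_clearance(-0.1, params())

    @settings(derandomize=True, max_examples=50)
    @given(
        emax=st.floats(0.0, 5.0),
        t50=st.floats(0.5, 30.0),
        hill=st.floats(0.3, 8.0),
        t=st.floats(0.0, 42.0),
        dt=st.floats(0.0, 10.0),
    )
    def test_monotone_and_bounded(self, emax, t50, hill, t, dt):
        p = params(emax=emax, t50=t50, hill=hill)
        cl_a = maturation_clearance(t, p)
        cl_b = maturation_clearance(t + dt, p)
        assert cl_b >= cl_a - 1e-12
        assert p.cl_bl_eff - 1e-12 <= cl_a <= p.cl_bl_eff + emax + 1e-12


class TestVolumeAndRates:
    @pytest.mark.parametrize(
        "weight, vol", [(1000.0, 0.7), (621.0, 0.4347), (889.0, 0.6223)]
    )
    def test_distribution_volume(self, weight, vol):
        assert distribution_volume(weight, params()) == pytest.approx(vol)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValidationError):
            distribution_volume(0.0, params())

    def test_ibuprofen_subtraction_is_absolute(self):
        p = params()
        assert apply_ibuprofen_effect(0.26625, True, p) == pytest.approx(
            0.26625 - 0.013536
        )
        assert apply_ibuprofen_effect(0.5, False, p) == 0.5
        assert apply_ibuprofen_effect(0.013, True, p) == CLEARANCE_FLOOR

    def test_elimination_rate_is_clearance_over_volume(self):
        p, prof = params(), profile(birth_weight=621.0)
        expected = maturation_clearance(0.0, p) / distribution_volume(621.0, p)
        assert elimination_rate(0.0, prof, p) == pytest.approx(expected)
        assert expected == pytest.approx(0.26625 / 0.4347)

    def test_elimination_rate_constant_without_maturation(self):
        p = params(emax=0.0)
        prof = profile()
        rates = [elimination_rate(t, prof, p) for t in (0.0, 5.0, 30.0)]
        assert max(rates) - min(rates) < 1e-15

    def test_exposure_shifts_rate_by_reduction_over_volume(self):
        p, prof = params(), profile()
        vd = distribution_volume(prof.birth_weight, p)
        delta = elimination_rate(8.0, prof, p, exposed=False) - elimination_rate(
            8.0, prof, p, exposed=True
        )
        assert delta == pytest.approx(p.ibuprofen_reduction / vd)


class TestSimulateConcentration:
    def test_exponential_decay_closed_form(self):
        # no production, constant clearance: C(t) = C0 exp(-ket t)
        p = params(emax=0.0, production_rate=0.0)
        prof = profile()
        ket = elimination_rate(0.0, prof, p)
        traj = simulate_concentration(prof, p, (), t_end=10.0, step=0.005)
        expected = prof.initial_creatinine * np.exp(-ket * traj.times)
        assert np.max(np.abs(traj.concentration - expected)) < 1e-6

    def test_steady_state_is_production_over_clearance(self):
        p = params(emax=0.0, production_rate=2.0)
        prof = profile()
        ket = elimination_rate(0.0, prof, p)
        t_end = round(8.0 * 5.0 / ket / 0.005) * 0.005
        traj = simulate_concentration(prof, p, (), t_end=t_end, step=0.005)
        c_ss = p.production_rate / (10.0 * maturation_clearance(0.0, p))
        assert traj.concentration[-1] == pytest.approx(c_ss, abs=1e-4)

    def test_step_halving_converged(self):
        p, prof = params(), profile()
        course = TreatmentCourse(start_day=1)
        a = simulate_concentration(prof, p, (course,), t_end=42.0, step=0.005)
        b = simulate_concentration(prof, p, (course,), t_end=42.0, step=0.0025)
        assert np.max(np.abs(b.concentration[::2] - a.concentration)) < 1e-5

    def test_matches_forward_euler_oracle(self):
        p, prof = params(), profile()
        course = TreatmentCourse(start_day=3)
        traj = simulate_concentration(prof, p, (course,), t_end=12.0, step=0.005)
        ref = euler_reference(prof, p, (course,), t_end=12.0)
        assert np.max(np.abs(traj.concentration - ref)) < 1e-4

    def test_exposure_flag_marks_closed_window(self):
        traj = simulate_concentration(
            profile(), params(), (TreatmentCourse(start_day=15),), t_end=42.0,
            step=0.005,
        )
        flagged = traj.times[traj.exposure_flag]
        assert flagged.min() == pytest.approx(14.0)
        assert flagged.max() == pytest.approx(17.0)
        # clearance channel shows the reduction exactly inside the window
        i_in = np.flatnonzero(traj.exposure_flag)[1]
        p = params()
        assert traj.clearance[i_in] == pytest.approx(
            maturation_clearance(traj.times[i_in], p) - p.ibuprofen_reduction
        )

    def test_exposed_dominates_and_coincides_before_window(self):
        p, prof = params(), profile()
        course = TreatmentCourse(start_day=15)
        base = simulate_concentration(prof, p, (), t_end=42.0, step=0.005)
        expo = simulate_concentration(prof, p, (course,), t_end=42.0, step=0.005)
        start = course.window[0]
        pre = base.times < start
        assert np.array_equal(base.concentration[pre], expo.concentration[pre])
        post = base.times >= start
        assert np.all(expo.concentration[post] >= base.concentration[post] - 1e-12)

    def test_overlapping_courses_rejected(self):
        with pytest.raises(ValidationError):
            simulate_concentration(
                profile(), params(),
                (TreatmentCourse(start_day=1), TreatmentCourse(start_day=3)),
                t_end=10.0,
            )

    def test_oversized_step_rejected(self):
        with pytest.raises(ValidationError):
            simulate_concentration(profile(), params(), (), t_end=10.0, step=0.1)


class TestDomainTypes:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(birth_weight=-5.0),
            dict(initial_creatinine=0.0),
            dict(gestational_age=20),
            dict(delivery_mode="breech"),
        ],
    )
    def test_profile_invariants(self, kw):
        with pytest.raises(ValidationError):
            profile(**kw)

    def test_course_window_and_dose_length(self):
        course = TreatmentCourse(start_day=29)
        assert course.window == (28.0, 31.0)
        with pytest.raises(ValidationError):
            TreatmentCourse(start_day=1, duration_days=2)  # 3 doses for 2 days
        with pytest.raises(ValidationError):
            TreatmentCourse(start_day=0)

    def test_parameters_reject_nonpositive_shape(self):
        with pytest.raises(ValidationError):
            params(hill=0.0)
        with pytest.raises(ValidationError):
            params(t50=-1.0)
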