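"""Reflex controller: stimulation laws, inhibitions, delay lines."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reflexwalk.params import muscle_index
from reflexwalk.reflexes import (DelayLine, SensorSnapshot,
                                 stimulate_all,
                                 stimulus_positive_force_feedback)


def quiet_snapshot(config, **kw):
    """Both legs in stance at the trunk setpoint with silent sensors."""
    l_opt = np.array([m.l_opt for m in config.muscles] * 2)
    defaults = dict(
        F_mtu=np.zeros(14), l_ce=0.3 * l_opt,
        knee_angle=np.full(2, math.radians(150.0)),
        knee_vel=np.zeros(2), phase=np.zeros(2, dtype=int),
        load_share=np.full(2, 0.5), lean=config.reflexes.theta_ref,
        lean_rate=0.0,
        lean_at_toe_off=np.full(2, config.reflexes.theta_ref))
    defaults.update(kw)
    return SensorSnapshot(**defaults)


def test_positive_force_feedback_formula():
    assert stimulus_positive_force_feedback(0.0, 0.01, 1e-3) == 0.01
    assert stimulus_positive_force_feedback(500.0, 0.01, 1e-3) \
        == pytest.approx(0.51)
    assert stimulus_positive_force_feedback(5000.0, 0.01, 1e-3) == 1.0
    with pytest.raises(ValueError):
        stimulus_positive_force_feedback(-1.0, 0.01, 1e-3)


def test_quiet_stance_gives_resting_stimulation(config):
    """Upright trunk at the reference lean, zero rate, symmetric load and
    no muscle force: every muscle sits at its resting stimulation."""
    S = stimulate_all(quiet_snapshot(config), config)
    S0 = np.array([config.activation.S0[m.name] for m in config.muscles] * 2)
    assert np.allclose(S, S0)


def test_vas_overextension_inhibition(config):
    """Knee beyond the threshold while extending lowers VAS drive."""
    i = muscle_index("VAS", "L")
    F = np.zeros(14)
    F[i] = 0.3 * config.muscles[3].F_max
    thr = config.reflexes.phi_knee_off
    base = stimulate_all(quiet_snapshot(
        config, F_mtu=F, knee_angle=np.array([thr - 0.1, 2.6]),
        knee_vel=np.array([0.5, 0.0])), config)
    inhib = stimulate_all(quiet_snapshot(
        config, F_mtu=F, knee_angle=np.array([thr + math.radians(1.0), 2.6]),
        knee_vel=np.array([0.5, 0.0])), config)
    flexing = stimulate_all(quiet_snapshot(
        config, F_mtu=F, knee_angle=np.array([thr + math.radians(1.0), 2.6]),
        knee_vel=np.array([-0.5, 0.0])), config)
    assert inhib[i] < base[i]
    assert flexing[i] == pytest.approx(base[i])   # only while extending


def test_contralateral_touchdown_modulation(config):
    """Toggling the trailing-leg flag raises HFL and lowers HAM on that
    leg, everything else fixed."""
    F = np.zeros(14)
    # some trunk-PD drive so HAM has room to decrease
    snap_off = quiet_snapshot(config, lean=config.reflexes.theta_ref + 0.08)
    snap_on = quiet_snapshot(config, lean=config.reflexes.theta_ref + 0.08,
                             contralateral_td=np.array([True, False]))
    S_off = stimulate_all(snap_off, config)
    S_on = stimulate_all(snap_on, config)
    assert S_on[muscle_index("HFL", "L")] > S_off[muscle_index("HFL", "L")]
    assert S_on[muscle_index("HAM", "L")] < S_off[muscle_index("HAM", "L")]
    # the leading (non-trailing) leg is untouched
    assert S_on[muscle_index("HFL", "R")] \
        == pytest.approx(S_off[muscle_index("HFL", "R")])


def test_stance_force_feedback_muscles(config):
    """SOL/GAS/VAS stimulation grows with their own delayed force."""
    for name in ("SOL", "GAS", "VAS"):
        i = muscle_index(name, "R")
        F = np.zeros(14)
        F[i] = 0.4 * config.muscles[muscle_index(name, "L")].F_max
        S_hi = stimulate_all(quiet_snapshot(config, F_mtu=F), config)
        S_lo = stimulate_all(quiet_snapshot(config), config)
        assert S_hi[i] > S_lo[i]


def test_unknown_phase_rejected(config):
    with pytest.raises(ValueError):
        quiet_snapshot(config, phase=np.array([0, 2]))


@settings(max_examples=40, deadline=None, derandomize=True)
@given(data=st.data())
def test_stimulations_bounded_for_arbitrary_sensors(data):
    """All 14 outputs stay in [0, 1] for arbitrary bounded inputs."""
    from reflexwalk import load_config
    config = load_config()
    F_max = np.array([m.F_max for m in config.muscles] * 2)
    l_opt = np.array([m.l_opt for m in config.muscles] * 2)
    F = F_max * data.draw(st.lists(
        st.floats(0, 2.0), min_size=14, max_size=14))
    lce = l_opt * np.array(data.draw(st.lists(
        st.floats(0.2, 2.0), min_size=14, max_size=14)))
    snap = SensorSnapshot(
        F_mtu=np.array(F), l_ce=lce,
        knee_angle=np.array([data.draw(st.floats(1.0, 3.3)),
                             data.draw(st.floats(1.0, 3.3))]),
        knee_vel=np.array([data.draw(st.floats(-9, 9)),
                           data.draw(st.floats(-9, 9))]),
        phase=np.array([data.draw(st.integers(0, 1)),
                        data.draw(st.integers(0, 1))]),
        load_share=np.array([data.draw(st.floats(0, 1)),
                             data.draw(st.floats(0, 1))]),
        lean=data.draw(st.floats(-1.0, 1.0)),
        lean_rate=data.draw(st.floats(-5, 5)),
        lean_at_toe_off=np.array([data.draw(st.floats(-1, 1)),
                                  data.draw(st.floats(-1, 1))]),
        contralateral_td=np.array([data.draw(st.booleans()),
                                   data.draw(st.booleans())]))
    S = stimulate_all(snap, config)
    assert np.all(S >= 0.0) and np.all(S <= 1.0)


def test_controller_is_deterministic(config):
    snap = quiet_snapshot(config, lean=0.2, lean_rate=0.4)
    S1 = stimulate_all(snap, config)
    S2 = stimulate_all(snap, config)
    assert np.array_equal(S1, S2)


def test_delay_line_reproduces_ramp():
    """A ramp read back at t - delay equals ramp(t - delay) exactly."""
    dl = DelayLine(delay=0.02, dt=1e-3, initial=0.0)
    slope = 3.0
    for k in range(100):
        t = k * 1e-3
        dl.push(t, slope * t)
        if t >= 0.02:
            assert dl.read(t) == pytest.approx(slope * (t - 0.02),
                                               abs=1e-12)
    # pre-history returns the initial value, never the future
    dl2 = DelayLine(delay=0.05, dt=1e-3, initial=7.0)
    dl2.push(0.0, 1.0)
    assert dl2.read(0.0) == 7.0
    assert dl2.read(0.049) == 7.0
    assert dl2.read(0.05) == 1.0
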