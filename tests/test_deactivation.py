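"""Stride-clocked deactivation: mask timing, settling gate, grid."""

import numpy as np
import pytest

from reflexwalk.deactivation import (DeactivationSchedule, DeactivationSpec,
                                     StrideClock, deactivation_grid,
                                     deactivation_mask)


def make_schedule(spec, touchdowns):
    clock = StrideClock()
    sched = DeactivationSchedule(spec, clock)
    for td in touchdowns:
        sched.on_touchdown(td)
    return sched


def test_zero_duration_mask_always_false():
    spec = DeactivationSpec("GAS", 50.0, 0.0)
    tds = np.arange(10) * 1.25
    for t in np.linspace(0, 12, 241):
        assert not deactivation_mask(t, spec, tds[tds <= t])


def test_settling_strides_gate():
    """No deactivation before the sixth touchdown, whatever the window."""
    spec = DeactivationSpec("VAS", 0.0, 1.0)
    tds = np.arange(1, 6) * 1.25          # five touchdowns only
    for t in np.linspace(0, 7.5, 150):
        assert not deactivation_mask(t, spec, tds[tds <= t])


def test_immediate_onset_full_second_window():
    """gc_off=0, t_off=1: mask true for exactly 1 s from each armed
    touchdown."""
    spec = DeactivationSpec("GAS", 0.0, 1.0)
    tds = np.arange(1, 9) * 1.25          # 6th touchdown at 7.5 s
    sched = make_schedule(spec, tds)
    # rebuild incrementally for exact timing checks
    for t, expected in [(7.49, False), (7.5 + 1e-6, True), (8.49, True),
                        (8.51, False), (8.75 + 1e-6, True), (9.74, True),
                        (9.76, False)]:
        assert deactivation_mask(t, spec, tds[tds <= t]) == expected, t


def test_mask_timing_uses_online_stride_estimate():
    """The trigger fires at touchdown + gc_off * (previous stride time)."""
    spec = DeactivationSpec("VAS", 40.0, 0.1)
    # irregular strides: previous-stride estimate differs from nominal
    tds = np.array([0.0, 1.0, 2.5, 3.5, 5.0, 6.0, 7.5])
    # 6th touchdown at 6.0 with previous stride = 1.0 -> trigger at 6.4
    assert not deactivation_mask(6.39, spec, tds)
    assert deactivation_mask(6.41, spec, tds)
    assert deactivation_mask(6.49, spec, tds)
    assert not deactivation_mask(6.51, spec, tds)


def test_overlapping_windows_merge():
    """A new window opening before the old one closes extends it."""
    spec = DeactivationSpec("VAS", 0.0, 1.0, start_stride=1)
    tds = [0.0, 0.6]                      # second TD inside first window
    sched = make_schedule(spec, tds)
    assert sched.mask(0.5)
    assert sched.mask(1.1)                # past first window, inside second
    assert sched.mask(1.59)
    assert not sched.mask(1.61)


def test_stride_clock_estimates():
    clock = StrideClock()
    assert clock.t_stride_est == pytest.approx(1.25)
    clock.touchdown(2.0)
    assert clock.t_stride_est == pytest.approx(1.25)   # still seeded
    clock.touchdown(3.1)
    assert clock.t_stride_est == pytest.approx(1.1)
    assert clock.stride_index == 2
    with pytest.raises(ValueError):
        clock.touchdown(3.0)


def test_full_grid_size_and_bounds():
    grid = deactivation_grid("GAS")
    assert len(grid) == 20000
    gcs = sorted({s.gc_off for s in grid})
    toffs = sorted({s.t_off for s in grid})
    assert len(gcs) == 50 and len(toffs) == 400
    assert gcs[0] == 0.0 and gcs[1] - gcs[0] == pytest.approx(2.0)
    assert toffs[0] == 0.0 and toffs[1] - toffs[0] == pytest.approx(0.0025)
    assert max(gcs) <= 100.0 and max(toffs) <= 1.0


def test_reduced_grid_covers_same_ranges():
    grid = deactivation_grid("HAM", n_gc=10, n_toff=20)
    assert len(grid) == 200
    assert {s.gc_off for s in grid} == set(np.linspace(0, 100, 11)[:-1])
    assert max(s.t_off for s in grid) == pytest.approx(0.95)


def test_spec_validation():
    with pytest.raises(ValueError):
        DeactivationSpec("SOL", 50.0, 0.1)      # not a studied muscle
    with pytest.raises(ValueError):
        DeactivationSpec("GAS", 120.0, 0.1)
    with pytest.raises(ValueError):
        DeactivationSpec("GAS", 50.0, 1.5)
    assert DeactivationSpec("gas", 52.0, 0.25).label() == "GAS (52%, 0.25 s)"
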