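"""Rigid-body dynamics oracles: equilibrium, point-mass limit, energy and
momentum conservation, mirror symmetry, kinematic consistency."""

import numpy as np
import pytest

from reflexwalk import _kernels, load_config
from reflexwalk.multibody import (GeneralizedState, forward_dynamics,
                                  joint_limit_torque, kinematics,
                                  linear_momentum, mechanical_energy)

TAU0 = np.zeros(6)
F0 = np.zeros((4, 2))


def _airborne_state(config, rng=None):
    q, _ = config.initial_q_qd()
    q = q.copy()
    q[1] = 3.0                      # well above ground
    qd = np.zeros(9)
    if rng is not None:
        qd[2:] = rng.uniform(-0.8, 0.8, 7)
    return q, qd


def _integrate_passive(config, q, qd, t_total, g, dt=1e-4):
    seg = config.seg_array()
    y = np.concatenate([q, qd])

    def rhs(y):
        qdd = _kernels.forward_dynamics_qdd(y[:9], y[9:], TAU0, F0, seg, g)
        return np.concatenate([y[9:], qdd])

    for _ in range(int(round(t_total / dt))):
        k1 = rhs(y)
        k2 = rhs(y + dt / 2 * k1)
        k3 = rhs(y + dt / 2 * k2)
        k4 = rhs(y + dt * k3)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    return GeneralizedState(y[:9], y[9:])


def test_equilibrium_without_loads_gives_zero_acceleration(config):
    q, _ = config.initial_q_qd()
    st = GeneralizedState(q, np.zeros(9))
    qdd = forward_dynamics(st, TAU0, None, config, gravity=0.0)
    assert np.allclose(qdd, 0.0, atol=1e-12)


def test_point_mass_free_fall(config):
    """With leg masses shrunk to ~0, the trunk falls at -g."""
    small = {"segments": {
        "thigh": {"mass": 1e-6, "length": 0.5, "com_offset": 0.3,
                  "inertia": 1e-8},
        "shank": {"mass": 1e-6, "length": 0.5, "com_offset": 0.3,
                  "inertia": 1e-8},
        "foot": {"mass": 1e-6, "inertia": 1e-8, "heel": [-0.07, -0.08],
                 "ball": [0.13, -0.08], "com": [0.04, -0.04]}}}
    cfg = load_config(overrides=small)
    q, _ = cfg.initial_q_qd()
    q[1] = 3.0
    st = GeneralizedState(q, np.zeros(9))
    qdd = forward_dynamics(st, TAU0, None, cfg)
    assert qdd[1] == pytest.approx(-9.81, rel=1e-4)


def test_passive_energy_conservation(config, rng):
    """Free airborne chain under gravity: energy drift < 0.1 % over 5 s."""
    q, qd = _airborne_state(config, rng)
    E0 = mechanical_energy(GeneralizedState(q, qd), config)
    st = _integrate_passive(config, q, qd, 5.0, config.gravity)
    E1 = mechanical_energy(st, config)
    assert abs(E1 - E0) / abs(E0) < 1e-3


def test_momentum_conserved_without_gravity(config, rng):
    q, qd = _airborne_state(config, rng)
    p0 = linear_momentum(GeneralizedState(q, qd), config)
    st = _integrate_passive(config, q, qd, 2.0, 0.0)
    p1 = linear_momentum(st, config)
    assert np.allclose(p1, p0, atol=1e-9)


def test_mirror_symmetry(config, rng):
    q, qd = _airborne_state(config, rng)
    qm, qdm = q.copy(), qd.copy()
    qm[3:6], qm[6:9] = q[6:9].copy(), q[3:6].copy()
    qdm[3:6], qdm[6:9] = qd[6:9].copy(), qd[3:6].copy()
    a = forward_dynamics(GeneralizedState(q, qd), TAU0, None, config)
    am = forward_dynamics(GeneralizedState(qm, qdm), TAU0, None, config)
    assert np.allclose(a[:3], am[:3], atol=1e-12)
    assert np.allclose(a[3:6], am[6:9], atol=1e-12)
    assert np.allclose(a[6:9], am[3:6], atol=1e-12)


def test_neutral_pose_stacks_leg_vertically(config):
    """Hip/knee straight (180 deg), ankle neutral: knee and ankle sit
    directly below the hip."""
    q = np.array([0.0, 1.2, 0.0, np.pi, np.pi, np.pi / 2,
                  np.pi, np.pi, np.pi / 2])
    kin = kinematics(GeneralizedState(q, np.zeros(9)), config)
    for leg in range(2):
        assert kin.knee[leg, 0] == pytest.approx(0.0, abs=1e-12)
        assert kin.ankle[leg, 0] == pytest.approx(0.0, abs=1e-12)
        assert kin.knee[leg, 1] == pytest.approx(1.2 - 0.5)
        assert kin.ankle[leg, 1] == pytest.approx(1.2 - 1.0)


def test_kinematics_translation_invariance(config, rng):
    q, qd = _airborne_state(config, rng)
    k0 = kinematics(GeneralizedState(q, qd), config)
    q2 = q.copy()
    q2[0] += 1.7
    q2[1] += 0.4
    k1 = kinematics(GeneralizedState(q2, qd), config)
    assert np.allclose(k1.com - k0.com, [1.7, 0.4])
    assert np.allclose(k1.knee - k0.knee, [1.7, 0.4])


def test_velocities_match_finite_differences(config, rng):
    """Kinematic velocities are the exact time derivatives of positions."""
    q, qd = _airborne_state(config, rng)
    qd[:2] = (0.9, -0.3)
    eps = 1e-6
    k0 = kinematics(GeneralizedState(q, qd), config)
    kp = kinematics(GeneralizedState(q + eps * qd, qd), config)
    km = kinematics(GeneralizedState(q - eps * qd, qd), config)
    for attr in ("com", "heel", "ball", "knee"):
        fd = (getattr(kp, attr) - getattr(km, attr)) / (2 * eps)
        vel = getattr(k0, f"{attr}_vel" if attr != "com" else "com_vel")
        assert np.max(np.abs(fd - vel)) < 1e-6


def test_joint_limit_torque_piecewise(config):
    row = config.joint_limits.table[1]          # knee
    lo, hi, k, _ = row
    mid = 0.5 * (lo + hi)
    assert joint_limit_torque("knee", mid, 3.0, config) == 0.0
    assert joint_limit_torque("knee", hi, 0.0, config) == 0.0
    past = hi + 0.1
    assert joint_limit_torque("knee", past, 0.0, config) \
        == pytest.approx(-k * 0.1)
    # damping never turns the stop attractive
    assert joint_limit_torque("knee", past, -50.0, config) <= 0.0
    assert joint_limit_torque("knee", lo - 0.1, 50.0, config) >= 0.0


def test_nonfinite_state_rejected(config):
    q, qd = config.initial_q_qd()
    with pytest.raises(ValueError):
        GeneralizedState(q * np.nan, qd)
    st = GeneralizedState(q, qd)
    with pytest.raises(ValueError):
        forward_dynamics(st, np.full(6, np.nan), None, config)
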