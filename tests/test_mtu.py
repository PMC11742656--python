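"""Hill-muscle oracles: activation closed forms, geometry consistency,
force normalization, curve properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reflexwalk.mtu import (MTUState, activation_rate, equilibrium_l_ce,
                            force_length, force_velocity, mtu_force,
                            mtu_length_and_moment_arms)
from reflexwalk.params import MUSCLES


def test_activation_fixed_point():
    assert activation_rate(0.3, 0.3, 0.01) == 0.0


def test_activation_step_response_closed_form(config):
    """a(0)=0, S=1: a(t) = 1 - exp(-t/tau); checked at t = tau."""
    tau = config.activation.tau
    a, dt = 0.0, tau / 2000
    for _ in range(2000):
        k1 = activation_rate(a, 1.0, tau)
        k2 = activation_rate(a + dt / 2 * k1, 1.0, tau)
        k3 = activation_rate(a + dt / 2 * k2, 1.0, tau)
        k4 = activation_rate(a + dt * k3, 1.0, tau)
        a += dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    assert a == pytest.approx(1 - math.exp(-1), abs=1e-10)


def test_deactivation_decay_matches_dense_reference(config):
    """a(0)=1, S=0 (the deactivation experiment): a(t) = exp(-t/tau)."""
    tau = config.activation.tau
    # dense-step RK4 reference integration
    a_ref, dt_ref = 1.0, tau / 2000
    for _ in range(2000):
        k1 = activation_rate(a_ref, 0.0, tau)
        k2 = activation_rate(a_ref + dt_ref / 2 * k1, 0.0, tau)
        k3 = activation_rate(a_ref + dt_ref / 2 * k2, 0.0, tau)
        k4 = activation_rate(a_ref + dt_ref * k3, 0.0, tau)
        a_ref += dt_ref / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    assert a_ref == pytest.approx(math.exp(-1.0), abs=1e-8)


def test_tau_must_be_positive():
    with pytest.raises(ValueError):
        activation_rate(0.5, 0.5, 0.0)


def test_reference_configuration_length(config):
    """At the reference joint angles the MTU sits at l_opt + l_slack."""
    for name, m in zip(MUSCLES, config.muscles):
        angles = {}
        for att in m.attachments:
            angles[att.joint] = att.phi_ref
        l, _ = mtu_length_and_moment_arms(config, name, angles)
        assert l == pytest.approx(m.l_opt + m.l_slack, abs=1e-12)


def test_gas_biarticular_signs(config):
    """GAS spans knee and ankle: lengthens with knee extension and with
    ankle dorsiflexion."""
    base = {"knee": math.radians(120), "ankle": math.radians(95)}
    l0, arms = mtu_length_and_moment_arms(config, "GAS", base)
    assert set(arms) == {"knee", "ankle"}
    l_ext, _ = mtu_length_and_moment_arms(
        config, "GAS", {**base, "knee": math.radians(140)})
    l_dorsi, _ = mtu_length_and_moment_arms(
        config, "GAS", {**base, "ankle": math.radians(85)})
    assert l_ext > l0
    assert l_dorsi > l0


def test_biarticular_flags(config):
    names = {m.name for m in config.muscles if m.biarticular}
    assert names == {"GAS", "HAM"}


def test_moment_arm_equals_length_gradient(config, rng):
    """Signed moment arm == d(l_mtu)/d(phi), finite-difference oracle."""
    for name in MUSCLES:
        for _ in range(10):
            angles = {"hip": rng.uniform(2.2, 3.6),
                      "knee": rng.uniform(1.5, 3.0),
                      "ankle": rng.uniform(1.2, 2.2)}
            _, arms = mtu_length_and_moment_arms(config, name, angles)
            for joint, arm in arms.items():
                eps = 1e-6
                up = dict(angles)
                up[joint] += eps
                dn = dict(angles)
                dn[joint] -= eps
                fd = (mtu_length_and_moment_arms(config, name, up)[0]
                      - mtu_length_and_moment_arms(config, name, dn)[0]) \
                    / (2 * eps)
                assert abs(fd - arm) <= 1e-4 * max(abs(arm), 1e-6)


def test_isometric_maximal_force(config):
    """a=1, l_ce=l_opt, v_ce=0 gives CE force F_max (f_l = f_v = 1)."""
    m = config.muscles[0]
    l_se = m.l_slack * (1 + config.hill.see_eps_ref)
    F, v = mtu_force(config, "SOL", MTUState(1.0, m.l_opt), m.l_opt + l_se)
    assert F == pytest.approx(m.F_max, rel=1e-9)
    assert abs(v) < 1e-6


def test_slack_tendon_no_force(config):
    m = config.muscles[0]
    F, _ = mtu_force(config, "SOL", MTUState(0.0, m.l_opt),
                     m.l_opt + 0.98 * m.l_slack)
    assert F == 0.0


def test_force_length_unimodal_peak_at_lopt(config):
    m = config.muscles[0]
    ls = np.linspace(0.4, 1.6, 121) * m.l_opt
    fl = np.array([force_length(config, "SOL", l) for l in ls])
    assert fl.max() == pytest.approx(1.0)
    assert ls[fl.argmax()] == pytest.approx(m.l_opt)
    peak = fl.argmax()
    assert np.all(np.diff(fl[:peak + 1]) > 0)
    assert np.all(np.diff(fl[peak:]) < 0)


def test_force_velocity_properties(config):
    m = config.muscles[0]
    vmax = m.v_max * m.l_opt
    assert force_velocity(config, "SOL", 0.0) == 1.0
    vs = np.linspace(-0.99 * vmax, 2 * vmax, 200)
    fv = np.array([force_velocity(config, "SOL", v) for v in vs])
    assert np.all(np.diff(fv) >= -1e-12)       # decreasing in shortening
    assert fv.max() <= config.hill.fv_N
    assert force_velocity(config, "SOL", -vmax) == 0.0


@settings(max_examples=30, deadline=None, derandomize=True)
@given(S=st.floats(0.0, 1.0), a0=st.floats(0.0, 1.0))
def test_activation_stays_in_unit_interval(S, a0):
    """Bounded stimulation keeps activation trajectories in [0, 1]."""
    tau, dt = 0.01, 1e-4
    a = a0
    for _ in range(500):
        a += dt * activation_rate(a, S, tau)
        assert -1e-12 <= a <= 1 + 1e-12


def test_force_fades_after_stimulation_removal(config):
    """With S forced to zero, force decays below 1 % F_max within a few
    tau once the MTU is inside its nominal range."""
    m = config.muscles[0]
    l_mtu = m.l_opt + m.l_slack
    a = 0.8
    l_ce = equilibrium_l_ce(config, "SOL", a, l_mtu)
    tau, dt = config.activation.tau, 1e-4
    t, F = 0.0, None
    for _ in range(int(10 * tau / dt)):
        F, v = mtu_force(config, "SOL", MTUState(max(a, 0.0), l_ce), l_mtu)
        a += dt * activation_rate(a, 0.0, tau)
        l_ce += dt * v
        t += dt
    assert F < 0.01 * m.F_max
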