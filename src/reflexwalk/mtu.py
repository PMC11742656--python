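"""Hill-type muscle-tendon units.

Each MTU is a contractile element (CE) in series with a nonlinear elastic
tendon (SEE), plus a parallel elasticity above the CE's nominal range and a
buffer elasticity below it (both numerical-stability aids that vanish in
the working range). Activation follows first-order excitation-contraction
coupling, ``tau da/dt = S - a``.

The CE velocity is obtained by inverting the force-velocity relation for
the factor required to balance the tendon force, the classic
algebraic-loop closure for this muscle family.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq

from reflexwalk import _kernels
from reflexwalk.params import (JOINTS, MTUParams, ModelConfig, MUSCLES,
                               N_MUSCLES_PER_LEG)


class MTUState:
    """Activation and CE length of one muscle."""

    __slots__ = ("a", "l_ce")

    def __init__(self, a: float, l_ce: float):
        if not 0.0 <= a <= 1.0:
            raise ValueError("activation outside [0, 1]")
        if l_ce <= 0.0:
            raise ValueError("l_ce must be positive")
        self.a = float(a)
        self.l_ce = float(l_ce)


def activation_rate(a: float, S: float, tau: float) -> float:
    """da/dt of the excitation-contraction coupling (fixed point a = S)."""
    if tau <= 0.0:
        raise ValueError("tau must be positive")
    return (S - a) / tau


def _musrow(config: ModelConfig, muscle: str) -> np.ndarray:
    return config.mus_array()[MUSCLES.index(muscle.upper())]


def mtu_length_and_moment_arms(config: ModelConfig, muscle: str,
                               joint_angles: dict) -> tuple[float, dict]:
    """MTU path length and signed moment arm per spanned joint.

    ``joint_angles`` maps joint name -> inner angle (rad). The returned
    moment arms equal d(l_mtu)/d(phi) exactly.
    """
    row = _musrow(config, muscle)
    phi = [joint_angles.get(j, math.nan) for j in JOINTS]
    spanned = {JOINTS[int(row[7 + 4 * k])] for k in range(int(row[6]))}
    for j in spanned:
        if math.isnan(joint_angles.get(j, math.nan)):
            raise ValueError(f"{muscle}: missing angle for spanned joint {j}")
    l, ah, ak, aa = _kernels.mtu_geometry(phi[0], phi[1], phi[2], row)
    arms = {}
    for j, a in zip(JOINTS, (ah, ak, aa)):
        if j in spanned:
            arms[j] = a
    return l, arms


def force_length(config: ModelConfig, muscle: str, l_ce: float) -> float:
    row = _musrow(config, muscle)
    h = config.hill_array()
    return _kernels.force_length(l_ce, row[1], h[0], h[1])


def force_velocity(config: ModelConfig, muscle: str, v_ce: float) -> float:
    """Force-velocity factor; v_ce in m/s, positive = lengthening."""
    row = _musrow(config, muscle)
    h = config.hill_array()
    return _kernels.force_velocity(v_ce, row[1], row[3], h[3], h[2])


def mtu_force(config: ModelConfig, muscle: str, state: MTUState,
              l_mtu: float) -> tuple[float, float]:
    """MTU force and CE velocity from the CE-SEE force balance.

    Returns ``(F_mtu, dl_ce/dt)``; F_mtu is the tendon (SEE) force and is
    never negative.
    """
    if l_mtu <= 0.0:
        raise ValueError("l_mtu must be positive")
    row = _musrow(config, muscle)
    F, v = _kernels.mtu_force_rate(state.a, state.l_ce, l_mtu, row,
                                   config.hill_array())
    if not (math.isfinite(F) and math.isfinite(v)):
        raise RuntimeError(
            f"{muscle}: force balance failed at a={state.a}, "
            f"l_ce={state.l_ce}, l_mtu={l_mtu}")
    return F, v


def equilibrium_l_ce(config: ModelConfig, muscle: str, a: float,
                     l_mtu: float) -> float:
    """CE length at static equilibrium (v_ce = 0) for a given activation.

    Solves ``F_see(l_mtu - l_ce) = a F_max f_l(l_ce) + F_pe - F_be`` by
    bracketing; used to initialize muscle states consistently.
    """
    row = _musrow(config, muscle)
    h = config.hill_array()
    F_max, l_opt, l_slack = row[0], row[1], row[2]

    def resid(l_ce):
        F_se = _kernels.see_force(l_mtu - l_ce, l_slack, h[4], F_max)
        F_ce = a * F_max * _kernels.force_length(l_ce, l_opt, h[0], h[1])
        F_pe = _kernels.pe_force(l_ce, l_opt, h[5], F_max)
        F_be = _kernels.be_force(l_ce, l_opt, h[6], h[7], F_max)
        return F_se - F_ce - F_pe + F_be

    lo, hi = 0.2 * l_opt, 2.0 * l_opt
    flo, fhi = resid(lo), resid(hi)
    if flo * fhi > 0:
        # slack tendon over the whole bracket: CE sits wherever the passive
        # elements balance; fall back to the slack-consistent length
        return min(max(l_mtu - l_slack, 0.5 * l_opt), 1.5 * l_opt)
    return float(brentq(resid, lo, hi, xtol=1e-12))


def initial_muscle_state(config: ModelConfig, q: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Consistent (a, l_ce) arrays for all 14 muscles at pose q."""
    a = np.empty(2 * N_MUSCLES_PER_LEG)
    l_ce = np.empty(2 * N_MUSCLES_PER_LEG)
    mus = config.mus_array()
    a_init = config.initial_state.get("activation", {})
    a_leg = (config.initial_state.get("activation_left", {}),
             config.initial_state.get("activation_right", {}))
    for leg in range(2):
        b = 3 + 3 * leg
        angles = {"hip": q[b], "knee": q[b + 1], "ankle": q[b + 2]}
        for m, name in enumerate(MUSCLES):
            i = 7 * leg + m
            a[i] = a_leg[leg].get(name, a_init.get(name, mus[m, 4]))
            l_mtu, _ = mtu_length_and_moment_arms(config, name, angles)
            l_ce[i] = equilibrium_l_ce(config, name, a[i], l_mtu)
    return a, l_ce
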