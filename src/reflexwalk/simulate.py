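"""Closed-loop simulation driver.

Integrates multibody dynamics + ground contact + Hill MTUs + reflex
control (+ optional stride-clocked deactivation) with a fixed-step RK4
scheme and a 1 kHz controller/neural update, for 20 s or until the walker
falls. The loop is a DDE (reflex transport delays), handled with
control-rate ring-buffer delay lines. The integrator is deterministic:
identical inputs give bitwise-identical trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from reflexwalk import _kernels
from reflexwalk.deactivation import DeactivationSpec, T_STRIDE_SEED
from reflexwalk.mtu import initial_muscle_state
from reflexwalk.params import MUSCLES, ModelConfig, load_config
from reflexwalk.trial import GaitTrial

_TERMINATION = {0: "completed", 1: "fell", 2: "solver_failure"}


@dataclass
class SimConfig:
    """Simulation settings.

    t_sim_des: desired horizon [s]; dt: inner RK4 step [s]; the controller
    and output sampling run every ``substeps`` inner steps (default 1 kHz).
    """

    t_sim_des: float = 20.0
    dt: float = 1e-4
    substeps: int = 10
    t_stride_seed: float = T_STRIDE_SEED

    def __post_init__(self):
        if self.t_sim_des <= 0 or self.dt <= 0 or self.substeps < 1:
            raise ValueError("t_sim_des, dt and substeps must be positive")

    @property
    def dt_out(self) -> float:
        return self.dt * self.substeps


def run_trial(config: ModelConfig | None = None,
              sim: SimConfig | None = None,
              deactivation: DeactivationSpec | None = None) -> GaitTrial:
    """Run one closed-loop walking trial.

    Early termination (fall or integrator blow-up) is recorded in the
    trial's ``termination``/``t_end`` fields, never raised.
    """
    config = config if config is not None else load_config()
    sim = sim if sim is not None else SimConfig()

    q0, qd0 = config.initial_q_qd()
    a0, lce0 = initial_muscle_state(config, q0)
    y0 = np.concatenate([q0, qd0, a0, lce0])

    n_ctrl = int(round(sim.t_sim_des / sim.dt_out))
    n = n_ctrl
    out = {
        "q": np.zeros((n, 9)), "qd": np.zeros((n, 9)),
        "tau": np.zeros((n, 6)), "S": np.zeros((n, 14)),
        "a": np.zeros((n, 14)), "lce": np.zeros((n, 14)),
        "F": np.zeros((n, 14)), "grf": np.zeros((n, 2, 2)),
        "cop": np.zeros((n, 2)), "flags": np.zeros((n, 4), dtype=np.bool_),
        "alpha": np.zeros((n, 2)), "mask": np.zeros((n, 2), dtype=np.bool_),
        "imp": np.zeros((n, 2, 2)),
    }

    if deactivation is None:
        dm, gc, toff, start = -1, 0.0, 0.0, 6
    else:
        dm = MUSCLES.index(deactivation.muscle)
        gc = deactivation.gc_off / 100.0
        toff = deactivation.t_off
        start = deactivation.start_stride

    n_done, cause, t_stride6, td_l, td_r = _kernels.simulate_loop(
        y0, config.seg_array(), config.mus_array(), config.hill_array(),
        config.jlim_array(), config.contact.as_array(),
        config.reflexes.as_array(), config.gravity, config.activation.tau,
        sim.dt, sim.substeps, n_ctrl,
        dm, gc, toff, start, sim.t_stride_seed,
        config.failure["min_height_frac"], config.failure["max_lean"],
        config.standing_hip_height(),
        out["q"], out["qd"], out["tau"], out["S"], out["a"], out["lce"],
        out["F"], out["grf"], out["cop"], out["flags"], out["alpha"],
        out["mask"], out["imp"])

    k = n_done
    t = np.arange(k) * sim.dt_out
    q = out["q"][:k]
    qd = out["qd"][:k]

    # post-hoc kinematics channels (COMs, foot points) for the metrics layer
    com = np.zeros((k, 7, 2))
    com_vel = np.zeros((k, 7, 2))
    heel = np.zeros((k, 2, 2))
    ball = np.zeros((k, 2, 2))
    heel_vel = np.zeros((k, 2, 2))
    ball_vel = np.zeros((k, 2, 2))
    knee_pos = np.zeros((k, 2, 2))
    seg = config.seg_array()
    for i in range(k):
        pts, ptv, coms, comv = _kernels.kin_points(q[i], qd[i], seg)
        com[i] = coms
        com_vel[i] = comv
        for leg in range(2):
            o = 4 * leg
            knee_pos[i, leg] = pts[o]
            heel[i, leg] = pts[o + 2]
            ball[i, leg] = pts[o + 3]
            heel_vel[i, leg] = ptv[o + 2]
            ball_vel[i, leg] = ptv[o + 3]

    meta = {
        "sim": {"t_sim_des": sim.t_sim_des, "dt": sim.dt,
                "substeps": sim.substeps,
                "t_stride_seed": sim.t_stride_seed},
        "deactivation": (None if deactivation is None else {
            "muscle": deactivation.muscle, "gc_off": deactivation.gc_off,
            "t_off": deactivation.t_off,
            "start_stride": deactivation.start_stride}),
        "touchdowns": {"left": int(td_l), "right": int(td_r)},
        "total_mass": config.total_mass(),
        "standing_hip_height": config.standing_hip_height(),
        "masses": {name: config.segments[name].mass
                   for name in ("HAT", "thigh", "shank", "foot")},
        "muscle_params": {
            "F_max": [config.muscles[m % 7].F_max for m in range(14)],
            "l_opt": [config.muscles[m % 7].l_opt for m in range(14)],
        },
    }

    return GaitTrial(
        t=t, q=q, qd=qd, tau=out["tau"][:k], S=out["S"][:k],
        a=out["a"][:k], l_ce=out["lce"][:k], F_mtu=out["F"][:k],
        grf=out["grf"][:k], cop_x=out["cop"][:k],
        contact_flags=out["flags"][:k], load_share=out["alpha"][:k],
        grf_impulse=out["imp"][:k],
        deact_mask=out["mask"][:k], com=com, com_vel=com_vel,
        heel=heel, ball=ball, heel_vel=heel_vel, ball_vel=ball_vel,
        knee_pos=knee_pos,
        t_end=float(k * sim.dt_out), termination=_TERMINATION[cause],
        t_stride6=(float(t_stride6) if t_stride6 >= 0 else math.nan),
        meta=meta)
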