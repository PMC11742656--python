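"""Planar rigid-body dynamics of the 7-segment walker.

The walker is a kinematic tree rooted at the hip point: a head-arm-trunk
(HAT) segment and two three-segment legs (thigh, shank, rigid heel/ball
foot) connected by revolute hips, knees and ankles. Generalized
coordinates are the hip-point position, the trunk forward-lean angle and
the six inner joint angles (see :mod:`reflexwalk.params` for conventions).

The equations of motion are assembled from per-body COM Jacobians
(``M = sum J^T M_b J``), which is exact for a rigid tree; correctness is
pinned by energy- and momentum-conservation tests rather than by the
assembly method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from reflexwalk import _kernels
from reflexwalk.params import ModelConfig, NQ


@dataclass
class GeneralizedState:
    """Configuration and velocity of the 9-DOF walker at time t."""

    q: np.ndarray
    qd: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.qd = np.asarray(self.qd, dtype=float)
        if self.q.shape != (NQ,) or self.qd.shape != (NQ,):
            raise ValueError(f"q and qd must have shape ({NQ},)")
        if not (np.all(np.isfinite(self.q)) and np.all(np.isfinite(self.qd))):
            raise ValueError("non-finite state")


@dataclass
class Kinematics:
    """World positions/velocities of joints, COMs and foot contact points."""

    hip: np.ndarray
    hip_vel: np.ndarray
    knee: np.ndarray          # (2,2) rows L, R
    ankle: np.ndarray
    heel: np.ndarray
    ball: np.ndarray
    knee_vel: np.ndarray
    ankle_vel: np.ndarray
    heel_vel: np.ndarray
    ball_vel: np.ndarray
    com: np.ndarray           # (7,2): HAT, thighL, shankL, footL, thighR, ...
    com_vel: np.ndarray
    segment_order: tuple = ("HAT", "thigh_L", "shank_L", "foot_L",
                            "thigh_R", "shank_R", "foot_R")


def kinematics(state: GeneralizedState, config: ModelConfig) -> Kinematics:
    """Forward kinematics of every joint center, COM and foot point."""
    pts, ptv, coms, comv = _kernels.kin_points(state.q, state.qd,
                                               config.seg_array())
    sel = lambda i: np.vstack([pts[i], pts[i + 4]])
    selv = lambda i: np.vstack([ptv[i], ptv[i + 4]])
    return Kinematics(
        hip=state.q[:2].copy(), hip_vel=state.qd[:2].copy(),
        knee=sel(0), ankle=sel(1), heel=sel(2), ball=sel(3),
        knee_vel=selv(0), ankle_vel=selv(1), heel_vel=selv(2),
        ball_vel=selv(3), com=coms, com_vel=comv)


def forward_dynamics(state: GeneralizedState, joint_torques: np.ndarray,
                     external_forces: np.ndarray | None,
                     config: ModelConfig, gravity: float | None = None
                     ) -> np.ndarray:
    """Generalized accelerations under joint torques and contact forces.

    joint_torques: 6-vector (hip, knee, ankle) x (left, right), positive
    driving the inner angle up (extension / extension / plantarflexion).
    external_forces: (4, 2) world forces at heelL, ballL, heelR, ballR
    (or None).
    """
    tau = np.asarray(joint_torques, dtype=float)
    if tau.shape != (6,) or not np.all(np.isfinite(tau)):
        raise ValueError("joint_torques must be a finite 6-vector")
    if external_forces is None:
        f_ext = np.zeros((4, 2))
    else:
        f_ext = np.asarray(external_forces, dtype=float)
        if f_ext.shape != (4, 2) or not np.all(np.isfinite(f_ext)):
            raise ValueError("external_forces must be finite with shape (4,2)")
    g = config.gravity if gravity is None else gravity
    return _kernels.forward_dynamics_qdd(state.q, state.qd, tau, f_ext,
                                         config.seg_array(), g)


def joint_limit_torque(joint: str, angle: float, velocity: float,
                       config: ModelConfig) -> float:
    """Soft-stop torque of one joint (zero inside the anatomical range)."""
    from reflexwalk.params import JOINTS
    row = config.joint_limits.table[JOINTS.index(joint)]
    return _kernels.joint_limit_torque(angle, velocity, row[0], row[1],
                                       row[2], row[3])


def mechanical_energy(state: GeneralizedState, config: ModelConfig,
                      gravity: float | None = None) -> float:
    """Total kinetic + gravitational potential energy of all segments."""
    g = config.gravity if gravity is None else gravity
    seg = config.seg_array()
    _, _, coms, comv = _kernels.kin_points(state.q, state.qd, seg)
    masses = np.array([seg[1], seg[5], seg[9], seg[11],
                       seg[5], seg[9], seg[11]])
    inertias = np.array([seg[2], seg[6], seg[10], seg[12],
                         seg[6], seg[10], seg[12]])
    omegas = np.empty(7)
    omegas[0] = -state.qd[2]
    for leg in range(2):
        ad_t, ad_s, gd_f = _kernels.leg_abs_rates(state.qd, leg)
        omegas[1 + 3 * leg:4 + 3 * leg] = (ad_t, ad_s, gd_f)
    ke = 0.5 * np.sum(masses * np.sum(comv ** 2, axis=1)) \
        + 0.5 * np.sum(inertias * omegas ** 2)
    pe = g * np.sum(masses * coms[:, 1])
    return float(ke + pe)


def linear_momentum(state: GeneralizedState, config: ModelConfig
                    ) -> np.ndarray:
    """Total linear momentum of all seven segments."""
    seg = config.seg_array()
    _, _, _, comv = _kernels.kin_points(state.q, state.qd, seg)
    masses = np.array([seg[1], seg[5], seg[9], seg[11],
                       seg[5], seg[9], seg[11]])
    return masses @ comv
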