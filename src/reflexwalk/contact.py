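"""Nonlinear spring-damper point contact at the heel and ball of each foot.

Vertical force: one-sided spring with penetration-rate-dependent damping,
clamped at zero (the ground never pulls). Horizontal force: stiction via an
anchor spring-damper bounded by the stiction cone, with kinetic sliding
friction once the cone is exceeded; the anchor resets on lift-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from reflexwalk import _kernels
from reflexwalk.params import ContactParams, ModelConfig


@dataclass
class ContactOutput:
    """Per-point forces and flags plus per-leg and global aggregates."""

    point_force: np.ndarray    # (4,2): heelL, ballL, heelR, ballR
    flags: np.ndarray          # (4,) bool
    leg_grf: np.ndarray        # (2,2)
    leg_cop_x: np.ndarray      # (2,), nan when airborne
    total_grf: np.ndarray      # (2,)
    global_cop_x: float        # nan when airborne


def contact_force(point_pos, point_vel, params: ContactParams,
                  anchor_x: float | None = None, sliding: bool = False):
    """Force at one contact point; returns ((fx, fy), in_contact)."""
    px, py = point_pos
    vx, vy = point_vel
    ax = px if anchor_x is None else anchor_x
    fx, fy, flag = _kernels.contact_point_force(px, py, vx, vy, ax,
                                                sliding, params.as_array())
    return np.array([fx, fy]), bool(flag)


def evaluate_contacts(point_pos: np.ndarray, point_vel: np.ndarray,
                      params: ContactParams,
                      anchors: np.ndarray | None = None,
                      sliding: np.ndarray | None = None) -> ContactOutput:
    """Contact forces, flags and COPs for all four foot points."""
    forces = np.zeros((4, 2))
    flags = np.zeros(4, dtype=bool)
    if anchors is None:
        anchors = point_pos[:, 0]
    if sliding is None:
        sliding = np.zeros(4, dtype=bool)
    for p in range(4):
        f, flag = contact_force(point_pos[p], point_vel[p], params,
                                anchors[p], bool(sliding[p]))
        forces[p] = f
        flags[p] = flag
    leg_grf = np.vstack([forces[:2].sum(axis=0), forces[2:].sum(axis=0)])
    leg_cop = np.full(2, np.nan)
    for leg in range(2):
        fy = forces[2 * leg:2 * leg + 2, 1]
        if fy.sum() > 0:
            leg_cop[leg] = (point_pos[2 * leg:2 * leg + 2, 0] * fy).sum() \
                / fy.sum()
    total = forces.sum(axis=0)
    gcop = np.nan
    if forces[:, 1].sum() > 0:
        gcop = float((point_pos[:, 0] * forces[:, 1]).sum()
                     / forces[:, 1].sum())
    return ContactOutput(forces, flags, leg_grf, leg_cop, total, gcop)


def leg_loads(leg_grf: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-leg vertical loads and load shares (zeros in flight)."""
    fy = np.maximum(leg_grf[:, 1], 0.0)
    tot = fy.sum()
    shares = fy / tot if tot > 0 else np.zeros(2)
    return fy, shares
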