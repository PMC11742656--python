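"""Model parameters: segments, muscles, reflex gains, contact, joint limits.

Every physical constant of the walker lives in a YAML config (see
``data/default_model.yaml``); the dataclasses here validate it and pack it
into flat float64 arrays consumed by the numba kernels.

Conventions (frozen across the package):

* world frame: x forward, y up, CCW rotations positive
* generalized coordinates ``q = [x, y, lean, hipL, kneeL, ankleL, hipR,
  kneeR, ankleR]`` where (x, y) is the hip point shared by both legs and
  ``lean`` is the forward trunk-lean angle (rad, positive = leaning forward)
* joint angles are inner angles: hip and knee straight = pi, ankle
  neutral = pi/2; positive generalized joint torque drives the angle up
  (hip extension, knee extension, ankle plantarflexion)
* muscles per leg, in index order: SOL, TA, GAS, VAS, HAM, GLU, HFL;
  left-leg muscles occupy indices 0-6, right-leg 7-13
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

MUSCLES = ("SOL", "TA", "GAS", "VAS", "HAM", "GLU", "HFL")
N_MUSCLES_PER_LEG = len(MUSCLES)
N_MUSCLES = 2 * N_MUSCLES_PER_LEG
JOINTS = ("hip", "knee", "ankle")
NQ = 9

# indices into q
IQ_X, IQ_Y, IQ_LEAN = 0, 1, 2
IQ_HIP_L, IQ_KNEE_L, IQ_ANKLE_L = 3, 4, 5
IQ_HIP_R, IQ_KNEE_R, IQ_ANKLE_R = 6, 7, 8


def muscle_index(name: str, leg: str) -> int:
    """Flat muscle index for ``name`` on leg ``'L'`` or ``'R'``."""
    m = MUSCLES.index(name.upper())
    return m if leg.upper() == "L" else m + N_MUSCLES_PER_LEG


@dataclass
class SegmentParams:
    """Rigid-segment parameters; feet carry heel/ball/COM points in the
    foot frame (origin at the ankle, x toward the toes)."""

    name: str
    mass: float
    length: float
    com_offset: float
    inertia: float
    heel: tuple[float, float] | None = None
    ball: tuple[float, float] | None = None
    com_point: tuple[float, float] | None = None

    def __post_init__(self):
        if self.mass <= 0 or self.inertia <= 0:
            raise ValueError(f"{self.name}: mass and inertia must be positive")
        if not 0.0 <= self.com_offset <= self.length:
            raise ValueError(f"{self.name}: com_offset outside [0, length]")
        if self.heel is not None and self.ball is not None:
            if self.heel[0] >= self.ball[0]:
                raise ValueError(f"{self.name}: heel must lie posterior to ball")


@dataclass
class MTUAttachment:
    joint: str                  # 'hip' | 'knee' | 'ankle'
    r: float                    # signed lever arm scale, m (= d l_mtu / d phi)
    phi_ref: float              # rad; l_mtu = l_opt + l_slack at reference angles
    phi_max: float = math.nan   # rad; nan => constant lever arm


@dataclass
class MTUParams:
    name: str
    F_max: float
    l_opt: float
    l_slack: float
    v_max: float                # in l_opt / s
    attachments: list[MTUAttachment] = field(default_factory=list)

    def __post_init__(self):
        for v, lbl in ((self.F_max, "F_max"), (self.l_opt, "l_opt"),
                       (self.l_slack, "l_slack"), (self.v_max, "v_max")):
            if v <= 0:
                raise ValueError(f"{self.name}: {lbl} must be positive")
        if not 1 <= len(self.attachments) <= 2:
            raise ValueError(f"{self.name}: MTUs span one or two joints")

    @property
    def biarticular(self) -> bool:
        return len(self.attachments) == 2


@dataclass
class HillParams:
    fl_width: float = 0.56
    fl_c: float = math.log(0.05)
    fv_N: float = 1.5
    fv_K: float = 5.0
    see_eps_ref: float = 0.04
    pe_width: float = 0.56
    be_rel_length: float = 0.44
    be_width: float = 0.28


@dataclass
class ActivationParams:
    tau: float = 0.01
    S0: dict = field(default_factory=dict)      # per muscle name
    delay: dict = field(default_factory=dict)   # per muscle name, s

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        for name, s0 in self.S0.items():
            if not 0.0 <= s0 <= 1.0:
                raise ValueError(f"{name}: S0 outside [0, 1]")
        for name, dt in self.delay.items():
            if dt < 0:
                raise ValueError(f"{name}: delay must be >= 0")


@dataclass
class ReflexGains:
    """Feedback gains of the decentralized stance/swing reflex controller."""

    G_SOL: float
    G_TA: float
    l_off_TA: float
    G_SOLTA: float
    G_GAS: float
    G_VAS: float
    k_phi: float
    phi_knee_off: float         # rad
    G_VAS_DS: float
    theta_ref: float
    kp_trunk: float
    kd_trunk: float
    c_GLU: float
    c_HAM: float
    c_HFL: float
    k_DS_HFL: float
    k_DS_HAM: float
    G_HFL: float
    l_off_HFL: float
    G_HAMHFL: float
    l_off_HAMHFL: float
    k_lean: float
    G_GLU_sw: float
    G_HAM_sw: float

    def __post_init__(self):
        if not math.pi / 2 < self.phi_knee_off <= math.pi:
            raise ValueError("VAS inhibition threshold must lie in (90, 180] deg")

    def as_array(self) -> np.ndarray:
        return np.array([
            self.G_SOL, self.G_TA, self.l_off_TA, self.G_SOLTA, self.G_GAS,
            self.G_VAS, self.k_phi, self.phi_knee_off, self.G_VAS_DS,
            self.theta_ref, self.kp_trunk, self.kd_trunk, self.c_GLU,
            self.c_HAM, self.c_HFL, self.k_DS_HFL, self.k_DS_HAM, self.G_HFL,
            self.l_off_HFL, self.G_HAMHFL, self.l_off_HAMHFL, self.k_lean,
            self.G_GLU_sw, self.G_HAM_sw,
        ])


@dataclass
class ContactParams:
    k_vertical: float
    exponent: float
    v_damping: float
    mu_stiction: float
    mu_sliding: float
    k_horizontal: float
    d_horizontal: float
    v_slide_ref: float
    v_restick: float

    def __post_init__(self):
        if self.k_vertical <= 0 or self.k_horizontal <= 0:
            raise ValueError("contact stiffnesses must be positive")
        if self.mu_stiction < 0 or self.mu_sliding < 0:
            raise ValueError("friction coefficients must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([
            self.k_vertical, self.exponent, self.v_damping, self.mu_stiction,
            self.mu_sliding, self.k_horizontal, self.d_horizontal,
            self.v_slide_ref, self.v_restick,
        ])


@dataclass
class JointLimitParams:
    """One-sided spring-damper stops per joint: rows hip, knee, ankle with
    columns (lo, hi, stiffness, damping); angles rad, stiffness N m/rad."""

    table: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.table, dtype=float)
        if t.shape != (3, 4):
            raise ValueError("joint-limit table must be 3x4")
        if np.any(t[:, 2] < 0) or np.any(t[:, 3] < 0):
            raise ValueError("stop stiffness/damping must be >= 0")
        if np.any(t[:, 0] >= t[:, 1]):
            raise ValueError("lower engagement must be below upper engagement")
        self.table = t


@dataclass
class ModelConfig:
    """Aggregate of every physical parameter needed to simulate the walker."""

    gravity: float
    segments: dict
    muscles: list
    hill: HillParams
    activation: ActivationParams
    reflexes: ReflexGains
    contact: ContactParams
    joint_limits: JointLimitParams
    failure: dict
    initial_state: dict
    raw: dict = field(default_factory=dict, repr=False)

    # ---- packing for the kernels -------------------------------------
    def seg_array(self) -> np.ndarray:
        s = self.segments
        f = s["foot"]
        return np.array([
            s["HAT"].com_offset, s["HAT"].mass, s["HAT"].inertia,
            s["thigh"].length, s["thigh"].com_offset, s["thigh"].mass, s["thigh"].inertia,
            s["shank"].length, s["shank"].com_offset, s["shank"].mass, s["shank"].inertia,
            f.mass, f.inertia,
            f.heel[0], f.heel[1], f.ball[0], f.ball[1],
            f.com_point[0], f.com_point[1],
        ])

    def mus_array(self) -> np.ndarray:
        """(7, 15) per-leg muscle table:
        [F_max, l_opt, l_slack, v_max, S0, delay,
         n_att, j1, r1, phimax1, phiref1, j2, r2, phimax2, phiref2]"""
        out = np.zeros((N_MUSCLES_PER_LEG, 15))
        for i, m in enumerate(self.muscles):
            out[i, 0:4] = (m.F_max, m.l_opt, m.l_slack, m.v_max)
            out[i, 4] = self.activation.S0[m.name]
            out[i, 5] = self.activation.delay[m.name]
            out[i, 6] = len(m.attachments)
            for k, att in enumerate(m.attachments):
                base = 7 + 4 * k
                out[i, base] = JOINTS.index(att.joint)
                out[i, base + 1] = att.r
                out[i, base + 2] = att.phi_max
                out[i, base + 3] = att.phi_ref
        return out

    def hill_array(self) -> np.ndarray:
        h = self.hill
        return np.array([h.fl_width, h.fl_c, h.fv_N, h.fv_K, h.see_eps_ref,
                         h.pe_width, h.be_rel_length, h.be_width])

    def jlim_array(self) -> np.ndarray:
        return self.joint_limits.table.copy()

    def standing_hip_height(self) -> float:
        s = self.segments
        return s["thigh"].length + s["shank"].length - s["foot"].heel[1]

    def total_mass(self) -> float:
        s = self.segments
        return s["HAT"].mass + 2 * (s["thigh"].mass + s["shank"].mass
                                    + s["foot"].mass)

    def initial_q_qd(self) -> tuple[np.ndarray, np.ndarray]:
        ini = self.initial_state
        d = math.radians
        q = np.array([
            ini["hip_xy"][0], ini["hip_xy"][1], d(ini["lean_deg"]),
            d(ini["left"]["hip_deg"]), d(ini["left"]["knee_deg"]),
            d(ini["left"]["ankle_deg"]),
            d(ini["right"]["hip_deg"]), d(ini["right"]["knee_deg"]),
            d(ini["right"]["ankle_deg"]),
        ])
        qd = np.zeros(NQ)
        qd[IQ_X] = ini["forward_velocity"]
        qd[IQ_Y] = ini.get("vertical_velocity", 0.0)
        qd[IQ_LEAN] = d(ini.get("lean_rate_deg", 0.0))
        rates = ini.get("joint_rates_deg", {})
        for leg, key in ((0, "left"), (1, "right")):
            r = rates.get(key, {})
            for j, joint in enumerate(("hip", "knee", "ankle")):
                qd[3 + 3 * leg + j] = d(r.get(joint, 0.0))
        return q, qd


def _build_segments(raw: dict) -> dict:
    segs = {}
    for name in ("HAT", "thigh", "shank"):
        r = raw[name]
        segs[name] = SegmentParams(name, r["mass"], r["length"],
                                   r["com_offset"], r["inertia"])
    f = raw["foot"]
    length = f["ball"][0] - f["heel"][0]
    segs["foot"] = SegmentParams(
        "foot", f["mass"], length, com_offset=f["com"][0] - f["heel"][0],
        inertia=f["inertia"], heel=tuple(f["heel"]), ball=tuple(f["ball"]),
        com_point=tuple(f["com"]))
    return segs


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> ModelConfig:
    """Load a model config; ``overrides`` is a nested dict merged on top."""
    if path is None:
        src = resources.files("reflexwalk.data").joinpath("default_model.yaml")
        raw = yaml.safe_load(src.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    if overrides:
        raw = _merge(raw, overrides)

    muscles = []
    S0, delay = {}, {}
    for name in MUSCLES:
        m = raw["muscles"][name]
        atts = [
            MTUAttachment(
                joint=a["joint"], r=a["r"],
                phi_ref=math.radians(a["phi_ref_deg"]),
                phi_max=(math.nan if a.get("phi_max_deg") is None
                         else math.radians(a["phi_max_deg"])),
            ) for a in m["attachments"]
        ]
        muscles.append(MTUParams(name, m["F_max"], m["l_opt"], m["l_slack"],
                                 m["v_max"], atts))
        S0[name] = m["S0"]
        delay[name] = m["delay"]

    rf = dict(raw["reflexes"])
    rf["phi_knee_off"] = math.radians(rf.pop("phi_knee_off_deg"))
    gains = ReflexGains(**rf)

    jl = raw["joint_limits"]
    table = np.array([
        [math.radians(jl[j]["lo_deg"]), math.radians(jl[j]["hi_deg"]),
         jl[j]["stiffness"], jl[j]["damping"]] for j in JOINTS
    ])

    fail = dict(raw["failure"])
    fail["max_lean"] = math.radians(fail.pop("max_lean_deg"))

    return ModelConfig(
        gravity=raw["gravity"],
        segments=_build_segments(raw["segments"]),
        muscles=muscles,
        hill=HillParams(**raw["hill"]),
        activation=ActivationParams(tau=raw["activation"]["tau"],
                                    S0=S0, delay=delay),
        reflexes=gains,
        contact=ContactParams(**raw["contact"]),
        joint_limits=JointLimitParams(table),
        failure=fail,
        initial_state=raw["initial_state"],
        raw=raw,
    )


def _merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out
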