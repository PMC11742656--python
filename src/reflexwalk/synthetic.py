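"""Synthetic gait-trial generator with fully known ground truth.

Produces :class:`~reflexwalk.trial.GaitTrial`-shaped surrogates: splined
periodic kinematics, double-hump vertical GRFs, an ankle power curve with
one negative lobe followed by an impulsive positive burst starting exactly
at the alleviation onset, and contact flags consistent with the prescribed
duty factor and event phases. Default event phases follow human gait
anchors (knee buckling 64 % of stance, alleviation onset 78 % of stance,
contralateral touchdown 82 % of stance; push-off inside 50-62 % of the
gait cycle).

The surrogates are kinematic/kinetic fabrications, not dynamically
consistent trajectories; their purpose is to make the metrics layer
testable with exact expected values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from reflexwalk.metrics import METABOLIC_DEFAULTS
from reflexwalk.trial import GaitTrial

_STANCE_DEFAULT = 0.62                 # duty factor
# human event anchors, fraction of stance
_ALLEVIATION_OF_STANCE = 0.78
_TDC_OF_STANCE = 0.82


@dataclass
class SyntheticSpec:
    """Construction parameters of one synthetic trial (times in s, % gc
    phases as fractions of the gait cycle in [0, 1])."""

    t_stride: float = 1.25
    duty_factor: float = _STANCE_DEFAULT
    n_strides: int = 4
    dt: float = 1e-3
    # event phases as gait-cycle fractions; defaults from the human anchors
    ho_frac: float = 0.45
    ta_frac: float = _ALLEVIATION_OF_STANCE * _STANCE_DEFAULT    # 0.4836
    tdc_frac: float = _TDC_OF_STANCE * _STANCE_DEFAULT           # 0.5084
    ball_on_frac: float = 0.08
    # ankle power lobes [W]
    P_neg: float = 60.0
    P_pos: float = 180.0
    ankle_rate_amp: float = 4.0        # rad/s scale of the stance ankle rate
    dorsi_rate_amp: float = 0.5
    # GRF humps, as multiples of body weight, and their phases (of stance)
    hump1: float = 1.10
    hump2: float = 1.05
    hump1_at: float = 0.22
    hump2_at: float = 0.75
    hump_width: float = 0.55
    grf_fx_amp: float = 0.18
    # kinematics
    speed: float = 1.30
    swing_apex: float = 0.12
    hip_zc_frac: float = 0.52          # onset of hip flexion (% gc)
    knee_tau_zc_frac: float = 0.51     # knee-torque zero crossing (% gc)
    knee_buckle_frac: float = 0.64 * _STANCE_DEFAULT
    # masses [kg]
    masses: dict = field(default_factory=lambda: {
        "HAT": 53.5, "thigh": 8.5, "shank": 3.5, "foot": 1.25})
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (self.ho_frac < self.tdc_frac < self.duty_factor):
            raise ValueError("event order must satisfy HO < TDc < TO")
        if not (self.ho_frac < self.ta_frac < self.duty_factor):
            raise ValueError("alleviation onset must lie between HO and TO")
        if self.t_stride <= 0 or self.dt <= 0 or self.n_strides < 2:
            raise ValueError("t_stride, dt > 0 and n_strides >= 2 required")
        if not 0.5 < self.duty_factor < 1.0:
            raise ValueError("walking requires duty factor in (0.5, 1)")


@dataclass
class GroundTruth:
    """Exact expected values implied by the construction, for the stride
    the metrics layer analyzes (the last complete one)."""

    leg: int
    td: float
    td_next: float
    ho: float
    tdc: float
    to: float
    t_a: float
    t_stride: float
    score: float
    v_x: float
    P_metab: float
    l_step: float
    P_amp: float
    P_max_pos: float
    P_min_neg: float
    y_f_max: float
    dp_x: float
    dp_y: float
    dalpha_p: float
    duty_factor: float

    def as_dict(self) -> dict:
        return asdict(self)


def _phase(t, t_stride, offset):
    # the small guard keeps samples that fall exactly on a stride boundary
    # on the contact side despite floating-point mod jitter
    return ((t / t_stride) - offset + 1e-12) % 1.0


def _snap_times(spec: SyntheticSpec) -> tuple[float, float, float]:
    """Snap stride time (to an even sample multiple, so half-stride leg
    offsets stay on the grid), the TDc offset and the alleviation onset to
    the sample grid; event-dependent scalars then recover exactly."""
    T = round(spec.t_stride / (2 * spec.dt)) * 2 * spec.dt
    delta = round((spec.tdc_frac - 0.5) * T / spec.dt) * spec.dt / T
    ta_frac = round(spec.ta_frac * T / spec.dt) * spec.dt / T
    return T, delta, ta_frac


def make_trial(spec: SyntheticSpec) -> tuple[GaitTrial, GroundTruth]:
    """Build one synthetic trial plus its ground-truth record."""
    T, _, _ = _snap_times(spec)
    D = (spec.n_strides + 0.55) * T
    t = np.arange(0.0, D, spec.dt)
    n = len(t)
    rng = np.random.default_rng(spec.seed)
    bw = sum(spec.masses[k] * (1 if k == "HAT" else 2)
             for k in spec.masses) * 9.81
    total_mass = bw / 9.81

    q = np.zeros((n, 9))
    qd = np.zeros((n, 9))
    tau = np.zeros((n, 6))
    grf = np.zeros((n, 2, 2))
    cop = np.full((n, 2), np.nan)
    flags = np.zeros((n, 4), dtype=bool)
    heel = np.zeros((n, 2, 2))
    ball = np.zeros((n, 2, 2))
    heel_v = np.zeros((n, 2, 2))
    ball_v = np.zeros((n, 2, 2))
    knee_pos = np.zeros((n, 2, 2))
    com = np.zeros((n, 7, 2))
    com_vel = np.zeros((n, 7, 2))
    S = np.zeros((n, 14))
    a = np.zeros((n, 14))
    l_ce = np.full((n, 14), 0.05)
    F = np.zeros((n, 14))

    q[:, 0] = spec.speed * t
    q[:, 1] = 0.95 + 0.01 * np.cos(4 * math.pi * t / T)
    q[:, 2] = 0.105 + 0.01 * np.sin(2 * math.pi * t / T)
    qd[:, 2] = 0.01 * 2 * math.pi / T * np.cos(2 * math.pi * t / T)

    df = spec.duty_factor
    stride_len = spec.speed * T
    # the contralateral-touchdown phase is set by the other leg's offset:
    # shifting the left leg by (tdc_frac - 0.5) places the left TD at the
    # prescribed fraction of each right-leg stride
    _, delta, ta_frac = _snap_times(spec)

    for leg, off in ((0, delta), (1, 0.5)):
        ph = _phase(t, T, off)
        stance = ph < df
        heel_c = ph < spec.ho_frac
        ball_c = (ph >= spec.ball_on_frac) & stance
        flags[:, 2 * leg] = heel_c
        flags[:, 2 * leg + 1] = ball_c

        # vertical GRF: two raised-cosine humps over stance
        sp = ph / df                       # stance phase in [0,1)
        fy = np.zeros(n)
        for amp, at in ((spec.hump1, spec.hump1_at),
                        (spec.hump2, spec.hump2_at)):
            w = spec.hump_width
            arg = (sp - at) / w
            lobe = np.where(np.abs(arg) < 0.5,
                            np.cos(math.pi * arg) ** 2, 0.0)
            fy += amp * bw * lobe
        fy[~stance] = 0.0
        fx = spec.grf_fx_amp * bw * (-np.sin(2 * math.pi * sp)) \
            * np.exp(-((sp - 0.5) / 0.6) ** 2)
        fx[~stance] = 0.0
        grf[:, leg, 0] = fx
        grf[:, leg, 1] = fy

        # foot position: stationary in stance, advancing arc in swing
        k_stride = np.floor((t / T) - off)
        foot_x0 = (k_stride + off) * stride_len
        swing_p = np.clip((ph - df) / (1 - df), 0.0, 1.0)
        adv = np.where(stance, 0.0,
                       stride_len * (0.5 - 0.5 * np.cos(math.pi * swing_p)))
        fx_pos = foot_x0 + adv
        arc = spec.swing_apex * np.sin(math.pi * swing_p)
        fy_pos = np.where(stance, 0.0, arc)
        heel[:, leg, 0] = fx_pos - 0.07
        heel[:, leg, 1] = fy_pos
        ball[:, leg, 0] = fx_pos + 0.13
        ball[:, leg, 1] = fy_pos
        heel_v[:, leg, 0] = np.gradient(heel[:, leg, 0], spec.dt)
        heel_v[:, leg, 1] = np.gradient(heel[:, leg, 1], spec.dt)
        ball_v[:, leg] = heel_v[:, leg]

        # center of pressure: rearfoot to forefoot, monotone over stance
        cop_leg = fx_pos - 0.07 + 0.20 * np.clip(sp, 0.0, 1.0)
        cop[:, leg] = np.where(fy > 0, cop_leg, np.nan)

        # knee center above the foot, used by the GRF-geometry layer
        knee_pos[:, leg, 0] = np.where(stance, fx_pos, fx_pos - 0.1)
        knee_pos[:, leg, 1] = 0.5

        # ankle power construction: torque = P / omega on a known rate
        phi1 = spec.knee_buckle_frac       # plantarflexion onset phase
        ta, to = ta_frac, df
        omega = np.zeros(n)
        inw = (ph >= phi1) & (ph < to)
        omega[inw] = spec.ankle_rate_amp * np.sin(
            math.pi * (ph[inw] - phi1) / (to - phi1))
        pre = ph < phi1
        omega[pre] -= spec.dorsi_rate_amp * np.sin(
            math.pi * ph[pre] / phi1)
        P = np.zeros(n)
        negw = (ph >= phi1) & (ph < ta)
        P[negw] = -spec.P_neg * np.sin(math.pi * (ph[negw] - phi1)
                                       / (ta - phi1))
        posw = (ph >= ta) & (ph < to)
        P[posw] = spec.P_pos * np.sin(math.pi * (ph[posw] - ta) / (to - ta))
        tau_a = np.where(np.abs(omega) > 1e-6, P / np.where(
            np.abs(omega) > 1e-6, omega, 1.0), 0.0)
        qd[:, 3 + 3 * leg + 2] = omega
        q[:, 3 + 3 * leg + 2] = math.pi / 2 \
            + np.cumsum(omega) * spec.dt * 0.0 + 0.1 * np.sin(
                2 * math.pi * ph)
        tau[:, 3 * leg + 2] = tau_a

        # hip rate: zero crossing (onset of hip flexion) at hip_zc_frac
        qd[:, 3 + 3 * leg] = -2.0 * np.sin(
            math.pi * (ph - spec.hip_zc_frac) / (1 - spec.hip_zc_frac + 1e-9))
        q[:, 3 + 3 * leg] = math.pi - 0.3 * np.sin(2 * math.pi * ph)
        # knee: angle dips (buckling), torque crosses zero down at the set phase
        q[:, 3 + 3 * leg + 1] = math.pi - 0.15 - 0.9 * np.clip(
            np.sin(math.pi * (ph - 0.5) / 0.5), 0, None)
        qd[:, 3 + 3 * leg + 1] = np.gradient(q[:, 3 + 3 * leg + 1], spec.dt)
        tau[:, 3 * leg + 1] = -30.0 * np.sin(
            math.pi * np.clip((ph - spec.knee_tau_zc_frac), -0.5, 0.5))

        # muscle channels: simple smooth activations for the energy model
        a[:, 7 * leg:7 * leg + 7] = 0.1 + 0.05 * np.sin(
            2 * math.pi * (ph[:, None] + np.arange(7) / 7.0))
        S[:, 7 * leg:7 * leg + 7] = a[:, 7 * leg:7 * leg + 7]
        F[:, 7 * leg:7 * leg + 7] = 200.0 * a[:, 7 * leg:7 * leg + 7]

        # leg segment COM velocities: smooth, known waveforms
        base = 1 + 3 * leg
        for si in range(3):
            amp = 0.4 + 0.2 * si
            com_vel[:, base + si, 0] = spec.speed + amp * np.sin(
                2 * math.pi * (ph + 0.1 * si))
            com_vel[:, base + si, 1] = 0.3 * amp * np.cos(
                2 * math.pi * (ph + 0.1 * si))
            com[:, base + si, 0] = spec.speed * t
            com[:, base + si, 1] = (0.9, 0.5, 0.1)[si]

    com[:, 0, 0] = spec.speed * t
    com[:, 0, 1] = 1.2
    com_vel[:, 0, 0] = spec.speed
    if spec.noise > 0:
        grf[:, :, 1] += spec.noise * bw * 0.01 * rng.standard_normal(
            (n, 2)) * (grf[:, :, 1] > 0)

    load = np.maximum(grf[:, :, 1], 0.0)
    tot = load.sum(axis=1, keepdims=True)
    share = np.divide(load, tot, out=np.zeros_like(load), where=tot > 0)

    trial = GaitTrial(
        t=t, q=q, qd=qd, tau=tau, S=S, a=a, l_ce=l_ce, F_mtu=F, grf=grf,
        grf_impulse=grf * spec.dt, cop_x=cop, contact_flags=flags, load_share=share,
        deact_mask=np.zeros((n, 2), dtype=bool), com=com, com_vel=com_vel,
        heel=heel, ball=ball, heel_vel=heel_v, ball_vel=ball_v,
        knee_pos=knee_pos, t_end=float(D), termination="completed",
        t_stride6=float(T),
        meta={"sim": {"t_sim_des": float(D)},
              "masses": dict(spec.masses),
              "total_mass": total_mass,
              "synthetic": True,
              "muscle_params": {"F_max": [1000.0] * 14,
                                "l_opt": [0.08] * 14}})

    gt = _ground_truth(spec, trial)
    return trial, gt


def _ground_truth(spec: SyntheticSpec, trial: GaitTrial) -> GroundTruth:
    """Expected metric values computed from the construction itself."""
    T, delta, ta_frac = _snap_times(spec)
    t = trial.t
    # the last complete stride is the right-leg stride starting at
    # (n_strides - 0.5) T (latest start with TO, TDc and next TD present)
    leg = 1
    td = (spec.n_strides - 0.5) * T
    td_next = td + T
    tdc = td + (0.5 + delta) * T
    t_a = td + ta_frac * T
    # TO and HO are flag-sampled events: take them from the constructed
    # contact channels inside this stride
    i_td = int(round(td / spec.dt))
    contact = trial.leg_contact(leg)
    heel_c = trial.contact_flags[:, 2 * leg]
    ball_c = trial.contact_flags[:, 2 * leg + 1]
    i_to = i_td + int(np.argmax(~contact[i_td:]))
    to = t[i_to]
    ho_idx = np.nonzero(heel_c[i_td:i_to - 1] & ~heel_c[i_td + 1:i_to]
                        & ball_c[i_td + 1:i_to])[0]
    ho = t[i_td + 1 + ho_idx[0]] if len(ho_idx) else math.nan

    i0 = i_td
    i1 = int(round(td_next / spec.dt))
    sel = slice(i0, i1)

    power = trial.ankle_power(leg)
    stance = (t >= td) & (t <= to)
    p_max = float(np.max(power[stance]))
    p_min = float(np.min(power[stance]))

    w = np.array([spec.masses["HAT"]] + [spec.masses[s] for s in
                                         ("thigh", "shank", "foot")] * 2)
    com_x = (trial.com[:, :, 0] * w).sum(axis=1) / w.sum()
    v_x = (com_x[i1 - 1] - com_x[i0]) / (t[i1 - 1] - t[i0])

    swing = (t >= to) & (t <= td_next)
    low = np.minimum(trial.heel[:, leg, 1], trial.ball[:, leg, 1])
    y_f_max = float(np.max(low[swing]))

    heel_x = np.interp(td, t, trial.heel[:, leg, 0])
    cop_o = np.interp(td, t, trial.cop_x[:, 1 - leg])
    l_step = heel_x - cop_o

    seg_m = [spec.masses[s] for s in ("thigh", "shank", "foot")]
    base = 1 + 3 * leg

    def momentum(tq):
        p = np.zeros(2)
        for off, m in enumerate(seg_m):
            for c in range(2):
                p[c] += m * np.interp(tq, t, trial.com_vel[:, base + off, c])
        return p

    p_a = momentum(t_a)
    p_to = momentum(to)
    dp = p_a - p_to
    cosang = np.dot(p_a, p_to) / (np.linalg.norm(p_a) * np.linalg.norm(p_to))
    dalpha = math.degrees(math.acos(min(1.0, max(-1.0, cosang))))

    # energy model, written out independently of the metrics module
    mp = trial.meta["muscle_params"]
    c = METABOLIC_DEFAULTS
    dt = spec.dt
    E = 0.0
    vce = np.gradient(trial.l_ce[sel], dt, axis=0)
    for m in range(14):
        aa = trial.a[sel][:, m]
        ww = -trial.F_mtu[sel][:, m] * vce[:, m]
        E += np.sum(c["k_maintenance"] * aa * mp["F_max"][m]
                    * mp["l_opt"][m]
                    + np.maximum(ww, 0) / c["eta_concentric"]
                    + np.maximum(-ww, 0) * c["eccentric_cost"]) * dt
    dist = trial.q[i1 - 1, 0] - trial.q[i0, 0]
    p_metab = E / (trial.meta["total_mass"] * dist)

    contact = trial.leg_contact(leg)[sel]
    df = float(np.mean(contact))

    score = (trial.t_end - trial.t_stride6) \
        / (trial.meta["sim"]["t_sim_des"] - trial.t_stride6) * 100.0

    return GroundTruth(
        leg=leg, td=td, td_next=td_next, ho=ho, tdc=tdc, to=to, t_a=t_a,
        t_stride=T, score=score, v_x=float(v_x), P_metab=float(p_metab),
        l_step=float(l_step), P_amp=abs(p_max / p_min), P_max_pos=p_max,
        P_min_neg=p_min, y_f_max=y_f_max, dp_x=float(dp[0]),
        dp_y=float(dp[1]), dalpha_p=float(dalpha), duty_factor=df)
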