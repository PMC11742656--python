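"""Gait metrics and event detection: the push-off analysis layer.

Everything operates on :class:`~reflexwalk.trial.GaitTrial` channels, so it
applies equally to simulated and synthetic trials. Scalar summaries follow
the push-off literature: a stability score (fraction of the desired horizon
survived after the settling strides), ankle power amplification
``|P_max / P_min|`` over stance, the trailing-leg momentum change between
alleviation onset (start of positive ankle power) and toe-off, and global
gait characteristics measured from the last complete stride.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from reflexwalk.trial import GaitTrial

#: metabolic model constants: per-muscle maintenance heat rate coefficient
#: [1/s] on a * F_max * l_opt, concentric efficiency, eccentric cost factor
METABOLIC_DEFAULTS = {"k_maintenance": 1.0, "eta_concentric": 0.25,
                      "eccentric_cost": 0.3}


# ----------------------------------------------------------------------
# elementary pieces
# ----------------------------------------------------------------------

def stability_score(t_end: float, t_stride6: float,
                    t_sim_des: float) -> float:
    """Percentage of the desired post-settling horizon that was survived."""
    if t_sim_des - t_stride6 <= 0:
        raise ValueError("t_sim_des must exceed t_stride6")
    if not t_stride6 <= t_end <= t_sim_des + 1e-9:
        raise ValueError("need t_stride6 <= t_end <= t_sim_des")
    return float((t_end - t_stride6) / (t_sim_des - t_stride6) * 100.0)


def power_amplification(power: np.ndarray) -> float:
    """|max positive / max negative| of an ankle power trace over stance.

    Raises if the trace has no negative phase (amplification undefined).
    """
    p = np.asarray(power, dtype=float)
    pmax = np.nanmax(p)
    pmin = np.nanmin(p)
    if pmin >= 0:
        raise ValueError("no negative ankle power phase; "
                         "amplification undefined")
    return float(abs(pmax / pmin))


def zero_crossings(t: np.ndarray, x: np.ndarray, direction: str = "any"
                   ) -> np.ndarray:
    """Zero-crossing times of a sampled signal (sign change + linear
    interpolation). direction: 'up' (- to +), 'down', or 'any'."""
    x = np.asarray(x, dtype=float)
    nz = np.nonzero(x != 0.0)[0]
    out = []
    for k in range(len(nz) - 1):
        i, j = nz[k], nz[k + 1]
        if x[i] * x[j] >= 0:
            continue
        if direction == "up" and not x[i] < 0 < x[j]:
            continue
        if direction == "down" and not x[i] > 0 > x[j]:
            continue
        if j == i + 1:
            frac = x[i] / (x[i] - x[j])
            out.append(t[i] + frac * (t[j] - t[i]))
        else:
            # a run of exact zeros between opposite signs: the signal
            # first reaches zero at sample i+1
            out.append(t[i + 1])
    return np.array(out)


# ----------------------------------------------------------------------
# events
# ----------------------------------------------------------------------

@dataclass
class StrideEvents:
    """Events of one analyzed stride of one leg (times in s)."""

    leg: int
    td: float
    td_next: float
    ho: float = math.nan
    tdc: float = math.nan
    to: float = math.nan
    t_a: float = math.nan
    t_a_reason: str = ""
    ankle_vel_zc: np.ndarray = field(default_factory=lambda: np.array([]))
    hip_vel_zc: np.ndarray = field(default_factory=lambda: np.array([]))
    knee_torque_zc: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def t_stride(self) -> float:
        return self.td_next - self.td


@dataclass
class EventTable:
    """Touchdown/lift-off/heel-off times per leg plus double support."""

    td: tuple          # (array, array) per leg
    to: tuple
    ho: tuple
    double_support: np.ndarray   # (k, 2) intervals
    diagnostics: str = ""

    def strides(self, leg: int) -> list:
        tds = self.td[leg]
        return [(tds[i], tds[i + 1]) for i in range(len(tds) - 1)]


def _flag_edges(t, flag):
    f = np.asarray(flag, dtype=bool)
    rising = np.nonzero(~f[:-1] & f[1:])[0] + 1
    falling = np.nonzero(f[:-1] & ~f[1:])[0] + 1
    return t[rising], t[falling]


def detect_events(trial: GaitTrial) -> EventTable:
    """Gait events from contact-flag transitions (any-point logic for
    TD/TO; heel-off = heel release while the ball stays loaded)."""
    t = trial.t
    td, to, ho = [], [], []
    for leg in range(2):
        contact = trial.leg_contact(leg)
        td_t, to_t = _flag_edges(t, contact)
        heel = trial.contact_flags[:, 2 * leg]
        ball = trial.contact_flags[:, 2 * leg + 1]
        ho_idx = np.nonzero(heel[:-1] & ~heel[1:] & ball[1:])[0] + 1
        td.append(td_t)
        to.append(to_t)
        ho.append(t[ho_idx])

    both = trial.leg_contact(0) & trial.leg_contact(1)
    ds_on, ds_off = _flag_edges(t, both)
    k = min(len(ds_on), len(ds_off))
    ds = np.column_stack([ds_on[:k], ds_off[:k]]) if k else np.zeros((0, 2))

    diag = ""
    if len(td[0]) + len(td[1]) < 1:
        diag = "fewer than one complete stride"
    return EventTable(td=tuple(td), to=tuple(to), ho=tuple(ho),
                      double_support=ds, diagnostics=diag)


def _events_in(arr, t0, t1):
    a = np.asarray(arr)
    return a[(a > t0) & (a < t1)]


def analyze_stride(trial: GaitTrial, events: EventTable, leg: int,
                   td: float, td_next: float,
                   min_ta_frac: float = 0.35) -> StrideEvents:
    """Within-stride events: HO, TDc, TO, alleviation onset and the
    zero crossings of ankle/hip angular velocity and knee torque."""
    se = StrideEvents(leg=leg, td=td, td_next=td_next)
    t = trial.t
    tos = _events_in(events.to[leg], td, td_next)
    se.to = tos[0] if len(tos) else math.nan
    hos = _events_in(events.ho[leg], td, se.to if np.isfinite(se.to)
                     else td_next)
    se.ho = hos[0] if len(hos) else math.nan
    tdcs = _events_in(events.td[1 - leg], td, se.to if np.isfinite(se.to)
                      else td_next)
    se.tdc = tdcs[-1] if len(tdcs) else math.nan

    sel = (t >= td) & (t <= td_next)
    ts = t[sel]
    se.ankle_vel_zc = zero_crossings(ts, trial.joint_rate("ankle", leg)[sel])
    se.hip_vel_zc = zero_crossings(ts, trial.joint_rate("hip", leg)[sel])
    se.knee_torque_zc = zero_crossings(ts, trial.joint_torque("knee",
                                                              leg)[sel])

    # alleviation onset: the start of the final positive power output at
    # the ankle — the last upward zero crossing before the push-off peak
    # (anchoring on the peak ignores millisecond sign flicker at toe-off)
    if np.isfinite(se.to):
        stance = (t >= td) & (t <= se.to)
        power = trial.ankle_power(leg)[stance]
        t_peak = t[stance][int(np.argmax(power))]
        zc = zero_crossings(t[stance], power, direction="up")
        zc = zc[zc <= t_peak]
        if len(zc) == 0:
            se.t_a_reason = "no positive ankle power onset before toe-off"
        else:
            ta = zc[-1]
            if ta - td < min_ta_frac * se.t_stride:
                se.t_a_reason = (f"alleviation onset at "
                                 f"{(ta - td) / se.t_stride:.0%} of stride, "
                                 f"before the {min_ta_frac:.0%} filter")
            else:
                se.t_a = ta
    else:
        se.t_a_reason = "incomplete stance (no toe-off)"
    return se


def last_complete_stride(trial: GaitTrial, events: EventTable
                         ) -> StrideEvents | None:
    """The trial's last stride with TD, TO, TDc and the next TD present.

    Scans backward over both legs' strides (latest start first).
    """
    candidates = []
    for leg in range(2):
        for (t0, t1) in events.strides(leg):
            candidates.append((t0, leg, t1))
    for t0, leg, t1 in sorted(candidates, reverse=True):
        se = analyze_stride(trial, events, leg, t0, t1)
        if np.isfinite(se.to) and np.isfinite(se.tdc):
            return se
    return None


# ----------------------------------------------------------------------
# momentum of the trailing leg
# ----------------------------------------------------------------------

def _interp_rows(t, arr, tq):
    """Linear interpolation of (n, ...) array rows at time tq."""
    out = np.empty(arr.shape[1:])
    flat = arr.reshape(len(t), -1)
    vals = np.array([np.interp(tq, t, flat[:, j])
                     for j in range(flat.shape[1])])
    return vals.reshape(arr.shape[1:])


def leg_momentum(trial: GaitTrial, leg: int, tq: float) -> np.ndarray:
    """Linear momentum of one leg's thigh+shank+foot at time tq."""
    masses = trial.meta.get("masses")
    if masses is None:
        raise ValueError("trial metadata lacks segment masses")
    base = 1 + 3 * leg
    p = np.zeros(2)
    for off, name in zip(range(3), ("thigh", "shank", "foot")):
        v = _interp_rows(trial.t, trial.com_vel[:, base + off, :], tq)
        p += masses[name] * v
    return p


def momentum_angle(p1: np.ndarray, p2: np.ndarray) -> float:
    """Angle between two momentum vectors, degrees in [0, 180]."""
    n1, n2 = np.linalg.norm(p1), np.linalg.norm(p2)
    if n1 == 0 or n2 == 0:
        return math.nan
    c = float(np.dot(p1, p2) / (n1 * n2))
    return math.degrees(math.acos(min(1.0, max(-1.0, c))))


def trailing_leg_momentum_change(trial: GaitTrial, stride: StrideEvents
                                 ) -> tuple[float, float, float]:
    """(dp_x, dp_y, dalpha_p): momentum at alleviation onset minus at
    toe-off, and the angle between the two vectors [deg]."""
    if not np.isfinite(stride.t_a):
        return math.nan, math.nan, math.nan
    p_a = leg_momentum(trial, stride.leg, stride.t_a)
    p_to = leg_momentum(trial, stride.leg, stride.to)
    dp = p_a - p_to
    return float(dp[0]), float(dp[1]), momentum_angle(p_a, p_to)


def grf_hump_count(trial: GaitTrial, stride: StrideEvents,
                   cutoff_hz: float = 10.0, prominence: float = 0.4,
                   min_sep: float = 0.22) -> int:
    """Number of prominent vertical-GRF maxima over one stance phase.

    The trace is zero-phase low-pass filtered (Butterworth, default
    10 Hz, the customary force-plate processing) so millisecond impact
    transients do not register as humps; maxima closer than ``min_sep``
    of stance or below ``prominence`` of the filtered peak are merged or
    ignored. Healthy walking shows the characteristic double hump.
    """
    from scipy.signal import butter, filtfilt
    t = trial.t
    sel = (t >= stride.td) & (t <= stride.to)
    fy = trial.grf[sel, stride.leg, 1]
    if len(fy) < 20 or fy.max() <= 0:
        return 0
    fs = 1.0 / trial.dt
    b, a = butter(2, cutoff_hz / (fs / 2), btype="low")
    f = filtfilt(b, a, fy)
    n = len(f)
    peaks = [i for i in range(1, n - 1)
             if f[i] > f[i - 1] and f[i] >= f[i + 1]
             and f[i] > prominence * f.max()]
    merged: list[int] = []
    for i in peaks:
        if merged and (i - merged[-1]) < min_sep * n:
            if f[i] > f[merged[-1]]:
                merged[-1] = i
        else:
            merged.append(i)
    return len(merged)


# ----------------------------------------------------------------------
# metabolic model
# ----------------------------------------------------------------------

def metabolic_energy(trial: GaitTrial, i0: int, i1: int,
                     constants: dict | None = None) -> float:
    """Muscle metabolic energy [J] over sample window [i0, i1).

    Maintenance/activation heat proportional to a * F_max * l_opt plus CE
    mechanical work rated by concentric efficiency and a reduced eccentric
    cost. F_max and l_opt per muscle come from trial metadata.
    """
    c = dict(METABOLIC_DEFAULTS, **(constants or {}))
    mp = trial.meta.get("muscle_params")
    if mp is None:
        raise ValueError("trial metadata lacks muscle_params")
    F_max = np.array(mp["F_max"])          # (14,)
    l_opt = np.array(mp["l_opt"])
    dt = trial.dt
    a = trial.a[i0:i1]
    F = trial.F_mtu[i0:i1]
    v_ce = np.gradient(trial.l_ce[i0:i1], dt, axis=0)
    w = -F * v_ce                           # CE power output, + concentric
    heat = c["k_maintenance"] * a * F_max * l_opt
    pos = np.maximum(w, 0.0) / c["eta_concentric"]
    neg = np.maximum(-w, 0.0) * c["eccentric_cost"]
    return float(np.sum(heat + pos + neg) * dt)


# ----------------------------------------------------------------------
# GRF / knee geometry
# ----------------------------------------------------------------------

@dataclass
class GRFSnapshot:
    """GRF vectors and knee geometry at one phase point around TDc."""

    time: float
    phase_label: str
    total_grf: np.ndarray
    global_cop_x: float
    leg_grf: np.ndarray        # (2,2)
    leg_cop_x: np.ndarray      # (2,)
    knee: np.ndarray           # trailing-leg knee center
    signed_distance: float     # + = line of action anterior to the knee
    classification: str        # anterior | through | posterior


def _line_knee_distance(cop_x: float, force: np.ndarray,
                        knee: np.ndarray) -> float:
    """Signed perpendicular distance of the knee center from the GRF line
    of action (origin at the COP on the ground). Positive when the line
    passes anterior to (in front of) the knee."""
    fn = np.linalg.norm(force)
    if fn == 0 or not np.isfinite(cop_x):
        return math.nan
    fhat = force / fn
    w = knee - np.array([cop_x, 0.0])
    # z-component of fhat x w: >0 when the knee lies left of the force
    # direction (force points up during stance => left = posterior)
    return float(fhat[0] * w[1] - fhat[1] * w[0])


def classify_distance(d: float, tol: float = 0.01) -> str:
    if not np.isfinite(d):
        return "undefined"
    if abs(d) < tol:
        return "through"
    return "anterior" if d > 0 else "posterior"


def grf_knee_snapshots(trial: GaitTrial, stride: StrideEvents,
                       tol: float = 0.01) -> list[GRFSnapshot]:
    """Five snapshots of GRF-vs-knee geometry around contralateral
    touchdown: 1 % gc before TDc, at TDc, and at 11/22/33 % of the second
    double-support phase (TDc to trailing-leg TO)."""
    if not (np.isfinite(stride.tdc) and np.isfinite(stride.to)):
        raise ValueError("stride lacks TDc/TO; cannot place snapshots")
    ds2 = stride.to - stride.tdc
    times = [stride.tdc - 0.01 * stride.t_stride, stride.tdc,
             stride.tdc + 0.11 * ds2, stride.tdc + 0.22 * ds2,
             stride.tdc + 0.33 * ds2]
    labels = ["1%gc before TDc", "TDc", "11% DS2", "22% DS2", "33% DS2"]
    snaps = []
    for tq, lab in zip(times, labels):
        grf = _interp_rows(trial.t, trial.grf, tq)
        total = grf.sum(axis=0)
        cops = np.empty(2)
        for leg in range(2):
            cop = trial.cop_x[:, leg]
            valid = np.isfinite(cop)     # airborne samples carry no COP
            cops[leg] = np.interp(tq, trial.t[valid], cop[valid]) \
                if valid.any() else math.nan
        fy = np.maximum(grf[:, 1], 0.0)
        gcop = float((cops * fy).sum() / fy.sum()) if fy.sum() > 0 \
            else math.nan
        knee = _interp_rows(trial.t, trial.knee_pos[:, stride.leg, :], tq)
        d = _line_knee_distance(gcop, total, knee)
        snaps.append(GRFSnapshot(
            time=tq, phase_label=lab, total_grf=total, global_cop_x=gcop,
            leg_grf=grf, leg_cop_x=cops, knee=knee, signed_distance=d,
            classification=classify_distance(d, tol)))
    return snaps


# ----------------------------------------------------------------------
# the full scalar summary
# ----------------------------------------------------------------------

@dataclass
class TrialMetrics:
    """Scalar summary of one trial (the push-off analysis row)."""

    score: float = math.nan
    v_x: float = math.nan            # m/s
    P_metab: float = math.nan        # J/(kg m)
    t_stride: float = math.nan       # s
    l_step: float = math.nan         # m
    P_amp: float = math.nan
    P_max_pos: float = math.nan      # W
    P_min_neg: float = math.nan      # W
    y_f_max: float = math.nan        # m
    dp_x: float = math.nan           # kg m/s
    dp_y: float = math.nan
    dalpha_p: float = math.nan       # deg
    duty_factor: float = math.nan
    valid: bool = False
    reason: str = ""

    def as_dict(self) -> dict:
        return asdict(self)

    COMPARABLE = ("v_x", "P_metab", "t_stride", "l_step", "P_amp",
                  "P_max_pos", "y_f_max", "dp_x", "dp_y", "dalpha_p",
                  "duty_factor")

    def relative_changes(self, ref: "TrialMetrics") -> dict:
        """Percent change of each measure vs a reference trial."""
        out = {}
        for k in self.COMPARABLE:
            a, b = getattr(self, k), getattr(ref, k)
            out[k] = 100.0 * (a - b) / abs(b) if np.isfinite(a) \
                and np.isfinite(b) and b != 0 else math.nan
        return out


def global_characteristics(trial: GaitTrial, stride: StrideEvents,
                           metabolic_constants: dict | None = None) -> dict:
    """Speed, metabolic cost, stride time, step length, duty factor, foot
    clearance and peak ankle power, measured over the given stride."""
    t = trial.t
    i0 = int(np.searchsorted(t, stride.td))
    i1 = int(np.searchsorted(t, stride.td_next))
    masses = trial.meta.get("masses")
    total_mass = trial.meta.get("total_mass")
    out = {}

    # average forward speed of the whole-body COM
    if masses is not None and total_mass:
        w = np.array([masses["HAT"]] + [masses[s] for s in
                                        ("thigh", "shank", "foot")] * 2)
        com_x = (trial.com[:, :, 0] * w).sum(axis=1) / w.sum()
        out["v_x"] = (com_x[i1 - 1] - com_x[i0]) / (t[i1 - 1] - t[i0])
    else:
        out["v_x"] = (trial.q[i1 - 1, 0] - trial.q[i0, 0]) \
            / (t[i1 - 1] - t[i0])

    out["t_stride"] = stride.t_stride

    # step length: touching-down foot's contact point vs contralateral COP
    leg = stride.leg
    heel_x = np.interp(stride.td, t, trial.heel[:, leg, 0])
    cop_o = np.interp(stride.td, t, trial.cop_x[:, 1 - leg])
    if np.isfinite(cop_o):
        out["l_step"] = heel_x - cop_o
    else:
        out["l_step"] = math.nan

    # duty factor
    contact = trial.leg_contact(leg)[i0:i1]
    out["duty_factor"] = float(np.mean(contact))

    # swing foot clearance: lowest foot point's maximum height in swing
    if np.isfinite(stride.to):
        swing = (t >= stride.to) & (t <= stride.td_next)
        low = np.minimum(trial.heel[:, leg, 1], trial.ball[:, leg, 1])
        out["y_f_max"] = float(np.max(low[swing])) if swing.any() \
            else math.nan
    else:
        out["y_f_max"] = math.nan

    # ankle power extrema over stance
    if np.isfinite(stride.to):
        stance = (t >= stride.td) & (t <= stride.to)
        power = trial.ankle_power(leg)[stance]
        out["P_max_pos"] = float(np.max(power))
        out["P_min_neg"] = float(np.min(power))
        out["P_amp"] = abs(out["P_max_pos"] / out["P_min_neg"]) \
            if out["P_min_neg"] < 0 else math.nan
    else:
        out["P_max_pos"] = out["P_min_neg"] = out["P_amp"] = math.nan

    # metabolic cost per kg per meter
    if total_mass and "muscle_params" in trial.meta:
        dist = trial.q[i1 - 1, 0] - trial.q[i0, 0]
        if dist > 0:
            E = metabolic_energy(trial, i0, i1, metabolic_constants)
            out["P_metab"] = E / (total_mass * dist)
        else:
            out["P_metab"] = math.nan
    else:
        out["P_metab"] = math.nan
    return out


def compute_metrics(trial: GaitTrial, t_sim_des: float | None = None,
                    metabolic_constants: dict | None = None
                    ) -> TrialMetrics:
    """Full scalar summary of one trial, from its last complete stride."""
    tm = TrialMetrics()
    if t_sim_des is None:
        t_sim_des = trial.meta.get("sim", {}).get("t_sim_des", trial.t_end)
    if np.isfinite(trial.t_stride6):
        tm.score = stability_score(min(trial.t_end, t_sim_des),
                                   trial.t_stride6, t_sim_des)
    events = detect_events(trial)
    if events.diagnostics:
        tm.reason = events.diagnostics
        return tm
    stride = last_complete_stride(trial, events)
    if stride is None:
        tm.reason = "no complete stride with TO and TDc"
        return tm
    gc = global_characteristics(trial, stride, metabolic_constants)
    for k, v in gc.items():
        setattr(tm, k, v)
    tm.dp_x, tm.dp_y, tm.dalpha_p = trailing_leg_momentum_change(trial,
                                                                 stride)
    if not np.isfinite(tm.dp_x) and stride.t_a_reason:
        tm.reason = stride.t_a_reason
    tm.valid = np.isfinite(tm.v_x) and np.isfinite(tm.t_stride)
    return tm
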