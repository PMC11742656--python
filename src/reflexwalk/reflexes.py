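"""Decentralized stance/swing reflex controller.

Stimulations are built from delayed proprioceptive signals: positive force
feedback for the plantarflexors and VAS in stance (with knee-overextension
inhibition of VAS), TA length feedback with SOL suppression, trunk-balance
PD on the stance hip muscles scaled by the leg's load share, swing-leg
placement reflexes, and contralateral-touchdown modulation (HFL up, HAM
down on the trailing leg). All outputs are clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from reflexwalk import _kernels
from reflexwalk.params import ModelConfig, MUSCLES, muscle_index


@dataclass
class SensorSnapshot:
    """Delayed sensor data consumed by the controller at one instant.

    F_mtu / l_ce: 14-vectors (already delayed by each muscle's loop delay);
    knee_angle / knee_vel: per-leg delayed knee state; phase: 0 stance,
    1 swing per leg; load_share: per-leg fraction of total vertical GRF;
    lean / lean_rate: trunk state; lean_at_toe_off: per-leg lean sampled at
    the leg's last toe-off; contralateral_td: per-leg flag, True while the
    leg is the trailing stance leg of a double-support phase.
    """

    F_mtu: np.ndarray
    l_ce: np.ndarray
    knee_angle: np.ndarray
    knee_vel: np.ndarray
    phase: np.ndarray
    load_share: np.ndarray
    lean: float
    lean_rate: float
    lean_at_toe_off: np.ndarray = field(default=None)
    contralateral_td: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.lean_at_toe_off is None:
            self.lean_at_toe_off = np.zeros(2)
        if self.contralateral_td is None:
            self.contralateral_td = np.zeros(2, dtype=bool)
        self.phase = np.asarray(self.phase, dtype=np.int64)
        if not np.all((self.phase == 0) | (self.phase == 1)):
            raise ValueError("phase entries must be 0 (stance) or 1 (swing)")
        if np.any(np.asarray(self.load_share) < 0):
            raise ValueError("load shares must be >= 0")


class DelayLine:
    """Fixed-rate ring buffer with interpolating delayed reads.

    Queries never extrapolate into the future; reads before the recorded
    history return the earliest stored value.
    """

    def __init__(self, delay: float, dt: float, initial: float = 0.0):
        if delay < 0 or dt <= 0:
            raise ValueError("delay >= 0 and dt > 0 required")
        self.dt = dt
        self.delay = delay
        n = max(int(np.ceil(delay / dt)) + 2, 2)
        self._buf = np.full(n, float(initial))
        self._t = np.full(n, -np.inf)
        self._idx = 0
        self._initial = float(initial)

    def push(self, t: float, value: float) -> None:
        self._buf[self._idx] = value
        self._t[self._idx] = t
        self._idx = (self._idx + 1) % len(self._buf)

    def read(self, t: float) -> float:
        """Value at time ``t - delay`` by linear interpolation."""
        tq = t - self.delay
        order = np.argsort(self._t)
        ts = self._t[order]
        vs = self._buf[order]
        valid = np.isfinite(ts)
        ts, vs = ts[valid], vs[valid]
        if ts.size == 0 or tq < ts[0]:
            return self._initial
        if tq >= ts[-1]:
            return float(vs[-1])
        return float(np.interp(tq, ts, vs))


def stimulus_positive_force_feedback(F_delayed: float, S0: float, G: float,
                                     F_max: float = 1.0) -> float:
    """Monosynaptic positive force feedback: clip(S0 + G * F / F_max, 0, 1)."""
    if F_delayed < 0:
        raise ValueError("muscle force must be >= 0")
    return float(np.clip(S0 + G * F_delayed / F_max, 0.0, 1.0))


def stimulate_all(sensors: SensorSnapshot, config: ModelConfig) -> np.ndarray:
    """All 14 muscle stimulations for one controller evaluation."""
    return _kernels.stimulations(
        sensors.phase,
        np.asarray(sensors.load_share, dtype=float),
        np.asarray(sensors.contralateral_td, dtype=np.bool_),
        float(sensors.lean), float(sensors.lean_rate),
        np.asarray(sensors.lean_at_toe_off, dtype=float),
        np.asarray(sensors.F_mtu, dtype=float),
        np.asarray(sensors.l_ce, dtype=float),
        np.asarray(sensors.knee_angle, dtype=float),
        np.asarray(sensors.knee_vel, dtype=float),
        config.mus_array(), config.reflexes.as_array())
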