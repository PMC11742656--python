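"""Stride-clocked muscle deactivation: the core experimental manipulation.

A selected muscle's stimulation is forced to zero on both legs. Each leg
triggers off its own touchdown: a timer starts at touchdown, and when it
reaches ``gc_off * t_stride`` (with the stride time estimated online from
the previous completed stride) the stimulation is silenced for ``t_off``
seconds. Nothing happens before the settling strides. Overlapping windows
from consecutive strides merge (union).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STUDIED_MUSCLES = ("GAS", "VAS", "HAM")

#: reference stride time used to seed the online estimator [s]
T_STRIDE_SEED = 1.25


@dataclass(frozen=True)
class DeactivationSpec:
    """Which muscle is silenced, from which gait-cycle fraction, how long.

    gc_off in percent of the gait cycle [0, 100]; t_off in seconds [0, 1].
    Deactivation is always bilateral, armed from touchdown number
    ``start_stride`` of each leg.
    """

    muscle: str
    gc_off: float
    t_off: float
    start_stride: int = 6

    def __post_init__(self):
        if self.muscle.upper() not in STUDIED_MUSCLES:
            raise ValueError(f"muscle must be one of {STUDIED_MUSCLES}")
        if not 0.0 <= self.gc_off <= 100.0:
            raise ValueError("gc_off must be in [0, 100] %")
        if not 0.0 <= self.t_off <= 1.0:
            raise ValueError("t_off must be in [0, 1] s")
        if self.start_stride < 1:
            raise ValueError("start_stride must be >= 1")
        object.__setattr__(self, "muscle", self.muscle.upper())

    def label(self) -> str:
        """Table-style label, e.g. ``GAS (52%, 0.25 s)``."""
        return f"{self.muscle} ({self.gc_off:g}%, {self.t_off:g} s)"


@dataclass
class StrideClock:
    """Per-leg touchdown bookkeeping with an online stride-time estimate."""

    t_stride_seed: float = T_STRIDE_SEED
    last_touchdown: float = float("nan")
    stride_index: int = 0
    t_stride_est: float = field(default=None)

    def __post_init__(self):
        if self.t_stride_est is None:
            self.t_stride_est = self.t_stride_seed

    def touchdown(self, t: float) -> None:
        if np.isfinite(self.last_touchdown):
            est = t - self.last_touchdown
            if est <= 0:
                raise ValueError("touchdowns must be strictly increasing")
            self.t_stride_est = est
        self.last_touchdown = t
        self.stride_index += 1

    def timer(self, t: float) -> float:
        """Time since the last touchdown (nan before the first)."""
        return t - self.last_touchdown


class DeactivationSchedule:
    """Incremental evaluation of the deactivation mask for one leg."""

    def __init__(self, spec: DeactivationSpec, clock: StrideClock):
        self.spec = spec
        self.clock = clock
        self._pending: list[float] = []
        self._window_until = -np.inf

    def on_touchdown(self, t: float) -> None:
        self.clock.touchdown(t)
        if self.clock.stride_index >= self.spec.start_stride:
            self._pending.append(
                t + self.spec.gc_off / 100.0 * self.clock.t_stride_est)

    def mask(self, t: float) -> bool:
        """True while the muscle's stimulation must be forced to zero."""
        fired = [p for p in self._pending if p <= t]
        for p in fired:
            self._window_until = max(self._window_until, p + self.spec.t_off)
            self._pending.remove(p)
        return t < self._window_until


def deactivation_mask(t: float, spec: DeactivationSpec,
                      touchdowns: np.ndarray,
                      t_stride_seed: float = T_STRIDE_SEED) -> bool:
    """Mask value at time ``t`` for a leg with the given touchdown times.

    Convenience wrapper replaying the touchdown history through a
    :class:`DeactivationSchedule`.
    """
    clock = StrideClock(t_stride_seed=t_stride_seed)
    sched = DeactivationSchedule(spec, clock)
    for td in np.sort(np.asarray(touchdowns, dtype=float)):
        if td <= t:
            sched.on_touchdown(td)
    return sched.mask(t)


def deactivation_grid(muscle: str, n_gc: int = 50, n_toff: int = 400,
                      gc_range: tuple = (0.0, 100.0),
                      toff_range: tuple = (0.0, 1.0),
                      start_stride: int = 6) -> list[DeactivationSpec]:
    """Full (or reduced) experimental grid of deactivation specs.

    The full protocol uses 50 gait-cycle increments (2 % each) by 400
    duration increments (0.025 s each) = 20,000 cells. Cell values are the
    lower edge of each increment, so both grids start exactly at the range
    minimum (gc_off = 0 %, t_off = 0 s).
    """
    gcs = np.linspace(gc_range[0], gc_range[1], n_gc + 1)[:-1]
    toffs = np.linspace(toff_range[0], toff_range[1], n_toff + 1)[:-1]
    return [DeactivationSpec(muscle, float(g), float(d), start_stride)
            for g in gcs for d in toffs]
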