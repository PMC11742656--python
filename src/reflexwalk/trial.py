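"""GaitTrial: the uniform-timestep record of one simulation.

All channels share one time base (default 1 kHz). Trials round-trip
losslessly through an HDF5 container with named channels and a JSON
metadata sidecar embedded as an attribute; a tidy CSV export is provided
for interoperability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from reflexwalk.params import MUSCLES

#: COM channel order
SEGMENTS7 = ("HAT", "thigh_L", "shank_L", "foot_L",
             "thigh_R", "shank_R", "foot_R")

_ARRAY_FIELDS = ("t", "q", "qd", "tau", "S", "a", "l_ce", "F_mtu", "grf",
                 "grf_impulse", "cop_x", "contact_flags", "load_share",
                 "deact_mask",
                 "com", "com_vel", "heel", "ball", "heel_vel", "ball_vel",
                 "knee_pos")


@dataclass
class GaitTrial:
    """One simulated (or synthetic) gait trial.

    Array shapes (n = number of 1 ms samples): q/qd (n,9); tau (n,6) in
    (hip,knee,ankle)x(L,R) order; S/a/l_ce/F_mtu (n,14); grf (n,2,2);
    cop_x (n,2); contact_flags (n,4) heel/ball x L/R; load_share (n,2);
    deact_mask (n,2); com/com_vel (n,7,2); heel/ball and velocities (n,2,2);
    knee_pos (n,2,2).
    """

    t: np.ndarray
    q: np.ndarray
    qd: np.ndarray
    tau: np.ndarray
    S: np.ndarray
    a: np.ndarray
    l_ce: np.ndarray
    F_mtu: np.ndarray
    grf: np.ndarray
    grf_impulse: np.ndarray
    cop_x: np.ndarray
    contact_flags: np.ndarray
    load_share: np.ndarray
    deact_mask: np.ndarray
    com: np.ndarray
    com_vel: np.ndarray
    heel: np.ndarray
    ball: np.ndarray
    heel_vel: np.ndarray
    ball_vel: np.ndarray
    knee_pos: np.ndarray
    t_end: float = 0.0
    termination: str = "completed"
    t_stride6: float = float("nan")
    meta: dict = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else 1e-3

    @property
    def n(self) -> int:
        return len(self.t)

    def leg_contact(self, leg: int) -> np.ndarray:
        """Boolean any-point contact of leg 0 (left) or 1 (right)."""
        return (self.contact_flags[:, 2 * leg]
                | self.contact_flags[:, 2 * leg + 1])

    def joint_angle(self, joint: str, leg: int) -> np.ndarray:
        from reflexwalk.params import JOINTS
        return self.q[:, 3 + 3 * leg + JOINTS.index(joint)]

    def joint_rate(self, joint: str, leg: int) -> np.ndarray:
        from reflexwalk.params import JOINTS
        return self.qd[:, 3 + 3 * leg + JOINTS.index(joint)]

    def joint_torque(self, joint: str, leg: int) -> np.ndarray:
        from reflexwalk.params import JOINTS
        return self.tau[:, 3 * leg + JOINTS.index(joint)]

    def ankle_power(self, leg: int) -> np.ndarray:
        """Net ankle joint power; plantarflexion torque x plantarflexion
        velocity is positive, so push-off shows as a positive burst."""
        return self.joint_torque("ankle", leg) * self.joint_rate("ankle", leg)

    def muscle_channel(self, name: str, leg: str, channel: str) -> np.ndarray:
        from reflexwalk.params import muscle_index
        return getattr(self, channel)[:, muscle_index(name, leg)]

    # ------------------------------------------------------------- I/O
    def save(self, path: str | Path) -> None:
        """Write the trial as an HDF5 container with named channels."""
        with h5py.File(path, "w") as f:
            for name in _ARRAY_FIELDS:
                f.create_dataset(name, data=getattr(self, name))
            f.attrs["t_end"] = self.t_end
            f.attrs["termination"] = self.termination
            f.attrs["t_stride6"] = self.t_stride6
            f.attrs["meta"] = json.dumps(self.meta)

    @classmethod
    def load(cls, path: str | Path) -> "GaitTrial":
        with h5py.File(path, "r") as f:
            arrays = {name: f[name][...] for name in _ARRAY_FIELDS}
            return cls(**arrays, t_end=float(f.attrs["t_end"]),
                       termination=str(f.attrs["termination"]),
                       t_stride6=float(f.attrs["t_stride6"]),
                       meta=json.loads(f.attrs["meta"]))

    def to_dataframe(self) -> pd.DataFrame:
        """Flat tabular view of the scalar-per-sample channels."""
        cols = {"t": self.t}
        qn = ("x", "y", "lean", "hip_L", "knee_L", "ankle_L",
              "hip_R", "knee_R", "ankle_R")
        for i, nm in enumerate(qn):
            cols[f"q_{nm}"] = self.q[:, i]
            cols[f"qd_{nm}"] = self.qd[:, i]
        tn = ("hip_L", "knee_L", "ankle_L", "hip_R", "knee_R", "ankle_R")
        for i, nm in enumerate(tn):
            cols[f"tau_{nm}"] = self.tau[:, i]
        for leg, lname in enumerate("LR"):
            for m, mname in enumerate(MUSCLES):
                i = 7 * leg + m
                for ch in ("S", "a", "l_ce", "F_mtu"):
                    cols[f"{ch}_{mname}_{lname}"] = getattr(self, ch)[:, i]
            cols[f"grf_x_{lname}"] = self.grf[:, leg, 0]
            cols[f"grf_y_{lname}"] = self.grf[:, leg, 1]
            cols[f"cop_x_{lname}"] = self.cop_x[:, leg]
            cols[f"load_share_{lname}"] = self.load_share[:, leg]
            cols[f"contact_{lname}"] = self.leg_contact(leg)
            cols[f"deact_mask_{lname}"] = self.deact_mask[:, leg]
        return pd.DataFrame(cols)

    def save_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)
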