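"""Systematic deactivation sweeps and viability maps.

Runs the (muscle, gc_off, t_off) grid cell by cell — embarrassingly
parallel, with results independent of execution order and worker count —
normalizes durations by each trial's own last-stride time, and applies the
detailed-trial selection rule (maximum stable deactivation duration with
onset inside the preswing window, 50-62 % of the gait cycle).
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from reflexwalk.deactivation import DeactivationSpec, deactivation_grid
from reflexwalk.metrics import TrialMetrics, compute_metrics
from reflexwalk.params import ModelConfig, load_config
from reflexwalk.simulate import SimConfig, run_trial

PRESWING_WINDOW = (50.0, 62.0)    # % of the gait cycle

_KEY = ["muscle", "gc_off", "t_off"]


def evaluate_cell(spec: DeactivationSpec, config: ModelConfig,
                  sim: SimConfig) -> dict:
    """Simulate one grid cell and summarize it as a result row."""
    trial = run_trial(config, sim, spec)
    tm = compute_metrics(trial, sim.t_sim_des)
    score = tm.score if np.isfinite(tm.score) else 0.0
    row = {"muscle": spec.muscle, "gc_off": spec.gc_off,
           "t_off": spec.t_off, "score": score,
           "t_end": trial.t_end, "termination": trial.termination}
    row.update(tm.as_dict())
    row["score"] = score
    row["toff_norm"] = 100.0 * spec.t_off / tm.t_stride \
        if np.isfinite(tm.t_stride) and tm.t_stride > 0 else math.nan
    return row


def run_sweep(muscle: str, config: ModelConfig | None = None,
              sim: SimConfig | None = None,
              specs: list | None = None,
              n_gc: int = 50, n_toff: int = 400,
              gc_range: tuple = (0.0, 100.0),
              toff_range: tuple = (0.0, 1.0),
              n_jobs: int = 1, backend: str = "loky",
              reference: TrialMetrics | None = None,
              cache_path: str | Path | None = None) -> pd.DataFrame:
    """Run a deactivation sweep; returns one row per grid cell.

    Failed trials keep Score < 100 and are flagged invalid rather than
    dropped; individual cell failures never abort the sweep. With a
    ``cache_path``, rows already present there are skipped (resume).
    """
    config = config if config is not None else load_config()
    sim = sim if sim is not None else SimConfig()
    if specs is None:
        specs = deactivation_grid(muscle, n_gc, n_toff, gc_range, toff_range)

    done = None
    if cache_path is not None and Path(cache_path).exists():
        done = pd.read_csv(cache_path)
        have = set(map(tuple, done[_KEY].itertuples(index=False)))
        specs = [s for s in specs
                 if (s.muscle, s.gc_off, s.t_off) not in have]

    if n_jobs == 1:
        rows = [evaluate_cell(s, config, sim) for s in specs]
    else:
        rows = Parallel(n_jobs=n_jobs, backend=backend)(
            delayed(evaluate_cell)(s, config, sim) for s in specs)

    df = pd.DataFrame(rows)
    if done is not None and len(done):
        df = pd.concat([done, df], ignore_index=True)
    if len(df):
        df = df.sort_values(_KEY).reset_index(drop=True)
    if cache_path is not None and len(df):
        df.to_csv(cache_path, index=False)
    if reference is not None and len(df):
        df = add_relative_changes(df, reference)
    return df


def add_relative_changes(df: pd.DataFrame,
                         reference: TrialMetrics) -> pd.DataFrame:
    """Percent change vs the reference for every comparable measure.

    Defined only for stable rows (Score = 100); others get NaN.
    """
    df = df.copy()
    stable = df["score"] >= 100.0 - 1e-9
    for k in TrialMetrics.COMPARABLE:
        ref = getattr(reference, k)
        col = f"rel_{k}"
        if np.isfinite(ref) and ref != 0:
            df[col] = np.where(stable, 100.0 * (df[k] - ref) / abs(ref),
                               math.nan)
        else:
            df[col] = math.nan
    return df


def select_detailed_trial(df: pd.DataFrame,
                          window: tuple = PRESWING_WINDOW):
    """The stable cell with maximum deactivation duration whose onset lies
    in the preswing window; ties break toward smaller gc_off, then first
    row order. Returns the row (pd.Series) or None if no candidate."""
    cand = df[(df["score"] >= 100.0 - 1e-9)
              & (df["gc_off"] >= window[0]) & (df["gc_off"] <= window[1])]
    if len(cand) == 0:
        return None
    cand = cand.sort_values(["t_off", "gc_off"],
                            ascending=[False, True], kind="stable")
    return cand.iloc[0]


def max_stable_duration(muscle: str, gc_values, toff_step: float = 0.025,
                        toff_max: float = 1.0,
                        config: ModelConfig | None = None,
                        sim: SimConfig | None = None,
                        patience: int = 2,
                        cache_path: str | Path | None = None
                        ) -> pd.DataFrame:
    """Ascending-duration probe of the viability boundary (desk-scale
    utility; the headline maps use the plain grid).

    For each onset, durations grow in ``toff_step`` increments until
    ``patience`` consecutive failures.
    """
    config = config if config is not None else load_config()
    sim = sim if sim is not None else SimConfig()
    done = {}
    if cache_path is not None and Path(cache_path).exists():
        prev = pd.read_csv(cache_path)
        done = {(r["muscle"], r["gc_off"], r["t_off"]): r.to_dict()
                for _, r in prev.iterrows()}
    rows = []
    for gc in gc_values:
        fails = 0
        k = 0
        while k * toff_step <= toff_max + 1e-9 and fails < patience:
            toff = min(round(k * toff_step, 9), toff_max)
            key = (muscle, float(gc), float(toff))
            if key in done:
                row = done[key]
            else:
                row = evaluate_cell(
                    DeactivationSpec(muscle, float(gc), float(toff)),
                    config, sim)
            rows.append(row)
            if row["score"] >= 100.0 - 1e-9:
                fails = 0
            else:
                fails += 1
            k += 1
    df = pd.DataFrame(rows).sort_values(_KEY).reset_index(drop=True)
    if cache_path is not None and len(df):
        df.to_csv(cache_path, index=False)
    return df


def viability_map(df: pd.DataFrame, color: str = "score",
                  path: str | Path | None = None, title: str = ""):
    """Scatter map of gc_off vs stride-normalized duration, colored by a
    result column; color scale spans the 1st-99th percentile, outliers
    gray. Returns the matplotlib figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    d = df.dropna(subset=["toff_norm"])
    vals = d[color].to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    fig, ax = plt.subplots(figsize=(6, 4))
    if len(finite):
        lo, hi = np.percentile(finite, [1, 99])
        out = (vals < lo) | (vals > hi) | ~np.isfinite(vals)
        ax.scatter(d["gc_off"][out], d["toff_norm"][out], c="0.6", s=12)
        sc = ax.scatter(d["gc_off"][~out], d["toff_norm"][~out],
                        c=vals[~out], s=12, cmap="viridis",
                        vmin=lo, vmax=hi)
        fig.colorbar(sc, ax=ax, label=color)
    ax.set_xlabel("deactivation onset gc_off [% gait cycle]")
    ax.set_ylabel("duration t_off [% stride time]")
    ax.set_title(title or color)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
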