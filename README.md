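# reflexwalk

Predictive neuromuscular simulation of human walking for studying how the
knee muscles shape ankle push-off.

`reflexwalk` implements a planar (sagittal) musculoskeletal walker — seven
rigid segments, nine degrees of freedom, seven Hill-type muscle-tendon
units per leg (SOL, TA, GAS, VAS, HAM, GLU, HFL) — driven by a
decentralized spinal-reflex controller with positive force feedback in the
stance extensors. On top of the simulator sits the experiment that the
package exists for: silencing one knee muscle (GAS, VAS or HAM) on both
legs, stride-clocked — each leg starts a timer at its own touchdown and
zeroes the muscle's stimulation from `gc_off · t_stride` for `t_off`
seconds — and measuring what that does to the ankle push-off catapult.

The analysis layer computes, per trial:

* a stability score, Score = (t_end − t_stride6)/(t_sim,des − t_stride6)·100;
* ankle power amplification P_amp = |P_max,ank / P_min,ank| over stance;
* the trailing-leg momentum change ΔP_TL = P_TL(t_a) − P_TL(t_to) between
  alleviation onset (ankle power turning positive) and toe-off, with the
  angle Δα_p between the two momentum vectors;
* global gait characteristics (v̄x, P_metab, t_stride, l_step, duty
  factor, swing foot clearance, peak ankle power);
* gait-event timing (HO, TDc, TO, zero crossings of ankle/hip angular
  velocity and knee torque, double-support phases);
* GRF line-of-action geometry relative to the knee center around
  contralateral touchdown (anterior / through / posterior).

Sweeping the deactivation grid (50 onsets × 400 durations per muscle)
yields viability maps of when and for how long each muscle may be
silenced while the model keeps walking. It is intended for researchers in
computational biomechanics, gait analysis and legged robotics who want a
fully inspectable, scriptable reimplementation of this experiment class.

The synthetic-gait module (`reflexwalk.synthetic`) fabricates
trial-shaped surrogate data with exactly known ground truth, so the whole
measurement layer is testable independently of the physics.

## Quick start

```python
from reflexwalk import (load_config, run_trial, SimConfig,
                        DeactivationSpec, compute_metrics)

cfg = load_config()                       # reference model parameters
sim = SimConfig(t_sim_des=20.0)

ref = run_trial(cfg, sim)                 # unperturbed 20 s walk
print(ref.termination, ref.t_end)         # 'completed' 20.0

spec = DeactivationSpec("VAS", gc_off=54.0, t_off=0.3)
trial = run_trial(cfg, sim, spec)         # VAS silenced in preswing
m_ref, m_off = compute_metrics(ref), compute_metrics(trial)
print(m_off.relative_changes(m_ref))      # % change per gait measure
```

Command line:

```bash
reflexwalk simulate --t-sim 20                      # one reference trial
reflexwalk simulate --muscle GAS --gc-off 50 --t-off 0.25
reflexwalk sweep VAS --n-gc 10 --n-toff 20 --select # reduced grid + map
reflexwalk metrics trial_out/trial.h5 --out metrics.csv
```

## Worked example

(see `scripts/acceptance.py` for the exact pipeline; numbers below are
its output for the shipped reference configuration)

```text
$ python scripts/acceptance.py --seed 1 --out results/acceptance.json
{
  "t1": {
    "value": 1.2621,
    "n": 8
  },
  "t3": {
    "value": -11.04,
    "n": 63
  },
  "t5": {
    "value": 1.224,
    "n": 63
  },
  "t6": {
    "value": -0.51,
    "n": 60
  },
  "t7": {
    "value": -3.57,
    "n": 60
  },
  "t8": {
    "value": 48.35,
    "n": 60
  },
  "t11": {
    "value": 675.0,
    "n": 79
  },
  "t12": {
    "value": 130.96,
    "n": 11
  }
}
```

`t1` is the steady stride time of the reference gait in seconds. The
other entries are the selected-trial results: relative changes (%) of
metabolic cost (GAS off), forward speed, power amplification and vertical
trailing-leg momentum magnitude (VAS off), the longest stable HAM
silencing in milliseconds, and the largest deviation of any gait measure
for that HAM trial.

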