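# Methods

## The model

`reflexwalk` simulates sagittal-plane human walking with a predictive
neuromuscular model: motion is generated by forward dynamics under a
spinal-reflex controller, not by tracking recorded data.

**Multibody system.** Seven rigid bodies — a lumped head-arm-trunk (HAT)
segment and thigh, shank and rigid foot per leg — connected by revolute
hips, knees and ankles, give nine degrees of freedom (hip-point x/y, trunk
pitch, and six joint angles). Both legs share a single hip point. Joint
angles are inner angles: hip and knee straight = 180°, ankle neutral =
90°, so "knee overextended beyond 175°" reads verbatim against the state.
The equations of motion are assembled exactly per body from COM Jacobians
(`M = Σ Jᵀ M_b J`); correctness is pinned by energy conservation of the
passive chain (< 0.1 % drift over 5 s in the test suite; observed
~1e-13), momentum conservation with gravity off, and exact left-right
mirror symmetry, rather than by the assembly method itself. Anatomical
joint ranges are enforced by one-sided spring-damper stops that are
strictly zero inside the free range and never attract toward the stop.

**Muscle-tendon units.** Seven Hill-type MTUs per leg: soleus (SOL),
tibialis anterior (TA), gastrocnemius (GAS, biarticular knee-ankle),
vastus group (VAS), hamstrings (HAM, biarticular hip-knee), gluteus group
(GLU) and hip flexors (HFL). Each has a contractile element (CE) with
bell-shaped force-length (width 0.56 l_opt, 5 % tails) and Hill
force-velocity curves (curvature K = 5, eccentric plateau N = 1.5), in
series with a quadratic-stiffness tendon (4 % strain at F_max). A parallel
elasticity above l_opt and a buffer elasticity below 0.44 l_opt keep the
CE in a sane range when it is unloaded; both vanish in the nominal
working range, so a muscle whose stimulation is removed loses its force —
CE force fades with activation, and a slack tendon transmits nothing.
The CE velocity closes the CE-SEE force balance by inverting the
force-velocity relation, the standard algebraic-loop treatment for this
muscle family. Muscle path lengths are linear (hip) or cosine-shaped
(knee, ankle) functions of the spanned joint angles; the signed lever arm
at each joint is defined as ∂l_mtu/∂φ exactly, and a finite-difference
test enforces that identity, so muscle forces and joint torques are
energetically consistent.

**Activation.** First-order excitation-contraction coupling
τ da/dt = S − a with τ = 10 ms. Stimulations S are clipped to [0, 1].

**Ground contact.** Each foot carries a heel and a ball contact point. The
vertical force is a one-sided spring (78.5 kN/m) with
penetration-rate-proportional damping (doubling at 0.03 m/s penetration
rate), clamped at zero — the ground never pulls. Horizontally, a stiction
anchor spring-damper acts while the demanded force stays inside the
stiction cone (μ_st = 0.9); beyond it the point slides with kinetic
friction (μ_sl = 0.8, tanh-smoothed around zero velocity). Anchors reset
on lift-off. Contact flags are strictly positive penetration, no
hysteresis.

**Reflex controller.** Decentralized stance/swing reflexes per leg:

* stance SOL, GAS, VAS: positive force feedback
  S = S₀ + G·F(t−Δt)/F_max — loading reinforces extensor drive;
* VAS is inhibited beyond 175° knee angle while the knee extends
  (overextension protection) and, on the trailing leg during double
  support, proportionally to the contralateral load — this is the "knee
  catch release" that lets the knee buckle in preswing;
* stance TA: length feedback with SOL-force suppression;
* stance HAM/GLU/HFL: trunk-balance PD on forward lean, scaled by the
  leg's share of vertical load; at contralateral touchdown the trailing
  leg's HFL is additionally excited and HAM inhibited (swing
  initiation);
* swing HFL: length feedback plus a lean feedforward held from toe-off,
  suppressed by HAM stretch (leg-deceleration handshake); swing GLU and
  HAM: positive force feedback decelerating the leg; swing TA: length
  feedback (foot clearance).

Sensor channels are transported through muscle-specific delays (20 ms
ankle, 10 ms knee, 5 ms hip level) in control-rate ring buffers.

**Numerics.** The closed loop is a delay-differential system, so the
driver uses a fixed-step RK4 integrator (dt = 0.1 ms) with a 1 kHz
controller/neural update and zero-order-held stimulations; outputs are
sampled at the controller rate (1 kHz, millisecond event resolution).
The integrator is bitwise deterministic. Ground-contact mode changes
(stiction/sliding, anchor resets) are resolved at the controller rate,
not by event detection, mirroring the disabled zero-crossing treatment
customary for this contact model. Simulations terminate early when the
hip drops below 70 % of standing height or trunk pitch exceeds 60°
(fall), or when the state leaves the representable range (recorded as a
solver failure, never an exception).

## Parameters and calibration

Segment dimensions and masses (80 kg, 1.80 m scale), muscle architecture
(F_max, l_opt, l_slack, v_max, lever arms), contact constants and reflex
delays follow the published description of this reflex-walker family.
The reflex gains, trunk-balance setpoint/gains, initial state and
activation preloads are configuration data, calibrated **once** by
randomized search against the reference gait surface — completing the
20 s horizon with steady strides near 1.25 s, forward speed near
1.27 m/s, a double-hump vertical GRF, a late-stance (push-off) ankle
power peak, and robustness of the limit cycle to preswing muscle
silencing — and then frozen: every deactivation experiment runs with the
identical controller, with no re-optimization. All values live in
`src/reflexwalk/data/default_model.yaml`; nothing is hard-coded.

The shipped calibration walks the full horizon with stride time
≈ 1.26 s, COM speed ≈ 1.25 m/s, duty factor ≈ 0.57, power
amplification ≈ 3 and stride-to-stride variation well below 2 % (all
recomputed by the acceptance pipeline and test suite). Two traits of the calibrated
limit cycle matter when interpreting deactivation results and are
discussed under Limitations: its double support is shorter than human
(≈ 7 % vs ≈ 12 % of the cycle), and its muscle redundancy differs from
the reference model family's original tuning — SOL can carry
plantarflexion without GAS, and GLU can balance the trunk without HAM —
so the silencing-tolerance boundaries of those muscles sit far higher
than the original model reports.

## The deactivation experiment

A `DeactivationSpec` silences one muscle (GAS, VAS or HAM) bilaterally.
Each leg arms at its own sixth touchdown; a timer started at every
touchdown triggers the window at gc_off · t_stride, where t_stride is
estimated online from that leg's previous stride (seeded 1.25 s), and
holds the muscle's stimulation at zero for t_off seconds. Stimulation —
not activation — is silenced, so force fades with τ rather than
stepping. Overlapping windows from consecutive strides merge. The full
protocol grid is 50 onset increments × 400 duration increments = 20,000
cells per muscle; reduced and preswing-restricted grids (onsets in
50-62 % gc, 0.025 s duration steps) are used for desk-scale work and for
the detailed-trial selection rule: among stable cells (Score = 100) with
preswing onset, take the longest deactivation, breaking ties toward the
earlier onset.

## Analysis layer

All scalar measures are taken from the last complete stride (touchdown to
same-leg touchdown with toe-off and contralateral touchdown inside),
assuming steady, near-symmetric walking:

* **Stability score** = (t_end − t_stride6)/(t_sim_des − t_stride6)·100,
  the percentage of the post-settling horizon survived;
* **ankle power amplification** = |max positive / max negative| net ankle
  joint power over stance (plantarflexion torque × plantarflexion
  velocity positive);
* **alleviation onset t_a** = last negative-to-positive zero crossing of
  ankle power before toe-off; samples with t_a before 35 % of the stride
  are rejected as non-physiological;
* **trailing-leg momentum change** ΔP = P(t_a) − P(t_to) with
  P = Σ mᵢvᵢ over thigh, shank, foot COMs, and the angle between the two
  momentum vectors (arccos of the normalized dot product, 0-180°);
* **global characteristics**: COM forward speed, stride time, step
  length (touching heel vs contralateral COP), duty factor, swing foot
  clearance (peak height of the lowest foot point), peak positive ankle
  power;
* **metabolic cost**: a configurable muscle-energetics model — per-muscle
  maintenance heat (coefficient × a × F_max × l_opt, 1/s) plus CE
  mechanical work rated at 25 % concentric efficiency and a 0.3 eccentric
  cost factor — normalized by body mass × distance (J/(kg·m)). Only
  relative changes between trials are interpreted; the absolute level
  depends on the heat coefficients.
* **GRF line-of-action geometry**: at five phase points around
  contralateral touchdown (1 % gc before TDc; TDc; 11/22/33 % of the
  second double support), the signed perpendicular distance from the
  trailing knee center to the total-GRF line of action through the global
  COP; |d| < 1 cm counts as "through" (knee-radius scale — the analysis
  is qualitative), positive = anterior.

Event detection uses contact-flag transitions (any-point logic for
touchdown/toe-off, heel release with loaded ball for heel-off) and
sign-change-plus-interpolation zero crossings, robust to exact-zero runs.

Two measurement details guard against sampling artifacts of the stiff
contact dynamics. First, the 1 kHz GRF channel aliases the ~10 ms
heel-strike transient, which biases naive stride-impulse integrals by a
few percent; each trial therefore carries a `grf_impulse` channel — the
RK4-quadrature contact impulse accumulated inside the integrator — on
which the impulse-equals-weight-times-stride-time invariant holds to
better than 1 %. Second, the double-hump assessment of the vertical GRF
runs on a zero-phase 10 Hz Butterworth-filtered trace (customary
force-plate processing) with quarter-stance peak merging, so millisecond
impact spikes do not register as humps.

## Synthetic fixtures

`synthetic.make_trial` fabricates GaitTrial-shaped surrogates with fully
known ground truth: periodic flags from a prescribed duty factor and
event phases (defaults at the human anchors: alleviation 78 % and
contralateral touchdown 82 % of stance; preswing inside 50-62 % gc),
double-hump vertical GRFs, an ankle power trace built as two half-sine
lobes whose torque channel is power/velocity on a known ankle rate, a
monotone rearfoot-to-forefoot COP, and known segment-COM velocity
waveforms. Stride time is snapped to an even sample multiple and the
alleviation onset to the grid so that every metric the analysis layer
computes is recovered exactly (events within one sample; scalars to
≤1e-9 relative in the test suite). These surrogates are deliberately not
dynamically consistent — they validate the measurement layer, not the
simulator — so passing them says nothing about the physics, which is
covered by the mechanics oracles and the calibrated reference gait
instead.

## Scale of the shipped experiments

The acceptance pipeline runs desk-scale versions of the protocol: the
preswing selection sweeps probe onsets at 50, 56 and 62 % gc with an
ascending-duration ladder (0.025 s steps; 0.05 s for GAS, whose viable
range is long) that stops after two consecutive failures — viable
regions are contiguous in duration up to isolated boundary cells — rather
than the full 20,000-cell grids. The full grid remains available through
`reflexwalk sweep` / `run_sweep`.

## Known limitations

* 2D sagittal dynamics only; no frontal-plane balance, no trunk
  articulation, no RF muscle.
* The reflex parameter set is a reconstruction calibrated to the
  reference gait surface, not a copy of a published table; absolute
  metric levels (e.g. J/(kg·m)) carry that uncertainty, which is why the
  experiment layer reports relative changes against the same model's
  reference trial.
* The calibrated walker is **more redundant** than the original model
  family: SOL force feedback absorbs the load of a silenced GAS and GLU
  covers trunk balance without HAM, so the upper viability boundaries for
  GAS and HAM silencing are much longer here than the original reports,
  and the maximum-duration selection rule can land on windows where a
  silenced muscle's metabolic saving outweighs the compensation cost.
* Because double support is short and the trailing knee stays near its
  extension stop until ~20 ms before toe-off, the "more dynamic gait"
  response to preswing VAS silencing (faster walking, near-doubled power
  amplification) does not express in this calibration; the measured VAS
  effects are a larger vertical trailing-leg momentum change and higher
  swing foot clearance at roughly unchanged speed.
* The stance knee rests against the soft hyperextension stop through much
  of single support — the passive "GRF keeps the leg straight" posture —
  so knee-buckling onset is driven by weight transfer rather than by an
  extensor force balance; the GRF line of action approaches the knee's
  neutral axis around contralateral touchdown (within 2-3 cm) but does
  not cross behind it before toe-off.
* The fixed-step integrator resolves contact transitions at 0.1 ms; very
  stiff impact transients are smoothed relative to an event-detecting
  variable-step scheme. Failure times near the viability boundary can
  therefore shift by single cells.
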