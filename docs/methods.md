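# Methods

## The task and the measurement problem

In a dyadic handover trial a giver grasps an object resting on a table,
lifts it, carries it toward a receiver, and lets go once the receiver has
grasped it. Grip force of each actor is measured by force sensors in the
object's grasp surfaces; object and wrist positions come from optical
motion capture. Both stream at 100 Hz, synchronized by an LED flash that
marks the start of force acquisition in the camera frames.

Anticipatory grip-force control is read out of these channels through four
per-trial variables: the lift delay (how long the giver needs from first
touch to lift-off — longer when load forces were under-planned), the
maximum transport velocity (lower for heavier objects), and the peak grip
force rate (PGFR) of each actor, the classic index of the weight the actor
*expected* — the force rate is programmed before sensory feedback about
the true weight can arrive.

## Event model

Four events divide the trial; detection operates on filtered signals:

| event | rule | default |
|-------|------|---------|
| A, giver contact | force deviates from pre-trial baseline | ≥ 0.07 N |
| B, lift-off | object vertical position changed from its height at A | ≥ 2 mm |
| C, receiver contact | receiver force deviates from baseline | ≥ 0.09 N |
| D, giver release | giver force back within threshold of baseline | ≤ 0.07 N |

The baseline is the median of the first 20 frames. "Force change" is
interpreted as deviation from that baseline rather than a frame-to-frame
difference; this is robust to sensor offset/drift and matches the semantics
of an *initial contact*. The receiver threshold is deliberately stricter so
that an incidental collision at the reach's end does not count as grasping.
The displacement rule uses absolute change (an accidental drop also ends
the reach-and-grasp phase), with the coordinate frame assumed z-up. Frames
are 0-based and phases are half-open: reach-and-grasp [A, B), transport
[B, C), transfer [C, D). A trial whose detectors fail or whose events come
out of order is rejected with a recorded reason — the automated counterpart
of discarding trials on visual inspection; thresholds are fixed, not tuned
per trial.

The signal used for event D is a design choice: release is declared when
the giver's grip force returns to within the contact threshold (0.07 N,
symmetric to A) of baseline.

## Preprocessing

All channels are low-pass filtered with a second-order Butterworth at
15 Hz. The filter is applied **zero-phase** (forward–backward): event
latencies are read off the filtered signals, and a causal filter would
shift every detected event by the group delay. The cost is a doubled
attenuation, irrelevant this far below Nyquist. Edges use mirror padding of
one settling length; trials begin and end at rest, so reflection introduces
no spurious onsets. Derivatives are central differences (one-sided at the
edges), which are phase-unbiased, so rate peaks are not displaced in time.
Wrist position is the arithmetic midpoint of the radius and ulna markers.

The PGFR picker returns the first local maximum of dF/dt that reaches
30 N/s inside the actor's window — giver: [A, C), receiver: the transfer
phase [C, D). A local maximum is a sample strictly greater than both
neighbouring *distinct* values; a flat plateau resolves to its first
sample, making the rule deterministic on quantized data. Later peaks are
treated as corrective adjustments; sub-threshold bumps are collisions. When
no peak qualifies, the window's absolute maximum is taken and flagged
(`fallback_used`). The giver window endpoint at C (rather than B) is a
logged assumption; the giver's anticipatory pulse always peaks well before
transport ends, so the choice is inert in practice.

## Statistical stage

Each dependent variable belongs to the actor who produced it (kinematic
measures and giver PGFR → the trial's giver; receiver PGFR → the
receiver), so each of the 2·n_dyads participants contributes 60 trials per
variable. Values are z-scored within participant (sample SD), reduced to
participant × size × weight cell means, and fitted with the classical
two-way fully-within ANOVA: each effect is tested against its own
effect-by-subject interaction; with n participants the dfs are weight
(2, 2(n−1)), size (1, n−1), interaction (2, 2(n−1)). No sphericity or
multiple-testing correction is applied. Generalized eta squared uses the
manipulated-factors convention

    ges = SS_effect / (SS_effect + SS_subjects + SS_As + SS_Bs + SS_ABs),

cross-checked against pingouin's `ng2` in the tests. Aggregating trials to
cell means before fitting is itself a choice — the repeated-measures
decomposition needs one value per cell, and trial-level fitting would
change the dfs. Post-hoc paired t-tests between weight levels average over
size first; differences are taken second-minus-first level so a measure
that grows with weight has positive paired Cohen's d = mean(Δ)/SD(Δ).
Outliers beyond 1.5·IQR of the quartiles (linear interpolation) can be
flagged and excluded; on simulated data the conclusions are unchanged
either way, so they are kept by default.

## The simulator

The generator produces full multichannel trials with exact ground truth
from a minimal mechanical model:

- **Timeline.** A minimum-jerk reach ends at giver contact. The load force
  then ramps linearly at r_L (default 50 N/s) after a contact latency t_lat
  (default 125 ms); true lift-off occurs when load = m·g, so the true lift
  delay is t_lat + m·g/r_L — the weight → delay effect emerges from
  mechanics, not from a lookup. Just after lift-off the net upward force is
  the continuing ramp, giving z(τ) = r_L·τ³/(6m); the pipeline's 2 mm
  criterion therefore lags true lift-off by exactly (6·m·d/r_L)^{1/3},
  which the tests use as a closed-form oracle. After a 6 mm ballistic rise
  and a 100 ms settle, a horizontal minimum-jerk transport of 0.40 m
  follows whose peak speed (1.875·distance/duration) is drawn around
  weight-dependent targets 0.47/0.44/0.42 m/s. The receiver grasps at
  arrival; after a hold, the giver's force decays linearly to zero.
- **Grip forces.** Each actor's force is the integral of a bell-shaped
  (Hann) rate pulse whose peak *is* the drawn PGFR: receiver peaks drawn
  around 78/85/89 N/s for 400/700/1000 g (the receiver anticipates weight),
  giver peaks around 96 (small) / 112 (big) N/s, independent of weight by
  construction (the giver cannot know it) — so the size-not-weight pattern
  of the giver is built in, and recovering it is a pipeline property, not a
  statistical accident. A drawn peak below what is needed to hold
  1.2·m·g extends the pulse duration instead (a weaker rate simply takes
  longer to build force); if even the capped duration (1 s) cannot support
  the weight, the trial raises an unliftable-object error.
- **Contact transient.** A small fast force step (0.2 N over 20 ms) is
  superimposed at each true contact, modelling finger-pad compression at
  touch. Its rate (~16 N/s) stays below the 30 N/s peak threshold, but it
  gives the 0.07/0.09 N criteria a physically sharp onset so detected
  contacts land within one sample of the true contact time. Without it, a
  purely smooth anticipatory pulse has quadratic force onset and the
  detected contact would trail truth by tens of milliseconds.
- **Variability and noise.** Per-participant offsets (stable across a
  person's trials: PGFR ±45/35 N/s s.d. for giver/receiver, latency
  ±30 ms, peak speed ±0.05 m/s) sit on top of per-trial draws (PGFR
  ±30/25 N/s, latency ±30 ms, load rate ±10%, speed ±0.04 m/s) and i.i.d.
  Gaussian sensor noise of 0.01 N / 0.2 mm — small relative to the 0.07 N
  and 2 mm criteria, so detection stays stable. Draws are truncated from
  below (PGFR at 40 N/s, speed at 0.32 m/s) to keep every trial physically
  liftable and supra-threshold; the truncation's bias on condition means is
  well under one standard error at n = 1000.
- **Reproducibility.** One master seed; per-trial generators derive from
  (seed, dyad, block, trial) and participant offsets from (seed, dyad), so
  any single trial regenerates in isolation.

Defaults the data do not constrain (reach duration 0.5 s, transport
distance 0.40 m, hold 0.25 s, release 0.25 s, lift height ~1.6 cm) were
chosen once as typical for seated tabletop handovers and left alone; they
move absolute event times but none of the condition contrasts.

### What the simulator does and does not emulate

It reproduces the event structure, the direction and rough magnitude of all
four condition effects, participant idiosyncrasy, trial-to-trial
variability and sensor noise. It does **not** model friction cones,
individual digit forces, marker occlusion or soft-tissue artefact,
force-sensor drift, clock drift between streams (a constant-offset
alignment is assumed), or the possibility that givers partially anticipate
weight from sequence learning. Passing tests therefore certify the
*analysis* — that the detectors and statistics recover known structure
under realistic noise — not that real handover data are this clean; on
real recordings the rejection and fallback paths matter more.

## Calibration checks

The two-parameter lift-timing model is identified from two anchors: solving
detected-delay(0.4 kg) = 249 ms and detected-delay(1.0 kg) = 383 ms for
(t_lat, r_L) via the closed-form model t_lat + m·g/r_L + (6·m·d/r_L)^{1/3}
(the mass-difference equation is monotone in r_L, so a bracketed root find
suffices) gives t_lat = 124.8 ms, r_L = 50.0 N/s. The held-out medium
prediction of the *full pipeline* (simulate → filter → detect) is then
310 ms against the 311 ms reference — the constant-rate model is an
approximation, so agreement at the held-out weight is the informative
check, with detected values quantized to the 10 ms frame grid. The
transport check is analogous with peak speed linear in mass through
0.47/0.42 m/s, predicting 0.445 m/s at 700 g against 0.44.

## Numerical choices and degenerate inputs

Filtering rejects NaN inputs and cutoffs at or above Nyquist. Contact
detection reports the maximum observed deviation when it fails. A release
threshold wider than the force plateau degenerates to the receiver-contact
frame and warns. The ANOVA flags a zero-variance response (F undefined)
instead of dividing by zero; z-scoring refuses constant participants by
name; the IQR rule requires n ≥ 4. Problem sizes in the shipped analyses —
20 dyads / 2400 trials end-to-end, 500-trial Monte-Carlo event recovery,
1000-draw calibration checks — were chosen to make the statistical
assertions stable at comfortable margins; the full suite runs in well under
a minute.
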