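# handover-analysis

Simulation and analysis pipeline for **dyadic object-handover experiments**:
a giver grasps an object of unknown weight, lifts it and transports it to a
receiver, who grasps it and takes over the load. The scientific question this
kind of experiment addresses is anticipatory grip-force control in joint
action — in particular whether the *receiver* can infer the object's weight
purely from watching the giver lift it, which shows up as a weight-scaled
peak grip force rate in the receiver even though the weight changes
unpredictably from trial to trial.

The package is aimed at movement scientists who want a tested, reproducible
implementation of the standard grasp–lift event analysis (and a ground-truth
simulator to validate it against), rather than one-off analysis scripts.

## What it computes

Per trial, from 100 Hz grip-force and motion-capture channels (filtered with
a second-order zero-phase Butterworth low-pass at 15 Hz):

- **Phase segmentation** by four events: giver contact *A* (force deviates
  ≥ 0.07 N from baseline), object lift-off *B* (≥ 2 mm vertical
  displacement), receiver contact *C* (≥ 0.09 N, stricter to skip collision
  bumps) and giver release *D* (force back within 0.07 N of baseline).
  Phases: reach-and-grasp [A, B), transport [B, C), transfer [C, D).
- **Lift delay** = (B − A)/fs — the time the giver needs to build up load
  force; it grows with object mass *m* as the load force must reach *m·g*.
- **Maximum lift velocity** — peak 3-D speed of the wrist-marker midpoint
  during transport.
- **Peak grip force rate (PGFR)** — the value of the *first* local maximum
  of dF/dt ≥ 30 N/s in the actor's window (later peaks are corrective);
  if no peak qualifies, the window's absolute maximum is used and flagged.

At the experiment level, each dependent variable is z-scored within
participant, reduced to participant × size × weight cell means, and fitted
with a classical two-way fully-within ANOVA. Effect sizes use generalized
eta squared,

    η²_G = SS_effect / (SS_effect + SS_subjects + Σ SS_error),

and post-hoc paired *t*-tests between weight levels report the paired
Cohen's *d* = mean(Δ)/SD(Δ).

The **simulator** (`handover.simulate`) generates complete trials with exact
ground truth from a small mechanical model: load force ramps at rate *r_L*
after a contact latency *t_lat*, so true lift-off occurs at
*t_lat + m·g/r_L*; the 2 mm detection criterion lags it by the closed form
*(6·m·d/r_L)^{1/3}*; transport is a minimum-jerk move (peak speed
1.875·distance/duration); grip forces rise as integrated bell-shaped rate
pulses whose peaks carry the condition effects (receiver PGFR scales with
weight, giver PGFR with size only).

## Worked example

```
python analysis/01_simulate_experiment.py   # 20 dyads, 2400 trials
python analysis/02_run_analysis.py          # pipeline + ANOVA
python analysis/03_calibration_checks.py    # two-point interpolation checks
```

`02_run_analysis.py` simulates 20 dyads (2400 trials, seed 11), rejects
none, and prints the detected condition means:

| weight | lift delay (ms) | max lift velocity (m/s) | receiver PGFR (N/s) |
|--------|-----------------|-------------------------|---------------------|
| light  | 246.3 ± 47.3    | 0.472 ± 0.064           | 87.8 ± 37.4         |
| medium | 316.3 ± 46.9    | 0.445 ± 0.066           | 93.9 ± 37.9         |
| heavy  | 381.9 ± 50.6    | 0.425 ± 0.064           | 97.3 ± 38.7         |

and the ANOVA summary (40 participants), e.g. weight on lift delay
F(2,78) = 6768.0, p < .001, η²_G = 0.98; weight on receiver PGFR
F(2,78) = 37.0, p < .001, η²_G = 0.27; size on giver PGFR F(1,39) = 182.8,
p < .001, η²_G = 0.46 while weight on giver PGFR stays null
(F(2,78) = 0.41, p = .66) — the signature of a giver who cannot anticipate
the weight and a receiver who can. Heavier objects mean longer lift delays,
slower transport, stronger receiver grip-force scaling.

`03_calibration_checks.py` solves the simulator's two lift-timing parameters
from the light/heavy anchors (249/383 ms → t_lat = 124.8 ms,
r_L = 50.0 N/s) and reports the held-out medium prediction: 310 ms detected
vs. 311 ms reference (−0.3%); the linear-in-mass speed interpolation gives
0.445 m/s detected vs. 0.44 reference (+1.1%).

There is also a CLI for file-based stage-by-stage runs:
`handover simulate|segment|features|stats|run-all` (see `handover --help`).

## Layout

- `src/handover/` — library: `schedule`, `simulate`, `trial_io`,
  `preprocessing`, `events`, `features`, `stats`, `calibration`,
  `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers writing tables to `results/`.
- `docs/methods.md` — model, assumptions, parameter choices, limitations.
- `tests/` — unit, property and end-to-end tests (oracle cross-checks
  against brute-force scans and pingouin).
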