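#!/usr/bin/env python
"""Interpolation checks of the noise-free timing and transport models.

Two two-point calibrations, each validated at the held-out middle weight:

1. Lift delay. The contact latency and constant load-force rate are solved
   in closed form so the pipeline-detected lift delays at 400 g and 1000 g
   equal 249 ms and 383 ms; the detected 700 g delay is then compared with
   the 311 ms reference value.
2. Maximum lift velocity. The peak transport speed is linear in object mass
   through 0.47 m/s (400 g) and 0.42 m/s (1000 g); the detected 700 g
   maximum is compared with the 0.44 m/s reference value.

Writes results/calibration_checks.csv.
"""

from dataclasses import replace
from pathlib import Path

import pandas as pd

from handover.calibration import calibrate_lift_delay_params, interpolate_peak_speed
from handover.pipeline import PipelineSettings, process_trial
from handover.schedule import Weight
from handover.simulate import SimulatorConfig, simulate_trial

import sys

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "tests"))
from conftest import make_condition  # noqa: E402

ROOT = Path(__file__).resolve().parents[1]

DELAY_REFS_MS = {Weight.LIGHT: 249.0, Weight.MEDIUM: 311.0, Weight.HEAVY: 383.0}
SPEED_REFS = {Weight.LIGHT: 0.47, Weight.MEDIUM: 0.44, Weight.HEAVY: 0.42}


def main() -> None:
    rows = []

    t_lat, r_load = calibrate_lift_delay_params({0.400: 0.249, 1.000: 0.383})
    print(
        f"lift-delay calibration: contact latency {t_lat * 1000:.1f} ms, "
        f"load-force rate {r_load:.2f} N/s"
    )
    cfg = replace(
        SimulatorConfig().noise_free(), contact_latency=t_lat, load_force_rate=r_load
    )
    for w, ref in DELAY_REFS_MS.items():
        rec, _ = simulate_trial(make_condition(weight=w), cfg, rng=0)
        det = process_trial(rec, PipelineSettings(simulator=cfg)).lift_delay
        rows.append(
            {
                "check": "lift_delay_ms",
                "weight": w.value,
                "role": "anchor" if w != Weight.MEDIUM else "held-out",
                "detected": det,
                "reference": ref,
                "rel_err_pct": round(100 * (det - ref) / ref, 2),
            }
        )

    v_med = interpolate_peak_speed({0.400: 0.47, 1.000: 0.42}, 0.700)
    cfg2 = replace(
        SimulatorConfig().noise_free(),
        peak_speed={Weight.LIGHT: 0.47, Weight.MEDIUM: v_med, Weight.HEAVY: 0.42},
    )
    for w, ref in SPEED_REFS.items():
        rec, _ = simulate_trial(make_condition(weight=w), cfg2, rng=0)
        det = process_trial(rec, PipelineSettings(simulator=cfg2)).max_lift_velocity
        rows.append(
            {
                "check": "max_lift_velocity_m_s",
                "weight": w.value,
                "role": "anchor" if w != Weight.MEDIUM else "held-out",
                "detected": round(det, 5),
                "reference": ref,
                "rel_err_pct": round(100 * (det - ref) / ref, 2),
            }
        )

    df = pd.DataFrame(rows)
    (ROOT / "results").mkdir(exist_ok=True)
    df.to_csv(ROOT / "results" / "calibration_checks.csv", index=False)
    print(df.to_string(index=False))
    print("\nwrote results/calibration_checks.csv")


if __name__ == "__main__":
    main()
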