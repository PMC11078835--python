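"""Closed-form timing model of the noise-free simulator, and its inversion.

In the noise-free simulator the pipeline-detected lift delay for an object of
mass ``m`` is (up to frame quantization)

    delay(m) = t_lat + m*g / r_L + (6*m*d / r_L)**(1/3)

where ``t_lat`` is the contact latency, ``r_L`` the constant load-force rate
and ``d`` the 2 mm lift-off displacement criterion — the cube-root term is
the deterministic lag between true lift-off and the 2 mm detection under the
integrated constant-ramp kinematics. Given two printed condition means as
anchors (light and heavy), the two free parameters are recovered exactly:
the difference of the two equations depends on ``r_L`` alone and is strictly
decreasing in it, so a bracketing root find followed by back-substitution
solves the system.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from handover.simulate import GRAVITY

__all__ = [
    "liftoff_detection_lag",
    "lift_delay_model",
    "calibrate_lift_delay_params",
    "interpolate_peak_speed",
]


def liftoff_detection_lag(
    mass_kg: float, load_force_rate: float, displacement_m: float = 0.002
) -> float:
    """Time (s) for the object to rise ``displacement_m`` after true lift-off
    under the constant load ramp: (6*m*d / r_L)**(1/3)."""
    return (6.0 * mass_kg * displacement_m / load_force_rate) ** (1.0 / 3.0)


def lift_delay_model(
    mass_kg: float,
    contact_latency: float,
    load_force_rate: float,
    displacement_m: float = 0.002,
    gravity: float = GRAVITY,
) -> float:
    """Pipeline-detected lift delay (s) predicted by the noise-free model."""
    return (
        contact_latency
        + mass_kg * gravity / load_force_rate
        + liftoff_detection_lag(mass_kg, load_force_rate, displacement_m)
    )


def calibrate_lift_delay_params(
    anchors: dict[float, float],
    displacement_m: float = 0.002,
    gravity: float = GRAVITY,
) -> tuple[float, float]:
    """Solve for (contact_latency, load_force_rate) from two delay anchors.

    ``anchors`` maps object mass (kg) to the target detected lift delay (s),
    e.g. ``{0.400: 0.249, 1.000: 0.383}``.
    """
    if len(anchors) != 2:
        raise ValueError("exactly two (mass, delay) anchors required")
    (m1, d1), (m2, d2) = sorted(anchors.items())
    if d2 <= d1:
        raise ValueError("delay must increase with mass")

    def delta(r: float) -> float:
        return (
            (m2 - m1) * gravity / r
            + liftoff_detection_lag(m2, r, displacement_m)
            - liftoff_detection_lag(m1, r, displacement_m)
            - (d2 - d1)
        )

    r_load = brentq(delta, 1.0, 5000.0, xtol=1e-12)
    t_lat = d1 - m1 * gravity / r_load - liftoff_detection_lag(m1, r_load, displacement_m)
    if t_lat <= 0:
        raise ValueError(
            f"anchors imply non-positive contact latency ({t_lat:.4f} s)"
        )
    return float(t_lat), float(r_load)


def interpolate_peak_speed(
    anchors: dict[float, float], mass_kg: float
) -> float:
    """Linear-in-mass peak transport speed through two anchors, e.g.
    ``{0.400: 0.47, 1.000: 0.42}`` evaluated at 0.700 kg."""
    if len(anchors) != 2:
        raise ValueError("exactly two (mass, speed) anchors required")
    (m1, v1), (m2, v2) = sorted(anchors.items())
    return float(v1 + (v2 - v1) * (mass_kg - m1) / (m2 - m1))
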