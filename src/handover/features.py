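"""Per-trial outcome variables: lift delay, maximum lift velocity, peak grip
force rates.

Lift delay is the time from giver-object contact to object lift-off (events
A to B). Maximum lift velocity is the peak 3-D speed of the wrist midpoint
during the transport phase [B, C). The peak grip force rate (PGFR) of each
actor is the value of the *first* local maximum of the grip-force rate that
reaches 30 N/s inside the actor's window — later peaks are corrective
adjustments, and sub-threshold bumps are incidental collisions. When no
qualifying peak exists (rare), the window's absolute maximum is used and the
fallback is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from handover.events import EventSet, PhaseSegmentation, PipelineConfig
from handover.preprocessing import derivative, wrist_midpoint
from handover.schedule import TrialCondition
from handover.trial_io import TrialRecording

__all__ = [
    "TrialFeatures",
    "lift_delay",
    "max_lift_velocity",
    "peak_grip_force_rate",
    "extract_features",
]


@dataclass(frozen=True)
class TrialFeatures:
    """The four outcome variables of one trial."""

    lift_delay: float           # ms
    max_lift_velocity: float    # m/s
    giver_pgfr: float           # N/s
    receiver_pgfr: float        # N/s
    receiver_pgfr_fallback_used: bool
    giver_pgfr_fallback_used: bool
    condition: TrialCondition

    def __post_init__(self) -> None:
        if self.lift_delay <= 0:
            raise ValueError("lift_delay must be positive")
        for name in ("max_lift_velocity", "giver_pgfr", "receiver_pgfr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def lift_delay(events: EventSet, fs: float) -> float:
    """Lift delay in ms: (B - A) / fs * 1000."""
    return (events.B_liftoff - events.A_contact_giver) / fs * 1000.0


def max_lift_velocity(
    wrist_mid: np.ndarray, transport: tuple[int, int], fs: float
) -> float:
    """Maximum 3-D speed (m/s) of the wrist midpoint within [B, C).

    ``wrist_mid`` is the full (n, 3) midpoint series in mm; the derivative is
    taken on the full series (so the interval edges use genuine central
    differences) and the maximum of the Euclidean speed is read off inside
    the transport interval.
    """
    b, c = transport
    wrist_mid = np.asarray(wrist_mid, dtype=float)
    if c - b < 3:
        raise ValueError(f"transport interval [{b}, {c}) shorter than 3 samples")
    if not 0 <= b < c <= wrist_mid.shape[0]:
        raise ValueError(f"transport interval [{b}, {c}) outside recording")
    vel = derivative(wrist_mid / 1000.0, fs)  # m/s
    speed = np.linalg.norm(vel, axis=1)
    return float(speed[b:c].max())


def _first_plateau_local_maxima(w: np.ndarray) -> list[int]:
    """Indices of local maxima: samples strictly greater than both distinct
    neighbours; a flat plateau resolves to its first sample. Endpoints are
    never maxima."""
    n = w.shape[0]
    out: list[int] = []
    i = 1
    while i < n - 1:
        if w[i] > w[i - 1]:
            j = i
            while j + 1 < n and w[j + 1] == w[i]:
                j += 1
            if j < n - 1 and w[j + 1] < w[i]:
                out.append(i)
            i = j + 1
        else:
            i += 1
    return out


def peak_grip_force_rate(
    force_rate: np.ndarray,
    window: tuple[int, int],
    min_peak: float = 30.0,
) -> tuple[float, bool]:
    """First supra-threshold local maximum of the grip-force rate in a window.

    Returns ``(value, fallback_used)``. The value is the first local maximum
    >= ``min_peak`` inside ``[start, stop)``; if none exists, the window's
    absolute maximum with ``fallback_used=True``.
    """
    if min_peak <= 0:
        raise ValueError("min_peak must be strictly positive")
    start, stop = window
    force_rate = np.asarray(force_rate, dtype=float)
    if not 0 <= start < stop <= force_rate.shape[0]:
        raise ValueError(f"window [{start}, {stop}) outside signal")
    w = force_rate[start:stop]
    if w.size == 0:
        raise ValueError("empty window")
    for idx in _first_plateau_local_maxima(w):
        if w[idx] >= min_peak:
            return float(w[idx]), False
    return float(w.max()), True


def extract_features(
    rec: TrialRecording,
    events: EventSet,
    phases: PhaseSegmentation,
    config: PipelineConfig | None = None,
) -> TrialFeatures:
    """Assemble all outcome variables for one segmented (filtered) trial.

    The giver's PGFR window spans initial contact to receiver contact
    [A, C); the receiver's spans the transfer phase [C, D).
    """
    if config is None:
        config = PipelineConfig()
    fs = rec.fs
    giver_rate = derivative(rec.giver_force, fs)
    receiver_rate = derivative(rec.receiver_force, fs)

    giver_window = (events.A_contact_giver, events.C_contact_receiver)
    giver_pgfr, giver_fb = peak_grip_force_rate(
        giver_rate, giver_window, config.pgfr_min_peak
    )
    receiver_pgfr, receiver_fb = peak_grip_force_rate(
        receiver_rate, phases.transfer, config.pgfr_min_peak
    )
    mid = wrist_midpoint(rec.radius_marker, rec.ulna_marker)
    return TrialFeatures(
        lift_delay=lift_delay(events, fs),
        max_lift_velocity=max_lift_velocity(mid, phases.transport, fs),
        giver_pgfr=giver_pgfr,
        receiver_pgfr=receiver_pgfr,
        receiver_pgfr_fallback_used=receiver_fb,
        giver_pgfr_fallback_used=giver_fb,
        condition=rec.meta.condition,
    )
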