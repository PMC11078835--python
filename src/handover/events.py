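"""Detection of the four phase-dividing events and the phase segmentation.

A handover trial is divided by four events:

* **A** — initial giver-object contact: earliest frame at which the giver's
  filtered grip force deviates from its pre-trial baseline by >= 0.07 N.
* **B** — object lift-off: earliest frame (at or after A) at which the
  object's vertical position has changed by >= 2 mm from its height at A.
* **C** — initial receiver-object contact: as A but on the receiver's force
  with the stricter 0.09 N threshold, which rejects incidental collision
  bumps when the receiver first reaches the object.
* **D** — giver release: earliest frame (at or after C) at which the giver's
  force has returned to within 0.07 N of the pre-trial baseline.

The phases are the half-open frame intervals reach-and-grasp [A, B),
transport [B, C) and transfer [C, D). "Force change" is interpreted as a
deviation from a baseline (the median of the first ``baseline_window``
frames), not a frame-to-frame difference, which is robust to sensor offset
and drift. A trial on which any detector fails, or whose events violate
A < B < C < D, is rejected with a reason — the automated analogue of
discarding trials on visual inspection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from handover.trial_io import TrialRecording

__all__ = [
    "PipelineConfig",
    "EventSet",
    "PhaseSegmentation",
    "SegmentationError",
    "NoContactError",
    "NoLiftError",
    "NoReleaseError",
    "TrialRejected",
    "detect_contact",
    "detect_liftoff",
    "detect_release",
    "segment_trial",
]


class SegmentationError(RuntimeError):
    """Base class for event-detection failures."""


class NoContactError(SegmentationError):
    """Force never deviated from baseline by the contact threshold."""

    def __init__(self, message: str, max_deviation: float):
        super().__init__(f"{message} (max deviation observed: {max_deviation:.4g} N)")
        self.max_deviation = max_deviation


class NoLiftError(SegmentationError):
    """Object vertical position never changed by the lift-off displacement."""


class NoReleaseError(SegmentationError):
    """Giver force never returned to baseline after receiver contact."""


class TrialRejected(SegmentationError):
    """Trial excluded from analysis, with a reason."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass(frozen=True)
class PipelineConfig:
    """Detection thresholds of the segmentation stage (defaults as tuned
    for the 100 Hz handover recordings)."""

    giver_contact_threshold: float = 0.07    # N
    receiver_contact_threshold: float = 0.09  # N
    liftoff_displacement: float = 2.0        # mm
    pgfr_min_peak: float = 30.0              # N/s
    release_threshold: float = 0.07          # N
    baseline_window: int = 20                # frames

    def __post_init__(self) -> None:
        for name in (
            "giver_contact_threshold",
            "receiver_contact_threshold",
            "liftoff_displacement",
            "pgfr_min_peak",
            "release_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.receiver_contact_threshold < self.giver_contact_threshold:
            raise ValueError(
                "receiver contact threshold must be >= giver contact threshold"
            )
        if self.baseline_window < 1:
            raise ValueError("baseline_window must be >= 1")


@dataclass(frozen=True)
class EventSet:
    """Frame indices (0-based) of the four phase-dividing events."""

    A_contact_giver: int
    B_liftoff: int
    C_contact_receiver: int
    D_release_giver: int

    def __post_init__(self) -> None:
        a, b, c, d = (
            self.A_contact_giver,
            self.B_liftoff,
            self.C_contact_receiver,
            self.D_release_giver,
        )
        if not a < b < c < d:
            raise ValueError(f"events must satisfy A < B < C < D, got {(a, b, c, d)}")
        if a < 0:
            raise ValueError("event frames must be non-negative")


@dataclass(frozen=True)
class PhaseSegmentation:
    """Half-open frame intervals of the three analysis phases."""

    reach_and_grasp: tuple[int, int]  # [A, B)
    transport: tuple[int, int]        # [B, C)
    transfer: tuple[int, int]         # [C, D)

    @classmethod
    def from_events(cls, ev: EventSet) -> "PhaseSegmentation":
        return cls(
            reach_and_grasp=(ev.A_contact_giver, ev.B_liftoff),
            transport=(ev.B_liftoff, ev.C_contact_receiver),
            transfer=(ev.C_contact_receiver, ev.D_release_giver),
        )


def detect_contact(
    force: np.ndarray, threshold: float, baseline_window: int = 20
) -> int:
    """Earliest frame at which ``force`` deviates from baseline by >= threshold.

    The baseline is the median of the first ``baseline_window`` frames, which
    are assumed to precede any contact.
    """
    force = np.asarray(force, dtype=float)
    if force.shape[0] < baseline_window:
        raise ValueError(
            f"signal ({force.shape[0]} frames) shorter than baseline window "
            f"({baseline_window})"
        )
    baseline = float(np.median(force[:baseline_window]))
    deviation = np.abs(force - baseline)
    hits = np.flatnonzero(deviation >= threshold)
    if hits.size == 0:
        raise NoContactError("no contact detected", float(deviation.max()))
    return int(hits[0])


def detect_liftoff(
    object_z: np.ndarray, start_frame: int, displacement: float = 2.0
) -> int:
    """Earliest frame >= ``start_frame`` at which the object's vertical
    position has changed by >= ``displacement`` (mm) from its height at
    ``start_frame`` (absolute change, so an accidental drop also counts)."""
    object_z = np.asarray(object_z, dtype=float)
    if not 0 <= start_frame < object_z.shape[0]:
        raise ValueError(f"start_frame {start_frame} outside signal")
    reference = object_z[start_frame]
    hits = np.flatnonzero(np.abs(object_z[start_frame:] - reference) >= displacement)
    if hits.size == 0:
        raise NoLiftError(
            f"object never moved {displacement} mm vertically after frame "
            f"{start_frame}"
        )
    return int(start_frame + hits[0])


def detect_release(
    giver_force: np.ndarray,
    after_frame: int,
    threshold: float = 0.07,
    baseline_window: int = 20,
) -> int:
    """Earliest frame >= ``after_frame`` (receiver contact) at which the
    giver's force is back within ``threshold`` of the pre-trial baseline."""
    giver_force = np.asarray(giver_force, dtype=float)
    if not 0 <= after_frame < giver_force.shape[0]:
        raise ValueError(f"after_frame {after_frame} outside signal")
    baseline = float(np.median(giver_force[:baseline_window]))
    deviation = np.abs(giver_force[after_frame:] - baseline)
    hits = np.flatnonzero(deviation <= threshold)
    if hits.size == 0:
        raise NoReleaseError("giver force never returned to baseline")
    frame = int(after_frame + hits[0])
    if frame == after_frame:
        warnings.warn(
            "giver force already within release threshold at receiver contact; "
            "release event degenerate",
            RuntimeWarning,
            stacklevel=2,
        )
    return frame


def segment_trial(
    rec: TrialRecording, config: PipelineConfig | None = None
) -> tuple[EventSet, PhaseSegmentation]:
    """Detect events A-D on a *preprocessed* (filtered) recording.

    Raises :class:`TrialRejected` with a reason when any detector fails or
    the detected events are out of order.
    """
    if config is None:
        config = PipelineConfig()
    try:
        a = detect_contact(
            rec.giver_force, config.giver_contact_threshold, config.baseline_window
        )
    except NoContactError as err:
        raise TrialRejected("no giver contact") from err
    try:
        b = detect_liftoff(rec.object_pos[:, 2], a, config.liftoff_displacement)
    except NoLiftError as err:
        raise TrialRejected("no lift") from err
    try:
        c = detect_contact(
            rec.receiver_force,
            config.receiver_contact_threshold,
            config.baseline_window,
        )
    except NoContactError as err:
        raise TrialRejected("no receiver contact") from err
    try:
        d = detect_release(
            rec.giver_force, c, config.release_threshold, config.baseline_window
        )
    except NoReleaseError as err:
        raise TrialRejected("no release") from err
    try:
        events = EventSet(a, b, c, d)
    except ValueError as err:
        raise TrialRejected(f"event order violation: {err}") from err
    return events, PhaseSegmentation.from_events(events)
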