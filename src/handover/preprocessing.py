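"""Signal conditioning: low-pass filtering, differentiation, wrist midpoint.

All raw channels are low-pass filtered with a second-order Butterworth at
15 Hz before any event detection. The filter is applied zero-phase
(forward-backward) so detected event latencies carry no group delay; the
price is a doubled attenuation, which is irrelevant this far below Nyquist.
Derivatives use central differences (one-sided at the edges), which are
phase-unbiased and therefore do not shift rate peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from handover.trial_io import TrialRecording

__all__ = [
    "FilterSpec",
    "lowpass",
    "derivative",
    "wrist_midpoint",
    "preprocess_recording",
]


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth low-pass specification (order 2, 15 Hz by default)."""

    order: int = 2
    cutoff: float = 15.0
    fs: float = 100.0

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if not 0 < self.cutoff < self.fs / 2:
            raise ValueError(
                f"cutoff must lie in (0, fs/2) = (0, {self.fs / 2}); "
                f"got {self.cutoff}"
            )


def lowpass(x: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Zero-phase Butterworth low-pass along axis 0.

    Accepts 1-D signals or (n, k) channel stacks. Edge transients are
    suppressed by mirror (even) padding of one settling length; trials begin
    and end at rest, so reflection introduces no spurious onsets.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains NaN or infinite samples")
    n = x.shape[0]
    if n <= 3 * spec.order:
        raise ValueError(f"signal too short ({n}) for order-{spec.order} filter")
    b, a = signal.butter(spec.order, spec.cutoff, btype="low", fs=spec.fs)
    padlen = min(n - 1, 3 * (max(len(a), len(b)) - 1) * 10)
    return signal.filtfilt(b, a, x, axis=0, padtype="even", padlen=padlen)


def derivative(x: np.ndarray, fs: float) -> np.ndarray:
    """First time derivative in input-units per second.

    Central differences in the interior, one-sided at both edges; same
    length as the input. Works on 1-D signals and (n, k) stacks.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("derivative requires at least 3 samples")
    return np.gradient(x, 1.0 / fs, axis=0)


def wrist_midpoint(radius: np.ndarray, ulna: np.ndarray) -> np.ndarray:
    """Per-sample arithmetic mean of the radius and ulna marker positions."""
    radius = np.asarray(radius, dtype=float)
    ulna = np.asarray(ulna, dtype=float)
    if radius.shape != ulna.shape:
        raise ValueError(
            f"marker series differ in shape: {radius.shape} vs {ulna.shape}"
        )
    return 0.5 * (radius + ulna)


def preprocess_recording(rec: TrialRecording, spec: FilterSpec | None = None) -> TrialRecording:
    """Return a copy of the recording with all channels low-pass filtered."""
    if spec is None:
        spec = FilterSpec(fs=rec.fs)
    elif spec.fs != rec.fs:
        spec = replace(spec, fs=rec.fs)
    return TrialRecording(
        time=rec.time.copy(),
        giver_force=lowpass(rec.giver_force, spec),
        receiver_force=lowpass(rec.receiver_force, spec),
        object_pos=lowpass(rec.object_pos, spec),
        radius_marker=lowpass(rec.radius_marker, spec),
        ulna_marker=lowpass(rec.ulna_marker, spec),
        meta=rec.meta,
    )
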