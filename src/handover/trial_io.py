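"""On-disk trial format and force/mocap stream synchronization.

A trial is stored as a pair of files: a CSV with the synchronized channels
(columns ``t, Fg, Fr, ox, oy, oz, rx, ry, rz, ux, uy, uz``) and a JSON
sidecar with the metadata (condition, sampling rate, units, sync frames).
Units are fixed to seconds, newtons and millimetres; a sidecar declaring
metre positions is converted on read.

Force and motion-capture acquisition start at different times; a flashing
LED, visible to the cameras, marks the mocap frame at which the force
recording began. :func:`sync_streams` aligns the two streams on that frame
and trims them to their common interval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from handover.schedule import Size, TrialCondition, Weight

__all__ = [
    "CSV_COLUMNS",
    "TrialMetadata",
    "TrialRecording",
    "TrialFormatError",
    "ForceStream",
    "MocapStream",
    "write_trial",
    "read_trial",
    "sync_streams",
]

CSV_COLUMNS = ["t", "Fg", "Fr", "ox", "oy", "oz", "rx", "ry", "rz", "ux", "uy", "uz"]

DEFAULT_UNITS = {"time": "s", "force": "N", "position": "mm"}


class TrialFormatError(ValueError):
    """Raised when a trial file pair is missing, malformed or inconsistent."""


@dataclass
class TrialMetadata:
    """Condition and acquisition metadata attached to one trial."""

    condition: TrialCondition
    fs: float = 100.0
    led_onset_frame_mocap: int = 0
    force_start_frame: int = 0
    units: dict = field(default_factory=lambda: dict(DEFAULT_UNITS))

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.led_onset_frame_mocap < 0:
            raise ValueError("led_onset_frame_mocap must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["condition"]["size"] = self.condition.size.value
        d["condition"]["weight"] = self.condition.weight.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrialMetadata":
        cond = d["condition"]
        condition = TrialCondition(
            dyad_id=cond["dyad_id"],
            block=int(cond["block"]),
            trial_in_block=int(cond["trial_in_block"]),
            giver_id=cond["giver_id"],
            receiver_id=cond["receiver_id"],
            size=Size(cond["size"]),
            weight=Weight(cond["weight"]),
        )
        return cls(
            condition=condition,
            fs=float(d["fs"]),
            led_onset_frame_mocap=int(d.get("led_onset_frame_mocap", 0)),
            force_start_frame=int(d.get("force_start_frame", 0)),
            units=dict(d.get("units", DEFAULT_UNITS)),
        )


@dataclass
class TrialRecording:
    """Synchronized multi-channel time series for one handover trial.

    All channels share one uniform time grid at ``meta.fs``; forces in N,
    positions in mm.
    """

    time: np.ndarray          # (n,) s
    giver_force: np.ndarray   # (n,) N
    receiver_force: np.ndarray  # (n,) N
    object_pos: np.ndarray    # (n, 3) mm
    radius_marker: np.ndarray  # (n, 3) mm
    ulna_marker: np.ndarray   # (n, 3) mm
    meta: TrialMetadata

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        n = self.time.shape[0]
        if n < 2:
            raise TrialFormatError("recording must contain at least 2 samples")
        for name in ("giver_force", "receiver_force"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise TrialFormatError(
                    f"channel '{name}' has length {arr.shape[0]}, expected {n}"
                )
            setattr(self, name, arr)
        for name in ("object_pos", "radius_marker", "ulna_marker"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n, 3):
                raise TrialFormatError(
                    f"channel '{name}' has shape {arr.shape}, expected ({n}, 3)"
                )
            setattr(self, name, arr)
        dt = np.diff(self.time)
        expected = 1.0 / self.meta.fs
        if np.any(dt <= 0) or np.max(np.abs(dt - expected)) > 1e-6:
            raise TrialFormatError(
                f"time grid is not uniform at fs={self.meta.fs} Hz"
            )
        if not np.all(np.isfinite(self._stack())):
            raise TrialFormatError("recording contains non-finite samples")

    def _stack(self) -> np.ndarray:
        return np.column_stack(
            [
                self.time,
                self.giver_force,
                self.receiver_force,
                self.object_pos,
                self.radius_marker,
                self.ulna_marker,
            ]
        )

    @property
    def n_samples(self) -> int:
        return self.time.shape[0]

    @property
    def fs(self) -> float:
        return self.meta.fs


def _paths(path: str | Path) -> tuple[Path, Path]:
    base = Path(path)
    if base.suffix == ".csv":
        base = base.with_suffix("")
    return base.with_suffix(".csv"), base.with_suffix(".json")


def write_trial(rec: TrialRecording, path: str | Path) -> tuple[Path, Path]:
    """Write a trial as ``<path>.csv`` + ``<path>.json`` and return the paths."""
    csv_path, json_path = _paths(path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(rec._stack(), columns=CSV_COLUMNS)
    # %.17g guarantees exact float64 round-trip.
    df.to_csv(csv_path, index=False, float_format="%.17g")
    json_path.write_text(json.dumps(rec.meta.to_dict(), indent=1))
    return csv_path, json_path


def read_trial(path: str | Path) -> TrialRecording:
    """Read a trial file pair written by :func:`write_trial`.

    Raises :class:`TrialFormatError` on a missing sidecar, malformed header,
    channel length mismatch, undeclared/unknown units or a non-uniform time
    grid. Positions declared in metres are converted to millimetres.
    """
    csv_path, json_path = _paths(path)
    if not json_path.exists():
        raise TrialFormatError(f"missing metadata sidecar: {json_path}")
    if not csv_path.exists():
        raise TrialFormatError(f"missing trial data file: {csv_path}")
    meta = TrialMetadata.from_dict(json.loads(json_path.read_text()))

    df = pd.read_csv(csv_path)
    if list(df.columns) != CSV_COLUMNS:
        raise TrialFormatError(
            f"malformed header: expected columns {CSV_COLUMNS}, "
            f"got {list(df.columns)}"
        )
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise TrialFormatError(f"missing samples in channel(s) {bad}")

    pos_unit = meta.units.get("position")
    if pos_unit not in ("mm", "m"):
        raise TrialFormatError(f"undeclared or unsupported position unit: {pos_unit!r}")
    if meta.units.get("force") != "N":
        raise TrialFormatError(f"unsupported force unit: {meta.units.get('force')!r}")
    scale = 1000.0 if pos_unit == "m" else 1.0
    meta.units["position"] = "mm"

    return TrialRecording(
        time=df["t"].to_numpy(),
        giver_force=df["Fg"].to_numpy(),
        receiver_force=df["Fr"].to_numpy(),
        object_pos=df[["ox", "oy", "oz"]].to_numpy() * scale,
        radius_marker=df[["rx", "ry", "rz"]].to_numpy() * scale,
        ulna_marker=df[["ux", "uy", "uz"]].to_numpy() * scale,
        meta=meta,
    )


@dataclass
class ForceStream:
    """Raw force acquisition: giver and receiver grip force at fs (N)."""

    giver_force: np.ndarray
    receiver_force: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.giver_force = np.asarray(self.giver_force, dtype=float)
        self.receiver_force = np.asarray(self.receiver_force, dtype=float)
        if self.giver_force.shape != self.receiver_force.shape:
            raise TrialFormatError("force channels differ in length")

    def __len__(self) -> int:
        return self.giver_force.shape[0]


@dataclass
class MocapStream:
    """Raw motion capture: object and wrist marker positions at fs (mm)."""

    object_pos: np.ndarray
    radius_marker: np.ndarray
    ulna_marker: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        for name in ("object_pos", "radius_marker", "ulna_marker"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise TrialFormatError(f"mocap channel '{name}' must be (n, 3)")
            setattr(self, name, arr)
        if not (
            len(self.object_pos) == len(self.radius_marker) == len(self.ulna_marker)
        ):
            raise TrialFormatError("mocap channels differ in length")

    def __len__(self) -> int:
        return self.object_pos.shape[0]


def sync_streams(
    force: ForceStream,
    mocap: MocapStream,
    led_onset_frame: int,
    condition: TrialCondition,
) -> TrialRecording:
    """Align force and mocap streams on the LED onset and trim to the overlap.

    Force frame 0 corresponds to mocap frame ``led_onset_frame`` (the frame
    at which the LED flash marked the start of force acquisition). Samples
    outside the common interval are discarded; the returned recording starts
    at t=0 on the common grid.
    """
    if force.fs != mocap.fs:
        raise TrialFormatError(
            f"sampling rates differ: force {force.fs} Hz vs mocap {mocap.fs} Hz"
        )
    n_mocap, n_force = len(mocap), len(force)
    if not 0 <= led_onset_frame < n_mocap:
        raise TrialFormatError(
            f"led_onset_frame {led_onset_frame} outside mocap range [0, {n_mocap})"
        )
    n_common = min(n_force, n_mocap - led_onset_frame)
    if n_common < 2:
        raise TrialFormatError("empty overlap between force and mocap streams")
    sl_mocap = slice(led_onset_frame, led_onset_frame + n_common)
    meta = TrialMetadata(
        condition=condition,
        fs=force.fs,
        led_onset_frame_mocap=led_onset_frame,
        force_start_frame=0,
    )
    return TrialRecording(
        time=np.arange(n_common) / force.fs,
        giver_force=force.giver_force[:n_common],
        receiver_force=force.receiver_force[:n_common],
        object_pos=mocap.object_pos[sl_mocap],
        radius_marker=mocap.radius_marker[sl_mocap],
        ulna_marker=mocap.ulna_marker[sl_mocap],
        meta=meta,
    )
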