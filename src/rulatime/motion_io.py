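"""Reading, validating, writing and resampling joint-angle recordings.

This module fixes the channel naming and sign conventions that every other
module relies on.  A recording is a delimited text file (comma, UTF-8, header
row) with one row per frame: a time column ``t_s`` (seconds), the sided angle
and flag channels with ``_r``/``_l`` suffixes, and the axial channels.

Sign conventions (all angles in degrees):

* flexion positive, extension negative (upper arm, wrist, neck, trunk);
* ``wrist_deviation`` is the absolute radial/ulnar deviation from the wrist
  midline, hence non-negative;
* rotations and side bends are signed, scoring uses their magnitude.

Motion-capture exports whose conventions differ must be mapped onto this
contract before loading (e.g. via a per-channel sign map applied upstream);
the loader validates but never silently re-signs data.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ANGLE_CHANNELS",
    "FLAG_CHANNELS",
    "ALL_CHANNELS",
    "TIME_COLUMN",
    "Occupation",
    "Specialization",
    "MotionRecording",
    "MotionError",
    "MotionFormatError",
    "MotionIntegrityError",
    "MotionParseError",
    "read_recording",
    "write_recording",
    "resample",
]

TIME_COLUMN = "t_s"

_SIDED_ANGLES = (
    "upper_arm_flexion",
    "upper_arm_abduction",
    "lower_arm_flexion",
    "wrist_flexion",
    "wrist_deviation",
)
_SIDED_FLAGS = (
    "shoulder_raise_flag",
    "arm_supported_flag",
    "arm_across_midline_flag",
    "wrist_twist_endrange_flag",
)
_AXIAL_ANGLES = (
    "neck_flexion",
    "neck_rotation",
    "neck_side_bend",
    "trunk_flexion",
    "trunk_rotation",
    "trunk_side_bend",
)
_AXIAL_FLAGS = ("trunk_supported_flag", "legs_supported_flag")

SIDES = ("r", "l")

ANGLE_CHANNELS: tuple[str, ...] = tuple(
    f"{name}_{side}" for name in _SIDED_ANGLES for side in SIDES
) + _AXIAL_ANGLES

FLAG_CHANNELS: tuple[str, ...] = tuple(
    f"{name}_{side}" for name in _SIDED_FLAGS for side in SIDES
) + _AXIAL_FLAGS

ALL_CHANNELS: tuple[str, ...] = ANGLE_CHANNELS + FLAG_CHANNELS

#: Maximum tolerated timestamp jitter relative to the nominal frame spacing.
TIME_TOLERANCE_S = 1e-6


class MotionError(ValueError):
    """Base class for recording I/O and validation errors."""


class MotionFormatError(MotionError):
    """A required channel/column is missing or the dialect is wrong."""


class MotionIntegrityError(MotionError):
    """Content violates a recording invariant (timestamps, ranges)."""


class MotionParseError(MotionError):
    """A cell could not be parsed; carries the 1-based data row number."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class Occupation(str, Enum):
    D = "D"
    DA = "DA"


class Specialization(str, Enum):
    GENERALIST = "generalist"
    ORTHODONTIST = "orthodontist"
    OMS = "oms"
    ENDODONTOLOGIST = "endodontologist"
    STUDENT = "student"


@dataclass
class MotionRecording:
    """A validated joint-angle recording plus subject/session metadata.

    ``data`` holds one row per frame: ``t_s`` plus every channel in
    :data:`ALL_CHANNELS` (angles float degrees, flags bool).  Extra columns
    are preserved but ignored by scoring.
    """

    subject_id: str
    occupation: Occupation
    pair_id: str
    dwc: int
    specialization: Specialization
    sampling_rate: float
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        self.occupation = Occupation(self.occupation)
        self.specialization = Specialization(self.specialization)
        self.dwc = int(self.dwc)
        if self.dwc not in (1, 2, 3, 4):
            raise MotionIntegrityError(f"dwc must be in 1..4, got {self.dwc}")
        if not self.sampling_rate > 0:
            raise MotionIntegrityError("sampling_rate must be > 0")
        self._validate_data()

    def _validate_data(self) -> None:
        df = self.data
        if len(df) < 1:
            raise MotionIntegrityError("recording must contain at least one frame")
        missing = [c for c in (TIME_COLUMN, *ALL_CHANNELS) if c not in df.columns]
        if missing:
            raise MotionFormatError(f"missing required channel(s): {', '.join(missing)}")
        t = df[TIME_COLUMN].to_numpy(dtype=float)
        if len(t) > 1:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise MotionIntegrityError("timestamps must be strictly increasing")
            expected = 1.0 / self.sampling_rate
            if np.any(np.abs(dt - expected) > TIME_TOLERANCE_S):
                bad = int(np.argmax(np.abs(dt - expected) > TIME_TOLERANCE_S)) + 1
                raise MotionIntegrityError(
                    f"timestamp spacing deviates from 1/{self.sampling_rate} Hz "
                    f"by more than {TIME_TOLERANCE_S} s at frame {bad}"
                )
        for c in ANGLE_CHANNELS:
            col = df[c].to_numpy(dtype=float)
            if not np.all(np.isfinite(col)):
                raise MotionIntegrityError(f"non-finite angle in channel {c}")
            if np.any(np.abs(col) > 180.0):
                raise MotionIntegrityError(f"angle out of [-180, 180] in channel {c}")
        if np.any(self.data["wrist_deviation_r"].to_numpy(float) < 0) or np.any(
            self.data["wrist_deviation_l"].to_numpy(float) < 0
        ):
            raise MotionIntegrityError("wrist_deviation must be non-negative")

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.sampling_rate

    def metadata(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "occupation": self.occupation.value,
            "pair_id": self.pair_id,
            "dwc": self.dwc,
            "specialization": self.specialization.value,
            "sampling_rate": self.sampling_rate,
        }


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def read_recording(path: str | Path, metadata: dict | None = None) -> MotionRecording:
    """Read a delimited-text recording and validate it.

    ``metadata`` supplies the subject descriptors; when omitted, a JSON
    sidecar ``<file>.meta.json`` written by :func:`write_recording` is used.
    """
    path = Path(path)
    if metadata is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise MotionFormatError(
                f"no metadata given and sidecar {sidecar.name} not found"
            )
        metadata = json.loads(sidecar.read_text())

    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise MotionFormatError(f"{path.name}: empty file") from None
        missing = [c for c in (TIME_COLUMN, *ALL_CHANNELS) if c not in header]
        if missing:
            raise MotionFormatError(
                f"{path.name}: missing required channel(s): {', '.join(missing)}"
            )
        rows = list(reader)

    idx = {name: header.index(name) for name in header}
    n = len(rows)
    if n == 0:
        raise MotionIntegrityError(f"{path.name}: no frames")

    columns: dict[str, np.ndarray] = {}
    for name in (TIME_COLUMN, *ANGLE_CHANNELS):
        col = np.empty(n, dtype=float)
        j = idx[name]
        for i, row in enumerate(rows):
            try:
                col[i] = float(row[j])
            except (ValueError, IndexError):
                raise MotionParseError(
                    f"{path.name}: non-numeric value {row[j]!r} for "
                    f"{name} in data row {i + 1}",
                    row=i + 1,
                ) from None
        columns[name] = col
    for name in FLAG_CHANNELS:
        col = np.empty(n, dtype=bool)
        j = idx[name]
        for i, row in enumerate(rows):
            cell = row[j].strip().lower()
            if cell in ("1", "true", "t"):
                col[i] = True
            elif cell in ("0", "false", "f"):
                col[i] = False
            else:
                raise MotionParseError(
                    f"{path.name}: non-boolean value {row[j]!r} for "
                    f"{name} in data row {i + 1}",
                    row=i + 1,
                )
        columns[name] = col

    df = pd.DataFrame(columns, columns=[TIME_COLUMN, *ALL_CHANNELS])
    return MotionRecording(data=df, **metadata)


def write_recording(rec: MotionRecording, path: str | Path, sidecar: bool = True) -> Path:
    """Write ``rec`` in the same dialect :func:`read_recording` expects.

    Floats are formatted with Python's shortest round-trip repr, so
    ``read_recording(write_recording(r)) == r`` exactly; flags become 0/1.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = [TIME_COLUMN, *ALL_CHANNELS]
    df = rec.data
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        arrays = [df[c].to_numpy() for c in cols]
        flag_set = set(FLAG_CHANNELS)
        for i in range(len(df)):
            writer.writerow(
                [
                    ("1" if arr[i] else "0") if c in flag_set else repr(float(arr[i]))
                    for c, arr in zip(cols, arrays)
                ]
            )
    if sidecar:
        _sidecar_path(path).write_text(json.dumps(rec.metadata(), indent=1))
    return path


def resample(rec: MotionRecording, target_rate: float) -> MotionRecording:
    """Decimate ``rec`` to ``target_rate`` by keeping every k-th frame.

    The source rate must be an integer multiple of the target; the first
    frame is always retained and flags travel with their frame.  Decimation
    (rather than filtering) is deliberate: the downstream scores are
    threshold functions of posture and anti-alias filtering would blur
    threshold crossings in what is predominantly quasi-static movement.
    """
    ratio = rec.sampling_rate / target_rate
    k = round(ratio)
    if not target_rate > 0 or abs(ratio - k) > 1e-9 or k < 1:
        raise MotionIntegrityError(
            f"source rate {rec.sampling_rate} Hz is not an integer multiple "
            f"of target rate {target_rate} Hz"
        )
    if k == 1:
        return rec
    df = rec.data.iloc[::k].reset_index(drop=True)
    return replace(rec, sampling_rate=target_rate, data=df)
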