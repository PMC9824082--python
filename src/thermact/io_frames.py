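"""Reading and writing low-resolution infrared (LRIR) frame streams.

A sensor channel delivers timestamped 8x8 thermal frames (temperatures in
degrees Celsius) at a nominal 10 frames/s.  Streams are stored as plain CSV,
one row per frame: the timestamp (seconds since record start) followed by the
64 pixel values flattened in **row-major** order over the 8x8 grid (row 0
left-to-right first).  This pixel ordering is the package-wide convention;
:func:`read_frame_stream` and :func:`write_frame_stream` round-trip it
exactly.  Datasets are described by a YAML manifest listing, per record, the
activity label, participant identifier(s), layout and the per-sensor CSV
paths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

GRID_SHAPE = (8, 8)
N_PIXELS = 64

#: Activity vocabularies.  Single-subject activities carry an AS (small
#: layout) or AL (large layout) prefix; double-subject activities (B1-B7)
#: exist only in the large layout.  C1-C9 are the single-subject activities
#: of the second (different-environment) dataset design.
SINGLE_SUBJECT_ACTIVITIES = {
    1: "sit-down",
    2: "stand-still",
    3: "sit-down-stand-up",
    4: "stand-up",
    5: "left-right-move",
    6: "for-backward-move",
    7: "walking-diagonally-1",
    8: "walking-diagonally-2",
}
DOUBLE_SUBJECT_ACTIVITIES = {
    1: "both-sitting",
    2: "sitting-moving",
    3: "sitting-standing",
    4: "random-moving",
    5: "both-standing",
    6: "standing-moving",
    7: "walking-across",
}
ADL_SINGLE_ACTIVITIES = {
    1: "walking-lr",
    2: "walking-rl",
    3: "walking-away",
    4: "walking-toward",
    5: "falling",
    6: "stand-to-sit",
    7: "sit-to-stand",
    8: "sitting-still",
    9: "standing-still",
}

DEFAULT_VOCABULARY = tuple(
    [f"AS{i}" for i in SINGLE_SUBJECT_ACTIVITIES]
    + [f"AL{i}" for i in SINGLE_SUBJECT_ACTIVITIES]
    + [f"B{i}" for i in DOUBLE_SUBJECT_ACTIVITIES]
    + [f"C{i}" for i in ADL_SINGLE_ACTIVITIES]
)

#: Plausibility band for indoor thermal readings, degrees Celsius.  Values
#: outside trigger a warning, not an error, to tolerate sensor artifacts.
PLAUSIBLE_TEMP_RANGE = (0.0, 60.0)


class FrameParseError(ValueError):
    """A CSV row could not be parsed as ``timestamp + 64 pixels``."""


class StreamValidationError(ValueError):
    """A frame stream violates a structural invariant."""


@dataclass(frozen=True)
class Frame:
    """One 8x8 thermal frame with its acquisition time."""

    pixels: np.ndarray  # (8, 8) float, degrees C
    timestamp: float  # seconds since record start

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.shape != GRID_SHAPE:
            raise StreamValidationError(
                f"frame must be {GRID_SHAPE}, got {px.shape}"
            )
        if not np.all(np.isfinite(px)):
            raise StreamValidationError("frame contains non-finite pixels")
        object.__setattr__(self, "pixels", px)
        lo, hi = PLAUSIBLE_TEMP_RANGE
        if px.min() < lo or px.max() > hi:
            warnings.warn(
                f"frame at t={self.timestamp:.3f}s has temperatures outside "
                f"the plausible band [{lo}, {hi}] degC",
                stacklevel=2,
            )


@dataclass
class FrameStream:
    """Ordered frames from one sensor channel of one activity record."""

    frames: list[Frame]
    sensor_id: str = "S1"
    fps: float = 10.0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise StreamValidationError("fps must be positive")
        ts = np.array([f.timestamp for f in self.frames])
        if len(ts) > 1 and not np.all(np.diff(ts) > 0):
            raise StreamValidationError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def as_array(self) -> np.ndarray:
        """Stack frames into an ``(n, 8, 8)`` array."""
        return np.stack([f.pixels for f in self.frames])

    def timestamps(self) -> np.ndarray:
        return np.array([f.timestamp for f in self.frames])

    @classmethod
    def from_arrays(
        cls,
        pixels: np.ndarray,
        timestamps: Sequence[float],
        sensor_id: str = "S1",
        fps: float = 10.0,
    ) -> "FrameStream":
        pixels = np.asarray(pixels, dtype=float)
        frames = [Frame(p, float(t)) for p, t in zip(pixels, timestamps, strict=True)]
        return cls(frames, sensor_id=sensor_id, fps=fps)


@dataclass
class ActivityRecord:
    """All sensor channels of one recorded activity."""

    streams: dict[str, FrameStream]
    label: str
    subjects: tuple[str, ...]
    layout: str = "large"  # "small" | "large"
    n_subjects: int = 1

    def __post_init__(self) -> None:
        if self.layout not in ("small", "large"):
            raise StreamValidationError(f"unknown layout {self.layout!r}")
        if self.n_subjects not in (1, 2, 3):
            raise StreamValidationError("n_subjects must be 1, 2 or 3")


def read_frame_stream(path: str | Path, sensor_id: str = "S1", fps: float = 10.0) -> FrameStream:
    """Read one channel's CSV into a :class:`FrameStream`.

    Each row must contain a timestamp followed by 64 pixel values (row-major
    8x8).  Malformed rows raise :class:`FrameParseError` naming the row;
    non-monotone timestamps raise :class:`StreamValidationError`.
    """
    path = Path(path)
    rows: list[np.ndarray] = []
    with path.open() as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            fields = line.split(",")
            if len(fields) != 1 + N_PIXELS:
                raise FrameParseError(
                    f"{path}: row {i}: expected {1 + N_PIXELS} fields, got {len(fields)}"
                )
            try:
                rows.append(np.array([float(x) for x in fields]))
            except ValueError as exc:
                raise FrameParseError(f"{path}: row {i}: non-numeric field ({exc})") from None
    arr = np.array(rows)
    if arr.size == 0:
        raise FrameParseError(f"{path}: no data rows")
    return FrameStream.from_arrays(
        arr[:, 1:].reshape(-1, *GRID_SHAPE), arr[:, 0], sensor_id=sensor_id, fps=fps
    )


def write_frame_stream(stream: FrameStream, path: str | Path) -> None:
    """Write a stream as CSV (timestamp + 64 row-major pixel values per row)."""
    if len(stream) == 0:
        raise StreamValidationError("refusing to write an empty stream")
    path = Path(path)
    with path.open("w") as fh:
        for f in stream.frames:
            vals = [repr(float(f.timestamp))] + [repr(float(v)) for v in f.pixels.ravel()]
            fh.write(",".join(vals) + "\n")


def load_dataset(
    manifest: str | Path, vocabulary: Sequence[str] = DEFAULT_VOCABULARY
) -> list[ActivityRecord]:
    """Load all records listed in a YAML manifest.

    The manifest maps ``records`` to a list of entries with keys ``label``,
    ``subjects``, ``layout``, ``n_subjects`` and ``streams`` (sensor id ->
    CSV path, relative to the manifest).  Unknown labels and missing files
    raise errors naming the offending record.
    """
    manifest = Path(manifest)
    with manifest.open() as fh:
        spec = yaml.safe_load(fh)
    records = []
    vocab = set(vocabulary)
    for i, entry in enumerate(spec["records"]):
        label = entry["label"]
        if label not in vocab:
            raise ValueError(f"record {i}: unknown activity label {label!r}")
        streams = {}
        for sensor_id, rel in entry["streams"].items():
            p = manifest.parent / rel
            if not p.exists():
                raise FileNotFoundError(f"record {i} ({label}): missing stream file {p}")
            streams[sensor_id] = read_frame_stream(p, sensor_id=sensor_id, fps=entry.get("fps", 10.0))
        records.append(
            ActivityRecord(
                streams=streams,
                label=label,
                subjects=tuple(str(s) for s in entry["subjects"]),
                layout=entry.get("layout", "large"),
                n_subjects=int(entry.get("n_subjects", 1)),
            )
        )
    return records


def write_dataset(records: Sequence[ActivityRecord], out_dir: str | Path) -> Path:
    """Write records (CSV per stream) plus a YAML manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, rec in enumerate(records):
        stream_map = {}
        for sensor_id, stream in rec.streams.items():
            rel = f"rec{i:04d}_{sensor_id}.csv"
            write_frame_stream(stream, out_dir / rel)
            stream_map[sensor_id] = rel
        entries.append(
            {
                "label": rec.label,
                "subjects": list(rec.subjects),
                "layout": rec.layout,
                "n_subjects": rec.n_subjects,
                "streams": stream_map,
            }
        )
    manifest = out_dir / "manifest.yaml"
    with manifest.open("w") as fh:
        yaml.safe_dump({"records": entries}, fh, sort_keys=False)
    return manifest
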