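"""Frame equalization and vectorization into 40x64 spatiotemporal maps.

Record durations vary (roughly 2-28 s at 10 frames/s), so every stream is
first equalized to a fixed length of 40 frames (4 s): longer streams drop
frames at regular intervals, shorter streams insert neighbor-mean frames.
Each equalized 8x8 frame is then flattened row-major into a 64-vector and the
40 vectors stacked into a 40x64 map (rows = time, columns = pixels).  The map
is the unit of denoising and feature extraction; a dataset is a stack of Z
maps with aligned labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_frames import ActivityRecord, Frame, FrameStream

MAP_SHAPE = (40, 64)
TARGET_FRAMES = 40


@dataclass
class SpatioTemporalMap:
    """A 40x64 time-by-pixels map with carried-through record metadata."""

    values: np.ndarray  # (40, 64) degrees C
    label: str = ""
    subjects: tuple[str, ...] = ()
    layout: str = "large"
    sensor_id: str = "S1"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != MAP_SHAPE:
            raise ValueError(f"map must be {MAP_SHAPE}, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("map contains non-finite values")
        self.values = v


@dataclass
class DatasetTensor:
    """Z stacked maps with aligned labels (and optional record metadata)."""

    maps: np.ndarray  # (Z, 40, 64)
    labels: np.ndarray  # (Z,) activity codes
    subjects: np.ndarray | None = None  # (Z,) subject key per map
    layouts: np.ndarray | None = None  # (Z,)

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float).reshape(-1, *MAP_SHAPE)
        self.labels = np.asarray(self.labels)
        if len(self.labels) != len(self.maps):
            raise ValueError("one label per map required")
        for attr in ("subjects", "layouts"):
            v = getattr(self, attr)
            if v is not None:
                v = np.asarray(v)
                if len(v) != len(self.maps):
                    raise ValueError(f"{attr} must align with maps")
                setattr(self, attr, v)

    def __len__(self) -> int:
        return len(self.maps)

    @property
    def n_features(self) -> int:
        return MAP_SHAPE[0] * MAP_SHAPE[1]

    def vectors(self) -> np.ndarray:
        """Maps flattened to (Z, 2560)."""
        return self.maps.reshape(len(self), -1)

    def subset(self, idx: np.ndarray) -> "DatasetTensor":
        return DatasetTensor(
            self.maps[idx],
            self.labels[idx],
            None if self.subjects is None else self.subjects[idx],
            None if self.layouts is None else self.layouts[idx],
        )

    def replace_maps(self, maps: np.ndarray) -> "DatasetTensor":
        return DatasetTensor(maps, self.labels, self.subjects, self.layouts)


def _retain_indices(n: int, target: int) -> np.ndarray:
    """Evenly spaced frame indices (endpoints kept, ties toward the earlier index)."""
    x = np.arange(target) * (n - 1) / (target - 1)
    # round half-down so .5 ties break toward the earlier index
    return np.ceil(x - 0.5).astype(int)


def equalize_frames(stream: FrameStream, target_len: int = TARGET_FRAMES) -> FrameStream:
    """Equalize a stream to exactly ``target_len`` frames.

    Longer streams retain ``target_len`` evenly spaced frames including both
    endpoints.  Shorter streams repeatedly insert, at the largest inter-frame
    time gap (leftmost on ties), a new frame equal to the element-wise mean
    of its two neighbors (timestamp at the midpoint).
    """
    if len(stream) < 2:
        raise ValueError("equalization requires at least 2 frames")
    n = len(stream)
    if n == target_len:
        return stream
    if n > target_len:
        idx = _retain_indices(n, target_len)
        frames = [stream.frames[i] for i in idx]
        return FrameStream(frames, sensor_id=stream.sensor_id, fps=stream.fps)
    px = [f.pixels for f in stream.frames]
    ts = [f.timestamp for f in stream.frames]
    while len(px) < target_len:
        gaps = np.diff(ts)
        g = int(np.argmax(gaps))  # argmax returns the leftmost maximum
        px.insert(g + 1, (px[g] + px[g + 1]) / 2.0)
        ts.insert(g + 1, (ts[g] + ts[g + 1]) / 2.0)
    frames = [Frame(p, t) for p, t in zip(px, ts)]
    return FrameStream(frames, sensor_id=stream.sensor_id, fps=stream.fps)


def vectorize(stream: FrameStream, label: str = "", subjects: tuple[str, ...] = (),
              layout: str = "large") -> SpatioTemporalMap:
    """Flatten a 40-frame stream into a 40x64 map (row-major per frame).

    Row ``t`` holds frame ``t``; column ``8*r + c`` holds pixel ``(r, c)``.
    """
    if len(stream) != TARGET_FRAMES:
        raise ValueError(
            f"vectorize expects exactly {TARGET_FRAMES} frames, got {len(stream)}; "
            "run equalize_frames first"
        )
    values = stream.as_array().reshape(TARGET_FRAMES, -1)
    return SpatioTemporalMap(values, label=label, subjects=subjects, layout=layout,
                             sensor_id=stream.sensor_id)


def devectorize(stmap: SpatioTemporalMap | np.ndarray) -> np.ndarray:
    """Inverse of :func:`vectorize`: a (40, 8, 8) frame stack."""
    values = stmap.values if isinstance(stmap, SpatioTemporalMap) else np.asarray(stmap)
    if values.shape != MAP_SHAPE:
        raise ValueError(f"expected a {MAP_SHAPE} map")
    return values.reshape(TARGET_FRAMES, 8, 8)


def build_dataset(records: Sequence[ActivityRecord], sensor_id: str,
                  target_len: int = TARGET_FRAMES) -> DatasetTensor:
    """Equalize + vectorize one sensor channel of every record into a tensor."""
    maps, labels, subjects, layouts = [], [], [], []
    for i, rec in enumerate(records):
        if sensor_id not in rec.streams:
            raise KeyError(f"record {i} ({rec.label}) has no sensor {sensor_id!r}")
        eq = equalize_frames(rec.streams[sensor_id], target_len)
        maps.append(vectorize(eq).values)
        labels.append(rec.label)
        subjects.append("+".join(rec.subjects))
        layouts.append(rec.layout)
    if not maps:
        return DatasetTensor(np.empty((0, *MAP_SHAPE)), np.empty((0,), dtype=object))
    return DatasetTensor(np.stack(maps), np.array(labels), np.array(subjects), np.array(layouts))
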