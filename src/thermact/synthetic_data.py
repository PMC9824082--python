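"""Synthetic low-resolution infrared activity records.

The simulator emulates the statistical structure of the reference study
designs so that every pipeline stage is testable without the deposited
sensor data: three sensors around a shared activity area (two side views,
one front view), 8x8 frames at 10 frames/s, record durations of 2-28 s,
ambient backgrounds drifting from ~18 to ~21 degC across a session, and one
or two warm moving subjects rendered as anisotropic Gaussian temperature
bumps (~10 degC over ambient, truncated by the sensor grid and quantized at
0.25 degC, typical of 8x8 thermopile arrays).

Geometry.  World coordinates put the traversal axis ``y`` parallel to the
side sensors' image plane: side sensor S1 sees ``y`` as its horizontal image
axis and ``x`` as depth, the front sensor S2 sees ``x`` horizontally and
``y`` as depth (so subjects walking across move *toward/away* from it), and
S3 mirrors S1 from the other side.  Apparent blob size and intensity fall
off with distance, which is what distinguishes the small layout (sensors at
1.5 m) from the large layout (2.5 m).

Activity scripts are minimal kinematic sketches (centroid trajectory,
posture height, body extent), not biomechanical models; their contract is
class separability and a plausible motion-energy ordering.  Horizontal and
vertical periodic stripe noise can additionally be injected directly in the
map domain at exact central-stripe frequencies, keeping the clean map
available as an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from .io_frames import (
    ADL_SINGLE_ACTIVITIES,
    DOUBLE_SUBJECT_ACTIVITIES,
    SINGLE_SUBJECT_ACTIVITIES,
    ActivityRecord,
    FrameStream,
)
from .preprocess import MAP_SHAPE, SpatioTemporalMap

SENSOR_IDS = ("S1", "S2", "S3")


@dataclass
class SceneConfig:
    """Scene and sensor parameters of the simulator."""

    ambient_start: float = 18.0  # degC at the start of a session
    ambient_end: float = 21.0  # degC at the end of a session
    blob_amplitude: float = 10.0  # degC over ambient at 1.5 m
    fps: float = 10.0
    duration_mean: float = 6.9  # s; reference streams average 69 frames
    duration_sd: float = 2.7
    duration_range: tuple[float, float] = (2.0, 28.0)
    pixel_noise: float = 0.10  # degC per pixel per frame
    quantization: float = 0.25  # degC sensor step
    layout_distance: dict = field(
        default_factory=lambda: {"small": 1.5, "large": 2.5}
    )  # m from sensors to the activity area
    sensors: tuple[str, ...] = SENSOR_IDS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        lo, hi = self.duration_range
        if not (0 < lo < hi):
            raise ValueError("invalid duration range")


@dataclass(frozen=True)
class ActivityScript:
    """An activity code plus its per-frame blob program name(s)."""

    code: str  # e.g. "AS3", "B7", "C5"
    programs: tuple[str, ...]  # one motion program per subject


@dataclass(frozen=True)
class NoiseInjection:
    """Additive sinusoidal stripe noise specified in the map domain.

    Frequencies are integer cycle counts along the 64-pixel axis (vertical
    stripes, horizontal-stripe spectral peaks; 1..31) or the 40-frame axis
    (horizontal stripes, vertical-stripe peaks; 1..19).
    """

    direction: str = "vertical"  # "vertical" | "horizontal" | "both"
    frequencies: tuple[int, ...] = (8,)
    amplitudes: tuple[float, ...] = (1.0,)

    def __post_init__(self) -> None:
        if self.direction not in ("vertical", "horizontal", "both"):
            raise ValueError("direction must be vertical, horizontal or both")


# --------------------------------------------------------------------------
# motion programs
# --------------------------------------------------------------------------

STAND_H, SIT_H, FLOOR_H = 0.62, 0.34, 0.12


def _smooth(t: np.ndarray, t0: float, t1: float) -> np.ndarray:
    """Smoothstep ramp 0 -> 1 between t0 and t1."""
    s = np.clip((t - t0) / max(t1 - t0, 1e-9), 0.0, 1.0)
    return s * s * (3 - 2 * s)


def _wander(n: int, rng: np.random.Generator, step: float, decay: float = 0.92) -> np.ndarray:
    """Mean-reverting random walk (per-frame steps) for sway and random moves."""
    out = np.empty(n)
    v = 0.0
    for i in range(n):
        v = decay * v + rng.normal(0.0, step)
        out[i] = v
    return out


def _triangle(u: np.ndarray) -> np.ndarray:
    """Period-2 triangle wave in [-1, 1] with value -1 at u = 0."""
    return 2.0 * np.abs(((u + 1.0) % 2.0) - 1.0) - 1.0


def _base_state(n: int, rng: np.random.Generator) -> dict:
    return {
        "x": np.full(n, rng.uniform(-0.06, 0.06)),
        "y": np.full(n, rng.uniform(-0.06, 0.06)),
        "h": np.full(n, STAND_H),
        "body_h": np.full(n, 1.0),
        "body_w": np.full(n, 1.0),
    }


#: walking speed in world units per second (the activity area spans ~1 unit)
WALK_SPEED = 0.35
#: lateral/for-backward oscillation frequency, Hz
OSC_FREQ = 0.3


def _program(name: str, t: np.ndarray, ts: np.ndarray,
             rng: np.random.Generator, speed: float) -> dict:
    """Evaluate one subject's motion program.

    ``t`` is normalized record time in [0, 1] (used by posture transitions,
    which span the record); ``ts`` is wall-clock seconds (used by walking
    and oscillation, whose speeds do not depend on record length).
    """
    n = len(t)
    st = _base_state(n, rng)
    sway = lambda s: _wander(n, rng, s)  # noqa: E731
    phase = rng.uniform(0, 2 * np.pi)
    freq = OSC_FREQ * speed * rng.uniform(0.9, 1.1)
    # walking bounces between +/-0.42 with a small random start phase that
    # keeps the initial direction characteristic of the activity
    walk_u = WALK_SPEED * speed / 0.84 * ts + rng.uniform(0.0, 0.25)
    gait = 0.03 * np.sin(2 * np.pi * 1.8 * speed * ts + phase)

    if name == "stand-still":
        st["x"] = st["x"] + sway(0.004)
        st["y"] = st["y"] + sway(0.004)
    elif name == "sitting-still":
        st["h"][:] = SIT_H
        st["body_h"][:] = 0.7
        st["x"] = st["x"] + sway(0.003)
    elif name == "sit-down":
        drop = _smooth(t, 0.35, 0.65)
        st["h"] = STAND_H - (STAND_H - SIT_H) * drop
        st["body_h"] = 1.0 - 0.3 * drop
    elif name == "stand-up":
        rise = _smooth(t, 0.35, 0.65)
        st["h"] = SIT_H + (STAND_H - SIT_H) * rise
        st["body_h"] = 0.7 + 0.3 * rise
    elif name == "sit-down-stand-up":
        drop = _smooth(t, 0.15, 0.4) - _smooth(t, 0.6, 0.85)
        st["h"] = STAND_H - (STAND_H - SIT_H) * drop
        st["body_h"] = 1.0 - 0.3 * drop
    elif name == "left-right-move":
        st["y"] = st["y"] + 0.3 * np.sin(2 * np.pi * freq * ts + phase)
    elif name == "for-backward-move":
        st["x"] = st["x"] + 0.3 * np.sin(2 * np.pi * freq * ts + phase)
    elif name == "walking-diagonally-1":
        st["y"] = st["y"] + 0.35 * _triangle(walk_u)
        st["x"] = st["x"] + 0.35 * _triangle(walk_u)
        st["h"] = st["h"] + gait
    elif name == "walking-diagonally-2":
        st["y"] = st["y"] - 0.35 * _triangle(walk_u)
        st["x"] = st["x"] + 0.35 * _triangle(walk_u)
        st["h"] = st["h"] + gait
    elif name in ("walk-across-lr", "walking-lr"):
        st["y"] = st["y"] + 0.42 * _triangle(walk_u)
        st["h"] = st["h"] + gait
    elif name in ("walk-across-rl", "walking-rl"):
        st["y"] = st["y"] - 0.42 * _triangle(walk_u)
        st["h"] = st["h"] + gait
    elif name == "walking-away":
        st["x"] = st["x"] + 0.42 * _triangle(walk_u)
        st["h"] = st["h"] + gait
    elif name == "walking-toward":
        st["x"] = st["x"] - 0.42 * _triangle(walk_u)
        st["h"] = st["h"] + gait
    elif name == "falling":
        drop = _smooth(t, 0.4, 0.55)
        st["h"] = STAND_H - (STAND_H - FLOOR_H) * drop
        st["body_h"] = 1.0 - 0.55 * drop
        st["body_w"] = 1.0 + 0.9 * drop
    elif name == "stand-to-sit":
        drop = _smooth(t, 0.25, 0.75)
        st["h"] = STAND_H - (STAND_H - SIT_H) * drop
        st["body_h"] = 1.0 - 0.3 * drop
    elif name == "sit-to-stand":
        rise = _smooth(t, 0.25, 0.75)
        st["h"] = SIT_H + (STAND_H - SIT_H) * rise
        st["body_h"] = 0.7 + 0.3 * rise
    elif name == "random-small":
        st["x"] = st["x"] + sway(0.03)
        st["y"] = st["y"] + sway(0.03)
    else:
        raise KeyError(f"unknown motion program {name!r}")
    return st


#: program(s) per activity code family
_SINGLE_PROGRAMS = {
    1: ("sit-down",),
    2: ("stand-still",),
    3: ("sit-down-stand-up",),
    4: ("stand-up",),
    5: ("left-right-move",),
    6: ("for-backward-move",),
    7: ("walking-diagonally-1",),
    8: ("walking-diagonally-2",),
}
_DOUBLE_PROGRAMS = {
    1: ("sitting-still", "sitting-still"),
    2: ("sitting-still", "walk-across-lr"),
    3: ("sitting-still", "stand-still"),
    4: ("random-small", "random-small"),
    5: ("stand-still", "stand-still"),
    6: ("stand-still", "walk-across-rl"),
    7: ("walk-across-lr", "walk-across-rl"),
}
_ADL_PROGRAMS = {
    1: ("walking-lr",),
    2: ("walking-rl",),
    3: ("walking-away",),
    4: ("walking-toward",),
    5: ("falling",),
    6: ("stand-to-sit",),
    7: ("sit-to-stand",),
    8: ("sitting-still",),
    9: ("stand-still",),
}


def script_for(code: str) -> ActivityScript:
    """Resolve an activity code (AS1..AS8, AL1..AL8, B1..B7, C1..C9)."""
    try:
        if code.startswith(("AS", "AL")):
            return ActivityScript(code, _SINGLE_PROGRAMS[int(code[2:])])
        if code.startswith("B"):
            return ActivityScript(code, _DOUBLE_PROGRAMS[int(code[1:])])
        if code.startswith("C"):
            return ActivityScript(code, _ADL_PROGRAMS[int(code[1:])])
    except (KeyError, ValueError):
        pass
    raise KeyError(f"unknown activity code {code!r}")


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def _subject_traits(subject: str) -> tuple[float, float, float]:
    """(size, speed, temperature offset) for a participant id like 'P3'."""
    idx = int(subject.lstrip("P")) - 1
    rng = np.random.default_rng(7_000 + idx)
    size = 0.85 + 0.3 * rng.uniform()
    spd = 0.85 + 0.3 * rng.uniform()
    dtemp = rng.uniform(-0.6, 0.6)
    return size, spd, dtemp


def _render_stream(
    states: list[dict],
    traits: list[tuple[float, float, float]],
    sensor_id: str,
    distance: float,
    ambient: float,
    scene: SceneConfig,
    rng: np.random.Generator,
    timestamps: np.ndarray,
) -> FrameStream:
    n = len(timestamps)
    rr, cc = np.meshgrid(np.arange(8.0), np.arange(8.0), indexing="ij")
    frames = np.full((n, 8, 8), ambient)
    # mild within-record ambient drift
    frames += np.linspace(0.0, 0.1, n)[:, None, None]
    for st, (size, _spd, dtemp) in zip(states, traits):
        if sensor_id == "S1":
            u, depth = st["y"], st["x"]
        elif sensor_id == "S2":
            u, depth = st["x"], st["y"]
        else:  # S3, opposite side: mirrored horizontal, mirrored depth
            u, depth = -st["y"], -st["x"]
        dist = distance + depth  # m
        scale = 1.5 / dist  # apparent size relative to a 1.5 m baseline
        half_fov = 0.35 * dist  # world metres spanned by half the image
        col_c = 3.5 + u / half_fov * 3.5
        row_c = (1.0 - st["h"]) * 7.0
        sig_r = np.clip(1.6 * st["body_h"] * size * scale, 0.45, 4.0)
        sig_c = np.clip(1.0 * st["body_w"] * size * scale, 0.35, 4.0)
        amp = (scene.blob_amplitude + dtemp) * scale**1.5
        bump = amp[:, None, None] * np.exp(
            -((rr[None] - row_c[:, None, None]) ** 2) / (2 * sig_r[:, None, None] ** 2)
            - ((cc[None] - col_c[:, None, None]) ** 2) / (2 * sig_c[:, None, None] ** 2)
        )
        frames += bump
    frames += rng.normal(0.0, scene.pixel_noise, frames.shape)
    if scene.quantization > 0:
        frames = np.round(frames / scene.quantization) * scene.quantization
    return FrameStream.from_arrays(frames, timestamps, sensor_id=sensor_id, fps=scene.fps)


def simulate_record(
    script: ActivityScript | str,
    scene: SceneConfig,
    seed: int,
    subjects: tuple[str, ...] = ("P1",),
    layout: str = "large",
    ambient: float | None = None,
) -> ActivityRecord:
    """Simulate all sensor channels of one activity record.

    Deterministic per ``seed``: duration, jitters, motion phases and pixel
    noise all derive from it.
    """
    if isinstance(script, str):
        script = script_for(script)
    if len(script.programs) != len(subjects):
        raise ValueError(
            f"{script.code} needs {len(script.programs)} subject(s), got {len(subjects)}"
        )
    rng = np.random.default_rng(seed)
    lo, hi = scene.duration_range
    duration = float(np.clip(rng.normal(scene.duration_mean, scene.duration_sd), lo, hi))
    n = max(int(round(duration * scene.fps)), 2)
    timestamps = np.arange(n) / scene.fps
    t = np.linspace(0.0, 1.0, n)
    if ambient is None:
        ambient = rng.uniform(scene.ambient_start, scene.ambient_end)

    traits = [_subject_traits(s) for s in subjects]
    states = []
    for prog, (_, spd, _), k in zip(script.programs, traits, range(len(subjects))):
        st = _program(prog, t, timestamps, rng, spd)
        if len(subjects) > 1:  # keep two subjects apart along the traversal axis
            st["y"] = st["y"] + (-0.22 if k == 0 else 0.22)
        states.append(st)

    distance = scene.layout_distance[layout]
    streams = {
        sid: _render_stream(states, traits, sid, distance, ambient, scene,
                            np.random.default_rng(rng.integers(2**31)), timestamps)
        for sid in scene.sensors
    }
    return ActivityRecord(
        streams=streams, label=script.code, subjects=tuple(subjects),
        layout=layout, n_subjects=len(subjects),
    )


def _record_seed(seed: int, *fields: int) -> int:
    ss = np.random.SeedSequence([int(seed), *[int(f) for f in fields]])
    return int(ss.generate_state(1)[0] % (2**31))


def build_coventry_like(scene: SceneConfig | None = None, seed: int = 0) -> list[ActivityRecord]:
    """The full two-layout study design as synthetic records.

    3 participants x 8 single-subject activities x 10 repeats per layout x
    2 layouts = 480 single-subject records, plus 3 participant pairs x 7
    double-subject activities x 10 repeats in the large layout = 210
    double-subject records.  Ambient temperature ramps across each layout
    session (small: 17.5 -> 19.5 degC, large: 18 -> 21 degC).
    """
    scene = scene or SceneConfig()
    records = []
    for li, layout in enumerate(("small", "large")):
        prefix = "AS" if layout == "small" else "AL"
        ramp = (17.5, 19.5) if layout == "small" else (18.0, 21.0)
        total = 3 * 8 * 10
        i = 0
        for si, subj in enumerate(("P1", "P2", "P3")):
            for act in range(1, 9):
                for rep in range(10):
                    ambient = ramp[0] + (ramp[1] - ramp[0]) * i / max(total - 1, 1)
                    records.append(
                        simulate_record(
                            f"{prefix}{act}", scene,
                            _record_seed(seed, li, si, act, rep),
                            subjects=(subj,), layout=layout, ambient=ambient,
                        )
                    )
                    i += 1
    pairs = (("P1", "P2"), ("P1", "P3"), ("P2", "P3"))
    total = 3 * 7 * 10
    i = 0
    for pi, pair in enumerate(pairs):
        for act in range(1, 8):
            for rep in range(10):
                ambient = 18.0 + 3.0 * i / max(total - 1, 1)
                records.append(
                    simulate_record(
                        f"B{act}", scene, _record_seed(seed, 9, pi, act, rep),
                        subjects=pair, layout="large", ambient=ambient,
                    )
                )
                i += 1
    return records


def build_infra_adl_like(scene: SceneConfig | None = None, seed: int = 0) -> list[ActivityRecord]:
    """Single-subject records of the second study design: 9 participants x
    9 activities x 3 repeats = 243 records (one layout)."""
    scene = scene or SceneConfig()
    records = []
    for si in range(9):
        for act in range(1, 10):
            for rep in range(3):
                records.append(
                    simulate_record(
                        f"C{act}", scene, _record_seed(seed, 100, si, act, rep),
                        subjects=(f"P{si + 1}",), layout="large",
                    )
                )
    return records


# --------------------------------------------------------------------------
# map-domain periodic noise injection
# --------------------------------------------------------------------------

_MAX_FREQ = {"vertical": MAP_SHAPE[1] // 2 - 1, "horizontal": MAP_SHAPE[0] // 2 - 1}


def _stripe_wave(direction: str, freq: int, amp: float, phase: float) -> np.ndarray:
    M, N = MAP_SHAPE
    fmax = _MAX_FREQ[direction]
    if not (isinstance(freq, (int, np.integer)) and 1 <= freq <= fmax):
        raise ValueError(
            f"{direction} stripe frequency must be an integer in 1..{fmax} "
            "(a central-stripe bin of the shifted spectrum)"
        )
    if direction == "vertical":  # stripes across the pixel axis, constant in time
        return amp * np.cos(2 * np.pi * freq * np.arange(N) / N + phase)[None, :] * np.ones((M, 1))
    return amp * np.cos(2 * np.pi * freq * np.arange(M) / M + phase)[:, None] * np.ones((1, N))


def inject_periodic_noise(
    stmap: SpatioTemporalMap | np.ndarray, spec: NoiseInjection, seed: int = 0
) -> np.ndarray:
    """Add sinusoidal stripe noise to one map; the input is left untouched.

    Phases are drawn from ``seed``.  Frequencies must land exactly on
    central-stripe bins; off-grid values raise an error.
    """
    values = stmap.values if isinstance(stmap, SpatioTemporalMap) else np.asarray(stmap, float)
    if values.shape != MAP_SHAPE:
        raise ValueError(f"expected a {MAP_SHAPE} map")
    rng = np.random.default_rng(seed)
    amps = spec.amplitudes
    if len(amps) == 1 and len(spec.frequencies) > 1:
        amps = amps * len(spec.frequencies)
    directions = ("vertical", "horizontal") if spec.direction == "both" else (spec.direction,)
    out = values.copy()
    for direction in directions:
        for freq, amp in zip(spec.frequencies, amps, strict=True):
            out += _stripe_wave(direction, freq, amp, rng.uniform(0, 2 * np.pi))
    return out


def inject_noise_dataset(maps: np.ndarray, spec: NoiseInjection, seed: int = 0) -> np.ndarray:
    """Inject stripe noise into a (Z, 40, 64) stack with per-map phases."""
    rng = np.random.default_rng(seed)
    return np.stack(
        [inject_periodic_noise(m, spec, seed=int(rng.integers(2**31))) for m in maps]
    )
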