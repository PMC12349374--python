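"""Synthetic ground-truth generators.

Everything the toolkit consumes from hardware — landmark streams, fixation
protocols, played maze sessions — can be generated here with known ground
truth: programmed gaze-ratio trajectories are inverted into landmark
frames (so the real ratio formulas are exercised on recovery), fixation
protocols follow the five-point validation sequence, and a scripted maze
bot produces command streams with an exact, known collision count.

Noise model: ``noise_sd`` is expressed in ratio units but applied as
Gaussian jitter on the pupil position (scaled by the eye extent), so noise
propagates through the actual pupil-to-ratio pipeline rather than being
added to the ratios directly.  All generators are seeded; there are no
unseeded entry points.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .control import Command
from .gaze import EyeLandmarks, LandmarkFrame, Point2D, TherapyMode, gaze_sample
from .maze import FINISH, Cell, Maze

__all__ = [
    "EyeGeometry",
    "Waveform",
    "EyeOffset",
    "TraceSpec",
    "landmark_frames_from_ratios",
    "generate_trace",
    "generate_fixation_protocol",
    "maze_bot",
    "FIXATION_TARGETS",
]


@dataclass(frozen=True)
class EyeGeometry:
    """Static contour geometry of one synthetic eye in normalized image
    coordinates (y down)."""

    outer: Point2D
    inner: Point2D
    upper: Point2D
    lower: Point2D
    iris_radius: float = 0.012

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("eye geometry needs positive width and height")
        if not (0 < self.iris_radius < min(self.width, self.height) / 2):
            raise ValueError("iris radius must be < half of both eye extents")

    @property
    def width(self) -> float:
        return abs(self.inner.x - self.outer.x)

    @property
    def height(self) -> float:
        return abs(self.lower.y - self.upper.y)

    @classmethod
    def default_right(cls) -> "EyeGeometry":
        return cls(outer=Point2D(0.30, 0.50), inner=Point2D(0.42, 0.50),
                   upper=Point2D(0.36, 0.47), lower=Point2D(0.36, 0.53))

    @classmethod
    def default_left(cls) -> "EyeGeometry":
        return cls(outer=Point2D(0.70, 0.50), inner=Point2D(0.58, 0.50),
                   upper=Point2D(0.64, 0.47), lower=Point2D(0.64, 0.53))


@dataclass(frozen=True)
class Waveform:
    """Sinusoid in ratio units: center + amplitude * sin(2*pi*t/period + phase)."""

    center: float
    amplitude: float = 0.0
    period_s: float = 4.0
    phase: float = 0.0

    def at(self, t_s: np.ndarray) -> np.ndarray:
        if self.amplitude == 0.0:
            return np.full_like(t_s, self.center, dtype=float)
        return self.center + self.amplitude * np.sin(
            2.0 * math.pi * t_s / self.period_s + self.phase)


@dataclass(frozen=True)
class EyeOffset:
    """Per-eye deviation from the programmed binocular trajectory."""

    lat_center: float = 0.0
    ap_center: float = 0.0
    phase: float = 0.0


@dataclass(frozen=True)
class TraceSpec:
    """Programmed gaze trajectory for one synthetic session.

    Defaults emulate a therapy-like sweep: lateral oscillation across most
    of the eye and a gentler vertical oscillation around mid-height, at a
    30 Hz landmark stream.
    """

    duration_s: float = 60.0
    sample_hz: float = 30.0
    lateral: Waveform = field(default_factory=lambda: Waveform(0.5, 0.3, 8.0))
    anteroposterior: Waveform = field(default_factory=lambda: Waveform(-0.5, 0.2, 5.0))
    noise_sd: float = 0.0
    seed: int = 0
    right_offset: EyeOffset = field(default_factory=EyeOffset)
    left_offset: EyeOffset = field(default_factory=EyeOffset)

    def __post_init__(self) -> None:
        if self.sample_hz <= 0:
            raise ValueError("sample_hz must be positive")
        for off in (self.right_offset, self.left_offset):
            lat = self.lateral
            ap = self.anteroposterior
            if not (0.0 <= lat.center + off.lat_center - lat.amplitude
                    and lat.center + off.lat_center + lat.amplitude <= 1.0):
                raise ValueError("lateral waveform leaves [0, 1]")
            if not (-1.0 <= ap.center + off.ap_center - ap.amplitude
                    and ap.center + off.ap_center + ap.amplitude <= 0.0):
                raise ValueError("anteroposterior waveform leaves [-1, 0]")


RatioPair = tuple[float, float]


def _eye_from_ratios(lat: float, ap: float, geom: EyeGeometry,
                     jitter: tuple[float, float]) -> EyeLandmarks:
    px = geom.outer.x + lat * (geom.inner.x - geom.outer.x) + jitter[0]
    py = geom.upper.y + (-ap) * (geom.lower.y - geom.upper.y) + jitter[1]
    r = geom.iris_radius
    iris = (Point2D(px - r, py), Point2D(px + r, py),
            Point2D(px, py - r), Point2D(px, py + r))
    return EyeLandmarks(iris=iris, outer_corner=geom.outer,
                        inner_corner=geom.inner, upper=geom.upper,
                        lower=geom.lower)


def landmark_frames_from_ratios(
    ratios: Sequence[Union[RatioPair, tuple[RatioPair, RatioPair]]],
    geom_right: Optional[EyeGeometry] = None,
    geom_left: Optional[EyeGeometry] = None,
    *,
    sample_hz: float = 30.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    t0_ms: int = 0,
    distance_mm: Optional[float] = 450.0,
) -> list[LandmarkFrame]:
    """Invert programmed gaze ratios into landmark frames.

    Each element of ``ratios`` is either one ``(lat, ap)`` pair applied to
    both eyes or a ``((lat_r, ap_r), (lat_l, ap_l))`` pair of pairs.  In
    the noise-free case running :func:`oculomaze.gaze.gaze_sample` on the
    output recovers the programmed ratios exactly; with ``noise_sd > 0``
    an independent Gaussian pupil jitter of that many ratio units (scaled
    to image units by the eye extent) is applied per frame and per eye.
    """
    geom_right = geom_right or EyeGeometry.default_right()
    geom_left = geom_left or EyeGeometry.default_left()
    rng = np.random.default_rng(seed)
    dt_ms = 1000.0 / sample_hz
    frames: list[LandmarkFrame] = []
    for i, entry in enumerate(ratios):
        if np.isscalar(entry[0]):
            (lat_r, ap_r) = (lat_l, ap_l) = entry  # same programme for both eyes
        else:
            (lat_r, ap_r), (lat_l, ap_l) = entry
        for lat, ap in ((lat_r, ap_r), (lat_l, ap_l)):
            if not (0.0 <= lat <= 1.0 and -1.0 <= ap <= 0.0):
                raise ValueError(f"ratios out of range: ({lat}, {ap})")
        if noise_sd > 0.0:
            jr = (rng.normal(0.0, noise_sd * geom_right.width),
                  rng.normal(0.0, noise_sd * geom_right.height))
            jl = (rng.normal(0.0, noise_sd * geom_left.width),
                  rng.normal(0.0, noise_sd * geom_left.height))
        else:
            jr = jl = (0.0, 0.0)
        frames.append(LandmarkFrame(
            timestamp_ms=int(round(t0_ms + i * dt_ms)),
            right=_eye_from_ratios(lat_r, ap_r, geom_right, jr),
            left=_eye_from_ratios(lat_l, ap_l, geom_left, jl),
            distance_mm=distance_mm,
        ))
    return frames


def generate_trace(spec: TraceSpec,
                   geom_right: Optional[EyeGeometry] = None,
                   geom_left: Optional[EyeGeometry] = None) -> list[LandmarkFrame]:
    """Landmark frames for a programmed sinusoidal gaze trajectory."""
    n = int(round(spec.duration_s * spec.sample_hz))
    t = np.arange(n) / spec.sample_hz
    out = []
    for off in (spec.right_offset, spec.left_offset):
        lat = Waveform(spec.lateral.center + off.lat_center, spec.lateral.amplitude,
                       spec.lateral.period_s, spec.lateral.phase + off.phase)
        ap = Waveform(spec.anteroposterior.center + off.ap_center,
                      spec.anteroposterior.amplitude,
                      spec.anteroposterior.period_s,
                      spec.anteroposterior.phase + off.phase)
        out.append(np.column_stack([lat.at(t), ap.at(t)]))
    right, left = out
    ratios = [((float(right[i, 0]), float(right[i, 1])),
               (float(left[i, 0]), float(left[i, 1]))) for i in range(n)]
    return landmark_frames_from_ratios(
        ratios, geom_right, geom_left,
        sample_hz=spec.sample_hz, noise_sd=spec.noise_sd, seed=spec.seed)


#: Fixation-protocol target ratios per segment label.  The protocol runs
#: the anteroposterior sequence top -> center -> bottom, then the lateral
#: sequence right -> center -> left, 10 s of steady gaze per point.
FIXATION_TARGETS: dict[str, dict[str, float]] = {
    "anteroposterior": {"top": -0.2, "center": -0.5, "bottom": -0.8},
    "lateral": {"right": 0.2, "center": 0.5, "left": 0.8},
}


def generate_fixation_protocol(
    users: Sequence[str] = ("16", "17", "18", "19"),
    n_trials: int = 5,
    fixation_s: float = 10.0,
    sample_hz: float = 30.0,
    noise_sd: float = 0.02,
    seed: int = 0,
    user_spread: float = 0.03,
) -> pd.DataFrame:
    """Simulate the five-point fixation validation protocol.

    Each user performs ``n_trials`` anteroposterior trials (top, center,
    bottom) and ``n_trials`` lateral trials (right, center, left), holding
    each point ``fixation_s`` seconds.  Users get a small deterministic
    idiosyncratic offset (``user_spread``) so inter-user variability is
    non-zero.  Frames are rendered as landmarks and pushed through the
    real gaze pipeline; returns a long-form frame with columns ``user``,
    ``axis``, ``trial``, ``segment``, ``t_ms`` and the four gaze ratios.
    """
    rng = np.random.default_rng(seed)
    n_per_seg = int(round(fixation_s * sample_hz))
    rows = []
    for user in users:
        u_lat = float(rng.normal(0.0, user_spread))
        u_ap = float(rng.normal(0.0, user_spread))
        for axis, targets in FIXATION_TARGETS.items():
            for trial in range(1, n_trials + 1):
                t_ms = 0
                for segment, target in targets.items():
                    if axis == "lateral":
                        lat, ap = min(max(target + u_lat, 0.0), 1.0), -0.5 + u_ap
                    else:
                        lat, ap = 0.5 + u_lat, min(max(target + u_ap, -1.0), 0.0)
                    frames = landmark_frames_from_ratios(
                        [(lat, ap)] * n_per_seg,
                        sample_hz=sample_hz, noise_sd=noise_sd,
                        seed=int(rng.integers(0, 2**31)), t0_ms=t_ms)
                    t_ms += int(round(n_per_seg * 1000.0 / sample_hz))
                    for fr in frames:
                        s = gaze_sample(fr, TherapyMode.BIN)
                        rows.append({
                            "user": user, "axis": axis, "trial": trial,
                            "segment": segment, "t_ms": fr.timestamp_ms,
                            "ratio_right": s.ratio_right,
                            "ratio_V_right": s.ratio_V_right,
                            "ratio_left": s.ratio_left,
                            "ratio_V_left": s.ratio_V_left,
                        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Maze bot
# ---------------------------------------------------------------------------

_STEP_TO_CMD = {(0, -1): Command.UP, (0, 1): Command.DOWN,
                (-1, 0): Command.LEFT, (1, 0): Command.RIGHT}
_DELTAS = {v: k for k, v in _STEP_TO_CMD.items()}


def _bfs(maze: Maze, start: Cell, goal: frozenset[Cell]) -> list[Cell]:
    if start in goal:
        return [start]
    prev: dict[Cell, Cell] = {start: start}
    queue = deque([start])
    while queue:
        cur = queue.popleft()
        for dx, dy in _STEP_TO_CMD:
            nxt = (cur[0] + dx, cur[1] + dy)
            if nxt in prev or maze.blocked(nxt):
                continue
            prev[nxt] = cur
            if nxt in goal:
                path = [nxt]
                while path[-1] != start:
                    path.append(prev[path[-1]])
                return path[::-1]
            queue.append(nxt)
    raise ValueError("maze is unsolvable: no path to target region")


def _blocked_direction(maze: Maze, pos: Cell) -> Command:
    for cmd, (dx, dy) in _DELTAS.items():
        if maze.blocked((pos[0] + dx, pos[1] + dy)):
            return cmd
    raise ValueError(f"no adjacent wall at {pos} to bump into")


def maze_bot(maze: Maze,
             collision_script: Optional[Iterable[tuple[int, Optional[Command]]]] = None,
             ) -> list[Command]:
    """Command stream that solves a level with an exact collision count.

    The nominal plan is the BFS shortest path through the pending
    checkpoints (zone by zone, then the finish).  ``collision_script``
    lists ``(tick, direction)`` pairs: at that tick of the final stream a
    deliberate bump into an adjacent wall is issued instead of progress
    (``direction=None`` picks any adjacent wall).  Replaying the stream
    through the engine yields exactly ``len(collision_script)`` errors and
    ``len(commands)`` consumed ticks.
    """
    script = sorted(collision_script or [], key=lambda e: e[0])
    targets: list[frozenset[Cell]] = []
    for cp in maze.checkpoints:
        targets.append(maze.finish if cp == FINISH else maze.zones[cp])
    targets.append(maze.finish)

    pos = maze.start
    plan: list[Command] = []
    for goal in targets:
        path = _bfs(maze, pos, goal)
        for a, b in zip(path, path[1:]):
            plan.append(_STEP_TO_CMD[(b[0] - a[0], b[1] - a[1])])
        pos = path[-1]

    if script and script[-1][0] >= len(plan) + len(script):
        raise ValueError("collision script extends past the end of the run")

    commands: list[Command] = []
    pos = maze.start
    plan_iter = iter(plan)
    script_by_tick = dict(script)
    if len(script_by_tick) != len(script):
        raise ValueError("collision script has duplicate ticks")
    tick = 0
    while True:
        if tick in script_by_tick:
            wanted = script_by_tick.pop(tick)
            if wanted is None:
                wanted = _blocked_direction(maze, pos)
            else:
                dx, dy = _DELTAS[wanted]
                if not maze.blocked((pos[0] + dx, pos[1] + dy)):
                    raise ValueError(
                        f"scripted bump {wanted.value} at tick {tick} is not "
                        f"against a wall from {pos}")
            commands.append(wanted)  # position unchanged: move is blocked
        else:
            try:
                nxt = next(plan_iter)
            except StopIteration:
                break
            dx, dy = _DELTAS[nxt]
            pos = (pos[0] + dx, pos[1] + dy)
            commands.append(nxt)
        tick += 1
    if script_by_tick:
        raise ValueError("collision script extends past the end of the run")
    return commands
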