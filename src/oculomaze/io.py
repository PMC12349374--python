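"""Readers and writers for the toolkit's on-disk formats.

Formats: landmark streams (JSON Lines, one frame per line), maze
definitions (JSON), session and displacement tables (CSV, matching the
device's report layouts), SUS questionnaires (CSV), telemetry (JSONL)
and a YAML config file.  The device's relational store is realized as
these on-disk tables; every writer/reader pair round-trips losslessly.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import pandas as pd
import yaml

from .control import Command, ZoneThresholds
from .gaze import EyeLandmarks, LandmarkFrame, Point2D
from .maze import BallState, Maze, SessionRecord, _LevelProgress, step
from .usability import SUSRecord, SUSResponse, sus_score

__all__ = [
    "StreamFormatError",
    "read_landmark_stream",
    "write_landmark_stream",
    "read_sus_csv",
    "sessions_frame",
    "extremes_frame",
    "write_sessions_csv",
    "telemetry_records",
    "write_telemetry",
    "load_config",
    "thresholds_from_config",
    "bundled_usability_scores",
    "bundled_session_results",
]

PathLike = Union[str, Path]


class StreamFormatError(ValueError):
    """A malformed landmark-stream line, reported with its line number."""

    def __init__(self, line_no: int, message: str):
        super().__init__(f"line {line_no}: {message}")
        self.line_no = line_no


# ---------------------------------------------------------------------------
# Landmark JSONL
# ---------------------------------------------------------------------------

def _eye_to_json(eye: EyeLandmarks) -> dict:
    return {
        "iris": [[p.x, p.y] for p in eye.iris],
        "outer": [eye.outer_corner.x, eye.outer_corner.y],
        "inner": [eye.inner_corner.x, eye.inner_corner.y],
        "upper": [eye.upper.x, eye.upper.y],
        "lower": [eye.lower.x, eye.lower.y],
    }


def _eye_from_json(doc: dict) -> EyeLandmarks:
    iris = doc["iris"]
    if len(iris) != 4:
        raise ValueError(f"iris must have exactly 4 points, got {len(iris)}")
    return EyeLandmarks(
        iris=tuple(Point2D(float(x), float(y)) for x, y in iris),
        outer_corner=Point2D(*map(float, doc["outer"])),
        inner_corner=Point2D(*map(float, doc["inner"])),
        upper=Point2D(*map(float, doc["upper"])),
        lower=Point2D(*map(float, doc["lower"])),
    )


def write_landmark_stream(frames: Iterable[LandmarkFrame], path: PathLike) -> None:
    with open(path, "w") as fh:
        for fr in frames:
            fh.write(json.dumps({
                "t_ms": fr.timestamp_ms,
                "left": _eye_to_json(fr.left),
                "right": _eye_to_json(fr.right),
                "dist_mm": fr.distance_mm,
            }) + "\n")


def read_landmark_stream(path: PathLike) -> Iterator[LandmarkFrame]:
    """Lazily parse a landmark JSONL stream.

    Raises :class:`StreamFormatError` naming the offending line on any
    schema violation, including timestamps that go backwards.
    """
    last_t: Optional[int] = None
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                doc = json.loads(line)
                frame = LandmarkFrame(
                    timestamp_ms=int(doc["t_ms"]),
                    left=_eye_from_json(doc["left"]),
                    right=_eye_from_json(doc["right"]),
                    distance_mm=(None if doc.get("dist_mm") is None
                                 else float(doc["dist_mm"])),
                )
            except (KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
                raise StreamFormatError(line_no, str(exc)) from exc
            if last_t is not None and frame.timestamp_ms < last_t:
                raise StreamFormatError(
                    line_no, f"timestamp {frame.timestamp_ms} decreases "
                             f"(previous {last_t})")
            last_t = frame.timestamp_ms
            yield frame


# ---------------------------------------------------------------------------
# SUS CSV
# ---------------------------------------------------------------------------

def read_sus_csv(path: PathLike) -> list[SUSRecord]:
    """Read SUS data from CSV.

    Accepts either 10 item columns ``q1..q10`` (scored here) or a
    precomputed ``Score`` column in the survey-table layout
    (``Id, Age, Sex, Visual Condition, Score``).
    """
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    item_cols = [cols.get(f"q{i}") for i in range(1, 11)]
    records: list[SUSRecord] = []
    for _, row in df.iterrows():
        rid = str(row[cols["id"]]) if "id" in cols else str(len(records) + 1)
        if all(c is not None for c in item_cols):
            score = sus_score(SUSResponse(tuple(int(row[c]) for c in item_cols)))
        elif "score" in cols:
            score = float(row[cols["score"]])
        else:
            raise ValueError("SUS CSV needs either q1..q10 columns or a Score column")
        records.append(SUSRecord(
            id=rid,
            score=score,
            age=int(row[cols["age"]]) if "age" in cols else None,
            sex=str(row[cols["sex"]]) if "sex" in cols else None,
            visual_condition=(str(row[cols["visual condition"]])
                              if "visual condition" in cols else None),
        ))
    return records


# ---------------------------------------------------------------------------
# Session tables (report layouts)
# ---------------------------------------------------------------------------

_EXTREME_SIGNALS = ["LD", "AD", "LI", "AI", "LB", "AB"]


def sessions_frame(records: Sequence[SessionRecord]) -> pd.DataFrame:
    """Per-level session table in the therapy-report layout: checkpoint
    times, total time, errors and performance ratio (empty for
    zero-error levels)."""
    from .metrics import performance_ratio
    rows = []
    for rec in records:
        for lv in rec.levels:
            cps = list(lv.checkpoint_times) + [None] * (3 - len(lv.checkpoint_times))
            ratio = performance_ratio(lv.total_ms, lv.errors) if lv.total_ms else None
            rows.append({
                "ID": rec.user_id,
                "Level": lv.level,
                "Time-CHKP-1 (ms)": cps[0],
                "Time-CHKP-2 (ms)": cps[1],
                "Total Time (ms)": lv.total_ms,
                "Errors": lv.errors,
                "Performance Ratio (ms/E)": ratio,
                "Operation": rec.mode,
            })
    return pd.DataFrame(rows)


def extremes_frame(records: Sequence[SessionRecord]) -> pd.DataFrame:
    """Displacement-extremes table in the report layout.

    Signals an occluded eye never produced are rendered as 0.00, matching
    the device's monocular exports.
    """
    from .gaze import TherapyMode
    from .metrics import displacement_extremes
    rows = []
    for rec in records:
        row: dict = {"ID": rec.user_id}
        if rec.gaze_trace:
            ext = displacement_extremes(rec.gaze_trace, TherapyMode.parse(rec.mode))
        else:
            ext = None
        for sig in _EXTREME_SIGNALS:
            row[f"{sig} Max"] = round(ext.max[sig], 2) if ext and sig in ext.max else 0.0
        for sig in _EXTREME_SIGNALS:
            row[f"{sig} Min"] = round(ext.min[sig], 2) if ext and sig in ext.min else 0.0
        row["Operation"] = rec.mode
        rows.append(row)
    return pd.DataFrame(rows)


def write_sessions_csv(records: Sequence[SessionRecord], path: PathLike) -> None:
    sessions_frame(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Telemetry
# ---------------------------------------------------------------------------

def telemetry_records(maze: Maze, commands: Iterable[Command], tick_ms: int = 100,
                      distance_mm: Optional[float] = None) -> Iterator[dict]:
    """Replay a command stream and yield one telemetry message per tick:
    elapsed time, level, cumulative errors, ball position, distance and
    the command applied."""
    ball = BallState(pos=maze.start, tick_ms=tick_ms)
    progress = _LevelProgress(pending=list(maze.checkpoints),
                              current_zone=maze.zone_of(ball.pos))
    for cmd in commands:
        ball, _ = step(maze, ball, cmd, progress)
        yield {
            "t_ms": progress.ticks * tick_ms,
            "level": maze.level,
            "errors": progress.errors,
            "ball": list(ball.pos),
            "dist_mm": distance_mm,
            "cmd": cmd.value,
        }
        if progress.finished:
            break


def write_telemetry(messages: Iterable[dict], path: PathLike) -> None:
    with open(path, "w") as fh:
        for msg in messages:
            fh.write(json.dumps(msg) + "\n")


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

_DEFAULT_CONFIG = {
    "control": {
        "lat_center": 0.5, "ap_center": -0.5,
        "band_lat": 0.12, "band_ap": 0.12,
        "margin": 0.10, "iqr_k": 1.5,
        "distance_min_mm": 400.0, "distance_max_mm": 500.0,
    },
}


def load_config(path: Optional[PathLike] = None) -> dict:
    """Load the YAML config, merged over built-in defaults."""
    cfg = {k: dict(v) for k, v in _DEFAULT_CONFIG.items()}
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for section, values in user.items():
            cfg.setdefault(section, {}).update(values or {})
    return cfg


def thresholds_from_config(cfg: dict) -> ZoneThresholds:
    c = cfg["control"]
    return ZoneThresholds(
        lat_center=c["lat_center"], ap_center=c["ap_center"],
        lat_left=c["lat_center"] + c["band_lat"],
        lat_right=c["lat_center"] - c["band_lat"],
        ap_up=c["ap_center"] + c["band_ap"],
        ap_down=c["ap_center"] - c["band_ap"],
    )


# ---------------------------------------------------------------------------
# Bundled reference data
# ---------------------------------------------------------------------------

def _bundled_csv(name: str) -> pd.DataFrame:
    ref = resources.files("oculomaze").joinpath(f"data/{name}")
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def bundled_usability_scores() -> list[SUSRecord]:
    """The device's published usability survey: 15 adult respondents with
    precomputed SUS scores and visual-condition metadata."""
    df = _bundled_csv("usability_scores.csv")
    return [SUSRecord(id=str(r["Id"]), score=float(r["Score"]), age=int(r["Age"]),
                      sex=str(r["Sex"]), visual_condition=str(r["Visual Condition"]))
            for _, r in df.iterrows()]


def bundled_session_results() -> pd.DataFrame:
    """The device's published level-2 therapy session results: checkpoint
    times, totals, collision counts and performance ratios for 17 runs
    (15 binocular plus one monocular run each for two amblyopic users)."""
    return _bundled_csv("session_results.csv")
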