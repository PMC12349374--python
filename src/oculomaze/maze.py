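"""Grid maze session engine.

Simulates the on-screen maze game: a ball on a discrete cell grid driven
by joystick commands, wall collisions counted as errors, numbered zones
whose first entries are timestamped, and three checkpoints per level (two
numbered zones plus the finish line).  Five levels of increasing
complexity make up a therapy session; time advances in fixed ticks so a
replayed command log reproduces a session exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

from .control import Command

__all__ = [
    "FINISH",
    "Maze",
    "BallState",
    "EventKind",
    "SessionEvent",
    "LevelResult",
    "SessionRecord",
    "CHECKPOINTS_BY_LEVEL",
    "checkpoints_for_level",
    "step",
    "run_level",
    "run_session",
    "load_maze",
    "save_maze",
]

Cell = tuple[int, int]

#: Sentinel checkpoint id for the finish line.
FINISH = "F"

#: Ordered checkpoint zones per level: two numbered zones, then the finish.
CHECKPOINTS_BY_LEVEL: dict[int, list[Union[int, str]]] = {
    1: [2, 4, FINISH],
    2: [3, 7, FINISH],
    3: [6, 11, FINISH],
    4: [3, 7, FINISH],
    5: [9, 6, FINISH],
}

_DELTAS = {
    Command.UP: (0, -1),
    Command.DOWN: (0, 1),
    Command.LEFT: (-1, 0),
    Command.RIGHT: (1, 0),
}


def checkpoints_for_level(level: int) -> list[Union[int, str]]:
    """The three timed checkpoint targets of a level, in visiting order."""
    if level not in CHECKPOINTS_BY_LEVEL:
        raise ValueError(f"level must be in 1..5, got {level}")
    return list(CHECKPOINTS_BY_LEVEL[level])


class EventKind(Enum):
    COLLISION = "COLLISION"
    ZONE_ENTER = "ZONE_ENTER"
    CHECKPOINT = "CHECKPOINT"
    FINISH = "FINISH"


@dataclass(frozen=True)
class SessionEvent:
    kind: EventKind
    t_ms: int
    zone_id: Optional[Union[int, str]] = None


@dataclass(frozen=True)
class Maze:
    """One maze level: walls, numbered zone regions, start/finish cells.

    The grid uses screen coordinates (x right, y down).  ``zones`` maps a
    zone id to the set of cells it covers; ``checkpoints`` lists the two
    timed zone ids followed by the finish sentinel.
    """

    level: int
    width: int
    height: int
    walls: frozenset[Cell]
    start: Cell
    finish: frozenset[Cell]
    zones: dict[int, frozenset[Cell]]
    checkpoints: list[Union[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start in self.walls:
            raise ValueError("start cell is a wall")
        if not self.finish:
            raise ValueError("finish region is empty")
        for cp in self.checkpoints:
            if cp != FINISH and cp not in self.zones:
                raise ValueError(f"checkpoint zone {cp} not among maze zones")

    def in_bounds(self, cell: Cell) -> bool:
        x, y = cell
        return 0 <= x < self.width and 0 <= y < self.height

    def blocked(self, cell: Cell) -> bool:
        return not self.in_bounds(cell) or cell in self.walls

    def zone_of(self, cell: Cell) -> Optional[int]:
        for zid, region in self.zones.items():
            if cell in region:
                return zid
        return None


@dataclass(frozen=True)
class BallState:
    pos: Cell
    step: int = 1
    tick_ms: int = 100

    def __post_init__(self) -> None:
        if self.step < 1:
            raise ValueError("step must be >= 1 cell per tick")
        if self.tick_ms <= 0:
            raise ValueError("tick_ms must be positive")


@dataclass
class _LevelProgress:
    """Mutable bookkeeping while a level runs."""

    ticks: int = 0
    errors: int = 0
    pending: list[Union[int, str]] = field(default_factory=list)
    checkpoint_times: list[int] = field(default_factory=list)
    current_zone: Optional[int] = None
    finished: bool = False


def step(maze: Maze, ball: BallState, cmd: Command,
         progress: Optional[_LevelProgress] = None) -> tuple[BallState, list[SessionEvent]]:
    """Advance the ball one tick.

    A directional command tries to move ``ball.step`` cells; the ball
    stops at the last free cell before a wall and a single COLLISION is
    emitted for the blocked tick.  Zone entries, checkpoint first-entries
    and finish entry are emitted as events with the elapsed level time.
    """
    if progress is None:
        progress = _LevelProgress(pending=list(maze.checkpoints),
                                  current_zone=maze.zone_of(ball.pos))
    progress.ticks += 1
    t_ms = progress.ticks * ball.tick_ms
    events: list[SessionEvent] = []

    if cmd is Command.STAY:
        return ball, events

    dx, dy = _DELTAS[cmd]
    pos = ball.pos
    collided = False
    for _ in range(ball.step):
        nxt = (pos[0] + dx, pos[1] + dy)
        if maze.blocked(nxt):
            collided = True
            break
        pos = nxt
    if collided:
        events.append(SessionEvent(EventKind.COLLISION, t_ms))
        progress.errors += 1

    if pos != ball.pos:
        zone = maze.zone_of(pos)
        if zone is not None and zone != progress.current_zone:
            events.append(SessionEvent(EventKind.ZONE_ENTER, t_ms, zone))
        progress.current_zone = zone

        if progress.pending:
            target = progress.pending[0]
            hit = (pos in maze.finish) if target == FINISH else (zone == target)
            if hit:
                events.append(SessionEvent(EventKind.CHECKPOINT, t_ms, target))
                progress.checkpoint_times.append(t_ms)
                progress.pending.pop(0)

        if pos in maze.finish:
            events.append(SessionEvent(EventKind.FINISH, t_ms))
            progress.finished = True

    return replace(ball, pos=pos), events


@dataclass(frozen=True)
class LevelResult:
    """Outcome of one maze level: checkpoint first-entry times (ms from
    level start), total time, collision count, and whether the finish was
    reached (aborted levels keep the progress made so far)."""

    level: int
    checkpoint_times: list[int]
    total_ms: int
    errors: int
    completed: bool
    events: list[SessionEvent] = field(default_factory=list)

    @property
    def performance_ratio(self) -> Optional[float]:
        from .metrics import performance_ratio
        if self.errors == 0:
            return None
        return performance_ratio(self.total_ms, self.errors)


def run_level(maze: Maze, commands: Iterable[Command], tick_ms: int = 100,
              step_cells: int = 1) -> LevelResult:
    """Drive a level with a command stream until the finish is entered or
    the stream is exhausted (an abort: progress so far is recorded)."""
    ball = BallState(pos=maze.start, step=step_cells, tick_ms=tick_ms)
    progress = _LevelProgress(pending=list(maze.checkpoints),
                              current_zone=maze.zone_of(ball.pos))
    all_events: list[SessionEvent] = []
    for cmd in commands:
        ball, events = step(maze, ball, cmd, progress)
        all_events.extend(events)
        if progress.finished:
            break
    return LevelResult(
        level=maze.level,
        checkpoint_times=list(progress.checkpoint_times),
        total_ms=progress.ticks * tick_ms,
        errors=progress.errors,
        completed=progress.finished,
        events=all_events,
    )


@dataclass
class SessionRecord:
    """One therapy run: user, modality, per-level results and the traces
    that produced them."""

    user_id: str
    mode: str
    levels: list[LevelResult] = field(default_factory=list)
    started_at: Optional[str] = None
    gaze_trace: Optional[list] = None
    distance_readings: list[float] = field(default_factory=list)

    @property
    def total_ms(self) -> int:
        return sum(lv.total_ms for lv in self.levels)

    @property
    def total_errors(self) -> int:
        return sum(lv.errors for lv in self.levels)


def run_session(mazes: Iterable[Maze], command_source, user_id: str = "anon",
                mode: str = "Bin", tick_ms: int = 100) -> SessionRecord:
    """Run consecutive levels with per-level command streams.

    ``command_source(maze)`` must return the command iterable for that
    level.  A stream that ends before the finish aborts the session; the
    completed prefix plus the partial level are recorded.
    """
    record = SessionRecord(user_id=user_id, mode=mode)
    for maze in mazes:
        result = run_level(maze, command_source(maze), tick_ms=tick_ms)
        record.levels.append(result)
        if not result.completed:
            break
    return record


# ---------------------------------------------------------------------------
# Maze JSON serialization
# ---------------------------------------------------------------------------

def save_maze(maze: Maze, path: Union[str, Path]) -> None:
    doc = {
        "level": maze.level,
        "width": maze.width,
        "height": maze.height,
        "walls": sorted(list(c) for c in maze.walls),
        "start": list(maze.start),
        "finish": sorted(list(c) for c in maze.finish),
        "zones": {str(z): sorted(list(c) for c in cells)
                  for z, cells in sorted(maze.zones.items())},
        "checkpoints": maze.checkpoints,
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def load_maze(source: Union[str, Path, dict]) -> Maze:
    if isinstance(source, (str, Path)):
        doc = json.loads(Path(source).read_text())
    else:
        doc = source
    try:
        return Maze(
            level=int(doc["level"]),
            width=int(doc["width"]),
            height=int(doc["height"]),
            walls=frozenset(tuple(c) for c in doc["walls"]),
            start=tuple(doc["start"]),
            finish=frozenset(tuple(c) for c in doc["finish"]),
            zones={int(z): frozenset(tuple(c) for c in cells)
                   for z, cells in doc["zones"].items()},
            checkpoints=[c if c == FINISH else int(c) for c in doc["checkpoints"]],
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"malformed maze definition: {exc}") from exc
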