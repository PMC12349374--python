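"""Built-in maze levels.

The original device ships five hand-drawn maze layouts of increasing
complexity; only their checkpoint structure is documented, not their
geometry.  These fixture levels reproduce that structure: serpentine
corridor mazes whose single path is partitioned into numbered zones, with
per-level checkpoint zones matching the documented mapping (level 5
visits zone 9 before zone 6, so its zone numbering is permuted along the
path).  Grids are coarser than the 128x64 display to keep the JSON
fixtures human-readable; the engine itself is grid-size agnostic.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Union

from .maze import CHECKPOINTS_BY_LEVEL, FINISH, Cell, Maze, load_maze

__all__ = ["build_level", "default_levels", "load_bundled_level", "serpentine_path"]

# (width, height, zone ids in path order) per level
_LEVEL_SPECS: dict[int, tuple[int, int, list[int]]] = {
    1: (13, 7, [1, 2, 3, 4, 5]),
    2: (17, 9, [1, 2, 3, 4, 5, 6, 7, 8]),
    3: (19, 11, [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12]),
    4: (17, 11, [1, 2, 3, 4, 5, 6, 7, 8]),
    5: (19, 13, [1, 2, 3, 4, 5, 9, 7, 8, 6, 10, 11]),
}


def serpentine_path(width: int, height: int) -> list[Cell]:
    """Ordered corridor cells of a serpentine maze: rows at odd y, joined
    by one-cell connectors at alternating ends."""
    path: list[Cell] = []
    rows = list(range(1, height - 1, 2))
    for i, y in enumerate(rows):
        xs = range(1, width - 1)
        if i % 2 == 1:
            xs = reversed(xs)
        for x in xs:
            path.append((x, y))
        if i < len(rows) - 1:
            connector_x = width - 2 if i % 2 == 0 else 1
            path.append((connector_x, y + 1))
    return path


def build_level(level: int) -> Maze:
    """Construct one of the five built-in levels programmatically."""
    if level not in _LEVEL_SPECS:
        raise ValueError(f"level must be in 1..5, got {level}")
    width, height, zone_order = _LEVEL_SPECS[level]
    path = serpentine_path(width, height)
    walls = frozenset(
        (x, y) for x in range(width) for y in range(height)
    ) - frozenset(path)

    # Split the path (past the start cell) into contiguous equal segments,
    # one per zone, labelled in the level's path order.
    n_zones = len(zone_order)
    body = path[1:]
    seg = len(body) // n_zones
    zones: dict[int, frozenset[Cell]] = {}
    for i, zid in enumerate(zone_order):
        lo = i * seg
        hi = (i + 1) * seg if i < n_zones - 1 else len(body)
        zones[zid] = frozenset(body[lo:hi])

    finish = frozenset(path[-2:])
    return Maze(
        level=level,
        width=width,
        height=height,
        walls=walls,
        start=path[0],
        finish=finish,
        zones=zones,
        checkpoints=list(CHECKPOINTS_BY_LEVEL[level]),
    )


def default_levels() -> list[Maze]:
    """All five built-in levels, in play order."""
    return [build_level(lv) for lv in range(1, 6)]


def load_bundled_level(level: int) -> Maze:
    """Load a level from the versioned JSON fixtures bundled with the
    package (identical to :func:`build_level` output)."""
    ref = resources.files("oculomaze").joinpath(f"data/mazes/level{level}.json")
    with resources.as_file(ref) as path:
        return load_maze(path)


def write_bundled_fixtures(directory: Union[str, Path]) -> None:
    """Regenerate the bundled maze JSON files (maintenance helper)."""
    from .maze import save_maze
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for lv in range(1, 6):
        save_maze(build_level(lv), directory / f"level{lv}.json")
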