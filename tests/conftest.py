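import math

import pytest

from oculomaze.gaze import Circle, EyeLandmarks, Point2D
from oculomaze.maze import FINISH, Maze


@pytest.fixture
def square_iris_eye() -> EyeLandmarks:
    """Eye whose iris landmarks are the corners of a square around (0.5, 0.5)."""
    return EyeLandmarks(
        iris=(Point2D(0.48, 0.48), Point2D(0.52, 0.48),
              Point2D(0.48, 0.52), Point2D(0.52, 0.52)),
        outer_corner=Point2D(0.40, 0.50),
        inner_corner=Point2D(0.60, 0.50),
        upper=Point2D(0.50, 0.45),
        lower=Point2D(0.50, 0.55),
    )


@pytest.fixture
def tiny_maze() -> Maze:
    """Hand-traced 5x3 fixture: one corridor row with a single wall gap.

        #####       walls border the grid; corridor y=1 from x=1..3,
        #..Z#       zone 1 = {(3,1)} which is also the finish
        #####
    """
    cells = {(x, y) for x in range(5) for y in range(3)}
    corridor = {(1, 1), (2, 1), (3, 1)}
    return Maze(
        level=1, width=5, height=3,
        walls=frozenset(cells - corridor),
        start=(1, 1),
        finish=frozenset({(3, 1)}),
        zones={1: frozenset({(3, 1)})},
        checkpoints=[1, FINISH],
    )


def brute_force_mec(points: list[tuple[float, float]]) -> Circle:
    """Exhaustive minimum enclosing circle: try every circle defined by a
    pair (as diameter) or triple (circumcircle) of points, keep the
    smallest that covers all.  Independent oracle for Welzl."""
    pts = [Point2D(x, y) for x, y in points]
    if len(pts) == 1:
        return Circle(pts[0], 0.0)
    candidates: list[Circle] = []
    n = len(pts)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = pts[i], pts[j]
            candidates.append(Circle(
                Point2D((a.x + b.x) / 2, (a.y + b.y) / 2),
                math.hypot(a.x - b.x, a.y - b.y) / 2))
            for k in range(j + 1, n):
                c = pts[k]
                d = 2 * (a.x * (b.y - c.y) + b.x * (c.y - a.y) + c.x * (a.y - b.y))
                if d == 0:
                    continue
                ux = ((a.x ** 2 + a.y ** 2) * (b.y - c.y)
                      + (b.x ** 2 + b.y ** 2) * (c.y - a.y)
                      + (c.x ** 2 + c.y ** 2) * (a.y - b.y)) / d
                uy = ((a.x ** 2 + a.y ** 2) * (c.x - b.x)
                      + (b.x ** 2 + b.y ** 2) * (a.x - c.x)
                      + (c.x ** 2 + c.y ** 2) * (b.x - a.x)) / d
                center = Point2D(ux, uy)
                candidates.append(Circle(center, math.hypot(a.x - ux, a.y - uy)))
    covering = [c for c in candidates
                if all(c.contains(p, tol=1e-9) for p in pts)]
    return min(covering, key=lambda c: c.radius)
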