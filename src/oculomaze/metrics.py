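"""Per-session quantitative metrics.

Displacement extremes per gaze signal, displacement ellipses, the
performance ratio (milliseconds of play per wall collision), and
per-segment descriptive statistics (mean, sample standard deviation,
coefficient of variation).

Signal naming follows the session-table convention: L/A for
lateral/anteroposterior, D/I/B for right (derecho), left (izquierdo) and
binocular, e.g. ``LD`` is the right eye's lateral ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .gaze import GazeSample, TherapyMode

__all__ = [
    "SIGNALS",
    "DisplacementExtremes",
    "EllipseParams",
    "SegmentStats",
    "displacement_extremes",
    "ellipse_from_extremes",
    "performance_ratio",
    "segment_stats",
]

#: signal code -> GazeSample attribute
SIGNALS: dict[str, str] = {
    "LD": "ratio_right",
    "AD": "ratio_V_right",
    "LI": "ratio_left",
    "AI": "ratio_V_left",
    "LB": "ratio_bin",
    "AB": "ratio_V_bin",
}

_MODE_SIGNALS = {
    TherapyMode.BIN: ("LD", "AD", "LI", "AI", "LB", "AB"),
    TherapyMode.MON_IZQ: ("LI", "AI"),
    TherapyMode.MON_DER: ("LD", "AD"),
}


@dataclass(frozen=True)
class DisplacementExtremes:
    """Per-signal max/min over a session trace.  Signals an eye never
    produced (monocular sessions) are absent from the maps."""

    max: dict[str, float]
    min: dict[str, float]

    def __post_init__(self) -> None:
        for sig in self.max:
            if self.min[sig] > self.max[sig]:
                raise ValueError(f"min > max for signal {sig}")


@dataclass(frozen=True)
class EllipseParams:
    """Axis-aligned displacement ellipse in ratio space: centered at the
    midpoints of the observed ranges, semi-axes equal to the half-ranges."""

    center_x: float
    center_y: float
    semi_axis_x: float
    semi_axis_y: float

    def __post_init__(self) -> None:
        if self.semi_axis_x < 0 or self.semi_axis_y < 0:
            raise ValueError("semi-axes must be >= 0")

    @property
    def area(self) -> float:
        return math.pi * self.semi_axis_x * self.semi_axis_y


@dataclass(frozen=True)
class SegmentStats:
    """Descriptive statistics of one maze segment for one eye.

    Segments follow the session-report convention: HD = rightward lateral
    travel, HI = leftward lateral travel, V = upward anteroposterior
    travel.  CV is 100 * std / |mean| (undefined for zero mean)."""

    segment: str
    eye: str
    mean_lat: float
    std_lat: float
    mean_ap: float
    std_ap: float
    cv_lat_percent: Optional[float]
    cv_ap_percent: Optional[float]
    n: int


def displacement_extremes(trace: Sequence[GazeSample],
                          mode: TherapyMode = TherapyMode.BIN) -> DisplacementExtremes:
    """Max and min of every gaze signal over a trace.

    Binocular extremes are taken over the pointwise-mean signal, so when
    the two eyes' extremes do not co-occur the binocular extreme is
    strictly inside the mean of the per-eye extremes.
    """
    if not trace:
        raise ValueError("displacement_extremes requires a nonempty trace")
    maxima: dict[str, float] = {}
    minima: dict[str, float] = {}
    for sig in _MODE_SIGNALS[mode]:
        attr = SIGNALS[sig]
        values = [getattr(s, attr) for s in trace if getattr(s, attr) is not None]
        if not values:
            continue
        maxima[sig] = max(values)
        minima[sig] = min(values)
    return DisplacementExtremes(max=maxima, min=minima)


def ellipse_from_extremes(x_min: float, x_max: float,
                          y_min: float, y_max: float) -> EllipseParams:
    """Displacement ellipse from the lateral (x) and anteroposterior (y)
    extremes of a session."""
    if x_min > x_max or y_min > y_max:
        raise ValueError("inverted extremes")
    return EllipseParams(
        center_x=(x_min + x_max) / 2.0,
        center_y=(y_min + y_max) / 2.0,
        semi_axis_x=(x_max - x_min) / 2.0,
        semi_axis_y=(y_max - y_min) / 2.0,
    )


def performance_ratio(total_ms: float, errors: int) -> Optional[float]:
    """Milliseconds per error, rounded to 2 decimals.

    A session with zero collisions has no defined ratio and returns
    ``None`` (rendered as an empty cell on export).
    """
    if total_ms <= 0:
        raise ValueError("total_ms must be positive")
    if errors < 0:
        raise ValueError("errors must be >= 0")
    if errors == 0:
        return None
    return round(total_ms / errors, 2)


def _cv(mean: float, std: float) -> Optional[float]:
    if mean == 0:
        return None
    return 100.0 * std / abs(mean)


def segment_stats(trace: Sequence[GazeSample],
                  segment_windows: Mapping[str, Sequence[tuple[int, int]]],
                  ) -> list[SegmentStats]:
    """Mean, sample standard deviation (n-1) and CV of the lateral and
    anteroposterior ratios within each segment's time windows.

    ``segment_windows`` maps a segment label (e.g. HD/HI/V) to a list of
    half-open ``[t0, t1)`` millisecond intervals.  One row per segment
    per eye that carries signal in the trace.
    """
    out: list[SegmentStats] = []
    for segment, windows in segment_windows.items():
        samples = [s for s in trace
                   if any(t0 <= s.timestamp_ms < t1 for (t0, t1) in windows)]
        for eye, lat_attr, ap_attr in (("right", "ratio_right", "ratio_V_right"),
                                       ("left", "ratio_left", "ratio_V_left")):
            lats = np.array([getattr(s, lat_attr) for s in samples
                             if getattr(s, lat_attr) is not None])
            aps = np.array([getattr(s, ap_attr) for s in samples
                            if getattr(s, ap_attr) is not None])
            if lats.size == 0 and aps.size == 0:
                continue
            if lats.size < 2 or aps.size < 2:
                raise ValueError(
                    f"segment {segment!r}/{eye}: need >= 2 samples for std")
            mean_lat, std_lat = float(lats.mean()), float(lats.std(ddof=1))
            mean_ap, std_ap = float(aps.mean()), float(aps.std(ddof=1))
            out.append(SegmentStats(
                segment=segment, eye=eye,
                mean_lat=mean_lat, std_lat=std_lat,
                mean_ap=mean_ap, std_ap=std_ap,
                cv_lat_percent=_cv(mean_lat, std_lat),
                cv_ap_percent=_cv(mean_ap, std_ap),
                n=int(lats.size),
            ))
    return out
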