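"""Five-zone gaze-to-command control.

The eye region is split into five zones in ratio space: a central
rectangle where the ball stays put, and four surrounding zones mapped to
the joystick directions.  Zone borders default to a center of
(0.5, -0.5) with a band half-width of 0.12 on each axis and can be
re-derived per user from a short central-fixation baseline (adaptive
thresholding from reference points).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from .gaze import GazeSample, TherapyMode

__all__ = [
    "Command",
    "ZoneThresholds",
    "CalibrationError",
    "classify_zone",
    "calibrate_thresholds",
    "session_ready",
    "DEFAULT_THRESHOLDS",
]


class Command(Enum):
    UP = "UP"
    DOWN = "DOWN"
    LEFT = "LEFT"
    RIGHT = "RIGHT"
    STAY = "STAY"


class CalibrationError(ValueError):
    """Raised when a calibration baseline is unusable."""


@dataclass(frozen=True)
class ZoneThresholds:
    """Zone borders in ratio space.

    The lateral ratio is referenced to the outer eye corner and grows
    toward the inner corner, so the LEFT zone sits at high lateral values
    (``lat > lat_left``) and the RIGHT zone at low ones
    (``lat < lat_right``).  The anteroposterior ratio is negative and
    grows toward zero as gaze rises, so UP is ``ap > ap_up`` and DOWN is
    ``ap < ap_down``.
    """

    lat_center: float = 0.5
    ap_center: float = -0.5
    lat_left: float = 0.62
    lat_right: float = 0.38
    ap_up: float = -0.38
    ap_down: float = -0.62

    def __post_init__(self) -> None:
        if not self.lat_right < self.lat_center < self.lat_left:
            raise ValueError("require lat_right < lat_center < lat_left")
        if not self.ap_down < self.ap_center < self.ap_up:
            raise ValueError("require ap_down < ap_center < ap_up")
        if not (0.0 <= self.lat_right and self.lat_left <= 1.0):
            raise ValueError("lateral thresholds must lie in [0, 1]")
        if not (-1.0 <= self.ap_down and self.ap_up <= 0.0):
            raise ValueError("anteroposterior thresholds must lie in [-1, 0]")

    @property
    def band_lat(self) -> float:
        return self.lat_left - self.lat_center

    @property
    def band_ap(self) -> float:
        return self.ap_up - self.ap_center


DEFAULT_THRESHOLDS = ZoneThresholds()


def _controlling_ratios(sample: GazeSample, mode: TherapyMode) -> tuple[float, float]:
    if mode is TherapyMode.BIN:
        lat, ap = sample.ratio_bin, sample.ratio_V_bin
    elif mode is TherapyMode.MON_IZQ:
        lat, ap = sample.ratio_left, sample.ratio_V_left
    else:
        lat, ap = sample.ratio_right, sample.ratio_V_right
    if lat is None or ap is None:
        raise ValueError(f"sample lacks the controlling ratios for mode {mode.value}")
    return lat, ap


def classify_zone(sample: GazeSample, thr: ZoneThresholds = DEFAULT_THRESHOLDS,
                  mode: TherapyMode = TherapyMode.BIN) -> Command:
    """Map a gaze sample to a maze command.

    STAY iff both controlling ratios are strictly inside the center band.
    When both axes exceed their band the axis with the larger
    band-normalized deviation wins; ties resolve to the lateral axis.
    """
    lat, ap = _controlling_ratios(sample, mode)

    # Signed excess beyond the band on each axis, normalized by band width.
    if lat >= thr.lat_left:
        lat_dev = (lat - thr.lat_left) / (thr.lat_left - thr.lat_center)
        lat_cmd = Command.LEFT
    elif lat <= thr.lat_right:
        lat_dev = (thr.lat_right - lat) / (thr.lat_center - thr.lat_right)
        lat_cmd = Command.RIGHT
    else:
        lat_dev, lat_cmd = 0.0, None

    if ap >= thr.ap_up:
        ap_dev = (ap - thr.ap_up) / (thr.ap_up - thr.ap_center)
        ap_cmd = Command.UP
    elif ap <= thr.ap_down:
        ap_dev = (thr.ap_down - ap) / (thr.ap_center - thr.ap_down)
        ap_cmd = Command.DOWN
    else:
        ap_dev, ap_cmd = 0.0, None

    if lat_cmd is None and ap_cmd is None:
        return Command.STAY
    if ap_cmd is None:
        return lat_cmd
    if lat_cmd is None:
        return ap_cmd
    return ap_cmd if ap_dev > lat_dev else lat_cmd


def calibrate_thresholds(baseline: Sequence[GazeSample], margin: float = 0.10,
                         iqr_k: float = 1.5,
                         mode: TherapyMode = TherapyMode.BIN) -> ZoneThresholds:
    """Derive zone thresholds from a central-fixation baseline.

    Centers are the per-axis medians of the baseline ratios; band
    half-widths are ``max(margin, iqr_k * IQR)`` per axis so jittery users
    get a wider dead zone.  Requires at least 10 samples.
    """
    if len(baseline) < 10:
        raise CalibrationError(
            f"calibration needs >= 10 baseline samples, got {len(baseline)}")
    lats, aps = zip(*(_controlling_ratios(s, mode) for s in baseline))

    def iqr(values: Sequence[float]) -> float:
        q1, _, q3 = statistics.quantiles(values, n=4, method="inclusive")
        return q3 - q1

    lat_c = statistics.median(lats)
    ap_c = statistics.median(aps)
    hw_lat = max(margin, iqr_k * iqr(lats))
    hw_ap = max(margin, iqr_k * iqr(aps))
    return ZoneThresholds(
        lat_center=lat_c, ap_center=ap_c,
        lat_left=min(lat_c + hw_lat, 1.0), lat_right=max(lat_c - hw_lat, 0.0),
        ap_up=min(ap_c + hw_ap, 0.0), ap_down=max(ap_c - hw_ap, -1.0),
    )


def session_ready(distance_mm: float, min_mm: float = 400.0,
                  max_mm: float = 500.0) -> bool:
    """True iff the user sits in the working band of 40-50 cm from the
    device (both endpoints inclusive)."""
    if distance_mm < 0:
        raise ValueError("distance_mm must be >= 0")
    return min_mm <= distance_mm <= max_mm
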