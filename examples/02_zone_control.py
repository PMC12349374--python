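"""Turn gaze samples into joystick commands via the five-zone layout.

The ratio plane is split into a central STAY rectangle and four
directional zones; thresholds can be recalibrated from a short central
fixation so each user's resting gaze defines the dead zone.
"""

from oculomaze import calibrate_thresholds, classify_zone, session_ready
from oculomaze.control import ZoneThresholds
from oculomaze.gaze import GazeSample

thr = ZoneThresholds()  # defaults: center (0.5, -0.5), half-width 0.12

for lat, ap, label in [(0.50, -0.50, "center fixation"),
                       (0.70, -0.50, "gaze toward inner corner"),
                       (0.50, -0.30, "gaze raised"),
                       (0.67, -0.82, "diagonal, vertical dominates")]:
    s = GazeSample(timestamp_ms=0, ratio_bin=lat, ratio_V_bin=ap)
    print(f"({lat:.2f}, {ap:.2f})  {label:32s} -> {classify_zone(s, thr).value}")

# Adaptive thresholds: a user resting slightly off-center shifts the bands.
baseline = [GazeSample(timestamp_ms=i, ratio_bin=0.46, ratio_V_bin=-0.55)
            for i in range(15)]
adapted = calibrate_thresholds(baseline, margin=0.10)
print(f"calibrated center: ({adapted.lat_center:.2f}, {adapted.ap_center:.2f}), "
      f"lateral band [{adapted.lat_right:.2f}, {adapted.lat_left:.2f}]")

# Sessions only start inside the 40-50 cm working distance.
for mm in (350.0, 450.0):
    print(f"distance {mm:.0f} mm -> session_ready = {session_ready(mm)}")
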