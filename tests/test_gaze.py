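import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oculomaze.gaze import (
    DegenerateGeometryError,
    EyeLandmarks,
    Point2D,
    TherapyMode,
    anteroposterior_ratio,
    gaze_sample,
    lateral_ratio,
    min_enclosing_circle,
    pupil_center,
)
from oculomaze.synthetic import landmark_frames_from_ratios

from conftest import brute_force_mec


class TestMinEnclosingCircle:
    @pytest.mark.parametrize("points,center,radius", [
        ([(0.3, 0.4)], (0.3, 0.4), 0.0),
        ([(0, 0), (2, 0)], (1, 0), 1.0),
        ([(0, 0), (1, 0), (0, 1), (1, 1)], (0.5, 0.5), math.sqrt(2) / 2),
        # obtuse triangle: circle spanned by the widest pair only
        ([(0, 0), (4, 0), (1, 0.5)], (2, 0), 2.0),
    ])
    def test_known_circles(self, points, center, radius):
        c = min_enclosing_circle([Point2D(*p) for p in points])
        assert c.center.x == pytest.approx(center[0], abs=1e-4)
        assert c.center.y == pytest.approx(center[1], abs=1e-4)
        assert c.radius == pytest.approx(radius, abs=1e-3)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            min_enclosing_circle([])

    def test_repeated_points_degenerate(self):
        c = min_enclosing_circle([Point2D(0.1, 0.2)] * 4)
        assert (c.center.x, c.center.y, c.radius) == (0.1, 0.2, 0.0)

    def test_agrees_with_shapely(self):
        """Cross-check the radius against GEOS's minimum bounding circle
        on random point clouds."""
        from shapely import MultiPoint, minimum_bounding_radius
        rng = np.random.default_rng(31)
        for _ in range(50):
            pts = rng.uniform(-1, 1, size=(int(rng.integers(2, 9)), 2))
            mine = min_enclosing_circle([Point2D(x, y) for x, y in pts])
            assert mine.radius == pytest.approx(
                minimum_bounding_radius(MultiPoint(pts.tolist())), abs=1e-9)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.lists(
        st.tuples(st.floats(-1, 1, allow_nan=False, width=32),
                  st.floats(-1, 1, allow_nan=False, width=32)),
        min_size=1, max_size=8))
    def test_agrees_with_brute_force_oracle(self, points):
        """Welzl result covers every point and matches the exhaustive
        pair/triple oracle's radius."""
        mine = min_enclosing_circle([Point2D(*p) for p in points])
        oracle = brute_force_mec(points)
        for x, y in points:
            assert mine.contains(Point2D(x, y), tol=1e-9)
        assert mine.radius == pytest.approx(oracle.radius, abs=1e-9)


class TestPupilCenter:
    def test_square_iris_symmetry(self, square_iris_eye):
        p = pupil_center(square_iris_eye)
        assert (p.x, p.y) == (pytest.approx(0.5), pytest.approx(0.5))

    def test_asymmetric_iris_matches_oracle(self, square_iris_eye):
        iris = (Point2D(0.0, 0.0), Point2D(0.04, 0.0),
                Point2D(0.02, 0.02), Point2D(0.02, -0.02))
        eye = EyeLandmarks(iris=iris, outer_corner=square_iris_eye.outer_corner,
                           inner_corner=square_iris_eye.inner_corner,
                           upper=square_iris_eye.upper, lower=square_iris_eye.lower)
        p = pupil_center(eye)
        assert (p.x, p.y) == (pytest.approx(0.02), pytest.approx(0.0, abs=1e-12))


class TestRatios:
    def test_lateral_ratio_hand_values(self, square_iris_eye):
        eye = square_iris_eye
        assert lateral_ratio(Point2D(eye.outer_corner.x, 0.5), eye) == 0.0
        assert lateral_ratio(Point2D(0.5, 0.5), eye) == pytest.approx(0.5)

    def test_lateral_ratio_formula(self):
        eye = EyeLandmarks(
            iris=(Point2D(0.34, 0.5),) * 4,
            outer_corner=Point2D(0.30, 0.50), inner_corner=Point2D(0.40, 0.50),
            upper=Point2D(0.35, 0.47), lower=Point2D(0.35, 0.53))
        assert lateral_ratio(Point2D(0.342, 0.5), eye) == pytest.approx(0.42)

    @pytest.mark.parametrize("pupil_y,expected", [(0.45, 0.0), (0.55, -1.0),
                                                  (0.50, -0.5)])
    def test_anteroposterior_endpoints(self, square_iris_eye, pupil_y, expected):
        r = anteroposterior_ratio(Point2D(0.5, pupil_y), square_iris_eye)
        assert r == pytest.approx(expected)

    def test_overshoot_clamps_not_raises(self, square_iris_eye):
        assert lateral_ratio(Point2D(0.99, 0.5), square_iris_eye) == 1.0
        assert anteroposterior_ratio(Point2D(0.5, 0.99), square_iris_eye) == -1.0

    def test_zero_width_is_degenerate(self, square_iris_eye):
        with pytest.raises(DegenerateGeometryError):
            EyeLandmarks(iris=square_iris_eye.iris,
                         outer_corner=Point2D(0.5, 0.5),
                         inner_corner=Point2D(0.5, 0.5),
                         upper=Point2D(0.5, 0.45), lower=Point2D(0.5, 0.55))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(0, 1), st.floats(0, 1))
    def test_ratios_stay_in_legal_ranges(self, fx, fy):
        """Any pupil inside the contour box yields lateral in [0,1] and
        anteroposterior in [-1,0]."""
        eye = EyeLandmarks(
            iris=(Point2D(0.36, 0.5),) * 4,
            outer_corner=Point2D(0.30, 0.50), inner_corner=Point2D(0.42, 0.50),
            upper=Point2D(0.36, 0.47), lower=Point2D(0.36, 0.53))
        pupil = Point2D(0.30 + 0.12 * fx, 0.47 + 0.06 * fy)
        assert 0.0 <= lateral_ratio(pupil, eye) <= 1.0
        assert -1.0 <= anteroposterior_ratio(pupil, eye) <= 0.0


class TestGazeSample:
    def test_identical_eyes_give_equal_binocular(self):
        frames = landmark_frames_from_ratios([(0.7, -0.3)])
        s = gaze_sample(frames[0], TherapyMode.BIN)
        assert s.ratio_bin == pytest.approx(s.ratio_left)
        assert s.ratio_bin == pytest.approx(s.ratio_right)

    def test_binocular_mean_of_differing_eyes(self):
        frames = landmark_frames_from_ratios([((0.71, -0.5), (0.90, -0.5))])
        s = gaze_sample(frames[0], TherapyMode.BIN)
        assert s.ratio_bin == pytest.approx(0.805)

    def test_monocular_right_leaves_left_absent(self):
        frames = landmark_frames_from_ratios([(0.5, -0.5)])
        s = gaze_sample(frames[0], TherapyMode.MON_DER)
        assert s.ratio_left is None and s.ratio_V_left is None
        assert s.ratio_bin is None
        assert s.ratio_right == pytest.approx(0.5)

    def test_monocular_left_leaves_right_absent(self):
        frames = landmark_frames_from_ratios([(0.5, -0.5)])
        s = gaze_sample(frames[0], TherapyMode.MON_IZQ)
        assert s.ratio_right is None and s.ratio_V_right is None
        assert s.ratio_left == pytest.approx(0.5)

    def test_binocular_extremes_bounded_by_per_eye_extremes(self):
        """max over time of the binocular mean never exceeds the mean of
        the per-eye maxima (and dually for minima)."""
        rng = np.random.default_rng(7)
        ratios = [((float(a), -0.5), (float(b), -0.5))
                  for a, b in rng.uniform(0.1, 0.9, size=(200, 2))]
        samples = [gaze_sample(f) for f in landmark_frames_from_ratios(ratios)]
        rb = [s.ratio_bin for s in samples]
        rl = [s.ratio_left for s in samples]
        rr = [s.ratio_right for s in samples]
        assert max(rb) <= (max(rl) + max(rr)) / 2 + 1e-12
        assert min(rb) >= (min(rl) + min(rr)) / 2 - 1e-12

    def test_mode_labels_parse(self):
        assert TherapyMode.parse("binocular") is TherapyMode.BIN
        assert TherapyMode.parse("Mon-Izq") is TherapyMode.MON_IZQ
        assert TherapyMode.parse("right") is TherapyMode.MON_DER
        with pytest.raises(ValueError):
            TherapyMode.parse("cyclops")
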