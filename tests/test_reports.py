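import json

import numpy as np
import pandas as pd
import pytest

from oculomaze.maze import LevelResult, SessionRecord
from oculomaze.reports import (
    fixation_validation_stats,
    linear_regression,
    two_way_anova,
    weekly_report,
)
from oculomaze.synthetic import generate_fixation_protocol


def normal_equations_fit(x, y):
    """Independent closed-form OLS oracle via the normal equations."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return beta[1], beta[0], 1 - ss_res / ss_tot


class TestLinearRegression:
    def test_perfect_fit(self):
        r = linear_regression([0, 1, 2, 3], [1, 3, 5, 7])
        assert r.slope == pytest.approx(2.0)
        assert r.intercept == pytest.approx(1.0)
        assert r.r_squared == pytest.approx(1.0)
        assert 0 < r.p_value <= 1

    def test_constant_response(self):
        r = linear_regression([1, 2, 3, 4], [5, 5, 5, 5])
        assert r.slope == 0.0
        assert r.r_squared == 0.0

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(11)
        x = np.arange(6, dtype=float)
        y = 3.0 - 0.4 * x + rng.normal(0, 0.5, size=6)
        r = linear_regression(x, y)
        slope, intercept, r2 = normal_equations_fit(x, y)
        assert r.slope == pytest.approx(slope, abs=1e-10)
        assert r.intercept == pytest.approx(intercept, abs=1e-10)
        assert r.r_squared == pytest.approx(r2, abs=1e-10)

    def test_r_squared_is_squared_pearson(self):
        rng = np.random.default_rng(5)
        x = np.arange(10, dtype=float)
        y = 2 * x + rng.normal(0, 2, size=10)
        r = linear_regression(x, y)
        assert r.r_squared == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2)

    def test_p_value_invariant_under_affine_rescaling(self):
        rng = np.random.default_rng(9)
        x = np.arange(8, dtype=float)
        y = 1 + 0.3 * x + rng.normal(0, 1, size=8)
        p1 = linear_regression(x, y).p_value
        p2 = linear_regression(x, 100.0 * y - 7.0).p_value
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            linear_regression([1], [2])
        with pytest.raises(ValueError):
            linear_regression([2, 2, 2], [1, 2, 3])

    def test_two_points_have_no_p_value(self):
        r = linear_regression([0, 1], [0, 2])
        assert r.p_value is None
        assert r.slope == pytest.approx(2.0)


def toy_table(values_by_cell, replicates=2):
    rows = []
    for (u, m), vals in values_by_cell.items():
        for v in vals:
            rows.append({"user": u, "movement": m, "value": v})
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_all_cells_identical_gives_zero_f(self):
        table = toy_table({(u, m): [1.0, 1.0]
                           for u in "ab" for m in "xy"})
        res = two_way_anova(table)
        assert res.f_user == res.f_movement == res.f_interaction == 0.0

    def test_matches_textbook_ss_decomposition(self):
        """2 users x 2 movements x 2 replicates, checked against the
        hand-computed balanced sums-of-squares formulas."""
        table = toy_table({("a", "x"): [3.0, 5.0], ("a", "y"): [6.0, 8.0],
                           ("b", "x"): [2.0, 4.0], ("b", "y"): [9.0, 11.0]})
        res = two_way_anova(table)

        y = table["value"].to_numpy()
        grand = y.mean()
        cell_means = table.groupby(["user", "movement"])["value"].mean()
        user_means = table.groupby("user")["value"].mean()
        mov_means = table.groupby("movement")["value"].mean()
        n_rep, n_u, n_m = 2, 2, 2
        ss_user = n_rep * n_m * float(((user_means - grand) ** 2).sum())
        ss_mov = n_rep * n_u * float(((mov_means - grand) ** 2).sum())
        ss_cells = n_rep * float(((cell_means - grand) ** 2).sum())
        ss_inter = ss_cells - ss_user - ss_mov
        ss_err = float(sum((table[(table.user == u) & (table.movement == m)]["value"]
                            - cell_means[(u, m)]).pow(2).sum()
                           for u in "ab" for m in "xy"))
        assert res.ss["user"] == pytest.approx(ss_user, abs=1e-9)
        assert res.ss["movement"] == pytest.approx(ss_mov, abs=1e-9)
        assert res.ss["interaction"] == pytest.approx(ss_inter, abs=1e-9)
        assert res.ss["error"] == pytest.approx(ss_err, abs=1e-9)

    def test_ss_decomposition_closes(self):
        rng = np.random.default_rng(2)
        table = toy_table({(u, m): rng.normal(0, 1, 3).tolist()
                           for u in "abcd" for m in "xy"})
        res = two_way_anova(table)
        total = sum(res.ss[k] for k in ("user", "movement", "interaction", "error"))
        y = table["value"].to_numpy()
        assert total == pytest.approx(float(((y - y.mean()) ** 2).sum()), abs=1e-9)

    def test_injected_user_effect_dominates(self):
        rng = np.random.default_rng(4)
        user_effects = {"a": -1.0, "b": 0.0, "c": 1.0, "d": 2.0}
        table = toy_table({(u, m): (user_effects[u]
                                    + rng.normal(0, 0.3, 5)).tolist()
                           for u in "abcd" for m in "xy"})
        res = two_way_anova(table)
        assert res.f_user > res.f_movement

    def test_unbalanced_design_rejected(self):
        table = toy_table({("a", "x"): [1, 2, 3], ("a", "y"): [1, 2],
                           ("b", "x"): [1, 2], ("b", "y"): [1, 2]})
        with pytest.raises(ValueError):
            two_way_anova(table)

    def test_single_replicate_rejected(self):
        table = toy_table({(u, m): [1.0] for u in "ab" for m in "xy"})
        with pytest.raises(ValueError):
            two_way_anova(table)


class TestFixationValidation:
    @pytest.fixture
    def protocol(self):
        return generate_fixation_protocol(users=("16", "17"), n_trials=2,
                                          fixation_s=2.0, noise_sd=0.0, seed=0)

    def test_row_count_is_users_times_variables(self, protocol):
        stats = fixation_validation_stats(protocol)
        assert len(stats) == 2 * 4

    def test_noise_free_protocol_has_zero_cv(self, protocol):
        stats = fixation_validation_stats(protocol)
        assert (stats["CV (%)"].abs() < 1e-9).all()

    def test_programmed_jitter_recovered_as_cv(self):
        """Jitter sigma=0.03 around a mean near 0.5 should appear as a CV
        near 100*0.03/0.5 = 6%, within sampling error."""
        df = generate_fixation_protocol(users=("16",), n_trials=5,
                                        fixation_s=10.0, noise_sd=0.03,
                                        seed=1, user_spread=0.0)
        stats = fixation_validation_stats(df)
        row = stats[stats["Variable"] == "ratio_right"].iloc[0]
        expected_cv = 100 * 0.03 / abs(row["Mean"])
        assert row["CV (%)"] == pytest.approx(expected_cv, rel=0.15)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            fixation_validation_stats(pd.DataFrame({"user": [], "trial": []}))


def make_session(idx, total_ms, errors, trace=None):
    lv = LevelResult(level=2, checkpoint_times=[total_ms // 3, 2 * total_ms // 3,
                                               total_ms],
                     total_ms=total_ms, errors=errors, completed=True)
    return SessionRecord(user_id=f"u{idx}", mode="Bin", levels=[lv],
                         gaze_trace=trace)


class TestWeeklyReport:
    def test_single_session_omits_regression(self, tmp_path):
        report = weekly_report([make_session(1, 60000, 10)], tmp_path)
        assert report["regressions"] == {}
        assert (tmp_path / "report.json").exists()
        assert (tmp_path / "tables" / "sessions.csv").exists()

    def test_decreasing_times_give_negative_slope(self, tmp_path):
        records = [make_session(i, 90000 - 5000 * i, 30 - 3 * i)
                   for i in range(1, 6)]
        report = weekly_report(records, tmp_path)
        assert report["regressions"]["total_ms"]["slope"] < 0
        assert report["regressions"]["errors"]["slope"] < 0

    def test_bundle_reproducible(self, tmp_path):
        from oculomaze.gaze import TherapyMode, gaze_sample
        from oculomaze.synthetic import landmark_frames_from_ratios
        trace = [gaze_sample(f) for f in landmark_frames_from_ratios(
            [(0.3, -0.3), (0.7, -0.7)])]
        records = [make_session(i, 80000 + i * 1000, 20 + i, trace)
                   for i in range(1, 4)]
        a_dir, b_dir = tmp_path / "a", tmp_path / "b"
        ra = weekly_report(records, a_dir)
        rb = weekly_report(records, b_dir)
        assert ra == rb
        assert ((a_dir / "report.json").read_bytes()
                == (b_dir / "report.json").read_bytes())
        for name in ("sessions.csv", "displacements.csv"):
            assert ((a_dir / "tables" / name).read_bytes()
                    == (b_dir / "tables" / name).read_bytes())
        # figures asserted via their underlying data (the report numbers),
        # not pixels; presence is enough here
        assert (a_dir / "figures" / "ellipses.svg").exists()
        assert (a_dir / "figures" / "regression_total_ms.svg").exists()
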