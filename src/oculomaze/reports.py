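"""Session-over-session reporting.

Weekly progress reports bundle displacement ellipses, tabulated session
metrics, and ordinary-least-squares regressions of total time and error
count against session index (slope, R², two-sided p).  Fixation
validation traces are summarized per user (mean ± STD and CV per gaze
variable) and compared across users and movement axes with a two-way
fixed-effects ANOVA with interaction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegressionResult",
    "AnovaResult",
    "linear_regression",
    "two_way_anova",
    "fixation_validation_stats",
    "weekly_report",
]


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of a response against session index."""

    slope: float
    intercept: float
    r_squared: float
    p_value: Optional[float]
    n: int


@dataclass(frozen=True)
class AnovaResult:
    """Two-way fixed-effects ANOVA with interaction.

    F and p per factor (user, movement, user x movement), plus the
    sums-of-squares decomposition."""

    f_user: float
    p_user: float
    f_movement: float
    p_movement: float
    f_interaction: float
    p_interaction: float
    ss: dict[str, float]


def linear_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares of y on x.

    R² is 1 - SS_res/SS_tot; the p-value is the two-sided test of a
    nonzero slope on the t distribution with n-2 degrees of freedom
    (reported only for n >= 3).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("regression needs >= 2 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("x values are all equal; slope is undefined")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        # Constant response: zero slope, nothing explained, no evidence
        # against the null.
        return RegressionResult(slope=0.0, intercept=float(y.mean()),
                                r_squared=0.0,
                                p_value=1.0 if x.size >= 3 else None,
                                n=int(x.size))
    fit = stats.linregress(x, y)
    # A numerically perfect fit underflows the t tail; keep p in (0, 1].
    p_value = max(float(fit.pvalue), 5e-324) if x.size >= 3 else None
    return RegressionResult(slope=float(fit.slope), intercept=float(fit.intercept),
                            r_squared=float(fit.rvalue ** 2),
                            p_value=p_value, n=int(x.size))


def two_way_anova(table: pd.DataFrame, value: str = "value", user: str = "user",
                  movement: str = "movement") -> AnovaResult:
    """Balanced two-factor fixed-effects ANOVA with interaction.

    ``table`` is long-form with one row per trial.  The design must be
    balanced with at least 2 replicates per (user, movement) cell, as in
    the validation protocol (5 trials x 4 users x 2 movement axes).
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    counts = table.groupby([user, movement], observed=True)[value].count()
    expected_cells = table[user].nunique() * table[movement].nunique()
    if len(counts) != expected_cells or counts.nunique() != 1:
        raise ValueError("design must be balanced (all user x movement cells filled "
                         "with equal replicate counts)")
    if counts.iloc[0] < 2:
        raise ValueError("need >= 2 replicates per cell for the interaction term")

    df = table.rename(columns={value: "_y", user: "_u", movement: "_m"})
    if np.ptp(df["_y"].to_numpy(dtype=float)) == 0.0:
        # Perfectly flat response: every SS is zero and each F is 0/0;
        # report no effect rather than NaN.
        zeros = {k: 0.0 for k in ("user", "movement", "interaction", "error")}
        zeros["total"] = 0.0
        return AnovaResult(f_user=0.0, p_user=1.0, f_movement=0.0, p_movement=1.0,
                           f_interaction=0.0, p_interaction=1.0, ss=zeros)
    model = ols("_y ~ C(_u) * C(_m)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    ss = {
        "user": float(aov.loc["C(_u)", "sum_sq"]),
        "movement": float(aov.loc["C(_m)", "sum_sq"]),
        "interaction": float(aov.loc["C(_u):C(_m)", "sum_sq"]),
        "error": float(aov.loc["Residual", "sum_sq"]),
    }
    ss["total"] = sum(ss.values())

    def f_p(term: str, ss_term: float) -> tuple[float, float]:
        # A factor with zero SS over zero error SS is a flat response:
        # no effect, F = 0 by convention.
        if ss_term == 0.0:
            return 0.0, 1.0
        return float(aov.loc[term, "F"]), float(aov.loc[term, "PR(>F)"])

    f_u, p_u = f_p("C(_u)", ss["user"])
    f_m, p_m = f_p("C(_m)", ss["movement"])
    f_i, p_i = f_p("C(_u):C(_m)", ss["interaction"])
    return AnovaResult(f_user=f_u, p_user=p_u, f_movement=f_m, p_movement=p_m,
                       f_interaction=f_i, p_interaction=p_i, ss=ss)


_VARIABLES = ["ratio_right", "ratio_V_right", "ratio_left", "ratio_V_left"]


def fixation_validation_stats(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-user fixation-stability table.

    ``trials`` is long-form with columns ``user``, ``trial``, ``segment``
    and the four gaze variables (one row per frame; ``segment`` labels
    which fixation target the frame belongs to).  Returns one row per
    user per variable with columns ``User``, ``Variable``, ``Mean``,
    ``STD``, ``CV (%)``.

    The mean is the grand mean over all of the user's frames.  The STD is
    the *within-fixation* sample standard deviation, pooled over the
    (trial, segment) fixations — i.e. the steadiness of the held gaze,
    not the programmed travel between targets — and CV = 100·STD/|mean|.
    """
    required = {"user", "trial", "segment"} | set(_VARIABLES)
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trials table missing columns: {sorted(missing)}")
    rows = []
    for usr, grp in trials.groupby("user", sort=True):
        if grp["trial"].nunique() < 1:
            raise ValueError(f"user {usr}: no trials")
        for var in _VARIABLES:
            vals = grp[var].dropna()
            mean = float(vals.mean())
            # Pooled within-group variance: sum of squared residuals about
            # each fixation's own mean, over (n_total - n_groups).
            groups = grp.loc[vals.index].groupby(["trial", "segment"],
                                                 observed=True)[var]
            sse = float(((vals - groups.transform("mean")) ** 2).sum())
            dof = int(vals.size - groups.ngroups)
            std = math.sqrt(sse / dof) if dof > 0 else 0.0
            cv = 100.0 * std / abs(mean) if mean != 0 else np.nan
            rows.append({"User": usr, "Variable": var, "Mean": mean,
                         "STD": std, "CV (%)": cv})
    return pd.DataFrame(rows)


def weekly_report(records: Sequence, out_dir: Union[str, Path],
                  mode_attr: str = "mode") -> dict:
    """Build a report bundle for a batch of session records.

    Writes ``report.json`` (all numbers), ``tables/*.csv`` (displacement
    and session layouts) and ``figures/*.svg`` (ellipses per session,
    regression lines).  Regressions of total time and errors against
    session index are included once there are at least 2 sessions.
    Returns the report dictionary.
    """
    from .io import sessions_frame, extremes_frame
    from .metrics import displacement_extremes, ellipse_from_extremes
    from .gaze import TherapyMode

    if not records:
        raise ValueError("weekly_report needs at least one session record")
    out_dir = Path(out_dir)
    (out_dir / "tables").mkdir(parents=True, exist_ok=True)
    (out_dir / "figures").mkdir(parents=True, exist_ok=True)

    report: dict = {"n_sessions": len(records), "sessions": [], "regressions": {}}
    ellipses = []
    for idx, rec in enumerate(records, start=1):
        entry = {
            "index": idx,
            "user_id": rec.user_id,
            "mode": getattr(rec, mode_attr),
            "total_ms": rec.total_ms,
            "errors": rec.total_errors,
        }
        if rec.gaze_trace:
            mode = TherapyMode.parse(rec.mode)
            ext = displacement_extremes(rec.gaze_trace, mode)
            lat_sig, ap_sig = _primary_signals(mode)
            ell = ellipse_from_extremes(ext.min[lat_sig], ext.max[lat_sig],
                                        ext.min[ap_sig], ext.max[ap_sig])
            entry["extremes"] = {"max": ext.max, "min": ext.min}
            entry["ellipse"] = {
                "center_x": ell.center_x, "center_y": ell.center_y,
                "semi_axis_x": ell.semi_axis_x, "semi_axis_y": ell.semi_axis_y,
            }
            ellipses.append((idx, ell))
        report["sessions"].append(entry)

    totals = [rec.total_ms for rec in records]
    errors = [rec.total_errors for rec in records]
    if len(records) >= 2:
        xs = list(range(1, len(records) + 1))
        for name, ys in (("total_ms", totals), ("errors", errors)):
            r = linear_regression(xs, [float(v) for v in ys])
            report["regressions"][name] = {
                "slope": r.slope, "intercept": r.intercept,
                "r_squared": r.r_squared, "p_value": r.p_value, "n": r.n,
            }

    extremes_frame(records).to_csv(out_dir / "tables" / "displacements.csv",
                                   index=False)
    sessions_frame(records).to_csv(out_dir / "tables" / "sessions.csv", index=False)

    _render_figures(out_dir / "figures", ellipses, totals, errors,
                    report["regressions"])
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True)
                                         + "\n")
    return report


def _primary_signals(mode) -> tuple[str, str]:
    from .gaze import TherapyMode
    if mode is TherapyMode.MON_IZQ:
        return "LI", "AI"
    if mode is TherapyMode.MON_DER:
        return "LD", "AD"
    return "LB", "AB"


def _render_figures(fig_dir: Path, ellipses, totals, errors, regressions) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse as MplEllipse

    if ellipses:
        fig, ax = plt.subplots(figsize=(5, 5))
        for idx, ell in ellipses:
            ax.add_patch(MplEllipse((ell.center_x, ell.center_y),
                                    2 * ell.semi_axis_x, 2 * ell.semi_axis_y,
                                    fill=False, label=f"session {idx}"))
        ax.set_xlim(0, 1)
        ax.set_ylim(-1, 0)
        ax.set_xlabel("lateral ratio")
        ax.set_ylabel("anteroposterior ratio")
        ax.legend(loc="lower right", fontsize="small")
        fig.savefig(fig_dir / "ellipses.svg", metadata={"Date": None})
        plt.close(fig)

    if regressions:
        xs = np.arange(1, len(totals) + 1)
        for name, ys in (("total_ms", totals), ("errors", errors)):
            reg = regressions[name]
            fig, ax = plt.subplots(figsize=(5, 4))
            ax.plot(xs, ys, "o")
            ax.plot(xs, reg["intercept"] + reg["slope"] * xs, "-")
            label = f"R²={reg['r_squared']:.3f}"
            if reg["p_value"] is not None:
                label += f", p={reg['p_value']:.3g}"
            ax.set_title(f"{name} vs session ({label})")
            ax.set_xlabel("session index")
            ax.set_ylabel(name)
            fig.savefig(fig_dir / f"regression_{name}.svg", metadata={"Date": None})
            plt.close(fig)
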