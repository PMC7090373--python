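"""Multi-timepoint stability analysis of calculated tHb-mass.

With the time-dependent CO-loss corrections applied, the tHb-mass computed
from a blood sample at any time between ~7 and 20 min should agree: the
corrections exactly offset the post-peak decline of COHb%. This module
computes tHb-mass on a sampling-time grid per subject, summarizes the
cohort per timepoint, and tests stability with a paired contrast
(reference vs comparison time) and a one-way repeated-measures ANOVA.

The analysis is exposed statsmodels-style: build a :class:`StabilityModel`
from sessions or a long-format table, call :meth:`~StabilityModel.fit`, and
read estimates, p-values and a ``summary()`` table off the returned
:class:`StabilityResults`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import core, stats
from .core import CorrectionParams, THbResult
from .errors import OcorError
from .session import OcorSession, Subject

__all__ = [
    "DEFAULT_TIME_GRID",
    "PairedContrast",
    "StabilityModel",
    "StabilityResults",
    "thb_timecourse",
    "timepoint_summary",
    "paired_contrast",
    "repeated_measures_anova",
    "cohort_summary",
]

#: Sampling grid of the standard extended protocol (minutes); 7 is the
#: symbolic mean-of-6-and-8 measurement point.
DEFAULT_TIME_GRID: tuple[float, ...] = (6.0, 7.0, 8.0, 10.0, 12.0, 15.0, 20.0)

#: Grid used for the repeated-measures ANOVA (actual draws only).
ANOVA_TIME_GRID: tuple[float, ...] = (6.0, 8.0, 10.0, 12.0, 15.0, 20.0)


@dataclass(frozen=True)
class PairedContrast:
    ref_time: float
    cmp_time: float
    n_pairs: int
    mean_diff_g: float
    pct_diff: float
    t: float
    p: float
    degenerate_variance: bool = False


def thb_timecourse(
    session: OcorSession,
    times: Sequence[float] = DEFAULT_TIME_GRID,
    params: CorrectionParams | None = None,
) -> list[THbResult]:
    """tHb-mass at each requested time; missing/invalid times are flagged, not fatal."""
    params = params or CorrectionParams()
    out: list[THbResult] = []
    for t in times:
        try:
            out.append(core.thb_mass_at(session, t, params))
        except OcorError as exc:
            out.append(
                THbResult(
                    time_min=t,
                    delta_cohb_pct=math.nan,
                    absorbed_co_ml=math.nan,
                    thb_mass_g=math.nan,
                    flags=(type(exc).__name__,),
                )
            )
    return out


def cohort_timecourse(
    sessions: Iterable[OcorSession],
    times: Sequence[float] = DEFAULT_TIME_GRID,
    params: CorrectionParams | None = None,
) -> pd.DataFrame:
    """Long-format table (subject_id, time_min, cohb_pct, thb_mass_g) for a cohort."""
    rows = []
    for session in sessions:
        base = core.baseline_cohb(session)
        for res in thb_timecourse(session, times, params):
            cohb = base + res.delta_cohb_pct if math.isfinite(res.delta_cohb_pct) else math.nan
            rows.append(
                {
                    "subject_id": session.subject_id,
                    "time_min": res.time_min,
                    "cohb_pct": cohb,
                    "thb_mass_g": res.thb_mass_g,
                }
            )
    return pd.DataFrame(rows, columns=["subject_id", "time_min", "cohb_pct", "thb_mass_g"])


def timepoint_summary(timecourse: pd.DataFrame, times: Sequence[float] | None = None) -> pd.DataFrame:
    """Per-timepoint cohort summary: median [Q1-Q3] COHb%, mean ± SD tHb-mass.

    Quartiles use the midpoint-of-halves convention (median excluded from
    the halves); SD is the sample SD (n−1).
    """
    if timecourse.empty:
        raise OcorError("timepoint_summary requires a non-empty cohort")
    times = tuple(times) if times is not None else tuple(sorted(timecourse["time_min"].unique()))
    rows = []
    for t in times:
        sub = timecourse[timecourse["time_min"] == t].dropna(subset=["thb_mass_g"])
        if len(sub) < 2:
            raise OcorError(f"timepoint_summary requires >= 2 subjects at t={t}")
        q1, med, q3 = stats.tukey_quartiles(sub["cohb_pct"].to_numpy())
        rows.append(
            {
                "time_min": t,
                "n": len(sub),
                "cohb_median_pct": med,
                "cohb_q1_pct": q1,
                "cohb_q3_pct": q3,
                "thb_mean_g": float(sub["thb_mass_g"].mean()),
                "thb_sd_g": float(sub["thb_mass_g"].std(ddof=1)),
            }
        )
    return pd.DataFrame(rows)


def _pivot(timecourse: pd.DataFrame, times: Sequence[float]) -> pd.DataFrame:
    wide = timecourse.pivot(index="subject_id", columns="time_min", values="thb_mass_g")
    missing = [t for t in times if t not in wide.columns]
    if missing:
        raise OcorError(f"no results at requested times {missing}")
    return wide[list(times)]


def paired_contrast(
    timecourse: pd.DataFrame, ref_time: float, cmp_time: float
) -> PairedContrast:
    """Paired comparison of tHb-mass between two sampling times.

    Pairwise-complete subjects; mean difference is comparison − reference,
    percent difference is relative to the reference-time mean.
    """
    wide = _pivot(timecourse, [ref_time, cmp_time]).dropna()
    if len(wide) < 2:
        raise OcorError("paired_contrast requires >= 2 complete pairs")
    ref = wide[ref_time].to_numpy()
    cmp_ = wide[cmp_time].to_numpy()
    res = stats.paired_t(cmp_ - ref)
    ref_mean = float(ref.mean())
    return PairedContrast(
        ref_time=ref_time,
        cmp_time=cmp_time,
        n_pairs=len(wide),
        mean_diff_g=res.mean_diff,
        pct_diff=100.0 * res.mean_diff / ref_mean,
        t=res.t,
        p=res.p,
        degenerate_variance=res.degenerate_variance,
    )


def repeated_measures_anova(
    timecourse: pd.DataFrame, times: Sequence[float] = ANOVA_TIME_GRID
) -> stats.RMAnovaResult:
    """One-way within-subject ANOVA of tHb-mass across the time grid.

    Complete cases only (listwise deletion over the grid).
    """
    wide = _pivot(timecourse, times).dropna()
    return stats.rm_anova(wide.to_numpy())


def cohort_summary(table: pd.DataFrame) -> dict:
    """Cohort description from a per-patient table.

    Expects columns sex, hb_g_l, thb_mass_g, dose_co_ml, dose_ml_per_kg,
    delta_cohb7_pct. Returns the study-style summary: mean ± SD doses and
    tHb-mass, median [Q1-Q3] [Hb], WHO anemia count/percent with subgroup
    [Hb] means, and the male dose-level breakdown.
    """
    from .dosing import classify_anemia

    if table.empty:
        raise OcorError("cohort_summary requires a non-empty cohort")
    anemic = table.apply(lambda r: classify_anemia(r["hb_g_l"], r["sex"]), axis=1)
    q1, med, q3 = stats.tukey_quartiles(table["hb_g_l"].to_numpy())
    males = table[table["sex"] == "male"]
    dose_levels = {
        round(level, 1): int((males["dose_ml_per_kg"].round(1) == round(level, 1)).sum())
        for level in sorted(males["dose_ml_per_kg"].round(1).unique())
    }
    n = len(table)
    summary = {
        "n": n,
        "mean_dose_ml_per_kg": float(table["dose_ml_per_kg"].mean()),
        "sd_dose_ml_per_kg": float(table["dose_ml_per_kg"].std(ddof=1)),
        "mean_dose_ml": float(table["dose_co_ml"].mean()),
        "sd_dose_ml": float(table["dose_co_ml"].std(ddof=1)),
        "mean_thb_mass_g": float(table["thb_mass_g"].mean()),
        "sd_thb_mass_g": float(table["thb_mass_g"].std(ddof=1)),
        "median_hb_g_l": med,
        "hb_q1_g_l": q1,
        "hb_q3_g_l": q3,
        "mean_delta_cohb7_pct": float(table["delta_cohb7_pct"].mean()),
        "sd_delta_cohb7_pct": float(table["delta_cohb7_pct"].std(ddof=1)),
        "anemic_n": int(anemic.sum()),
        "anemic_pct": 100.0 * float(anemic.mean()),
        "anemic_mean_hb_g_l": float(table.loc[anemic, "hb_g_l"].mean()),
        "non_anemic_mean_hb_g_l": float(table.loc[~anemic, "hb_g_l"].mean()),
        "n_males": len(males),
        "males_by_dose_level": dose_levels,
    }
    return summary


class StabilityModel:
    """Timepoint-stability analysis of calculated tHb-mass.

    Parameters
    ----------
    timecourse : DataFrame
        Long format with columns subject_id, time_min, cohb_pct,
        thb_mass_g (one row per subject × time).
    """

    def __init__(self, timecourse: pd.DataFrame):
        required = {"subject_id", "time_min", "thb_mass_g"}
        missing = required - set(timecourse.columns)
        if missing:
            raise OcorError(f"timecourse table missing columns {sorted(missing)}")
        if "cohb_pct" not in timecourse.columns:
            timecourse = timecourse.assign(cohb_pct=np.nan)
        self.data = timecourse.reset_index(drop=True)

    @classmethod
    def from_sessions(
        cls,
        sessions: Iterable[OcorSession],
        times: Sequence[float] = DEFAULT_TIME_GRID,
        params: CorrectionParams | None = None,
    ) -> "StabilityModel":
        return cls(cohort_timecourse(sessions, times, params))

    def fit(
        self,
        ref_time: float = core.SEVEN_MIN,
        cmp_time: float = 20.0,
        anova_times: Sequence[float] = ANOVA_TIME_GRID,
    ) -> "StabilityResults":
        available = set(self.data["time_min"].unique())
        anova_times = tuple(t for t in anova_times if t in available)
        summary = timepoint_summary(self.data)
        contrast = paired_contrast(self.data, ref_time, cmp_time)
        anova = repeated_measures_anova(self.data, anova_times)
        return StabilityResults(
            model=self,
            per_timepoint=summary,
            contrast=contrast,
            anova=anova,
            anova_times=anova_times,
        )


@dataclass
class StabilityResults:
    """Fitted stability analysis: per-timepoint summaries, contrast, ANOVA."""

    model: StabilityModel
    per_timepoint: pd.DataFrame
    contrast: PairedContrast
    anova: stats.RMAnovaResult
    anova_times: tuple[float, ...]

    @property
    def anova_f(self) -> float:
        return self.anova.f

    @property
    def anova_p(self) -> float:
        return self.anova.p

    def summary(self) -> str:
        """Plain-text report in the style of a results section."""
        lines = ["tHb-mass timepoint stability", "=" * 46]
        lines.append(f"{'t (min)':>8} {'n':>4} {'COHb% median [IQR]':>24} {'tHb mean±SD (g)':>20}")
        for _, row in self.per_timepoint.iterrows():
            cohb = (
                f"{row.cohb_median_pct:.2f} [{row.cohb_q1_pct:.2f}-{row.cohb_q3_pct:.2f}]"
                if math.isfinite(row.cohb_median_pct)
                else "-"
            )
            lines.append(
                f"{row.time_min:>8g} {int(row.n):>4} {cohb:>24} "
                f"{row.thb_mean_g:>12.1f} ± {row.thb_sd_g:.1f}"
            )
        c = self.contrast
        lines.append("")
        lines.append(
            f"Paired contrast {c.ref_time:g} vs {c.cmp_time:g} min (n={c.n_pairs}): "
            f"mean diff {c.mean_diff_g:.1f} g ({c.pct_diff:.1f}%), "
            f"t={c.t:.2f}, p={c.p:.2f}"
        )
        lines.append(
            f"RM-ANOVA over {list(map(float, self.anova_times))} min: "
            f"F({self.anova.df_time},{self.anova.df_error})={self.anova.f:.2f}, "
            f"p={self.anova.p:.2f}"
        )
        return "\n".join(lines)
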