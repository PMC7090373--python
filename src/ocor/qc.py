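"""Session validity gating.

A session yields a reliable tHb-mass only when the COHb rise is large
relative to hemoximeter resolution. The gating rules:

* ΔCOHb%(7 min) < 4.0  → INSUFFICIENT_RISE, session invalid (excluded).
* ΔCOHb%(7 min) > 6.5  → DELTA_ABOVE_TARGET_BAND, warning only (such
  sessions were retained in the study).
* any COHb reading ≥ 10.0% → PEAK_HIGH, warning only (the one study
  subject peaking at 10.1% was retained).
* negative ΔCOHb → NEGATIVE_DELTA, invalid.
* dose outside 0.4–1.0 ml/kg → DOSE_OUT_OF_RANGE, warning (needs weight).
* missing 6- or 8-min samples → MISSING_TIMEPOINT, invalid.

All thresholds are policy-overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from . import core
from .core import CorrectionParams
from .errors import MissingDataError, OcorError
from .session import OcorSession

__all__ = ["QCFlag", "QCPolicy", "QCReport", "validate_session", "filter_cohort"]


class QCFlag:
    INSUFFICIENT_RISE = "INSUFFICIENT_RISE"
    PEAK_HIGH = "PEAK_HIGH"
    DELTA_ABOVE_TARGET_BAND = "DELTA_ABOVE_TARGET_BAND"
    NEGATIVE_DELTA = "NEGATIVE_DELTA"
    DOSE_OUT_OF_RANGE = "DOSE_OUT_OF_RANGE"
    MISSING_TIMEPOINT = "MISSING_TIMEPOINT"


@dataclass(frozen=True)
class QCPolicy:
    min_delta_pct: float = 4.0
    max_target_delta_pct: float = 6.5
    peak_warn_pct: float = 10.0
    dose_range_ml_per_kg: tuple[float, float] = (0.4, 1.0)


@dataclass(frozen=True)
class QCReport:
    session_id: str
    valid: bool
    flags: frozenset[str]
    delta_cohb7_pct: Optional[float] = None
    peak_cohb_pct: Optional[float] = None
    dose_ml_per_kg: Optional[float] = None
    detail: str = ""

    def as_dict(self) -> dict:
        return {
            "session_id": self.session_id,
            "valid": self.valid,
            "flags": sorted(self.flags),
            "delta_cohb7_pct": self.delta_cohb7_pct,
            "peak_cohb_pct": self.peak_cohb_pct,
            "dose_ml_per_kg": self.dose_ml_per_kg,
            "detail": self.detail,
        }


def validate_session(
    session: OcorSession,
    params: CorrectionParams | None = None,
    policy: QCPolicy | None = None,
    *,
    weight_kg: Optional[float] = None,
) -> QCReport:
    """Evaluate the validity rules for one session.

    ``weight_kg`` enables the dose-range check; without it the weight-indexed
    dose cannot be derived from the session alone.
    """
    params = params or CorrectionParams()
    policy = policy or QCPolicy()
    flags: set[str] = set()

    dose_ml_per_kg = None
    if weight_kg is not None and weight_kg > 0:
        dose_ml_per_kg = session.dose_co_ml / weight_kg
        lo, hi = policy.dose_range_ml_per_kg
        # printed doses are 0.1-resolution; don't flag 0.4 stored as 0.39999
        if not lo - 1e-9 <= dose_ml_per_kg <= hi + 1e-9:
            flags.add(QCFlag.DOSE_OUT_OF_RANGE)

    peak = max((s.mean for s in session.timed), default=None)
    if peak is not None and peak >= policy.peak_warn_pct:
        flags.add(QCFlag.PEAK_HIGH)

    try:
        delta7 = core.delta_cohb(session, core.SEVEN_MIN)
    except MissingDataError as exc:
        flags.add(QCFlag.MISSING_TIMEPOINT)
        return QCReport(
            session_id=session.subject_id,
            valid=False,
            flags=frozenset(flags),
            peak_cohb_pct=peak,
            dose_ml_per_kg=dose_ml_per_kg,
            detail=str(exc),
        )

    if delta7 < 0:
        flags.add(QCFlag.NEGATIVE_DELTA)
    if delta7 < policy.min_delta_pct:
        flags.add(QCFlag.INSUFFICIENT_RISE)
    elif delta7 > policy.max_target_delta_pct:
        flags.add(QCFlag.DELTA_ABOVE_TARGET_BAND)

    valid = not ({QCFlag.INSUFFICIENT_RISE, QCFlag.NEGATIVE_DELTA} & flags)
    return QCReport(
        session_id=session.subject_id,
        valid=valid,
        flags=frozenset(flags),
        delta_cohb7_pct=delta7,
        peak_cohb_pct=peak,
        dose_ml_per_kg=dose_ml_per_kg,
    )


def filter_cohort(
    sessions: Sequence[OcorSession],
    params: CorrectionParams | None = None,
    policy: QCPolicy | None = None,
    *,
    weights_kg: Optional[dict[str, float]] = None,
) -> tuple[list[OcorSession], list[OcorSession], list[QCReport]]:
    """Partition sessions into (valid, excluded) by the validity rules.

    Order-preserving; per-session computation errors yield invalid reports
    rather than aborting the cohort.
    """
    valid: list[OcorSession] = []
    excluded: list[OcorSession] = []
    reports: list[QCReport] = []
    for session in sessions:
        weight = (weights_kg or {}).get(session.subject_id)
        try:
            report = validate_session(session, params, policy, weight_kg=weight)
        except OcorError as exc:
            report = QCReport(
                session_id=session.subject_id,
                valid=False,
                flags=frozenset({QCFlag.MISSING_TIMEPOINT}),
                detail=str(exc),
            )
        reports.append(report)
        (valid if report.valid else excluded).append(session)
    return valid, excluded, reports
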