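"""Core oCOR calculator: absorbed CO and tHb-mass with time-dependent losses.

The optimized CO-rebreathing method binds a known CO volume to circulating
haemoglobin and reads the resulting rise in carboxyhaemoglobin, ΔCOHb%.
Because 1 g of haemoglobin binds ~1.39 ml CO (the Hüfner constant), the
total haemoglobin mass follows from a simple dilution argument:

    tHb-mass [g] = M_CO(t) × 100 / (ΔCOHb%(t) × 1.39)

where M_CO(t) is the CO volume actually bound to circulating Hb at sampling
time t: the administered dose minus CO still in the spirometer/lung at
disconnection, minus CO exhaled after disconnection, minus CO diffused to
myoglobin. Both loss fluxes grow with time, which is why later blood samples
need larger corrections; with them applied, tHb-mass computed from any
sample between ~7 and 20 min should agree.

Loss models
-----------
* Myoglobin flux: linear in time and proportional to dose,
  ``k_myo_per_min × dose × t`` (default k = 0.00175 /min).
* Exhaled CO: constant rate after disconnection,
  ``exhale_rate_ml_per_min × max(0, t − rebreathe_end_min)``.

The canonical measurement point is the "7-min value": the mean of the
replicate-averaged COHb% readings at 6 and 8 min, with losses evaluated at
t = 7. Because both loss models are linear in t this is algebraically
identical to averaging the 6- and 8-min results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .errors import (
    ConfigurationError,
    InfeasibleSessionError,
    InvalidRiseError,
    MissingDataError,
    MissingTimepointError,
)
from .session import COSample, OcorSession

__all__ = [
    "CorrectionParams",
    "THbResult",
    "baseline_cohb",
    "cohb_at",
    "seven_min_cohb",
    "delta_cohb",
    "co_loss_myoglobin",
    "co_loss_exhaled",
    "absorbed_co",
    "stpd",
    "thb_mass_at",
    "SEVEN_MIN",
    "TIME_TOLERANCE_MIN",
]

#: Symbolic sampling time: mean of the 6- and 8-min draws, losses at t = 7.
SEVEN_MIN = 7.0

#: A nominal query time matches a stored sample within this window (minutes).
TIME_TOLERANCE_MIN = 0.5

#: Saturated water-vapor pressure over liquid water, mmHg, by °C.
#: Standard rounded clinical table; linear interpolation between entries.
_P_H2O_MMHG: Mapping[float, float] = {
    0.0: 4.6,
    5.0: 6.5,
    10.0: 9.2,
    15.0: 12.8,
    18.0: 15.5,
    20.0: 17.5,
    22.0: 19.8,
    25.0: 23.8,
    30.0: 31.8,
    35.0: 42.2,
    37.0: 47.1,
    40.0: 55.3,
}


@dataclass(frozen=True)
class CorrectionParams:
    """Physical constants and loss-model parameters.

    huefner_ml_per_g : CO binding capacity of Hb, ml CO per g Hb (1.39).
    k_myo_per_min    : fraction of the dose diffusing to myoglobin per
                       minute (0.00175 /min; 20-min totals over 40–72 ml
                       doses then span 1.4–2.5 ml).
    exhale_rate_ml_per_min : CO exhaled per minute after circuit
                       disconnection (0.15 ml/min default; sessions may
                       override with a measured value).
    apply_stpd       : standardize the syringe CO volume to STPD using the
                       session's ambient temperature/pressure. Off by
                       default so that doses are used as administered.
    """

    huefner_ml_per_g: float = 1.39
    k_myo_per_min: float = 0.00175
    exhale_rate_ml_per_min: float = 0.15
    apply_stpd: bool = False
    vapor_table_mmhg: Mapping[float, float] = field(default_factory=lambda: dict(_P_H2O_MMHG))

    def __post_init__(self) -> None:
        if self.huefner_ml_per_g <= 0:
            raise ValueError("huefner_ml_per_g must be positive")
        if self.k_myo_per_min < 0 or self.exhale_rate_ml_per_min < 0:
            raise ValueError("loss rates cannot be negative")


@dataclass(frozen=True)
class THbResult:
    """tHb-mass computed from one sampling time, with its ingredients."""

    time_min: float
    delta_cohb_pct: float
    absorbed_co_ml: float
    thb_mass_g: float
    flags: tuple[str, ...] = ()


def baseline_cohb(session: OcorSession) -> float:
    """Mean baseline COHb% over all baseline draws (replicates averaged per draw)."""
    if not session.baseline:
        raise MissingDataError(f"session {session.subject_id}: no baseline samples")
    means = [s.mean for s in session.baseline]
    return sum(means) / len(means)


def _find_sample(session: OcorSession, time_min: float) -> COSample:
    candidates = [
        s for s in session.timed if abs(s.time_min - time_min) <= TIME_TOLERANCE_MIN + 1e-12
    ]
    if not candidates:
        raise MissingTimepointError(
            f"session {session.subject_id}: no sample within "
            f"±{TIME_TOLERANCE_MIN} min of t={time_min} min"
        )
    # nearest sample; ties broken toward the earlier draw
    return min(candidates, key=lambda s: (abs(s.time_min - time_min), s.time_min))


def cohb_at(session: OcorSession, time_min: float) -> float:
    """Replicate-averaged COHb% of the timed sample nearest ``time_min``."""
    return _find_sample(session, time_min).mean


def seven_min_cohb(session: OcorSession) -> float:
    """The method's canonical "7-min value": mean of the 6- and 8-min COHb%."""
    return 0.5 * (cohb_at(session, 6.0) + cohb_at(session, 8.0))


def delta_cohb(session: OcorSession, time_min: float) -> float:
    """Absolute COHb% rise from baseline at ``time_min`` (7 = symbolic 7-min value).

    May be negative for noisy or failed sessions; downstream consumers flag
    or reject negative rises rather than clamping them here.
    """
    base = baseline_cohb(session)
    if time_min == SEVEN_MIN:
        post = seven_min_cohb(session)
    else:
        post = cohb_at(session, time_min)
    return post - base


def co_loss_myoglobin(dose_co_ml: float, time_min: float, params: CorrectionParams) -> float:
    """CO volume (ml) diffused from blood to myoglobin by ``time_min``."""
    if time_min < 0:
        raise ValueError("time_min must be non-negative")
    return params.k_myo_per_min * dose_co_ml * time_min


def co_loss_exhaled(
    session: OcorSession, time_min: float, params: CorrectionParams
) -> float:
    """CO volume (ml) exhaled between circuit disconnection and ``time_min``.

    Zero while the subject is still on the rebreathing circuit. Uses the
    session's measured exhalation rate when available.
    """
    if time_min < 0:
        raise ValueError("time_min must be non-negative")
    rate = (
        session.exhale_rate_ml_per_min
        if session.exhale_rate_ml_per_min is not None
        else params.exhale_rate_ml_per_min
    )
    return rate * max(0.0, time_min - session.rebreathe_end_min)


def stpd(
    volume_ml: float,
    temp_c: Optional[float],
    pressure_mmhg: Optional[float],
    params: CorrectionParams,
) -> float:
    """Standardize a gas volume to STPD (0 °C, 760 mmHg, dry).

    Identity when ``params.apply_stpd`` is false. Saturated water-vapor
    pressure is interpolated linearly from ``params.vapor_table_mmhg``.
    """
    if not params.apply_stpd:
        return volume_ml
    if temp_c is None or pressure_mmhg is None:
        raise ConfigurationError("STPD correction requires ambient temperature and pressure")
    table = sorted(params.vapor_table_mmhg.items())
    temps = [t for t, _ in table]
    if not temps[0] <= temp_c <= temps[-1]:
        raise ConfigurationError(
            f"ambient temperature {temp_c} °C outside vapor table range "
            f"[{temps[0]}, {temps[-1]}]"
        )
    # linear interpolation without pulling in numpy for a 12-entry table
    p_h2o = dict(table).get(temp_c)
    if p_h2o is None:
        for (t0, p0), (t1, p1) in zip(table, table[1:]):
            if t0 <= temp_c <= t1:
                p_h2o = p0 + (temp_c - t0) / (t1 - t0) * (p1 - p0)
                break
    return volume_ml * (pressure_mmhg - p_h2o) / 760.0 * 273.15 / (273.15 + temp_c)


def _effective_dose(session: OcorSession, params: CorrectionParams) -> float:
    return stpd(session.dose_co_ml, session.ambient_temp_c, session.ambient_pressure_mmhg, params)


def absorbed_co(session: OcorSession, time_min: float, params: CorrectionParams) -> float:
    """M_CO(t): CO volume bound to circulating Hb at ``time_min`` (ml).

    dose (STPD-corrected if enabled) − spirometer/lung residual − exhaled −
    myoglobin-bound. Raises when modelled losses meet or exceed the dose.
    """
    dose = _effective_dose(session, params)
    residual = session.residual_system_co_ml or 0.0
    losses = (
        residual
        + co_loss_exhaled(session, time_min, params)
        + co_loss_myoglobin(dose, time_min, params)
    )
    m_co = dose - losses
    if m_co <= 0:
        raise InfeasibleSessionError(
            f"session {session.subject_id}: CO losses ({losses:.2f} ml) meet or exceed "
            f"dose ({dose:.2f} ml) at t={time_min} min"
        )
    return m_co


def thb_mass_at(
    session: OcorSession, time_min: float, params: CorrectionParams | None = None
) -> THbResult:
    """tHb-mass (g) from the COHb% rise at ``time_min``.

    ``time_min = 7`` uses the symbolic 7-min value (mean of the 6- and 8-min
    draws) with losses evaluated at t = 7.
    """
    params = params or CorrectionParams()
    d_cohb = delta_cohb(session, time_min)
    if d_cohb <= 0:
        raise InvalidRiseError(
            f"session {session.subject_id}: ΔCOHb% = {d_cohb:.2f} at t={time_min} min "
            "(must be positive)"
        )
    m_co = absorbed_co(session, time_min, params)
    thb = m_co * 100.0 / (d_cohb * params.huefner_ml_per_g)
    return THbResult(
        time_min=time_min,
        delta_cohb_pct=d_cohb,
        absorbed_co_ml=m_co,
        thb_mass_g=thb,
    )
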