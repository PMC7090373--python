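"""Domain containers: subjects, COHb samples and rebreathing sessions.

Conventions
-----------
* Times are decimal minutes measured from the **start** of CO inhalation.
* Baseline venous draws are stored separately from timed draws; by file
  convention a baseline row carries ``sample_time_min = -1``.
* COHb is expressed in percent of total haemoglobin; each sample may hold
  several replicate hemoximeter readings which are averaged before any
  further arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = ["Sex", "COSample", "OcorSession", "Subject"]


class Sex:
    MALE = "male"
    FEMALE = "female"


@dataclass(frozen=True)
class COSample:
    """One venous draw: a nominal time and replicate COHb% readings."""

    time_min: float
    readings: tuple[float, ...]

    def __init__(self, time_min: float, readings: Sequence[float]):
        readings = tuple(float(r) for r in readings)
        if not readings:
            raise ValueError("COSample requires at least one reading")
        for r in readings:
            if not 0.0 <= r <= 100.0:
                raise ValueError(f"COHb reading {r} outside [0, 100] percent")
        object.__setattr__(self, "time_min", float(time_min))
        object.__setattr__(self, "readings", readings)

    @property
    def mean(self) -> float:
        """Replicate-averaged COHb% for this draw."""
        return sum(self.readings) / len(self.readings)


@dataclass
class OcorSession:
    """A single optimized CO-rebreathing test.

    Parameters
    ----------
    dose_co_ml : float
        Administered CO volume at syringe conditions (ml).
    rebreathe_end_min : float
        Minute at which the subject disconnects from the rebreathing
        circuit (2 min in the standard protocol).
    baseline, timed : sequences of COSample
        Pre-exposure and post-exposure venous draws.
    residual_system_co_ml : float, optional
        CO left in the spirometer + lung at disconnection, if measured.
    exhale_rate_ml_per_min : float, optional
        Per-session measured exhalation loss rate; overrides the
        correction-parameter default when present.
    ambient_temp_c, ambient_pressure_mmhg : float, optional
        Needed only when the STPD gas-volume correction is enabled.
    """

    subject_id: str
    dose_co_ml: float
    baseline: Sequence[COSample]
    timed: Sequence[COSample]
    rebreathe_end_min: float = 2.0
    residual_system_co_ml: Optional[float] = None
    exhale_rate_ml_per_min: Optional[float] = None
    ambient_temp_c: Optional[float] = None
    ambient_pressure_mmhg: Optional[float] = None

    def __post_init__(self) -> None:
        if self.dose_co_ml <= 0:
            raise ValueError("dose_co_ml must be positive")
        if self.rebreathe_end_min <= 0:
            raise ValueError("rebreathe_end_min must be positive")
        if not self.baseline:
            raise ValueError("at least one baseline sample is required")
        self.baseline = tuple(self.baseline)
        self.timed = tuple(self.timed)
        times = [s.time_min for s in self.timed]
        if any(b >= a for a, b in zip(times[1:], times[:-1])):
            raise ValueError("timed samples must be strictly increasing in time")
        if self.residual_system_co_ml is not None and self.residual_system_co_ml < 0:
            raise ValueError("residual_system_co_ml cannot be negative")

    @property
    def sample_times(self) -> tuple[float, ...]:
        return tuple(s.time_min for s in self.timed)


@dataclass(frozen=True)
class Subject:
    """Covariates feeding CO dosing and blood-volume derivatives.

    ``performance_status`` is the WHO/Zubrod 0–5 ordinal scale (0 = fully
    active); ``training_status`` distinguishes the athlete dose tier from
    untrained and further-debilitated subjects. ``hb_g_l`` is the venous
    haemoglobin concentration in g/l.
    """

    id: str
    sex: str
    weight_kg: float
    height_cm: float
    hb_g_l: float
    age_y: Optional[float] = None
    hct: Optional[float] = None
    performance_status: int = 1
    training_status: str = "debilitated"
    polycythemia: bool = False

    def __post_init__(self) -> None:
        if self.sex not in (Sex.MALE, Sex.FEMALE):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.weight_kg <= 0 or self.height_cm <= 0:
            raise ValueError("weight and height must be positive")
        if self.hb_g_l <= 0:
            raise ValueError("hb_g_l must be positive")
        if not 0 <= self.performance_status <= 5:
            raise ValueError("performance_status must be in 0..5")
        if self.training_status not in ("trained", "untrained", "debilitated"):
            raise ValueError(f"unknown training_status {self.training_status!r}")
        if self.hct is not None and not 0 < self.hct < 1:
            raise ValueError("hct must be a fraction in (0, 1)")
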