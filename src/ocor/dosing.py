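"""CO dose recommendation from subject covariates.

The dosing rule hierarchy targets an absolute COHb rise of 4.0–6.5% with
peaks below 10%:

1. Base dose by sex × training tier: trained men 1.0, untrained or further
   debilitated men 0.8 ml/kg; trained women 0.7, untrained/debilitated
   women 0.6 ml/kg.
2. +0.1 ml/kg for polycythemia (high Hb dilutes the bolus) and +0.1 for a
   subject judged fully fit (WHO performance status 0), capped at 1.0.
3. −0.1 ml/kg for WHO anemia ([Hb] < 130 g/l men, < 120 g/l non-pregnant
   women). The study applied this at investigator discretion, so it is
   default-on but overridable per subject.
4. A further −0.1 per frailty step when performance status is at or above
   the policy threshold (default ≥ 2).
5. Clamp to the clinically used range 0.4–1.0 ml/kg.

Basis weight is actual body weight unless BMI > 30 kg/m², in which case the
Devine ideal body weight is used. The absolute dose is the basis weight ×
ml/kg rounded to the syringe resolution (1 ml).

Every applied rule is appended to an ordered rationale trace so a
recommendation can be audited line by line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

from .errors import ConfigurationError
from .session import Sex, Subject

__all__ = [
    "DosingPolicy",
    "DoseOverrides",
    "DoseRecommendation",
    "classify_anemia",
    "bmi",
    "ideal_body_weight",
    "recommend_dose",
]

ANEMIA_THRESHOLD_G_L = {Sex.MALE: 130.0, Sex.FEMALE: 120.0}


@dataclass(frozen=True)
class DosingPolicy:
    """Tunable dosing configuration (all doses in ml CO per kg)."""

    base_male_trained: float = 1.0
    base_male_untrained: float = 0.8
    base_female_trained: float = 0.7
    base_female_untrained: float = 0.6
    step_ml_per_kg: float = 0.1
    min_ml_per_kg: float = 0.4
    max_ml_per_kg: float = 1.0
    ps_reduction_threshold: int = 2
    bmi_ibw_threshold: float = 30.0
    syringe_resolution_ml: float = 1.0
    anemia_reduction_default: bool = True

    def base_dose(self, subject: Subject) -> float:
        trained = subject.training_status == "trained"
        if subject.sex == Sex.MALE:
            return self.base_male_trained if trained else self.base_male_untrained
        return self.base_female_trained if trained else self.base_female_untrained


@dataclass(frozen=True)
class DoseOverrides:
    """Per-subject discretionary departures from the default rules.

    ``None`` means "follow the rule"; explicit values record investigator
    discretion (the study applied the anemia reduction to only some anemic
    subjects and chose frailty step counts case by case).
    """

    apply_anemia_reduction: Optional[bool] = None
    frailty_steps: Optional[int] = None
    fit_steps: int = 0
    extra_steps: int = 0
    reason: str = ""


@dataclass(frozen=True)
class DoseRecommendation:
    ml_per_kg: float
    dose_ml: float
    basis_weight_kg: float
    adjustments: tuple[str, ...]


def classify_anemia(hb_g_l: float, sex: str) -> bool:
    """WHO anemia rule: [Hb] < 130 g/l (men) or < 120 g/l (non-pregnant women)."""
    if hb_g_l <= 0:
        raise ValueError("hb_g_l must be positive")
    return hb_g_l < ANEMIA_THRESHOLD_G_L[sex]


def bmi(weight_kg: float, height_cm: float) -> float:
    """Body mass index, kg/m², reported to one decimal."""
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be positive")
    h_m = height_cm / 100.0
    return round(weight_kg / (h_m * h_m), 1)


def ideal_body_weight(height_cm: float, sex: str) -> float:
    """Devine ideal body weight (kg), floored at the base value below 60 in."""
    if height_cm <= 0:
        raise ValueError("height_cm must be positive")
    base = 50.0 if sex == Sex.MALE else 45.5
    inches = height_cm / 2.54
    return base + 2.3 * max(0.0, inches - 60.0)


def _round_to_resolution(value: float, resolution: float) -> float:
    return math.floor(value / resolution + 0.5) * resolution


def recommend_dose(
    subject: Subject,
    policy: DosingPolicy | None = None,
    overrides: DoseOverrides | None = None,
) -> DoseRecommendation:
    """Apply the dosing rule hierarchy and return the dose with its rationale."""
    policy = policy or DosingPolicy()
    ov = overrides or DoseOverrides()
    step = policy.step_ml_per_kg
    trace: list[str] = []

    dose = policy.base_dose(subject)
    trace.append(
        f"base {dose:.1f} ml/kg ({subject.sex}, {subject.training_status})"
    )

    if subject.polycythemia:
        dose = min(dose + step, policy.max_ml_per_kg)
        trace.append(f"+{step:.1f} polycythemia (high [Hb] dilutes bolus) -> {dose:.1f}")
    if ov.fit_steps:
        dose = min(dose + ov.fit_steps * step, policy.max_ml_per_kg)
        trace.append(
            f"+{ov.fit_steps * step:.1f} discretionary fitness boost"
            f"{' (' + ov.reason + ')' if ov.reason else ''} -> {dose:.1f}"
        )

    anemic = classify_anemia(subject.hb_g_l, subject.sex)
    apply_anemia = (
        ov.apply_anemia_reduction
        if ov.apply_anemia_reduction is not None
        else (policy.anemia_reduction_default and anemic)
    )
    if apply_anemia and anemic:
        dose -= step
        trace.append(f"-{step:.1f} anemia ([Hb] {subject.hb_g_l:.0f} g/l) -> {dose:.1f}")
    elif anemic:
        trace.append("anemia reduction waived (investigator discretion)")

    frailty_steps = ov.frailty_steps
    if frailty_steps is None:
        frailty_steps = 1 if subject.performance_status >= policy.ps_reduction_threshold else 0
    if frailty_steps:
        dose -= frailty_steps * step
        trace.append(
            f"-{frailty_steps * step:.1f} frailty (performance status "
            f"{subject.performance_status}) -> {dose:.1f}"
        )

    if ov.extra_steps:
        dose += ov.extra_steps * step
        trace.append(
            f"{ov.extra_steps * step:+.1f} discretionary adjustment"
            f"{' (' + ov.reason + ')' if ov.reason else ''} -> {dose:.1f}"
        )

    clamped = min(max(dose, policy.min_ml_per_kg), policy.max_ml_per_kg)
    if clamped != dose:
        trace.append(f"clamped to [{policy.min_ml_per_kg}, {policy.max_ml_per_kg}] -> {clamped:.1f}")
    # steps are exact decimals; kill float crumbs so 0.8-0.1-0.1 == 0.6
    ml_per_kg = round(clamped, 10)

    subject_bmi = bmi(subject.weight_kg, subject.height_cm)
    if subject_bmi > policy.bmi_ibw_threshold:
        basis = ideal_body_weight(subject.height_cm, subject.sex)
        trace.append(
            f"BMI {subject_bmi:.1f} > {policy.bmi_ibw_threshold:.0f}: dose based on "
            f"ideal body weight {basis:.1f} kg"
        )
    else:
        basis = subject.weight_kg

    dose_ml = _round_to_resolution(ml_per_kg * basis, policy.syringe_resolution_ml)
    trace.append(
        f"{ml_per_kg:.1f} ml/kg x {basis:.1f} kg = {ml_per_kg * basis:.1f} "
        f"-> {dose_ml:.0f} ml (syringe resolution {policy.syringe_resolution_ml:g} ml)"
    )
    return DoseRecommendation(
        ml_per_kg=ml_per_kg,
        dose_ml=dose_ml,
        basis_weight_kg=basis,
        adjustments=tuple(trace),
    )
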