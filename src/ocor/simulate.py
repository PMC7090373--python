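"""Synthetic cohorts of COHb wash-in curves with known ground truth.

The generator emulates the statistical structure the analysis assumes for a
debilitated, largely anemic clinical cohort:

* true tHb-mass ~ N(650, 150) g truncated above 200 g;
* baseline COHb ~ N(1.62, 0.77)% truncated at 0.3% (chronically elevated
  endogenous CO production);
* venous [Hb] ~ N(115, 20) g/l, calibrated so WHO anemia prevalence is
  ~77% at defaults; blood volume then follows from tHb-mass and [Hb];
* doses assigned through the dosing rule engine (sex/anemia/frailty);
* wash-in: CO mixing rises with a lagged exponential (lag 0.5 min,
  τ = 1.2 min) normalised to reach completeness exactly at 6 min — the
  first post-baseline draw — after which the curve declines only through
  the exhalation and myoglobin loss fluxes of the core calculator;
* measurement: per-replicate Gaussian hemoximeter noise (SD 0.10
  percentage points) quantized to the instrument's 0.1% resolution.

Because the generator and the calculator share the loss model, noise-free
sessions are inverted exactly: the calculator returns the generator's true
tHb-mass at every grid time. That identity is the package's core oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import CorrectionParams
from .dosing import DoseOverrides, DosingPolicy, _round_to_resolution, recommend_dose
from .errors import OcorError
from .session import COSample, OcorSession, Sex, Subject
from .volumes import DEFAULT_CELL_FACTOR

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_subject",
    "simulate_washin",
    "simulate_cohort",
    "simulate_valid_cohort",
]


class RegenerateDoseError(OcorError):
    """The assigned dose would drive ΔCOHb beyond the feasible ceiling."""


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults are the emulated study conditions."""

    n_subjects: int = 13
    seed: int = 0

    # cohort covariates
    male_prob: float = 11.0 / 13.0
    age_mean_y: float = 52.0
    age_sd_y: float = 13.8
    weight_mean_kg: float = 79.1
    weight_sd_kg: float = 11.4
    weight_min_kg: float = 45.0
    height_mean_cm: float = 175.0
    height_sd_cm: float = 6.8

    # physiology
    thb_mean_g: float = 650.0
    thb_sd_g: float = 150.0
    thb_min_g: float = 200.0
    #: tHb-mass rises with body mass (lean-mass scaling); the residual SD is
    #: derived so the marginal tHb SD stays at thb_sd_g
    thb_weight_slope_g_per_kg: float = 9.0
    #: women carry less haemoglobin per kg body mass than men
    thb_female_factor: float = 0.85
    #: deconditioned subjects (performance status >= 2) have reduced lean
    #: mass and correspondingly reduced tHb-mass
    thb_deconditioned_factor: float = 0.92
    #: correlation between venous [Hb] and tHb-mass (weak in this
    #: population because plasma volume varies independently)
    hb_thb_corr: float = 0.41
    baseline_mean_pct: float = 1.62
    baseline_sd_pct: float = 0.77
    baseline_min_pct: float = 0.3
    hb_mean_g_l: float = 115.0
    hb_sd_g_l: float = 20.0
    hb_min_g_l: float = 60.0
    mchc_mean_g_l: float = 340.0
    mchc_sd_g_l: float = 15.0
    cell_factor: float = DEFAULT_CELL_FACTOR

    # investigator-discretion rates for dose adjustments, matching the
    # emulated study's practice (anemia reduction in 5/10 anemic subjects,
    # frailty reductions in 3/13, fitness boosts in 2/13)
    anemia_reduction_prob: float = 0.5
    performance_status_probs: tuple[float, ...] = (0.15, 0.55, 0.2, 0.1)  # PS 0..3
    fit_boost_if_ps0: bool = True

    # wash-in kinetics and losses
    tau_min: float = 1.2
    t_lag_min: float = 0.5
    mix_complete_min: float = 6.0
    exhale_rate_range: tuple[float, float] = (0.06, 0.28)
    k_myo_per_min: float = 0.00175
    residual_dose_frac: float = 0.12
    rebreathe_end_min: float = 2.0
    max_delta_inf_pct: float = 12.0

    # measurement model
    noise_sd_pct: float = 0.10
    resolution_pct: float = 0.1
    replicates: int = 2

    grid: tuple[float, ...] = (6.0, 8.0, 10.0, 12.0, 15.0, 20.0)
    dosing_policy: DosingPolicy = field(default_factory=DosingPolicy)

    def __post_init__(self) -> None:
        if min(self.noise_sd_pct, self.resolution_pct, self.baseline_sd_pct, self.thb_sd_g) < 0:
            raise ValueError("dispersions cannot be negative")
        if self.tau_min <= 0:
            raise ValueError("tau_min must be positive")
        if list(self.grid) != sorted(self.grid):
            raise ValueError("grid must be sorted")

    def correction_params(self) -> CorrectionParams:
        return CorrectionParams(k_myo_per_min=self.k_myo_per_min)


@dataclass(frozen=True)
class SimTruth:
    """Per-subject ground truth recorded before measurement noise."""

    subject_id: str
    thb_mass_g: float
    bv_ml: float
    pv_ml: float
    baseline_cohb_pct: float
    hb_g_l: float
    hct: float
    exhale_rate_ml_per_min: float
    dose_co_ml: float
    residual_co_ml: float
    delta_inf_pct: float


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, low: float) -> float:
    if sd == 0:
        return max(mean, low)
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= low:
            return x
    return low


def simulate_subject(config: SimConfig, rng: np.random.Generator) -> tuple[Subject, SimTruth]:
    """Draw one subject's covariates and ground-truth physiology.

    [Hb] is drawn and blood volume derived from true tHb-mass via the
    cell-factor relation, so that derived volumes are exactly consistent
    with the volumes module and anemia prevalence lands near the
    calibrated 77% at defaults.
    """
    sex = Sex.MALE if rng.random() < config.male_prob else Sex.FEMALE
    age = _truncated_normal(rng, config.age_mean_y, config.age_sd_y, 18.0)
    weight = _truncated_normal(rng, config.weight_mean_kg, config.weight_sd_kg, config.weight_min_kg)
    height = _truncated_normal(rng, config.height_mean_cm, config.height_sd_cm, 140.0)

    ps_levels = list(range(len(config.performance_status_probs)))
    performance_status = int(rng.choice(ps_levels, p=config.performance_status_probs))

    slope = config.thb_weight_slope_g_per_kg
    explained_var = (slope * config.weight_sd_kg) ** 2
    resid_sd = math.sqrt(max(config.thb_sd_g**2 - explained_var, 0.0))
    # sex and deconditioning scale tHb-mass at fixed body mass; normalise by
    # the population-expected factor so the marginal mean stays thb_mean_g
    factor = 1.0
    if sex == Sex.FEMALE:
        factor *= config.thb_female_factor
    deconditioned = performance_status >= 2
    if deconditioned:
        factor *= config.thb_deconditioned_factor
    p_female = 1.0 - config.male_prob
    p_decond = sum(config.performance_status_probs[2:])
    expected_factor = (
        config.male_prob + p_female * config.thb_female_factor
    ) * (1.0 - p_decond + p_decond * config.thb_deconditioned_factor)
    thb_center = (
        (config.thb_mean_g + slope * (weight - config.weight_mean_kg))
        * factor
        / expected_factor
    )
    thb = _truncated_normal(rng, thb_center, resid_sd, config.thb_min_g)
    rho = config.hb_thb_corr
    hb_center = config.hb_mean_g_l + rho * config.hb_sd_g_l / config.thb_sd_g * (
        thb - config.thb_mean_g
    )
    hb_resid_sd = config.hb_sd_g_l * math.sqrt(max(1.0 - rho**2, 0.0))
    hb = _truncated_normal(rng, hb_center, hb_resid_sd, config.hb_min_g_l)
    baseline = _truncated_normal(
        rng, config.baseline_mean_pct, config.baseline_sd_pct, config.baseline_min_pct
    )
    mchc = _truncated_normal(rng, config.mchc_mean_g_l, config.mchc_sd_g_l, 280.0)
    hct = min(hb / mchc, 0.65)

    bv = thb * 1000.0 / (hb * config.cell_factor)
    rcv = bv * hct * config.cell_factor
    pv = bv - rcv

    subject_id = f"sim{rng.integers(0, 10**9):09d}"
    subject = Subject(
        id=subject_id,
        sex=sex,
        age_y=age,
        weight_kg=weight,
        height_cm=height,
        hb_g_l=hb,
        hct=hct,
        performance_status=performance_status,
        training_status="debilitated",
    )

    # investigator discretion: the anemia reduction is applied to only a
    # fraction of anemic subjects; fully fit (PS 0) subjects get the boost
    apply_anemia = bool(rng.random() < config.anemia_reduction_prob)
    overrides = DoseOverrides(
        apply_anemia_reduction=apply_anemia,
        fit_steps=1 if (config.fit_boost_if_ps0 and performance_status == 0) else 0,
    )
    rec = recommend_dose(subject, config.dosing_policy, overrides)
    ml_per_kg, dose_ml = rec.ml_per_kg, rec.dose_ml
    huefner = 1.39
    policy = config.dosing_policy

    def _delta_inf(dose: float) -> float:
        return dose * (1.0 - config.residual_dose_frac) * 100.0 / (huefner * thb)

    # small tHb-mass: step the dose down (as a clinician would) until the
    # projected COHb rise is below the feasibility ceiling
    while (
        _delta_inf(dose_ml) > config.max_delta_inf_pct
        and ml_per_kg - policy.step_ml_per_kg >= policy.min_ml_per_kg - 1e-9
    ):
        ml_per_kg = round(ml_per_kg - policy.step_ml_per_kg, 10)
        dose_ml = _round_to_resolution(
            ml_per_kg * rec.basis_weight_kg, policy.syringe_resolution_ml
        )

    exhale_rate = rng.uniform(*config.exhale_rate_range)
    residual = config.residual_dose_frac * dose_ml
    delta_inf = _delta_inf(dose_ml)

    truth = SimTruth(
        subject_id=subject_id,
        thb_mass_g=thb,
        bv_ml=bv,
        pv_ml=pv,
        baseline_cohb_pct=baseline,
        hb_g_l=hb,
        hct=hct,
        exhale_rate_ml_per_min=exhale_rate,
        dose_co_ml=dose_ml,
        residual_co_ml=residual,
        delta_inf_pct=delta_inf,
    )
    return subject, truth


def _mixing_fraction(t: float, config: SimConfig) -> float:
    """Lagged-exponential mixing, normalised to reach exactly 1 at 6 min."""
    if t >= config.mix_complete_min:
        return 1.0
    if t <= config.t_lag_min:
        return 0.0
    rise = 1.0 - math.exp(-(t - config.t_lag_min) / config.tau_min)
    full = 1.0 - math.exp(-(config.mix_complete_min - config.t_lag_min) / config.tau_min)
    return rise / full


def noise_free_cohb(t: float, truth: SimTruth, config: SimConfig) -> float:
    """The generator's COHb% curve before noise and quantization."""
    huefner = 1.39
    mixed = _mixing_fraction(t, config) * truth.delta_inf_pct
    exhaled = truth.exhale_rate_ml_per_min * max(0.0, t - config.rebreathe_end_min)
    myo = config.k_myo_per_min * truth.dose_co_ml * t
    loss_pct = 100.0 * (exhaled + myo) / (huefner * truth.thb_mass_g)
    return truth.baseline_cohb_pct + mixed - loss_pct


def _measure(value: float, config: SimConfig, rng: np.random.Generator) -> tuple[float, ...]:
    readings = value + rng.normal(0.0, config.noise_sd_pct, size=config.replicates)
    if config.resolution_pct > 0:
        readings = np.round(readings / config.resolution_pct) * config.resolution_pct
    return tuple(float(max(r, 0.0)) for r in readings)


def simulate_washin(
    subject: Subject, truth: SimTruth, config: SimConfig, rng: np.random.Generator
) -> OcorSession:
    """Generate one rebreathing session for a subject with known truth."""
    if truth.delta_inf_pct > config.max_delta_inf_pct:
        raise RegenerateDoseError(
            f"subject {subject.id}: ΔCOHb∞ {truth.delta_inf_pct:.1f}% exceeds "
            f"{config.max_delta_inf_pct}% ceiling; regenerate dose"
        )
    baseline = COSample(-1.0, _measure(truth.baseline_cohb_pct, config, rng))
    timed = [
        COSample(t, _measure(noise_free_cohb(t, truth, config), config, rng))
        for t in config.grid
    ]
    return OcorSession(
        subject_id=subject.id,
        dose_co_ml=truth.dose_co_ml,
        baseline=[baseline],
        timed=timed,
        rebreathe_end_min=config.rebreathe_end_min,
        residual_system_co_ml=truth.residual_co_ml,
        exhale_rate_ml_per_min=truth.exhale_rate_ml_per_min,
    )


def simulate_cohort(
    config: SimConfig, seed: Optional[int] = None
) -> tuple[list[Subject], list[OcorSession], pd.DataFrame]:
    """n independent subjects with one session each; fully seed-determined.

    Subjects whose assigned dose would be infeasible (ΔCOHb∞ above the
    ceiling) are redrawn; the seed fully determines the output.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    subjects: list[Subject] = []
    sessions: list[OcorSession] = []
    truths: list[SimTruth] = []
    for _ in range(config.n_subjects):
        for _attempt in range(100):
            subject, truth = simulate_subject(config, rng)
            try:
                session = simulate_washin(subject, truth, config, rng)
            except RegenerateDoseError:
                continue
            break
        else:
            raise OcorError("could not draw a feasible subject in 100 attempts")
        subjects.append(subject)
        sessions.append(session)
        truths.append(truth)
    truth_df = pd.DataFrame([t.__dict__ for t in truths])
    return subjects, sessions, truth_df


def simulate_valid_cohort(
    config: SimConfig, seed: Optional[int] = None, max_draws: int = 1000
) -> tuple[list[Subject], list[OcorSession], pd.DataFrame]:
    """Enrol subjects until ``config.n_subjects`` sessions pass QC gating.

    Mirrors a study enrolment in which under-dosed sessions (insufficient
    COHb rise) are excluded and replaced, so the analysed cohort has exactly
    the configured size.
    """
    from .qc import validate_session

    rng = np.random.default_rng(config.seed if seed is None else seed)
    params = config.correction_params()
    subjects: list[Subject] = []
    sessions: list[OcorSession] = []
    truths: list[SimTruth] = []
    for _ in range(max_draws):
        if len(sessions) >= config.n_subjects:
            break
        subject, truth = simulate_subject(config, rng)
        try:
            session = simulate_washin(subject, truth, config, rng)
        except RegenerateDoseError:
            continue
        if not validate_session(session, params).valid:
            continue
        subjects.append(subject)
        sessions.append(session)
        truths.append(truth)
    else:
        raise OcorError(
            f"could not enrol {config.n_subjects} valid sessions in {max_draws} draws"
        )
    truth_df = pd.DataFrame([t.__dict__ for t in truths])
    return subjects, sessions, truth_df
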