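"""Synthetic iCPET cohort generator with ground-truth pathway parameters.

Each subject is built top-down so that every stage of the pipeline can be
tested without external data:

1. demographics are drawn per group (age, sex, height, BMI-derived weight),
2. the Wasserman-predicted V̇O2 anchors the predicted-normal parameter set,
3. the subject's *true* parameters are the normals times per-parameter
   lognormal impairment factors (median = the group's impairment profile,
   spread on the log scale — positivity-preserving, right-skewed like
   physiological capacities),
4. the forward transport model is solved for the noiseless operating point,
5. measured record fields are derived from that operating point (V̇e from
   true V̇a and a drawn Vd/Vt, blood gases from the operating blood points,
   CO = Q̇, RER kept above the control eligibility threshold for controls),
6. multiplicative measurement noise is applied per channel; blood-gas noise
   perturbs the PO2s with saturations recomputed from the curve, keeping
   each blood point internally consistent (gas-analyzer-style error).

The default impairment profiles are group-to-control ratios of published
peak-exercise medians in PASC / CFS-like cohorts; the generator's ground
truth is retained alongside the records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .core import (
    BloodPoint,
    CurveSettings,
    Environment,
    InfeasibleOperatingPoint,
    PeakMeasurementRecord,
    PhysiologyError,
    SubjectDemographics,
)
from .estimation import PARAM_ORDER, EstimationSettings, PathwayParameters
from .forward import predict_vo2
from .norms import ReferenceModelTable, default_reference_table, normal_parameter_values, predicted_vo2_wasserman

__all__ = [
    "ImpairmentProfile",
    "NoiseModel",
    "DemographicsModel",
    "GeneratorConfig",
    "DEFAULT_PROFILES",
    "generate_subject",
    "generate_cohort",
    "cohort_to_frames",
]


@dataclass(frozen=True)
class ImpairmentProfile:
    """Multiplicative impairment of the six parameters relative to normal.

    ``factors[x]`` is the median fraction-of-normal for parameter x;
    ``spread`` is the sd of the lognormal factor on the log scale."""

    label: str
    factors: Dict[str, float]
    spread: float = 0.10

    def __post_init__(self) -> None:
        for name in PARAM_ORDER:
            if self.factors.get(name, 1.0) <= 0:
                raise PhysiologyError(f"impairment factor for {name} must be positive")
        if self.spread < 0:
            raise PhysiologyError("spread must be non-negative")


#: Default group profiles: control at normal; patient-group factors are the
#: group-to-control ratios of published peak-exercise pathway medians.
DEFAULT_PROFILES: Dict[str, ImpairmentProfile] = {
    "control": ImpairmentProfile(
        "control", {p: 1.0 for p in PARAM_ORDER}, spread=0.10
    ),
    "PASC": ImpairmentProfile(
        "PASC",
        {"va": 0.65, "dl": 0.52, "q": 0.78, "hb": 0.97, "dm": 0.71, "vmax": 0.66},
        spread=0.10,
    ),
    "CFS": ImpairmentProfile(
        "CFS",
        {"va": 0.59, "dl": 0.38, "q": 0.65, "hb": 0.95, "dm": 0.52, "vmax": 0.54},
        spread=0.10,
    ),
}


@dataclass(frozen=True)
class NoiseModel:
    """Per-channel multiplicative measurement noise (coefficient of
    variation). Defaults reflect typical measurement repeatability:
    metabolic-cart gas exchange ~3%, blood-gas analyzers ~2%, direct-Fick
    cardiac output ~5%."""

    vo2_cv: float = 0.03
    ve_cv: float = 0.03
    blood_gas_cv: float = 0.02
    co_cv: float = 0.05

    def __post_init__(self) -> None:
        for cv in (self.vo2_cv, self.ve_cv, self.blood_gas_cv, self.co_cv):
            if cv < 0:
                raise PhysiologyError("noise CVs must be non-negative")

    @classmethod
    def none(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0.0)

    @classmethod
    def uniform(cls, cv: float) -> "NoiseModel":
        return cls(cv, cv, cv, cv)


@dataclass(frozen=True)
class DemographicsModel:
    """Group demographic distributions (normal draws, truncated)."""

    age_median: float
    age_sd: float
    female_fraction: float
    bmi_median: float
    bmi_sd: float
    vd_vt_median: float
    vd_vt_sd: float = 0.06


#: Guided by published cohort demographics (medians / IQR-derived sds).
DEFAULT_DEMOGRAPHICS: Dict[str, DemographicsModel] = {
    "control": DemographicsModel(41.0, 15.0, 0.60, 25.0, 3.0, 0.283),
    "PASC": DemographicsModel(44.0, 14.0, 0.91, 31.0, 5.0, 0.406),
    "CFS": DemographicsModel(37.0, 10.0, 0.88, 27.0, 5.0, 0.315),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-level generation settings (sizes match the study arms)."""

    n_control: int = 11
    n_pasc: int = 15
    n_cfs: int = 11
    seed: int = 0
    profiles: Dict[str, ImpairmentProfile] = field(default_factory=lambda: dict(DEFAULT_PROFILES))
    demographics: Dict[str, DemographicsModel] = field(
        default_factory=lambda: dict(DEFAULT_DEMOGRAPHICS)
    )
    noise: NoiseModel = NoiseModel()
    #: optional shared-severity latent factor: loading on every log-factor,
    #: letting tests probe correlated multi-system defects (0 = independent)
    severity_loading: float = 0.0

    def __post_init__(self) -> None:
        if min(self.n_control, self.n_pasc, self.n_cfs) < 0:
            raise PhysiologyError("group sizes must be non-negative")
        if not 0.0 <= self.severity_loading < 1.0:
            raise PhysiologyError("severity loading must lie in [0, 1)")


def _trunc_normal(rng: np.random.Generator, loc: float, scale: float, lo: float, hi: float) -> float:
    for _ in range(100):
        x = rng.normal(loc, scale)
        if lo <= x <= hi:
            return x
    return min(max(loc, lo), hi)


def _draw_demographics(
    rng: np.random.Generator, subject_id: str, group: str, model: DemographicsModel
) -> SubjectDemographics:
    age = _trunc_normal(rng, model.age_median, model.age_sd, 18.0, 85.0)
    sex = "female" if rng.random() < model.female_fraction else "male"
    height = _trunc_normal(rng, 164.0 if sex == "female" else 178.0, 7.0, 145.0, 205.0)
    bmi = _trunc_normal(rng, model.bmi_median, model.bmi_sd, 17.0, 45.0)
    weight = bmi * (height / 100.0) ** 2
    return SubjectDemographics(
        subject_id=subject_id, age=age, sex=sex, height=height, weight=weight, group=group
    )


def generate_subject(
    rng: np.random.Generator,
    subject_id: str,
    group: str,
    profile: ImpairmentProfile,
    demo_model: DemographicsModel,
    noise: NoiseModel = NoiseModel(),
    table: Optional[ReferenceModelTable] = None,
    env: Environment = Environment(),
    settings: EstimationSettings = EstimationSettings(),
    curve: CurveSettings = CurveSettings(),
    severity_loading: float = 0.0,
    max_retries: int = 20,
) -> Tuple[SubjectDemographics, PeakMeasurementRecord, PathwayParameters, float]:
    """Generate one subject; returns (demographics, record, true parameters,
    predicted V̇O2). Infeasible draws are resampled up to ``max_retries``
    times before raising."""
    table = table or default_reference_table()
    last_err: Optional[Exception] = None
    for _ in range(max_retries):
        demo = _draw_demographics(rng, subject_id, group, demo_model)
        predicted = predicted_vo2_wasserman(demo)
        if predicted <= 0:
            continue
        normals, _ = normal_parameter_values(predicted, table)
        s = rng.normal() if severity_loading > 0 else 0.0
        resid_scale = math.sqrt(1.0 - severity_loading**2)
        factors = {}
        for name in PARAM_ORDER:
            z = severity_loading * s + resid_scale * rng.normal()
            factors[name] = profile.factors.get(name, 1.0) * math.exp(profile.spread * z)
        truth = PathwayParameters(
            **{name: getattr(normals, name) * factors[name] for name in PARAM_ORDER}
        )
        try:
            op = predict_vo2(truth, env, settings, curve)
        except (PhysiologyError, RuntimeError) as exc:
            last_err = exc
            continue

        vd_vt = _trunc_normal(rng, demo_model.vd_vt_median, demo_model.vd_vt_sd, 0.05, 0.6)
        ve = truth.va / (1.0 - vd_vt)
        if group == "control":
            rer = _trunc_normal(rng, 1.12, 0.05, 1.06, 1.35)
        else:
            rer = _trunc_normal(rng, 1.10, 0.08, 0.90, 1.40)
        vco2 = rer * op.vo2
        rest_co = _trunc_normal(rng, 6.0, 1.0, 3.5, 9.0)
        rest_mpap = _trunc_normal(rng, 15.0, 2.0, 8.0, 24.0)
        slope = (
            _trunc_normal(rng, 0.8, 0.4, 0.2, 2.5)
            if group == "control"
            else _trunc_normal(rng, 1.2, 0.8, 0.2, 4.5)
        )
        peak_co_true = truth.q
        mpap = rest_mpap + slope * max(peak_co_true - rest_co, 0.5)
        hr_frac = rng.uniform(0.85, 1.0) if group == "control" else rng.uniform(0.75, 0.95)
        hr = (220.0 - demo.age) * hr_frac
        lactate_loc = {"control": 5.5, "PASC": 5.2, "CFS": 2.6}[group] if group in ("control", "PASC", "CFS") else 5.0
        lactate = _trunc_normal(rng, lactate_loc, 1.2, 0.5, 14.0)
        rap = _trunc_normal(rng, 4.0 if group == "control" else 3.0, 2.0, 0.0, 12.0)
        pcwp = _trunc_normal(rng, 12.0 if group == "control" else 9.0, 3.0, 2.0, 22.0)

        # measurement noise, multiplicative lognormal per channel
        vo2_m = op.vo2 * math.exp(noise.vo2_cv * rng.normal())
        vco2_m = vco2 * math.exp(noise.vo2_cv * rng.normal())
        ve_m = ve * math.exp(noise.ve_cv * rng.normal())
        co_m = peak_co_true * math.exp(noise.co_cv * rng.normal())
        pao2_m = op.arterial.po2 * math.exp(noise.blood_gas_cv * rng.normal())
        pvo2_m = op.venous.po2 * math.exp(noise.blood_gas_cv * rng.normal())
        if pvo2_m >= pao2_m:  # noise cannot invert the a-v gradient
            pvo2_m = 0.95 * pao2_m
        paco2 = _trunc_normal(rng, 42.0, 5.0, 25.0, 65.0)

        try:
            record = PeakMeasurementRecord(
                subject_id=subject_id,
                vo2=vo2_m,
                vco2=vco2_m,
                ve=ve_m,
                vd_vt=vd_vt,
                co=co_m,
                hb=truth.hb,
                arterial=BloodPoint.from_po2(pao2_m, truth.hb, curve),
                paco2=paco2,
                venous=BloodPoint.from_po2(pvo2_m, truth.hb, curve),
                rer=rer,
                mpap=mpap,
                pcwp=pcwp,
                rap=rap,
                hr=hr,
                lactate=lactate,
                rest_mpap=rest_mpap,
                rest_co=rest_co,
            )
        except PhysiologyError as exc:
            last_err = exc
            continue
        return demo, record, truth, predicted
    raise InfeasibleOperatingPoint(
        f"could not generate a feasible subject for group {group!r} "
        f"after {max_retries} attempts: {last_err}"
    )


def generate_cohort(
    config: GeneratorConfig = GeneratorConfig(),
    table: Optional[ReferenceModelTable] = None,
    env: Environment = Environment(),
    settings: EstimationSettings = EstimationSettings(),
    curve: CurveSettings = CurveSettings(),
):
    """Generate a full three-group cohort.

    Returns (subjects, failures) where ``subjects`` is a list of
    (demographics, record, true parameters, predicted V̇O2) tuples and
    ``failures`` counts subject-level generation failures (resampling already
    exhausted). Deterministic for a fixed config (seeded)."""
    rng = np.random.default_rng(config.seed)
    table = table or default_reference_table()
    sizes = {"control": config.n_control, "PASC": config.n_pasc, "CFS": config.n_cfs}
    subjects = []
    failures = 0
    counter = 1
    for group, n in sizes.items():
        for _ in range(n):
            subject_id = f"S{counter:04d}"
            counter += 1
            try:
                subjects.append(
                    generate_subject(
                        rng, subject_id, group,
                        config.profiles[group], config.demographics[group],
                        config.noise, table, env, settings, curve,
                        config.severity_loading,
                    )
                )
            except InfeasibleOperatingPoint:
                failures += 1
    return subjects, failures


def cohort_to_frames(subjects) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten generated subjects into the subject-CSV schema and the
    ground-truth table (true parameters + predicted V̇O2)."""
    rows = []
    truth_rows = []
    for demo, rec, truth, predicted in subjects:
        rows.append(
            {
                "subject_id": demo.subject_id,
                "group": demo.group,
                "age": demo.age,
                "sex": demo.sex,
                "height_cm": demo.height,
                "weight_kg": demo.weight,
                "vo2_ml_min": rec.vo2,
                "vco2_ml_min": rec.vco2,
                "ve_l_min": rec.ve,
                "vd_vt": rec.vd_vt,
                "co_l_min": rec.co,
                "hb_g_dl": rec.hb,
                "pao2_mmhg": rec.arterial.po2,
                "paco2_mmhg": rec.paco2,
                "sao2_pct": 100.0 * rec.arterial.so2,
                "pvo2_mmhg": rec.venous.po2,
                "svo2_pct": 100.0 * rec.venous.so2,
                "rer": rec.rer,
                "mpap_mmhg": rec.mpap,
                "pcwp_mmhg": rec.pcwp,
                "rap_mmhg": rec.rap,
                "hr_bpm": rec.hr,
                "lactate_mmol_l": rec.lactate,
                "rest_mpap_mmhg": rec.rest_mpap,
                "rest_co_l_min": rec.rest_co,
            }
        )
        truth_rows.append(
            {
                "subject_id": demo.subject_id,
                **{f"true_{name}": getattr(truth, name) for name in PARAM_ORDER},
                "predicted_vo2": predicted,
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)
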