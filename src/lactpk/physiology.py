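"""Virtual-subject anthropometry and hepatic physiology.

Height in children is a sex-specific polynomial in age fitted to growth
charts; weight is a function of age and height.  Adults use fixed
sex-specific means with lognormal variability.  Liver mass, hepatic blood
flow, AAG concentration and per-gram metabolic capacity are age-dependent
allometries defined in :class:`PhysiologyConfig`, so the pediatric scaling
is a documented configuration, not constants scattered through the code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "Subject",
    "PopulationSpec",
    "PhysiologyConfig",
    "height_for_age",
    "weight_for_height_age",
    "liver_weight",
    "hepatic_blood_flow",
    "aag_for_age",
    "metabolic_capacity",
    "sample_subject",
    "sample_population",
]

WEEKS_PER_YEAR = 52.1775

# Height-for-age polynomial coefficients (cm), highest degree first.
_HEIGHT_COEFFS_MALE = (
    0.0000176179, -0.00119874, 0.0323848, -0.444112,
    3.2946, -13.2191, 33.75, 45.62152,
)
_HEIGHT_COEFFS_FEMALE = (
    -0.00000151027, 0.000121261, -0.0040023, 0.070179,
    -0.708233, 4.1872, -14.3393, 33.84778, 40.535477,
)

# Weight = A*(1 - exp(-k*age)) + exp(c*height) + b*age
_WEIGHT_PARAMS = {
    "male": (6.026, 1.2, 0.0209, 0.023),
    "female": (4.054, 1.57, 0.0224, 0.019),
}


class PhysiologyConfig(BaseModel):
    """Age-dependent physiology: coefficients, CVs, and maturation curves.

    liver_frac_*: liver mass as a fraction of body weight decays
        exponentially from ``liver_frac_birth`` toward ``liver_frac_adult``
        with time constant ``liver_frac_tau`` (years).
    q_h_per_kg_liver: hepatic blood flow per kg liver (L/h/kg).
    aag_*: AAG rises from ``aag_birth_frac`` of the adult 0.7 g/L level with
        a Hill-type curve in postnatal weeks.
    capacity_*: metabolically active protein per gram of liver
        (microsomal/mitochondrial content) matures independently of any
        isozyme ontogeny, from ``capacity_birth`` of the adult level.
    """

    child_height_cv: float = 0.04
    child_weight_cv: float = 0.15
    adult_height_cv: float = 0.10
    adult_weight_cv: float = 0.20
    adult_height_mean: dict[str, float] = Field(
        default_factory=lambda: {"male": 176.0, "female": 163.0}
    )
    adult_weight_mean: dict[str, float] = Field(
        default_factory=lambda: {"male": 75.0, "female": 60.0}
    )
    liver_frac_birth: float = 0.040
    liver_frac_adult: float = 0.021
    liver_frac_tau: float = 3.0
    q_h_per_kg_liver: float = 60.0
    aag_adult: float = 0.7
    aag_birth_frac: float = 0.32
    aag_age50_weeks: float = 30.0
    capacity_birth: float = 0.25
    capacity_age50_weeks: float = 6.0
    capacity_hill: float = 1.5
    iiv_cv_cl: float = 0.35
    iiv_cv_v: float = 0.25


DEFAULT_PHYSIOLOGY = PhysiologyConfig()


@dataclass
class Subject:
    """One virtual individual."""

    age: float  # years
    sex: str  # "male" | "female"
    height: float  # cm
    weight: float  # kg
    liver_weight: float  # kg
    hepatic_blood_flow: float  # L/h
    aag: float  # g/L
    iiv_multipliers: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.age <= 60.0):
            raise ValueError(f"age out of supported range: {self.age}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be male/female, got {self.sex}")
        for name in ("height", "weight", "liver_weight", "hepatic_blood_flow", "aag"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be positive")
        if self.liver_weight >= self.weight:
            raise ValueError("liver mass must be below body mass")


class PopulationSpec(BaseModel):
    n_subjects: int = Field(gt=0)
    age_range: tuple[float, float]
    proportion_female: float = Field(ge=0.0, le=1.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check_ages(self) -> "PopulationSpec":
        lo, hi = self.age_range
        if not (0.0 <= lo <= hi):
            raise ValueError(f"age_range must be ordered and non-negative: {self.age_range}")
        return self


def _polyval(coeffs, x: float) -> float:
    acc = 0.0
    for c in coeffs:
        acc = acc * x + c
    return acc


def height_for_age(age: float, sex: str) -> float:
    """Mean height (cm) for a child of given age (years, < 18) and sex."""
    if age < 0.0:
        raise ValueError(f"age must be non-negative, got {age}")
    if age >= 18.0:
        raise ValueError("growth polynomials apply below 18 years; adults use fixed means")
    coeffs = _HEIGHT_COEFFS_MALE if sex == "male" else _HEIGHT_COEFFS_FEMALE
    return _polyval(coeffs, age)


def weight_for_height_age(height: float, age: float, sex: str) -> float:
    """Mean weight (kg) for a child of given height (cm), age (years) and sex."""
    if height <= 0.0:
        raise ValueError(f"height must be positive, got {height}")
    if age < 0.0:
        raise ValueError(f"age must be non-negative, got {age}")
    a_sat, k, c, b = _WEIGHT_PARAMS[sex]
    return a_sat * (1.0 - math.exp(-k * age)) + math.exp(c * height) + b * age


def liver_weight(age: float, weight: float,
                 config: PhysiologyConfig = DEFAULT_PHYSIOLOGY) -> float:
    """Liver mass (kg): per-kg fraction decays from the infant to adult level."""
    if age < 0.0 or weight <= 0.0:
        raise ValueError("age must be >= 0 and weight > 0")
    frac = config.liver_frac_adult + (
        config.liver_frac_birth - config.liver_frac_adult
    ) * math.exp(-age / config.liver_frac_tau)
    return frac * weight


def hepatic_blood_flow(liver_kg: float,
                       config: PhysiologyConfig = DEFAULT_PHYSIOLOGY) -> float:
    """Hepatic blood flow (L/h) proportional to liver mass."""
    if liver_kg <= 0.0:
        raise ValueError("liver mass must be positive")
    return config.q_h_per_kg_liver * liver_kg


def aag_for_age(age: float, config: PhysiologyConfig = DEFAULT_PHYSIOLOGY) -> float:
    """AAG concentration (g/L), maturing from a neonatal fraction of 0.7 g/L."""
    if age < 0.0:
        raise ValueError(f"age must be non-negative, got {age}")
    w = age * WEEKS_PER_YEAR
    frac = config.aag_birth_frac + (1.0 - config.aag_birth_frac) * w / (
        w + config.aag_age50_weeks
    )
    return config.aag_adult * frac


def metabolic_capacity(age: float,
                       config: PhysiologyConfig = DEFAULT_PHYSIOLOGY) -> float:
    """Metabolically active protein per gram liver, as a fraction of adult.

    Distinct from isozyme ontogeny: this is the maturation of total
    microsomal/mitochondrial protein content of hepatic tissue.
    """
    if age < 0.0:
        raise ValueError(f"age must be non-negative, got {age}")
    w = age * WEEKS_PER_YEAR
    wh = w ** config.capacity_hill
    a50h = config.capacity_age50_weeks ** config.capacity_hill
    return config.capacity_birth + (1.0 - config.capacity_birth) * wh / (wh + a50h)


def _lognormal_mult(rng: np.random.Generator, cv: float) -> float:
    # median-1 lognormal deviate with the requested coefficient of variation
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return math.exp(sigma * rng.standard_normal())


def sample_subject(spec: PopulationSpec, rng: np.random.Generator,
                   config: PhysiologyConfig = DEFAULT_PHYSIOLOGY) -> Subject:
    """Draw one subject: uniform age, Bernoulli sex, lognormal size variability."""
    lo, hi = spec.age_range
    if hi > lo:
        age = rng.uniform(lo, hi)
    else:
        age = lo
    sex = "female" if rng.uniform() < spec.proportion_female else "male"
    if age < 18.0:
        height = height_for_age(age, sex) * _lognormal_mult(rng, config.child_height_cv)
        weight = weight_for_height_age(height, age, sex) * _lognormal_mult(
            rng, config.child_weight_cv
        )
    else:
        height = config.adult_height_mean[sex] * _lognormal_mult(rng, config.adult_height_cv)
        weight = config.adult_weight_mean[sex] * _lognormal_mult(rng, config.adult_weight_cv)
    lw = liver_weight(age, weight, config)
    return Subject(
        age=age,
        sex=sex,
        height=height,
        weight=weight,
        liver_weight=lw,
        hepatic_blood_flow=hepatic_blood_flow(lw, config),
        aag=aag_for_age(age, config),
        iiv_multipliers={
            "cl": _lognormal_mult(rng, config.iiv_cv_cl),
            "v": _lognormal_mult(rng, config.iiv_cv_v),
        },
    )


def sample_population(spec: PopulationSpec,
                      config: PhysiologyConfig = DEFAULT_PHYSIOLOGY,
                      rng: np.random.Generator | None = None) -> list[Subject]:
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    return [sample_subject(spec, rng, config) for _ in range(spec.n_subjects)]


def typical_adult(sex: str = "female", age: float = 30.0,
                  config: PhysiologyConfig = DEFAULT_PHYSIOLOGY) -> Subject:
    """Deterministic reference adult (no variability), used for calibration."""
    weight = config.adult_weight_mean[sex]
    lw = liver_weight(age, weight, config)
    return Subject(
        age=age,
        sex=sex,
        height=config.adult_height_mean[sex],
        weight=weight,
        liver_weight=lw,
        hepatic_blood_flow=hepatic_blood_flow(lw, config),
        aag=aag_for_age(age, config),
        iiv_multipliers={"cl": 1.0, "v": 1.0},
    )
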