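"""Enzyme ontogeny: per-pathway activity as a fraction of adult activity
per gram of liver.

Each profile is a Hill curve in postnatal age (weeks) rising from
``f_birth`` toward 1.  MAO-A ontogeny is uncharacterized, so two scenario
presets bracket it: ``maoa_none`` (adult activity at all ages) and
``maoa_slow`` (half-maturation around one year).  CYP2D6 matures within the
first weeks of life.
"""

from __future__ import annotations

from pydantic import BaseModel, Field

from .physiology import WEEKS_PER_YEAR

__all__ = ["OntogenyProfile", "fraction_adult", "PRESETS", "resolve_profile"]


class OntogenyProfile(BaseModel):
    """Hill-type maturation curve; f_birth=1 encodes 'no ontogeny'."""

    f_birth: float = Field(ge=0.0, le=1.0)
    age50: float = Field(gt=0.0, description="postnatal weeks at half-maturation")
    hill: float = Field(gt=0.0)


def fraction_adult(age: float, profile: OntogenyProfile) -> float:
    """Fraction of adult activity per gram of liver at an age in years."""
    if age < 0.0:
        raise ValueError(f"age must be non-negative, got {age}")
    if profile.f_birth >= 1.0:
        return 1.0
    w = age * WEEKS_PER_YEAR
    wh = w ** profile.hill
    return profile.f_birth + (1.0 - profile.f_birth) * wh / (
        wh + profile.age50 ** profile.hill
    )


PRESETS: dict[str, OntogenyProfile] = {
    # fast postnatal maturation, literature-shaped
    "cyp2d6_default": OntogenyProfile(f_birth=0.05, age50=2.0, hill=1.0),
    # adult activity at all ages
    "maoa_none": OntogenyProfile(f_birth=1.0, age50=1.0, hill=1.0),
    # conservative scenario: ~35% of adult at birth, half-mature near 1 year
    "maoa_slow": OntogenyProfile(f_birth=0.35, age50=52.0, hill=1.0),
}


def resolve_profile(spec: str | OntogenyProfile | dict) -> OntogenyProfile:
    """Resolve a preset name, inline dict, or profile into an OntogenyProfile."""
    if isinstance(spec, OntogenyProfile):
        return spec
    if isinstance(spec, dict):
        return OntogenyProfile(**spec)
    if spec in PRESETS:
        return PRESETS[spec]
    raise KeyError(
        f"unknown ontogeny preset {spec!r}; available: {sorted(PRESETS)}"
    )
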