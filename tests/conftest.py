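import pytest

from lactpk.binding import primaquine
from lactpk.engine import Regimen
from lactpk.physiology import (
    Subject,
    aag_for_age,
    height_for_age,
    hepatic_blood_flow,
    liver_weight,
    typical_adult,
    weight_for_height_age,
)

MATERNAL_REGIMEN = Regimen(dose_per_kg=500.0, interval=24.0, n_doses=14)
ADULT_ONTOGENY = {"MAOA": "maoa_none", "CYP2D6": "maoa_none"}
INFANT_ONTOGENY = {"MAOA": "maoa_none", "CYP2D6": "cyp2d6_default"}


def typical_child(age: float, sex: str = "male") -> Subject:
    """Deterministic child at the growth-curve means (no variability)."""
    height = height_for_age(age, sex)
    weight = weight_for_height_age(height, age, sex)
    lw = liver_weight(age, weight)
    return Subject(
        age=age, sex=sex, height=height, weight=weight, liver_weight=lw,
        hepatic_blood_flow=hepatic_blood_flow(lw), aag=aag_for_age(age),
    )


@pytest.fixture(scope="session")
def drug():
    """Shipped primaquine parameterization (pre-calibrated defaults)."""
    return primaquine()


@pytest.fixture(scope="session")
def mother():
    return typical_adult()


@pytest.fixture(scope="session")
def maternal_regimen():
    return MATERNAL_REGIMEN
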