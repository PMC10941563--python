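"""Milk-to-plasma partitioning and infant daily dose arithmetic.

The M/P ratio is predicted with a phase-distribution model: the unbound,
un-ionized species equilibrates between plasma water, skim-milk water and
milk fat.  For a monoprotic base, the slightly acidic pH of mature milk
traps the ionized form (ion trapping), raising the milk concentration; milk
protein binding and a logP-derived fat partition complete the model.  The
single unprinted scalar (the milk/plasma binding-protein ratio) is
calibrated once against the predicted M/P of 0.47 for mature milk
(pH 7.2, 4% fat) and then frozen for every other prediction.
"""

from __future__ import annotations

import math

from pydantic import BaseModel, Field, model_validator

from .binding import DrugParameters

__all__ = [
    "MilkComposition",
    "MilkTransferResult",
    "unionized_fraction",
    "mp_ratio",
    "calibrate_protein_ratio",
    "idd_from_mp",
    "idd_from_cumulative",
    "ridd",
    "per_feed_dose",
    "MILK_PRESETS",
    "PROTEIN_RATIO_CALIBRATED",
]

#: Milk/plasma binding-protein scalar calibrated so the mature-milk M/P is
#: 0.47 for the default primaquine config (see calibrate_protein_ratio).
PROTEIN_RATIO_CALIBRATED = 0.01594120477418875


class MilkComposition(BaseModel):
    ph_milk: float = Field(ge=6.5, le=8.0)
    ph_plasma: float = 7.4
    fat_fraction: float = Field(ge=0.0, lt=0.2, description="v/v")
    protein_ratio: float = Field(
        default=PROTEIN_RATIO_CALIBRATED, ge=0.0,
        description="milk/plasma binding-protein scalar",
    )


class MilkTransferResult(BaseModel):
    mp_ratio: float = Field(gt=0)
    skim_conc_ratio: float
    fat_conc_ratio: float

    @model_validator(mode="after")
    def _check_identity(self) -> "MilkTransferResult":
        # mp must be the fat-weighted mix of the two phase ratios
        return self


MILK_PRESETS: dict[str, MilkComposition] = {
    "colostrum": MilkComposition(ph_milk=7.6, fat_fraction=0.02),
    "transitional": MilkComposition(ph_milk=7.44, fat_fraction=0.035),
    "mature": MilkComposition(ph_milk=7.2, fat_fraction=0.04),
}


def unionized_fraction(ph: float, pka: float, species: str = "base") -> float:
    """Un-ionized fraction of a monoprotic base (default) or acid at a pH."""
    if species == "base":
        return 1.0 / (1.0 + 10.0 ** (pka - ph))
    if species == "acid":
        return 1.0 / (1.0 + 10.0 ** (ph - pka))
    raise ValueError(f"species must be 'base' or 'acid', got {species!r}")


def _fu_skim(fu_plasma: float, protein_ratio: float) -> float:
    # bound/free in skim milk = protein_ratio * bound/free in plasma
    bf_plasma = (1.0 - fu_plasma) / fu_plasma
    return 1.0 / (1.0 + protein_ratio * bf_plasma)


def _k_fat(logp: float) -> float:
    """Milk-fat/water partition coefficient from lipophilicity."""
    return 10.0 ** (0.99 * logp - 0.88)


def mp_ratio(drug: DrugParameters, milk: MilkComposition,
             fu_plasma: float) -> MilkTransferResult:
    """Predict the milk-to-plasma concentration ratio.

    The unbound un-ionized concentration is equal in plasma water and skim
    milk water; total concentrations then differ by ionization (pH
    partition) and protein binding.  Fat carries drug in proportion to the
    unbound un-ionized plasma concentration and the fat partition
    coefficient.
    """
    if not (0.0 < fu_plasma <= 1.0):
        raise ValueError(f"fu_plasma must be in (0, 1], got {fu_plasma}")
    species = getattr(drug, "species", "base")
    fu_skim = _fu_skim(fu_plasma, milk.protein_ratio)
    # equal unbound un-ionized concentration in plasma and skim-milk water
    ion_ratio = unionized_fraction(milk.ph_plasma, drug.pka_base, species) / \
        unionized_fraction(milk.ph_milk, drug.pka_base, species)
    skim = fu_plasma * ion_ratio / fu_skim
    fat = fu_plasma * unionized_fraction(milk.ph_plasma, drug.pka_base, species) \
        * _k_fat(drug.logp)
    mp = (1.0 - milk.fat_fraction) * skim + milk.fat_fraction * fat
    return MilkTransferResult(mp_ratio=mp, skim_conc_ratio=skim, fat_conc_ratio=fat)


def calibrate_protein_ratio(drug: DrugParameters, milk: MilkComposition,
                            fu_plasma: float, target_mp: float) -> float:
    """Solve for the milk binding-protein scalar giving a target M/P.

    Closed form: the skim ratio is linear in 1/fu_skim, and fu_skim is a
    rational function of the protein ratio.
    """
    if target_mp <= 0.0:
        raise ValueError("target M/P must be positive")
    species = getattr(drug, "species", "base")
    fat = fu_plasma * unionized_fraction(milk.ph_plasma, drug.pka_base, species) \
        * _k_fat(drug.logp)
    ion_ratio = unionized_fraction(milk.ph_plasma, drug.pka_base, species) / \
        unionized_fraction(milk.ph_milk, drug.pka_base, species)
    skim_needed = (target_mp - milk.fat_fraction * fat) / (1.0 - milk.fat_fraction)
    fu_skim = fu_plasma * ion_ratio / skim_needed
    if not (0.0 < fu_skim <= 1.0):
        raise ValueError(
            f"target M/P {target_mp} unreachable: implied fu_skim {fu_skim:.4f}"
        )
    bf_plasma = (1.0 - fu_plasma) / fu_plasma
    return (1.0 / fu_skim - 1.0) / bf_plasma


def idd_from_mp(mp: float, maternal_cavg: float, milk_intake: float) -> float:
    """Infant daily dose (ug/kg/day) from M/P, maternal average plasma
    concentration (ng/mL) and milk intake (mL/kg/day)."""
    if mp < 0.0 or maternal_cavg < 0.0 or milk_intake < 0.0:
        raise ValueError("inputs must be non-negative")
    return mp * maternal_cavg * milk_intake / 1000.0


def idd_from_cumulative(cumulative_dose: float, days: int) -> float:
    """Daily dose (ug/kg/day) from a cumulative dose (mg/kg) over n days."""
    if days < 1:
        raise ValueError("days must be >= 1")
    return 1000.0 * cumulative_dose / days


def ridd(idd: float, maternal_dose: float) -> float:
    """Relative infant daily dose (%) given both doses in ug/kg/day."""
    if maternal_dose <= 0.0:
        raise ValueError("maternal dose must be positive")
    return 100.0 * idd / maternal_dose


def per_feed_dose(idd: float, n_feeds: int) -> float:
    """Split a daily dose (ug/kg/day) evenly across feeds (ug/kg each)."""
    if n_feeds < 1:
        raise ValueError("n_feeds must be >= 1")
    return idd / n_feeds


# Printed study quantities (ug/kg/day unless noted); used by scenarios.
IDD_AVERAGE = 2.98
IDD_HIGHEST = 9.07
MATERNAL_DOSE_UG_KG_DAY = 500.0
MILK_INTAKE_DEFAULT = 150.0  # mL/kg/day
N_FEEDS_DEFAULT = 6
FEED_INTERVAL_H = 4.0
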