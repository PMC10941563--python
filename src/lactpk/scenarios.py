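"""Named study scenarios and sensitivity scans.

Each scenario bundles a population, a dosing regimen (either given
directly, as for the mothers and children, or derived from an infant daily
dose consumed as six 4-hourly milk feeds), ontogeny assignments and a milk
mode.  Milk modes:

``fixed_idd``
    use a stated infant daily dose (the study's reported average
    2.98 ug/kg/day or highest 9.07 ug/kg/day);
``observed_mp`` / ``predicted_mp``
    derive the IDD from the simulated maternal day-14 average plasma
    concentration via the observed M/P of 0.34 or the model-predicted
    M/P, and the configured milk intake (mL/kg/day).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .binding import DrugParameters, primaquine
from .engine import DAY14_WINDOW, Regimen, pk_metrics, simulate_subject
from .milk import (
    FEED_INTERVAL_H,
    IDD_AVERAGE,
    IDD_HIGHEST,
    MILK_INTAKE_DEFAULT,
    MILK_PRESETS,
    N_FEEDS_DEFAULT,
    MilkComposition,
    idd_from_mp,
    mp_ratio,
    per_feed_dose,
)
from .binding import fu_at_aag
from .ontogeny import PRESETS, resolve_profile
from .physiology import DEFAULT_PHYSIOLOGY, PhysiologyConfig, PopulationSpec
from .physiology import typical_adult
from .trials import TrialSummary, relative_exposure, run_trial_set

__all__ = [
    "ScenarioConfig",
    "ScenarioResult",
    "run_scenario",
    "sensitivity_scan",
    "SCENARIOS",
    "make_scenario",
]

OBSERVED_MP = 0.34


class ScenarioConfig(BaseModel):
    """Validated description of one virtual study."""

    name: str
    population: PopulationSpec
    ontogeny: dict[str, object] = Field(
        default_factory=lambda: {"MAOA": "maoa_none", "CYP2D6": "cyp2d6_default"}
    )
    regimen: Optional[Regimen] = None
    milk_mode: Optional[Literal["observed_mp", "predicted_mp", "fixed_idd"]] = None
    idd: Optional[float] = Field(default=None, description="ug/kg/day")
    milk_preset: str = "mature"
    milk_intake: float = MILK_INTAKE_DEFAULT
    n_feeds: int = N_FEEDS_DEFAULT
    feed_interval: float = FEED_INTERVAL_H
    duration_days: int = 14
    n_trials: int = 10
    seed: int = 0
    metric_window: tuple[float, float] = DAY14_WINDOW
    dt: float = 0.1
    aag_fold: float = 1.0
    compare_to_mother: bool = False

    @model_validator(mode="after")
    def _validate(self) -> "ScenarioConfig":
        errors = []
        if self.regimen is None and self.milk_mode is None:
            errors.append("either a regimen or a milk_mode must be given")
        if self.milk_mode == "fixed_idd" and self.idd is None:
            errors.append("milk_mode 'fixed_idd' requires an idd value")
        if self.milk_preset not in MILK_PRESETS:
            errors.append(f"unknown milk preset {self.milk_preset!r}")
        for pathway, preset in self.ontogeny.items():
            try:
                resolve_profile(preset)  # type: ignore[arg-type]
            except KeyError:
                errors.append(f"unknown ontogeny preset for {pathway}: {preset!r}")
        if errors:
            raise ValueError("; ".join(errors))
        return self


@dataclass
class ScenarioResult:
    config: ScenarioConfig
    summary: TrialSummary
    idd: Optional[float]  # ug/kg/day actually used (None for direct regimens)
    mp: Optional[float]  # M/P ratio used to derive the IDD, if any
    mother: Optional[TrialSummary] = None
    relative: Optional[dict] = None
    outputs: Optional[dict] = None


def _maternal_cavg(drug: DrugParameters, config: PhysiologyConfig,
                   dt: float) -> float:
    """Day-14 average plasma concentration of the reference nursing mother."""
    mother = typical_adult(config=config)
    regimen = Regimen(dose_per_kg=500.0, interval=24.0, n_doses=14)
    profile = simulate_subject(
        mother, drug, regimen, {"MAOA": "maoa_none", "CYP2D6": "maoa_none"},
        config, dt=dt,
    )
    return pk_metrics(profile, DAY14_WINDOW).cavg


def _resolve_regimen(config: ScenarioConfig, drug: DrugParameters,
                     phys: PhysiologyConfig) -> tuple[Regimen, Optional[float], Optional[float]]:
    """Return (regimen, idd, mp) for a scenario."""
    if config.regimen is not None:
        return config.regimen, None, None
    if config.milk_mode == "fixed_idd":
        idd, mp = config.idd, None
    else:
        cavg = _maternal_cavg(drug, phys, config.dt)
        if config.milk_mode == "observed_mp":
            mp = OBSERVED_MP
        else:
            milk = MILK_PRESETS[config.milk_preset]
            mother = typical_adult(config=phys)
            fu = fu_at_aag(drug.binding_model(), mother.aag)
            mp = mp_ratio(drug, milk, fu).mp_ratio
        idd = idd_from_mp(mp, cavg, config.milk_intake)
    regimen = Regimen(
        dose_per_kg=per_feed_dose(idd, config.n_feeds),
        interval=config.feed_interval,
        n_doses=int(round(config.duration_days * 24.0 / config.feed_interval)),
    )
    return regimen, idd, mp


def mother_reference_config(seed: int = 0, n_trials: int = 10) -> ScenarioConfig:
    return ScenarioConfig(
        name="mother_lactation",
        population=PopulationSpec(
            n_subjects=20, age_range=(18.0, 40.0), proportion_female=1.0
        ),
        regimen=Regimen(dose_per_kg=500.0, interval=24.0, n_doses=14),
        ontogeny={"MAOA": "maoa_none", "CYP2D6": "maoa_none"},
        n_trials=n_trials,
        seed=seed,
    )


def run_scenario(config: ScenarioConfig,
                 drug: DrugParameters | None = None,
                 phys: PhysiologyConfig = DEFAULT_PHYSIOLOGY,
                 outdir: str | Path | None = None) -> ScenarioResult:
    """Execute a scenario: resolve the regimen, run the trial set, and
    optionally write the artifact bundle (CSV profiles summary, JSON
    summary, plain-text run log)."""
    if drug is None:
        drug = primaquine()
    regimen, idd, mp = _resolve_regimen(config, drug, phys)
    summary = run_trial_set(
        drug, config.population, regimen, config.ontogeny,
        n_trials=config.n_trials, seed=config.seed,
        metric_window=config.metric_window, config=phys, dt=config.dt,
        aag_fold=config.aag_fold,
    )
    mother = None
    relative = None
    if config.compare_to_mother:
        mother_cfg = mother_reference_config(seed=config.seed, n_trials=config.n_trials)
        mother = run_trial_set(
            drug, mother_cfg.population, mother_cfg.regimen, mother_cfg.ontogeny,
            n_trials=mother_cfg.n_trials, seed=mother_cfg.seed,
            metric_window=mother_cfg.metric_window, config=phys, dt=config.dt,
        )
        relative = relative_exposure(summary, mother)
    outputs = None
    if outdir is not None:
        outputs = _write_bundle(config, summary, idd, mp, relative, Path(outdir))
    return ScenarioResult(
        config=config, summary=summary, idd=idd, mp=mp,
        mother=mother, relative=relative, outputs=outputs,
    )


def _write_bundle(config: ScenarioConfig, summary: TrialSummary,
                  idd, mp, relative, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / f"{config.name}_subjects.csv"
    summary.subjects.to_csv(csv_path, index=False)
    payload = {
        "scenario": config.name,
        "seed": config.seed,
        "n_trials": summary.n_trials,
        "n_per_trial": summary.n_per_trial,
        "idd_ug_kg_day": idd,
        "mp_ratio": mp,
        "pooled": summary.pooled,
        "per_trial": summary.per_trial,
        "max_conc_ng_ml": summary.max_conc,
        "relative_exposure_pct": relative,
    }
    json_path = outdir / f"{config.name}_summary.json"
    json_path.write_text(json.dumps(payload, indent=2))
    cfg_json = config.model_dump_json()
    log_path = outdir / f"{config.name}_run.log"
    log_path.write_text(
        f"scenario: {config.name}\nseed: {config.seed}\n"
        f"lactpk version: {__version__}\n"
        f"config sha256: {hashlib.sha256(cfg_json.encode()).hexdigest()}\n"
        f"config: {cfg_json}\n"
    )
    return {"csv": str(csv_path), "json": str(json_path), "log": str(log_path)}


def make_scenario(name: str, seed: int = 0, n_trials: int = 10) -> ScenarioConfig:
    """Build one of the shipped named scenarios."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}")
    return SCENARIOS[name](seed, n_trials)


def _infant_pop(n=20):
    # 1.5-22 months, 33% girls, matching the lactation study infants
    return PopulationSpec(n_subjects=n, age_range=(0.125, 1.83), proportion_female=0.33)


def _neonate_pop(n=20):
    return PopulationSpec(n_subjects=n, age_range=(0.0, 28.0 / 365.25),
                          proportion_female=0.5)


SCENARIOS = {
    "mother_lactation": lambda seed, n_trials: mother_reference_config(seed, n_trials),
    "children_6_10": lambda seed, n_trials: ScenarioConfig(
        name="children_6_10",
        population=PopulationSpec(n_subjects=15, age_range=(6.0, 10.0),
                                  proportion_female=0.40),
        regimen=Regimen(dose_per_kg=500.0, interval=24.0, n_doses=1),
        metric_window=(0.0, 24.0),
        seed=seed, n_trials=n_trials,
    ),
    "infant_avg_idd": lambda seed, n_trials: ScenarioConfig(
        name="infant_avg_idd", population=_infant_pop(),
        milk_mode="fixed_idd", idd=IDD_AVERAGE,
        compare_to_mother=True, seed=seed, n_trials=n_trials,
    ),
    "infant_high_idd": lambda seed, n_trials: ScenarioConfig(
        name="infant_high_idd", population=_infant_pop(),
        milk_mode="fixed_idd", idd=IDD_HIGHEST,
        compare_to_mother=True, seed=seed, n_trials=n_trials,
    ),
    "neonate_no_ontogeny": lambda seed, n_trials: ScenarioConfig(
        name="neonate_no_ontogeny", population=_neonate_pop(),
        ontogeny={"MAOA": "maoa_none", "CYP2D6": "cyp2d6_default"},
        milk_mode="fixed_idd", idd=IDD_AVERAGE,
        compare_to_mother=True, seed=seed, n_trials=n_trials,
    ),
    "neonate_slow_ontogeny": lambda seed, n_trials: ScenarioConfig(
        name="neonate_slow_ontogeny", population=_neonate_pop(),
        ontogeny={"MAOA": "maoa_slow", "CYP2D6": "cyp2d6_default"},
        milk_mode="fixed_idd", idd=IDD_AVERAGE,
        compare_to_mother=True, seed=seed, n_trials=n_trials,
    ),
}

# Brazilian pediatric cohorts: (age range, daily dose ug/kg, n per trial)
BRAZIL_COHORTS = {
    "brazil_2_3y": ((2.0, 3.0), 420.0, 22),
    "brazil_4_8y": ((4.0, 8.0), 500.0, 20),
    "brazil_9_11y": ((9.0, 11.0), 440.0, 21),
    "brazil_12_14y": ((12.0, 14.0), 460.0, 22),
}

for _name, (_ages, _dose, _n) in BRAZIL_COHORTS.items():
    SCENARIOS[_name] = (
        lambda seed, n_trials, _ages=_ages, _dose=_dose, _n=_n, _name=_name:
        ScenarioConfig(
            name=_name,
            population=PopulationSpec(n_subjects=_n, age_range=_ages,
                                      proportion_female=0.5),
            regimen=Regimen(dose_per_kg=_dose, interval=24.0, n_doses=7),
            metric_window=(144.0, 168.0),
            seed=seed, n_trials=n_trials,
        )
    )


SCAN_PARAMETERS = ("aag_fold", "milk_ph", "milk_fat", "intake")


def sensitivity_scan(config: ScenarioConfig, parameter: str, grid,
                     drug: DrugParameters | None = None,
                     phys: PhysiologyConfig = DEFAULT_PHYSIOLOGY) -> pd.DataFrame:
    """Re-run a scenario across a one-parameter grid, everything else fixed.

    Milk parameters (``milk_ph``, ``milk_fat``) report the predicted M/P and
    rescale the infant daily dose proportionally; ``aag_fold`` scales every
    subject's AAG; ``intake`` scales the milk volume per kg.  Relative
    exposure columns appear when the scenario compares to the mother.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("sensitivity grid must be non-empty")
    if parameter not in SCAN_PARAMETERS:
        raise ValueError(f"unsupported parameter {parameter!r}; one of {SCAN_PARAMETERS}")
    if drug is None:
        drug = primaquine()
    if parameter in ("milk_ph", "milk_fat") and config.milk_mode is None:
        raise ValueError("milk parameter scans require a milk-mode scenario")
    rows = []
    base_milk = MILK_PRESETS[config.milk_preset]
    mother = typical_adult(config=phys)
    fu = fu_at_aag(drug.binding_model(), mother.aag)
    base_mp = mp_ratio(drug, base_milk, fu).mp_ratio
    for value in grid:
        update: dict = {}
        mp_here = None
        if parameter == "aag_fold":
            update["aag_fold"] = config.aag_fold * value
        elif parameter == "intake":
            update["milk_intake"] = value
            if config.milk_mode == "fixed_idd":
                update["idd"] = config.idd * value / config.milk_intake
        else:
            milk_kwargs = dict(ph_milk=base_milk.ph_milk,
                               fat_fraction=base_milk.fat_fraction,
                               protein_ratio=base_milk.protein_ratio)
            if parameter == "milk_ph":
                milk_kwargs["ph_milk"] = value
            else:
                milk_kwargs["fat_fraction"] = value
            mp_here = mp_ratio(drug, MilkComposition(**milk_kwargs), fu).mp_ratio
            if config.milk_mode == "fixed_idd":
                update["idd"] = config.idd * mp_here / base_mp
        scanned = config.model_copy(update=update)
        result = run_scenario(scanned, drug=drug, phys=phys)
        row = {
            "parameter": parameter,
            "value": value,
            "mp_ratio": mp_here,
            "idd_ug_kg_day": result.idd,
            "pooled_median_cmax": result.summary.pooled_median("cmax"),
            "pooled_median_auc": result.summary.pooled_median("auc"),
            "max_conc": result.summary.max_conc,
        }
        if result.relative is not None:
            row["rel_cmax_pct"] = result.relative["cmax"]
            row["rel_auc_pct"] = result.relative["auc"]
        rows.append(row)
    return pd.DataFrame(rows)
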