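"""PBPK engine: analytic oracles, superposition, mass balance, well-stirred
scaling, and calibration to the printed maternal exposure."""

import math

import numpy as np
import pytest

from lactpk.binding import fu_at_aag
from lactpk.engine import (
    CalibrationError,
    ConcentrationProfile,
    ModelParams,
    Regimen,
    calibrate_adult,
    pk_metrics,
    scaled_clearance,
    simulate,
    simulate_subject,
)
from lactpk.ontogeny import OntogenyProfile

from conftest import ADULT_ONTOGENY, INFANT_ONTOGENY, typical_child


def one_compartment_params() -> ModelParams:
    return ModelParams(
        ka=1.0, fa=1.0, v_central=100.0, v_peripheral=0.0, q_inter=0.0,
        cl_int_scaled={"X": 30.0}, q_hepatic=90.0, fu_blood=0.3,
    )


def analytic_oral_1cpt(t, params: ModelParams, dose_ug: float) -> np.ndarray:
    """Closed-form single oral dose, one compartment, first-pass extraction."""
    f_oral = params.fa * (1.0 - params.extraction)
    k = params.cl_hepatic / params.v_central
    ka = params.ka
    return (f_oral * dose_ug * ka / (params.v_central * (ka - k))
            * (np.exp(-k * t) - np.exp(-ka * t)))


def test_single_dose_matches_closed_form():
    params = one_compartment_params()
    regimen = Regimen(dose_per_kg=500.0, interval=24.0, n_doses=1)
    prof = simulate(params, regimen, weight=70.0)
    exact = analytic_oral_1cpt(prof.times, params, params.fa * 500.0 * 70.0)
    cmax = exact.max()
    assert np.max(np.abs(prof.conc - exact)) <= 1e-3 * cmax


def test_multiple_doses_equal_superposition_of_shifted_singles():
    params = one_compartment_params()
    multi = simulate(params, Regimen(dose_per_kg=500.0, interval=24.0, n_doses=14),
                     weight=70.0)
    single = simulate(params, Regimen(dose_per_kg=500.0, interval=24.0, n_doses=1),
                      weight=70.0, t_end=336.0)
    steps = int(round(24.0 / 0.1))
    super_conc = np.zeros_like(single.conc)
    for j in range(14):
        shift = j * steps
        super_conc[shift:] += single.conc[: len(single.conc) - shift]
    assert np.max(np.abs(multi.conc - super_conc)) <= 1e-3 * multi.conc.max()


def test_dose_linearity():
    params = one_compartment_params()
    lo = simulate(params, Regimen(dose_per_kg=250.0, interval=24.0, n_doses=3),
                  weight=70.0)
    hi = simulate(params, Regimen(dose_per_kg=500.0, interval=24.0, n_doses=3),
                  weight=70.0)
    assert np.allclose(hi.conc, 2.0 * lo.conc, rtol=1e-9, atol=1e-12)


def test_mass_balance_closed_at_every_grid_point(drug, mother, maternal_regimen):
    prof = simulate_subject(mother, drug, maternal_regimen, ADULT_ONTOGENY)
    total = prof.amounts.sum(axis=1)
    steps_per_dose = int(round(maternal_regimen.interval / 0.1))
    dose_amt = drug.fa * maternal_regimen.dose_per_kg * mother.weight
    n_given = np.minimum(
        np.arange(len(prof.times)) // steps_per_dose + 1, maternal_regimen.n_doses
    )
    expected = n_given * dose_amt
    assert np.max(np.abs(total - expected) / expected) <= 1e-3


def test_two_compartment_profile_is_nonnegative_and_finite(drug, mother,
                                                           maternal_regimen):
    prof = simulate_subject(mother, drug, maternal_regimen, ADULT_ONTOGENY)
    assert np.all(np.isfinite(prof.conc)) and np.all(prof.conc >= 0)


def test_misaligned_interval_rejected():
    params = one_compartment_params()
    with pytest.raises(ValueError):
        simulate(params, Regimen(dose_per_kg=1.0, interval=0.25, n_doses=2),
                 weight=10.0)


class TestPkMetrics:
    def test_constant_profile(self):
        t = np.linspace(0.0, 24.0, 241)
        prof = ConcentrationProfile(times=t, conc=np.full_like(t, 5.0))
        m = pk_metrics(prof, (0.0, 24.0))
        assert m.cmax == 5.0
        assert m.auc_tau == pytest.approx(120.0, rel=1e-12)
        assert m.cavg == pytest.approx(5.0, rel=1e-12)

    def test_triangle_exact_area(self):
        prof = ConcentrationProfile(times=np.array([0.0, 1.0, 2.0]),
                                    conc=np.array([0.0, 1.0, 0.0]))
        assert pk_metrics(prof, (0.0, 2.0)).auc_tau == pytest.approx(1.0, rel=1e-12)

    def test_grid_refinement_converges(self, drug, mother, maternal_regimen):
        coarse = simulate_subject(mother, drug, maternal_regimen, ADULT_ONTOGENY,
                                  dt=0.1)
        fine = simulate_subject(mother, drug, maternal_regimen, ADULT_ONTOGENY,
                                dt=0.01)
        a = pk_metrics(coarse, (312.0, 336.0)).auc_tau
        b = pk_metrics(fine, (312.0, 336.0)).auc_tau
        assert abs(a - b) / b < 5e-4

    def test_empty_window_rejected(self, drug, mother, maternal_regimen):
        prof = simulate_subject(mother, drug, maternal_regimen, ADULT_ONTOGENY)
        with pytest.raises(ValueError):
            pk_metrics(prof, (400.0, 500.0))

    def test_cmax_at_least_cavg(self, drug, mother, maternal_regimen):
        prof = simulate_subject(mother, drug, maternal_regimen, ADULT_ONTOGENY)
        m = pk_metrics(prof, (312.0, 336.0))
        assert m.cmax >= m.cavg


class TestScaledClearance:
    def test_zero_maturation_gives_zero_clearance(self, drug):
        newborn = typical_child(0.0)
        hep = scaled_clearance(
            newborn, drug,
            {p: OntogenyProfile(f_birth=0.0, age50=52.0, hill=1.0)
             for p in drug.fm_by_pathway},
        )
        assert hep.cl_hepatic == 0.0

    def test_low_extraction_limit(self, drug, mother):
        tiny = drug.model_copy(update={"cl_int_per_kg_liver": 0.05})
        hep = scaled_clearance(mother, tiny, ADULT_ONTOGENY)
        assert hep.cl_hepatic == pytest.approx(
            hep.fu_blood * hep.cl_int_total, rel=0.01
        )

    def test_well_stirred_never_exceeds_liver_flow(self, drug, mother):
        huge = drug.model_copy(update={"cl_int_per_kg_liver": 1e6})
        hep = scaled_clearance(mother, huge, ADULT_ONTOGENY)
        assert hep.cl_hepatic < hep.q_hepatic
        assert hep.extraction == pytest.approx(1.0, abs=0.01)

    def test_aag_elevation_raises_exposure_by_fu_ratio(self, drug):
        """In the low-extraction regime, 4x AAG lowers fu and raises AUC by
        close to the fu fold-change (the mechanism behind the infant
        sensitivity analysis)."""
        infant = typical_child(0.98)
        elevated = typical_child(0.98)
        elevated.aag *= 4.0
        regimen = Regimen(dose_per_kg=2.98 / 6, interval=4.0, n_doses=84)
        auc = {}
        for label, subj in [("base", infant), ("4x", elevated)]:
            prof = simulate_subject(subj, drug, regimen, INFANT_ONTOGENY)
            auc[label] = pk_metrics(prof, (312.0, 336.0)).auc_tau
        model = drug.binding_model()
        fu_fold = fu_at_aag(model, infant.aag) / fu_at_aag(model, elevated.aag)
        assert auc["4x"] / auc["base"] == pytest.approx(fu_fold, rel=0.10)


class TestExposureMonotonicity:
    def test_exposure_decreases_with_maturation_fraction(self, drug):
        neonate = typical_child(0.0)
        regimen = Regimen(dose_per_kg=2.98 / 6, interval=4.0, n_doses=84)
        aucs = []
        for frac in (0.2, 0.5, 1.0):
            omap = {"MAOA": {"f_birth": frac, "age50": 52.0, "hill": 1.0},
                    "CYP2D6": "cyp2d6_default"}
            prof = simulate_subject(neonate, drug, regimen, omap)
            aucs.append(pk_metrics(prof, (312.0, 336.0)).auc_tau)
        assert aucs[0] > aucs[1] > aucs[2]

    def test_exposure_decreases_with_fraction_unbound(self, drug):
        regimen = Regimen(dose_per_kg=2.98 / 6, interval=4.0, n_doses=84)
        aucs = []
        for aag_fold in (4.0, 2.0, 1.0):  # decreasing AAG -> increasing fu
            subj = typical_child(0.98)
            subj.aag *= aag_fold
            prof = simulate_subject(subj, drug, regimen, INFANT_ONTOGENY)
            aucs.append(pk_metrics(prof, (312.0, 336.0)).auc_tau)
        assert aucs[0] > aucs[1] > aucs[2]


class TestCalibration:
    def test_targets_hit_within_half_percent(self, drug, mother, maternal_regimen):
        cal = calibrate_adult(drug, maternal_regimen)
        prof = simulate_subject(mother, cal, maternal_regimen, ADULT_ONTOGENY)
        m = pk_metrics(prof, (312.0, 336.0))
        assert m.cmax == pytest.approx(129.0, rel=0.005)
        assert m.auc_tau == pytest.approx(988.0, rel=0.005)

    def test_apparent_clearance_identity(self, drug, mother, maternal_regimen):
        cal = calibrate_adult(drug, maternal_regimen)
        prof = simulate_subject(mother, cal, maternal_regimen, ADULT_ONTOGENY)
        auc = pk_metrics(prof, (312.0, 336.0)).auc_tau
        cl_f_per_kg = maternal_regimen.dose_per_kg / auc  # L/h/kg at steady state
        assert cl_f_per_kg == pytest.approx(500.0 / 988.0, rel=0.01)

    def test_infeasible_targets_raise(self, drug, maternal_regimen):
        # Cmax below the steady-state average concentration is unreachable
        with pytest.raises(CalibrationError):
            calibrate_adult(drug, maternal_regimen, target_cmax=10.0,
                            target_auc=988.0)

    def test_calibration_responds_to_targets(self, drug, maternal_regimen):
        lo = calibrate_adult(drug, maternal_regimen)
        hi = calibrate_adult(drug, maternal_regimen, target_cmax=129.0 * 2,
                             target_auc=988.0 * 2)
        # doubled exposure at fixed dose -> halved apparent clearance
        assert hi.cl_int_per_kg_liver == pytest.approx(
            lo.cl_int_per_kg_liver / 2, rel=0.02
        )


def test_pediatric_cohort_cmax_within_printed_band(drug):
    """Day-7 Cmax for the four pediatric cohorts (daily dosing at the study
    doses) falls within 1.5-fold of the reported predictions."""
    printed = {(2.0, 3.0): (420.0, 113.0), (4.0, 8.0): (500.0, 127.0),
               (9.0, 11.0): (440.0, 106.0), (12.0, 14.0): (460.0, 112.0)}
    for (lo, hi), (dose, target) in printed.items():
        child = typical_child((lo + hi) / 2.0)
        regimen = Regimen(dose_per_kg=dose, interval=24.0, n_doses=7)
        prof = simulate_subject(child, drug, regimen, INFANT_ONTOGENY)
        cmax = pk_metrics(prof, (144.0, 168.0)).cmax
        assert target / 1.5 <= cmax <= target * 1.5
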