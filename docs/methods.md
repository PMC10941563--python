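# Methods

This note documents the model structure, parameter provenance, the
synthetic-data generator, the numerical choices, and the known
limitations of `lactpk`.

## 1. Drug and binding model (`lactpk.binding`)

Primaquine is treated as a monoprotic base (pKa 10.4, logP 3.0) cleared
hepatically by two pathways, MAO-A (fm 0.90) and CYP2D6 (fm 0.10).
Plasma protein binding is dominated by α1-acid glycoprotein (AAG) and is
modeled as single-site and linear in AAG:

    fu(AAG) = 1 / (1 + ka·AAG),  ka = (1 − fu_ref) / (fu_ref·AAG_ref)

anchored at fu_ref = 0.33 at AAG_ref = 0.6 g/L (pregnancy). At the
postpartum 0.7 g/L this predicts fu = 0.2969, reported as 0.29
(two significant figures, truncated — the convention of the reported
value). The blood/plasma ratio is fixed at 1.

## 2. Physiology and growth (`lactpk.physiology`)

Virtual children get height from sex-specific age polynomials
(degree 7 for boys, degree 8 for girls) and weight from

    W = A·(1 − e^(−k·age)) + e^(c·height) + b·age

with (A, k-rate, c, b) = (6.026, 1.2, 0.0209, 0.023) for boys and
(4.054, 1.57, 0.0224, 0.019) for girls. These equations are accurate in
the infant-to-child range that the analysis targets; adult mothers use
fixed sex-specific means (163 cm/60 kg female, 176 cm/75 kg male) with
lognormal variability rather than the equations.

Age-dependent physiology:

- **Liver mass**: fraction of body weight 0.021 + 0.019·e^(−age/3)
  (≈4% at birth → 2.1% adult; ~1.5 kg for a 70 kg adult).
- **Hepatic blood flow**: 60 L/h per kg liver.
- **AAG**: 0.7·(0.32 + 0.68·w/(w + 30)) g/L with w = postnatal weeks —
  ~0.22 g/L at birth maturing hyperbolically to 0.7 g/L.
- **Metabolic capacity per gram liver**: 0.25 + 0.75·w^1.5/(w^1.5 + 6^1.5),
  a Hill curve from 25% of adult at birth to ~adult by ~2 years. This is
  distinct from isozyme ontogeny: it represents the maturation of total
  metabolically active hepatic protein (MPPGL-like). It is the least
  literature-constrained element of the model; its shape was fixed
  during model development so that pediatric scaling reproduces the
  expected qualitative pattern (children ≈ adults; infants far below
  mothers; neonates above infants even with adult-level MAO-A activity
  per gram).

Inter-individual variability: lognormal, median-preserving, CV 35% on
intrinsic clearance and 25% on distribution volumes; height/weight CVs
of 4%/15% (children) and 10%/20% (adults).

## 3. Enzyme ontogeny (`lactpk.ontogeny`)

Pathway activity relative to adult follows a Hill function of postnatal
age: f(age) = f_birth + (1 − f_birth)·w^h/(w^h + age50^h). Shipped
presets:

| preset | f_birth | age50 (weeks) | hill | use |
|---|---|---|---|---|
| `maoa_none` | 1.0 | — | — | adult-level MAO-A (base case) |
| `maoa_slow` | 0.35 | 52 | 1 | hypothetical slow MAO-A maturation |
| `cyp2d6_default` | 0.05 | 2 | 1 | rapid postnatal CYP2D6 surge |

MAO-A ontogeny is not established in the literature; the base analysis
therefore assumes adult activity per gram liver (conservative for the
neonate only through the capacity curve), and `maoa_slow` is a
sensitivity case chosen so that neonatal relative exposure stays below
~0.5%.

## 4. Milk transfer (`lactpk.milk`)

Phase-distribution model. Milk is skim + fat; only unbound, un-ionized
drug equilibrates across phases:

- skim/plasma ratio = fu_plasma · [f_un(pH_plasma)/f_un(pH_milk)] / fu_skim,
  where f_un is the Henderson–Hasselbalch un-ionized fraction and
  fu_skim derives from plasma binding scaled by the milk
  binding-protein content (`protein_ratio`);
- fat/plasma ratio = fu_plasma · f_un(pH_plasma) · K_fat with
  K_fat = 10^(0.99·logP − 0.88);
- M/P = (1 − fat_fraction)·skim_ratio + fat_fraction·fat_ratio.

`protein_ratio` is the single calibrated constant: fixed once so that
mature milk (pH 7.2, 4% fat) gives M/P = 0.47 at the postpartum fu
(AAG = 0.7 g/L), giving protein_ratio = 0.01594. The model then
*predicts* 0.48 at 2% fat (fat content is nearly irrelevant for this
drug) and ~0.20 at pH 7.6 (ion trapping of the base dominates). The
observed study M/P of 0.34 is available as a separate constant and is
the default for deriving infant doses in `observed_mp` mode.

Infant daily dose (IDD, µg/kg/day) = M/P × maternal day-14 average
plasma concentration × milk intake (150 mL/kg/day standard,
200 conservative). Study-anchored values: average 2.98 and highest
9.07 µg/kg/day (the latter from the 0.127 mg/kg cumulative 14-day
dose), i.e. relative infant doses of ~0.6% and ~1.8%. Feeding schedule:
six 4-hourly feeds per day (feed times were not reported; this is a
named, overridable default).

## 5. PBPK engine (`lactpk.engine`)

Lumped model with four states — gut depot, central, peripheral,
eliminated — linear and time-invariant between doses:

- absorption ka = 1/h, fa = 1;
- well-stirred liver: E = fu_b·CL_int/(Q_h + fu_b·CL_int), first-pass
  F = fa·(1 − E), systemic hepatic clearance CL_h = Q_h·E. Oral AUC is
  therefore exactly fa·Dose/(fu_b·CL_int), which is what makes
  steady-state exposure scale inversely with fraction unbound — the
  mechanism behind the AAG sensitivity analysis (4× AAG → ~2.9-fold
  exposure);
- scaled intrinsic clearance per subject =
  CL_int,adult/kg liver × liver mass × capacity(age) × Σ fm_p·ontogeny_p(age);
- two-compartment distribution (V1 1.71 L/kg calibrated, V2 1.0 L/kg,
  Q 0.2 L/h/kg).

**Numerical method.** The system is propagated with a per-step matrix
exponential (`scipy.linalg.expm`) on a fixed 0.1 h grid, with doses
aligned to grid points. Between doses the model is linear
time-invariant, so this is exact to machine precision, unconditionally
stable, and deterministic — an adaptive stiff ODE integrator would add
tolerance-dependent error and cost without benefit for a linear system.
Correctness is checked against independent closed-form solutions
(one-compartment oral formula), superposition, dose linearity and mass
balance, all to ≤0.1%; AUC uses trapezoidal quadrature (grid-refinement
convergence verified).

**Calibration.** `calibrate_adult` solves a 2-dimensional root problem
(log intrinsic clearance, log central volume; `scipy.optimize.root`,
hybr) so that the deterministic typical mother (60 kg, 0.5 mg/kg q.d.
× 14) hits the day-14 targets median Cmax 129 ng/mL and AUC24
988 ng·h/mL within 0.5%. The resulting constants
(CL_int = 80.448 L/h/kg liver, V1 = 1.714 L/kg) are the shipped drug
defaults; the consistency check CL/F = dose/AUC ≈ 0.506 L/h/kg holds by
construction.

## 6. Virtual trials and scenarios (`lactpk.trials`, `lactpk.scenarios`)

A study is 10 trials × N subjects (N = 20 unless stated). Reproducibility
uses `numpy.random.SeedSequence` spawning: the study seed spawns one
stream per trial, each trial samples its subjects and their lognormal
kinetic multipliers. Summaries report per-trial and pooled median, p5,
p95 of Cmax and AUC over the day-14 dosing interval (or day 7/day 1
windows for the pediatric cohorts), plus the maximum concentration over
all subjects and times. Relative exposure = 100 × pooled infant median /
pooled maternal median.

Scenario bundles (written with `--out`) contain a per-subject CSV, a
JSON summary, and a plain-text run log with seed, package version and a
SHA-256 of the full config — sufficient to regenerate outputs
bit-identically.

Sensitivity scans re-run a scenario over a one-parameter grid with the
same seed: `aag_fold` (scales each subject's AAG), `milk_ph`,
`milk_fat` (recompute M/P and rescale the IDD), `intake`.

## 7. Synthetic data (`lactpk.synthdata`)

Because no raw clinical data ship with the package, a generator
produces "observed" datasets with the statistical structure the
analysis assumes: sparse samples (pre-dose, 2, 4, 8, 12, 24 h within a
dosing day), combined residual error obs = truth·(1 + ε_prop) + ε_add
(CV 20%, SD 0.05 ng/mL — typical bioanalytical magnitudes,
configurable), and censoring below the LLOQ (1 ng/mL default): a value
is flagged BLQ exactly when its pre-censoring value falls below the
LLOQ. The generator reproduces the study's central observation
qualitatively: simulated infant plasma (median Cmax ~0.16 ng/mL) is
100% BLQ at a 1 ng/mL LLOQ, while maternal plasma and milk are fully
quantifiable.

`recover_idd` estimates the IDD from milk observations as the
trapezoidal time-average of quantified concentrations × intake. The
full loop (simulate mother → milk via M/P → sample with error and
censoring → recover IDD → re-simulate infant) recovers the generating
IDD within 10% (median over 200 seeds) — the analysis-level
parameter-recovery check.

## 8. Limitations

- **Lumped, not organ-level, PBPK**: a two-compartment disposition
  model with a well-stirred liver reproduces the printed exposure
  metrics but not tissue-level kinetics; no enterohepatic or renal
  pathways.
- **Metabolic-capacity curve**: the per-gram hepatic capacity
  maturation is the least constrained element (see section 2); different
  plausible shapes would move neonatal predictions within roughly a
  factor of two while leaving infant and child predictions essentially
  unchanged.
- **MAO-A ontogeny is unknown**; the base case assumes adult activity
  per gram, and the slow-maturation preset is a labeled hypothetical.
- **Growth equations** are used only up to mid-childhood; the weight
  equation under-predicts adolescent mass under the adopted
  parenthesization, so adults use fixed anthropometric means.
- **Milk model** assumes instantaneous equilibrium, a single calibrated
  milk-protein constant, and no active transport; carboxy-primaquine
  and other metabolites are not modeled.
- **No plasma-concentration data are fitted**: the model is calibrated
  to two summary statistics (day-14 Cmax and AUC) and validated against
  printed bounds, ratios and orderings, not against raw profiles.
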