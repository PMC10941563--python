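# lactpk

Physiologically based pharmacokinetic (PBPK) simulation of **primaquine
during breastfeeding**: how much drug a nursing mother on radical-cure
dosing (0.5 mg/kg once daily for 14 days) passes into her milk, and what
plasma exposure that produces in her breastfed infant or neonate.

Primaquine is the main drug able to clear dormant liver stages of
*Plasmodium vivax* malaria, but it has historically been withheld from
breastfeeding women for fear of infant exposure. `lactpk` implements the
full chain of reasoning needed to quantify that exposure:

1. **Plasma protein binding** — primaquine binds α1-acid glycoprotein
   (AAG); a single-site model anchored at fraction unbound 0.33 at
   0.6 g/L AAG predicts the unbound fraction at any AAG level
   (0.29 at the postpartum 0.7 g/L).
2. **Milk transfer** — a phase-distribution (pH-partition) model splits
   milk into skim and fat phases; ion trapping of the basic drug
   (pKa 10.4), milk protein binding and fat partitioning (logP 3.0)
   yield a milk-to-plasma (M/P) ratio of 0.47 for mature milk (pH 7.2,
   4% fat), falling to ~0.20 in colostrum-like milk at pH 7.6.
3. **Infant daily dose (IDD)** — M/P × maternal average plasma
   concentration × milk intake (150 mL/kg/day), or taken directly from
   the observed study values (average 2.98, highest 9.07 µg/kg/day,
   i.e. a relative infant dose of ~0.6–1.8% of the maternal
   weight-adjusted dose).
4. **Pediatric PBPK** — virtual infants and children with
   height/weight growth equations, age-dependent liver mass, hepatic
   blood flow, AAG and metabolic capacity, plus isozyme ontogeny for
   the two clearance pathways (MAO-A ~90%, CYP2D6 ~10%); a lumped
   two-compartment disposition model with a well-stirred liver and
   explicit first-pass extraction.
5. **Virtual trials** — populations of 10 trials × 20 subjects with
   lognormal inter-individual variability, summarized as pooled
   medians and 5th/95th percentiles, fully reproducible from
   (config, seed).

The headline result this package reproduces: a breastfed infant
receiving the average IDD over six 4-hourly feeds reaches a median Cmax
about **0.12% of the maternal median Cmax** (bound ≤ 0.13%), and even at
the highest observed IDD **no simulated infant concentration exceeds
2 ng/mL** — supporting the safety of maternal primaquine during
breastfeeding.

## Worked example

```python
from lactpk import make_scenario, run_scenario

result = run_scenario(make_scenario("infant_avg_idd", seed=1))
pooled = result.summary.pooled["cmax"]
print(f"infant daily dose: {result.idd} ug/kg/day over six 4-hourly feeds")
print(f"pooled infant Cmax (ng/mL): median {pooled['median']:.3f} "
      f"[p5 {pooled['p5']:.3f}, p95 {pooled['p95']:.3f}]")
print(f"maternal pooled median Cmax (ng/mL): "
      f"{result.mother.pooled['cmax']['median']:.1f}")
print(f"infant/mother median Cmax ratio: {result.relative['cmax']:.3f}%")
print(f"highest infant concentration anywhere: {result.summary.max_conc:.3f} ng/mL")
```

Output:

```text
infant daily dose: 2.98 ug/kg/day over six 4-hourly feeds
pooled infant Cmax (ng/mL): median 0.158 [p5 0.103, p95 0.259]
maternal pooled median Cmax (ng/mL): 126.7
infant/mother median Cmax ratio: 0.124%
highest infant concentration anywhere: 0.388 ng/mL
```

## Command line

A `lactpk` console script wraps the library (exit codes: 0 ok,
1 validation error, 2 compute failure):

```bash
lactpk simulate infant_avg_idd --seed 1 --out out/      # artifact bundle
lactpk trials mother_lactation --seed 1                 # per-trial + pooled JSON
lactpk calibrate                                        # re-derive kinetic params
lactpk sensitivity infant_avg_idd --parameter aag_fold --grid 1,2,4
lactpk synth --seed 3 --out milk.csv                    # synthetic milk dataset
```

`lactpk calibrate` re-fits the intrinsic clearance and central volume to
the day-14 maternal exposure targets (median Cmax 129 ng/mL, AUC
988 ng·h/mL) and prints:

```json
{
  "cl_int_per_kg_liver": 80.44796538660643,
  "v_central_per_kg": 1.7141916189257802
}
```

`lactpk synth` generates a sparse, noisy, LLOQ-censored synthetic milk
dataset from the simulated maternal profile and recovers the infant
daily dose from it, exercising the whole analysis loop without any
external data.

Shipped scenarios: `mother_lactation`, `infant_avg_idd`,
`infant_high_idd`, `neonate_no_ontogeny`, `neonate_slow_ontogeny`,
`children_6_10`, and the four pediatric malaria-treatment cohorts
`brazil_2_3y` / `brazil_4_8y` / `brazil_9_11y` / `brazil_12_14y`.
Custom studies can be described in YAML and run with
`lactpk simulate --config study.yaml`.

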