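# agnor

AgNOR morphometry and survival analysis for silver-stained histology.

Argyrophilic nucleolar-organizer-region proteins (**AgNORs**) appear after
silver staining as dark dots inside cell nuclei; their number, area and
spatial arrangement track ribosomal biogenesis and hence proliferation. In
breast-carcinoma pathology they are a candidate objective replacement for
the observer-dependent components of histological grading. This package is
for researchers who want to (a) quantify AgNORs inside marked tumour nuclei,
(b) aggregate the classical case-level AgNOR parameter menu, and (c) relate
those parameters to patient survival — plus a fully seeded synthetic
generator so every stage can be validated against known ground truth.

## What it computes

**Detection.** Inside each supplied nucleus mask, particles are connected
components of sub-threshold pixels (per-nucleus Otsu with a contrast guard,
or a fixed level), filtered by a minimum area. Dots fused into one component
are *conglomerates*: a particle with area A above κ·A_ref (κ = 1.5, A_ref a
robust per-case single-AgNOR reference area) is counted as round(A/A_ref) ≥ 2
AgNORs, otherwise as one.

**Case features.** With corrected per-nucleus counts `c_i` over n nuclei and
normalised radial particle positions `d ∈ [0, 1)`:

- `nornbc_m = (1/n) Σ c_i` — mean corrected AgNOR count per nucleus
- `nor_kK = 100 · #{i : c_i = K}/n` — percentage of nuclei with exactly K AgNORs
- `snar_r_v` — mean within-nucleus SD of per-mille area fractions `a_j/Σa · 1000`
- `mnrat2_m` — mean largest/total AgNOR area ratio per nucleus (per mille)
- `cent_r_v`, `bord_r_v` — across-nucleus SDs of the central-zone
  (`d ≤ 0.5`) and peripheral-zone (`d ≥ 0.8`) particle proportions
- `center_v`, `locat_v` — SD of `d` over central particles and variance of
  `d` over all particles, pooled across nuclei

**Survival.** Kaplan–Meier curves; Cox proportional hazards
`h(t|x) = h₀(t)·exp(β'x)` (Breslow or Efron ties) with listwise deletion;
backward stepwise likelihood-ratio selection (remove the covariate with the
largest LR p-value while it exceeds `p_remove = 0.10`); and SPSS-style
case-processing summaries for two endpoints — overall survival and
breast-cancer-specific survival (other-cause deaths censored).

## Worked example

```python
import numpy as np
from agnor import (CohortEffectSpec, CoxBackwardStepwise, DetectionParams,
                   detect_case, features_from_records, generate_cohort,
                   generate_image_set, scenario_preset)

# 1. render a synthetic field of 25 nuclei and measure it
sc = scenario_preset("high_variability", n_nuclei=25)
images, masks, truth = generate_image_set(sc, seed=1)
records = detect_case(images[0], masks[0], DetectionParams(calibration=0.25))
feats = features_from_records(records)
print(f"mean corrected count:    {feats.nornbc_m:.2f}"
      f" (truth {truth.counts_per_nucleus().mean():.2f})")
print(f"largest/total area (pm): {feats.mnrat2_m:.1f}")

# 2. a cohort whose hazard rises with pleomorphism and mnrat2_m
spec = CohortEffectSpec(coefficients={"polym": 0.9, "mnrat2_m": 0.004},
                        baseline_hazard=2e-5, admin_censor_months=240.0)
cohort = generate_cohort(300, spec, seed=1)
model = CoxBackwardStepwise(cohort, ["pT", "pN", "G", "polym", "mnrat2_m", "locat_v"],
                            endpoint="overall")
print(model.fit(p_remove=0.10).summary())
```

This prints (abridged):

```
mean corrected count:    4.24 (truth 3.92)
largest/total area (pm): 626.4
Cox regression, backward stepwise (likelihood ratio), endpoint=overall, removal threshold p > 0.1
Step 1:
    pT           significance  0.301
    pN           significance  0.837  -> removed
    ...
Final model:
              coef  se(coef)        HR          lr_p
G        -0.311171  0.154965  0.732589  4.473361e-02
polym     1.083940  0.157437  2.956305  1.384548e-13
mnrat2_m  0.004792  0.000813  1.004803  1.132999e-09
```

The detected mean count slightly exceeds the truth because the
high-variability preset mixes very different dot sizes, so some outsized
singletons trigger the area-ratio conglomerate rule. The stepwise trace
drops the pure-noise staging covariates one at a time; the two covariates
the hazard was built on are retained with hazard ratios near their true
values (true HR for `polym` is e^0.9 ≈ 2.46), alongside one borderline
false positive (`G` at p = 0.045) — exactly the behaviour the selection
simulations in the test suite quantify.

There is also a CLI mirroring the pipeline stages:

```bash
agnor simulate-images --preset low_variability --seed 7 --outdir fields/
agnor detect --image fields/field_000.tif --mask fields/field_000_labels.tif --out particles.csv
agnor simulate-cohort --n 244 --seed 7 --effect polym=0.9 --out cohort.csv
agnor survival --cohort cohort.csv --covariate polym --covariate pN --outdir surv/
agnor run-all --config run.yaml --outdir out/
```

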