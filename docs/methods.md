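# Methods

This note documents the models, conventions and design choices behind the
package: what the AgNOR quantities are, how they are measured, how the
synthetic data are generated, and where the genuinely open choices were
made.

## Background and scope

Argyrophilic nucleolar-organizer-region proteins (AgNORs) appear after
silver staining as dark intranuclear dots whose number and area reflect
ribosomal biogenesis and hence proliferative activity. In breast-carcinoma
grading they are a candidate objective replacement for the observer-dependent
mitosis component of histological grade. The package implements the
semi-automatic workflow of the classical morphometry systems: tumour nuclei
are *marked* (label masks are inputs, not computed — tumour sections contain
several cell types and the selection of tumour nuclei is the observer's
task), dots are detected *inside* those masks, case-level parameters are
aggregated, and their prognostic value is assessed by Cox regression with
backward stepwise likelihood-ratio selection against overall and
breast-cancer-specific survival.

Factor analysis of the AgNOR parameters, competing-risks models, and the
internals of Bloom–Richardson scoring (the seven-point score `pkt_grad` and
pleomorphism `polym` are consumed as given ordinals) are out of scope.

## Detection model

Within one nucleus mask, particle candidates are connected components
(8-connectivity) of pixels *below* a threshold:

* **Threshold.** Per-nucleus Otsu on the within-mask intensities by default;
  a fixed grey level can be configured. Otsu always produces a split, even
  on a particle-free nucleus where it would carve components out of noise,
  so the split is accepted only when the two class means differ by at least
  `min_contrast` grey levels (default 25). Stained dots are ~110 grey levels
  darker than the nucleoplasm in the synthetic material, while noise-only
  splits differ by a few levels, so the guard has a wide safety margin.
* **Minimum area.** 2 pixels (suppresses single-pixel noise).
* **Units.** Pixel centres, 0-based `(row, col)`; areas are pixel counts
  times the squared calibration (µm/px, default 0.25 — a typical 40×
  scanner resolution). Particles are sorted by descending area with a
  `(y, x)` lexicographic tie-break.

### Radial position

Positional features use a shape-independent normalised radial coordinate:
`d_norm` = (distance from the nucleus centroid to the particle centroid)
divided by (distance from the centroid to the mask boundary along the same
ray), so `d_norm ∈ [0, 1)` for any convex nucleus and a particle at the
centroid has `d_norm = 0`. The boundary intersection is found by marching
along the ray in 0.5 px steps and refining by bisection (30 iterations);
the value is clipped at 0.999.

### Conglomerate correction

Dots lying so close together that they fuse into one component are recorded
as a *conglomerate* and counted as more than one AgNOR. The rule needs a
reference single-AgNOR area `A_ref` and a tolerance factor `κ > 1`
(default 1.5):

* a particle with area `A ≤ κ·A_ref` counts as **1**;
* otherwise it is a conglomerate counted as `round(A / A_ref)`
  (half up), floored at **2**.

`A_ref` is estimated per case in one trimming pass: the median of all
particle areas defines a crude centre, particles above `κ` times that
median are set aside as conglomerates, and `A_ref` is the median of the
rest. The κ = 1.5 default corresponds to a ~22 % radius tolerance on
equal-intensity disks; with particle radii spread wider than that within a
case, outsized singletons are inevitably flagged — this is a property of
any area-ratio rule, and the feature-recovery tests therefore use
size-homogeneous scenarios when exact count equality is asserted.

## Case-level parameters

Per nucleus: the corrected count; per-particle area fractions in per mille
of the nucleus's total AgNOR area; their population SD; the largest/total
ratio (per mille); the proportions of particles in the central
(`d_norm ≤ 0.5`) and peripheral (`d_norm ≥ 0.8`) zones. Zone cutoffs are
configurable; the named zones have no canonical definition in the
morphometry literature, so the defaults split the nucleus into an inner
half-radius core and an outer rim.

Per case (nuclei without particles contribute a zero count but are excluded
from area/zone aggregates, whose values are undefined for them):

| name       | definition                                                             |
|------------|------------------------------------------------------------------------|
| `nornbc_m` | mean corrected count per nucleus                                       |
| `nor_k0…8` | % of nuclei with corrected count exactly k                             |
| `snar_r_v` | mean over nuclei of the within-nucleus SD of per-mille area fractions  |
| `mnrat2_m` | mean over nuclei of the largest/total per-mille ratio                  |
| `cent_r_v` | SD across nuclei of the central-zone proportion                        |
| `bord_r_v` | SD across nuclei of the peripheral-zone proportion                     |
| `center_v` | SD of `d_norm` over centrally located particles, pooled across nuclei  |
| `locat_v`  | variance of `d_norm` over all particles, pooled across nuclei          |

The dispersion-type parameters are ambiguous between within-nucleus and
across-nucleus aggregation; the defaults above were chosen so that each of
the three plausible levels (within-nucleus spread, across-nucleus spread of
proportions, pooled particle spread) is represented, and they are the
package's documented convention. Population SDs (ddof = 0) are used so
single-particle and single-nucleus cases are well defined. `nor_k` is
computed uniformly for k = 0…8 (some published menus omit individual k
values; computing all of them costs nothing). Per-mille quantities are kept
unrounded internally; rounding happens only in reports.

## Survival analysis

* **Endpoints.** `overall` (any death) and `cause_specific` (breast-cancer
  deaths; deaths from other causes are censored at the death time).
* **Kaplan–Meier.** Product-limit estimator (via lifelines), reported as a
  `(time, at_risk, events, censored, survival)` table.
* **Cox model.** The partial likelihood is maximised by an in-package
  damped-Newton solver (`agnor._coxlib`) supporting Breslow (default — the
  historical default of the classical stats packages this report format
  mimics) and Efron tie handling. The solver is validated in the test suite
  against statsmodels `PHReg` (both tie methods, agreement to ~1e-10) and
  lifelines (Efron). Listwise deletion of cases with missing covariates;
  constant covariates and cohorts with fewer than two events raise errors
  naming the offender.
* **Backward stepwise LR.** Start from the full model; at each step compute,
  for every covariate, the likelihood-ratio p-value of the 1-df chi-square
  comparing the model with and without it; remove the covariate with the
  largest p if it exceeds `p_remove`; stop when all remaining p ≤ `p_remove`.
  The analysed case set is fixed by listwise deletion on the full covariate
  menu before the first step. `p_remove` defaults to 0.10 — reported
  selections of this kind retain variables with p ≈ 0.08–0.11, which places
  the removal threshold at the classical 0.10 rather than 0.05. Reduced-model
  fits are warm-started from the current full-model estimates.
* **Case-processing summary.** Each case is classified as event, censored,
  missing-covariate (any required covariate absent), or censored before the
  earliest event time in its stratum (single stratum by default). Report
  percentages are of the grand total, rounded half away from zero to one
  decimal, with leading-zero suppression for values below 1 (".4%"), matching
  the layout of classical statistical reports.

## Synthetic data generator

### Images

Nuclei are ellipses (axis ratio uniform in [0.6, 1.0], random orientation)
with radius drawn from a configurable µm range, placed on a jittered grid
(auto-sized field) or uniformly at random in a fixed field (raising an
explicit error when placement fails — never silent truncation). AgNORs are
anti-aliased dark disks; the true per-nucleus count is drawn from a
categorical or truncated-Poisson distribution on 0…12, radial positions
from a configurable distribution on [0, 1), and with probability
`conglomerate_probability` 2–3 dots are placed with centre spacing below
the sum of their radii so they merge into one component (ground truth keeps
the member-level multiplicity). Disjoint groups keep a 1.6 px boundary gap
so rasterisation cannot fuse them; total particle area is capped at 18 % of
the nucleus area (crowded draws have their radii rescaled) so placement
terminates. Intensities: background 205, nucleoplasm 150, particles 40,
additive Gaussian noise with configurable SD, clipped to 8 bits.

Randomness is a pure function of (scenario, seed): one `SeedSequence` per
call, spawned per field and per nucleus, so outputs are stable under
changes of field count.

Two presets anchor the qualitative phenotypes seen in stained sections:
`low_variability` (counts 2–4, radii 0.45–0.60 µm, radial positions
Beta(4, 6), 5 % conglomerates) versus `high_variability` (truncated-Poisson
counts with mean 4.5, radii 0.25–0.85 µm, uniform radial positions, 25 %
conglomerates). No per-case distributional parameters are published for
real cohorts, so the presets are calibrated only to this qualitative
contrast; the generator does **not** emulate staining colour, multiple cell
types, out-of-focus blur or uneven illumination. Passing tests therefore
demonstrate correctness of the measurement and inference chain, not
segmentation robustness on real slides.

### Cohorts

Covariates are drawn independently from configurable marginals (ordinal
categoricals for pT/pN/G/`pkt_grad`/`polym` with frequencies typical of an
unselected series; clipped Gaussians for the AgNOR features on the scales
the pipeline produces). Event times are exponential with rate
`λ0 · exp(Σ βⱼ xⱼ)`; censoring is administrative (default horizon 240
months, matching a ~20-year follow-up window) and/or independent
exponential; events are breast-cancer deaths with probability `cause_mix`
(default 0.8). `baseline_for_event_fraction` solves for `λ0` giving a
target expected event fraction by bisection on a 20 000-row probe draw, so
study conditions like "a 30 %-event cohort" can be pinned independently of
the effect sizes. Independence of the covariates is a deliberate
simplification: it makes selection behaviour interpretable (every retained
noise covariate is a false positive) but understates the collinearity of
real AgNOR parameters.

### End-to-end pipeline

In synthetic mode each case gets its own rendered field; the per-case mean
AgNOR count is drawn uniformly from `count_lambda_range` (default 1.5–7.0),
which is what gives the AgNOR features genuine between-case variation. The
true hazard acts on the *ground-truth* feature values plus the drawn
clinical covariates; the analysis then runs on the *detected* features,
exactly as it would on real material. Default problem sizes (80 cases of
12 nuclei in the pipeline, 50-nucleus fields in recovery checks, 150–500
case cohorts, 15–150 replicates in the simulation studies) were chosen as
the smallest sizes at which the binomial/simulation error of the checked
quantities is well below the asserted bounds.

## Numerical choices and degenerate inputs

* Rounding of report percentages: half away from zero, one decimal
  (`decimal.Decimal`, `ROUND_HALF_UP`), applied only at report time.
* LR statistics are clipped at 0 (a reduced model can exceed the full model
  only by optimiser noise at the 1e-12 level).
* Newton fitting: start at β = 0 (or a warm start), step-halving line
  search, convergence when the gradient sup-norm < 1e-7 or the relative
  log-likelihood change < 1e-9; standard errors from the pseudo-inverse of
  the negative Hessian.
* A nucleus whose within-mask intensities are constant, or whose Otsu split
  fails the contrast guard, yields an empty particle list (not an error).
* `km_estimate` rejects negative times; `case_processing_summary` with no
  events classifies every censored case as pre-first-event (degenerate but
  well defined).

## Known limitations

* The conglomerate multiplicity is an area-ratio heuristic; it cannot
  distinguish one large AgNOR from a fused pair of small ones.
* `d_norm` relies on the mask centroid being inside the mask (true for the
  convex synthetic nuclei; strongly non-convex masks would need a geodesic
  definition).
* Cause-of-death in the generator is independent of covariates given the
  event; real cause-specific hazards may differ in structure.
* The published cohort behind the report formats (244 patients) is not
  deposited, so the package reproduces that study's *arithmetic* (the
  case-processing tables) and its *procedures*, not its patient-level
  significance values.
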