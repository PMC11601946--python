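# Methods

## Indirect calorimetry

Each chamber session provides minute-resolution V̇O₂ and V̇CO₂ (L/min).
Per-minute energy expenditure uses the Lusk caloric equivalent of oxygen:
EE = V̇O₂ × (4.686 + (RQ − 0.707) × 0.361/0.293) kcal/min. The bracketed
term is read as a kcal-per-litre-O₂ factor scaled by V̇O₂; at V̇O₂ = 1 L/min
the alternative reading (RQ term unscaled) coincides, which is how the
constant checks are framed. 24-h EE is the mean per-minute EE × 1,440; 24-h
RQ is the ratio of gas totals (each litre of gas weighted equally) rather
than the mean of per-minute ratios — the two differ only when EE and RQ
covary within the day, and the choice is recorded here because source
descriptions of chamber pipelines rarely state it.

Protein oxidation is 6.25 g per g of 24-h urinary nitrogen. Substrate
oxidation uses Frayn-form stoichiometry with gas volumes per gram of
substrate — carbohydrate 0.746/0.746, fat 2.019/1.427, protein 0.966/0.782
L O₂ / L CO₂ — giving the inversion CARBOX = 4.55 V̇CO₂ − 3.21 V̇O₂ −
2.87 N and LIPOX = 1.67 (V̇O₂ − V̇CO₂) − 1.92 N (L/day, g/day). Energy
densities are 3.74 (glucose), 9.46 (fat) and 4.70 (protein) kcal/g. These
constants make the forward and inverse directions consistent to ≲1.2% for
pure substrates (coefficient rounding), which motivates the 2% tolerance on
all round-trip checks. The nonprotein RQ subtracts protein-attributable gas
before forming the quotient; values outside (0.69, 1.05) are flagged but
kept, as are negative oxidation estimates (possible at RQ extremes, e.g.
net lipogenesis), so downstream models can exclude them explicitly rather
than inherit silent clipping.

Minute-gap policy: gaps of ≤ 5 consecutive minutes (absent or
nonphysiologic readings) are linearly interpolated; sessions with a longer
gap or < 95% minute coverage are rejected as unsummarisable. The 5-minute
bound keeps interpolation shorter than the time scale of meal-induced EE
transients; the 95% floor matches the compliance spirit of the protocol.

## Protocol encoding

Seven dietary conditions: EB (multiplier 1), FAST (0), and five overfeeding
diets at 200% of the participant's EB 24-h EE. Macronutrient energy splits
default to EB/SOF 0.50/0.30/0.20 (C/F/P), LPF 0.51/0.46/0.03, FNP
0.20/0.60/0.20, HPF 0.25/0.45/0.30, CNP 0.75/0.05/0.20. These are synthetic
defaults — the clinical menus are not public — chosen to preserve the design
contrasts (3% protein in LPF, fat-heavy FNP/HPF, carbohydrate-heavy CNP);
all are overridable via a plain-text config.

A schedule consists of an initial eucaloric calibration session (measuring
the EE that becomes the EB intake) followed by seven analysis chambers:
EB always at order 1, the six interventions in a seeded Fisher–Yates
permutation with fixed 3-day washouts. The calibration session is stored
separately from the analysis chambers so "chamber order" in the statistical
models matches the convention that energy balance is order 1 for everyone.
Compliance is evaluated on energy (> 95% of provided kcal consumed; fasting
always kept); the food-mass accounting used in practice is collapsed to
kcal.

## Synthetic cohort

The generator's defaults define the study conditions used throughout the
tests: 30 participants (20% female, age ≈ 38 ± 10, BMI ≈ 27 ± 4, three
race levels 60/25/15%), 80 metabolites across five classes
(acylcarnitines 20%, amino acids 25% — one fifth branched-chain,
glycerophospholipids 25%, fatty acyls 15%, other 15%).

Energy need is allometric, 65 · kg^0.75 with 8% lognormal between-person
spread — a deliberately simple rule, since only relative structure matters.
Whole-day EE scales by a diet factor (FAST 0.92; overfeeding 1.05–1.10,
highest for the high-protein diet, encoding diet-induced thermogenesis).
The oxidised fuel mix is a 50/50 blend of a 0.50/0.30/0.20 baseline with
the diet's composition; fasting instead drains linearly from the baseline
to 0.10/0.80/0.10 across the day. A per-session N(0, 0.05) energy-fraction
shift between carbohydrate and fat creates within-diet variation in
substrate preference. Minute-level gas exchange follows from forward
stoichiometry shaped by a diurnal profile (sleep at 0.80 of daytime EE from
minute 960; Gaussian post-meal thermogenesis bumps, amplitude 0.25 and SD
45 min, after the 11:00/16:00/19:00 meals) with shared AR(1) multiplicative
noise (SD 3%, lag coefficient 0.9) plus 1% independent measurement noise.
Urinary nitrogen equals protein oxidised / 6.25 exactly.

Metabolite panels: prechamber log2 abundances are normal around per-
metabolite baselines U(10, 20) with 0.6 between-participant and 0.3
within-participant SD (log-normal on the raw scale). Postchamber log2 level
adds (i) a diet-by-class effect (log2 units, ±0.3–0.8 for the active
cells; acylcarnitines and fatty acyls up under FAST/FNP/HPF and down under
CNP, glycerophospholipids opposite, amino acids down in fasting except
branched-chain up), (ii) a coupling term γ_class × standardized session
LIPOX (acylcarnitines +0.30, fatty acyls +0.25, glycerophospholipids
−0.20 per SD) that gives the pooled, diet-adjusted association models a
recoverable within-diet signal, (iii) a participant random intercept
(SD 0.15) and (iv) residual noise (SD 0.25). Effect magnitudes were set
once as plausible mid-size metabolomic responses. 5% of metabolites carry
sporadic missing values; two prechamber outliers are injected per study,
calibrated against the inclusive-SD form of the 5-SD rule (see below);
pooled-QC replicates (10% of sample count, ≥ 3) carry 5% multiplicative
CV. NEFA: post = pre + 0.15 × standardized LIPOX + N(0, 0.05), in mEq/L
(pre ≈ 0.50 ± 0.10).

What the generator does **not** emulate: insulin dynamics, adaptive
thermogenesis beyond the static diet factor, metabolite–metabolite
correlation structure, batch effects, and heavy-tailed abundance noise.
Passing tests therefore demonstrate that the pipeline recovers the
structure it assumes, not that real chamber data satisfy those assumptions.

## Quality control

Order is fixed: pooled-QC CV (raw scale, 100·SD/mean per metabolite, median
and IQR summarised across metabolites) → 5-SD prechamber outlier blanking →
any-missingness metabolite exclusion → log2 transform. The 5-SD z-score is
computed per (diet, metabolite) group on log2 values **with the candidate
included** (leave-one-out is not assumed); this caps the attainable z at
(g−1)/√g for group size g, so the simulator's outlier injection targets the
inclusive score directly. Groups smaller than three are never trimmed.
Postchamber values are not screened. Missing values are never imputed.
The pipeline is idempotent: rerunning it on its own output changes nothing,
because any metabolite touched by blanking is removed by the missingness
rule.

## Statistics

Paired tests are one-sample t tests on per-participant log2 fold changes
(identical to paired t tests on log2 levels), BH-adjusted strictly within
each chamber's metabolite family; fewer than three pairs or zero-variance
differences yield flags, not p-values. The crossover model per metabolite is
`log2_post ~ log2_pre + diet (EB referent) + chamber order +
(1 | participant)`, REML-fitted; chamber order is numeric by default. In
the categorical variant, order 1 is merged into the reference level: EB is
always first, so a full set of order indicators is exactly collinear with
the diet dummies. Non-convergent fits are reported with a flag.

Physiology associations fit, per metabolite, `outcome ~ log2FC + log2 pre +
diet + age + sex + race + BMI + (1 | participant)` pooled, and the same
without diet term or random effect within one diet (one session per
participant enforced). The NEFA model adds prechamber NEFA as a covariate
and keeps the fold change as the exposure, mirroring the fold-change
coefficient waterfalls the pooled models produce for the other outcomes.
Fold-change and pre-level covariates stay unstandardised so betas read as
outcome change per doubling. BH adjustment across metabolites within an
outcome family is attached by default but toggleable, and raw p-values are
always emitted, since FDR control for these models is an analysis choice
rather than a fixed convention.

## Numerical and design notes

* Tolerances: 2% per substrate for stoichiometric round trips (constant
  rounding), 3% for energy closure on mixed days, 1% for EB energy
  recovery on noiseless traces.
* Simulation sizes used by the test suite: 500 replicates × 200 metabolites
  for FDR calibration of the paired-t/BH pipeline (empirical FDR ≤ 7% at
  q < 0.05 under a 20%-non-null mixture); 200 replicates of 60-participant
  crossover studies for mixed-model CI coverage (≥ 93%); the default
  30 × 80 study for sign-structure checks.
* All randomness flows through `numpy.random.Generator` seeded per run;
  a fixed seed reproduces every dataset byte-identically.
* Known limitations: the Frayn inversion assumes no ketone excretion or
  lipogenesis–oxidation mixing within the day; the mixed models use
  normal-approximation CIs (statsmodels MixedLM); group-size-capped z
  scores make single gross outliers undetectable in groups of fewer than
  ~27 observations under the inclusive 5-SD rule.
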