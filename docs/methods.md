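# Methods

## Scope and model structure

`crcscreen` models the *distributional* consequences of risk-stratified CRC
screening policies: given a population's joint distribution of lifestyle
factors, family history and polygenic risk, which fraction of people lands in
each screening group, and which fraction of the expected 10-year cancers
occurs there. It does not model screening episodes, uptake, test
specificity, stage shift, costs, or competing mortality.

A person's combined relative risk is the product of three component RRs
(log-additive combination, no interaction terms — there is no good evidence
of interactions between the three risk domains, and none are modelled):

1. **Lifestyle.** Categorical factors, each with level prevalences and level
   RRs supplied as configuration. Each factor's contribution is its level RR
   divided by the factor's population-mean RR, so the lifestyle component has
   population mean 1 under the configured prevalences. This normalisation is
   a design choice: it prevents double-counting of the population baseline
   when the component is combined with an already-centered polygenic score,
   and leaves overall calibration to the absolute-risk step. The alternative
   (raw level RRs, calibration absorbing everything) is algebraically
   equivalent for the final absolute risks under global calibration.
2. **Family history.** An ordered first-match rule table over constellations
   (counts of affected first/second-degree relatives, youngest diagnosis
   age), referent RR 1.0 for no family history. This component is *not*
   centered — its RRs are interpretable relative to "no family history" and
   drive the guideline categories directly — so its population mean slightly
   exceeds 1; the calibration step absorbs that.
3. **Polygenic.** Per SNP, genotypes follow Hardy–Weinberg proportions from
   the risk-allele frequency; the per-genotype log-RR `g·log OR` is centered
   by `log E[OR^g]`, making the mean RR exactly 1 SNP by SNP, hence for the
   whole panel (independence; linkage disequilibrium is ignored). Two
   samplers are provided: `exact` (draw genotypes) and `lognormal`
   (Normal(−σ²/2, σ²) on the log scale, `σ² = Σ 2p(1−p)(log OR)²`). For
   panels of ≥30 modest-effect SNPs the two are indistinguishable in
   practice (two-sample KS ≈ 0.004 at n = 10⁵ for the default panel); the
   bootstrap uses `lognormal` by default for speed, switchable in config.

RRs are treated as age- and sex-constant hazard multipliers; this is the
simplest defensible reading and a known limitation (the attenuation of familial
RRs with age is not modelled).

## Absolute risk

The incidence table (annual rate per person-year by single year of age and
sex, coverage 35–83 minimum) is divided by the cohort-mean combined RR to
give a baseline hazard; the 10-year risk at age *a* is
`1 − exp(−RR · Σ_{t=a}^{a+9} h₀(t,sex))` over the half-open window
[a, a+10). Calibration is *global* by default — one divisor, so the
cohort-average hazard reproduces the population incidence; a `stratified`
mode divides each (age, sex) cell by its own cohort-mean RR instead (cells
without cohort members fall back to the global mean). Expected-cancer shares
weight each person by this 10-year risk; people shares and cancer shares
each sum to exactly 1 across the three groups within every replicate.

## Scenarios and boundary semantics

Category bounds are inclusive on the upper edge (RR = 2.0 is category 1);
absolute thresholds are strict ("exceeds": a 10-year risk of exactly 0.9%
is not screened). Scenario 2 is evaluated cross-sectionally at each
person's current age, not as an age-at-crossing rule; a longitudinal variant
is out of scope. The per-category age rules are configuration with these
defaults (the guideline sources are only partially explicit, so these are
deliberate, overridable choices):

| category | rule |
|----------|------|
| 1  | iFOBT every 2 years, ages 50–74 |
| 1a | iFOBT every 2 years, ages 45–74 (S4 only) |
| 2  | iFOBT every 2 years 40–49, colonoscopy every 5 years 50–74 |
| 3  | iFOBT every 2 years 35–44, colonoscopy every 5 years 45–74 |

Scenario 2a/2b thresholds are calibrated by bisection on the pooled cohort
(colonoscopy threshold first, then iFOBT on the remainder), matching each
group separately: 2a matches scenario 1's *people counts* (exact, ±0 when
risks are distinct; ties raise a diagnostic error with the achievable
range), 2b matches *cancer shares* to relative tolerance 1e-3. Calibrated
thresholds are then fixed across replicates; per-replicate re-calibration
would conflate threshold uncertainty with sampling uncertainty.

## Bootstrap

Each replicate draws `sample_size` people with replacement (nonparametric in
lifestyle and family history), re-simulates every sampled person's polygenic
RR (parametric), re-calibrates the baseline within the replicate, and
assigns every scenario. Summaries are medians with 2.5th/97.5th percentile
intervals, computed with linear-interpolation percentiles (index = q·(n−1));
population counts are scaled per replicate (people: share × projected total;
cancers: cancer share × replicate mean risk × projected total) and
summarised on the count scale. Per-replicate generators are spawned from a
single `SeedSequence`, so runs are byte-deterministic from one master seed
and replicates are order-independent. Defaults: 500 replicates × 4000
people, the scale at which the full run takes a few seconds on one CPU.

## Synthetic defaults and what they do and do not show

No public individual-level dataset exists for this problem, so the package
ships a synthetic-cohort generator and synthetic tables:

* **Cohort** (default n = 4747, ages uniform 35–74, sexes balanced):
  lifestyle factors sampled independently per factor; family history from a
  finite constellation distribution (88% none, 10% one affected relative,
  2% two or more). Real populations have correlated risk factors — the joint
  dependencies are exactly what registry data would contribute — so absolute
  spread of the combined RR here is conservative. The generator accepts any
  factor/prevalence configuration but does not model factor dependence.
* **Factors**: ten generic categorical factors with RRs in 0.7–1.5. These
  are placeholders with realistic magnitudes, not published model
  coefficients (which are not re-derived here).
* **SNP panel**: 45 synthetic SNPs, ORs uniform in [1.05, 1.25], RAFs in
  [0.1, 0.9], drawn once from a fixed generator seed; panel σ² ≈ 0.41
  (log-RR SD ≈ 0.64), in the range of published CRC polygenic scores.
* **Incidence**: log-linear from 3×10⁻⁵/yr at 35 to 3×10⁻³/yr at 84, male
  rates 1.2× and female 0.8× the common curve, the surface scaled (by root
  finding) so the sex-averaged 10-year risk at age 50 is exactly 0.9% —
  anchoring scenario 2's iFOBT threshold to "average risk at the standard
  starting age".
* **Projection**: exponentially declining age profile normalised to a fixed
  total of 12,221,045 persons aged 35–74 (rounding residue absorbed in one
  cell so the total is exact).

Because the inputs are synthetic, passing tests demonstrate the *method* —
conservation, calibration identities, boundary semantics, oracle agreement,
parameter recovery against the analytic mixture, determinism — not agreement
with any published population's percentages. Tests that recover analytic
category probabilities enumerate the discrete lifestyle × family-history
joint exactly (5184 × 6 atoms) and integrate the lognormal polygenic
component in closed form, an oracle independent of the simulation path.

## Numerical choices

* `1 − exp(−x)` is computed as `-expm1(-x)` for accuracy at small hazards.
* Null SNPs (OR = 1) contribute exactly 1 in the exact sampler (skipped, no
  RNG draws consumed), so degenerate panels are bit-exact.
* Threshold bisection runs on the count/share step function with 200
  halvings; exact count match terminates early, unattainable targets raise
  `CalibrationError` with the achievable neighbourhood rather than
  returning a silently wrong threshold.
* Percentiles use the linear-interpolation convention so test expectations
  are exact; medians of even-length samples are midpoints.
* Cohort CSV and summary JSON/CSV writers use fixed column order, `\n` line
  endings and sorted JSON keys, making equal-seed outputs byte-identical.

## Known limitations

* Factor independence in the generator (see above).
* No competing mortality, so 10-year risks at older ages are slight
  overestimates of observable cancer incidence.
* RRs constant in age and sex; family-history RRs in reality attenuate with
  age.
* Scenario 2 is cross-sectional; lifetime screening trajectories are not
  simulated.
* The screen-detectable proportion weights cancer shares by one sensitivity
  per modality (colonoscopy 0.95, iFOBT 0.83) and ignores repeat-round gains
  and interval cancers.
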