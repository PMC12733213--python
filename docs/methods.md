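# Methods

## Unit of analysis and data model

One row is one modeled sub-scenario of a published economic evaluation:
publications stratified by age of intervention, prevention setting or risk
cohort contribute one row per sub-scenario, because those sub-cohorts are
analytically distinct populations with their own risk profiles and cost
trajectories. The packaged reference dataset (`mastaleru2025`, 17 rows, 8
publications, 6 countries, 2020–2025) is transcribed verbatim from the
source tables of a published Inclisiran meta-analysis.

Two transcription decisions deserve note:

- **Column semantics.** In the source the per-study summary labeled
  "Incremental Cost" matches the column headed "PPP-Adjusted ICER USD"
  (min/median/max 8,739.16 / 51,287.21 / 3,422,471.51), and the statistic
  labeled "ICER" matches the column headed "PPP-Adjusted ICER/QALY USD".
  The fixture therefore maps the former to `incremental_cost` (ΔC) and the
  latter to `icer_per_qaly`.
- **Country labels.** "UK" and "United Kingdom" are canonicalized to `UK`
  before any grouping or dummy coding, with the original string retained in
  record provenance.

Reported ICERs frequently disagree with ΔC/ΔE recomputed from the same row
(different rounding, different cost aggregates in the source models). A
configurable consistency check (default tolerance 1%) flags such rows —
14 of the 17 reference rows are flagged — but never rejects or alters
them; the reported ICER stays authoritative for ICER-based analyses and ΔC
for NMB-based ones. This is why `NMB > 0` and `ICER < λ` classifications
can legitimately disagree on real rows while coinciding exactly on
internally consistent ones.

Age groups (`<45`, `45-60`, `>60`) are assigned from the source's mean or
inclusion age; rows without a usable age are `unknown` and excluded from
age-stratified summaries.

## Harmonization

Monetary harmonization is `amount × CPI_c(t₁)/CPI_c(t₀) / PPP_c(t₁)`:
country-specific CPI inflation to the target price year (default 2024, a
parameter) followed by PPP conversion (local currency units per
international dollar). The same composite factor multiplies total cost,
incremental cost and ICER, so row-internal consistency is preserved;
QALYs are never touched; records already in PPP-USD pass through unchanged,
making the operation idempotent. CPI and PPP tables are user-supplied local
CSVs. Missing CPI years strictly inside a covered range may optionally be
filled log-linearly (constant inflation rate between neighbours); this is
off by default. Market exchange rates are deliberately not offered — PPP
avoids nominal-exchange-rate distortions. The reference dataset is stored
post-harmonization, so this stage is exercised by synthetic and config-file
tests.

## Net monetary benefit and classification

`NMB = λ·ΔE − cost` at thresholds λ (defaults 50,000 / 100,000 / 150,000
USD/QALY). The cost basis is an explicit parameter with two values because
published summaries use both:

- `incremental` (ΔC) — the standard definition and the default; reproduces
  the source's classification counts (3/17 cost-effective at 50k, 8/17 at
  150k).
- `total` (intervention-arm lifetime cost) — reproduces the source's NMB
  distribution tables (mean −51,978,100.73 and median −98,221.70 at 50k;
  max 32,134.82 at 100k).

Every report labels the basis used. NMB is affine in λ with slope ΔE, which
gives a closed-form re-thresholding identity (`nmb_linearity_shift`) tested
to machine precision. Affordability verdicts compare each country's mean
NMB at its own threshold (explicit entry, else a stated 1–3× multiple of
per-capita GDP, default 1×): `yes` iff mean NMB > 0 (a tie at exactly zero
is `no`), `unknown` when no threshold resolves. The per-country
cost-effective count uses `ICER < λ`, matching the source's country table.
Records with negative ΔE or ΔC are tagged by cost-effectiveness-plane
quadrant and excluded from ICER-threshold comparisons with a warning.

## Descriptive conventions

Sample SD uses the n−1 denominator; SE = SD/√n; 95% CI = mean ± 1.96·SE;
quantiles interpolate linearly at rank (n−1)·p. The quantile rule is the
discriminating convention: on the 17 sorted reference ICERs it lands
exactly on order statistics 4 and 12 (53,149.66 and 524,740.92), the only
standard rule reproducing both published quartiles. Values are kept at full
precision internally; rounding (2 decimals for USD, 2–3 significant figures
for QALYs) is purely presentational.

## Pooling

Fixed-effect: weights wᵢ = 1/SEᵢ², pooled μ̂ = Σwᵢyᵢ/Σwᵢ,
Q = Σwᵢ(yᵢ−μ̂)². Random effects: DerSimonian–Laird
τ² = max(0, (Q − df)/(Σwᵢ − Σwᵢ²/Σwᵢ)), re-weighting by 1/(SEᵢ²+τ²);
I² = max(0, (Q−df)/Q)·100. REML is available behind a flag as a
sensitivity option (bounded scalar optimization of the restricted
log-likelihood in log-τ² space). The implementation is cross-checked in the
tests against `statsmodels.stats.meta_analysis.combine_effects` and against
a literal textbook transcription of the formulas.

Study-level economic evaluations publish no within-study variances, so
pooling requires an explicit SE convention: `constant_cv` (SEᵢ = cv·|yᵢ|,
default cv = 0.2, floored at 10⁻⁶ of the column's mean absolute value),
`fixed_se`, or `user_column`. Pooled outputs carry the convention label.

ICERs are ratios and unsuitable for direct inverse-variance pooling; they
are pooled as log(ICER) and back-transformed, a geometric-mean-type
summary. A useful algebraic fact: with any *constant* log-scale SE the DL
weights are equal, the pooled log is the unweighted mean log, and (whenever
τ̂² > 0) SE²_pooled collapses to S²/k where S² is the sample variance of
the logs — so the back-transformed point estimate and CI are invariant to
the constant chosen. On the reference ICERs this yields 211,596 USD/QALY
[87,783–510,043]; under a unit log-SE specifically, τ̂² = S²−1 = 2.43 and
I² = 70.8%. τ² and I², unlike the point estimate and CI, do depend on the
convention and are only meaningful alongside it.

## Meta-regression

Unweighted OLS (no within-study variances exist to weight by) of NMB, ICER
or QALY gain on publication year plus treatment-coded country and
intervention indicators; reference levels Australia and Inclisiran, so each
dummy coefficient is a contrast against that baseline. Collinear columns
are dropped deterministically — columns are admitted in entered order and a
column numerically in the span of its predecessors (SVD tolerance 1e−10
relative) is dropped, i.e. last-entered first — and reported as
`dropped_terms` rather than silently zeroed. Inference is t-based with
n − rank degrees of freedom, no heteroskedasticity correction.
Added-variable data are provided per covariate; the Frisch–Waugh–Lovell
identity (partial-regression slope = full-model coefficient) is tested on
every fitted model. On the reference data the NMB models reproduce the
source's sign pattern (China and Singapore positive against the reference,
year negative) under the total-cost basis; coefficient magnitudes are not
asserted because the source's own tables are not internally consistent
about them.

## Bias diagnostics and sensitivity

Egger's test regresses the standardized effect yᵢ/SEᵢ on precision 1/SEᵢ;
the intercept's two-sided t-test (df = k−2) indicates small-study
asymmetry. The statistic is invariant to jointly rescaling all effects and
SEs, and its type-I error is verified by simulation to sit near the nominal
5%. On the reference data Egger's test runs only under a declared SE
convention, and its p-values are convention-dependent — they are reported
with the label, not asserted against the source.

Leave-one-out re-analysis recomputes a mean or median k times; for the mean
every row must satisfy mean₋ᵢ = (k·mean − xᵢ)/(k−1) exactly, which is
tested to machine precision. Leave-one-out for pooled estimates re-fits τ²
inside every replicate rather than plugging in the all-studies value.

## Synthetic-data model

True effects θᵢ ~ N(μ, τ²) truncated at zero; observed ΔEᵢ = θᵢ + SEᵢ·ε
(also truncated), SEᵢ ~ Uniform(0.02, 0.08) by default; ΔCᵢ lognormal
(median ≈ 49,000 USD, σ_log = 1.5) times a country multiplier
(0.6×–3.0× across six countries); ICERᵢ = ΔCᵢ/ΔEᵢ exactly, so generated
tables carry zero consistency flags; covariates assigned round-robin. Year
and intervention effects enter as NMB offsets (equivalently, ΔC offsets
with opposite sign), making the year coefficient of an NMB-on-year
regression the recoverable truth. Defaults (μ = 0.34, τ = 0.27, k = 17)
target the reference regime, including the right-skewed ICER distribution
with median ≪ mean. Four independent seeded streams (effects, costs,
covariates, selection) keep marginal draws stable as k changes; identical
seeds give bit-identical tables.

Two deliberate subtleties:

- **Truncation moments.** Because effects are truncated at zero, the
  recoverable ground truth is the truncated-normal mean and variance
  (μ + τλ(a), τ²(1 + aλ − λ²) with a = −μ/τ), computed in closed form by
  `effective_effect_moments`. At the default μ/τ ratio the effective
  variance is ≈ 0.79·τ²; recovery tests that compared against the raw τ²
  would report a spurious ~20% "bias". Against the effective moments, DL
  recovery at k = 20 over 200 replicates shows ~1% τ² bias and 94–96% CI
  coverage for μ.
- **Selection mechanism.** With selection strength s > 0, a candidate study
  is retained with probability exp(−s·(SEᵢ/SE̅)·Φ((μ−ΔEᵢ)/SEᵢ)) —
  decreasing in imprecision and in unfavorable effect — and candidates are
  drawn until k are retained (bounded retries, loud failure). Egger
  rejection rises steeply with s. Note that when the SE range is wide, the
  zero-truncation itself induces mild funnel asymmetry even at s = 0; this
  mirrors a real phenomenon (effects constrained positive near zero) and is
  why the power comparison is made against the matched s = 0 rate rather
  than the nominal α.

What the generator does **not** emulate: correlated sub-scenarios from a
shared publication (all rows are independent), reported-ICER inconsistency
with ΔC/ΔE, heavy-tailed per-patient microsimulation cost outliers of the
881M-USD kind present in the reference data, and missing covariates.
Passing recovery tests therefore demonstrates correctness of the
estimators under a clean meta-analytic model, not robustness to those
real-data pathologies.

## Problem sizes and numerical choices

Reference-data analyses are exact desk-scale computations on 17 rows.
Simulation checks use k = 20 studies with 200 replicates for recovery and
1,000 replicates for Egger calibration, sizes at which Monte-Carlo error is
small relative to the tested tolerances while the whole suite runs in
seconds. Collinearity tolerance is 1e−10 (relative SVD); the REML search is
bounded in log-τ² ∈ [−30, 15]; SE floors prevent infinite inverse-variance
weights; ties at NMB = 0 classify as not cost-effective.

## Known limitations

- Published pooled NMB/QALY/cost estimates with CIs and the NMB
  meta-regression coefficient magnitudes from the source analysis depend on
  an unstated within-study variance source and (for the regressions) on
  intermediate data that cannot be reconstructed; the package reproduces
  the reproducible quantities exactly, reproduces sign patterns and the
  log-ICER pooling in full, and documents the rest as convention-dependent.
- The source's classification count at λ = 100,000 (5 of 17) is not
  reproducible from its own data table under either cost basis
  (recomputation gives 6); the recomputed value is reported.
- Unweighted OLS meta-regression on 17 observations with 8 terms is
  fragile; the partial-regression data exist precisely to expose the
  leverage of extreme rows.
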