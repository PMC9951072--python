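# Methods

## Severity scoring model

The index assumes that clinical severity can be summarised per resident as
four additive dimension scores computed over a bounded exposure window.

**Exposure window.** Windows are half-open date intervals `[start, end)` of
at most 92 days — roughly the quarterly assessment cycle of US nursing
homes. For a resident who develops a pressure injury (PrI) the window ends
on the day of the first PrI; because the interval is half-open, observations
made on the PrI day itself are excluded as potentially
outcome-contaminated (whether to include that day is genuinely open; we
chose exclusion and document it here). For everyone else the window ends at
`min(end_of_stay, period_end)`. The start is clipped at admission, so short
stays produce short windows; the locomotion events/day denominator is the
realised window length, not 92. A PrI dated on or before admission violates
the "no existing PrI at entry" inclusion rule and rejects the resident with
a reason rather than silently dropping them.

**Levels and bands.** Each indicator's catalog entry defines up to four
severity-level bands as half-open intervals `[lo, hi)` that tile the whole
real line: every finite value maps to exactly one level, a boundary value
belongs to the band whose lower bound it is, and levels must be monotone in
the indicator's "worse" direction. The published source of this design does
not disclose its per-indicator threshold matrix, so the bundled default
catalog's thresholds are documented stand-ins drawn from standard adult
clinical reference ranges — the engine is fully data-driven and any
institution-specific matrix with the same schema can replace it.
Qualitative findings (rales, dyspnea, rigors, cachexia, pain, ECG rhythm,
…) carry a clinician-coded 1–4 severity as their observation value with
identity bands, because no numeric metric exists for them.

**Weights.** Level weights use `w = b^(level-1) − 1` with base `b > 1`
(default 2, giving 0/1/3/7). The exact exponential weighting used by the
original instrument is unpublished; this function was chosen because it is
the simplest form that is zero at "normal", strictly increasing, and convex
— severe derangements dominate sums of mild ones. The base is a catalog
parameter (`weight_base`), so the convexity of the index is tunable.

**Aggregation rules.** Per indicator, the single most abnormal in-window
observation sets the level (one fever counted once, however often
re-measured). Locomotion indicators first aggregate to average events/day
and band the rate. Underweight is scored from the minimum in-window BMI
derived from the weight series and height. Within an equivalence set only
the member with the maximal level contributes; ties go to the member listed
first in the catalog, deterministically, and losers are flagged
`suppressed_by_equivalence` in the audit trail. An indicator never observed
in the window scores level 1 / weight 0: in this care setting labs are
drawn mostly on acute events, so absence is treated as weak evidence of
normality. This is an assumption, not an imputation — users whose data
violate it should pre-filter residents by observation density.

Sex-specific indicators (hemoglobin/hematocrit) are modelled as separate
per-sex catalog entries carrying a sex-applicability flag; an indicator that
does not apply to a resident's sex is skipped entirely. This realises
"separate bands per sex" at the catalog level while keeping every band
table one-dimensional.

## Braden summaries

Braden totals are the sum of six subscales (five rated 1–4, friction/shear
1–3; totals 6–23, lower = worse). First and MEAN are taken over the whole
observation period, Worst (the numeric minimum) over the 92-day exposure
window. The published risk bands stop at a total of 10; totals 6–9 are
mapped to "high" as the natural extension of the bottom band, since any
admissible total can occur. A resident with no assessment in the window
gets `braden_worst = None` and is excluded from the analysis table with a
logged reason.

## Statistical workflow

Descriptive comparisons of residents with/without PrI use two-sample t
tests computed from group summary statistics and Pearson chi-square tests
without continuity correction (df = (r−1)(c−1)); no multiple-testing
correction is applied, matching conventional presentation. The automatic
t-variant choice screens the variance ratio `F = s1²/s2²` against a
two-sided α = 0.05 F test and switches to Welch (Welch–Satterthwaite df)
when variances differ; both variants are always callable explicitly, and
binary attributes are compared as pooled t on the 0/1 indicator (giving the
familiar integer df) — categorical chi-square is also available for them.
Predictor–outcome associations are point-biserial (Pearson) correlations,
overall and within Worst-Braden risk category; undefined cases (constant
predictor, single-class stratum) are reported absent rather than raising.

Propensity models are maximum-likelihood logistic regressions (statsmodels
Newton iterations, convergence tolerance 1e-8, max 200 iterations) with
Wald standard errors, p values, and 95% Wald CIs on odds ratios
(`exp(β ± 1.96·SE)`). Non-convergence or coefficient divergence
(|β| > 50, the signature of separation) is reported as an error with
diagnostics instead of returning a misleading fit. The C statistic is the
concordance probability with ties counted ½ (computed as ROC AUC; an
all-pairs enumeration oracle verifies it in the tests). Likelihood-ratio
tests require genuinely nested fits on the same subjects; the
dimensions-only model versus the Braden-only model is *not* nested, so the
suite reports that contrast only as a descriptive C-statistic difference
with an explicit caveat. Decile stratification sorts subjects by propensity
(stable sort, so ties keep input order) into 10 strata; when n is not
divisible by 10 the remainder is spread one-per-stratum over the *highest*
deciles. The 65/35 train/validation split takes `round(0.65·n)` training
subjects from a seeded permutation; the seed is a required, logged argument
and there is no hidden global random state.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
nursing-home physiology. One latent frailty factor `f ~ N(0,1)` per
resident drives (a) Braden totals `round(16.8 − 2.6·f + N(0, 2.0))` clipped
to 6–23, assessed at admission and every 91 days, with subscale vectors
drawn uniformly among decompositions of the total; (b) per-observation
abnormality: each observation's latent severity is `z = load·f + N(0,1)`
cut at family-specific thresholds to give its 1–4 level, and the recorded
value is drawn uniformly inside that level's band (coded findings record
the level itself); (c) locomotion intensity
`min(0.12·exp(1.1·f + N(0,0.6)), 3.5)` events/day, thinned into dated daily
counts; (d) BMI level `N(27, 5.5) − 0.8·max(f,0)` with monthly weights.
Observation sparsity follows the care setting: common labs ≈0.6
observations per indicator per 92 days, rarely ordered labs (blood gases,
HbA1c, urine protein, bands) ≈0.08, numeric vitals ≈8, coded findings
≈0.5. Sparsity rates, loads and thresholds are `SimulationConfig` fields.

The binary outcome is drawn from a logistic model on the resident's *true*
dimension scores and Worst-Braden, with default coefficients
(−0.12 Braden, 0.030 laboratory, 0.025 weights/vitals/pain, 0.145
locomotion, 0.10 underweight per unit) of the magnitude reported for this
kind of index. The intercept defaults to the value solved at generation
time (Brent root-finding on the realised linear predictor) that makes the
mean outcome probability equal the target incidence of 8.8%; an explicit
intercept is used verbatim, and raising it strictly raises incidence. For
cases, the first PrI is dated at the end of stay, so the pre-PrI window
coincides exactly with the discharge-anchored window — generator-side true
scores then equal engine scores, which makes end-to-end coefficient
recovery a clean test of the estimation pipeline. The cost is that the
simulator has no PrI-onset survival time and no post-onset data; it is not
suitable for time-to-event analyses.

Default rates and thresholds were calibrated once against the published
cohort's marginal moments (incidence ≈8.8%; dimension means/SDs of order
14.7/12.2 for weights/vitals/pain, 6.2/11.1 for laboratory, 2.3/3.1 for
locomotion; Worst-Braden ≈16.4/3.3) and then frozen; at n = 1015 a seeded
default cohort lands within broad bands of those targets (incidence
6%–12%). Braden measurement noise (SD 2.0) is deliberately larger than the
frailty signal alone would need, so that the severity dimensions carry
predictive signal beyond Braden by construction — fitted C(model 3)
exceeds C(model 1) by more than 0.02 at n = 2000.

What passing tests on this generator do **not** show: real EHR data have
informative observation timing (sicker residents are measured more), mixed
recording conventions, within-window trends, and PrI onset times that
truncate observation — none of which are emulated. Absolute C statistics on
synthetic cohorts (≈0.78–0.88) are therefore higher than one should expect
on real data (≈0.6–0.75), because the generator's outcome truly follows the
fitted functional form; only orderings and recovery properties transfer.

## Numerical choices and degenerate inputs

- Band lookup is `searchsorted` on band edges with right-closed handling,
  matching the half-open convention exactly; a linear-scan oracle verifies
  agreement on dense grids in the tests.
- Logistic convergence tolerance 1e-8; Wald z quantile 1.959963984540054.
- `percent_improvement` is reported to one decimal, as conventionally
  printed.
- Degenerate inputs fail loudly and specifically: empty catalogs,
  overlapping or gapped bands (named by indicator), PrI on admission,
  zero-length windows, out-of-range Braden subscales, single-class
  outcomes, constant predictors, zero chi-square marginals, splits without
  a seed. Malformed data rows are rejected row-by-row with reasons and
  counted so that rows read = used + rejected, never silently dropped.

## Problem sizes in the test suite

Structural tests use seeded cohorts of 250–500 residents; distributional
and discrimination properties use n = 2000; end-to-end coefficient recovery
uses n = 5000 under a shortened-period configuration (`light_config`) that
keeps the full 92-day window but caps stays near 130 days so the
observation volume per resident stays modest. Oracle equivalence runs on
200 randomized small records per pass. The brute-force re-scorer, the
all-pairs concordance counter and the textbook formula oracles live in
`tests/_oracles.py` and share no code with the implementation they check.

## Known limitations

- The default catalog's thresholds and the weight base are documented
  stand-ins, not a reconstruction of the original expert panel's
  unpublished matrix; scores from different catalogs are not comparable.
- Only the cardiovascular equivalence set is externally attested; the other
  shipped sets (anemia per sex, respiratory findings, urine protein) are
  clinically motivated defaults.
- Missing-as-normal biases dimension scores downward for sparsely observed
  residents.
- The analysis table treats underweight as a continuous dimension score
  (per-unit odds ratio); the categorical BMI bins are provided for
  descriptive tables only.
- `ModelSuiteReport` C statistics are in-sample unless taken from the
  train/validation split entries.
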