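# nhsi — nursing-home clinical severity scoring and pressure-injury risk modelling

`nhsi` implements the Nursing Home Severity Index tailored to pressure-injury
risk (NHSI-PrI): a configurable clinical-severity scoring engine for
longitudinal nursing-home resident records, together with the statistical
validation workflow built around it (Braden-scale summaries, two-group
descriptive comparisons, propensity logistic models with C-statistic
discrimination, decile stratification, and train/validation splits) and a
fully synthetic cohort simulator so the whole system is testable without any
real EHR data.

It is intended for biostatisticians and health-services researchers who want
to score clinical severity from routinely collected nursing-home data
(labs, vitals, coded clinical findings, locomotion-assistance documentation,
weights, Braden assessments) and to evaluate how much severity adds to
Braden-based pressure-injury (PrI) risk prediction.

## The model

**Severity scoring.** A data-driven criteria catalog assigns each clinical
indicator up to four severity levels via half-open value bands `[lo, hi)`
over its metric (level 1 normal … level 4 life-threatening). Over an
exposure window — the up-to-92-day period ending at the first PrI, or at
discharge/death/period end for residents without PrI — each indicator is
scored once from its single most abnormal observation (locomotion indicators
from their average events/day rate; underweight from the minimum in-window
BMI). Levels map to weights through the convex exponential weight function

    w(level) = b^(level-1) - 1,   default b = 2  ⇒  weights 0, 1, 3, 7,

so normal findings contribute nothing. Interchangeable indicators describing
one clinical attribute (an *equivalence set*, e.g. pulse rate / ECG rhythm /
blood pressure for cardiovascular abnormality) are counted once via their
most abnormal member. Summing contributing weights yields four dimension
scores: **laboratory**, **weights/vitals/pain**, **locomotion**,
**underweight**.

**Risk modelling.** Three logistic regressions predict PrI development:
model 1 = Worst-Braden total alone (the minimum Braden score in the window),
model 2 = the four dimension scores, model 3 = all five predictors. Fitted
probabilities are propensity scores; discrimination is the C statistic
(concordance, ties ½); nested models are compared by likelihood-ratio
chi-square; subjects are stratified into propensity deciles to count how
many PrIs the top three deciles capture.

## Worked example

```python
from nhsi import SimulationConfig, simulate_cohort, run_model_suite
from nhsi.pipeline import build_analysis_table

cfg = SimulationConfig(seed=1, n_residents=1015)
records, truth = simulate_cohort(cfg)
analysis, _ = build_analysis_table(records, period_end=cfg.period_end)
suite = run_model_suite(analysis, seed=1)
for mid, c in suite.c_statistics.items():
    print(f"C({mid}) = {c:.3f}")
strat = suite.deciles["model3_combined"]
print(f"top-3 deciles capture {strat.top3_capture_count} of "
      f"{strat.total_pri} PrIs ({strat.top3_capture_percent:.1f}%)")
```

prints

```
C(model1_braden) = 0.782
C(model2_nhsi) = 0.841
C(model3_combined) = 0.840
top-3 deciles capture 80 of 106 PrIs (75.5%)
```

On this synthetic cohort the Worst-Braden score alone discriminates
moderately (C = 0.78), adding the four severity dimensions raises
concordance to 0.84, and the combined model concentrates three quarters of
all pressure injuries in the three highest propensity deciles — the same
qualitative pattern the index is designed to reveal on real cohorts. The
`estimate`/`odds_ratio` columns of
`suite.fits["model3_combined"].summary_frame()` recover the generator's
outcome coefficients (e.g. locomotion 0.152 ± 0.045 against a generating
value of 0.145).

The same workflow runs from the shell:

```bash
nhsi simulate --seed 1 --n 1015 --out cohort/
nhsi score    --data cohort/ --out scores.csv
nhsi report   --data cohort/ --seed 1 --out report/
nhsi catalog validate my_catalog.yaml
```

`report/` then contains the dimension scores and per-indicator audit trail,
the descriptive comparison table, stratified correlations, per-model
coefficient/OR tables, decile data for replotting the capture histogram,
and a manifest with input/output checksums.

## Layout

- `src/nhsi/catalog.py` — criteria catalog, band validation, bundled default
  matrix (`data/default_catalog.yaml`)
- `src/nhsi/scoring.py` — the scoring engine (`SeverityScorer`,
  `score_dimensions`, level weights)
- `src/nhsi/windows.py` — exposure-window rules
- `src/nhsi/braden.py` — Braden totals, First/MEAN/Worst summaries, risk bands
- `src/nhsi/cohort_stats.py` — t tests, chi-square, point-biserial correlations
- `src/nhsi/risk_models.py` — `PropensityModel`, C statistic, LR tests,
  deciles, splits, the three-model suite
- `src/nhsi/simulate.py` — synthetic cohort generator
- `src/nhsi/io.py`, `src/nhsi/pipeline.py`, `src/nhsi/cli.py` — readers and
  writers, end-to-end pipeline, command line

See `docs/methods.md` for the scientific and numerical details.
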