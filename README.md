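# limbacc

Nocturnal limb-acceleration (LA) analysis for spinal cord injury (SCI)
research: from raw tri-axial ankle/wrist accelerometer traces recorded during
sleep to a fixed 133-feature vector per participant, and from there to
feature-selecting models of lower-limb **strength** (lower-extremity motor
score, LEMS 0–50), **sensation** (summed light-touch score 0–20) and
**spasticity** (Modified Ashworth Scale collapsed to none/mild/moderate).

It is written for rehabilitation and digital-biomarker researchers who want
to treat movements made while asleep — repositioning, rolling, periodic limb
movements, spasms — as an unobtrusive, continuous measure of neuromuscular
impairment.

## What it computes

1. **Movement detection.** Zero-phase high-pass filtering (0.25 Hz) per
   axis, a 0.5-s moving-RMS envelope of the filtered vector magnitude, and
   hysteresis thresholding at 0.05 g segment discrete movement events inside
   the sleep period (reported sleep window, or detected quiescence).
2. **133 LA features.** Sixty-one features per ankle movement across ten
   categories — statistical moments, power spectra, wavelet band energies
   and entropy, largest Lyapunov exponent, inter-axis correlations,
   inclination/gravity changes, median crossings, relation to recent
   movements, velocity/distance, timing — aggregated per night as median and
   IQR (plus the maximum movement duration), joined by ten night-level
   features (time asleep, movements/hour, PLM% and PLM index, limb-involvement
   proportions), then medianed across the participant's *typical* nights and
   min–max scaled across participants: 61×2 + 1 + 10 = 133 columns.
3. **Models.** LASSO via least-angle regression for the numeric outcomes and
   L1-penalized multinomial logistic regression for spasticity, with the
   penalty chosen by 10-fold block cross-validation and a final fit on all
   samples.
4. **Evaluation.** R², adjusted R² `1-(1-R²)(n-1)/(n-p-1)`, Cohen's
   f² `adjR²/(1-adjR²)`, MAE/MSE/RMSE; confusion-matrix precision, recall,
   F1 with macro/weighted averages and overall classification accuracy; the
   F-change and likelihood-ratio tests for covariates-only vs covariates+LA
   comparisons.
5. **Synthetic cohorts.** A seeded generator producing multi-night,
   multi-limb recordings whose movement amplitude, rate, rolling speed,
   timing regularity, PLM prevalence and spasm rate are monotone functions
   of a ground-truth phenotype, so the whole pipeline is testable without
   any data download. See `docs/methods.md` for the model and its limits.

## Worked example

```python
from limbacc.synthetic import CohortConfig
from limbacc.pipeline import run_study
from limbacc.evaluation import render_model_table

config = CohortConfig(n_participants=30, nights_per_participant=2,
                      night_duration_s=3600.0, seed=5)
report, features, outcomes = run_study(config)

print(f"participants: {report.n_participants}, features: {features.shape[1]}")
sel = report.selection[("lems", "la_only")]
print(f"strength model selected {len(sel.selected)} features, e.g. {sel.selected[:3]}")
print(render_model_table(
    {"strength": report.regression[("lems", "la_only")],
     "sensation": report.regression[("light_touch", "la_only")]},
    report.classification[("mas_category", "la_only")],
))
```

prints

```
participants: 30, features: 133
strength model selected 26 features, e.g. ['la.stat.sd__med', 'la.stat.min__iqr', 'la.stat.skewness__med']

Model          p      R2   adj R2     f2     MAE      MSE    RMSE
strength      26   0.999    0.992 125.67    0.32     0.17    0.41
sensation     10   0.720    0.572   1.34    1.75     5.27    2.29

OCA: 100.0%
Class             F1  Precision  Recall
none           1.000      1.000   1.000
mild           1.000      1.000   1.000
moderate       1.000      1.000   1.000
macro          1.000      1.000   1.000
weighted       1.000      1.000   1.000
```

Reading the table: the LASSO-LARS strength model explains 99.9% of the
variance in the ground-truth LEMS of this 30-person synthetic cohort
(in-sample), with 26 selected features led by amplitude-linked statistics —
exactly the behaviour the generator plants, since its burst amplitude and
movement rate increase monotonically with LEMS. The spasticity classifier
separates all three categories perfectly because simulated spasm bursts are
frequent 6-Hz packets that dominate several spectral and rate features. On
real recordings the same pipeline reports the same metric suite; near-perfect
scores here validate the machinery and parameter recovery, not clinical
effect sizes.

## Command line

```bash
limbacc show-config                       # print effective YAML config + hash
limbacc simulate --out cohort/            # write traces, sleep log, outcomes, ground truth
limbacc extract  --cohort-dir cohort/ --out features.csv
limbacc fit      --features features.csv --outcomes cohort/outcomes.csv --out report.json
limbacc table2-check                      # recompute published summary arithmetic
```

All commands are deterministic given the same config file and embed the
config hash and seed in their outputs. Validation problems exit with code 2.

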