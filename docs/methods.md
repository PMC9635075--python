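# Methods

`limbacc` analyses tri-axial accelerometry recorded at the ankles and
non-dominant wrist during sleep in adults with chronic spinal cord injury
(SCI). Movements made while asleep — repositioning, rolling, periodic limb
movements (PLM), spasms — carry information about lower-limb strength,
sensation and spasticity: stronger participants are expected to produce
higher-amplitude, faster and more complex movements; intact sensation cues
regular repositioning; spasticity produces frequent, short, repetitive
oscillatory bursts. The package turns raw traces into a fixed 133-feature
"limb acceleration" (LA) vector per participant and relates it to three
clinical outcomes with feature-selecting models.

## Movement detection

Each axis is high-pass filtered with a zero-phase 4th-order Butterworth
filter (cutoff 0.25 Hz) to remove gravity, the vector magnitude of the
filtered axes is enveloped with a 0.5-s moving RMS, and an event is a maximal
span where the envelope exceeds 0.05 g, extended outward by hysteresis to
half the threshold. Events separated by less than 0.5 s are merged and events
shorter than 0.3 s dropped. Events across limbs whose spans overlap or whose
onsets fall within 1 s are grouped into multi-limb events. The sleep period
is taken from the participant's reported sleep window when present; otherwise
it is the longest span whose 10-min moving RMS stays below 0.02 g (minimum
2 h). Published work in this area does not specify detector internals, so
these parameters are this package's declared defaults, chosen to separate
instrument noise (0.005–0.01 g in the generator, similar on GT9X-class
devices) from physiological movement by an order of magnitude; all are
configurable (`DetectionParams`). Indexing is 0-based and half-open
throughout, so `duration = (end - start) / fs` with no off-by-one ambiguity.

## The 133 LA features

Sixty-one features are computed per ankle movement, in ten movement-level
categories (counts in parentheses): statistical moments of the vector
magnitude (8), frequency domain (10), signal characteristics — wavelet band
energies, relative energies, wavelet entropy and the largest Lyapunov
exponent (9), inter-axis correlations (3), change in inclination angle (4),
change in per-axis gravity (3), median crossings (2), relation to recent
movements (11), velocity/distance estimates (7), and timing (4). Each
feature is aggregated per night as its median and IQR (type-7 linear-
interpolation quantiles) across all movements of that night, and movement
duration — the single max-aggregated feature — also contributes the night's
maximum. Ten night-level features are added: time asleep, movements per
hour, PLM% and PLM index, and six limb-involvement proportions. That gives
61×2 + 1 + 10 = 133 columns, asserted at import. The participant-level
vector is the per-feature median across the participant's *typical* nights
only (self-reported as representative; participants with no typical night
are excluded). Features are min–max scaled to [0, 1] across participants;
constant columns map to 0.5.

Notes on individual operations:

* **PSD features** use the averaged-periodogram (Welch) method on the
  mean-removed vector magnitude: Hann segments of up to 2 s with 50%
  overlap; segments shorter than 1 s are symmetrically padded. The second
  dominant frequency is the highest local maximum at least 0.5 Hz from the
  first.
* **Wavelet features** use a 3-level Daubechies-4 decomposition with
  periodization, which makes the band energies an exact partition of the
  signal energy (Parseval); wavelet entropy is the Shannon entropy (nats) of
  the 4-band energy distribution.
* **Lyapunov exponent** is a Rosenstein nearest-neighbour estimate: delay
  embedding (default dimension 5; delay at the first autocorrelation zero
  crossing, capped so the embedding window stays inside the segment),
  Theiler-window-excluded nearest neighbours, and a least-squares slope of
  the mean log divergence fit on the initial part of the curve (cut at the
  midpoint of its range when the curve saturates, i.e. spans more than one
  nat). Units are 1/sample ("per step"). Segments under 50 samples return
  missing. The estimator reproduces ln 2 on the fully chaotic logistic map
  and ~0 on periodic signals.
* **Orientation features** (inclination angle, per-axis gravity change) use
  a 0.25-Hz zero-phase low-pass gravity estimate computed on a ±6-s padded
  slice around each event (numerically equivalent to full-trace filtering to
  ~2e-4 g, and much cheaper). Segments whose gravity magnitude drops below
  0.5 g return missing.
* **PLM scoring** follows the standard polysomnography rule: candidate leg
  movements last 0.5–10 s; a PLM sequence is ≥4 candidates whose successive
  onset-to-onset intervals are 5–90 s. PLM% is sequence movements over all
  leg movements (pooled over both legs); PLM index is sequence movements per
  hour asleep.
* **Velocity/distance** integrates high-passed acceleration trapezoidally
  with linear drift removal of the velocity; because the high-pass filter
  removes the posture baseline these are order-of-magnitude estimates, which
  is one reason such features tend not to be selected by the models.
* **Missing values** stay missing through aggregation; at modeling time
  missing scaled values are mean-imputed with a logged warning (all-missing
  columns impute to the scale midpoint 0.5).

## Outcomes

Strength is the lower-extremity motor score (LEMS): ten myotome scores of
0–5 summed to 0–50. Sensation is the summed lower-limb light-touch score:
ten dermatome scores of 0–2 summed to 0–20. Spasticity is the Modified
Ashworth Scale at four sites (knee flexors, ankle plantarflexors,
bilaterally), collapsed to *none* (all sites 0), *moderate* (any site ≥ 2)
or *mild* (anything between); the "1+" grade is ranked 1.5, strictly between
1 and 2, and serialized verbatim.

## Models and evaluation

Numeric outcomes use the LASSO fit by least-angle regression: the LARS path
provides candidate penalties (capped at 30 grid points), 10-fold *block*
cross-validation (participants shuffled once by seed, then split into
contiguous blocks differing in size by at most one) picks the penalty with
minimal mean squared error (ties to the stronger penalty), and the final
model is a penalized refit on all samples at that penalty. An unpenalized
least-squares refit on the selected columns is also reported, since either
convention is defensible for final coefficients; the penalized fit is the
default. The categorical outcome uses multinomial (softmax) logistic
regression with an L1 penalty (saga solver), the penalty chosen by
cross-validated accuracy with ties toward the stronger penalty; per-class
selected features are the nonzero entries of each class's coefficient row —
deliberately not one-vs-rest, so per-class sparsity comes from the softmax
coefficients themselves.

Evaluation reproduces the full clinimetric suite: R², adjusted
R² = 1 − (1 − R²)(n − 1)/(n − p − 1), Cohen's f² = adj R²/(1 − adj R²)
(computed from the *adjusted* R², with 0.02/0.15/0.35 read as
small/medium/large), MAE/MSE/RMSE; and from the confusion matrix (rows =
actual) per-class precision/recall/F1, macro and support-weighted averages,
and overall classification accuracy. Nested linear models are compared with
the F-change test, nested logistic models with the likelihood-ratio
chi-square test. A verification harness (`limbacc table2-check`) recomputes
every derived statistic of the reference clinical study from its printed raw
inputs; one printed value (the sensation f² of 1.31) is reproducible only
from the unrounded R² — the printed R² of 0.733 gives 1.305 — and is checked
with a 0.01 band for that reason.

## Synthetic cohort generator

No participant-level data are deposited for this kind of study, so the
package ships a generator that emulates the *statistical structure the
analysis assumes*, with ground truth. Per participant: 25% are motor
complete (LEMS 0); the rest draw LEMS from a truncated normal (mean 26.9,
SD 15, range 2–49) matching the published cohort description; light touch
drifts upward with LEMS (3.8 + 0.26·LEMS, SD 5, truncated to 0–20);
spasticity categories draw with probabilities 0.395/0.368/0.237. The
phenotype maps monotonically to generative parameters: movement rate
6 + 0.30·LEMS events/h, burst amplitude 0.12 + 0.010·LEMS g, roll speed
20 + 1.6·LEMS deg/s, inter-movement interval CV 1.1 − 0.04·light-touch
(floor 0.25), PLM-train propensity 0.12 + 0.006·LEMS, and spasm rates
0/4/12 per hour for none/mild/moderate spasticity at 6 Hz (inside the 5–8 Hz
clonus band). These slopes were fixed once, as plausible encodings of the
clinical hypotheses (stronger → bigger/faster/more movements; better
sensation → more regular timing; more spasticity → more short oscillatory
bursts); no published amplitude/duration distributions exist for nocturnal
SCI movements, so they are declared study conditions, not estimates.

A night is a unit-gravity baseline at a uniformly random orientation plus
white noise (SD 0.008 g) plus events: Hann-windowed 0.5–3 Hz band-limited
noise bursts (1–8 s) for repositioning, spherical-linear gravity rotations
(with an accompanying burst) for rolls, trains of ≥4 short bursts 10–40 s
apart for PLM, and Hann-windowed 6-Hz sinusoidal packets (0.5–2 s,
0.10–0.25 g) for spasms. The wrist mirrors ankle event times with
independent amplitudes and 40% omission. Onsets of repositioning events
follow a gamma renewal process with the phenotype's interval CV. All
randomness derives from one master seed via counter-based `SeedSequence`
splitting, so cohorts are bit-reproducible regardless of generation order.

The default cohort is 200 participants × 3 nights at 30 Hz. Each simulated
night covers a 2-h consolidated-sleep window (±15% jitter per night). This
window is the package's choice of problem size: every rate-like feature is
per-hour, so the window length mainly sets how many movements each night
contributes (~15–60 per limb), and 2 h gives stable night medians while
keeping the default end-to-end study cheap enough to re-run routinely.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: sleep architecture (stages, wake-after-sleep-onset,
apnea), posture-dependent spasticity, medication effects, device artifacts
beyond white noise and the ±16 g range guard, and any realistic coupling of
the 24 questionnaire covariates to the outcomes (five covariate columns get
weak outcome correlations; the rest are noise). Model performance on the
synthetic cohort validates the *pipeline machinery and its monotone
parameter recovery*, not clinical effect sizes: in-sample R² near 1 on
synthetic data simply reflects the generator's clean monotone maps.

## Numerical choices and edge cases

Type-7 quantiles everywhere; skewness is adjusted Fisher–Pearson and
kurtosis bias-corrected excess (both missing for <4 samples or zero
variance); correlations are missing for zero-variance axes; an event's
spectral features are missing for an all-zero slice; the first movement of a
night has missing previous-movement features (not zero); zero ankle
movements in a night leaves all movement-aggregated columns missing with a
warning; a classifier class never predicted has undefined precision, dropped
from the macro average with a warning. Readers reject malformed input
(duplicate timestamps, gaps over one sample period, >1% sampling-rate
mismatch, out-of-range values) naming file and row, rather than coercing.

## Known limitations

The exact 61-feature membership in the reference study's supplement is not
public; the registry holds every feature named in its published tables and
fills the stated per-category counts with documented companions (the extras
are noted in the registry source). Which single feature the study
max-aggregated is likewise unstated; this package uses movement duration
(the longest movement of the night). The movement detector is a declared
stand-in for the unpublished detector of the reference study's prior work.
Velocity/distance estimates from high-passed acceleration are not
displacement measurements. The final-fit convention (penalized vs refit)
affects coefficient magnitudes but not selection; both are reported.
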