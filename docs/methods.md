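# Methods

This note records the models, conventions, parameter defaults, and design
choices behind the package, and what the synthetic data does and does not
establish about real recordings.

## Bout segmentation

The device's write rule is ambiguous between a window anchored at bout
onset and a maximum inter-lick gap. We implement the gap reading: a bout
ends once more than `gap` seconds (default 2.0 s) elapse after the previous
lick's **onset**, and the recorded span is floored at `gap`. This
reproduces both observed behaviors of the hardware record — a single lick
appears as a 2 s bout, and bouts can be arbitrarily long but never shorter
than 2 s. `gap` is exposed as a parameter rather than hard-coding firmware
behavior. Times are decimal seconds from session start, half-open
`[onset, offset)` intervals.

Session CSVs are denormalized (one bout per row with session metadata
repeated; a zero-bout session is one row with empty bout columns), UTF-8,
comma-separated, header mandatory. The hardware holds two bottles but the
paradigm uses one; an optional `bottle_side` column is carried and ignored
by analyses.

## Cleaning

Ordinary least squares of `n_licks` on `lick_duration` (response in lick
counts, predictor in seconds), pooled **globally** over all bouts by
default; `per_animal` grouping is available. The global default matches a
protocol whose retention is reported as a single pooled figure. Bouts with
|residual| > 3 lick units are removed in a single pass — no iterative
refit, no robust-regression variant. The threshold is in lick units
because the response is the lick count; the procedure is scale-covariant
in duration (rescaling durations rescales the slope and leaves residuals,
hence the kept set, unchanged).

A caveat the tests make explicit: a pooled OLS line is only meaningful
when artifacts are rare. Extremely long leak bouts act as high-leverage
points; at contamination fractions of a few percent they tilt the line and
misclassify genuine large bouts. At realistic contamination (≲ 0.1 % of
bouts) the line is stable and sensitivity/specificity of removal exceed
0.95. Degenerate groups (< 2 bouts or constant duration) raise an error
from the fitting API and are skipped with a warning in pipeline mode.

## Features

The 18-entry ordered registry is a module constant
(`sipstruct.features.FEATURE_NAMES`); the count and the named features
(latency, mean inter-drink interval, first-30-min front-loading measures,
per-bout maxima, totals) are fixed by the protocol, and the registry is the
package's canonical completion of that set. Conventions decided here:

* **Inter-drink interval**: bout end → next bout start (not
  onset-to-onset).
* **First 30 min membership**: a bout counts iff its start < 1800 s.
* **Latency**: first lick onset (equal to the first bout start under the
  device rule).
* **Imputation**: sessions with no bouts report zero totals/maxima and
  rates, latency = session length; sessions with < 2 bouts report both
  inter-drink-interval features as the session length in seconds (a
  censored "no second drink" value). This keeps the feature matrix
  rectangular for the classifier instead of dropping rows.
* **Dose is not a feature** — the registry is microstructure only.

Intake: water dose is fluid grams per kg body weight. Alcohol dose
converts bottle-weight loss to solution volume with the solution density,
takes 20 % v/v as ethanol, and weights by ethanol density:
`dose = Δw/ρ_sol · 0.20 · ρ_EtOH / bw_kg`. Density defaults:
ρ_water = 1.000, ρ_20%-solution = 0.970, ρ_EtOH = 0.789 g/ml (standard
handbook values; configurable).

Inclusion: per fluid group, animals whose intake summed over sessions 1–15
falls below the Tukey lower fence Q1 − 1.5·IQR (linear-interpolation
quantiles) are excluded. This is the standard reading of "outside the
lower interquartile range" and correctly excludes a near-zero drinker from
an otherwise stable group; groups smaller than 4 are kept whole with a
warning.

## Classifier

Architecture 2048–512–64–4, rectifier hidden units, softmax output, Adam
(step size 1e-3), categorical cross-entropy, one-hot labels over
water/alcohol × ChR2/eGFP. Epochs (100) and batch size (32) are defaults
of this package — the protocol leaves them unstated — with no early
stopping. Min-max normalization is fit on the **full table before**
cross-validation by default for fidelity to the analysed protocol; this
leaks the test folds' column ranges into training, so a `fold_safe` option
fits the scaler on training folds only. Stratified k-fold (k = 6, shuffled,
seeded) preserves class proportions within one sample per fold; a 998-row
table yields test folds {167, 167, 166, 166, 166, 166}, i.e. the modal
832-row training partition. Chance is the modal-class frequency (the best
label-independent guesser); the uniform 1/4 alternative is reported
alongside. Argmax prediction ties break toward the lowest class index.
One freshly initialized (He) network is trained per fold with a
fold-derived seed; per-epoch train/test loss and accuracy are recorded.

The backend is a dependency-free numpy MLP so the repository is testable
without a deep-learning framework and bit-reproducible across machines.
Accuracy-oriented tests and the acceptance script run a reduced
64–32–16–4 network for up to 40 epochs on cohorts of ~270 sessions — the
package's chosen desk-scale problem size; the full-width default spec is
used when fidelity, not turnaround, is the point.

## Synthetic cohort generator

Each session is a latent renewal process:

| parameter | default | meaning |
| --- | --- | --- |
| `latency_median_s`, `latency_sigma` | 240 s, 0.7 | log-normal latency to first bout |
| `ibi_shape`, `ibi_scale_s` | 2.0, 150 s | gamma inter-bout intervals (mean 300 s) |
| `bout_duration_median_s`, `bout_duration_sigma` | 4 s, 0.5 | log-normal bout durations |
| `lick_rate_hz` | 7 | within-bout lick rate (typical mouse licking) |
| `lick_len_mean_s`, `lick_len_cv` | 80 ms, 0.08 | per-lick beam-break length |
| `front_loading_boost` | 2.0 | interval scale ÷ boost during first 30 min |
| `grams_per_lick`, `intake_noise_cv` | 2 mg, 0.05 | intake coupling |
| `leak/chew_rate_per_session` | 0.002 each | expected planted artifacts |

Cohort defaults are 8/11/8/8 animals across water-ChR2 / water-eGFP /
alcohol-ChR2 / alcohol-eGFP, six weeks of five sessions (four 2 h, one
4 h). Class structure: alcohol sessions shift the baseline (latency ×1.5,
interval scale ×1.25, duration ×1.2, front-loading excess ×1.3), and the
ChR2 × alcohol class additionally loses bouts (−30 %), licks (−30 %, via
duration), and front-loading excess (−40 %) in weeks 5–6 only. All of
these multipliers are **invented magnitudes** matching the direction and
week-specificity of the circuit manipulation being emulated; they are free
parameters, not measurements. A single `class_separation` dial raises
every class multiplier to the power *d*: at *d* = 0 the four classes are
i.i.d. (classification must sit at chance), and separability — hence
downstream classifier accuracy — increases monotonically in *d*. Default
*d* = 1.

Randomness: one cohort seed spawns per-(class, animal, session)
`SeedSequence` substreams, so adding an animal or session never perturbs
existing data. Bottle-weight loss is total licks × grams-per-lick with
log-normal noise, so intake is a noisy monotone function of
microstructure (Pearson r ≳ 0.98 per fluid at defaults).

Contamination signatures: leaks are 5–12 s of beam-broken time with 1–3
licks; chews are 60–140 licks with 0.5–1.5 s of duration. Both sit tens of
lick units from the licks-vs-duration line (≫ the 3-unit threshold) while
staying inside the leverage-safe range discussed under Cleaning. The
per-lick length CV of 0.08 encodes stereotyped within-bout licking; it
implies genuine-bout residual SD ≈ 0.08·√n_licks, comfortably inside the
cleaning threshold, consistent with real datasets where > 99.9 % of bouts
survive cleaning.

What the generator does **not** emulate: circadian structure within
sessions beyond the front-loading window, day-to-day autocorrelation
within animals, bottle-side effects, evaporation, body-weight growth, or
any pharmacokinetics. Passing tests therefore demonstrate pipeline
correctness and statistical behavior under the stated model — not that
the model is the true law of mouse drinking.

## Synaptic sweeps and measurements

Waveforms are difference-of-exponentials
`A·(e^(−t/τ_d) − e^(−t/τ_r))/peak`, sampled at 10 kHz, with the sampled
extremum normalized to the configured amplitude so noiseless recovery is
exact. Fast (AMPA-like) kinetics default to τ_r = 1.5 ms, τ_d = 12 ms;
slow (NMDA-like) to 6/60 ms. Noise is white Gaussian, default σ = 2 pA.
Sign convention: inward currents negative, amplitudes reported positive.

Measurement geometry (all configurable): baseline = mean of 50 ms
pre-stimulus; evoked peak searched 2–50 ms post-stimulus; NMDA window mean
100–125 ms post-stimulus at +40 mV (the fast component has fully decayed
by then); paired-pulse P2 baseline = mean of the 5 ms immediately before
the second stimulus (absorbing P1's residual decay); population-spike
amplitude = baseline-to-negative-peak, with peak-to-peak as an option.
Replicate sweeps are averaged **before** peak extraction: the extremum of
a noisy trace is biased upward by roughly σ√(2 ln N) over an N-sample
window, and averaging 3 replicates keeps that bias within the stated 2 %
recovery tolerance at σ = 2 pA. AMPA amplitude at −80 mV is the peak (the
windowed-mean alternative is noted but not default). Ratios whose
denominator is at/below a noise floor return an `Undefined` sentinel, not
a number.

The spontaneous-event detector is a plain threshold detector (crossings of
−threshold relative to the trace median, runs merged within a 2 ms
refractory) with per-event amplitude, interpolated 10–90 % rise time, and
a bounded single-exponential decay fit started 4 ms past the peak — the
early decay is contaminated by the rise component, which biases τ upward
if the fit starts at the peak. It is a transparent reference detector by
design, not a clone of any commercial analysis tool.

QC: a recording is excluded iff either series resistance exceeds 25 MΩ or
|ΔRs|/Rs_start > 15 %. The rule is strictly greater-than at both bounds.

## Numerical and degenerate-input conventions

* Min-max normalization maps constant columns to 0; reused (training-fold)
  bounds clip test data into [0, 1].
* Empty bout lists, empty groups, and zero-variance correlations are
  defined outcomes (empty outputs / all-included-with-warning / NaN with a
  `defined` flag), not crashes; invalid parameters raise
  `ValidationError` and malformed files raise `ParseError` naming the row.
* Non-finite training loss aborts a fold with a diagnostic rather than
  returning silently wrong accuracies.
* All stochastic components (generator, fold shuffling, network
  initialization and batching) are driven by explicit integer seeds;
  identical seed + config ⇒ identical outputs, which the pipeline manifest
  records as a config hash.

## Known limitations

* The single-pass global OLS cleaning inherits the leverage sensitivity
  described above; per-animal grouping reduces pooling artifacts but needs
  enough bouts per animal.
* Whole-table normalization before cross-validation is a deliberate
  fidelity choice with a documented leakage caveat (`fold_safe` avoids it).
* The 18-feature registry is this package's canonical ordering; analyses
  comparing against other implementations should align registries first.
* Desk-scale cohorts put the classifier's over-chance ratio near ~1.5×;
  the larger the cohort (and the stronger `class_separation`), the larger
  the margin — small-sample fold accuracies are noisy.
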