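# Methods note

This note documents the model implemented by `hrvfatigue`, the procedure
for mapping HRV features to a Brief Fatigue Inventory estimate (MBFI), the
synthetic-data generator and its calibration, and the numerical choices
that matter for reproducibility. It states only what the code computes.

## 1. Measurement model

Each observation is a 2-minute interbeat-interval (IBI) segment recorded
hourly by a wrist PPG device. Per segment (`hrvfatigue.spectral`):

1. **Artifact cleaning.** Intervals outside 300–2000 ms or deviating more
   than 20% from an 11-beat running median are linearly interpolated over
   beat index. If more than 20% of beats needed correction the segment is
   flagged invalid.
2. **Heart rate.** HR = 60000 / mean cleaned interval (ms).
3. **Band powers.** The tachogram is linearly detrended and its power
   spectrum integrated over LF = [0.05, 0.15) Hz and HF = [0.15, 0.40] Hz.
   The default estimator is a Lomb-Scargle periodogram; an alternative
   resamples to 4 Hz with a cubic spline and uses a Hann-windowed
   periodogram (`method="resample"`).
4. **Ratio.** LF/HF is the sympathovagal index. It is NaN (record invalid)
   when cleaning failed or HF power is below 1e-6 ms².

The default bands partition the spectrum with a half-open split at
0.15 Hz. The overlapping pair sometimes quoted in the HRV literature
(HF from 0.14 Hz, overlapping LF) is available as
`SpectralBands.overlapping()`; it double-counts power in 0.14–0.15 Hz and
is not used by default.

## 2. Phase segmentation and features

Records are split by local clock time into a sleep phase (default window
22:00–08:00, half-open, wrapping midnight — 10 hourly slots) and an active
phase (14 slots). Post-midnight sleep records are attributed to the
previous calendar night. Per patient (`hrvfatigue.features`):

- **sleep disorder ratio** — fraction of valid sleep-phase records with
  LF/HF > 1 (also reported as the mean nightly count),
- **mean sleep LF/HF** — mean and sample SD (ddof = 1) over all valid
  sleep records,
- **active disorder ratio** — fraction of valid active-phase records with
  LF/HF < 1 (mean daily count).

Thresholds are strict: LF/HF exactly 1 counts in neither tally. Invalid
records are excluded from numerator *and* denominator; by default the
denominator is the observed number of valid slots, with the nominal 10/14
denominators available via `nominal_slots`. Daytime rest events can also
be detected jointly from LF/HF < 1 and a heart-rate drop of ≥ 5 bpm below
the patient's active-phase median (`detect_rest_events`).

## 3. BFI mapping and evaluation

Two mappings (`hrvfatigue.mapping`), both clipping negative estimates to 0
(the unclipped value is retained for diagnostics):

- **Fitted:** OLS of BFI on the three fraction-scale features with an
  intercept (statsmodels; ≥ 5 patients required; a rank-deficient design
  raises). R² is reported.
- **Unit-weight with compensation:** MBFI is the plain sum of the three
  features; patients are grouped by BFI (A: BFI = 0, B: 0 < BFI ≤ 3,
  C: BFI > 3) and each group's compensation factor
  CF_W = mean(BFI − MBFI) is added. By construction each group's
  pre-clipping residuals then average exactly zero on the calibration
  cohort.

Evaluation (`hrvfatigue.evaluation`) reports per-group and total MAE and
RMSE on the clipped estimates, the error rate MAE/10 × 100% (BFI is a
10-point scale), and Pearson (default) or Spearman feature–BFI
correlations. Correlation of a zero-variance vector raises rather than
returning NaN.

A separate severity labelling (No / Mild / Moderate / Severe) is provided
for display. Its quoted band edges ("mild < 3, moderate 4–7") leave
[3, 4) unassigned; the implementation folds that interval into Moderate.
This labelling is distinct from the A/B/C compensation groups and is not
used in any computation.

## 4. Reference cohort

`hrvfatigue.io` embeds the 12-patient summary table (per-patient BFI,
sleep disorder count and percentage, mean ± SD sleep LF/HF, active
disorder count and percentage, severity label). Loading re-derives each
percentage from its count (count/10 and count/14, rounded to integer
percent) and rejects inconsistent rows. `fixture_features()` converts the
counts to fraction-scale features for the mapping pipeline.

## 5. Synthetic generator

`hrvfatigue.synthetic` emulates the protocol, not the physiology of a real
PPG sensor. Two levels:

**Measurement streams.** Per sleep slot, a Bernoulli(`sleep_disorder_prob`)
indicator decides whether LF/HF exceeds 1; the value is then an
inverse-CDF draw from LogNormal(μ, σ) truncated above or below 1. σ is
fixed at `lfhf_dispersion`; the location μ is solved (Brent's method,
xtol = 1e-12) so the marginal mean equals `mean_sleep_lfhf`. Truncated
means are evaluated with log-space normal CDF ratios
(`exp(μ + σ²/2 + logΦ(z−σ) − logΦ(z))`) so extreme locations stay finite.

Nights follow a hypnogram of cycles drawn uniformly from 90–120 minutes,
each walking the non-REM ladder 1-2-3-4-3-2-1 (equal shares of 80% of the
cycle) and ending in REM (20%), truncated at the 10-hour window end.
Disordered draws whose slot midpoint falls in REM are multiplied by
`rem_burst_multiplier` (default 3). Two consequences:

- Because the multiplier applies only to above-1 draws, the exceedance
  probability P(LF/HF > 1) equals `sleep_disorder_prob` *exactly*,
  independent of sleep architecture.
- The location solve uses the *realized* fraction of slot midpoints in
  REM (computed from the patient's own hypnograms, generated first), not
  the nominal 20%: window truncation preferentially cuts REM, and using
  the nominal fraction would bias the marginal mean upward.

Active slots mirror this with exceedance 1 − `active_rest_prob` and target
mean `active_mean_lfhf`. Heart rate follows a piecewise nightly profile
(decline to a nadir at 60% of the night, pre-wake rise) plus Gaussian
noise; LF and HF powers are decomposed from the ratio against fixed totals
(800 ms² sleep, 1500 ms² active). Randomness is split with
`numpy.random.SeedSequence` into independent sleep/active/night streams,
so same-seed runs are byte-identical.

`make_profile(true_bfi, seed)` calibrates a profile linearly in BFI with
seeded patient-level jitter:

| parameter | value | clip |
|---|---|---|
| sleep_disorder_prob | 0.125 + 0.137·BFI + U(±0.10) | [0.01, 0.95] |
| mean_sleep_lfhf | 0.95 + 0.40·BFI + U(±0.15) | [0.30, 8.0] |
| active_rest_prob | 0.35 − 0.03·BFI + U(±0.18) | [0.01, 0.90] |
| lfhf_dispersion | 0.5 (fixed) | — |
| base_hr | 70 + U(±6) bpm | — |

Anchors place a BFI-0 patient in the low-fatigue band (disorder ratio
≤ 0.25, mean LF/HF ≈ 1) and a BFI ≈ 5.7 patient near disorder 0.9 and mean
LF/HF ≈ 3.2, matching the spread of the reference cohort; for a fixed seed
the calibration is monotone in BFI.

**Raw IBI segments.** `generate_ibi_segment(target_lf, target_hf, mean_hr)`
produces a 2-minute interval series: mean interval plus sinusoids at
0.10 Hz and 0.25 Hz with variances equal to the targets, plus white noise
(SD = 0.05·√(LF+HF)), centred so the mean interval is exact. These provide
a ground-truth oracle for the spectral estimator.

**Limitations.** The stream generator draws LF/HF values directly rather
than synthesising beat series per slot; slot values are i.i.d. given the
indicator (no autocorrelation across the night beyond the hypnogram);
hypnograms ignore awakenings and sleep-onset latency; HR and LF/HF noise
are independent; all generated records are marked valid (invalid-data
handling is exercised separately). The generator is a calibration device
for the pipeline, not a physiological simulator.

## 6. Key numerical choices

- **Nominal spectral time axis.** The tachogram time axis is beat index ×
  mean interval, with the mean quantized to 1e-6 ms. This makes the LF/HF
  ratio exactly invariant under amplitude scaling of the fluctuations, and
  the quantization prevents sub-femtosecond float noise in the mean from
  moving a frequency-grid point across the 0.15 Hz band edge (the 4×
  oversampled grid can place a point exactly on it).
- **Variance normalisation.** Band powers are scaled so the full-grid
  periodogram integral equals the detrended series variance, guaranteeing
  LF + HF ≤ total variance for any estimator.
- **Degenerate inputs.** Constant IBI segments yield (0, 0) power and an
  invalid record; constant BFI responses yield zero slopes with R² = 0; a
  singular regression design and zero-variance correlation inputs raise
  `ValueError`; fewer than 3 pairs for a correlation or 5 patients for a
  fit raise explicit errors.
- **Coefficient instability on rounded summary data.** The three features
  are strongly collinear across the 12-patient table (sleep disorder ratio
  and mean sleep LF/HF are highly correlated). Consequently the individual
  OLS coefficients are sensitive to the rounding of the table entries,
  while R² and the mapped values are stable. Coefficient values obtained
  from the table should therefore be compared on predictions and fit
  quality, not weight-by-weight.
- **Determinism.** All cohort-level results from the embedded table are
  deterministic; simulation results are reproducible from the profile seed
  alone.
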