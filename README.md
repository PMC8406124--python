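# hrvfatigue

Objective estimation of cancer-related fatigue from wearable heart-rate-
variability (HRV) recordings.

Cancer-related fatigue is usually assessed with self-report instruments such
as the Brief Fatigue Inventory (BFI, a 0–10 scale), but many patients
under-report it. A wrist-worn photoplethysmography device that records a
2-minute HRV measurement every hour offers an objective alternative: the
ratio of low-frequency (LF, 0.05–0.15 Hz) to high-frequency (HF,
0.15–0.40 Hz) spectral power of the interbeat-interval series indexes
sympathovagal balance, falls below 1 in deep (non-REM) sleep, and bursts
above it in REM and wakefulness. This package implements the full analysis
pipeline for such recordings, plus a calibrated simulator so every stage is
testable without device data.

## The method

For each patient *P*, hourly measurements over 7 days are split by clock
time into a nightly sleep phase (10 slots) and a daytime active phase
(14 slots). Three features summarise the stream:

- **sleep disorder ratio** `r_sleep` — fraction of sleep-phase measurements
  with LF/HF > 1 (shortened deep sleep),
- **mean sleep LF/HF** `m_sleep` — arithmetic mean of the sleep-phase ratio,
- **active disorder ratio** `r_active` — fraction of active-phase
  measurements with LF/HF < 1 (daytime sleep/rest events).

A mapped BFI (MBFI) is obtained either by ordinary least squares,

    MBFI_P = α·r_sleep + β·m_sleep + γ·r_active + ε,

or, to avoid refitting per cohort, by the **unit-weight mapping with group
compensation**: with α = β = γ = 1 (no intercept), patients are clustered by
BFI into groups A (BFI = 0), B (0 < BFI ≤ 3) and C (BFI > 3), each group's
compensation factor CF_W = mean(BFI − MBFI) is added back, and negative
results are clipped to 0. Mapping quality is reported as per-group and
total MAE/RMSE, an error rate (MAE as % of the 10-point scale), and the
feature–BFI correlations.

The package ships the published 12-patient summary table (lung-cancer
cohort under chemo/targeted therapy) as its reference input, and a
generator of synthetic patient streams: hypnograms with 90–120-minute
non-REM/REM cycles, truncated log-normal LF/HF draws whose exceedance
probability and mean are controlled exactly by a patient-level fatigue
parameter, REM bursts, daytime rest events, and raw interbeat-interval
segments with known band powers for validating the spectral estimator.

## Worked example

```
$ hrvfatigue reproduce-study
fitted weights: alpha=4.49 beta=0.86 gamma=0.71 epsilon=-1.65 (R^2=0.861)
compensation factors: A=-1.463, B=-0.644, C=+1.529

patient    BFI   MBFI  group
P03       0.00   0.00  A
P13       0.00   0.03  A
P06       0.00   0.00  A
P02       0.00   0.54  A
P10       1.22   0.87  B
P07       1.33   1.08  B
P11       1.78   1.70  B
P01       1.56   0.93  B
P12       1.22   1.59  B
P04       1.11   2.03  B
P08       5.00   4.91  C
P05       5.67   5.76  C

             MAE    RMSE    n
Group A     0.14    0.27    4
Group B     0.43    0.51    6
Group C     0.09    0.09    2
Total       0.28    0.40   12
error rate: 2.8%
```

Reading: the OLS fit explains 86% of the BFI variance across the cohort;
the unit-weight compensated mapping tracks self-reported BFI to within 0.28
points on average (2.8% of the scale), with essentially all residual error
in the mildly fatigued group B — the no-fatigue and moderate groups are
mapped to within ~0.1 points.

The same pipeline runs on simulated cohorts:

```
hrvfatigue simulate --seed 7 --n-patients 12 --out m.csv
hrvfatigue features --measurements m.csv --out f.csv
```

or from Python:

```python
import hrvfatigue as hf

profile = hf.make_profile(true_bfi=5.67, seed=3)
stream = hf.generate_measurements(profile)   # 168 hourly records (7 x 24)
features = hf.extract_features(stream)       # the three-feature triple
print(features.vector)                       # [0.94285714 3.12998201 0.24489796]
```

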