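# callvar

Multi-level variation analysis of pulsatile anuran advertisement calls.

The package measures six call parameters from mono WAV recordings
(call duration, call interval, dominant frequency, 5–95% energy
bandwidth, pulse number, pulse rate), then runs a reproducible
statistical pipeline over them:

1. **audio_features** — zero-phase high-pass filter (default 4th-order
   Butterworth at 500 Hz), Hann/512/50%-overlap spectrogram,
   RMS-envelope call segmentation, adaptive-threshold pulse detection
   with hysteresis, and spectral measurement per call. Pulse rate is
   `(pulse_number − 1) / (last onset − first onset)`.
2. **variation** — coefficients of variation at four levels (within
   individual, across individuals within a locality, within a
   geographic group, and overall across individual means), variability
   classification (static < 5% ≤ intermediate ≤ 12% < dynamic),
   discriminability ratios `CV_o / mean CV_i` and `CV_o / mean CV_g`,
   and a random-effects one-way ANOVA with η².
3. **temperature** — per-parameter OLS on recording temperature and a
   linear shift of significant parameters to a common reference
   temperature (`x − b·(T − T_ref)`); pulse number is exempt.
4. **geography** — haversine distances between localities and
   per-parameter Mantel permutation tests against absolute differences
   of locality means (exhaustive enumeration for ≤ 5 localities).
5. **group_comparison** — Shapiro–Wilk per group decides Student
   t-test (+ Bartlett) vs. Wilcoxon rank-sum (+ Levene); Gaussian KDE
   summaries with Silverman bandwidth.
6. **synthetic_data** — ground-truth generators: pulsatile call audio
   (raised-cosine pulse trains) and seeded hierarchical measurement
   tables with configurable locality/individual/within-call variance
   components, defaulting to the bundled nine-site survey design.

## CLI

```sh
# synthetic study-shaped dataset + full analysis
callvar simulate --out runs/demo --seed 1

# measure audio: metadata CSV needs individual_id, locality, group,
# latitude, longitude, temperature_c, wav_path
callvar measure --metadata meta.csv --out runs/m

# analysis stages from a per-call measurement CSV
callvar analyze --measurements runs/m/measurements.csv \
    --metadata meta.csv --out runs/a --seed 1

# audio end-to-end
callvar all --metadata meta.csv --out runs/full --seed 1
```

Outputs per run: `measurements.csv` (one row per call),
`variation.csv`, `temperature_models.csv`, `corrected_means.csv`,
`mantel.csv`, `group_comparison.csv`, `kde/<parameter>.json`, and a
`manifest.json` with the seed and config hash. Re-running with the
same seed reproduces the result tables byte-for-byte, and re-running
`analyze` from a persisted `measurements.csv` reproduces the
downstream tables exactly. A YAML config file (`--config`) can supply
any `RunConfig` field.

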