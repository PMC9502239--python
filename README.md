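# walkpd

Detection of Parkinson's disease (PD) from **free-living, wrist-worn
inertial sensor data** — multi-day triaxial accelerometer + gyroscope
recordings collected without supervision or activity labels.

Motor PD signs (bradykinesia, gait changes, 4–9 Hz tremor) surface while a
person walks, so the pipeline first isolates walking from the unconstrained
stream with rules-based human-activity recognition, then classifies only
those moments:

1. **Preprocess** — anti-alias filter and down-sample 100 Hz → 20 Hz, cut
   non-overlapping 5-s windows that never cross a day boundary.
2. **Dynamic gate** — per subject, an adaptive threshold from day 1 only:
   half the maximum dominant-axis detrended mean absolute value (MAV);
   windows whose dominant-axis accelerometer MAV exceeds it are *dynamic*.
3. **Walk-like detection** — Welch PSD of the dominant gyroscope axis; a
   dynamic window is *walk-like* when mean power in the 0.6–2 Hz walking
   band beats the rest of the spectrum and clears an absolute floor
   (100 (deg/s)²/Hz).
4. **Event classification** — a 1D CNN (four conv blocks, kernel 5, stride
   2, channels 8→16→32→64, batch norm + ReLU, 50% dropout, softmax head;
   pure NumPy, bit-reproducible) maps each 6×100 walk-like window to P(PD).
5. **Daily diagnosis** — majority vote over each day's event predictions,
   evaluated with leave-one-subject-out (LOGO) cross-validation on each
   subject's first 10 recorded days plus 5-day temporal holdouts 1–3 months
   out. Four classical baselines (logistic regression, random forest,
   gradient-boosted trees, elastic net) run on 35 hand-crafted features
   under identical folds.

Real PD wearable cohorts of this kind are access-restricted, so the package
ships a `synthetic` module that generates labelled free-living-like cohorts
(gravity + noise at rest, broadband non-walk bursts, quasi-periodic walk
bouts; PD subjects get attenuated walking amplitude, a 4–6 Hz tremor tone,
extra cycle-time jitter, and less daily walking). Every claim the test suite
makes is against this generator — see `docs/methods.md` for the signal model
and its limits.

## Worked example

Simulate a small labelled cohort and run the detector:

```bash
cat > run.yaml <<EOF
n_hc: 2
n_pd: 2
day_indices: [0, 1]
wear_hours_per_day: 0.1
seed: 7
EOF
walkpd simulate --config run.yaml --out sim
walkpd ingest --config run.yaml --raw sim --out ing
walkpd detect-walks --config run.yaml --windows ing --out det
```

which prints

```
simulated 8 subject-days -> sim
ingested 576 windows -> ing
windows in: 576, dynamic: 150, walk-like: 126 -> det
```

576 five-second windows survive ingestion (4 subjects × 2 days × ~6 min of
wear each, 20 Hz); 150 pass the adaptive amplitude gate (the rest is
resting wrist), and 126 of those show walking-band-dominant gyroscope
spectra — the walk-like events that feed the classifier. `det/` now holds
`annotations.csv` (per-window label, dominant axes, band powers),
`thresholds.csv` (the per-subject day-1 thresholds) and `walk_windows.csv`.

A full evaluation — simulate, detect, LOGO-train the CNN, vote daily,
score month-out holdouts — is one command (several minutes):

```bash
walkpd evaluate --config eval.yaml --out results/   # same keys as run.yaml,
                                                    # e.g. 4+4 subjects, 10 days
```

The library mirrors the CLI: `walkpd.synthetic.SimulationConfig`,
`walkpd.evaluation.prepare_cohort_windows`, `walkpd.evaluation.run_logo_cv`.

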