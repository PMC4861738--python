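# eegbench

Benchmark metrics for assessing EEG system quality in stationary vs. moving
recording conditions, built around an auditory oddball (P300) paradigm.

The package provides:

- **core** — domain types (`Recording`, `EventList`, `EpochSet`,
  `ERPWaveform`, `Montage`, `BandSet`, `MetricTable`), the 12-channel
  benchmark montage (Fpz, F3, Fz, F4, C3, Cz, C4, P3, Pz, P4, O1, O2) and
  BDF/EDF/CSV readers and writers. All amplitudes are microvolts.
- **preprocess** — zero-phase high-pass (default 1 Hz) and mains notch
  filtering, inverse-distance bad-channel interpolation, epoch extraction
  (−0.3 to 0.8 s around stimulus onset) and behavioral rejection of false
  positives / false negatives.
- **rejection** — sliding-window peak-to-peak amplitude (200 ms window,
  100 ms step), single-threshold rejection (canonical 75 μV), the
  75–400 μV threshold sweep, amplitude histograms (25 μV bins) and
  matched-count rejection across two conditions.
- **metrics** — pre-stimulus noise (RMS over −300 to 0 ms), band power via
  segment-averaged periodograms (256-point FFT, 128-sample Hamming
  segments), walking/seated power ratio, P300 SNR (peak in 300–500 ms over
  trial-averaged PSN), per-trial coefficient of variation and its epoch
  average (CV_ERP), and scalar-product ERP similarity with Fisher-domain
  averaging.
- **reliability** — test-retest ICC (single-measure, absolute agreement,
  two-way model), Cohen's d, and poor/moderate/good classification.
- **synth** — a deterministic oddball-session simulator (4 blocks × 160
  trials, 25% targets, 1420–1580 ms ISI) with a P300-like evoked bump, 1/f
  noise, alpha oscillation, a 1.2 Hz gait-locked artifact and optional
  blinks, so every pipeline stage is testable without recorded data.
- **pipeline / cli** — config-driven end-to-end runs producing metric
  tables, rejection curves, similarity tables and a reproducibility log.

## Command-line usage

```bash
# simulate a session (BDF or CSV inferred from suffix)
eegbench simulate --out session.csv --events events.json --seed 7

# epoch + amplitude-rejection statistics
eegbench reject --recording session.csv --events events.json \
    --thr 75 --sweep 75:400:25 --hist-bin 25

# single-condition metric table
eegbench metrics --recording session.csv --events events.json \
    --psn-window -0.3:0 --p300-window 0.3:0.5 --out metrics.csv

# full two-condition benchmark from a YAML config
eegbench run --config config.yaml --out-dir benchmark_out

# test-retest reliability from two metric tables
eegbench reliability --metric PSN --sessions test.csv retest.csv

# percent change between two metric tables
eegbench compare metrics_a.csv metrics_b.csv
```

A minimal `config.yaml` for `eegbench run`:

```yaml
subject: S01
system: SIM
threshold_uv: 75
conditions:
  - name: seated
    recording: seated.csv       # events embedded in the CSV sidecar JSON
  - name: walking
    recording: walking.csv
```

## File formats

- CSV recordings: header row of channel labels, one row per sample, and a
  `<name>.csv.json` sidecar holding the sampling rate, metadata and
  (optionally) events.
- BDF (24-bit) and EDF (16-bit) continuous files per the published formats.
- Events: JSON with `onsets` (0-based sample indices), `labels`
  (`target` / `non-target`) and `responses` (button-press samples).
- Metric tables: long-format CSV keyed by
  (subject, system, condition, channel, metric).
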