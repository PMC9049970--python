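# trrkit

Simulation and analysis of task-locked hemodynamic responses (TRRs) in
slow event-related designs, built around a fully synthetic data generator.

The package simulates a visual discrimination experiment — 15-s trials
(0.2-s stimulus + 14.8-s ISI), 16 trials per 240-s run, easy runs at a fixed
±20° tilt (~90% correct) and hard runs driven by a one-up/two-down staircase
(~70.7% correct) — together with every signal stream the analysis consumes:
ROI BOLD percent-signal-change series at TR = 1.5 s, 50-Hz pulse-oximeter and
respiration-belt traces, six head-motion parameters, and 500-Hz pupil/gaze
recordings with blinks (short 3.8-s-ISI protocol). It then runs the full
analysis chain and recovers the injected ground-truth parameters.

## What's inside

| module | contents |
|---|---|
| `trrkit.synthdata` | behavior tables, staircase, ground-truth gains/jitter, BOLD/physio/motion/pupil generators |
| `trrkit.hrf` | six-parameter double-gamma HRF: evaluation, canonical defaults, simplex fitting |
| `trrkit.design` | HRF-convolved task regressors (trial onset, button press, time-on-task), condition indicators, cardiac/respiration predicted-BOLD columns, motion, factorial interactions — 24 fixed-effect columns |
| `trrkit.preprocess` | percent change, global-signal regression, nuisance projection, ROI averaging, epoching with first-trial removal and lapse partitioning |
| `trrkit.spectral` | sinusoid/Fourier amplitude and phase at the 1/15-Hz task frequency; angular deviation √(2(1−R)) of per-trial phases |
| `trrkit.physio` | sub-sample pulse-peak refinement (flank-line intersection), heart rate, RMSSD, HR acceleration, respiration volume/frequency/variability in 15-s bins |
| `trrkit.pupil` | deblinking (piecewise-cubic), zero-phase 0.03–10 Hz Butterworth band-pass, task-evoked averages, fixation stability |
| `trrkit.stats` | mixed model (random intercept + slopes per observer) with Wald contrast F-tests, permutation tests with the (b+1)/(m+1) exact-p correction, two-stage adaptive FDR, visual-field border test, RT-modulation simulation |
| `trrkit.io` / `trrkit.cli` / `trrkit.config` | BIDS-style events TSV, gzipped physio TSV + JSON sidecar, BOLD TSV, TOML config, `trrkit` command line |

## CLI

```sh
trrkit simulate  --seed 1 --out runs/demo     # write a synthetic session
trrkit preprocess --out runs/demo             # ROI series + epochs
trrkit report     --out runs/demo             # counts, spectra, variability
trrkit permtest   --out runs/demo             # physio condition tests
trrkit analyze    --seed 1 --out runs/demo    # cohort GLMM + contrasts
trrkit pupil      --seed 1 --out runs/demo    # pupillometry pipeline
```

All commands accept `--config c.toml` (see `trrkit.config.RunConfig` for the
keys) and are byte-reproducible for a fixed config + seed.

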