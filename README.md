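# painbci

Closed-loop pain detection from EEG and skin conductance (SC), built as a
reusable, fully testable toolkit:

* **Offline decoding** — band-pass filtering (EEG 3–40 Hz order-2000
  Hamming-sinc FIR; SC 0.05–2 Hz Chebyshev-I order 3), centro-parietal
  channel selection (Cz, C3, C4, CPz, CP1, CP2), running observation
  windows (EEG 500 ms / 80 % overlap, SC 2 s / 80 %, patient 1 s / 0 %),
  peak-to-peak artifact rejection (150 µV / 10 µS), spectral + entropy EEG
  features and eleven SC amplitude descriptors, z-scoring, and an RBF-SVM
  (C = 1, γ = 0.01) evaluated with stimulus-grouped four-fold
  cross-validation so overlapping windows never leak across folds.
* **Online simulation** — deterministic playback streaming of recorded (or
  synthetic) sessions; per-chunk classification (0.5-s EEG chunks, rolling
  2-s SC window), per-second fusion by a weighted mean of the most recent
  posteriors, strict-threshold trigger release with a refractory period,
  trigger scoring against a response window (stimulus onset through 4 s
  past its end), modality-contribution accounting, a patient-mode
  majority-vote engine over 6-s chunks, and the Gaussian pulse-width
  envelope for the stimulation side.
* **Synthetic sessions** — seeded generators for the healthy protocol
  (randomized 12×P/12×NP/12×R, 4 s stimulation, 8 s ISI) and the patient
  protocol (six minutes of alternating 30-s rest/focus blocks), with EEG
  pain signatures (reduced alpha/beta/total power and RMS, increased
  spectral/sample entropy and fractal dimension) and stimulus-locked
  double-exponential SC responses. Everything in the repository runs with
  no external data.
* **Statistics** — Shapiro–Wilk normality gate, tie-corrected Friedman
  omnibus with all-pairs rank post hoc, paired *t* with Cohen's d and
  post-hoc power, and per-feature direction reports.

## Command line

All commands accept `--config <yaml>`, `--seed <int>`, `--log-level`.

```bash
# write a synthetic subject (CSV recordings + BIDS-style events TSV)
painbci --seed 0 simulate --out sim/ --subjects 1

# feature tables
painbci features --eeg sim/sub-00_eeg.csv --events sim/sub-00_events.tsv --out eeg.csv
painbci features --sc  sim/sub-00_sc.csv  --events sim/sub-00_events.tsv --out sc.csv

# train decoders and evaluate offline (grouped 4-fold CV)
painbci train --features eeg.csv --modality EEG --out eeg.decoder.zip
painbci train --features sc.csv  --modality SC  --out sc.decoder.zip
painbci evaluate-offline --features eeg.csv --out cv.json

# replay the session through the online engine, then re-score the log
painbci stream --eeg sim/sub-00_eeg.csv --sc sim/sub-00_sc.csv \
    --events sim/sub-00_events.tsv \
    --eeg-decoder eeg.decoder.zip --sc-decoder sc.decoder.zip \
    --out decisions.jsonl
painbci evaluate-online --log decisions.jsonl --events sim/sub-00_events.tsv --out online.json

# feature direction + significance report
painbci stats --features sc.csv --out directions.csv
```

Recordings are stored either as EDF or as a plain channels×samples CSV
with a JSON sidecar (`<file>.csv.json`) carrying sampling rate, channel
names and modality. Decoder artifacts are zip files (JSON metadata +
scaler arrays + fitted model).

## Layout

```
src/painbci/
  signal_io.py   recordings, events, decoder artifacts, playback streaming
  _edf.py        minimal EDF codec (plain 16-bit flavour)
  preprocess.py  filters, channel selection, windowing, artifact rejection
  features.py    PSD/band-power/entropy/fractal EEG features, SC descriptors
  decode.py      z-scoring, SVM training, grouped CV, metrics
  online.py      healthy + patient engines, fusion, triggers, pulse envelope
  synthetic.py   protocol schedules and signal generators
  stats.py       normality gate, Friedman + post hoc, paired t, directions
  pipeline.py    end-to-end offline recipes
  config.py      YAML configuration
  cli.py         click CLI (`painbci`)
```
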