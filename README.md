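# cbci — collaborative BCI group decisions

A toolkit for confidence-weighted and *anytime* group decision-making from
EEG, reconstructed response times (RTs) and self-reported confidence, in
two-alternative perceptual tasks.

It implements the full pipeline:

1. **`cbci.simulate`** — a seeded generator of complete synthetic
   experiments (behavioural trial tables, response-locked EEG epochs with
   a fronto-central correct-vs-incorrect component, and per-trial video
   frame streams with a hidden character-appearance step), so every stage
   is testable without any recording.
2. **`cbci.preprocess`** — continuous-EEG conditioning: zero-phase 0.15–40 Hz
   band-pass, ocular-artifact regression against the mean of the Fp1−F1 and
   Fp2−F2 derivations, response-locked epoching (−1700 … +200 ms), per-epoch
   detrend, equiripple (Remez) 14/16 Hz low-pass, decimation to 32 Hz and
   trimming to the 1500 ms ending at the response (48 samples/channel).
3. **`cbci.onsets`** — stimulus-onset reconstruction: backward scan of the
   frame stream from each response for the most recent supra-threshold
   inter-frame mean-RGB change, with fall-back to the previous trial's
   onset; RT = response time − onset time.
4. **`cbci.confidence`** — per-trial probability-of-correctness from CSP
   log-variance features (first + last components), reconstructed RT and
   optionally reported confidence, via 8-fold cross-validated random
   forests (100 trees, Gini); every confidence is out-of-fold.
5. **`cbci.groups`** — group decisions `sign(Σ w·d)` over all member
   combinations, with majority, dictator and confidence-weighted
   strategies, bootstrap SEMs per group size.
6. **`cbci.anytime`** — a group decision at every 100 ms tick after the
   first response, morphing each member from the without- to the
   with-reported-confidence estimator as their report arrives.
7. **`cbci.stats`** — exact-small-sample Wilcoxon signed-rank (with
   midranks), Holm step-down adjustment, bootstrap SEM, and grand-average
   ERP comparisons with pointwise significance masks.
8. **`cbci.io` / `cbci.cli`** — CSV/HDF5 data contracts and the command
   line.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (combinatorics,
preprocessing arithmetic, brute-force vote and CSP oracles, RT
reconstruction exactness, statistical-machinery oracles, pipeline ordering
on the default synthetic benchmark, anytime equivalence, and calibration).
The heavier end-to-end fixtures take a few minutes on one CPU.

## CLI

```sh
cbci simulate --seed 42 --out-dir out/               # synthetic experiment
cbci preprocess --epochs out/epochs_raw.h5 --out out/epochs_32hz.h5
cbci detect-onsets --frames out/frames.csv --trials out/trials.csv --out out/onsets.csv
cbci train    --config cfg.yaml --schema nf+rt --out-dir out/model/
cbci decide   --config cfg.yaml --strategy nf+rt+conf --out out/accuracy.csv
cbci anytime  --config cfg.yaml --pair cbci --out out/anytime.csv
cbci evaluate --config cfg.yaml --out-dir out/eval/
```

`cfg.yaml` holds a `simulate:` section with any `SimConfig` field, e.g.

```yaml
simulate:
  n_participants: 10
  accuracy_range: [0.65, 0.95]
  fs_raw: 128        # multiple of 32; up to 2048
  n_channels: 16     # up to 64
  seed: 42
```

## Data formats

- **Trial table (CSV)**: `participant_id, block, trial_id, true_label,
  decision, response_timestamp_s, reported_confidence,
  confidence_timestamp_s, correctness`; labels/decisions are ±1 (0 = empty
  trial), confidence on the 0–100 step-10 grid, missing values empty.
- **Frame stream (CSV)**: `trial_id, frame_index, timestamp_s, mean_r,
  mean_g, mean_b`.
- **Epochs (HDF5)**: `/participants/<id>/data` (trials × channels ×
  samples) with `fs`, `window_ms`, `channel_names` attributes plus
  `trial_ids`/`labels` datasets. Conditioned sets are 32 Hz, window
  (−1500, 0) ms, 48 samples.
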