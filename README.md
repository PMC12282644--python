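# agidet

A multimodal agitation-detection pipeline for dementia-care settings,
built as a fully tested, synthetic-data-driven artifact:

* **Wristband channel** — cleaning/filtering of raw wearable streams
  (3-axis accelerometer, electrodermal activity, skin temperature, pulse),
  1-minute window segmentation, a ~150-feature multi-domain vector
  (statistical, time, frequency, wavelet sub-band), and classical
  classifiers (Extra Trees, Gradient Boosting, Random Forest, MLP) under
  personalized (per participant) and general (pooled) 70/30 protocols with
  minority up-sampling and paired statistical comparison.
* **Video channel** — geometric features from 14-keypoint skeletal streams
  (temporal displacements, root distances, trunk-normalized positions,
  angles), correlation-threshold feature reduction (0.8), 30-s / 1-s-stride
  sliding windows, and single-cell GRU/LSTM classifiers with a sigmoid
  head (pure NumPy, deterministic, gradient-checked).
* **Event engine** — assembles streaming window decisions into detection
  events with 5-minute pre/post context buffers, computes alert lead times
  against ground truth, and manages the append-only alert log plus the
  review/retrain store.
* **Synthetic generators** — wristband sessions, minute-level digital
  biomarkers and pose sequences with scheduled agitation episodes
  (2–23 min), 7-minute pre-agitation ramps, per-participant dominant-channel
  rotation, and motor behaviors (idle/walk vs pace/rock/kick/flail), all
  deterministic under a seed.  The clinical data behind the original study
  are private; every downstream stage is exercised on these generators.

## Tests

```sh
python -m pytest -q tests/
```

Unit and property tests run in seconds; `tests/test_acceptance.py` holds
the acceptance criteria (oracle equivalences, closed-form window counts,
permutation nulls, the personalized-vs-general ordering, GRU/LSTM AUC and
reduction stability, the ≥6-minute lead-time property, and end-to-end
determinism) and takes a few minutes.

## CLI

```sh
# materialise a 10-participant synthetic cohort bundle
agidet simulate --out scratch/bundle --participants 10 --seed 1

# run pipeline stages on a fresh synthetic cohort
agidet run --out scratch/run --stage physio --participants 5 --seed 1
agidet run --out scratch/run --stage pose --seed 1
agidet run --out scratch/run --stage all --seed 1
```

Every output directory receives `config.json` (exact config + seed) and a
structured JSON-lines `run.log`.  Configuration is YAML
(`--config config.yaml`) with sections `physio`, `pose`, `models`,
`sequence`; all defaults match the published protocol values where they
exist (1-min wristband windows, 30-s/1-s pose windows, 0.8 correlation
threshold, 70/30 split, Adam, batch 256).

## Layout

```
src/agidet/
  data_model.py       core types, CSV/JSON-lines IO, window labelling
  synthetic.py        physio/pose/cohort generators
  physio_features.py  preprocessing, EDA decomposition, segmentation, features
  physio_models.py    classifiers, protocols, metrics, paired comparison
  pose_features.py    geometric features, correlation reduction, windows
  sequence_models.py  NumPy GRU/LSTM + training protocols
  event_engine.py     episode assembly, buffers, lead times, alerts, review
  pipeline.py         end-to-end orchestration
  cli.py              `agidet` command-line interface
```
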