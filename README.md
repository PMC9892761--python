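# xfnirs

Sliding-window fNIRS brain-state classification with Shapley-value channel
explanations.

The pipeline takes raw two-wavelength optical intensity recordings (or
simulates them), converts them to hemoglobin concentration changes via the
modified Beer-Lambert law, frames the multichannel series into overlapping
labeled windows, classifies left/right/rest states with small 1-D CNN and
LSTM networks, and explains the CNN's decisions by DeepLIFT-rescale
Shapley-value attribution (DeepSHAP) aggregated to named optode channels.

The neural networks, their training loop, and the attribution backprop are
implemented in NumPy — no deep-learning framework is required.

## Modules

| module | role |
| --- | --- |
| `xfnirs.io_preproc` | read recordings (csv+json dialect, minimal SNIRF), zero-phase 0.01–0.2 Hz band-pass, CV > 7.5 % channel rejection, optical density, Beer-Lambert conversion |
| `xfnirs.windowing` | sliding-window framing (M − WS frames at stride 1), majority / latest-second block labeling, stratified splits, z-scoring, HDF5 serialization |
| `xfnirs.models` | CNN (conv 32×3 → pool 2 → dense 500/120/3) and LSTM (120 units, sequence output) classifiers, Adam training, metrics, k-fold / repeated-split cross-validation with permuted-label controls |
| `xfnirs.explain` | DeepSHAP attribution of pre-softmax class scores, exact Shapley / interaction enumeration oracles, channel relevance ranking, beeswarm and dependence data |
| `xfnirs.synthetic` | ground-truthed generator: block paradigms, double-gamma HRF, planted lateralized channels, physiological noise, inverse Beer-Lambert down to raw intensities |
| `xfnirs.cli` | `xfnirs` command: `simulate`, `preprocess`, `train`, `evaluate`, `explain`, `all` |
| `xfnirs.nn` | NumPy layers (Conv1D, MaxPool1D, Dense, LSTM, Dropout), Adam, softmax cross-entropy |

## CLI

```sh
# end-to-end run on the synthetic fixture
xfnirs all --seed 1 --out runs/demo

# write a synthetic raw recording and preprocess it
xfnirs simulate --seed 1 --out runs/sim --preset datasetA
xfnirs preprocess runs/sim/recording.csv --out runs/sim/hemo.csv

# cross-validate a model; add --permute-labels for the chance control
xfnirs evaluate --seed 1 --model-kind lstm --out runs/eval
```

A run directory contains `config.yaml` (resolved config + hash),
`cv_report.csv`, `summary.json`, `channel_relevance.csv`, `beeswarm.csv`
and `attributions.h5`; identical configs reproduce identical reports.
Options can also come from a YAML config (`--config path`), with `--seed`
overriding the config seed.

## Data formats

- **csv+json dialect**: `<stem>.csv` with header `time,<chan>_<λ1>,<chan>_<λ2>,…`,
  plus `<stem>.montage.json` (names, distances, regions, wavelengths,
  sampling rate) and `<stem>.events.json` (`onset_s`, `duration_s`, `label`
  in {left, right, rest}).
- **SNIRF**: minimal continuous-wave reader (`read_recording(path, format="snirf")`).
- Hemoglobin export: `time,<chan>_HbO,…,<chan>_HbR,…,label` CSV.
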