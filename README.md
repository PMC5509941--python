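# musicmvpa

Encoding and decoding of musical features from fMRI multivoxel patterns.

The package implements a complete analysis pipeline for event-related music
listening experiments (25 six-second clips in 5 genres, 8 runs):

* **Stimulus features** (`musicmvpa.music_features`) — monophonic melody
  transcriptions on a 16th-note grid are encoded as binary pitch-class
  indicator matrices in absolute pitch and transposed to C (relative pitch);
  audio is folded into 12 pitch-class energy bands (chromagram). All three
  representations are resampled to a 0.1 s frame clock (60 x 12 per 6 s
  stimulus), reduced by SVD retaining >= 95% variance (fitted on training
  stimuli only), and stacked frame-wise into per-stimulus vectors.
* **GLM responses** (`musicmvpa.glm`) — per-voxel OLS on event boxcars
  convolved with a canonical double-gamma HRF, plus constant/linear-trend
  nuisance terms, yielding stimulus x run x voxel beta patterns.
  Z-scoring is folded into cross-validation (training-cell statistics only).
* **Decoding** (`musicmvpa.decoding`) — ANOVA voxel selection on dedicated
  selection runs (1 and 4, top 5,000 F-scores), linear SVM with
  C = 1 / (mean training-pattern L2 norm); song classifiers cross-validated
  leave-run-out, genre classifiers leave-one-stimulus-per-genre-out; group
  confusion matrices compared with behavioral confusions by Spearman
  correlation over strictly-upper-triangle cells.
* **Searchlight encoding** (`musicmvpa.searchlight`) — radius-3 voxel
  spheres on a scattered center lattice (spacing 3, random offset); ridge
  regression from feature vectors to sphere patterns, scored by the
  correlation-error probability (1 - p of the prediction/observation
  Pearson correlation); 5 held-out stimuli x 8 runs x 10 repetitions = 400
  tests per sphere.
* **Group statistics** (`musicmvpa.group_stats`) — per-subject
  randomized-target null maps, subject-wise bootstrap of group means,
  voxel-wise p < 0.001 thresholding, and FWE cluster correction (p < 0.05)
  against the null distribution of maximum cluster size; cluster tables
  report size, max, mean, std, center of mass, and cluster-level p.
* **Synthetic data** (`musicmvpa.synthetic_data`) — generators for all
  pipeline inputs with planted ground truth: genre-structured random-walk
  melodies, polyphonic chromagrams (chords, bass, amplitude modulation,
  noise, RMS balancing, onset/offset ramps), labeled brains whose regions
  linearly encode chosen feature kinds, HRF-convolved voxel time series at
  controlled SNR, and behavioral genre-confusion matrices.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes per-module unit tests, property tests (hypothesis), and
`tests/test_acceptance.py`, which implements the acceptance criteria
(sphere geometry, scattering economy, test-count bookkeeping, feature
dimensions, null decoding calibration at 4% / 20% chance, voxel-threshold
calibration, noise-free parameter recovery, planted-region recovery, and
oracle equivalences). Tests marked `slow` take a few minutes.

## CLI

```sh
musicmvpa run-all --config examples/demo_config.json --out scratch/demo
musicmvpa report --results scratch/demo
```

`run-all` executes simulate -> features -> GLM -> decoding -> searchlight ->
group statistics on synthetic data and writes NIfTI maps, events TSVs, beta
archives, cluster CSVs, and a `summary.json` with full provenance (config
hash + seeds). Individual stages are available as `simulate`, `features`,
`glm`, `decode`, `searchlight`, and `group-stats`; see `musicmvpa --help`.

## Notes on defaults

* Ridge penalty for searchlight encoding defaults to `lambda = 1.0` on
  z-scored data (configurable; the scale matters little at the default
  training size).
* Group-statistics defaults are desk-scale (20 null models/subject, 10,000
  bootstrap samples); publication-scale values (100 / 100,000) are plain
  config settings.
* Synthetic EPI volumes can be generated in float32 (`dtype=`) for speed;
  float64 is the default.
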