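# stimselect

Quantifying the **movement selectivity and diversity of peripheral-nerve
stimulation paradigms** from pose-estimation keypoint trajectories.

A multi-contact nerve cuff (here: 64 channels around the rat sciatic nerve)
can deliver stimulation in many electrode configurations and with different
waveforms — temporal interference stimulation (TIS: two kHz sinusoid pairs
beating at |f₁ − f₂|) or conventional charge-balanced biphasic pulses.  A
paradigm is *selective* if distinct configurations evoke distinct,
reproducible limb movements.  `stimselect` measures that from video-tracked
keypoints (DeepLabCut-dialect CSVs of hindlimb keypoints: hip, knee, ankle,
heel, instep, five toes) and a timestamped stimulation sweep log.

The package is aimed at neural-engineering and computational-ethology
groups who run configuration sweeps and want an unsupervised, quantitative
readout of which paradigm moves the limb more specifically and more
diversely.

## What it computes

1. **Preprocessing** — mask keypoints with tracking likelihood < 0.5,
   impute with the per-keypoint median, flatten (x, y) to per-keypoint
   Euclidean magnitudes (a T×10 position matrix), z-score, and gate out
   configurations whose stimulation-ON limb speed never exceeds a
   rest-epoch velocity threshold.
2. **Clustering arm** — per-animal 3-D UMAP embedding + HDBSCAN clusters
   (published presets per stimulation type), scored against the electrode
   configurations by **adjusted mutual information**

   AMI(U, V) = [MI(U, V) − E{MI}] / [½(H(U) + H(V)) − E{MI}],

   with row-shuffle and Gaussian-noise null controls that destroy the
   configuration↔movement correspondence.
3. **Syllable arm** — a sticky autoregressive HMM (VAR emissions in a 3-D
   latent, stickiness κ, AR-only phase then full phase) segments the pose
   dynamics into behavioral *syllables*; cosine-distance dendrograms
   summarize syllable diversity.
4. **Selectivity score** — for configuration *i* with syllable proportions
   p_ij and N total syllables in the trial:

   H_i = −Σ_j p_ij ln p_ij,  Selectivity_i = 1 − H_i / ln N ∈ [0, 1].

5. **Group statistics** — bootstrap resampling of scores (resample size
   100, 1000 iterations, 95% percentile CIs), beta regression with a logit
   mean link, Mann–Whitney U, Cohen's d and Cliff's delta.

A synthetic-trial generator with known configuration→motif ground truth
(stable latent VAR motifs, 5 s ON / 5 s OFF epochs at 60 fps, likelihood
dropouts, tracking noise; selective and non-selective regimes) makes every
stage testable without any recordings.

## Worked example

```python
import stimselect as ss

# simulate a selective trial: 8 configurations, one movement motif each
lib = ss.make_motif_library(range(1, 9), regime="selective", seed=3)
series, epochs, truth = ss.generate_trial(ss.TrialSpec(n_configs=8, seed=3), lib)

matrix = ss.preprocess_series(series, epochs)          # T x 10, z-scored
emb = ss.embed(matrix, profile="custom", seed=42)      # 3-D UMAP
clusters = ss.cluster_density(emb.coords, profile="custom")
on = matrix.epoch_tag != "OFF"
print("AMI vs configurations:", round(ss.ami(clusters[on], matrix.epoch_tag[on]), 3))

shuffled = ss.null_controls(matrix, "row_shuffle", seed=5)
emb_s = ss.embed(shuffled, profile="custom", seed=42)
clusters_s = ss.cluster_density(emb_s.coords, profile="custom")
print("AMI after row shuffle:", round(ss.ami(clusters_s[on], matrix.epoch_tag[on]), 3))
```

prints

```
AMI vs configurations: 0.959
AMI after row shuffle: 0.002
```

— the clusters align almost perfectly with the electrode configurations
(AMI ≈ 0.96), and destroying the frame↔epoch correspondence collapses the
agreement to chance level (AMI ≈ 0), showing the structure is real and not
an artifact of the embedding.

The full synthetic study (both regimes, both arms, group statistics) is one
call:

```bash
stimselect run-all --seed 0 --outdir study
```

which writes per-stage CSVs, figures and `study/summary.json` with AMI per
subject, per-configuration selectivity, bootstrap CIs, beta-regression and
effect sizes.

## Layout

```
src/stimselect/
  io.py          DLC-dialect CSV + sweep-log formats, KeypointSeries
  synthgen.py    synthetic trials with known configuration->motif structure
  preprocess.py  likelihood filter, median imputation, flattening, gating
  embedding.py   UMAP + HDBSCAN + K-means, AMI, null controls, tuning
  syllables.py   sticky AR-HMM, syllable statistics, cosine dendrograms
  selectivity.py entropy score, bootstrap, beta regression, effect sizes
  stimconfig.py  cuff sweeps, labeling, TIS envelope, charge metrics
  pipeline.py    end-to-end orchestration with per-stage seeds
  cli.py         `stimselect` subcommands (simulate / preprocess / ... / run-all)
```

See `docs/methods.md` for the model details, parameter choices and known
limitations.
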