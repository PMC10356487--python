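# kicksense

Football motion recognition and intensity estimation from a single
ankle-worn wearable IMU.

Coaches and sports scientists who instrument players with low-cost inertial
sensors (tri-axial accelerometer + tri-axial gyroscope) need two answers per
motion: *which* basic action was performed (e.g. inside-foot pass vs. arch
shot) and *how intensely* it was executed. kicksense implements a complete,
tested pipeline that answers both with one model:

1. **Preprocessing** — three-point moving-average denoising and automatic
   segmentation by peak detection on the acceleration norm.
2. **Spectral min/max features** — a short-time Fourier transform per
   sensor per window; the S smallest and L largest power densities,
   pooled over all time–frequency cells, form an ordered
   (SA, LA, SG, LG) feature matrix per window.
3. **Local-mean downsampling augmentation** — each feature matrix spawns
   half- and quarter-resolution variants by pairwise row averaging
   (dataset size triples), plus seeded per-class row randomization.
4. **Multitask LSTM** — a shared recurrent encoder feeding two heads in a
   single forward pass: a softmax classifier over C motion classes and a
   regression head estimating a nonnegative intensity, trained under the
   weighted composite loss

       L = α_c · Lc + α_i · Li,

   where Lc is the cross-entropy `−(1/N) Σ_i Σ_c 1[y_i ∈ C_c] · log p(y_i ∈ C_c)`,
   Li the mean squared intensity error, α_c = 1 and α_i = 0.001
   (count-mode default) or 0.1 (completion-rate mode). Optimization is
   Adam with decoupled weight decay plus an elastic L1+L2 penalty; the
   network (including backpropagation through time) is implemented in
   NumPy and verified against numerical gradients.
5. **Evaluation** — accuracy, macro F1 and mAP for classification, MAE and
   MAPE for intensity; stratified splits, k-fold and leave-one-subject-out
   cross-validation, and single-task vs. multitask comparison tables.

A seeded synthetic generator emulates the study conditions (two spectrally
disjoint motion classes, 20 motions per class per subject, integer
intensity levels driven by burst amplitude), so every stage is testable
without any data download. An adapter for the public UCI-HAR text layout
is included. See `docs/methods.md` for the model, its assumptions and all
numerical choices.

## Worked example

```python
import kicksense as ks

recordings, windows = ks.generate_dataset(ks.SyntheticConfig(n_subjects=3, seed=7))
cfg = ks.FeatureConfig(S=8, L=8)
samples = [ks.extract_features(w, cfg) for w in windows]

train, test = ks.split_train_test(ks.AugmentedDataset(samples=samples), 0.8, seed=7)
train = ks.randomize_within_class(ks.augment(train.samples), seed=7)

model_cfg = ks.MultitaskModelConfig(num_classes=2, batch_size=100, seed=7)
results = ks.MultitaskLSTM.from_dataset(train, config=model_cfg).fit(iterations=2000)
print(results.summary())

report = ks.evaluate_model(results, test)
print(f"accuracy={report.accuracy:.3f}  F1={report.f1:.3f}  "
      f"mAP={report.mAP:.3f}  MAE={report.mae:.3f}")
```

prints

```
Multitask LSTM results
==============================================
LSTM layers                 1
Hidden units                32
Extra FC units (regress.)   32
Classes                     2
Trainable parameters        5891
Iterations run              2000
alpha_c / alpha_i           1.0 / 0.001
Intensity mode              count
Final Lc                    0.335079
Final Li                    1.991560
Final total loss            0.402706
==============================================
accuracy=0.833  F1=0.833  mAP=0.931  MAE=1.000
```

Three synthetic subjects yield 120 labeled windows; at S = L = 8 each
window contributes 16 feature vectors, and augmentation triples the
training pool (288 samples). After a short 2,000-iteration run the model
classifies 83% of held-out windows correctly and estimates the 0–10
integer intensity with a mean absolute error of 1.0 level; longer training
on the full default generator (10 subjects, 400 windows, 14,000
iterations) reaches ≥ 0.90 held-out accuracy with MAE ≤ 1.0 — that
experiment runs as part of the test suite.

The fitted `results` object also exposes `predict()` (both heads from one
forward pass), `training_log` (per-iteration Lc, Li, total loss) and
`plot_training()`.

## Command line

Every stage is also a subcommand of the `kicksense` CLI:

```sh
kicksense simulate --seed 7 --out raw/
kicksense segment  --input raw/S01.csv --window-len 128 --output windows.csv
kicksense extract  --raw raw/S01.csv --windows windows.csv --s 50 --l 50 --output features.csv
kicksense augment  --input features.csv --levels 1,2 --shuffle-seed 17 --output augmented.csv
kicksense train    --data augmented.csv --out model_dir
kicksense evaluate --model model_dir --data test.csv --report report.json
kicksense compare  --grid grid.yaml --data features.csv --out table.csv
kicksense pipeline --config pipeline.yaml --out run/
```

`pipeline` chains all six stages from one YAML config and writes a
manifest (config hash, seeds, stage artifacts) so reruns are bit-for-bit
reproducible.

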