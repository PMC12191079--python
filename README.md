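# emognn

EEG emotion recognition with an attention-driven dynamic graph
convolutional network, plus everything needed to exercise it end to end
without any external dataset:

- **montage** — 62-channel 10–20 extended electrode space; left/right
  homolog pairs derived from label parity (27 pairs) and a packaged
  frontal→posterior pair table (23 pairs).
- **features** — preprocessing (resample to 200 Hz, 0.3–50 Hz zero-phase
  bandpass, 1 s non-overlapping segments) and five band-feature families:
  differential entropy (DE), band power (PSD), hemispheric difference /
  ratio asymmetry (DASM / RASM) and frontal–posterior differentials (DCAU)
  over five bands (δ, θ, α, β, γ).
- **model** — per layer: latent projection `H = XW`, data-dependent
  electrode adjacency `softmax(H A Hᵀ)` symmetrized by transpose
  averaging, aggregation `Z = A_att H`; global attention pooling with
  softmax node weights; four-layer fully connected softmax head. Ablation
  variants: fixed ring-graph GCN layer and direct-summation pooling.
- **domain_adapt** — gradient reversal layer (identity forward, `-α`
  gradient scaling backward, default `α = 0.1`) and a domain classifier
  (100 hidden units, batch norm, ReLU, log-softmax).
- **training** — Adam (lr 0.01, batch 64, 40 epochs, seed 100 defaults),
  leave-one-subject-out and per-subject 9/6-trial protocols, per-fold
  z-scoring from training statistics, accuracy/confusion reporting,
  four-variant ablation orchestration.
- **synthetic** — seeded generators for feature tensors (class patterns on
  designated electrodes + per-subject affine distortion) and raw
  band-limited oscillator recordings.

The network is implemented on a small reverse-mode autodiff engine over
numpy (`emognn.autodiff`); every backward rule is verified against central
finite differences in the test suite.

## CLI

```sh
# synthetic feature tensor with subject shift
emognn simulate --out feats.npz --n-subjects 5 --effect-size 2.5 \
    --subject-offset-sd 1.5 --seed 0

# band features from raw recordings (NPZ bundle of signal_<i> arrays)
emognn extract-features --input raw.npz --out de.npz --feature de

# leave-one-subject-out protocol with attention export
emognn loso --features feats.npz --config config.yaml \
    --report report.json --attention-csv attention.csv

# four-variant ablation table (full / plain_gcn / sum_pool / no_grl)
emognn ablate --features feats.npz --report ablation.json

# single-split training / evaluation with a checkpoint
emognn train --features feats.npz --checkpoint model.npz
emognn evaluate --features feats.npz --checkpoint model.npz
```

`config.yaml` mirrors the config dataclasses:

```yaml
model:
  layer_dims: [32, 64]
  classifier_dims: [256, 128, 64]
train:
  epochs: 40
  lr: 0.01
  seed: 100
adaptation:
  enabled: true
  alpha: 0.1
  scheme: binary_source_target
```

## Conventions and caveats

- The 23 frontal→posterior pairs cannot be derived from electrode names;
  the packaged table (`src/emognn/resources/esi62.csv`) follows the common
  62-channel convention and is user-editable.
- DCAU is a plain frontal-minus-posterior DE differential; despite the
  historical name, no causality estimator is involved.
- Band edges (δ 1–4, θ 4–8, α 8–14, β 14–31, γ 31–50 Hz), DE from
  band-filtered time-domain variance, and asymmetry features derived from
  DE are conventional defaults, all overridable.
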