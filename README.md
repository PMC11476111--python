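# cecsclip

Multimodal region–text object detection for camera-trap wildlife
monitoring, at desk scale.

Camera-trap surveys of rare and endangered species produce images in
which the animal is small, partially occluded, or camouflaged against its
habitat — exactly the regime where purely visual detectors struggle, and
where a large fraction of frames are *empty shots* containing no animal
at all. This package implements a two-stage detector that supplements
the image evidence with textual expert knowledge about each species
(coat colour, body shape, texture, size, distinctive marks), together
with the full evaluation suite needed to audit such a detector, and a
synthetic scene generator that stands in for restricted camera-trap
corpora.

## The model

Region features and species text features live in one embedding space:

- **Knowledge base.** Each species *n* gets a templated visual
  description embedded as a vector *sₙ*, a one-hot label vector *cₙ*
  padded to the same dimension, a composed knowledge vector
  *eₙ = sₙ + cₙ*, and an encoded text feature *tₙ = L(eₙ)* from a frozen
  text encoder. A background concept with its own descriptor anchors
  non-animal regions.
- **Region–text alignment.** A region encoder V is pretrained so that
  cosine similarity *s = (f·g)/(‖f‖‖g‖)* is high for matched
  (region, species text) pairs, with the symmetric contrastive loss
  `L = −(1/N) Σᵢ [log softmax_row(i,i) + log softmax_col(i,i)]` at
  temperature τ, plus a distillation term
  `Σᵢ (sᵢ_teacher − sᵢ_student)²` against a frozen teacher encoder.
- **Concept Enhancement (CE).** A cross-attention block fuses species
  text features into region features with residual connections:
  `V′ = V + CA(W_q V, W_k T, W_v T)` followed by
  `[V_bas, V_cap] = V′ + FFN(V′)`. Its output projections are
  zero-initialized, so an untrained block is exactly the identity.
- **Continuous feature Scaling (CS).** Region features are
  L2-normalized onto the unit hypersphere, where cosine similarity is an
  inner product, then rescaled as `V_scaled = (1/α)·V_norm`. The scale
  factor α ∈ (0, 1] (default 0.9) also replaces the softmax temperature
  in the class probabilities
  `p(y=i|x) = exp(cos(tᵢ, f)/α) / Σⱼ exp(cos(tⱼ, f)/α)` and is learned
  by gradient descent `α ← α − η ∂L/∂α`.
- **Two-stage detection.** An anchor-grid region proposal network scores
  objectness on the shared encoder features; ROI heads classify each
  proposal against the species text features (plus a learned background
  embedding) and regress box corrections, trained with
  `L = L_contrastive + L_cls + L_reg` (cross-entropy summed over ROIs;
  smooth-L1 box loss).
- **Metrics.** Precision/recall, the finite-difference PR-staircase
  `AP = Σₖ (Rₖ − Rₖ₋₁)·Pₖ` (with a COCO-interpolated mode),
  mAP and mAP50:95, size-stratified AP (COCO 32²/96² bands), detection
  rate / false-positive rate / miss rate (MR = 1 − DR), per-class
  confusion matrices, and the empty-shot absence-detection rate.

## Worked example

```python
from cecsclip.experiments import (build_toy_corpus, pretrain_encoder,
                                  train_variant, empty_shot_test)
from cecsclip.evaluation import evaluate_detector

catalog, kb, train, val, test = build_toy_corpus(seed=0)
encoder = pretrain_encoder(kb, train, seed=0)
model = train_variant("cecs", kb, train, seed=0, encoder_init=encoder)
report = evaluate_detector(model, test)
print(f"learned scale factor alpha: {model.scale.alpha:.3f}")
print(f"test mAP@0.5:     {report.mAP:.3f}")
print(f"test mAP@0.5:0.95: {report.mAP_50_95:.3f}")
print(f"detection rate:   {report.rates['DR']:.3f}")
print(f"empty-shot absence rate: {empty_shot_test(model):.2f}")
```

prints

```
learned scale factor alpha: 0.150
test mAP@0.5:     0.237
test mAP@0.5:0.95: 0.067
detection rate:   0.389
empty-shot absence rate: 0.96
```

The corpus is 200 synthetic 96×96 scenes of 3 species split 70/15/15.
During fine-tuning the scale factor sharpens from its 0.9 initialization
to ≈0.15: the learned temperature is what lifts correct classifications
over the 0.5 confidence threshold, so the full model detects while the
fixed-temperature baseline (α = 1) detects nothing — the ablation
`run_ablation()` reproduces that ordering over five seeds. The model
correctly leaves 96% of empty scenes detection-free.

## Command line

```sh
cecsclip generate --config run.yaml --out runs/ds        # synthetic dataset (COCO JSON + PNGs)
cecsclip pretrain --data runs/ds --out runs/pre          # teacher + distilled student encoder
cecsclip train    --data runs/ds --encoder runs/pre/encoder.npz --variant cecs --out runs/m
cecsclip evaluate runs/m/detector.npz --data runs/ds --split test --out runs/eval
cecsclip detect   runs/m/detector.npz image.png --data runs/ds --out runs/dets.json
cecsclip ablate   --out runs/ablation                    # {baseline, ce, cs, cecs} × seeds
```

Every command writes a `manifest.json` (config digest, seed, version)
beside its outputs and is deterministic given the same config and seed.

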