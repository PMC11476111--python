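# Methods

This note records the modelling assumptions, numerical choices, and
known limitations behind the package. It documents what the code does
and why; every number quoted here is computed by the test suite or by
`scripts/acceptance.py`.

## Synthetic scenes as study material

Real camera-trap corpora of endangered wildlife are typically not
redistributable, so all experiments run on synthetic scenes that
reproduce the *structure* of the problem rather than its photographic
appearance:

- **Species archetypes.** Up to 11 archetypes (named after plausible
  montane-forest species) with a silhouette family (blob, quadruped,
  bird), base colour, texture (plain/striped/spotted), a size range in
  pixels, and a camouflage affinity.
- **Backgrounds.** A vertical habitat gradient plus clutter blobs whose
  count scales with `clutter_level`, sensor grain, and a global lighting
  multiplier.
- **Camouflage** is alpha-blending of the target colour toward the mean
  of the local background patch by the species' camouflage affinity —
  a deliberate, tunable confound between animals and clutter.
- **Occlusion.** Every target draws an independent Bernoulli
  (`occlusion_prob`) flag; an occluded target's box is overlapped by a
  partner target drawn on top of it (a foliage strip when the scene has
  only one target). Independence keeps the flag fraction exactly
  binomial, which the generator tests verify against an exact 99% CI;
  the pairwise-overlap property is asserted for scenes with ≥ 2 targets.
- **Empty shots** (`n_targets = 0`) are first-class: they drive the
  image-level false-positive rate and the absence-detection protocol.

Defaults for the toy study conditions: 96×96 px scenes, 3 species,
3 targets per scene, occlusion 0.3, clutter 0.4, 200 scenes split
70/15/15 (floor-based, remainder to train), 500 detector iterations,
5 seeds for the ablation, 50 empty scenes for the absence test. The
sizes were chosen so the entire ablation runs in about two minutes on
one CPU while leaving every species with dozens of training instances.

What passing on this material does **not** show: robustness to
photographic nuisance (blur, weather, animal pose), realistic species
appearance, or transfer to real camera-trap imagery. The generator's
camouflage and clutter are honest analogues of the hard cases, but they
are low-dimensional ones.

## Text side

Descriptions are rendered from a deterministic template engine over the
archetype attributes (colour word, silhouette phrase, texture, size
class, distinctive mark, habitat phrase) — a seedable stand-in for
LLM-generated descriptor text. Description vectors use signed token
hashing (md5, so embeddings are identical across processes) averaged
over tokens; label vectors are one-hot padded into the same dimension
*d* (a seeded random projection when *d* < N), which makes the
composition E = S + C well-typed. A frozen two-layer tanh encoder maps
E to the text features T. A *background* concept — a habitat
descriptor with a zero label vector — is encoded the same way; it
anchors non-animal regions during pretraining and initializes the
detector's background embedding. Defaults: d = 32 for both the
composed vectors and the encoded features.

## Image side and alignment

Region appearance is an area-averaged `8×8` RGB resampling of the crop
(integral-image cell means; robust to the small box misalignment of
region proposals, where point sampling is not), flattened to 192
features. The region encoder is a 192→64→32 tanh MLP. The teacher is
the same architecture trained contrastively on the corpus and then
frozen; the student trains with contrastive + distillation loss against
it. Pretraining pairs are ground-truth boxes, jitter-augmented copies
(±15% of box size, so the embedding tolerates proposal-like
misalignment), and background crops matched to the background concept.
Within a contrastive batch, at most one pair per concept is kept:
duplicate text columns would make a matched pair repel its own class.

Temperature τ = 0.1 (the admissible range is the open unit interval);
batch 16; 40 epochs of SGD at 0.15. The contrastive loss follows the
stated form exactly: the sum of the region→text and text→region log
terms is divided by the batch size once.

## Detector

Two stages. The RPN scores a dense anchor grid (stride 8, scales
10/16/24/36 px, aspects 1.0/1.6) with a logistic regression on the
*shared encoder features* — objectness on raw pixels is not separable
here — keeping the top 30 proposals above 0.65 after proposal-level
NMS. The ROI head classifies each proposal by cosine against the
species text features plus a learned background embedding, with the
scale factor α in the temperature slot, and regresses class-agnostic
box deltas in the standard (dx, dy, dw, dh) parametrization from raw
context patches (the proposal expanded by 30%; a pooled semantic
embedding cannot indicate where inside the proposal the object sits).
Inference: propose → encode → concept-enhance → normalize → scale →
classify/regress → decode → per-class then cross-class NMS → confidence
threshold 0.5.

Training samples per iteration, from one scene: jittered ground-truth
positives, anchor positives (IoU ≥ 0.5), the trained RPN's own
false-positive proposals and partially overlapping anchors
(IoU ∈ [0.1, 0.35); the band up to 0.5 is ambiguous and excluded) as
negatives, plus random background boxes. The loss is the unweighted sum
of the contrastive, classification (summed over ROIs) and smooth-L1
regression terms; weights are configurable and default to 1.

Numerical choices that matter:

- **Smooth-L1 mode.** The printed piecewise form is discontinuous at
  |Δ| = 1; the default uses the standard continuous `|Δ| − 0.5` branch,
  and a `literal` mode preserves the printed formula for audits.
- **α update.** Plain gradient descent with η = 0.1, clamped into
  (10⁻³, 1] and trust-regioned to ±0.005 per step — softmax-temperature
  gradients grow like 1/α², and unbounded steps oscillate once α is
  small. The α gradient flows through the classification logits only;
  the regression input stays scale-stationary while α is being learned
  (a config switch re-couples the paths). Per-parameter gradient-norm
  clipping at 1.0 stabilizes the heads for the same reason.
- **Backbone freezing.** The pretrained encoder is frozen during
  detector fine-tuning by default (`encoder_lr_scale = 0`), and the
  fusion block adapts at 1% of the head learning rate: with bounded
  cosine logits, head-scale gradient steps through a small MLP destroy
  the pretrained alignment faster than fine-tuning improves it.
- **Variants share one forward path.** `baseline` = frozen
  zero-initialized fusion block and α pinned at 1; `ce` trains the
  block; `cs` learns α from 0.9; `cecs` both. Because the zero block
  is the exact identity and ×1/1 is exact, the full model with those
  settings is bitwise equal to the baseline — the ablation identity the
  tests assert.

## Why the ablation orders the way it does

With cosine-bounded logits, K species and a background class, a correct
classification exceeds the 0.5 confidence threshold only when
(margin)/α > ln K. The baseline's fixed α = 1 cannot reach that at the
margins a desk-scale encoder attains (≈0.35), so it detects essentially
nothing at the evaluation threshold; the learnable α sharpens to ≈0.15
during fine-tuning and lifts correct predictions over the threshold.
The measured effect of continuous feature scaling in this regime is
therefore large and direction-stable across seeds, which is what the
acceptance protocol checks — the absolute toy mAP values carry no
meaning beyond that ordering.

## Evaluation conventions

- AP is the literal finite-difference sum over the PR staircase by
  default; a COCO 101-point interpolated mode is reported alongside.
  Both are validated against a brute-force rank-enumeration oracle.
- Size bands follow COCO: small < 32², medium < 96², large ≥ 96².
  Bands without ground truth report `None` rather than zero.
- Precision is 1 when there are no detections (nothing asserted,
  nothing wrong); recall is undefined without ground truth.
- MR = 1 − DR exactly. FPR is image-level: the fraction of empty
  images on which anything at all was detected — the rate-based
  definition is not recoverable from per-box counts alone, so the
  choice is documented and configurable.
- The confusion matrix uses class-agnostic matching so cross-class
  confusions are visible; background occupies the extra row/column.

## Engineering notes

The environment provides no deep-learning framework, so the package
carries a ~250-line reverse-mode autodiff engine (`cecsclip.autodiff`)
over float64 numpy arrays; every operation's vector–Jacobian product is
tested against central finite differences, and the model-level gradient
checks in the acceptance script bound the worst error at ~10⁻⁹.
Determinism everywhere comes from `numpy.random.default_rng` seeded per
scene/run; identical (catalog, spec, seed) triples yield byte-identical
datasets, and training is reproducible bit-for-bit on a given platform.

## Limitations

- The linear-plus-MLP encoder on 8×8 average-pooled crops caps species
  margins near 0.35; heavily camouflaged archetypes are genuinely
  confusable with clutter blobs at that resolution, which is the main
  source of residual false positives.
- The regression head is linear on context patches; localization
  improves proposals (≈+0.05 IoU on average) but remains the weakest
  stage, visible in the gap between mAP@0.5 and mAP@0.5:0.95.
- Single-head attention only in the fusion block by default; deformable
  convolution offsets are not implemented — the block's insertion point
  treats "deformable" as naming the site, not the operator.
- α is a single global scalar; per-class or per-channel scaling is out
  of scope.
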