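"""Two-stage wildlife detector with concept enhancement and feature scaling.

Stage one proposes candidate boxes (a light anchor-grid RPN with a
logistic objectness scorer, or oracle proposals jittered off the ground
truth for unit testing downstream stages).  Stage two extracts region
features, optionally fuses them with species text features through the
concept-enhancement block, L2-normalizes them onto the unit hypersphere,
rescales by ``1/alpha``, and feeds them to the ROI heads: an
open-vocabulary cosine classifier over the species text features plus a
learned background embedding, and a class-agnostic box-delta regressor.

The training objective is the unweighted sum
``L = L_contrastive + L_cls + L_reg`` (weights configurable), with the
classification term summed over ROIs and the regression term a smooth-L1
on positive ROIs.  Four variants support the ablation protocol:
``baseline`` (identity CEM, alpha frozen at 1), ``ce`` (trainable CEM),
``cs`` (learnable alpha starting at 0.9), ``cecs`` (both).  All variants
share one forward path, so a zero CEM with alpha = 1 is bitwise equal to
the baseline.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Parameter, Tensor, sgd_step, zero_grads
from .alignment import ImageEncoder, contrastive_loss, cosine_matrix_t, patch_features
from .cem import CEMParams, cem_enhance
from .knowledge import KnowledgeBase
from .scaling import EPS_ALPHA, ScaleState, l2_normalize, update_scale

VARIANTS = ("baseline", "ce", "cs", "cecs")


class DetectorError(ValueError):
    pass


# ---------------------------------------------------------------------------
# box arithmetic

def iou(box_a, box_b) -> float:
    """Intersection over union of two ``(x0, y0, x1, y1)`` boxes."""
    ax0, ay0, ax1, ay1 = (float(v) for v in box_a)
    bx0, by0, bx1, by1 = (float(v) for v in box_b)
    if ax1 <= ax0 or ay1 <= ay0 or bx1 <= bx0 or by1 <= by0:
        raise DetectorError("degenerate box passed to iou")
    ix = max(0.0, min(ax1, bx1) - max(ax0, bx0))
    iy = max(0.0, min(ay1, by1) - max(ay0, by0))
    inter = ix * iy
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return inter / union


def iou_matrix(boxes_a: np.ndarray, boxes_b: np.ndarray) -> np.ndarray:
    """Pairwise IoU, vectorized; returns ``(len(a), len(b))``."""
    a = np.asarray(boxes_a, dtype=np.float64).reshape(-1, 4)
    b = np.asarray(boxes_b, dtype=np.float64).reshape(-1, 4)
    ix = np.maximum(
        0.0,
        np.minimum(a[:, None, 2], b[None, :, 2]) - np.maximum(a[:, None, 0], b[None, :, 0]),
    )
    iy = np.maximum(
        0.0,
        np.minimum(a[:, None, 3], b[None, :, 3]) - np.maximum(a[:, None, 1], b[None, :, 1]),
    )
    inter = ix * iy
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / union, 0.0)


def encode_box(gt_box: np.ndarray, anchor: np.ndarray) -> np.ndarray:
    """Standard (dx, dy, dw, dh) parametrization of ``gt`` against ``anchor``."""
    gx0, gy0, gx1, gy1 = gt_box
    ax0, ay0, ax1, ay1 = anchor
    aw, ah = ax1 - ax0, ay1 - ay0
    gw, gh = gx1 - gx0, gy1 - gy0
    return np.array(
        [
            ((gx0 + gx1) / 2 - (ax0 + ax1) / 2) / aw,
            ((gy0 + gy1) / 2 - (ay0 + ay1) / 2) / ah,
            np.log(gw / aw),
            np.log(gh / ah),
        ]
    )


def decode_box(anchor: np.ndarray, deltas: np.ndarray) -> np.ndarray:
    """Inverse of :func:`encode_box`."""
    ax0, ay0, ax1, ay1 = anchor
    aw, ah = ax1 - ax0, ay1 - ay0
    cx = (ax0 + ax1) / 2 + deltas[0] * aw
    cy = (ay0 + ay1) / 2 + deltas[1] * ah
    w = aw * np.exp(deltas[2])
    h = ah * np.exp(deltas[3])
    return np.array([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2])


def clip_box(box: np.ndarray, width: float, height: float) -> np.ndarray:
    x0, y0, x1, y1 = box
    return np.array(
        [
            np.clip(x0, 0, width - 1),
            np.clip(y0, 0, height - 1),
            np.clip(x1, 1, width),
            np.clip(y1, 1, height),
        ]
    )


# ---------------------------------------------------------------------------
# output containers

@dataclass(frozen=True)
class Proposal:
    box: tuple[float, float, float, float]
    objectness: float


@dataclass(frozen=True)
class Detection:
    box: tuple[float, float, float, float]
    label: int
    score: float

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise DetectorError(f"score must lie in [0, 1], got {self.score}")


def nms(detections: list[Detection], iou_threshold: float = 0.5) -> list[Detection]:
    """Greedy per-class non-maximum suppression by descending score."""
    survivors: list[Detection] = []
    for det in sorted(detections, key=lambda d: -d.score):
        if all(
            det.label != kept.label or iou(det.box, kept.box) <= iou_threshold
            for kept in survivors
        ):
            survivors.append(det)
    return survivors


# ---------------------------------------------------------------------------
# losses (public numpy surface; the trainer uses Tensor analogues)

def classification_loss(p: np.ndarray, y: np.ndarray, tol: float = 1e-6) -> float:
    """Cross-entropy ``-sum_c y_c log p_c`` for one ROI."""
    p = np.asarray(p, dtype=np.float64).reshape(-1)
    y = np.asarray(y, dtype=np.float64).reshape(-1)
    if abs(p.sum() - 1.0) > tol or (p < 0).any():
        raise DetectorError("p must be a probability vector")
    if p.shape != y.shape:
        raise DetectorError("p and y must align")
    c = int(np.argmax(y))
    return float(-np.log(max(p[c], 1e-300)))


def regression_loss(deltas: np.ndarray, mode: str = "continuous") -> float:
    """Smooth-L1 over the four box deltas.

    ``continuous`` uses the standard ``|d| - 0.5`` branch for ``|d| >= 1``;
    ``literal`` keeps the plain ``|d|`` branch (discontinuous at 1).
    """
    d = np.asarray(deltas, dtype=np.float64).reshape(-1)
    if not np.isfinite(d).all():
        raise DetectorError("non-finite deltas")
    a = np.abs(d)
    if mode == "continuous":
        per = np.where(a < 1.0, 0.5 * a**2, a - 0.5)
    elif mode == "literal":
        per = np.where(a < 1.0, 0.5 * a**2, a)
    else:
        raise DetectorError(f"unknown regression-loss mode {mode!r}")
    return float(per.sum())


def _regression_loss_t(d: Tensor, mode: str) -> Tensor:
    a = d.abs()
    mask = Tensor((np.abs(d.data) < 1.0).astype(float))
    quad = 0.5 * (a**2) * mask
    lin = (a - (0.5 if mode == "continuous" else 0.0)) * (1.0 - mask)
    return (quad + lin).sum()


def total_loss(
    l_contrastive: float,
    l_cls: float,
    l_reg: float,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
):
    """Combined objective ``L = L_contrastive + L_cls + L_reg`` (weighted)."""
    return (
        weights[0] * l_contrastive + weights[1] * l_cls + weights[2] * l_reg
    )


# ---------------------------------------------------------------------------
# region proposal network

_ANCHOR_CACHE: dict = {}


@dataclass
class RPNParams:
    """Anchor grid plus a logistic objectness scorer.

    Objectness is scored on the shared region-encoder features (the
    backbone), not raw pixels; ``encoder`` is attached when the detector
    is trained or loaded.
    """

    stride: int = 8
    scales: tuple[int, ...] = (10, 16, 24, 36)
    aspects: tuple[float, ...] = (1.0, 1.6)
    max_proposals: int = 30
    objectness_threshold: float = 0.65
    patch: int = 8
    w: np.ndarray | None = None
    b: float = 0.0
    encoder: "ImageEncoder | None" = None


def anchor_grid(width: int, height: int, params: RPNParams) -> np.ndarray:
    """Dense anchors over scales x aspect ratios, clipped to the image."""
    key = (width, height, params.stride, tuple(params.scales), tuple(params.aspects))
    cached = _ANCHOR_CACHE.get(key)
    if cached is not None:
        return cached
    cx, cy = np.meshgrid(
        np.arange(params.stride / 2, width, params.stride),
        np.arange(params.stride / 2, height, params.stride),
    )
    cx, cy = cx.ravel(), cy.ravel()
    parts = []
    for s in params.scales:
        for a in params.aspects:
            bw, bh = s * np.sqrt(a), s / np.sqrt(a)
            parts.append(
                np.stack([cx - bw / 2, cy - bh / 2, cx + bw / 2, cy + bh / 2], axis=1)
            )
    arr = np.concatenate(parts)
    arr[:, 0] = np.clip(arr[:, 0], 0, width - 1)
    arr[:, 1] = np.clip(arr[:, 1], 0, height - 1)
    arr[:, 2] = np.clip(arr[:, 2], 1, width)
    arr[:, 3] = np.clip(arr[:, 3], 1, height)
    _ANCHOR_CACHE[key] = arr
    return arr


def propose_regions(
    image: np.ndarray,
    params: RPNParams,
    oracle_boxes: np.ndarray | None = None,
    jitter: float = 0.0,
    seed: int = 0,
) -> list[Proposal]:
    """Candidate regions from the RPN, or oracle (jittered GT) proposals.

    Oracle mode perturbs each ground-truth box by a seeded uniform shift
    of up to ``jitter`` times its size; ``jitter=0`` echoes the ground
    truth exactly.  RPN mode scores the anchor grid with the trained
    objectness model and returns the top boxes above threshold.
    """
    h, w = image.shape[:2]
    if oracle_boxes is not None:
        rng = np.random.default_rng(seed)
        out = []
        for box in np.asarray(oracle_boxes, dtype=np.float64).reshape(-1, 4):
            bw, bh = box[2] - box[0], box[3] - box[1]
            shift = rng.uniform(-jitter, jitter, 4) * np.array([bw, bh, bw, bh])
            out.append(Proposal(tuple(clip_box(box + shift, w, h)), 1.0))
        return out[: params.max_proposals]
    if params.w is None:
        raise DetectorError("RPN objectness model is untrained")
    anchors = anchor_grid(w, h, params)
    X = patch_features(image, anchors, params.patch)
    if params.encoder is not None:
        X = params.encoder.encode(X)
    scores = 1.0 / (1.0 + np.exp(-(X @ params.w + params.b)))
    keep = np.flatnonzero(scores >= params.objectness_threshold)
    order = keep[np.argsort(-scores[keep])]
    # greedy proposal NMS: overlapping anchors describe the same object
    chosen: list[int] = []
    for i in order:
        if len(chosen) >= params.max_proposals:
            break
        if all(iou(anchors[i], anchors[j]) <= 0.5 for j in chosen):
            chosen.append(i)
    return [Proposal(tuple(anchors[i]), float(scores[i])) for i in chosen]


def train_rpn(scenes, params: RPNParams, seed: int = 0, epochs: int = 60, lr: float = 1.0):
    """Fit the logistic objectness scorer on anchors vs. ground truth.

    Positives are anchors with IoU >= 0.4 against any target (plus the
    targets themselves); negatives are anchors with IoU < 0.1.
    """
    rng = np.random.default_rng(seed)
    Xs, ys = [], []
    for scene in scenes:
        h, w = scene.image.shape[:2]
        anchors = anchor_grid(w, h, params)
        if scene.n_targets:
            m = iou_matrix(anchors, scene.boxes).max(axis=1)
        else:
            m = np.zeros(len(anchors))
        pos = np.flatnonzero(m >= 0.4)
        neg = np.flatnonzero(m < 0.1)
        neg = rng.choice(neg, size=min(len(neg), max(len(pos), 4) * 3), replace=False)
        take = np.concatenate([pos, neg])
        if len(take) == 0:
            continue
        X = patch_features(scene.image, anchors[take], params.patch)
        y = (m[take] >= 0.4).astype(float)
        if scene.n_targets:
            X = np.vstack([X, patch_features(scene.image, scene.boxes, params.patch)])
            y = np.concatenate([y, np.ones(scene.n_targets)])
        Xs.append(X)
        ys.append(y)
    X = np.vstack(Xs)
    if params.encoder is not None:
        X = params.encoder.encode(X)
    y = np.concatenate(ys)
    w_vec = np.zeros(X.shape[1])
    b = 0.0
    n = len(y)
    for _ in range(epochs):
        z = X @ w_vec + b
        p = 1.0 / (1.0 + np.exp(-z))
        g = p - y
        w_vec -= lr * (X.T @ g) / n
        b -= lr * g.mean()
    params.w = w_vec
    params.b = float(b)
    return params


# ---------------------------------------------------------------------------
# model state

@dataclass
class DetectorConfig:
    variant: str = "cecs"
    d: int = 32
    patch: int = 8
    iterations: int = 500
    lr: float = 0.1
    encoder_lr_scale: float = 0.0  # pretrained backbone frozen by default
    cem_lr_scale: float = 0.01  # the fusion block adapts gently
    alpha_init: float = 0.9
    alpha_eta: float = 0.1
    alpha_max_step: float = 0.005  # trust region per update
    max_grad_norm: float = 1.0
    tau: float = 0.1
    contrastive_in_finetune: bool = True
    couple_scale_paths: bool = False  # alpha gradient also via regression path
    loss_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    reg_mode: str = "continuous"
    rois_per_scene: int = 14
    proposal_jitter: float = 0.15
    score_threshold: float = 0.5
    nms_iou: float = 0.5
    refine_passes: int = 1
    rpn: RPNParams = field(default_factory=RPNParams)

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise DetectorError(f"variant must be one of {VARIANTS}")

    @property
    def use_cem(self) -> bool:
        return self.variant in ("ce", "cecs")

    @property
    def use_cs(self) -> bool:
        return self.variant in ("cs", "cecs")


class DetectorModel:
    """All trainable state of the two-stage detector."""

    def __init__(self, kb: KnowledgeBase, config: DetectorConfig, seed: int = 0):
        if kb.T.shape[1] != config.d:
            raise DetectorError(
                f"text features are {kb.T.shape[1]}-d but the detector is "
                f"configured for d={config.d}"
            )
        self.kb = kb
        self.config = config
        rng_seed = seed
        self.encoder = ImageEncoder(3 * config.patch**2, config.d, seed=rng_seed)
        self.cem = CEMParams(config.d, seed=rng_seed + 1)
        if kb.t_bg is not None:
            self.bg_embed = Parameter(kb.t_bg.copy())
        else:
            self.bg_embed = Parameter(
                np.random.default_rng(rng_seed + 2).normal(0, 1 / np.sqrt(config.d), config.d)
            )
        # the regressor reads raw (spatially structured) context patches:
        # a pooled semantic embedding cannot tell where inside the
        # proposal the object sits
        self.reg_W = Parameter(np.zeros((3 * config.patch**2, 4)))
        self.reg_b = Parameter(np.zeros(4))
        alpha0 = config.alpha_init if config.use_cs else 1.0
        self.scale = ScaleState(alpha=alpha0, eta=config.alpha_eta, learnable=config.use_cs)
        self.trained = False
        self.Tn = l2_normalize(kb.T)  # fixed text features on the hypersphere

    @property
    def trainable_params(self) -> list[Parameter]:
        ps = self.encoder.params + [self.bg_embed, self.reg_W, self.reg_b]
        if self.config.use_cem:
            ps += self.cem.params
        return ps

    # -- forward -------------------------------------------------------------
    def roi_forward(self, image: np.ndarray, boxes: np.ndarray):
        """Region features -> (class logits, box deltas, alpha tensor).

        Returns Tensors wired for backprop; the alpha tensor exposes
        ``dL/dalpha`` for the scale update.
        """
        X = patch_features(image, boxes, self.config.patch)
        V = self.encoder(X)
        V = cem_enhance(V, self.kb.T, self.cem)
        norms = ((V**2).sum(axis=1, keepdims=True)) ** 0.5
        Vn = V / norms
        alpha_t = Parameter(np.array([self.scale.alpha]))
        alpha_t.requires_grad = self.scale.learnable
        Vs = Vn * (1.0 / alpha_t)  # continuous feature scaling, Vn / alpha
        bgn = self.bg_embed / ((self.bg_embed**2).sum() ** 0.5)
        # cosine logits already divided by alpha via the scaled features
        logits = Tensor.concat(
            [Vs @ Tensor(self.Tn.T), (Vs @ bgn.reshape(-1, 1))], axis=1
        )
        # regression input: raw patches of the proposals expanded by 30%
        # context margin; scale-stationary (alpha-free) unless coupled
        h, w = image.shape[:2]
        b = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
        bw, bh = b[:, 2] - b[:, 0], b[:, 3] - b[:, 1]
        ctx = np.stack(
            [
                np.clip(b[:, 0] - 0.3 * bw, 0, w - 1),
                np.clip(b[:, 1] - 0.3 * bh, 0, h - 1),
                np.clip(b[:, 2] + 0.3 * bw, 1, w),
                np.clip(b[:, 3] + 0.3 * bh, 1, h),
            ],
            axis=1,
        )
        X_ctx = Tensor(patch_features(image, ctx, self.config.patch))
        scale_reg = (1.0 / alpha_t) if self.config.couple_scale_paths else 1.0
        deltas = (X_ctx @ self.reg_W) * scale_reg + self.reg_b
        return logits, deltas, alpha_t

    def class_probs(self, image: np.ndarray, boxes: np.ndarray) -> np.ndarray:
        logits, _, _ = self.roi_forward(image, boxes)
        return logits.softmax(axis=1).data

    # -- persistence ----------------------------------------------------------
    def state_dict(self) -> dict:
        return {
            "encoder": self.encoder.state_dict(),
            "cem": self.cem.state_dict(),
            "bg_embed": self.bg_embed.data.copy(),
            "reg_W": self.reg_W.data.copy(),
            "reg_b": self.reg_b.data.copy(),
            "alpha": self.scale.alpha,
            "rpn_w": self.config.rpn.w,
            "rpn_b": self.config.rpn.b,
        }

    def load_state_dict(self, state: dict) -> None:
        self.encoder.load_state_dict(state["encoder"])
        self.cem.load_state_dict(state["cem"])
        self.bg_embed.data = np.asarray(state["bg_embed"], dtype=np.float64).copy()
        self.reg_W.data = np.asarray(state["reg_W"], dtype=np.float64).copy()
        self.reg_b.data = np.asarray(state["reg_b"], dtype=np.float64).copy()
        self.scale = ScaleState(
            alpha=float(state["alpha"]),
            eta=self.config.alpha_eta,
            learnable=self.config.use_cs,
        )
        if state.get("rpn_w") is not None:
            self.config.rpn.w = np.asarray(state["rpn_w"], dtype=np.float64)
            self.config.rpn.b = float(state["rpn_b"])
        self.config.rpn.encoder = self.encoder
        self.trained = True


def save_checkpoint(model: DetectorModel, path: str) -> None:
    """Portable array container plus a JSON manifest."""
    state = model.state_dict()
    flat = {}
    for k, v in state.items():
        if isinstance(v, dict):
            for kk, vv in v.items():
                flat[f"{k}.{kk}"] = vv
        elif v is not None:
            flat[k] = np.asarray(v)
    np.savez(path if path.endswith(".npz") else path + ".npz", **flat)
    manifest = {
        "variant": model.config.variant,
        "alpha": model.scale.alpha,
        "d": model.config.d,
        "patch": model.config.patch,
        "species_ids": model.kb.species_ids,
    }
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def load_checkpoint(model: DetectorModel, path: str) -> DetectorModel:
    data = np.load(path if path.endswith(".npz") else path + ".npz")
    state: dict = {"encoder": {}, "cem": {}}
    for k in data.files:
        if "." in k:
            outer, inner = k.split(".", 1)
            state.setdefault(outer, {})[inner] = data[k]
        else:
            state[k] = data[k]
    state["alpha"] = float(state["alpha"])
    state["rpn_b"] = float(state.get("rpn_b", 0.0))
    if "rpn_w" not in state:
        state["rpn_w"] = None
    model.load_state_dict(state)
    return model


# ---------------------------------------------------------------------------
# inference

def detect(
    image: np.ndarray,
    model: DetectorModel,
    score_threshold: float | None = None,
) -> list[Detection]:
    """Full pipeline: propose, encode, enhance, scale, classify, regress,
    NMS, threshold."""
    if not model.trained:
        raise DetectorError("model is untrained; run train_detector first")
    cfg = model.config
    thr = cfg.score_threshold if score_threshold is None else score_threshold
    proposals = propose_regions(image, cfg.rpn)
    if not proposals:
        return []
    boxes = np.array([p.box for p in proposals])
    h, w = image.shape[:2]
    # iterative box refinement: re-extract features at the decoded box and
    # regress again; the final pass supplies the class scores
    for _ in range(max(cfg.refine_passes, 1)):
        logits, deltas, _ = model.roi_forward(image, boxes)
        decoded = np.stack(
            [clip_box(decode_box(b, d), w, h) for b, d in zip(boxes, deltas.data)]
        )
        ok = (decoded[:, 2] > decoded[:, 0]) & (decoded[:, 3] > decoded[:, 1])
        boxes = np.where(ok[:, None], decoded, boxes)
    probs = logits.softmax(axis=1).data
    n_cls = len(model.kb.species_ids)
    dets = []
    for i in range(len(boxes)):
        c = int(np.argmax(probs[i]))
        if c == n_cls:  # background
            continue
        score = float(probs[i, c])
        if score < thr:
            continue
        dets.append(Detection(tuple(boxes[i]), model.kb.species_ids[c], score))
    dets = nms(dets, cfg.nms_iou)
    # cross-class suppression: one object, one label
    survivors: list[Detection] = []
    for det in sorted(dets, key=lambda d: -d.score):
        if all(iou(det.box, kept.box) <= cfg.nms_iou for kept in survivors):
            survivors.append(det)
    return survivors


# ---------------------------------------------------------------------------
# training

def _scene_roi_pools(scene, cfg: DetectorConfig) -> dict:
    """Precomputed ROI candidate pools for one scene.

    Positives: anchors with IoU >= 0.5 (ground truth itself is jittered at
    sample time).  Negatives: partially overlapping anchors (IoU in
    [0.1, 0.35); the band up to 0.5 is ambiguous and ignored) and the
    trained RPN's own false-positive proposals — the clutter the ROI head
    must veto at inference.
    """
    h, w = scene.image.shape[:2]
    pools = {"anchor_pos": (np.zeros((0, 4)), np.zeros(0, dtype=int)),
             "hard_neg": np.zeros((0, 4)), "rpn_fp": np.zeros((0, 4))}
    props = propose_regions(scene.image, cfg.rpn)
    prop_boxes = np.array([p.box for p in props]).reshape(-1, 4)
    if scene.n_targets:
        anchors = anchor_grid(w, h, cfg.rpn)
        am = iou_matrix(anchors, scene.boxes)
        best = am.max(axis=1)
        pos_a = np.flatnonzero(best >= 0.5)
        hard_a = np.flatnonzero((best >= 0.1) & (best < 0.35))
        pools["anchor_pos"] = (
            anchors[pos_a],
            scene.labels[am[pos_a].argmax(axis=1)] if pos_a.size else np.zeros(0, dtype=int),
        )
        pools["hard_neg"] = anchors[hard_a]
        if len(prop_boxes):
            fp = iou_matrix(prop_boxes, scene.boxes).max(axis=1) < 0.3
            pools["rpn_fp"] = prop_boxes[fp]
    else:
        pools["rpn_fp"] = prop_boxes
    return pools


def _sample_rois(scene, pools: dict, cfg: DetectorConfig, rng: np.random.Generator):
    """Draw one training batch from the scene's ROI pools."""
    h, w = scene.image.shape[:2]
    boxes, labels = [], []
    if scene.n_targets:
        props = propose_regions(
            scene.image,
            cfg.rpn,
            oracle_boxes=scene.boxes,
            jitter=cfg.proposal_jitter,
            seed=int(rng.integers(0, 2**31)),
        )
        m = iou_matrix(np.array([p.box for p in props]), scene.boxes)
        for p, row in zip(props, m):
            j = int(np.argmax(row))
            boxes.append(np.asarray(p.box))
            labels.append(int(scene.labels[j]) if row[j] >= 0.5 else -1)
    a_boxes, a_labels = pools["anchor_pos"]
    if len(a_boxes):
        take = rng.choice(len(a_boxes), size=min(len(a_boxes), 3), replace=False)
        for i in take:
            boxes.append(a_boxes[i])
            labels.append(int(a_labels[i]))
    for pool, cap in (("rpn_fp", 4), ("hard_neg", 3)):
        cand = pools[pool]
        if len(cand):
            take = rng.choice(len(cand), size=min(len(cand), cap), replace=False)
            for i in take:
                boxes.append(cand[i])
                labels.append(-1)
    n_neg = max(cfg.rois_per_scene - len(boxes), 2)
    for _ in range(n_neg):
        bw = rng.uniform(8, w / 2)
        bh = rng.uniform(8, h / 2)
        x0 = rng.uniform(0, w - bw)
        y0 = rng.uniform(0, h - bh)
        cand = np.array([x0, y0, x0 + bw, y0 + bh])
        if scene.n_targets and iou_matrix(cand[None], scene.boxes).max() >= 0.3:
            continue  # too close to a target to serve as background
        boxes.append(cand)
        labels.append(-1)
    return np.stack(boxes), np.asarray(labels)


def train_detector(
    train_scenes,
    kb: KnowledgeBase,
    config: DetectorConfig | None = None,
    seed: int = 0,
    val_scenes=None,
    encoder_init: dict | None = None,
    log_every: int = 100,
) -> tuple[DetectorModel, list[dict]]:
    """Seeded training loop minimizing the combined detection objective.

    Returns the trained model and a metric trace with per-interval loss
    components, alpha, and (when ``val_scenes`` is given) validation mAP.
    Aborts with the last finite loss on divergence.
    """
    from .evaluation import evaluate_detector  # local import to avoid cycle

    config = config or DetectorConfig()
    model = DetectorModel(kb, config, seed=seed)
    if encoder_init is not None:
        model.encoder.load_state_dict(encoder_init)
    config.rpn.encoder = model.encoder
    train_rpn(train_scenes, config.rpn, seed=seed)
    pools = [_scene_roi_pools(s, config) for s in train_scenes]
    rng = np.random.default_rng(seed)
    row_of = {sid: i for i, sid in enumerate(kb.species_ids)}
    n_cls = len(kb.species_ids)
    trace: list[dict] = []
    interval = {"cls": 0.0, "reg": 0.0, "con": 0.0, "n": 0}
    for it in range(config.iterations):
        k = int(rng.integers(0, len(train_scenes)))
        scene = train_scenes[k]
        boxes, labels = _sample_rois(scene, pools[k], config, rng)
        logits, deltas, alpha_t = model.roi_forward(scene.image, boxes)
        logp = logits.log_softmax(axis=1)
        targets = np.array([row_of[l] if l >= 0 else n_cls for l in labels])
        l_cls = -(logp[np.arange(len(targets)), targets].sum())
        pos = np.flatnonzero(labels >= 0)
        if pos.size:
            gt_match = iou_matrix(boxes[pos], scene.boxes).argmax(axis=1)
            target_deltas = np.stack(
                [
                    encode_box(scene.boxes[g], boxes[p])
                    for p, g in zip(pos, gt_match)
                ]
            )
            l_reg = _regression_loss_t(
                deltas[pos] - Tensor(target_deltas), config.reg_mode
            )
        else:
            l_reg = Tensor(0.0)
        # one ROI per distinct species: duplicate texts in a contrastive
        # batch would make matched pairs repel their own class column
        con_idx, seen_species = [], set()
        for p in pos:
            if labels[p] not in seen_species:
                con_idx.append(p)
                seen_species.add(labels[p])
        if config.contrastive_in_finetune and len(con_idx) >= 2:
            X = patch_features(scene.image, boxes[con_idx], config.patch)
            V = model.encoder(X)
            S = cosine_matrix_t(V, kb.T[[row_of[labels[p]] for p in con_idx]])
            l_con = contrastive_loss(S, config.tau)
        else:
            l_con = Tensor(0.0)
        w0, w1, w2 = config.loss_weights
        loss = w0 * l_con + w1 * l_cls + w2 * l_reg
        if not np.isfinite(loss.data):
            raise RuntimeError(
                f"training diverged at iteration {it} (loss={loss.data!r})"
            )
        params = model.trainable_params
        zero_grads(params)
        alpha_t.grad = None
        loss.backward()
        enc_params = set(map(id, model.encoder.params))
        cem_params = set(map(id, model.cem.params))
        sgd_step(
            [p for p in params if id(p) not in enc_params and id(p) not in cem_params],
            config.lr,
            config.max_grad_norm,
        )
        sgd_step(model.encoder.params, config.lr * config.encoder_lr_scale, config.max_grad_norm)
        if config.use_cem:
            sgd_step(model.cem.params, config.lr * config.cem_lr_scale, config.max_grad_norm)
        if model.scale.learnable and alpha_t.grad is not None:
            model.scale = update_scale(
                model.scale, float(alpha_t.grad[0]), config.alpha_max_step
            )
        interval["cls"] += float(l_cls.data)
        interval["reg"] += float(l_reg.data)
        interval["con"] += float(l_con.data)
        interval["n"] += 1
        if (it + 1) % log_every == 0 or it + 1 == config.iterations:
            rec = {
                "iteration": it + 1,
                "loss_cls": interval["cls"] / interval["n"],
                "loss_reg": interval["reg"] / interval["n"],
                "loss_contrastive": interval["con"] / interval["n"],
                "alpha": model.scale.alpha,
            }
            rec["loss_total"] = (
                rec["loss_contrastive"] + rec["loss_cls"] + rec["loss_reg"]
            )
            if val_scenes:
                model.trained = True
                rec["val_map"] = evaluate_detector(model, val_scenes).mAP
            trace.append(rec)
            interval = {"cls": 0.0, "reg": 0.0, "con": 0.0, "n": 0}
    model.trained = True
    return model, trace
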