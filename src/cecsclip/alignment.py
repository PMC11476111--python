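"""Region-text alignment: similarity, match probability, contrastive and
distillation losses, and teacher-student pretraining of the region encoder.

Region appearance is summarised by a fixed patch featurization (crop,
nearest-neighbour resize to ``patch x patch`` RGB, scale to [0,1]); the
student image encoder is a trainable linear map from those features onto
the shared image-text space, and the teacher is the same architecture
trained briefly on the synthetic corpus and then frozen (a desk-scale
stand-in for a large pretrained vision-language encoder).

The contrastive objective is the symmetric softmax cross-entropy over the
region-text similarity matrix: for a batch of N matched pairs,

    L = -(1/N) * sum_i [ log softmax_row(i,i) + log softmax_col(i,i) ]

with temperature tau; the distillation term is the summed squared gap
between teacher and student pair similarities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Parameter, Tensor, sgd_step, zero_grads
from .knowledge import KnowledgeBase


class AlignmentError(ValueError):
    pass


# ---------------------------------------------------------------------------
# patch featurization (shared with the detector)

def patch_features(image: np.ndarray, boxes: np.ndarray, patch: int = 8) -> np.ndarray:
    """Fixed-length appearance features for each box: an ``n x 3*patch^2``
    matrix of area-averaged RGB crops scaled to [0, 1].

    Area averaging (integral-image cell means) is robust to the small box
    misalignments typical of region proposals, unlike point sampling.
    """
    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
    n = len(boxes)
    h, w = image.shape[:2]
    if n == 0:
        return np.zeros((0, 3 * patch * patch))
    img = image.astype(np.float64) / 255.0
    # integral image with a zero border: S[y, x] = sum of img[:y, :x]
    integral = np.zeros((h + 1, w + 1, 3))
    np.cumsum(np.cumsum(img, axis=0), axis=1, out=integral[1:, 1:])
    ix0 = np.clip(np.floor(boxes[:, 0]), 0, w - 1).astype(int)
    iy0 = np.clip(np.floor(boxes[:, 1]), 0, h - 1).astype(int)
    ix1 = np.clip(np.ceil(boxes[:, 2]), ix0 + 1, w).astype(int)
    iy1 = np.clip(np.ceil(boxes[:, 3]), iy0 + 1, h).astype(int)
    frac = np.arange(patch + 1) / patch
    ex = np.round(ix0[:, None] + (ix1 - ix0)[:, None] * frac[None, :]).astype(int)
    ey = np.round(iy0[:, None] + (iy1 - iy0)[:, None] * frac[None, :]).astype(int)
    exh = np.maximum(ex[:, 1:], ex[:, :-1] + 1)
    eyh = np.maximum(ey[:, 1:], ey[:, :-1] + 1)
    exl, eyl = ex[:, :-1], ey[:, :-1]
    area = (eyh - eyl)[:, :, None] * (exh - exl)[:, None, :]
    cell = (
        integral[eyh[:, :, None], exh[:, None, :]]
        - integral[eyl[:, :, None], exh[:, None, :]]
        - integral[eyh[:, :, None], exl[:, None, :]]
        + integral[eyl[:, :, None], exl[:, None, :]]
    )
    return (cell / area[..., None]).reshape(n, -1)


class ImageEncoder:
    """Trainable region encoder V: a small tanh MLP from patch features to
    the shared d-dim image-text space."""

    def __init__(self, d_in: int, d_out: int, hidden: int = 64, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.W1 = Parameter(rng.normal(0, 1 / np.sqrt(d_in), (d_in, hidden)))
        self.b1 = Parameter(np.zeros(hidden))
        self.W2 = Parameter(rng.normal(0, 1 / np.sqrt(hidden), (hidden, d_out)))
        self.b2 = Parameter(np.zeros(d_out))
        self.d_in, self.d_out, self.hidden = d_in, d_out, hidden

    def __call__(self, X) -> Tensor:
        X = X if isinstance(X, Tensor) else Tensor(X)
        return (X @ self.W1 + self.b1).tanh() @ self.W2 + self.b2

    def encode(self, X: np.ndarray) -> np.ndarray:
        return self(X).data

    @property
    def params(self) -> list[Parameter]:
        return [self.W1, self.b1, self.W2, self.b2]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {n: getattr(self, n).data.copy() for n in ("W1", "b1", "W2", "b2")}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for n in ("W1", "b1", "W2", "b2"):
            getattr(self, n).data = np.asarray(state[n], dtype=np.float64).copy()


# ---------------------------------------------------------------------------
# containers

@dataclass
class RegionFeatureSet:
    proposals: np.ndarray  # (n, 4) boxes
    features: np.ndarray  # (n, d) student features V
    teacher_features: np.ndarray | None = None

    def __post_init__(self):
        self.proposals = np.asarray(self.proposals, dtype=np.float64).reshape(-1, 4)
        self.features = np.atleast_2d(np.asarray(self.features, dtype=np.float64))
        if len(self.proposals) != len(self.features):
            raise AlignmentError("proposals and features must align")
        if not np.isfinite(self.features).all():
            raise AlignmentError("non-finite region features")


@dataclass
class TextFeatureSet:
    features: np.ndarray  # (N, d)

    def __post_init__(self):
        self.features = np.atleast_2d(np.asarray(self.features, dtype=np.float64))
        if not np.isfinite(self.features).all():
            raise AlignmentError("non-finite text features")


@dataclass
class AlignmentConfig:
    temperature: float = 0.1
    batch_size: int = 16
    distill_weight: float = 1.0
    lr: float = 0.15
    epochs: int = 40
    patch: int = 8
    d: int = 32

    def __post_init__(self):
        if not 0.0 < self.temperature < 1.0:
            raise AlignmentError(
                f"temperature must lie in (0, 1), got {self.temperature}"
            )
        if self.lr < 0 or self.batch_size < 1:
            raise AlignmentError("invalid optimizer settings")


# ---------------------------------------------------------------------------
# similarities and losses (numpy surface; Tensor versions power training)

def pairwise_similarity(f: np.ndarray, g: np.ndarray) -> float:
    """Cosine similarity ``(f.g)/(|f||g|)`` of two feature vectors."""
    f = np.asarray(f, dtype=np.float64).reshape(-1)
    g = np.asarray(g, dtype=np.float64).reshape(-1)
    if f.shape != g.shape:
        raise AlignmentError(f"dimension mismatch: {f.shape} vs {g.shape}")
    nf, ng = np.linalg.norm(f), np.linalg.norm(g)
    if nf == 0 or ng == 0:
        raise AlignmentError("cosine similarity undefined for a zero vector")
    return float(f @ g / (nf * ng))


def match_probability(s_row: np.ndarray, tau: float) -> np.ndarray:
    """Softmax over similarities with temperature ``tau`` in (0, 1)."""
    if not 0.0 < tau < 1.0:
        raise AlignmentError(f"temperature must lie in (0, 1), got {tau}")
    s = np.asarray(s_row, dtype=np.float64) / tau
    if not np.isfinite(s).all():
        raise AlignmentError("non-finite similarities")
    e = np.exp(s - s.max())
    return e / e.sum()


def _contrastive_t(S: Tensor, tau: float) -> Tensor:
    n = S.shape[0]
    row = (S / tau).log_softmax(axis=1)
    col = (S / tau).log_softmax(axis=0)
    diag = np.arange(n)
    return -(row[diag, diag].sum() + col[diag, diag].sum()) / n


def contrastive_loss(S: np.ndarray | Tensor, tau: float) -> float | Tensor:
    """Symmetric contrastive loss over a square similarity matrix.

    The diagonal holds the matched region-text pairs; the sum of the two
    directional terms is divided by the batch size once.
    """
    if tau <= 0:
        raise AlignmentError(f"temperature must be positive, got {tau}")
    is_tensor = isinstance(S, Tensor)
    St = S if is_tensor else Tensor(np.asarray(S, dtype=np.float64))
    if St.ndim != 2 or St.shape[0] != St.shape[1]:
        raise AlignmentError(f"similarity matrix must be square, got {St.shape}")
    out = _contrastive_t(St, tau)
    return out if is_tensor else float(out.data)


def distillation_loss(
    s_teacher: np.ndarray, s_student: np.ndarray | Tensor
) -> float | Tensor:
    """Summed squared teacher-student similarity gap."""
    t = np.asarray(s_teacher, dtype=np.float64).reshape(-1)
    is_tensor = isinstance(s_student, Tensor)
    s = s_student if is_tensor else Tensor(np.asarray(s_student, dtype=np.float64).reshape(-1))
    if t.shape != tuple(s.shape):
        raise AlignmentError(f"length mismatch: {t.shape} vs {tuple(s.shape)}")
    out = ((s - Tensor(t)) ** 2).sum()
    return out if is_tensor else float(out.data)


def cosine_matrix_t(V: Tensor, T: np.ndarray) -> Tensor:
    """Differentiable cosine-similarity matrix between region features and
    (fixed) text features."""
    vnorm = ((V**2).sum(axis=1, keepdims=True)) ** 0.5
    Vn = V / vnorm
    Tn = T / np.linalg.norm(T, axis=1, keepdims=True)
    return Vn @ Tensor(Tn.T)


# ---------------------------------------------------------------------------
# teacher and pretraining

def _pair_pool(
    scenes,
    kb: KnowledgeBase,
    patch: int,
    seed: int = 0,
    bg_per_scene: int = 6,
    jitter: float = 0.15,
):
    """Matched (patch feature, text row) pairs from ground-truth boxes,
    plus jitter-augmented copies (so the alignment is robust to the box
    misalignment of real region proposals) and background crops paired
    with the background concept row.

    Returns ``(features, rows, texts)`` where ``texts`` stacks ``kb.T``
    with the background text feature as its last row.
    """
    from .detector import iou_matrix  # deferred: detector imports this module

    rng = np.random.default_rng(seed)
    feats, rows = [], []
    row_of = {sid: i for i, sid in enumerate(kb.species_ids)}
    bg_row = len(kb.species_ids)
    for scene in scenes:
        h, w = scene.image.shape[:2]
        if scene.n_targets:
            aug = []
            for box in scene.boxes:
                bw, bh = box[2] - box[0], box[3] - box[1]
                shift = rng.uniform(-jitter, jitter, 4) * np.array([bw, bh, bw, bh])
                jit = np.clip(box + shift, [0, 0, 1, 1], [w - 1, h - 1, w, h])
                aug.append(jit if jit[2] > jit[0] and jit[3] > jit[1] else box)
            all_boxes = np.vstack([scene.boxes, np.asarray(aug)])
            X = patch_features(scene.image, all_boxes, patch)
            for x, label in zip(X, np.concatenate([scene.labels, scene.labels])):
                feats.append(x)
                rows.append(row_of[int(label)])
        if kb.t_bg is not None:
            for _ in range(bg_per_scene):
                bw, bh = rng.uniform(10, w / 2), rng.uniform(10, h / 2)
                x0, y0 = rng.uniform(0, w - bw), rng.uniform(0, h - bh)
                cand = np.array([x0, y0, x0 + bw, y0 + bh])
                if scene.n_targets and iou_matrix(cand[None], scene.boxes).max() >= 0.2:
                    continue
                feats.append(patch_features(scene.image, cand[None], patch)[0])
                rows.append(bg_row)
    if not feats:
        raise AlignmentError("no ground-truth boxes available for pretraining")
    texts = kb.T if kb.t_bg is None else np.vstack([kb.T, kb.t_bg[None, :]])
    return np.stack(feats), np.asarray(rows), texts


def train_teacher(
    scenes, kb: KnowledgeBase, config: AlignmentConfig | None = None, seed: int = 0
) -> ImageEncoder:
    """Contrastively train the teacher encoder on the corpus, then freeze."""
    config = config or AlignmentConfig()
    enc = ImageEncoder(3 * config.patch**2, config.d, seed=seed)
    _run_alignment(scenes, kb, enc, None, config, seed, epochs=config.epochs)
    for p in enc.params:
        p.requires_grad = False
    return enc


def _dedupe(idx: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Keep one pair per concept row: duplicate texts inside a contrastive
    batch would turn matched pairs into spurious negatives."""
    keep, seen = [], set()
    for i in idx:
        if rows[i] not in seen:
            keep.append(i)
            seen.add(rows[i])
    return np.asarray(keep)


def _run_alignment(scenes, kb, student, teacher, config, seed, epochs):
    X, rows, texts = _pair_pool(scenes, kb, config.patch, seed=seed)
    rng = np.random.default_rng(seed)
    trace = []
    for _ in range(epochs):
        order = rng.permutation(len(X))
        ep_con, ep_dis, nb = 0.0, 0.0, 0
        for start in range(0, len(order), config.batch_size):
            idx = _dedupe(order[start : start + config.batch_size], rows)
            if len(idx) < 2:
                continue
            V = student(X[idx])
            Tbatch = texts[rows[idx]]
            S = cosine_matrix_t(V, Tbatch)
            loss = contrastive_loss(S, config.temperature)
            con = float(loss.data)
            dis = 0.0
            if teacher is not None and config.distill_weight > 0:
                Vt = teacher.encode(X[idx])
                Tn = Tbatch / np.linalg.norm(Tbatch, axis=1, keepdims=True)
                Vtn = Vt / np.linalg.norm(Vt, axis=1, keepdims=True)
                s_teacher = np.sum(Vtn * Tn, axis=1)
                diag = np.arange(len(idx))
                s_student = S[diag, diag]
                dloss = distillation_loss(s_teacher, s_student)
                dis = float(dloss.data)
                loss = loss + config.distill_weight * dloss
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"alignment training diverged (loss={loss.data!r}); "
                    "reduce the learning rate"
                )
            zero_grads(student.params)
            loss.backward()
            sgd_step(student.params, config.lr)
            ep_con += con
            ep_dis += dis
            nb += 1
        trace.append((ep_con / max(nb, 1), ep_dis / max(nb, 1)))
    return trace


def pretrain_region_encoder(
    scenes,
    kb: KnowledgeBase,
    teacher: ImageEncoder | None,
    config: AlignmentConfig | None = None,
    seed: int = 0,
) -> tuple[ImageEncoder, list[tuple[float, float]]]:
    """Train the student region encoder with contrastive + distillation loss.

    Returns the trained student and a per-epoch ``(contrastive,
    distillation)`` loss trace.  Deterministic given ``seed``; aborts on
    divergence.
    """
    config = config or AlignmentConfig()
    student = ImageEncoder(3 * config.patch**2, config.d, seed=seed + 1)
    trace = _run_alignment(scenes, kb, student, teacher, config, seed, config.epochs)
    return student, trace
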