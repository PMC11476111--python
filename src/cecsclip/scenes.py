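"""Synthetic camera-trap scene generator.

Real camera-trap corpora of endangered wildlife are rarely shareable, so
this module fabricates desk-scale stand-ins with the statistical features
that make the detection problem hard: small targets, partial occlusion,
camouflage (target colour blended toward the local background), clutter,
and empty shots (scenes with no animal at all).  Every scene is rendered
deterministically from ``(catalog, spec, seed)``.

Scenes use continuous pixel coordinates with the origin at the top-left
corner; boxes are ``(x_min, y_min, x_max, y_max)``.  The COCO
``[x, y, width, height]`` convention appears only at serialization.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

SHAPE_FAMILIES = ("blob", "quadruped-silhouette", "bird-silhouette")
TEXTURES = ("plain", "striped", "spotted")


class ConfigurationError(ValueError):
    """Raised when generator inputs violate their invariants."""


@dataclass(frozen=True)
class SpeciesArchetype:
    """Appearance template for one synthetic species."""

    species_id: int
    name: str
    shape_family: str
    base_color: tuple[int, int, int]
    texture: str
    size_range: tuple[int, int]  # (min, max) box side length in px
    camouflage_affinity: float  # blend weight toward the local background

    def __post_init__(self):
        if self.species_id < 0:
            raise ConfigurationError("species_id must be >= 0")
        if self.shape_family not in SHAPE_FAMILIES:
            raise ConfigurationError(f"unknown shape family {self.shape_family!r}")
        if self.texture not in TEXTURES:
            raise ConfigurationError(f"unknown texture {self.texture!r}")
        if self.size_range[0] < 4:
            raise ConfigurationError("size_range.min must be >= 4 px")
        if not 0.0 <= self.camouflage_affinity <= 1.0:
            raise ConfigurationError("camouflage_affinity must lie in [0, 1]")


@dataclass(frozen=True)
class SceneSpec:
    """Parameters controlling one scene draw."""

    width: int = 96
    height: int = 96
    n_targets: int = 3
    occlusion_prob: float = 0.3
    clutter_level: float = 0.4
    lighting: float = 1.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_targets < 0:
            raise ConfigurationError("n_targets must be >= 0")
        for name in ("occlusion_prob", "clutter_level"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.lighting <= 2.0:
            raise ConfigurationError("lighting must lie in (0, 2]")


@dataclass
class AnnotatedScene:
    """An image plus its ground truth.

    ``boxes`` is an ``(n, 4)`` float array of ``(x_min, y_min, x_max,
    y_max)``; ``labels`` and ``occluded_flags`` run parallel to it.
    """

    image: np.ndarray
    boxes: np.ndarray
    labels: np.ndarray
    occluded_flags: np.ndarray
    scene_id: str = ""

    def __post_init__(self):
        self.boxes = np.asarray(self.boxes, dtype=np.float64).reshape(-1, 4)
        self.labels = np.asarray(self.labels, dtype=np.int64).reshape(-1)
        self.occluded_flags = np.asarray(self.occluded_flags, dtype=bool).reshape(-1)
        n = len(self.boxes)
        if not (len(self.labels) == len(self.occluded_flags) == n):
            raise ConfigurationError("boxes, labels and occluded_flags must align")
        h, w = self.image.shape[:2]
        if n:
            if (self.boxes[:, 2] <= self.boxes[:, 0]).any() or (
                self.boxes[:, 3] <= self.boxes[:, 1]
            ).any():
                raise ConfigurationError("degenerate box (non-positive extent)")
            if (
                (self.boxes[:, 0] < 0).any()
                or (self.boxes[:, 1] < 0).any()
                or (self.boxes[:, 2] > w).any()
                or (self.boxes[:, 3] > h).any()
            ):
                raise ConfigurationError("box outside image bounds")

    @property
    def n_targets(self) -> int:
        return len(self.boxes)


# ---------------------------------------------------------------------------
# default species catalog

_DEFAULT_SPECIES = [
    # name, shape family, base colour, texture, size range, camouflage
    ("giant panda", "quadruped-silhouette", (235, 235, 235), "spotted", (18, 40), 0.1),
    ("red panda", "quadruped-silhouette", (190, 90, 40), "striped", (12, 28), 0.3),
    ("tibetan macaque", "blob", (150, 120, 90), "plain", (10, 26), 0.4),
    ("golden snub-nosed monkey", "blob", (220, 170, 60), "plain", (10, 26), 0.2),
    ("porcupine", "blob", (70, 60, 50), "striped", (8, 20), 0.5),
    ("yellow-throated marten", "quadruped-silhouette", (210, 180, 70), "plain", (8, 20), 0.3),
    ("sambar", "quadruped-silhouette", (120, 90, 60), "plain", (20, 44), 0.6),
    ("tufted deer", "quadruped-silhouette", (90, 75, 60), "plain", (16, 36), 0.6),
    ("chinese serow", "quadruped-silhouette", (60, 55, 50), "plain", (16, 36), 0.7),
    ("blue sheep", "quadruped-silhouette", (140, 145, 155), "plain", (14, 32), 0.5),
    ("crested ibis", "bird-silhouette", (240, 230, 225), "plain", (8, 18), 0.2),
]


def default_catalog(n_species: int = 11) -> list[SpeciesArchetype]:
    """A catalog of up to 11 synthetic species archetypes."""
    if not 1 <= n_species <= len(_DEFAULT_SPECIES):
        raise ConfigurationError(f"n_species must be in [1, {len(_DEFAULT_SPECIES)}]")
    return [
        SpeciesArchetype(i, name, fam, color, tex, size, camo)
        for i, (name, fam, color, tex, size, camo) in enumerate(
            _DEFAULT_SPECIES[:n_species]
        )
    ]


def write_catalog(catalog: list[SpeciesArchetype], path: str) -> None:
    recs = [
        {
            "species_id": a.species_id,
            "name": a.name,
            "shape_family": a.shape_family,
            "base_color": list(a.base_color),
            "texture": a.texture,
            "size_range": list(a.size_range),
            "camouflage_affinity": a.camouflage_affinity,
        }
        for a in catalog
    ]
    with open(path, "w") as fh:
        json.dump(recs, fh, indent=1)


def read_catalog(path: str) -> list[SpeciesArchetype]:
    with open(path) as fh:
        recs = json.load(fh)
    return [
        SpeciesArchetype(
            r["species_id"],
            r["name"],
            r["shape_family"],
            tuple(r["base_color"]),
            r["texture"],
            tuple(r["size_range"]),
            r["camouflage_affinity"],
        )
        for r in recs
    ]


# ---------------------------------------------------------------------------
# rendering

def _background(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Habitat-like backdrop: vertical hue gradient plus clutter blobs."""
    h, w = spec.height, spec.width
    top = rng.uniform(60, 110, size=3)  # sky-ish
    bottom = rng.uniform(40, 90, size=3) + np.array([0.0, 25.0, 0.0])  # vegetation
    t = np.linspace(0.0, 1.0, h)[:, None, None]
    img = top[None, None, :] * (1 - t) + bottom[None, None, :] * t
    img = img + rng.normal(0.0, 6.0, size=(h, w, 3))  # sensor-ish grain
    n_blobs = int(round(spec.clutter_level * 12))
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n_blobs):
        cx, cy = rng.uniform(0, w), rng.uniform(0, h)
        rx, ry = rng.uniform(4, w / 4), rng.uniform(3, h / 5)
        tint = rng.uniform(-35, 35, size=3)
        mask = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0
        img[mask] += tint
    return img


def _sprite_mask(family: str, w: int, h: int) -> np.ndarray:
    """Boolean silhouette of a target on a ``h x w`` grid."""
    yy, xx = np.mgrid[0:h, 0:w] + 0.5
    cx, cy = w / 2.0, h / 2.0
    if family == "blob":
        return ((xx - cx) / (w / 2)) ** 2 + ((yy - cy) / (h / 2)) ** 2 <= 1.0
    if family == "quadruped-silhouette":
        body = ((xx - cx) / (w / 2)) ** 2 + ((yy - 0.4 * h) / (0.32 * h)) ** 2 <= 1.0
        head = ((xx - 0.85 * w) / (0.16 * w)) ** 2 + (
            (yy - 0.22 * h) / (0.18 * h)
        ) ** 2 <= 1.0
        legs = np.zeros((h, w), dtype=bool)
        for fx in (0.18, 0.38, 0.62, 0.82):
            legs |= (np.abs(xx - fx * w) <= max(w * 0.05, 0.8)) & (yy >= 0.45 * h)
        return body | head | legs
    # bird-silhouette
    body = ((xx - cx) / (0.38 * w)) ** 2 + ((yy - 0.6 * h) / (0.3 * h)) ** 2 <= 1.0
    head = ((xx - 0.7 * w) / (0.14 * w)) ** 2 + ((yy - 0.3 * h) / (0.16 * h)) ** 2 <= 1.0
    wing = (yy >= 0.25 * h) & (yy <= 0.65 * h) & (xx <= cx) & (
        yy - 0.25 * h >= (cx - xx) * 0.8
    )
    return body | head | wing


def _textured_color(
    arch: SpeciesArchetype, w: int, h: int, rng: np.random.Generator
) -> np.ndarray:
    color = np.broadcast_to(
        np.asarray(arch.base_color, dtype=np.float64), (h, w, 3)
    ).copy()
    if arch.texture == "striped":
        xx = np.arange(w)
        stripes = (xx // max(2, w // 6)) % 2 == 1
        color[:, stripes] *= 0.55
    elif arch.texture == "spotted":
        yy, xx = np.mgrid[0:h, 0:w]
        for _ in range(max(3, (w * h) // 60)):
            sx, sy = rng.uniform(0, w), rng.uniform(0, h)
            r = rng.uniform(1.0, max(1.5, w / 8))
            spot = (xx - sx) ** 2 + (yy - sy) ** 2 <= r**2
            color[spot] *= 0.45
    return color


def _render_scene(
    catalog: list[SpeciesArchetype], spec: SceneSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    h, w = spec.height, spec.width
    img = _background(spec, rng)
    n = spec.n_targets
    boxes = np.zeros((n, 4))
    labels = np.zeros(n, dtype=np.int64)
    occluded = rng.random(n) < spec.occlusion_prob if n else np.zeros(0, dtype=bool)

    # choose species and sizes first so partner placement can see them
    sizes = np.zeros((n, 2))
    for i in range(n):
        arch = catalog[rng.integers(0, len(catalog))]
        labels[i] = arch.species_id
        side = rng.uniform(*arch.size_range)
        aspect = {"blob": 1.0, "quadruped-silhouette": 1.5, "bird-silhouette": 1.2}[
            arch.shape_family
        ]
        bw = min(side * aspect, w - 2.0)
        bh = min(side, h - 2.0)
        sizes[i] = (bw, bh)

    arch_by_id = {a.species_id: a for a in catalog}
    for i in range(n):
        bw, bh = sizes[i]
        if i > 0 and occluded[i - 1]:
            # partner: centre inside the occluded target's box, so the two
            # boxes overlap regardless of clipping
            px0, py0, px1, py1 = boxes[i - 1]
            cx = rng.uniform(px0 + (px1 - px0) * 0.25, px0 + (px1 - px0) * 0.75)
            cy = rng.uniform(py0 + (py1 - py0) * 0.25, py0 + (py1 - py0) * 0.75)
        elif i == n - 1 and n >= 2 and occluded[i]:
            # last target has no successor; overlap the first target instead
            px0, py0, px1, py1 = boxes[0]
            cx = rng.uniform(px0 + (px1 - px0) * 0.25, px0 + (px1 - px0) * 0.75)
            cy = rng.uniform(py0 + (py1 - py0) * 0.25, py0 + (py1 - py0) * 0.75)
        else:
            cx = rng.uniform(bw / 2 + 1, w - bw / 2 - 1)
            cy = rng.uniform(bh / 2 + 1, h - bh / 2 - 1)
        x0 = min(max(cx - bw / 2, 0.0), w - bw - 1e-6)
        y0 = min(max(cy - bh / 2, 0.0), h - bh - 1e-6)
        boxes[i] = (x0, y0, x0 + bw, y0 + bh)

    def blit(i: int) -> None:
        x0, y0, x1, y1 = boxes[i]
        ix0, iy0 = int(math.floor(x0)), int(math.floor(y0))
        ix1, iy1 = int(math.ceil(x1)), int(math.ceil(y1))
        sw, sh = ix1 - ix0, iy1 - iy0
        arch = arch_by_id[int(labels[i])]
        mask = _sprite_mask(arch.shape_family, sw, sh)
        color = _textured_color(arch, sw, sh, rng)
        patch = img[iy0:iy1, ix0:ix1]
        local_bg = patch.reshape(-1, 3).mean(axis=0)
        a = arch.camouflage_affinity
        color = (1 - a) * color + a * local_bg[None, None, :]
        m = mask[: patch.shape[0], : patch.shape[1]]
        patch[m] = color[: patch.shape[0], : patch.shape[1]][m]

    for i in range(n):
        blit(i)
    # re-draw each occluded target's partner so it sits on top; the partner
    # of the last target is whichever box it was placed to overlap
    for i in range(n):
        if occluded[i]:
            if i < n - 1:
                blit(i + 1)
            elif n >= 2:
                blit(n - 2 if occluded[n - 2] else 0)
            else:
                # singleton scene: unlabeled foliage strip across the target
                x0, y0, x1, y1 = boxes[i]
                sx0 = int((x0 + x1) / 2)
                sx1 = min(int(x1), w)
                img[int(y0) : int(y1), sx0:sx1] = np.array([45.0, 80.0, 40.0])

    img = np.clip(img * spec.lighting, 0, 255).astype(np.uint8)
    return img, boxes, labels, occluded


# ---------------------------------------------------------------------------
# public operations

def generate_dataset(
    catalog: list[SpeciesArchetype],
    n_scenes: int,
    spec: SceneSpec,
    seed: int,
) -> list[AnnotatedScene]:
    """Render ``n_scenes`` reproducible scenes from the catalog.

    The same ``(catalog, spec, seed)`` triple yields byte-identical images
    and annotations; each scene draws from an independent child stream of
    ``seed`` so scenes are order-independent.
    """
    if not catalog:
        raise ConfigurationError("catalog must not be empty")
    if n_scenes < 1:
        raise ConfigurationError("n_scenes must be >= 1")
    scenes = []
    for i in range(n_scenes):
        rng = np.random.default_rng([seed, i])
        img, boxes, labels, occ = _render_scene(catalog, spec, rng)
        scenes.append(
            AnnotatedScene(img, boxes, labels, occ, scene_id=f"scene_{i:05d}")
        )
    return scenes


def split_dataset(
    scenes: list[AnnotatedScene],
    fractions: tuple[float, float, float],
    seed: int,
) -> tuple[list[AnnotatedScene], list[AnnotatedScene], list[AnnotatedScene]]:
    """Shuffle and partition into train/val/test.

    Sizes are floor-based; the remainder joins the training split (the
    conventional 70/15/15 protocol leaves no remainder at round sizes).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError(f"fractions must sum to 1, got {sum(fractions)}")
    n = len(scenes)
    idx = np.random.default_rng(seed).permutation(n)
    n_val = int(math.floor(fractions[1] * n))
    n_test = int(math.floor(fractions[2] * n))
    n_train = n - n_val - n_test
    train = [scenes[i] for i in idx[:n_train]]
    val = [scenes[i] for i in idx[n_train : n_train + n_val]]
    test = [scenes[i] for i in idx[n_train + n_val :]]
    return train, val, test


def write_coco(
    scenes: list[AnnotatedScene],
    path: str,
    catalog: list[SpeciesArchetype] | None = None,
) -> str:
    """Write scenes as PNGs plus a COCO-style annotation file.

    ``path`` is a directory; images land in ``path/images`` and the
    annotation JSON at ``path/annotations.json``.  Returns the JSON path.
    """
    img_dir = os.path.join(path, "images")
    os.makedirs(img_dir, exist_ok=True)
    names = {a.species_id: a.name for a in catalog} if catalog else {}
    cat_ids = sorted(
        set(int(l) for s in scenes for l in s.labels) | set(names.keys())
    )
    doc = {
        "images": [],
        "annotations": [],
        "categories": [
            {"id": cid, "name": names.get(cid, f"species_{cid}")} for cid in cat_ids
        ],
    }
    ann_id = 0
    for img_id, scene in enumerate(scenes):
        fname = f"{scene.scene_id or f'scene_{img_id:05d}'}.png"
        Image.fromarray(scene.image).save(os.path.join(img_dir, fname))
        h, w = scene.image.shape[:2]
        doc["images"].append(
            {"id": img_id, "file_name": fname, "width": w, "height": h}
        )
        for box, label, occ in zip(scene.boxes, scene.labels, scene.occluded_flags):
            x0, y0, x1, y1 = (float(v) for v in box)
            doc["annotations"].append(
                {
                    "id": ann_id,
                    "image_id": img_id,
                    "category_id": int(label),
                    "bbox": [x0, y0, x1 - x0, y1 - y0],
                    "area": (x1 - x0) * (y1 - y0),
                    "iscrowd": 0,
                    "attributes": {"occluded": bool(occ)},
                }
            )
            ann_id += 1
    ann_path = os.path.join(path, "annotations.json")
    with open(ann_path, "w") as fh:
        json.dump(doc, fh)
    return ann_path


def read_coco(path: str) -> list[AnnotatedScene]:
    """Read back a dataset written by :func:`write_coco`.

    Raises ``IOError`` naming the offending record on malformed boxes or
    missing image files.
    """
    ann_path = path if path.endswith(".json") else os.path.join(path, "annotations.json")
    root = os.path.dirname(ann_path)
    try:
        with open(ann_path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as e:
        raise IOError(f"malformed annotation JSON at {ann_path}: {e}") from e
    by_image: dict[int, list[dict]] = {}
    for k, ann in enumerate(doc.get("annotations", [])):
        bw, bh = ann["bbox"][2], ann["bbox"][3]
        if bw <= 0 or bh <= 0:
            raise IOError(
                f"annotation record {k} (id={ann.get('id')}) has degenerate "
                f"bbox {ann['bbox']}"
            )
        by_image.setdefault(ann["image_id"], []).append(ann)
    scenes = []
    for rec in doc["images"]:
        img_path = os.path.join(root, "images", rec["file_name"])
        if not os.path.exists(img_path):
            raise IOError(f"image record {rec['id']}: missing file {img_path}")
        img = np.asarray(Image.open(img_path).convert("RGB"))
        anns = by_image.get(rec["id"], [])
        boxes = np.array(
            [
                [a["bbox"][0], a["bbox"][1], a["bbox"][0] + a["bbox"][2], a["bbox"][1] + a["bbox"][3]]
                for a in anns
            ]
        ).reshape(-1, 4)
        labels = np.array([a["category_id"] for a in anns], dtype=np.int64)
        occ = np.array(
            [bool(a.get("attributes", {}).get("occluded", False)) for a in anns],
            dtype=bool,
        )
        scenes.append(
            AnnotatedScene(img, boxes, labels, occ, scene_id=os.path.splitext(rec["file_name"])[0])
        )
    return scenes
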