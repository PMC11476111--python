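"""Expert knowledge base: species descriptors and their encoded features.

Each species gets a textual visual description rendered from a
deterministic template engine (a seedable stand-in for LLM-generated
descriptor text), an embedded description vector ``s_n``, an embedded
class-label vector ``c_n``, their sum ``e_n = s_n + c_n`` (the composed
knowledge vector), and an encoded text feature ``t_n`` produced by a
small frozen text encoder.

The description text is embedded with a hashing trick (signed token
hashing via md5, so the embedding is stable across processes); labels use
one-hot padding into the same dimension ``d`` so that the addition
``E = S + C`` is well-typed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .scenes import SpeciesArchetype


class KnowledgeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# descriptor construction

_COLOR_NAMES = [
    ((245, 245, 245), "white"),
    ((20, 20, 20), "black"),
    ((128, 128, 128), "gray"),
    ((120, 90, 60), "brown"),
    ((190, 90, 40), "russet"),
    ((220, 170, 60), "golden"),
    ((210, 180, 70), "yellow"),
    ((140, 145, 155), "slate"),
    ((70, 60, 50), "dark brown"),
    ((235, 235, 235), "ivory"),
]

_SHAPE_PHRASES = {
    "blob": "stocky rounded",
    "quadruped-silhouette": "four-legged",
    "bird-silhouette": "winged",
}

_TEMPLATES = [
    (
        "a {size} {shape} animal with a {texture} {color} coat, "
        "distinguished by {mark}, often seen in {habitat}"
    ),
    (
        "the {color} {texture} pelage and {shape} body of this {size} species "
        "stand out; its {mark} aids identification in {habitat}"
    ),
    (
        "{size} in stature and {shape}, this species shows {texture} {color} "
        "fur and {mark}; it frequents {habitat}"
    ),
]

_HABITATS = ["dense bamboo understory", "montane forest", "rocky alpine slopes", "river valleys"]


def color_name(rgb: tuple[int, int, int]) -> str:
    """Nearest named colour by squared RGB distance."""
    arr = np.asarray(rgb, dtype=np.float64)
    dists = [((arr - np.asarray(c)) ** 2).sum() for c, _ in _COLOR_NAMES]
    return _COLOR_NAMES[int(np.argmin(dists))][1]


def _size_class(size_range: tuple[int, int]) -> str:
    mid = sum(size_range) / 2
    return "small" if mid < 16 else ("medium-sized" if mid < 30 else "large")


def _distinctive_mark(arch: SpeciesArchetype) -> str:
    if arch.texture == "striped":
        return "bold flank stripes"
    if arch.texture == "spotted":
        return "contrasting dark patches"
    if arch.camouflage_affinity >= 0.5:
        return "cryptic background-matching coloration"
    return "a plain unmarked coat"


@dataclass
class ConceptDescriptor:
    """Structured visual attributes and rendered description for a species."""

    species_id: int
    attributes: dict[str, str]
    rendered_text: str

    def __post_init__(self):
        if not self.attributes:
            raise KnowledgeError("attributes must be non-empty")
        if not self.rendered_text:
            raise KnowledgeError("rendered_text must be non-empty")


def build_descriptions(
    catalog: list[SpeciesArchetype],
    template_set: list[str] | None = None,
    seed: int = 0,
) -> list[ConceptDescriptor]:
    """One rendered descriptor per species, deterministically templated.

    The rendered text mentions every archetype attribute: colour words,
    shape family, texture, size class, and a distinctive mark.
    """
    if not catalog:
        raise KnowledgeError("catalog must not be empty")
    templates = template_set or _TEMPLATES
    rng = np.random.default_rng(seed)
    out = []
    for arch in catalog:
        attrs = {
            "name": arch.name,
            "color": color_name(arch.base_color),
            "shape": _SHAPE_PHRASES[arch.shape_family],
            "texture": arch.texture,
            "size": _size_class(arch.size_range),
            "mark": _distinctive_mark(arch),
            "habitat": _HABITATS[int(rng.integers(0, len(_HABITATS)))],
        }
        tmpl = templates[int(rng.integers(0, len(templates)))]
        text = f"{arch.name}: " + tmpl.format(**attrs)
        out.append(ConceptDescriptor(arch.species_id, attrs, text))
    return out


# ---------------------------------------------------------------------------
# embeddings

def _token_hash(token: str, d: int) -> tuple[int, float]:
    h = hashlib.md5(token.encode()).digest()
    idx = int.from_bytes(h[:4], "little") % d
    sign = 1.0 if h[4] % 2 == 0 else -1.0
    return idx, sign


def embed_text(text: str, d: int) -> np.ndarray:
    """Signed token-hash embedding, averaged over tokens."""
    tokens = [t for t in text.lower().replace(",", " ").replace(":", " ").replace(";", " ").split() if t]
    v = np.zeros(d)
    for tok in tokens:
        idx, sign = _token_hash(tok, d)
        v[idx] += sign
    return v / max(len(tokens), 1)


def embed_descriptions(descriptors: list[ConceptDescriptor], d: int) -> np.ndarray:
    """Stack description vectors ``s_n`` into an ``N x d`` matrix ``S``."""
    return np.stack([embed_text(desc.rendered_text, d) for desc in descriptors])


def embed_labels(N: int, d: int, projection_seed: int | None = None) -> np.ndarray:
    """Class-label vectors ``c_n`` as an ``N x d`` matrix ``C``.

    Default scheme pads the one-hot label into ``d`` dimensions (requires
    ``d >= N``); with ``projection_seed`` set, a seeded random linear
    projection maps the one-hot vectors into any ``d``.
    """
    if N < 1:
        raise KnowledgeError("N must be >= 1")
    if projection_seed is None:
        if d < N:
            raise KnowledgeError(
                f"one-hot padding needs d >= N (got d={d}, N={N}); "
                "configure a projection instead"
            )
        C = np.zeros((N, d))
        C[np.arange(N), np.arange(N)] = 1.0
        return C
    proj = np.random.default_rng(projection_seed).normal(0, 1 / np.sqrt(N), (N, d))
    return np.eye(N) @ proj


def compose_knowledge(S: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Elementwise composition ``E = S + C`` of descriptions and labels."""
    S, C = np.asarray(S, dtype=np.float64), np.asarray(C, dtype=np.float64)
    if S.shape != C.shape:
        raise KnowledgeError(f"shape mismatch: S is {S.shape}, C is {C.shape}")
    return S + C


class TextEncoder:
    """Small frozen two-layer text encoder ``L`` mapping ``E`` rows to ``T``.

    Weights are drawn once from ``seed`` and never updated, mirroring a
    frozen pretrained language encoder.
    """

    def __init__(self, d_in: int, d_out: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        h = max(d_in, d_out)
        self.W1 = rng.normal(0, 1 / np.sqrt(d_in), (d_in, h))
        self.W2 = rng.normal(0, 1 / np.sqrt(h), (h, d_out))
        self.d_in, self.d_out = d_in, d_out

    def __call__(self, E: np.ndarray) -> np.ndarray:
        E = np.asarray(E, dtype=np.float64)
        if E.ndim != 2 or E.shape[1] != self.d_in:
            raise KnowledgeError(
                f"encoder expects (N, {self.d_in}) input, got {E.shape}"
            )
        return np.tanh(E @ self.W1) @ self.W2


def encode_texts(E: np.ndarray, encoder: TextEncoder) -> np.ndarray:
    """Encoded semantic features ``T = L(E)``; one row per species."""
    T = encoder(np.atleast_2d(E))
    if not np.isfinite(T).all():
        raise KnowledgeError("encoder produced non-finite features")
    return T


# ---------------------------------------------------------------------------
# the assembled knowledge base

BACKGROUND_TEXT = (
    "empty habitat background: vegetation, foliage, rocks, soil, sky and "
    "shadow with no animal present"
)


@dataclass
class KnowledgeBase:
    """All text-side artifacts for a catalog of ``N`` species.

    ``t_bg`` is the encoded background concept (descriptor text with a
    zero label vector): it anchors non-animal regions in the shared space
    so region features can discriminate species from habitat.
    """

    descriptors: list[ConceptDescriptor]
    S: np.ndarray
    C: np.ndarray
    E: np.ndarray
    T: np.ndarray
    species_ids: list[int] = field(default_factory=list)
    t_bg: np.ndarray | None = None

    @property
    def N(self) -> int:
        return self.S.shape[0]

    def row_for(self, species_id: int) -> int:
        return self.species_ids.index(species_id)


def build_knowledge_base(
    catalog: list[SpeciesArchetype],
    d: int = 32,
    d_enc: int = 32,
    seed: int = 0,
) -> KnowledgeBase:
    """Descriptor texts -> S, C, E = S + C, T = L(E), in one call."""
    descs = build_descriptions(catalog, seed=seed)
    N = len(descs)
    S = embed_descriptions(descs, d)
    C = embed_labels(N, d) if d >= N else embed_labels(N, d, projection_seed=seed)
    E = compose_knowledge(S, C)
    encoder = TextEncoder(d, d_enc, seed=seed)
    T = encode_texts(E, encoder)
    # background concept: description only, zero label vector
    t_bg = encode_texts(embed_text(BACKGROUND_TEXT, d)[None, :], encoder)[0]
    return KnowledgeBase(descs, S, C, E, T, [a.species_id for a in catalog], t_bg)


def write_knowledge_base(kb: KnowledgeBase, path: str) -> None:
    doc = {
        "species": [
            {
                "species_id": desc.species_id,
                "attributes": desc.attributes,
                "rendered_text": desc.rendered_text,
            }
            for desc in kb.descriptors
        ],
        "S": kb.S.tolist(),
        "C": kb.C.tolist(),
        "E": kb.E.tolist(),
        "T": kb.T.tolist(),
        "species_ids": kb.species_ids,
        "t_bg": None if kb.t_bg is None else kb.t_bg.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_knowledge_base(path: str) -> KnowledgeBase:
    with open(path) as fh:
        doc = json.load(fh)
    descs = [
        ConceptDescriptor(r["species_id"], r["attributes"], r["rendered_text"])
        for r in doc["species"]
    ]
    return KnowledgeBase(
        descs,
        np.asarray(doc["S"]),
        np.asarray(doc["C"]),
        np.asarray(doc["E"]),
        np.asarray(doc["T"]),
        list(doc["species_ids"]),
        None if doc.get("t_bg") is None else np.asarray(doc["t_bg"]),
    )
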