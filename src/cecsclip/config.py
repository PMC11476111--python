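"""Run configuration: one YAML document covering dataset, model, training
and evaluation settings, with full defaulting.

Every constant the method leaves open — the contrastive temperature tau,
the scale-factor initial value and learnability, size bands, the
smooth-L1 mode, confidence and NMS thresholds — surfaces here so a run
can be audited or toggled to the literal printed formulas.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .detector import DetectorConfig, RPNParams, VARIANTS
from .scenes import SceneSpec


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    seed: int = 0
    # dataset
    catalog_path: str | None = None
    n_species: int = 3
    n_scenes: int = 200
    split: tuple[float, float, float] = (0.7, 0.15, 0.15)
    scene: SceneSpec = field(default_factory=lambda: SceneSpec(width=96, height=96, n_targets=3))
    # knowledge / alignment
    d: int = 32
    tau: float = 0.1
    pretrain_epochs: int = 10
    distill_weight: float = 1.0
    # detector
    variant: str = "cecs"
    iterations: int = 500
    lr: float = 0.1
    alpha_init: float = 0.9
    alpha_learnable: bool = True
    alpha_eta: float = 0.02
    reg_mode: str = "continuous"
    contrastive_in_finetune: bool = True
    # evaluation
    score_threshold: float = 0.5
    nms_iou: float = 0.5
    eval_iou: float = 0.5

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ConfigError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.reg_mode not in ("continuous", "literal"):
            raise ConfigError("reg_mode must be 'continuous' or 'literal'")

    def detector_config(self) -> DetectorConfig:
        return DetectorConfig(
            variant=self.variant,
            d=self.d,
            iterations=self.iterations,
            lr=self.lr,
            alpha_init=self.alpha_init,
            alpha_eta=self.alpha_eta,
            tau=self.tau,
            contrastive_in_finetune=self.contrastive_in_finetune,
            reg_mode=self.reg_mode,
            score_threshold=self.score_threshold,
            nms_iou=self.nms_iou,
            rpn=RPNParams(),
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["split"] = list(self.split)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path: str | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config (all keys optional) and apply CLI overrides."""
    doc: dict = {}
    if path:
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
    if overrides:
        doc.update({k: v for k, v in overrides.items() if v is not None})
    scene_doc = doc.pop("scene", None)
    if "split" in doc:
        doc["split"] = tuple(doc["split"])
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**doc)
    if scene_doc:
        cfg.scene = SceneSpec(**scene_doc)
    return cfg
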