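"""Desk-scale experiment protocols: corpus building, the four-variant
ablation, and the empty-shot robustness test.

The toy study conditions are fixed here: 3 species, 96x96 scenes, 200
training scenes with a 70/15/15 split, 500 detector iterations, and 50
empty scenes for the absence test.  The ablation compares the mean test
mAP of the variants {baseline, ce, cs, cecs} over several seeds with an
otherwise identical training recipe; it checks the direction of the
module contributions, not any absolute benchmark value.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .alignment import AlignmentConfig, pretrain_region_encoder, train_teacher
from .detector import DetectorConfig, DetectorModel, RPNParams, train_detector
from .evaluation import EvalReport, absence_detection, evaluate_detector
from .knowledge import KnowledgeBase, build_knowledge_base
from .scenes import SceneSpec, default_catalog, generate_dataset, split_dataset

TOY_N_SPECIES = 3
TOY_N_SCENES = 200
TOY_ITERATIONS = 500
TOY_SCENE = SceneSpec(width=96, height=96, n_targets=3, occlusion_prob=0.3, clutter_level=0.4)
TOY_N_EMPTY = 50


def build_toy_corpus(
    n_species: int = TOY_N_SPECIES,
    n_scenes: int = TOY_N_SCENES,
    scene_spec: SceneSpec = TOY_SCENE,
    seed: int = 0,
):
    """Catalog, knowledge base, and 70/15/15 scene splits for toy runs."""
    catalog = default_catalog(n_species)
    scenes = generate_dataset(catalog, n_scenes, scene_spec, seed)
    train, val, test = split_dataset(scenes, (0.7, 0.15, 0.15), seed)
    kb = build_knowledge_base(catalog, seed=seed)
    return catalog, kb, train, val, test


def pretrain_encoder(kb: KnowledgeBase, train_scenes, seed: int = 0) -> dict:
    """Teacher training plus distilled student pretraining; returns the
    student encoder weights used to initialize detector fine-tuning."""
    acfg = AlignmentConfig()
    teacher = train_teacher(train_scenes, kb, acfg, seed=seed)
    student, _ = pretrain_region_encoder(train_scenes, kb, teacher, acfg, seed=seed)
    return student.state_dict()


def train_variant(
    variant: str,
    kb: KnowledgeBase,
    train_scenes,
    seed: int = 0,
    iterations: int = TOY_ITERATIONS,
    encoder_init: dict | None = None,
) -> DetectorModel:
    if encoder_init is None:
        encoder_init = pretrain_encoder(kb, train_scenes, seed=seed)
    config = DetectorConfig(variant=variant, iterations=iterations, rpn=RPNParams())
    model, _ = train_detector(
        train_scenes, kb, config, seed=seed, encoder_init=encoder_init
    )
    return model


def run_ablation(
    variants=("baseline", "ce", "cs", "cecs"),
    seeds=(0, 1, 2, 3, 4),
    n_species: int = TOY_N_SPECIES,
    n_scenes: int = TOY_N_SCENES,
    iterations: int = TOY_ITERATIONS,
    corpus_seed: int = 0,
) -> dict[str, dict[str, float]]:
    """Mean test metrics per variant over seeds.

    Every variant sees the same corpus, the same split and the same seed
    list; only the module toggles differ.  Returns
    ``{variant: {AP, AP50, APs, APm, APl}}`` where AP is mAP50:95 and
    AP50 is mAP at IoU 0.5, averaged over seeds (absent size bands are
    skipped in the averages).
    """
    _, kb, train, _, test = build_toy_corpus(n_species, n_scenes, seed=corpus_seed)
    encoders = {s: pretrain_encoder(kb, train, seed=s) for s in seeds}
    results: dict[str, dict[str, float]] = {}
    for variant in variants:
        rows = []
        for seed in seeds:
            model = train_variant(
                variant, kb, train, seed=seed, iterations=iterations,
                encoder_init=encoders[seed],
            )
            rep = evaluate_detector(model, test)
            rows.append(
                {
                    "AP": rep.mAP_50_95,
                    "AP50": rep.mAP,
                    "APs": rep.ap_small,
                    "APm": rep.ap_medium,
                    "APl": rep.ap_large,
                }
            )
        results[variant] = {
            k: float(np.mean([r[k] for r in rows if r[k] is not None]))
            if any(r[k] is not None for r in rows)
            else float("nan")
            for k in rows[0]
        }
    return results


def empty_shot_test(
    model: DetectorModel,
    n_empty: int = TOY_N_EMPTY,
    scene_spec: SceneSpec = TOY_SCENE,
    seed: int = 1000,
) -> float:
    """Absence-detection rate on freshly generated empty scenes."""
    empty_spec = replace(scene_spec, n_targets=0)
    catalog = default_catalog(TOY_N_SPECIES)
    scenes = generate_dataset(catalog, n_empty, empty_spec, seed)
    return absence_detection(scenes, model)
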