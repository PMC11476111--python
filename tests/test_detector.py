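"""Two-stage detector: box arithmetic, proposals, losses, training
behaviour, and the ablation identity."""

import numpy as np
import pytest

from cecsclip.detector import (
    Detection,
    DetectorConfig,
    DetectorError,
    DetectorModel,
    RPNParams,
    classification_loss,
    decode_box,
    detect,
    encode_box,
    iou,
    nms,
    propose_regions,
    regression_loss,
    total_loss,
    train_detector,
)

RNG = np.random.default_rng(17)


# -- iou ----------------------------------------------------------------------

@pytest.mark.parametrize(
    "a,b,expected",
    [
        ((0, 0, 10, 10), (0, 0, 10, 10), 1.0),
        ((0, 0, 10, 10), (20, 20, 30, 30), 0.0),
        ((0, 0, 10, 10), (5, 0, 15, 10), 1 / 3),  # inter 50, union 150
    ],
)
def test_iou_values(a, b, expected):
    assert iou(a, b) == pytest.approx(expected, abs=1e-12)
    assert iou(b, a) == pytest.approx(expected, abs=1e-12)


def test_iou_degenerate_box_rejected():
    with pytest.raises(DetectorError):
        iou((0, 0, 0, 10), (0, 0, 10, 10))


# -- box encode / decode ------------------------------------------------------

def test_box_encode_decode_round_trip():
    for _ in range(50):
        x0, y0 = RNG.uniform(0, 40, 2)
        gt = np.array([x0, y0, x0 + RNG.uniform(2, 30), y0 + RNG.uniform(2, 30)])
        anchor = np.array([5.0, 5.0, 25.0, 30.0]) + RNG.uniform(-2, 2, 4)
        anchor[2:] = np.maximum(anchor[2:], anchor[:2] + 1.0)
        back = decode_box(anchor, encode_box(gt, anchor))
        assert np.abs(back - gt).max() < 1e-9


# -- classification loss ------------------------------------------------------

def test_classification_loss_values():
    assert classification_loss([1.0, 0.0], [1, 0]) == 0.0
    assert classification_loss([0.5, 0.5], [1, 0]) == pytest.approx(
        np.log(2), abs=1e-9
    )


def test_classification_loss_monotone_in_true_prob():
    prev = np.inf
    for p in [0.2, 0.5, 0.8, 0.99]:
        val = classification_loss([p, 1 - p], [1, 0])
        assert val < prev
        prev = val


def test_classification_loss_rejects_non_probability():
    with pytest.raises(DetectorError):
        classification_loss([0.9, 0.3], [1, 0])


# -- regression loss ----------------------------------------------------------

@pytest.mark.parametrize(
    "deltas,mode,expected",
    [
        ((0, 0, 0, 0), "continuous", 0.0),
        ((0.5, 0, 0, 0), "continuous", 0.125),
        ((2.0, 0, 0, 0), "continuous", 1.5),
        ((2.0, 0, 0, 0), "literal", 2.0),
    ],
)
def test_regression_loss_branches(deltas, mode, expected):
    assert regression_loss(deltas, mode) == pytest.approx(expected, abs=1e-12)


def test_regression_loss_rejects_non_finite():
    with pytest.raises(DetectorError):
        regression_loss([np.nan, 0, 0, 0])


# -- total loss ---------------------------------------------------------------

def test_total_loss_sums_components():
    assert total_loss(0, 0, 0) == 0.0
    assert total_loss(0.1, 0.2, 0.3) == pytest.approx(0.6)
    assert total_loss(0.1, 0.2, 0.3, weights=(1, 1, 1)) == pytest.approx(0.6)
    parts = (0.4, 1.1, 0.2)
    assert total_loss(*parts) - sum(parts) == 0.0


# -- nms ----------------------------------------------------------------------

def test_nms_behaviour():
    d1 = Detection((0, 0, 10, 10), 0, 0.9)
    d2 = Detection((0, 0, 10, 10), 0, 0.8)
    d3 = Detection((50, 50, 60, 60), 0, 0.7)
    d4 = Detection((0, 0, 10, 10), 1, 0.6)  # other class survives per-class NMS
    out = nms([d1, d2, d3, d4], 0.5)
    assert d1 in out and d3 in out and d4 in out and d2 not in out
    assert nms([d1], 0.5) == [d1]


def test_detection_score_range_enforced():
    with pytest.raises(DetectorError):
        Detection((0, 0, 1, 1), 0, 1.5)


# -- proposals ----------------------------------------------------------------

def test_oracle_proposals_echo_ground_truth(scenes_small):
    s = scenes_small[0]
    props = propose_regions(s.image, RPNParams(), oracle_boxes=s.boxes, jitter=0.0)
    assert np.allclose(np.array([p.box for p in props]), s.boxes)
    assert all(p.objectness == 1.0 for p in props)


def test_oracle_proposals_jitter_seeded(scenes_small):
    s = scenes_small[0]
    a = propose_regions(s.image, RPNParams(), oracle_boxes=s.boxes, jitter=0.2, seed=3)
    b = propose_regions(s.image, RPNParams(), oracle_boxes=s.boxes, jitter=0.2, seed=3)
    assert np.allclose([p.box for p in a], [p.box for p in b])


def test_proposals_clipped_and_truncated(scenes_small):
    s = scenes_small[0]
    params = RPNParams(max_proposals=2)
    props = propose_regions(s.image, params, oracle_boxes=s.boxes, jitter=0.5, seed=0)
    assert len(props) <= 2
    h, w = s.image.shape[:2]
    for p in props:
        assert 0 <= p.box[0] < p.box[2] <= w
        assert 0 <= p.box[1] < p.box[3] <= h


def test_untrained_rpn_rejected(scenes_small):
    with pytest.raises(DetectorError):
        propose_regions(scenes_small[0].image, RPNParams())


# -- training behaviour -------------------------------------------------------

def test_train_zero_lr_leaves_weights_unchanged(scenes_small, kb3):
    cfg = DetectorConfig(
        variant="cecs", iterations=5, lr=0.0, alpha_eta=1e-12, rpn=RPNParams()
    )
    model, _ = train_detector(scenes_small, kb3, cfg, seed=0)
    fresh = DetectorModel(kb3, DetectorConfig(variant="cecs", rpn=RPNParams()), seed=0)
    for a, b in zip(
        model.encoder.params + model.cem.params + [model.bg_embed, model.reg_W],
        fresh.encoder.params + fresh.cem.params + [fresh.bg_embed, fresh.reg_W],
    ):
        assert np.array_equal(a.data, b.data)


def test_train_reduces_loss(toy_corpus, pretrained_encoder):
    _, kb, train, _, _ = toy_corpus
    cfg = DetectorConfig(variant="cecs", iterations=300, rpn=RPNParams())
    model, trace = train_detector(
        train, kb, cfg, seed=0, encoder_init=pretrained_encoder, log_every=50
    )
    assert trace[-1]["loss_total"] < trace[0]["loss_total"]
    assert model.trained


def test_ablation_identity_zero_cem_alpha_one(scenes_small, kb3):
    """A cecs model with its zero-initialized CEM and alpha pinned to 1 is
    bitwise-identical to the baseline on every ROI output."""
    base = DetectorModel(kb3, DetectorConfig(variant="baseline", rpn=RPNParams()), seed=0)
    cecs = DetectorModel(
        kb3,
        DetectorConfig(variant="cecs", alpha_init=1.0, rpn=RPNParams()),
        seed=0,
    )
    s = scenes_small[0]
    lb, db, _ = base.roi_forward(s.image, s.boxes)
    lc, dc, _ = cecs.roi_forward(s.image, s.boxes)
    assert np.array_equal(lb.data, lc.data)
    assert np.array_equal(db.data, dc.data)


def test_detect_deterministic_and_requires_training(trained_cecs, toy_corpus):
    _, _, _, _, test = toy_corpus
    img = test[0].image
    a = detect(img, trained_cecs)
    b = detect(img, trained_cecs)
    assert [(d.box, d.label, d.score) for d in a] == [
        (d.box, d.label, d.score) for d in b
    ]
    untrained = DetectorModel(
        trained_cecs.kb, DetectorConfig(variant="cecs", rpn=RPNParams()), seed=0
    )
    with pytest.raises(DetectorError):
        detect(img, untrained)


def test_checkpoint_round_trip(tmp_path, trained_cecs, toy_corpus):
    from cecsclip.detector import load_checkpoint, save_checkpoint

    _, kb, _, _, test = toy_corpus
    path = str(tmp_path / "ckpt.npz")
    save_checkpoint(trained_cecs, path)
    clone = DetectorModel(kb, DetectorConfig(variant="cecs", rpn=RPNParams()), seed=99)
    load_checkpoint(clone, path)
    img = test[0].image
    a = detect(img, trained_cecs)
    b = detect(img, clone)
    assert [(d.box, d.label) for d in a] == [(d.box, d.label) for d in b]
    assert clone.scale.alpha == trained_cecs.scale.alpha


def test_invalid_variant_rejected():
    with pytest.raises(DetectorError):
        DetectorConfig(variant="nope")
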