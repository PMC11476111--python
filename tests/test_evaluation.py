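"""Metric suite: matching, precision/recall, AP against a brute-force
oracle, mAP invariances, size bands, rates, confusion, absence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cecsclip.detector import Detection
from cecsclip.evaluation import (
    EvaluationError,
    PRCurve,
    absence_detection,
    average_precision,
    confusion_matrix,
    dataset_ap,
    detection_rates,
    evaluate_detections,
    map_range,
    match_detections,
    mean_ap,
    pr_curve,
    precision_recall,
    size_band,
    size_stratified_ap,
)

RNG = np.random.default_rng(23)


def _det(x0, y0, x1, y1, label=0, score=0.9):
    return Detection((x0, y0, x1, y1), label, score)


# -- matching -----------------------------------------------------------------

def test_match_perfect_single():
    m = match_detections([_det(0, 0, 10, 10)], [[0, 0, 10, 10]], [0], 0.5)
    assert (m.n_tp, m.n_fp, m.n_fn) == (1, 0, 0)


def test_match_one_gt_two_coincident_detections():
    dets = [_det(0, 0, 10, 10, score=0.9), _det(0, 0, 10, 10, score=0.8)]
    m = match_detections(dets, [[0, 0, 10, 10]], [0], 0.5)
    assert (m.n_tp, m.n_fp) == (1, 1)  # one match per GT


def test_match_no_detections_all_fn():
    m = match_detections([], [[0, 0, 5, 5], [8, 8, 12, 12]], [0, 0], 0.5)
    assert (m.n_tp, m.n_fp, m.n_fn) == (0, 0, 2)


def test_match_respects_class():
    m = match_detections([_det(0, 0, 10, 10, label=1)], [[0, 0, 10, 10]], [0], 0.5)
    assert (m.n_tp, m.n_fp, m.n_fn) == (0, 1, 1)
    m2 = match_detections(
        [_det(0, 0, 10, 10, label=1)], [[0, 0, 10, 10]], [0], 0.5, class_agnostic=True
    )
    assert m2.n_tp == 1


def test_tp_plus_fp_equals_detections():
    for _ in range(20):
        n_det, n_gt = RNG.integers(0, 6), RNG.integers(0, 4)
        dets = [
            _det(*np.sort(RNG.uniform(0, 30, 2)), *np.sort(RNG.uniform(31, 60, 2)),
                 label=int(RNG.integers(0, 2)), score=float(RNG.uniform(0.1, 1)))
            for _ in range(n_det)
        ]
        gt = [np.sort(RNG.uniform(0, 30, 2)).tolist() + np.sort(RNG.uniform(31, 60, 2)).tolist() for _ in range(n_gt)]
        gt = [[g[0], g[2], g[1], g[3]] for g in gt]
        m = match_detections(dets, np.array(gt).reshape(-1, 4), RNG.integers(0, 2, n_gt), 0.5)
        assert m.n_tp + m.n_fp == n_det
        assert m.n_fn == n_gt - m.n_tp


# -- precision / recall -------------------------------------------------------

def test_precision_recall_basic():
    assert precision_recall(1, 0, 0) == (1.0, 1.0)
    p, r = precision_recall(0, 0, 0)
    assert p == 1.0 and r is None


def test_precision_recall_contingency_ratios():
    """Ratios from whole-test-set contingency counts reproduce the printed
    per-species rates."""
    _, r = precision_recall(214, 0, 249 - 214)
    assert round(r, 3) == 0.859
    _, r = precision_recall(16, 0, 30 - 16)
    assert round(r, 3) == 0.533


def test_precision_recall_rejects_negative():
    with pytest.raises(EvaluationError):
        precision_recall(-1, 0, 0)


# -- AP -----------------------------------------------------------------------

def test_ap_single_true_positive():
    curve = pr_curve(np.array([0.9]), np.array([True]), n_gt=1)
    assert average_precision(curve) == 1.0


def test_ap_derived_staircase():
    # flags (TP, FP, TP) with 2 GT: 0.5*1 + 0*0.5 + 0.5*(2/3) = 0.8333
    curve = pr_curve(np.array([0.9, 0.8, 0.7]), np.array([True, False, True]), 2)
    assert average_precision(curve) == pytest.approx(5 / 6, abs=1e-12)


def test_ap_all_false_positives():
    curve = pr_curve(np.array([0.9, 0.8]), np.array([False, False]), 2)
    assert average_precision(curve) == 0.0


def test_ap_appending_fps_after_full_recall_is_noop():
    scores = np.array([0.9, 0.8])
    flags = np.array([True, True])
    base = average_precision(pr_curve(scores, flags, 2))
    extended = average_precision(
        pr_curve(np.concatenate([scores, [0.1, 0.05]]),
                 np.concatenate([flags, [False, False]]), 2)
    )
    assert extended == pytest.approx(base, abs=1e-12)


def test_ap_rejects_non_monotone_recall():
    with pytest.raises(EvaluationError):
        average_precision(PRCurve([0.5, 0.3], [1.0, 1.0]))


def _brute_force_ap(scores, flags, n_gt):
    """Independent oracle: enumerate every rank cutoff, recompute P and R
    from scratch, and accumulate the staircase sum."""
    order = np.argsort(-np.asarray(scores))
    f = np.asarray(flags, dtype=bool)[order]
    ap, r_prev = 0.0, 0.0
    for k in range(1, len(f) + 1):
        tp = int(f[:k].sum())
        p_k = tp / k
        r_k = tp / n_gt if n_gt else 0.0
        ap += (r_k - r_prev) * p_k
        r_prev = r_k
    return ap


@settings(max_examples=50, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_ap_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 12))
    n_gt = int(rng.integers(1, 6))
    scores = rng.uniform(0, 1, n)
    flags = rng.random(n) < 0.5
    flags[: min(n, n_gt)] &= True  # arbitrary; oracle handles any flags
    # cap TPs at n_gt to keep recall <= 1
    if flags.sum() > n_gt:
        idx = np.flatnonzero(flags)[n_gt:]
        flags[idx] = False
    got = average_precision(pr_curve(scores, flags, n_gt))
    want = _brute_force_ap(scores, flags, n_gt)
    assert got == pytest.approx(want, abs=1e-12)


def test_interpolated_ap_bounds_literal():
    curve = pr_curve(np.array([0.9, 0.8, 0.7]), np.array([True, False, True]), 2)
    lit = average_precision(curve)
    interp = average_precision(curve, interpolated=True)
    assert 0.0 <= interp <= 1.0
    assert interp >= lit - 0.05  # 101-point grid is never much below


# -- mAP ----------------------------------------------------------------------

def test_mean_ap_values_and_errors():
    assert mean_ap({0: 1.0, 1: 0.0}) == 0.5
    assert mean_ap([0.4]) == pytest.approx(0.4)
    with pytest.raises(EvaluationError):
        mean_ap({})


def test_map_invariant_to_class_relabeling():
    dets = [[_det(0, 0, 10, 10, label=0), _det(20, 20, 30, 30, label=1, score=0.7)]]
    gt = [(np.array([[0, 0, 10, 10], [20, 20, 30, 30]]), np.array([0, 1]))]
    a = mean_ap(dataset_ap(dets, gt, [0, 1]))
    swapped = [[_det(0, 0, 10, 10, label=1), _det(20, 20, 30, 30, label=0, score=0.7)]]
    gt_sw = [(gt[0][0], np.array([1, 0]))]
    b = mean_ap(dataset_ap(swapped, gt_sw, [0, 1]))
    assert a == pytest.approx(b)


def test_map_range_single_threshold_degenerates_to_map():
    dets = [[_det(0, 0, 10, 10)]]
    gt = [(np.array([[0, 0, 10, 10]]), np.array([0]))]
    assert map_range(dets, gt, [0], thresholds=[0.5]) == pytest.approx(
        mean_ap(dataset_ap(dets, gt, [0], 0.5))
    )


# -- size bands ---------------------------------------------------------------

def test_size_band_membership():
    assert size_band(20 * 20) == "small"  # 400 < 1024
    assert size_band(100 * 100) == "large"  # 10000 >= 9216
    assert size_band(50 * 50) == "medium"


def test_size_bands_partition_all_boxes():
    for _ in range(100):
        area = RNG.uniform(1, 20000)
        assert sum(size_band(area) == b for b in ("small", "medium", "large")) == 1


def test_size_stratified_perfect_detector():
    boxes = np.array([[0, 0, 20, 20], [0, 0, 50, 50], [0, 0, 100, 100]])
    dets = [[_det(*b) for b in boxes]]
    gt = [(boxes, np.zeros(3, dtype=int))]
    bands = size_stratified_ap(dets, gt, [0])
    assert bands == {"small": 1.0, "medium": 1.0, "large": 1.0}


def test_size_stratified_absent_bands_flagged():
    boxes = np.array([[0, 0, 20, 20]])
    dets = [[_det(0, 0, 20, 20)]]
    gt = [(boxes, np.zeros(1, dtype=int))]
    bands = size_stratified_ap(dets, gt, [0])
    assert bands["small"] == 1.0
    assert bands["medium"] is None and bands["large"] is None


# -- rates --------------------------------------------------------------------

def test_detection_rates_perfect():
    m = match_detections([_det(0, 0, 10, 10)], [[0, 0, 10, 10]], [0], 0.5)
    rates = detection_rates([m], empty_image_detection_counts=[0, 0])
    assert rates == {"P": 1.0, "DR": 1.0, "FPR": 0.0, "MR": 0.0}


def test_mr_is_exact_complement_of_dr():
    from cecsclip.evaluation import MatchResult

    for _ in range(20):
        n_det = int(RNG.integers(1, 10))
        n_gt = int(RNG.integers(1, 10))
        tp_flags = RNG.random(n_det) < 0.5
        tp_flags[min(n_gt, n_det):] = False
        m = MatchResult(
            scores=np.sort(RNG.uniform(0, 1, n_det))[::-1],
            tp=tp_flags,
            n_gt=n_gt,
            matched_gt=np.where(tp_flags, 0, -1),
        )
        rates = detection_rates([m])
        assert rates["MR"] == 1.0 - rates["DR"]  # exact complement


def test_detection_rates_none_detected():
    m = match_detections([], [[0, 0, 10, 10]], [0], 0.5)
    rates = detection_rates([m])
    assert rates["DR"] == 0.0 and rates["MR"] == 1.0 and rates["FPR"] is None


def test_image_level_fpr_counts_firing_empties():
    m = match_detections([_det(0, 0, 10, 10)], [[0, 0, 10, 10]], [0], 0.5)
    rates = detection_rates([m], empty_image_detection_counts=[0, 2, 1, 0])
    assert rates["FPR"] == 0.5


# -- confusion ----------------------------------------------------------------

def test_confusion_perfect_diagonal():
    boxes = np.array([[0, 0, 10, 10], [20, 20, 30, 30]])
    dets = [[_det(*boxes[0], label=0), _det(*boxes[1], label=1, score=0.8)]]
    gt = [(boxes, np.array([0, 1]))]
    M = confusion_matrix(dets, gt, [0, 1], normalize=True)
    assert np.allclose(np.diag(M)[:2], 1.0)


def test_confusion_systematic_misclassification():
    boxes = np.array([[0, 0, 10, 10]])
    dets = [[_det(*boxes[0], label=1)]]
    gt = [(boxes, np.array([0]))]
    M = confusion_matrix(dets, gt, [0, 1], normalize=True)
    assert M[0, 1] == 1.0  # class 0 always predicted as class 1


def test_confusion_rows_normalize():
    dets = [[_det(0, 0, 10, 10, label=0), _det(50, 50, 60, 60, label=1, score=0.3)]]
    gt = [(np.array([[0, 0, 10, 10], [30, 30, 40, 40]]), np.array([0, 1]))]
    M = confusion_matrix(dets, gt, [0, 1], normalize=True)
    sums = M.sum(axis=1)
    assert ((np.isclose(sums, 1.0)) | (np.isclose(sums, 0.0))).all()
    assert (M >= 0).all()


# -- absence ------------------------------------------------------------------

def test_absence_detection_counts(trained_cecs, catalog3):
    from cecsclip.scenes import SceneSpec, generate_dataset

    empties = generate_dataset(catalog3, 10, SceneSpec(n_targets=0), seed=50)
    rate = absence_detection(empties, trained_cecs)
    assert 0.0 <= rate <= 1.0
    # a threshold of 1.0 means nothing ever fires
    assert absence_detection(empties, trained_cecs, score_threshold=1.01 - 1e-9) == 1.0


def test_absence_requires_empty_scenes(trained_cecs, scenes_small):
    with pytest.raises(EvaluationError):
        absence_detection(scenes_small, trained_cecs)


# -- end-to-end report --------------------------------------------------------

def test_oracle_predictions_score_perfectly(scenes_small):
    """Echoing the ground truth back as detections yields mAP = 1."""
    dets = [
        [_det(*b, label=int(l)) for b, l in zip(s.boxes, s.labels)]
        for s in scenes_small
    ]
    report = evaluate_detections(dets, scenes_small)
    assert report.mAP == pytest.approx(1.0)
    assert report.mAP_50_95 == pytest.approx(1.0)
    assert report.rates["P"] == 1.0 and report.rates["MR"] == 0.0
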