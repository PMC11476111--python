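"""Region-text alignment: similarity, match probability, the symmetric
contrastive loss, distillation, and encoder pretraining."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cecsclip.alignment import (
    AlignmentConfig,
    AlignmentError,
    ImageEncoder,
    contrastive_loss,
    cosine_matrix_t,
    distillation_loss,
    match_probability,
    pairwise_similarity,
    pretrain_region_encoder,
    train_teacher,
)
from cecsclip.autodiff import Tensor, numeric_grad

RNG = np.random.default_rng(7)


# -- pairwise similarity ------------------------------------------------------

@pytest.mark.parametrize(
    "f,g,expected",
    [
        ([1, 0], [1, 0], 1.0),
        ([1, 0], [0, 1], 0.0),
        ([3, 4], [4, 3], 0.96),  # 24 / (5 * 5)
    ],
)
def test_pairwise_similarity_values(f, g, expected):
    assert pairwise_similarity(f, g) == pytest.approx(expected, abs=1e-12)


def test_pairwise_similarity_symmetric_scale_invariant():
    f, g = RNG.normal(size=5), RNG.normal(size=5)
    assert pairwise_similarity(f, g) == pytest.approx(pairwise_similarity(g, f))
    assert pairwise_similarity(3.7 * f, g) == pytest.approx(pairwise_similarity(f, g))


def test_pairwise_similarity_zero_vector_rejected():
    with pytest.raises(AlignmentError):
        pairwise_similarity([0, 0], [1, 0])


# -- match probability --------------------------------------------------------

def test_match_probability_uniform_for_equal_similarities():
    p = match_probability(np.array([0.4, 0.4, 0.4]), tau=0.2)
    assert np.allclose(p, 1 / 3)


def test_match_probability_normalizes():
    p = match_probability(RNG.normal(size=9), tau=0.5)
    assert p.sum() == pytest.approx(1.0, abs=1e-12)


def test_match_probability_derived_two_way():
    p = match_probability(np.array([1.0, 0.0]), tau=0.1)
    expected = np.array([1 / (1 + np.exp(-10)), np.exp(-10) / (1 + np.exp(-10))])
    assert np.allclose(p, expected, atol=1e-15)


@pytest.mark.parametrize("tau", [0.0, 1.0, -0.5, 2.0])
def test_match_probability_tau_range_enforced(tau):
    with pytest.raises(AlignmentError):
        match_probability(np.array([1.0, 0.0]), tau)


def test_match_probability_monotone_in_own_similarity():
    base = np.array([0.2, 0.5, -0.1])
    p0 = match_probability(base, 0.3)[0]
    base2 = base.copy()
    base2[0] += 0.05
    assert match_probability(base2, 0.3)[0] > p0


# -- contrastive loss ---------------------------------------------------------

def test_contrastive_single_pair_is_zero():
    assert contrastive_loss(np.array([[5.0]]), tau=0.7) == pytest.approx(0.0, abs=1e-12)


def test_contrastive_identity_two_by_two():
    # -(1/2) * [2*log(e/(e+1)) + 2*log(e/(e+1))] = 2*log(1+1/e) = 0.62652
    assert contrastive_loss(np.eye(2), tau=1.0) == pytest.approx(0.62652, abs=1e-5)


def test_contrastive_shift_invariance():
    S = RNG.normal(size=(4, 4))
    assert contrastive_loss(S, 0.3) == pytest.approx(
        contrastive_loss(S + 7.3, 0.3), abs=1e-9
    )


def test_contrastive_permutation_equivariance():
    S = RNG.normal(size=(5, 5))
    perm = RNG.permutation(5)
    assert contrastive_loss(S, 0.4) == pytest.approx(
        contrastive_loss(S[np.ix_(perm, perm)], 0.4), abs=1e-9
    )


def test_contrastive_nonnegative_and_small_when_diagonal_dominates():
    S = np.eye(3) * 50.0
    assert 0.0 <= contrastive_loss(S, 0.5) < 1e-10


def test_contrastive_rejects_non_square():
    with pytest.raises(AlignmentError):
        contrastive_loss(np.zeros((2, 3)), 0.5)


def test_contrastive_gradient_matches_finite_differences():
    S0 = RNG.normal(size=(4, 4))
    t = Tensor(S0.copy(), requires_grad=True)
    loss = contrastive_loss(t, 0.2)
    loss.backward()
    num = numeric_grad(lambda x: float(contrastive_loss(x, 0.2)), S0.copy())
    assert np.abs(t.grad - num).max() < 1e-4


# -- distillation loss --------------------------------------------------------

def test_distillation_zero_when_equal():
    s = RNG.normal(size=6)
    assert distillation_loss(s, s.copy()) == 0.0


def test_distillation_value_and_additivity():
    assert distillation_loss([0.5], [0.3]) == pytest.approx(0.04, abs=1e-12)
    a_t, a_s = RNG.normal(size=3), RNG.normal(size=3)
    b_t, b_s = RNG.normal(size=2), RNG.normal(size=2)
    joint = distillation_loss(np.concatenate([a_t, b_t]), np.concatenate([a_s, b_s]))
    assert joint == pytest.approx(
        distillation_loss(a_t, a_s) + distillation_loss(b_t, b_s)
    )


def test_distillation_length_mismatch():
    with pytest.raises(AlignmentError):
        distillation_loss([0.1, 0.2], [0.1])


def test_distillation_gradient_matches_finite_differences():
    t = RNG.normal(size=5)
    s0 = RNG.normal(size=5)
    st = Tensor(s0.copy(), requires_grad=True)
    distillation_loss(t, st).backward()
    num = numeric_grad(lambda x: float(distillation_loss(t, x)), s0.copy())
    assert np.abs(st.grad - num).max() < 1e-6


# -- config -------------------------------------------------------------------

def test_alignment_config_tau_enforced():
    with pytest.raises(AlignmentError):
        AlignmentConfig(temperature=1.0)


# -- pretraining --------------------------------------------------------------

def test_pretrain_zero_lr_is_a_no_op(scenes_small, kb3):
    cfg = AlignmentConfig(lr=0.0, epochs=1)
    student, trace = pretrain_region_encoder(scenes_small, kb3, None, cfg, seed=0)
    fresh = ImageEncoder(3 * cfg.patch**2, cfg.d, seed=1)
    for k, v in student.state_dict().items():
        assert np.array_equal(v, fresh.state_dict()[k])


def test_pretrain_reduces_combined_loss(scenes_small, kb3):
    cfg = AlignmentConfig(epochs=8)
    teacher = train_teacher(scenes_small, kb3, cfg, seed=0)
    student, trace = pretrain_region_encoder(scenes_small, kb3, teacher, cfg, seed=0)
    first = trace[0][0] + trace[0][1]
    last = trace[-1][0] + trace[-1][1]
    assert last < first
    assert all(np.isfinite(c) and np.isfinite(d) for c, d in trace)


def test_student_equal_to_teacher_gives_zero_distillation(scenes_small, kb3):
    cfg = AlignmentConfig(epochs=2)
    teacher = train_teacher(scenes_small, kb3, cfg, seed=0)
    X = RNG.normal(size=(4, 3 * cfg.patch**2))
    Vt = teacher.encode(X)
    Tn = kb3.T[:3] / np.linalg.norm(kb3.T[:3], axis=1, keepdims=True)
    Vtn = Vt[:3] / np.linalg.norm(Vt[:3], axis=1, keepdims=True)
    s_teacher = np.sum(Vtn * Tn, axis=1)
    assert distillation_loss(s_teacher, s_teacher.copy()) == 0.0


def test_pretrain_deterministic_given_seed(scenes_small, kb3):
    cfg = AlignmentConfig(epochs=2)
    a, _ = pretrain_region_encoder(scenes_small, kb3, None, cfg, seed=9)
    b, _ = pretrain_region_encoder(scenes_small, kb3, None, cfg, seed=9)
    for k in a.state_dict():
        assert np.array_equal(a.state_dict()[k], b.state_dict()[k])


# -- property: cosine matrix agrees with pairwise similarity ------------------

@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_cosine_matrix_matches_pairwise(seed):
    rng = np.random.default_rng(seed)
    V = rng.normal(size=(3, 6)) + 0.01
    T = rng.normal(size=(2, 6)) + 0.01
    S = cosine_matrix_t(Tensor(V), T).data
    for i in range(3):
        for j in range(2):
            assert S[i, j] == pytest.approx(pairwise_similarity(V[i], T[j]), abs=1e-12)
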