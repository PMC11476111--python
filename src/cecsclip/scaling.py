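"""Continuous Feature Scaling (CS).

Region and text features are L2-normalized onto the unit hypersphere so
cosine similarity reduces to an inner product; a learnable scale factor
``alpha`` in (0, 1] then plays two roles: it replaces the softmax
temperature when converting similarities to class probabilities, and it
rescales normalized features by ``1/alpha`` before the detection heads.
``alpha`` follows plain gradient descent ``alpha <- alpha - eta * dL/dalpha``
and is clamped to ``(eps, 1]`` with ``eps = 1e-3`` to keep both roles
well-defined (the stated range is open at zero and the rescale must stay
finite).  Default initial value: 0.9.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

EPS_ALPHA = 1e-3


class ScalingError(ValueError):
    pass


@dataclass(frozen=True)
class ScaleState:
    """The scale factor and its update settings."""

    alpha: float = 0.9
    eta: float = 0.01
    learnable: bool = True

    def __post_init__(self):
        if not 0.0 < self.alpha <= 1.0:
            raise ScalingError(f"alpha must lie in (0, 1], got {self.alpha}")
        if self.eta <= 0:
            raise ScalingError("eta must be positive")


def l2_normalize(V: np.ndarray) -> np.ndarray:
    """Map each row onto the unit hypersphere.

    Raises on any zero row, identifying its index.
    """
    V = np.atleast_2d(np.asarray(V, dtype=np.float64))
    norms = np.linalg.norm(V, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ScalingError(f"cannot normalize zero row(s) at index {zero.tolist()}")
    return V / norms[:, None]


def cosine_similarity(u: np.ndarray, v: np.ndarray, tol: float = 1e-6) -> float:
    """Inner product of two unit-norm vectors (checked)."""
    u = np.asarray(u, dtype=np.float64).reshape(-1)
    v = np.asarray(v, dtype=np.float64).reshape(-1)
    for name, x in (("first", u), ("second", v)):
        dev = abs(np.linalg.norm(x) - 1.0)
        if dev > tol:
            raise ScalingError(
                f"{name} input is not unit-norm (deviation {dev:.2e}); "
                "apply l2_normalize first"
            )
    return float(u @ v)


def class_probabilities(
    f: np.ndarray, T: np.ndarray, scale: ScaleState
) -> np.ndarray:
    """Temperature-softmax class probabilities from image-text cosines.

    ``p(y=i|x) = exp(cos(t_i, f)/alpha) / sum_j exp(cos(t_j, f)/alpha)``
    with ``alpha`` in the temperature slot.
    """
    if scale.alpha <= 0:
        raise ScalingError("alpha must be positive")
    f = np.asarray(f, dtype=np.float64).reshape(-1)
    T = np.atleast_2d(np.asarray(T, dtype=np.float64))
    fn = l2_normalize(f[None, :])[0]
    Tn = l2_normalize(T)
    s = Tn @ fn / scale.alpha
    e = np.exp(s - s.max())
    return e / e.sum()


def scale_features(V_norm: np.ndarray, scale: ScaleState) -> np.ndarray:
    """Continuous weighting ``V_scaled = (1/alpha) * V_norm``."""
    if scale.alpha <= 0:
        raise ScalingError("alpha must be positive")
    return np.asarray(V_norm, dtype=np.float64) / scale.alpha


def update_scale(scale: ScaleState, grad: float, max_step: float | None = None) -> ScaleState:
    """One gradient-descent step on alpha, clamped into ``(eps, 1]``.

    ``max_step`` bounds the per-update change (a trust region): softmax
    temperatures see gradients that grow like 1/alpha^2, so an unbounded
    step oscillates once alpha gets small.
    """
    if not scale.learnable:
        raise ScalingError("scale factor is frozen (learnable=False)")
    if not np.isfinite(grad):
        raise ScalingError(f"non-finite gradient {grad!r}")
    step = scale.eta * grad
    if max_step is not None:
        step = float(np.clip(step, -max_step, max_step))
    new_alpha = float(np.clip(scale.alpha - step, EPS_ALPHA, 1.0))
    return replace(scale, alpha=new_alpha)
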