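"""Concept Enhancement Module (CEM).

Cross-attention from region features onto species text features with a
residual connection, followed by a residual two-layer feedforward
network:

    V'  = V + CA(W_q V, W_k T, W_v T)
    [V_bas, V_cap] = V' + FFN(V')

Attention is single-head scaled dot-product by default.  The attention
output projection and the FFN output layer are zero-initialized, so a
freshly constructed CEM is exactly the identity on ``V``: inserting it
into a detector changes nothing until it has been trained.  The post-FFN
output is interpreted as two components split evenly along the feature
axis and re-concatenated for the downstream heads.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter, Tensor


class CEMError(ValueError):
    pass


class CEMParams:
    """Projection matrices and FFN weights of one CEM block.

    ``W_o`` (attention output projection) and ``W2`` (FFN output layer)
    start at zero -> identity at initialization.
    """

    def __init__(self, d: int, d_attn: int | None = None, d_ff: int | None = None, seed: int = 0):
        if d <= 0:
            raise CEMError("feature dimension must be positive")
        d_attn = d_attn or d
        d_ff = d_ff or 2 * d
        rng = np.random.default_rng(seed)
        s = 1 / np.sqrt(d)
        self.W_q = Parameter(rng.normal(0, s, (d, d_attn)))
        self.W_k = Parameter(rng.normal(0, s, (d, d_attn)))
        self.W_v = Parameter(rng.normal(0, s, (d, d_attn)))
        self.W_o = Parameter(np.zeros((d_attn, d)))
        self.W1 = Parameter(rng.normal(0, s, (d, d_ff)))
        self.b1 = Parameter(np.zeros(d_ff))
        self.W2 = Parameter(np.zeros((d_ff, d)))
        self.b2 = Parameter(np.zeros(d))
        self.d, self.d_attn, self.d_ff = d, d_attn, d_ff

    @property
    def params(self) -> list[Parameter]:
        return [self.W_q, self.W_k, self.W_v, self.W_o, self.W1, self.b1, self.W2, self.b2]

    def state_dict(self) -> dict[str, np.ndarray]:
        names = ("W_q", "W_k", "W_v", "W_o", "W1", "b1", "W2", "b2")
        return {n: getattr(self, n).data.copy() for n in names}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for n, v in state.items():
            getattr(self, n).data = np.asarray(v, dtype=np.float64).copy()


def _lift(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.atleast_2d(np.asarray(x, dtype=np.float64)))


def _check_concepts(T) -> None:
    m = T.shape[0] if isinstance(T, Tensor) else np.atleast_2d(T).shape[0]
    if m == 0:
        raise CEMError("no concepts to attend over (T has zero rows)")


def attention_weights(V: np.ndarray, T: np.ndarray, params: CEMParams) -> np.ndarray:
    """The ``n x m`` softmax attention map from regions onto concepts."""
    _check_concepts(T)
    Q = np.atleast_2d(V) @ params.W_q.data
    K = np.atleast_2d(T) @ params.W_k.data
    logits = Q @ K.T / np.sqrt(params.d_attn)
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def cross_attend(V, T, params: CEMParams) -> Tensor:
    """Residual cross-attention: ``V + CA(W_q V, W_k T, W_v T)``."""
    _check_concepts(T)
    Vt, Tt = _lift(V), _lift(T)
    Q = Vt @ params.W_q
    K = Tt @ params.W_k
    Val = Tt @ params.W_v
    A = ((Q @ K.T) / np.sqrt(params.d_attn)).softmax(axis=1)
    return Vt + (A @ Val) @ params.W_o


def cem_forward(V, T, params: CEMParams) -> tuple[Tensor, Tensor]:
    """Full CEM: returns the ``(V_bas, V_cap)`` even split of the residual
    FFN output ``V' + FFN(V')`` along the feature axis."""
    Vp = cross_attend(V, T, params)
    ffn = (Vp @ params.W1 + params.b1).relu() @ params.W2 + params.b2
    out = Vp + ffn
    half = params.d // 2
    return out[:, :half], out[:, half:]


def cem_enhance(V, T, params: CEMParams) -> Tensor:
    """Concatenated ``[V_bas, V_cap]`` features for the detection heads."""
    bas, cap = cem_forward(V, T, params)
    return Tensor.concat([bas, cap], axis=1)
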