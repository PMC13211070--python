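"""Cross-attention fusion of reconstructed and original single-lead features,
followed by self-attention refinement and the pooling classifier.

In the cross-attention stage the reconstructed features provide the queries
while the original single-lead features provide keys and values, so the
fused representation attends from the (richer but possibly artifactual)
reconstruction into the (stable but limited) original signal.  A residual
connection from the query stream and a layer norm wrap the attention; the
classifier concatenates time-global average and max pooling before a single
affine map and softmax.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor, softmax


@dataclass
class FusionSpec:
    d_model: int
    n_heads: int = 2
    dropout: float = 0.1

    def __post_init__(self):
        if self.d_model % self.n_heads:
            raise ValueError(f"d_model {self.d_model} not divisible by "
                             f"n_heads {self.n_heads}")

    @property
    def d_k(self) -> int:
        return self.d_model // self.n_heads


def cross_attention_weights(q: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Plain single-head attention weights softmax(q k^T / sqrt(d_k));
    reference helper used for inspection and by the tests' oracles."""
    d_k = q.shape[-1]
    scores = q @ k.T / np.sqrt(d_k)
    scores -= scores.max(axis=-1, keepdims=True)
    e = np.exp(scores)
    return e / e.sum(axis=-1, keepdims=True)


class FusionModule(nn.Module):
    """(F_rec, F_single) -> F_enhance, shape preserved."""

    def __init__(self, spec: FusionSpec, seed: int = 0):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.cross = nn.MultiHeadAttention(spec.d_model, spec.n_heads, rng,
                                           dropout=spec.dropout)
        self.norm = nn.LayerNorm(spec.d_model)
        self.refine = nn.TransformerEncoderLayer(spec.d_model, spec.n_heads,
                                                 rng, dropout=spec.dropout)

    def cross_attend(self, f_rec: Tensor, f_single: Tensor) -> Tensor:
        if f_rec.shape != f_single.shape:
            raise ValueError(f"shape mismatch: {f_rec.shape} vs "
                             f"{f_single.shape}")
        attended = self.cross(f_rec, f_single, f_single)
        return self.norm(f_rec + attended)

    def forward(self, f_rec: Tensor, f_single: Tensor) -> Tensor:
        return self.refine(self.cross_attend(f_rec, f_single))


class Classifier(nn.Module):
    """Global average + max pooling, affine map, softmax: (B,T,C) -> (B,K).

    The same head serves the student (W_pred, b_pred) and the teacher
    (W_pre, b_pre); both pool the feature map identically.
    """

    def __init__(self, d_model: int, n_classes: int, seed: int = 0):
        super().__init__()
        if n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        self.n_classes = n_classes
        rng = np.random.default_rng(seed)
        self.linear = nn.Linear(2 * d_model, n_classes, rng)

    def logits(self, features: Tensor) -> Tensor:
        return self.linear(nn.global_avg_max_pool(features))

    def forward(self, features: Tensor) -> Tensor:
        return softmax(self.logits(features), axis=-1)
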