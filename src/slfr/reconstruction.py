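"""Feature reconstruction: map single-lead features toward the feature
distribution a frozen 12-lead extractor would produce.

A small transformer encoder (two layers by default) operates directly on the
(tokens x d_model) single-lead feature map and is trained to minimize an
alignment loss against the teacher's feature map — reconstruction happens in
feature space, never at the waveform level.

Loss variants
-------------
L1   mean absolute elementwise difference (default; the normalization by
     element count, rather than a plain sum, keeps the loss-weighting
     coefficient comparable across model widths)
L2   mean squared elementwise difference
COS  1 - mean per-token cosine similarity
KL   KL(softmax(target) || softmax(reconstruction)) per token (channels as
     the distribution axis), averaged; target-as-reference direction, natural
     log
JS   Jensen-Shannon divergence, base 2, symmetric, bounded in [0, 1]
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor, log_softmax, softmax

LOSS_KINDS = ("L1", "L2", "COS", "KL", "JS")


@dataclass
class ReconSpec:
    d_model: int
    n_layers: int = 2
    n_heads: int = 2
    loss_kind: str = "L1"
    dropout: float = 0.1

    def __post_init__(self):
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.loss_kind not in LOSS_KINDS:
            raise ValueError(f"loss_kind must be one of {LOSS_KINDS}, "
                             f"got {self.loss_kind!r}")


class ReconstructionModule(nn.Module):
    """Positional encoding + transformer encoder; shape-preserving."""

    def __init__(self, spec: ReconSpec, seed: int = 0):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.pos = nn.PositionalEncoding(spec.d_model)
        self.layers = [
            nn.TransformerEncoderLayer(spec.d_model, spec.n_heads, rng,
                                       dropout=spec.dropout)
            for _ in range(spec.n_layers)
        ]

    def forward(self, f_single: Tensor) -> Tensor:
        if f_single.shape[-1] != self.spec.d_model:
            raise ValueError(f"expected {self.spec.d_model} channels, "
                             f"got {f_single.shape[-1]}")
        h = self.pos(f_single)
        for layer in self.layers:
            h = layer(h)
        return h


def recon_loss(f_rec: Tensor | np.ndarray, f_full: Tensor | np.ndarray,
               loss_kind: str = "L1") -> Tensor:
    """Alignment loss between reconstructed and target feature maps.

    Accepts (tokens, channels) or (batch, tokens, channels); differentiable
    when given Tensors.
    """
    a = f_rec if isinstance(f_rec, Tensor) else Tensor(f_rec)
    b = f_full if isinstance(f_full, Tensor) else Tensor(f_full)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if loss_kind == "L1":
        return (a - b).abs().mean()
    if loss_kind == "L2":
        return ((a - b) ** 2).mean()
    if loss_kind == "COS":
        # cosine of eps-extended vectors: exactly 0 loss for identical
        # tokens (zero tokens included), bounded by Cauchy-Schwarz
        eps = 1e-12
        dot = (a * b).sum(axis=-1) + eps
        norms = (((a * a).sum(axis=-1) + eps)
                 * ((b * b).sum(axis=-1) + eps)).sqrt()
        return (1.0 - dot / norms).mean()
    if loss_kind == "KL":
        log_p = log_softmax(b, axis=-1)   # target as reference
        log_q = log_softmax(a, axis=-1)
        p = log_p.exp()
        return (p * (log_p - log_q)).sum(axis=-1).mean()
    if loss_kind == "JS":
        p = softmax(b, axis=-1)
        q = softmax(a, axis=-1)
        m = (p + q) * 0.5
        eps = 1e-12
        kl_pm = (p * ((p + eps).log() - (m + eps).log())).sum(axis=-1)
        kl_qm = (q * ((q + eps).log() - (m + eps).log())).sum(axis=-1)
        return ((kl_pm + kl_qm) * (0.5 / np.log(2.0))).mean()
    raise ValueError(f"loss_kind must be one of {LOSS_KINDS}, got {loss_kind!r}")
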