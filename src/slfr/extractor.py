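"""Multi-scale CNN-Transformer feature extractor shared by the 12-lead
teacher and the single-lead student (they differ only in input channels).

Stage contract for an input of N samples (N divisible by 64):

    omni-scale conv + SE + stride-2 max-pool   (leads, N)   -> (N/2,  C_os)
    5 x inverted-bottleneck CNN block           (N/2, C_os) -> (N/64, d_model)
    4 x pre-norm transformer encoder layer      (N/64, d_model) unchanged

Each CNN block is expansion (1x1 conv) -> depthwise conv k=3 stride 2 ->
compression (1x1 conv), every conv followed by BatchNorm, ReLU and an SE
channel gate. The total time reduction is 2 * 2^5 = 64.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor

TIME_REDUCTION = 64


@dataclass
class ExtractorSpec:
    """Architecture hyperparameters of the feature extraction module."""

    in_leads: int = 1
    oscnn_kernels: tuple[int, ...] = (1, 3, 5, 7, 11, 13)
    oscnn_out_channels: int = 192
    n_cnn_blocks: int = 5
    block_channels: tuple[int, ...] = (256, 384, 512, 1024, 1536)
    block_expansion: int = 4
    d_model: int = 1536
    n_transformer_layers: int = 4
    n_heads: int = 8
    se_reduction: int = 16
    dropout: float = 0.1

    def __post_init__(self):
        if self.in_leads not in (1, 3, 12):
            raise ValueError(f"in_leads must be 1, 3 or 12, got {self.in_leads}")
        if self.d_model != self.block_channels[-1]:
            raise ValueError(
                f"d_model ({self.d_model}) must equal the last block width "
                f"({self.block_channels[-1]})")
        if len(self.block_channels) != self.n_cnn_blocks:
            raise ValueError("block_channels length must equal n_cnn_blocks")
        if self.oscnn_out_channels % len(self.oscnn_kernels):
            raise ValueError(
                f"oscnn_out_channels ({self.oscnn_out_channels}) must divide "
                f"evenly over {len(self.oscnn_kernels)} kernel branches")
        if any(k % 2 == 0 for k in self.oscnn_kernels if k > 1):
            raise ValueError("oscnn_kernels must be odd (same padding)")
        if 2 * 2 ** self.n_cnn_blocks != TIME_REDUCTION:
            raise ValueError("stride schedule must reduce time by exactly 64")

    @classmethod
    def small(cls, in_leads: int = 1, **overrides) -> "ExtractorSpec":
        """Desk-test profile: all widths divided by 8, 2 attention heads.

        The time-reduction contract is width-independent, so every shape
        property of the full model holds for this profile too.
        """
        defaults = dict(
            in_leads=in_leads,
            oscnn_out_channels=24,
            block_channels=(32, 48, 64, 128, 192),
            d_model=192,
            n_heads=2,
            se_reduction=8,
        )
        defaults.update(overrides)
        return cls(**defaults)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ExtractorSpec":
        raw = json.loads(text)
        raw["oscnn_kernels"] = tuple(raw["oscnn_kernels"])
        raw["block_channels"] = tuple(raw["block_channels"])
        return cls(**raw)


@dataclass
class FeatureMap:
    """A (time-tokens x channels) representation produced by the extractor."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 1:
            raise ValueError("FeatureMap must be 2-D with >= 1 token")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("FeatureMap contains NaN/Inf")

    @property
    def tokens(self) -> int:
        return self.values.shape[0]

    @property
    def channels(self) -> int:
        return self.values.shape[1]


class OmniScaleConv(nn.Module):
    """Parallel same-padded convolutions over a spread of kernel sizes,
    channel-concatenated, SE-recalibrated, then stride-2 max-pooled."""

    def __init__(self, spec: ExtractorSpec, rng: np.random.Generator):
        super().__init__()
        per_branch = spec.oscnn_out_channels // len(spec.oscnn_kernels)
        self.branches = [
            nn.Conv1d(spec.in_leads, per_branch, k, rng, padding="same")
            for k in spec.oscnn_kernels
        ]
        self.se = nn.SqueezeExcite(spec.oscnn_out_channels,
                                   spec.se_reduction, rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] % 2:
            raise ValueError(f"input length {x.shape[-1]} must be even")
        out = nn.concatenate([b(x) for b in self.branches], axis=1)
        return nn.maxpool1d_stride2(self.se(out))


class CNNBlock(nn.Module):
    """Inverted bottleneck: expand (k=1) -> depthwise k=3 stride 2 -> compress
    (k=1), each conv followed by BN, ReLU and SE. Halves the time axis."""

    def __init__(self, in_channels: int, out_channels: int, expansion: int,
                 se_reduction: int, rng: np.random.Generator):
        super().__init__()
        mid = in_channels * expansion
        self.expand = nn.Conv1d(in_channels, mid, 1, rng)
        self.bn1 = nn.BatchNorm1d(mid)
        self.se1 = nn.SqueezeExcite(mid, se_reduction, rng)
        self.depthwise = nn.Conv1d(mid, mid, 3, rng, stride=2, padding=1,
                                   groups=mid)
        self.bn2 = nn.BatchNorm1d(mid)
        self.se2 = nn.SqueezeExcite(mid, se_reduction, rng)
        self.compress = nn.Conv1d(mid, out_channels, 1, rng)
        self.bn3 = nn.BatchNorm1d(out_channels)
        self.se3 = nn.SqueezeExcite(out_channels, se_reduction, rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] < 2:
            raise ValueError("time length must be >= 2")
        x = self.se1(self.bn1(self.expand(x)).relu())
        x = self.se2(self.bn2(self.depthwise(x)).relu())
        return self.se3(self.bn3(self.compress(x)).relu())


class FeatureExtractor(nn.Module):
    """The full extractor E: (B, leads, N) -> (B, N/64, d_model)."""

    def __init__(self, spec: ExtractorSpec, seed: int = 0):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.oscnn = OmniScaleConv(spec, rng)
        channels = [spec.oscnn_out_channels, *spec.block_channels]
        self.blocks = [
            CNNBlock(channels[i], channels[i + 1], spec.block_expansion,
                     spec.se_reduction, rng)
            for i in range(spec.n_cnn_blocks)
        ]
        self.pos = nn.PositionalEncoding(spec.d_model)
        self.encoder = [
            nn.TransformerEncoderLayer(spec.d_model, spec.n_heads, rng,
                                       dropout=spec.dropout)
            for _ in range(spec.n_transformer_layers)
        ]

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.spec.in_leads:
            raise ValueError(f"expected {self.spec.in_leads} leads, "
                             f"got {x.shape[1]}")
        if x.shape[-1] % TIME_REDUCTION:
            raise ValueError(
                f"input length {x.shape[-1]} is not divisible by "
                f"{TIME_REDUCTION}; run preprocess.fix_length first")
        h = self.oscnn(x)
        for block in self.blocks:
            h = block(h)
        h = h.transpose(0, 2, 1)  # (B, tokens, d_model)
        h = self.pos(h)
        for layer in self.encoder:
            h = layer(h)
        return h

    def extract(self, signal: np.ndarray) -> FeatureMap:
        """Single-record inference: (leads, N) -> FeatureMap (N/64, d_model)."""
        was_training = self.training
        self.eval()
        try:
            with nn.no_grad():
                out = self.forward(Tensor(np.asarray(signal)[None]))
        finally:
            self.train(was_training)
        return FeatureMap(out.numpy()[0])


def save_extractor(model: FeatureExtractor, path) -> None:
    """Weights file (.npz) plus a JSON sidecar of the exact ExtractorSpec."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.state_dict())
    path.with_suffix(".json").write_text(model.spec.to_json())


def load_extractor(path) -> FeatureExtractor:
    path = Path(path)
    spec = ExtractorSpec.from_json(path.with_suffix(".json").read_text())
    model = FeatureExtractor(spec)
    with np.load(path.with_suffix(".npz")) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
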