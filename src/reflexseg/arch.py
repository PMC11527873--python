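"""Encoder-decoder network for pupil-light-reflex segmentation.

The backbone is a five-stage SegNet-style encoder-decoder: every encoder
stage ends in a 2x2/stride-2 max pool whose argmax indices drive the
matching decoder unpooling, so spatial detail survives the bottleneck.
Two additions target the extremely small foreground (~17 px in a 512x512
image):

* multi-level skip connections — each encoder stage's pre-pool feature map
  is concatenated into the decoder stage operating at the same resolution;
* a 1x1-convolution-enhanced initial stage — a stem (3x3 conv then 1x1
  conv, each with BN+ReLU) followed by three ConvUNeXt-style residual
  blocks with depthwise kernels 5, 7 and 9; the stem output and the three
  block outputs are all concatenated into the final decoder stage.

Four ablation variants (A-D) remove the initial-stage skip, all other
skips, or swap the initial stage for a plain two-conv-block SegNet stem.
Index-based unpooling is part of the backbone and is retained in every
variant.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .nn import functional as F
from .nn.autograd import Tensor

#: variant name -> (initial_stage, skip_mode)
VARIANTS: dict[str, tuple[str, str]] = {
    "proposed": ("proposed", "all"),
    "A": ("proposed", "no_initial"),
    "B": ("proposed", "initial_only"),
    "C": ("segnet", "all"),
    "D": ("segnet", "none"),
}

_SKIP_MODES = ("all", "no_initial", "initial_only", "none")


@dataclass(frozen=True)
class NetworkConfig:
    """Declarative description of the network architecture."""

    encoder_channels: tuple[int, ...] = (64, 128, 256, 512, 512)
    decoder_channels: tuple[int, ...] = (512, 512, 256, 128, 64)
    num_classes: int = 1
    initial_stage: str = "proposed"
    skip_mode: str = "all"
    convunext_expansion: int = 256
    convunext_kernels: tuple[int, ...] = (5, 7, 9)
    bn_momentum: float = 0.1
    channel_scale: float = 1.0
    #: run the three initial residual blocks off the stem in parallel
    #: instead of sequentially (the default chains them)
    initial_parallel: bool = False

    def __post_init__(self):
        if len(self.encoder_channels) != 5 or len(self.decoder_channels) != 5:
            raise ValueError("encoder/decoder channel schedules must have length 5")
        if self.initial_stage not in ("proposed", "segnet"):
            raise ValueError(f"unknown initial_stage {self.initial_stage!r}")
        if self.skip_mode not in _SKIP_MODES:
            raise ValueError(f"unknown skip_mode {self.skip_mode!r}")
        if any(k < 3 or k % 2 == 0 for k in self.convunext_kernels):
            raise ValueError("convunext_kernels must be odd and >= 3")
        if self.channel_scale <= 0:
            raise ValueError("channel_scale must be positive")
        if min(self.scaled_encoder()) < 1 or min(self.scaled_decoder()) < 1:
            raise ValueError("all channel widths must be >= 1 after scaling")

    def _scale(self, c: int) -> int:
        return max(1, math.ceil(self.channel_scale * c))

    def scaled_encoder(self) -> tuple[int, ...]:
        return tuple(self._scale(c) for c in self.encoder_channels)

    def scaled_decoder(self) -> tuple[int, ...]:
        return tuple(self._scale(c) for c in self.decoder_channels)

    def scaled_expansion(self) -> int:
        return self._scale(self.convunext_expansion)

    def skip_active(self, stage: int) -> bool:
        """Whether decoder stage ``stage`` (1-based) receives a skip concat."""
        return {
            "all": True,
            "no_initial": stage <= 4,
            "initial_only": stage == 5,
            "none": False,
        }[self.skip_mode]

    def to_json(self) -> str:
        d = {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in self.__dict__.items()}
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "NetworkConfig":
        d = json.loads(text)
        for k in ("encoder_channels", "decoder_channels", "convunext_kernels"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass(frozen=True)
class AblationVariant:
    """Named structural variant; maps onto (initial_stage, skip_mode)."""

    name: str

    def __post_init__(self):
        if self.name not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.name!r}; expected one of {sorted(VARIANTS)}")

    @property
    def initial_stage(self) -> str:
        return VARIANTS[self.name][0]

    @property
    def skip_mode(self) -> str:
        return VARIANTS[self.name][1]

    def config(self, **overrides) -> NetworkConfig:
        return NetworkConfig(initial_stage=self.initial_stage,
                             skip_mode=self.skip_mode, **overrides)


@dataclass
class PooledFeature:
    """A pooled feature map together with its max-pool argmax indices.

    ``indices`` holds for each pooled position the row-major position
    (0..3) of the maximum inside its originating 2x2 window; unpooling
    scatters each value back to exactly that position.
    """

    values: Tensor
    indices: np.ndarray

    def __post_init__(self):
        if self.indices.shape != tuple(self.values.shape):
            raise ValueError("indices/values shape mismatch")

    def absolute_indices(self) -> np.ndarray:
        """Flat (row*W + col) positions in the pre-pool map of each maximum."""
        _, ho, wo, _ = self.indices.shape
        rows = np.arange(ho)[None, :, None, None] * 2 + self.indices // 2
        cols = np.arange(wo)[None, None, :, None] * 2 + self.indices % 2
        return rows * (wo * 2) + cols


@dataclass
class StageOutputs:
    """Everything the decoder needs from a forward pass of the encoder."""

    pre_pool: list[Tensor]
    pooled: list[PooledFeature]
    initial_block_outputs: list[Tensor] = field(default_factory=list)


class ConvBlock(nn.Module):
    """3x3 conv (stride 1, pad 1) -> BN -> ReLU; preserves spatial size."""

    def __init__(self, in_ch: int, out_ch: int, momentum: float,
                 rng: np.random.Generator, kernel_size: int = 3):
        super().__init__()
        if in_ch < 1 or out_ch < 1:
            raise ValueError("channel counts must be >= 1")
        pad = kernel_size // 2
        self.conv = nn.Conv2d(in_ch, out_ch, kernel_size, padding=pad,
                              bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(out_ch, momentum=momentum)

    def forward(self, x: Tensor) -> Tensor:
        return F.relu(self.bn(self.conv(x)))


def make_conv_block(in_ch: int, out_ch: int, momentum: float = 0.1,
                    rng: np.random.Generator | None = None) -> ConvBlock:
    return ConvBlock(in_ch, out_ch, momentum, rng or np.random.default_rng())


class ConvUNeXtBlock(nn.Module):
    """Residual block: depthwise conv -> BN -> 1x1 expand -> GELU -> 1x1 project.

    The depthwise kernel sets the block's receptive field; the inverted
    1x1 bottleneck adds channel-mixing non-linearity without growing it.
    """

    def __init__(self, channels: int, expansion: int, kernel: int,
                 momentum: float, rng: np.random.Generator):
        super().__init__()
        self.dw = nn.Conv2d(channels, channels, kernel, padding=kernel // 2,
                            groups=channels, bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(channels, momentum=momentum)
        self.pw1 = nn.Conv2d(channels, expansion, 1, rng=rng)
        self.pw2 = nn.Conv2d(expansion, channels, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.bn(self.dw(x))
        h = self.pw2(F.gelu(self.pw1(h)))
        return h + x


class InitialStageProposed(nn.Module):
    """Stem (3x3 conv + 1x1 conv, both BN+ReLU) and three ConvUNeXt blocks.

    Exposes four full-resolution taps — the stem output and each residual
    block output — that feed the final decoder stage.
    """

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        c1 = cfg.scaled_encoder()[0]
        self.stem3 = ConvBlock(3, c1, cfg.bn_momentum, rng)
        self.stem1 = ConvBlock(c1, c1, cfg.bn_momentum, rng, kernel_size=1)
        self.parallel = cfg.initial_parallel
        exp = cfg.scaled_expansion()
        blocks = [ConvUNeXtBlock(c1, exp, k, cfg.bn_momentum, rng)
                  for k in cfg.convunext_kernels]
        self.blocks = nn.Sequential(*blocks)

    @property
    def num_taps(self) -> int:
        return 1 + len(self.blocks)

    def forward(self, x: Tensor) -> tuple[Tensor, list[Tensor]]:
        stem = self.stem1(self.stem3(x))
        taps = [stem]
        h = stem
        for block in self.blocks:
            h = block(stem if self.parallel else h)
            taps.append(h)
        return taps[-1], taps


class InitialStageSegNet(nn.Module):
    """Conventional two-conv-block stem; a single tap."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        c1 = cfg.scaled_encoder()[0]
        self.block1 = ConvBlock(3, c1, cfg.bn_momentum, rng)
        self.block2 = ConvBlock(c1, c1, cfg.bn_momentum, rng)

    @property
    def num_taps(self) -> int:
        return 1

    def forward(self, x: Tensor) -> tuple[Tensor, list[Tensor]]:
        out = self.block2(self.block1(x))
        return out, [out]


def make_initial_stage_proposed(cfg: NetworkConfig,
                                rng: np.random.Generator | None = None
                                ) -> InitialStageProposed:
    return InitialStageProposed(cfg, rng or np.random.default_rng())


def make_initial_stage_segnet(cfg: NetworkConfig,
                              rng: np.random.Generator | None = None
                              ) -> InitialStageSegNet:
    return InitialStageSegNet(cfg, rng or np.random.default_rng())


#: conv blocks per encoder stage 2..5 (the three lowest-resolution stages
#: have three blocks, the rest two)
_ENC_BLOCKS = (2, 3, 3, 3)
#: conv blocks per decoder stage 1..5
_DEC_BLOCKS = (3, 3, 3, 2, 2)


class Encoder(nn.Module):
    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        enc = cfg.scaled_encoder()
        if cfg.initial_stage == "proposed":
            self.initial = InitialStageProposed(cfg, rng)
        else:
            self.initial = InitialStageSegNet(cfg, rng)
        for i in range(1, 5):  # stages 2..5
            n_blocks = _ENC_BLOCKS[i - 1]
            chans = [enc[i - 1]] + [enc[i]] * n_blocks
            stage = nn.Sequential(*[
                ConvBlock(a, b, cfg.bn_momentum, rng)
                for a, b in zip(chans[:-1], chans[1:])])
            setattr(self, f"stage{i + 1}", stage)

    def forward(self, x: Tensor) -> StageOutputs:
        h, w = x.shape[1], x.shape[2]
        if h % 32 or w % 32:
            raise ValueError(
                f"input spatial size {h}x{w} must be divisible by 32")
        pre_pool: list[Tensor] = []
        pooled: list[PooledFeature] = []
        f1, taps = self.initial(x)
        pre_pool.append(f1)
        z, idx = F.max_pool2d(f1)
        pooled.append(PooledFeature(z, idx))
        for i in range(2, 6):
            f = getattr(self, f"stage{i}")(z)
            pre_pool.append(f)
            z, idx = F.max_pool2d(f)
            pooled.append(PooledFeature(z, idx))
        initial_taps = taps if self.cfg.initial_stage == "proposed" else []
        return StageOutputs(pre_pool, pooled, initial_taps)


class Decoder(nn.Module):
    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        enc, dec = cfg.scaled_encoder(), cfg.scaled_decoder()
        n_taps = 4 if cfg.initial_stage == "proposed" else 1
        # Index-based unpooling forces each stage's output width to equal
        # the channel count of the encoder map whose pool indices the next
        # stage reuses; the last conv block of each stage performs that
        # reduction (the SegNet convention).
        for j in range(1, 6):
            unpool_ch = enc[4] if j == 1 else enc[5 - j]
            if cfg.skip_active(j):
                skip_ch = enc[0] * n_taps if j == 5 else enc[5 - j]
            else:
                skip_ch = 0
            out_ch = enc[4 - j] if j < 5 else dec[4]
            width = dec[j - 1]
            chans = [unpool_ch + skip_ch] \
                + [width] * (_DEC_BLOCKS[j - 1] - 1) + [out_ch]
            stage = nn.Sequential(*[
                ConvBlock(a, b, cfg.bn_momentum, rng)
                for a, b in zip(chans[:-1], chans[1:])])
            setattr(self, f"stage{j}", stage)
        self.head = nn.Conv2d(dec[4], cfg.num_classes, 1, rng=rng)
        # prior-probability initialisation: with a ~0.01%-foreground task a
        # strongly negative head bias starts predictions near background,
        # which removes the long initial phase of suppressing false positives
        self.head.bias.data[:] = -4.0

    def concat_width(self, j: int) -> int:
        """Channel width entering decoder stage ``j`` after concatenation."""
        return getattr(self, f"stage{j}").layers[0].conv.in_channels

    def forward(self, outs: StageOutputs) -> Tensor:
        cfg = self.cfg
        if len(outs.pooled) != 5 or len(outs.pre_pool) != 5:
            raise ValueError("StageOutputs must carry five encoder stages")
        z = outs.pooled[4].values
        for j in range(1, 6):
            pooled = outs.pooled[5 - j]
            up = F.max_unpool2d(z, pooled.indices)
            if cfg.skip_active(j):
                if j == 5 and cfg.initial_stage == "proposed":
                    if not outs.initial_block_outputs:
                        raise ValueError(
                            "decoder stage 5 requires initial-stage taps")
                    cat = nn.concat(list(outs.initial_block_outputs) + [up], axis=-1)
                else:
                    cat = nn.concat([outs.pre_pool[5 - j], up], axis=-1)
            else:
                cat = up
            z = getattr(self, f"stage{j}")(cat)
        return F.sigmoid(self.head(z))


class ReflexNet(nn.Module):
    """Full network: encoder, decoder and skip topology from a config."""

    def __init__(self, cfg: NetworkConfig | None = None,
                 seed: int | None = None):
        super().__init__()
        self.cfg = cfg or NetworkConfig()
        rng = np.random.default_rng(seed)
        self.encoder = Encoder(self.cfg, rng)
        self.decoder = Decoder(self.cfg, rng)

    def encode(self, x) -> StageOutputs:
        return self.encoder(as_input_tensor(x))

    def decode(self, outs: StageOutputs) -> Tensor:
        return self.decoder(outs)

    def forward(self, x) -> Tensor:
        return self.decode(self.encode(x))

    @property
    def concat_junctions(self) -> int:
        """Number of decoder stages receiving a skip concatenation."""
        return sum(self.cfg.skip_active(j) for j in range(1, 6))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path, **self.state_dict())
        path.with_suffix(".json").write_text(self.cfg.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "ReflexNet":
        path = Path(path)
        cfg = NetworkConfig.from_json(path.with_suffix(".json").read_text())
        net = cls(cfg)
        with np.load(path if path.suffix else path.with_suffix(".npz")) as f:
            net.load_state_dict(dict(f))
        return net


def as_input_tensor(x) -> Tensor:
    """Coerce an image array to a float32 channels-last (NHWC) tensor.

    Accepts (H, W, 3), (N, H, W, 3) or (N, 3, H, W) arrays with values
    in [0, 1], or an existing Tensor (returned unchanged).
    """
    if isinstance(x, Tensor):
        return x
    a = np.asarray(x, dtype=np.float32)
    if a.ndim == 3:
        a = a[None]
    if a.ndim != 4:
        raise ValueError(f"expected 3- or 4-d image array, got shape {a.shape}")
    if a.shape[1] in (1, 3) and a.shape[-1] not in (1, 3):
        a = a.transpose(0, 2, 3, 1)
    return Tensor(np.ascontiguousarray(a))


def build_variant(variant: str | AblationVariant, channel_scale: float = 1.0,
                  seed: int | None = None, **overrides) -> ReflexNet:
    """Assemble one of the five network variants.

    ``channel_scale`` uniformly scales every width (ceil) for desk-scale
    runs; ``seed`` makes the weight initialisation reproducible.
    """
    if isinstance(variant, str):
        variant = AblationVariant(variant)
    cfg = variant.config(channel_scale=channel_scale, **overrides)
    return ReflexNet(cfg, seed=seed)


def summarize_architecture(variant: str = "proposed",
                           channel_scale: float = 1.0,
                           input_size: int = 512) -> pd.DataFrame:
    """Per-stage table of channels, spatial sizes and parameter counts."""
    net = build_variant(variant, channel_scale=channel_scale, seed=0)
    enc, dec = net.cfg.scaled_encoder(), net.cfg.scaled_decoder()
    rows = []
    size = input_size
    rows.append({"stage": "encoder-1 (initial)", "out_channels": enc[0],
                 "spatial": f"{size}x{size}",
                 "params": net.encoder.initial.num_parameters()})
    for i in range(2, 6):
        size //= 2
        stage = getattr(net.encoder, f"stage{i}")
        rows.append({"stage": f"encoder-{i}", "out_channels": enc[i - 1],
                     "spatial": f"{size}x{size}",
                     "params": stage.num_parameters()})
    size //= 2
    for j in range(1, 6):
        size *= 2
        stage = getattr(net.decoder, f"stage{j}")
        rows.append({"stage": f"decoder-{j}", "out_channels": dec[j - 1],
                     "spatial": f"{size}x{size}",
                     "params": stage.num_parameters(),
                     "concat_in": net.decoder.concat_width(j)})
    rows.append({"stage": "head (1x1 + sigmoid)",
                 "out_channels": net.cfg.num_classes,
                 "spatial": f"{size}x{size}",
                 "params": net.decoder.head.num_parameters()})
    df = pd.DataFrame(rows)
    df.attrs["total_params"] = net.num_parameters()
    df.attrs["concat_junctions"] = net.concat_junctions
    return df


__all__ = [
    "NetworkConfig", "AblationVariant", "PooledFeature", "StageOutputs",
    "ConvBlock", "ConvUNeXtBlock", "InitialStageProposed",
    "InitialStageSegNet", "Encoder", "Decoder", "ReflexNet", "VARIANTS",
    "make_conv_block", "make_initial_stage_proposed",
    "make_initial_stage_segnet", "build_variant", "summarize_architecture",
    "as_input_tensor",
]
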