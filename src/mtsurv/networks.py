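"""Multitask network architectures for joint tumor segmentation and outcome
prediction on 3D volumes.

Two backbones are provided.  The CNN is a 3D UNet whose encoder blocks each
apply two 3x3x3 convolutions with instance normalization and Leaky ReLU
(slope 0.1), with max-pool halving between blocks and filter counts doubling
from ``base_filters`` up to ``max_filters``; the mirrored decoder upsamples
with 2x2x2 transposed convolutions and concatenates skip features, ending in
a single-channel sigmoid segmentation map.  Each encoder block additionally
feeds a 1x1x1 convolution (``per_block_outcome_filters`` filters) followed
by global average pooling; the pooled vectors are concatenated into the
outcome feature vector (4 blocks x 32 filters = 128 dimensions at the
default scale).  The ViT variant follows the UNETR layout: non-overlapping
patches are linearly embedded and processed by a transformer encoder;
intermediate token maps are reshaped to volumes and upsampled by
deconvolution stacks to form the skip pyramid of a UNet-style decoder, and
outcome features (16 per stage) are pooled from the four downsampling
stages.  An optional DenseNet branch consumes the input concatenated with
the predicted (soft) segmentation mask and contributes 3 x 32 pooled
features.

Outcome heads are layer normalization followed by one fully connected
layer: the Cox head emits a single tanh-bounded log-hazard, the
discrete-time head emits ``n_intervals`` sigmoid conditional survival
probabilities.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .autodiff import Tensor, concat, max_pool3d
from .layers import (
    AvgPool3d,
    Parameter,
    BatchNorm3d,
    Conv3d,
    ConvTranspose3d,
    InstanceNorm3d,
    LayerNorm,
    LeakyReLU,
    Linear,
    MaxPool3d,
    Module,
    ModuleList,
    ReLU,
    Sequential,
    global_avg_pool,
    softmax_last,
)

__all__ = [
    "NetworkConfig",
    "NetworkAudit",
    "build_network",
    "count_parameters",
    "forward_contract_check",
    "paper_cnn_config",
    "paper_vit_config",
    "tiny_cnn_config",
    "tiny_vit_config",
]

OUTCOME_MODES = ("single-cox", "single-gh", "multi")


@dataclass(frozen=True)
class NetworkConfig:
    """Scalable hyperparameters of the multitask architectures."""

    backbone: str = "unet"
    use_densenet: bool = False
    use_segmentation_loss: bool = True
    outcome_mode: str = "multi"
    input_shape: tuple = (48, 64, 64)
    channels: int = 1
    n_intervals: int = 10
    # UNet
    base_filters: int = 8
    encoder_blocks: int = 4
    max_filters: int = 64
    per_block_outcome_filters: int = 32
    # DenseNet branch
    densenet_init_filters: int = 24
    densenet_growth: int = 16
    densenet_block_layers: tuple = (4, 8, 16)
    densenet_bottleneck: int = 4
    densenet_compression: float = 0.5
    densenet_tap_filters: int = 32
    # ViT / UNETR
    vit_patch: int = 16
    vit_layers: int = 9
    vit_heads: int = 6
    vit_head_dim: int = 64
    vit_latent: int = 192
    vit_mlp: int = 768
    vit_feature_size: int = 16
    vit_tap_layers: tuple = (3, 6)

    def __post_init__(self):
        if self.backbone not in ("unet", "unetr"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.outcome_mode not in OUTCOME_MODES:
            raise ValueError(f"outcome_mode must be one of {OUTCOME_MODES}")
        if self.backbone == "unet":
            factor = 2 ** (self.encoder_blocks - 1)
            for name, extent in zip("ZYX", self.input_shape):
                if extent % factor:
                    raise ValueError(
                        f"input axis {name} ({extent}) not divisible by {factor} "
                        f"required for {self.encoder_blocks} encoder blocks"
                    )
        else:
            p = self.vit_patch
            if p & (p - 1):
                raise ValueError("vit_patch must be a power of two")
            for name, extent in zip("ZYX", self.input_shape):
                if extent % p:
                    raise ValueError(f"input axis {name} ({extent}) not divisible by patch {p}")

    # number of pooled outcome features the backbone + branches deliver
    @property
    def outcome_feature_dim(self) -> int:
        if self.backbone == "unet":
            dim = self.encoder_blocks * self.per_block_outcome_filters
        else:
            dim = 4 * self.vit_feature_size
        if self.use_densenet:
            dim += len(self.densenet_block_layers) * self.densenet_tap_filters
        return dim

    @property
    def unet_channels(self) -> list[int]:
        return [min(self.base_filters * 2**i, self.max_filters) for i in range(self.encoder_blocks)]

    # -- config file round-trip ------------------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "NetworkConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("input_shape", "densenet_block_layers", "vit_tap_layers"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass(frozen=True)
class NetworkAudit:
    """Parameter accounting of a built network."""

    trainable_parameters: int
    outcome_feature_dim: int
    segmentation_output_channels: int
    breakdown: dict = field(default_factory=dict)

    @property
    def millions(self) -> float:
        return self.trainable_parameters / 1e6

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


# -- presets -------------------------------------------------------------------


def paper_cnn_config(**overrides) -> NetworkConfig:
    """Full-scale multitask CNN (48x64x64 crops, 128-dim outcome features)."""
    return NetworkConfig(backbone="unet", **overrides)


def paper_vit_config(**overrides) -> NetworkConfig:
    """Full-scale UNETR-style ViT (9 layers, latent 192, 64-dim features).

    With the DenseNet branch enabled, its taps contribute 16 features per
    dense block (matching the 16-per-stage ViT taps) for 112 in total.
    """
    defaults = dict(backbone="unetr", densenet_tap_filters=16)
    defaults.update(overrides)
    return NetworkConfig(**defaults)


def tiny_cnn_config(**overrides) -> NetworkConfig:
    """Desk-scale CNN preset for CPU training: 16^3 volumes, 3 blocks."""
    defaults = dict(
        backbone="unet",
        input_shape=(16, 16, 16),
        base_filters=2,
        encoder_blocks=3,
        max_filters=8,
        per_block_outcome_filters=8,
        densenet_init_filters=8,
        densenet_growth=4,
        densenet_block_layers=(2, 2, 2),
        densenet_tap_filters=8,
    )
    defaults.update(overrides)
    return NetworkConfig(**defaults)


def tiny_vit_config(**overrides) -> NetworkConfig:
    """Desk-scale ViT preset: 16^3 volumes, patch 8, 3 transformer layers."""
    defaults = dict(
        backbone="unetr",
        input_shape=(16, 16, 16),
        vit_patch=8,
        vit_layers=3,
        vit_heads=2,
        vit_head_dim=8,
        vit_latent=16,
        vit_mlp=32,
        vit_feature_size=4,
        vit_tap_layers=(1, 2),
    )
    defaults.update(overrides)
    return NetworkConfig(**defaults)


# -- shared pieces -------------------------------------------------------------


class ConvBlock(Module):
    """Two 3x3x3 convolutions, each with instance norm and Leaky ReLU 0.1."""

    def __init__(self, cin, cout, rng):
        super().__init__()
        self.conv1 = Conv3d(cin, cout, 3, padding=1, bias=False, rng=rng)
        self.norm1 = InstanceNorm3d(cout)
        self.conv2 = Conv3d(cout, cout, 3, padding=1, bias=False, rng=rng)
        self.norm2 = InstanceNorm3d(cout)
        self.act = LeakyReLU(0.1)

    def forward(self, x):
        x = self.act(self.norm1(self.conv1(x)))
        return self.act(self.norm2(self.conv2(x)))


class OutcomeHeads(Module):
    """Layer normalization plus one fully connected layer per enabled head."""

    def __init__(self, feature_dim, mode, n_intervals, rng):
        super().__init__()
        self.mode = mode
        if mode in ("multi", "single-cox"):
            self.cox_norm = LayerNorm(feature_dim)
            self.cox_fc = Linear(feature_dim, 1, rng=rng)
        if mode in ("multi", "single-gh"):
            self.gh_norm = LayerNorm(feature_dim)
            self.gh_fc = Linear(feature_dim, n_intervals, rng=rng)

    def forward(self, features: Tensor) -> dict[str, Tensor]:
        out = {}
        if self.mode in ("multi", "single-cox"):
            out["log_hazard"] = self.cox_fc(self.cox_norm(features)).tanh().reshape(
                features.shape[0]
            )
        if self.mode in ("multi", "single-gh"):
            out["conditional_probs"] = self.gh_fc(self.gh_norm(features)).sigmoid()
        return out


class DenseLayer(Module):
    def __init__(self, cin, growth, bottleneck, rng):
        super().__init__()
        inner = bottleneck * growth
        self.norm1 = BatchNorm3d(cin)
        self.conv1 = Conv3d(cin, inner, 1, bias=False, rng=rng)
        self.norm2 = BatchNorm3d(inner)
        self.conv2 = Conv3d(inner, growth, 3, padding=1, bias=False, rng=rng)
        self.act = ReLU()

    def forward(self, x):
        y = self.conv1(self.act(self.norm1(x)))
        y = self.conv2(self.act(self.norm2(y)))
        return concat([x, y], axis=1)


class DenseBlock(Module):
    def __init__(self, cin, n_layers, growth, bottleneck, rng):
        super().__init__()
        self.layers = ModuleList(
            DenseLayer(cin + i * growth, growth, bottleneck, rng) for i in range(n_layers)
        )
        self.out_channels = cin + n_layers * growth

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class DenseNetBranch(Module):
    """Auxiliary outcome-feature extractor on image + predicted mask."""

    def __init__(self, config: NetworkConfig, rng):
        super().__init__()
        cfg = config
        cin = cfg.channels + 1  # image channels plus the soft mask
        f0 = cfg.densenet_init_filters
        self.conv0 = Conv3d(cin, f0, 7, stride=2, padding=3, bias=False, rng=rng)
        self.norm0 = BatchNorm3d(f0)
        self.act = ReLU()
        self.blocks = ModuleList()
        self.transitions = ModuleList()
        self.taps = ModuleList()
        self.tap_norms = ModuleList()
        channels = f0
        for i, n_layers in enumerate(cfg.densenet_block_layers):
            block = DenseBlock(channels, n_layers, cfg.densenet_growth, cfg.densenet_bottleneck, rng)
            self.blocks.append(block)
            channels = block.out_channels
            self.tap_norms.append(BatchNorm3d(channels))
            self.taps.append(Conv3d(channels, cfg.densenet_tap_filters, 1, rng=rng))
            if i + 1 < len(cfg.densenet_block_layers):
                out = int(channels * cfg.densenet_compression)
                self.transitions.append(
                    Sequential(
                        [
                            BatchNorm3d(channels),
                            ReLU(),
                            Conv3d(channels, out, 1, bias=False, rng=rng),
                            AvgPool3d(2),
                        ]
                    )
                )
                channels = out

    def forward(self, x: Tensor) -> list[Tensor]:
        y = self.act(self.norm0(self.conv0(x)))
        y = max_pool3d(y, 3, 2, 1)
        feats = []
        for i, block in enumerate(self.blocks):
            y = block(y)
            tap = self.act(self.taps[i](self.tap_norms[i](y)))
            feats.append(global_avg_pool(tap))
            if i < len(self.transitions):
                y = self.transitions[i](y)
        return feats


# -- the multitask UNet --------------------------------------------------------


class MultitaskUNet(Module):
    def __init__(self, config: NetworkConfig, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.config = config
        chans = config.unet_channels
        self.enc_blocks = ModuleList()
        cin = config.channels
        for c in chans:
            self.enc_blocks.append(ConvBlock(cin, c, rng))
            cin = c
        self.pool = MaxPool3d(2)
        self.upconvs = ModuleList()
        self.dec_blocks = ModuleList()
        for deep, shallow in zip(chans[::-1], chans[-2::-1]):
            self.upconvs.append(ConvTranspose3d(deep, shallow, 2, stride=2, rng=rng))
            self.dec_blocks.append(ConvBlock(2 * shallow, shallow, rng))
        self.seg_head = Conv3d(chans[0], 1, 1, rng=rng)
        self.taps = ModuleList(
            Conv3d(c, config.per_block_outcome_filters, 1, rng=rng) for c in chans
        )
        if config.use_densenet:
            self.densenet = DenseNetBranch(config, rng)
        self.heads = OutcomeHeads(
            config.outcome_feature_dim, config.outcome_mode, config.n_intervals, rng
        )

    def forward(self, x: Tensor) -> dict[str, Tensor]:
        skips = []
        feats = []
        y = x
        for i, block in enumerate(self.enc_blocks):
            if i > 0:
                y = self.pool(y)
            y = block(y)
            skips.append(y)
            feats.append(global_avg_pool(self.taps[i](y)))
        for upconv, dec, skip in zip(self.upconvs, self.dec_blocks, skips[-2::-1]):
            y = dec(concat([upconv(y), skip], axis=1))
        segmentation = self.seg_head(y).sigmoid()
        if self.config.use_densenet:
            feats.extend(self.densenet(concat([x, segmentation], axis=1)))
        out = self.heads(concat(feats, axis=1))
        out["segmentation"] = segmentation
        return out


# -- the UNETR-style ViT -------------------------------------------------------


class TransformerLayer(Module):
    def __init__(self, latent, heads, head_dim, mlp, rng):
        super().__init__()
        self.heads, self.head_dim = heads, head_dim
        inner = heads * head_dim
        self.norm1 = LayerNorm(latent)
        self.q = Linear(latent, inner, rng=rng)
        self.k = Linear(latent, inner, rng=rng)
        self.v = Linear(latent, inner, rng=rng)
        self.proj = Linear(inner, latent, rng=rng)
        self.norm2 = LayerNorm(latent)
        self.fc1 = Linear(latent, mlp, rng=rng)
        self.fc2 = Linear(mlp, latent, rng=rng)

    def _split(self, t: Tensor, n_tokens: int):
        return t.reshape(-1, n_tokens, self.heads, self.head_dim).transpose(0, 2, 1, 3)

    def forward(self, x: Tensor) -> Tensor:
        n_tokens = x.shape[1]
        h = self.norm1(x)
        q, k, v = (self._split(f(h), n_tokens) for f in (self.q, self.k, self.v))
        attn = softmax_last((q @ k.transpose(0, 1, 3, 2)) * (self.head_dim**-0.5))
        mixed = (attn @ v).transpose(0, 2, 1, 3).reshape(-1, n_tokens, self.heads * self.head_dim)
        x = x + self.proj(mixed)
        h = self.norm2(x)
        return x + self.fc2(self.fc1(h).leaky_relu(0.01))


class DeconvStack(Module):
    """Project token embeddings to a volume and upsample n times."""

    def __init__(self, latent, cout, n_ups, rng):
        super().__init__()
        self.proj = Conv3d(latent, cout, 1, rng=rng)
        self.ups = ModuleList(ConvTranspose3d(cout, cout, 2, stride=2, rng=rng) for _ in range(n_ups))
        self.act = LeakyReLU(0.01)

    def forward(self, x):
        y = self.act(self.proj(x))
        for up in self.ups:
            y = self.act(up(y))
        return y


class ResConvBlock(Module):
    """Residual pair of 3x3x3 convolutions with Leaky ReLU 0.01."""

    def __init__(self, cin, cout, rng):
        super().__init__()
        self.conv1 = Conv3d(cin, cout, 3, padding=1, bias=False, rng=rng)
        self.norm1 = InstanceNorm3d(cout)
        self.conv2 = Conv3d(cout, cout, 3, padding=1, bias=False, rng=rng)
        self.norm2 = InstanceNorm3d(cout)
        self.skip = Conv3d(cin, cout, 1, rng=rng) if cin != cout else None
        self.act = LeakyReLU(0.01)

    def forward(self, x):
        y = self.act(self.norm1(self.conv1(x)))
        y = self.norm2(self.conv2(y))
        res = x if self.skip is None else self.skip(x)
        return self.act(y + res)


class MultitaskUNETR(Module):
    def __init__(self, config: NetworkConfig, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.config = config
        cfg = config
        p = cfg.vit_patch
        n_ups = int(np.log2(p))
        if n_ups < 3:
            raise ValueError("vit_patch must be at least 8 for the decoder ladder")
        self.grid = tuple(s // p for s in cfg.input_shape)
        n_tokens = int(np.prod(self.grid))
        self.embed = Linear(cfg.channels * p**3, cfg.vit_latent, rng=rng)
        self.pos_embed = Parameter(
            rng.normal(0.0, 0.02, size=(n_tokens, cfg.vit_latent)).astype(np.float32)
        )
        self.layers = ModuleList(
            TransformerLayer(cfg.vit_latent, cfg.vit_heads, cfg.vit_head_dim, cfg.vit_mlp, rng)
            for _ in range(cfg.vit_layers)
        )
        self.final_norm = LayerNorm(cfg.vit_latent)
        f = cfg.vit_feature_size
        # encoder pyramid: input-level block plus deconv stacks from tapped layers
        self.enc0 = ResConvBlock(cfg.channels, f, rng)
        self.skip_deep = DeconvStack(cfg.vit_latent, 4 * f, 1, rng)  # one level above tokens
        self.skip_shallow = DeconvStack(cfg.vit_latent, 2 * f, 2, rng)  # two levels above
        self.bottleneck = ResConvBlock(cfg.vit_latent, 8 * f, rng)
        # decoder ladder: bottleneck at /2^n_ups back up to full resolution
        self.up_deep = ConvTranspose3d(8 * f, 4 * f, 2, stride=2, rng=rng)
        self.dec_deep = ResConvBlock(8 * f, 4 * f, rng)
        self.up_mid = ConvTranspose3d(4 * f, 2 * f, 2, stride=2, rng=rng)
        self.dec_mid = ResConvBlock(4 * f, 2 * f, rng)
        self.up_low = ConvTranspose3d(2 * f, f, 2, stride=2, rng=rng)
        if n_ups >= 4:  # patch 16: one more skip-free doubling
            self.dec_low = ResConvBlock(f, f, rng)
            self.up_full = ConvTranspose3d(f, f, 2, stride=2, rng=rng)
        else:
            self.dec_low = None
            self.up_full = None
        self.dec_full = ResConvBlock(2 * f, f, rng)
        self.seg_head = Conv3d(f, 1, 1, rng=rng)
        self.taps = ModuleList(
            Conv3d(c, f, 1, rng=rng) for c in (f, 2 * f, 4 * f, 8 * f)
        )
        if cfg.use_densenet:
            self.densenet = DenseNetBranch(cfg, rng)
        self.heads = OutcomeHeads(cfg.outcome_feature_dim, cfg.outcome_mode, cfg.n_intervals, rng)

    def _tokens_to_volume(self, tokens: Tensor) -> Tensor:
        gz, gy, gx = self.grid
        latent = self.config.vit_latent
        return tokens.reshape(-1, gz, gy, gx, latent).transpose(0, 4, 1, 2, 3)

    def forward(self, x: Tensor) -> dict[str, Tensor]:
        cfg = self.config
        p = cfg.vit_patch
        n, c = x.shape[:2]
        gz, gy, gx = self.grid
        patches = (
            x.reshape(n, c, gz, p, gy, p, gx, p)
            .transpose(0, 2, 4, 6, 1, 3, 5, 7)
            .reshape(n, gz * gy * gx, c * p**3)
        )
        tokens = self.embed(patches) + self.pos_embed
        tapped = {}
        for i, layer in enumerate(self.layers, start=1):
            tokens = layer(tokens)
            if i in cfg.vit_tap_layers:
                tapped[i] = tokens
        tokens = self.final_norm(tokens)
        shallow_idx, deep_idx = cfg.vit_tap_layers
        enc0 = self.enc0(x)
        enc_mid = self.skip_shallow(self._tokens_to_volume(tapped[shallow_idx]))
        enc_deep = self.skip_deep(self._tokens_to_volume(tapped[deep_idx]))
        bottleneck = self.bottleneck(self._tokens_to_volume(tokens))
        feats = [
            global_avg_pool(self.taps[0](enc0)),
            global_avg_pool(self.taps[1](enc_mid)),
            global_avg_pool(self.taps[2](enc_deep)),
            global_avg_pool(self.taps[3](bottleneck)),
        ]
        y = self.dec_deep(concat([self.up_deep(bottleneck), enc_deep], axis=1))
        y = self.dec_mid(concat([self.up_mid(y), enc_mid], axis=1))
        y = self.up_low(y)
        if self.up_full is not None:
            y = self.up_full(self.dec_low(y))
        segmentation = self.seg_head(self.dec_full(concat([y, enc0], axis=1))).sigmoid()
        if cfg.use_densenet:
            feats.extend(self.densenet(concat([x, segmentation], axis=1)))
        out = self.heads(concat(feats, axis=1))
        out["segmentation"] = segmentation
        return out


# -- public API ----------------------------------------------------------------


def build_network(config: NetworkConfig, seed: int | None = None) -> Module:
    """Instantiate the configured multitask network.

    The returned module maps a (batch, channels, Z, Y, X) Tensor or array to
    a dict with a ``segmentation`` probability map and, depending on
    ``outcome_mode``, ``log_hazard`` and/or ``conditional_probs``.
    """
    rng = np.random.default_rng(seed)
    if config.backbone == "unet":
        net = MultitaskUNet(config, rng)
    else:
        net = MultitaskUNETR(config, rng)
    return net


def predict(network: Module, volumes: np.ndarray) -> dict[str, np.ndarray]:
    """Evaluation-mode forward pass returning plain arrays."""
    was_training = network.training
    network.eval()
    out = network(Tensor(np.asarray(volumes, dtype=np.float32)))
    network.train(was_training)
    return {k: v.value for k, v in out.items()}


def _component_of(name: str) -> str:
    head = name.split(".", 1)[0]
    mapping = {
        "enc_blocks": "encoder",
        "pool": "encoder",
        "embed": "encoder",
        "pos": "encoder",
        "pos_embed": "encoder",
        "layers": "encoder",
        "final_norm": "encoder",
        "enc0": "encoder",
        "skip_shallow": "encoder",
        "skip_deep": "encoder",
        "bottleneck": "encoder",
        "upconvs": "decoder",
        "dec_blocks": "decoder",
        "seg_head": "decoder",
        "taps": "outcome_convs",
        "densenet": "densenet",
        "heads": "heads",
    }
    if head.startswith(("up_", "dec_")):
        return "decoder"
    return mapping.get(head, head)


def count_parameters(network: Module) -> NetworkAudit:
    """Exact trainable-parameter audit with a per-component breakdown."""
    breakdown: dict[str, int] = {}
    total = 0
    for name, p in network.named_parameters():
        comp = _component_of(name)
        breakdown[comp] = breakdown.get(comp, 0) + p.value.size
        total += p.value.size
    return NetworkAudit(
        trainable_parameters=total,
        outcome_feature_dim=network.config.outcome_feature_dim,
        segmentation_output_channels=1,
        breakdown=breakdown,
    )


def forward_contract_check(network: Module, config: NetworkConfig, batch: int = 2, seed: int = 0) -> dict:
    """Run a random batch and assert the output contracts.

    Checks: segmentation is a full-resolution single-channel map in [0, 1];
    the Cox log-hazard lies strictly inside (-1, 1); the discrete head
    produces ``n_intervals`` probabilities strictly inside (0, 1); heads
    absent in single-outcome modes are really absent.
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((batch, config.channels, *config.input_shape)).astype(np.float32)
    out = predict(network, x)
    seg = out["segmentation"]
    assert seg.shape == (batch, 1, *config.input_shape), f"segmentation shape {seg.shape}"
    assert np.all((seg >= 0) & (seg <= 1)), "segmentation outside [0, 1]"
    report = {"segmentation_shape": list(seg.shape)}
    if config.outcome_mode in ("multi", "single-cox"):
        lh = out["log_hazard"]
        assert lh.shape == (batch,), f"log-hazard shape {lh.shape}"
        assert np.all(np.abs(lh) < 1), "log-hazard outside (-1, 1)"
        report["log_hazard_range"] = [float(lh.min()), float(lh.max())]
    else:
        assert "log_hazard" not in out, "Cox head present in single-gh mode"
    if config.outcome_mode in ("multi", "single-gh"):
        probs = out["conditional_probs"]
        assert probs.shape == (batch, config.n_intervals), f"discrete head shape {probs.shape}"
        assert np.all((probs > 0) & (probs < 1)), "conditional probabilities outside (0, 1)"
        report["head_width"] = int(probs.shape[1])
    else:
        assert "conditional_probs" not in out, "discrete head present in single-cox mode"
    report["ok"] = True
    return report
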