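"""Self-attention-guided multi-scale pyramid illumination correction.

The corrected illumination map is produced from the abnormal image's
illumination component by a three-level pyramid:

* the input map I1 is max-pooled (2x2, stride 2) twice into I2 and I3;
* each level runs an entry 3x3 convolution and two residual blocks; the
  full-resolution branch additionally runs a pyramid pooling module
  (adaptive average pooling to 1, 2, 3 and 6 bins, per-bin channel
  compression, bilinear upsampling, concatenation, 1x1 projection and a
  residual add) to inject global context;
* each level's final features are modulated per pixel by a self-attention
  map, then upsampled bilinearly and concatenated into the next level,
  with a 1x1 convolution halving the channels after every concatenation;
* a two-convolution reconstruction head with a sigmoid yields the
  corrected map.

The attention map is built from the *inverse* illumination component
``1 - I`` stacked with the green and blue channels of the image to be
enhanced (vessels concentrate in G/B): three parallel dilated 3x3
convolutions (rates 1, 2 and 5) each produce one channel, their per-pixel
mean passes through a sigmoid.  Dark regions therefore receive weights
close to 1 and already-bright regions are attenuated, which counteracts
over-enhancement.

Training minimises ``L_r + 0.1 * L_i`` where ``L_r`` is the mean L1 of
``R_abnormal o I_hat`` against the *normal* image's appearance target and
``L_i`` is the same edge-aware smoothness penalty used by the
decomposition stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import imaging
from .autodiff import Tensor, concatenate, conv2d, maxpool2x2
from .decomposition import LAMBDA_G, loss_illumination_smoothness_t, _mean_l1_t, _t3
from .nn import Conv2d, Module, adaptive_avg_pool, resize_bilinear

__all__ = [
    "ICNConfig",
    "WEIGHT_ICN_SMOOTHNESS",
    "ResidualBlock",
    "PyramidPoolingModule",
    "AttentionModule",
    "IlluminationCorrectionNet",
    "build_pyramid",
    "attention_weight_map",
    "correct_illumination",
    "loss_icn_recon",
    "loss_icn_smooth",
    "loss_icn_total",
]

#: Weight of the smoothness term in the ICN total loss.
WEIGHT_ICN_SMOOTHNESS = 0.1


@dataclass(frozen=True)
class ICNConfig:
    """Architecture knobs of the correction network.

    Dilation rates and pooling bins are fixed by the method; width and
    residual depth are free choices kept configurable.
    """

    base_channels: int = 64
    residual_blocks_per_branch: int = 2
    dilation_rates: tuple[int, ...] = (1, 2, 5)
    ppm_bins: tuple[int, ...] = (1, 2, 3, 6)


class ResidualBlock(Module):
    """conv3x3 -> ReLU -> conv3x3, added to the skip path."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.conv1 = Conv2d(channels, channels, 3, rng=rng)
        self.conv2 = Conv2d(channels, channels, 3, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.conv2(self.conv1(x).relu()) + x


class PyramidPoolingModule(Module):
    """Multi-bin global pooling with residual, channel-preserving output."""

    def __init__(self, channels: int, bins: tuple[int, ...], rng: np.random.Generator):
        self.bins = bins
        # Compress each pooled branch so the concatenation doubles the width.
        branch = max(channels // len(bins), 1)
        self.branch_convs = [Conv2d(channels, branch, 1, rng=rng) for _ in bins]
        self.project = Conv2d(channels + branch * len(bins), channels, 1, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        h, w = x.shape[-2:]
        if h < max(self.bins) or w < max(self.bins):
            raise ValueError(f"PPM input {h}x{w} smaller than the largest bin grid {max(self.bins)}")
        pooled = [x]
        for bins, conv in zip(self.bins, self.branch_convs):
            p = conv(adaptive_avg_pool(x, bins))
            pooled.append(resize_bilinear(p, (h, w)))
        return self.project(concatenate(pooled, axis=1)) + x


class AttentionModule(Module):
    """Dilated-convolution spatial self-attention over [1 - I, G, B]."""

    def __init__(self, config: ICNConfig, rng: np.random.Generator):
        self.convs = [Conv2d(3, 1, 3, dilation=d, rng=rng) for d in config.dilation_rates]

    def __call__(self, stack: Tensor) -> Tensor:
        maps = [conv(stack) for conv in self.convs]
        mean = concatenate(maps, axis=1).mean(axis=1, keepdims=True)
        return mean.sigmoid()


class _Branch(Module):
    """Entry convolution plus residual blocks of one pyramid level."""

    def __init__(self, channels: int, depth: int, rng: np.random.Generator):
        self.entry = Conv2d(1, channels, 3, rng=rng)
        self.blocks = [ResidualBlock(channels, rng) for _ in range(depth)]

    def __call__(self, x: Tensor) -> Tensor:
        f = self.entry(x).relu()
        for block in self.blocks:
            f = block(f)
        return f


class IlluminationCorrectionNet(Module):
    """Three-level pyramid with attention modulation and PPM context."""

    def __init__(self, config: ICNConfig | None = None, seed: int | None = None):
        self.config = config or ICNConfig()
        rng = np.random.default_rng(seed)
        c = self.config.base_channels
        depth = self.config.residual_blocks_per_branch
        self.attention = AttentionModule(self.config, rng)
        self.branch_full = _Branch(c, depth, rng)
        self.branch_half = _Branch(c, depth, rng)
        self.branch_quarter = _Branch(c, depth, rng)
        self.ppm = PyramidPoolingModule(c, self.config.ppm_bins, rng)
        self.fuse_half = Conv2d(2 * c, c, 1, rng=rng)
        self.fuse_full = Conv2d(2 * c, c, 1, rng=rng)
        self.recon1 = Conv2d(c, c, 3, rng=rng)
        self.recon2 = Conv2d(c, 1, 3, rng=rng)

    def forward(self, i_abnormal: Tensor, s_abnormal: Tensor,
                use_attention: bool = True) -> Tensor:
        """(N,1,H,W) illumination + (N,3,H,W) image -> corrected (N,1,H,W)."""
        if i_abnormal.shape[-2:] != s_abnormal.shape[-2:]:
            raise ValueError(
                f"illumination {i_abnormal.shape[-2:]} and image {s_abnormal.shape[-2:]} disagree")
        i1, i2, i3 = build_pyramid_t(i_abnormal)

        if use_attention:
            stack = concatenate([1.0 - i_abnormal,
                                 s_abnormal[:, 1:2, :, :],
                                 s_abnormal[:, 2:3, :, :]], axis=1)
            att = self.attention(stack)
        else:
            att = None

        def modulate(f: Tensor) -> Tensor:
            if att is None:
                return f
            return f * resize_bilinear(att, f.shape[-2:])

        f3 = modulate(self.branch_quarter(i3))
        f2 = modulate(self.branch_half(i2))
        f1 = modulate(self.ppm(self.branch_full(i1)))

        m2 = self.fuse_half(concatenate([f2, resize_bilinear(f3, f2.shape[-2:])], axis=1))
        m1 = self.fuse_full(concatenate([f1, resize_bilinear(m2, f1.shape[-2:])], axis=1))
        return self.recon2(self.recon1(m1).relu()).sigmoid()

    __call__ = forward


def build_pyramid_t(i1: Tensor) -> tuple[Tensor, Tensor, Tensor]:
    """Full, half and quarter resolution levels via repeated 2x2 max pooling."""
    i2 = maxpool2x2(i1)
    i3 = maxpool2x2(i2)
    return i1, i2, i3


def build_pyramid(illumination: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Numpy pyramid of an (H, W, 1) map; sizes floor-halve per level."""
    i = imaging.as_single_channel(illumination)
    if i.shape[0] < imaging.MIN_SIZE or i.shape[1] < imaging.MIN_SIZE:
        raise ValueError(f"map must be at least {imaging.MIN_SIZE} on each side, got {i.shape[:2]}")
    levels = build_pyramid_t(Tensor(imaging.to_nchw(i, dtype=np.float64)))
    return tuple(imaging.from_nchw(level.data) for level in levels)


def attention_weight_map(illumination: np.ndarray, image: np.ndarray,
                         net: IlluminationCorrectionNet) -> np.ndarray:
    """(H, W, 1) attention weights in (0, 1) for a decomposed image."""
    i = imaging.as_single_channel(illumination)
    s = imaging.validate_rgb(image)
    if i.shape[:2] != s.shape[:2]:
        raise ValueError(f"shape mismatch: {i.shape[:2]} vs {s.shape[:2]}")
    it = Tensor(imaging.to_nchw(i))
    st = Tensor(imaging.to_nchw(s))
    stack = concatenate([1.0 - it, st[:, 1:2, :, :], st[:, 2:3, :, :]], axis=1)
    return imaging.from_nchw(net.attention(stack).data)


def correct_illumination(illumination: np.ndarray, image: np.ndarray,
                         net: IlluminationCorrectionNet,
                         use_attention: bool = True) -> np.ndarray:
    """Correct an abnormal (H, W, 1) illumination map; output in [0, 1]."""
    i = imaging.as_single_channel(illumination)
    s = imaging.validate_rgb(image)
    out = net(Tensor(imaging.to_nchw(i)), Tensor(imaging.to_nchw(s)),
              use_attention=use_attention)
    return imaging.from_nchw(out.data)


# -- losses ---------------------------------------------------------------


def loss_icn_recon_t(i_hat: Tensor, r_abnormal: Tensor, target: Tensor) -> Tensor:
    return _mean_l1_t(r_abnormal * i_hat, target)


def loss_icn_recon(i_hat: np.ndarray, r_abnormal: np.ndarray, target: np.ndarray) -> float:
    """Mean L1 of R_abnormal o I_hat against the reconstruction target."""
    i = imaging.as_single_channel(i_hat)
    if i.shape[:2] != np.asarray(r_abnormal).shape[:2]:
        raise ValueError("i_hat and reflectance sizes disagree")
    return loss_icn_recon_t(_t3(i), _t3(r_abnormal), _t3(target)).item()


def loss_icn_smooth(i_hat: np.ndarray, r_abnormal: np.ndarray,
                    lambda_g: float = LAMBDA_G) -> float:
    """Edge-aware smoothness of the corrected illumination map."""
    i = imaging.as_single_channel(i_hat)
    return loss_illumination_smoothness_t(_t3(i), _t3(r_abnormal), lambda_g).item()


def loss_icn_total(recon: float, smooth: float) -> float:
    """Total ICN loss: recon + 0.1 * smooth."""
    return recon + WEIGHT_ICN_SMOOTHNESS * smooth
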