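"""Retinex decomposition network and its training losses.

The network maps an RGB image to a 3-channel reflectance map and a
1-channel illumination map.  Its input is the image concatenated with the
per-pixel maximum over R, G and B (a cheap illumination prior), giving 4
input channels; a 9x9 convolution lifts these to 64 features, five 3x3
convolutions with ReLU form the body, and a final 3x3 convolution with a
sigmoid produces 4 channels that split 3 + 1 into reflectance and
illumination.  Head and output layers carry no ReLU.

Training uses three losses on paired abnormal/normal-illumination images:

* invariable reflectance: mean L1 between the two reflectance maps —
  reflectance is an object property and should not depend on lighting;
* illumination smoothness: total variation of the illumination map,
  down-weighted by ``exp(-lambda_g * |grad reflectance|)`` so illumination
  may jump where the scene itself has edges (``lambda_g = 10``);
* reconstruction: mean L1 of every cross-combination ``R_i o I_j``
  against ``S_j``, weight 1 on matched pairs and 0.1 on swapped ones.

The total is ``L_recon + 0.1 * L_smooth + 0.01 * L_invariable``.

All L1 norms are means over elements so loss magnitudes do not scale with
image resolution.
"""

from __future__ import annotations

import numpy as np

from . import imaging
from .autodiff import Tensor, concatenate
from .nn import Conv2d, Module, gradient_map_t

__all__ = [
    "LAMBDA_G",
    "WEIGHT_SMOOTHNESS",
    "WEIGHT_INVARIABLE",
    "LAMBDA_CROSS",
    "DecompositionNet",
    "decompose",
    "loss_invariable_reflectance",
    "loss_illumination_smoothness",
    "loss_illumination_smoothness_pair",
    "loss_reconstruction",
    "loss_decom_total",
    "model_storage_megabytes",
]

#: Gradient-aware balance coefficient of the smoothness loss.
LAMBDA_G = 10.0
#: Weight of the smoothness term in the total decomposition loss.
WEIGHT_SMOOTHNESS = 0.1
#: Weight of the invariable-reflectance term in the total loss.
WEIGHT_INVARIABLE = 0.01
#: Reconstruction weight for mismatched (i != j) reflectance/illumination.
LAMBDA_CROSS = 0.1


class DecompositionNet(Module):
    """4 -> 64 (9x9) -> 5 x [64 (3x3) + ReLU] -> 4 (3x3) -> sigmoid."""

    IN_CHANNELS = 4
    FEATURES = 64
    HEAD_KERNEL = 9
    BODY_KERNEL = 3
    BODY_DEPTH = 5
    OUT_CHANNELS = 4

    def __init__(self, seed: int | None = None):
        rng = np.random.default_rng(seed)
        self.head = Conv2d(self.IN_CHANNELS, self.FEATURES, self.HEAD_KERNEL, rng=rng)
        self.body = [Conv2d(self.FEATURES, self.FEATURES, self.BODY_KERNEL, rng=rng)
                     for _ in range(self.BODY_DEPTH)]
        self.out = Conv2d(self.FEATURES, self.OUT_CHANNELS, self.BODY_KERNEL, rng=rng)

    def forward(self, s: Tensor) -> tuple[Tensor, Tensor]:
        """(N, 3, H, W) image tensor -> reflectance (N, 3), illumination (N, 1)."""
        channel_max = Tensor(s.data.max(axis=1, keepdims=True))
        x = concatenate([s, channel_max], axis=1)
        f = self.head(x)
        for layer in self.body:
            f = layer(f).relu()
        f = self.out(f).sigmoid()
        return f[:, :3, :, :], f[:, 3:4, :, :]

    __call__ = forward


def decompose(image: np.ndarray, net: DecompositionNet) -> tuple[np.ndarray, np.ndarray]:
    """Split an (H, W, 3) image into reflectance (H, W, 3) and illumination (H, W, 1).

    The forward pass is deterministic; both outputs lie in [0, 1] by the
    sigmoid contract.
    """
    s = imaging.validate_rgb(image)
    r, i = net(Tensor(imaging.to_nchw(s)))
    return imaging.from_nchw(r.data), imaging.from_nchw(i.data)


# -- losses ---------------------------------------------------------------
#
# Each loss has a Tensor core (differentiable, used in training) and a thin
# numpy wrapper in (H, W, C) layout that returns a float.


def _mean_l1_t(a: Tensor, b: Tensor) -> Tensor:
    return (a - b).abs().mean()


def loss_invariable_reflectance_t(r_abnormal: Tensor, r_normal: Tensor) -> Tensor:
    return _mean_l1_t(r_abnormal, r_normal)


def loss_illumination_smoothness_t(i: Tensor, r: Tensor, lambda_g: float = LAMBDA_G) -> Tensor:
    """Mean of |grad I| * exp(-lambda_g * |grad mean_c(R)|) over pixels."""
    r_mean = r.mean(axis=1, keepdims=True)
    weight = (gradient_map_t(r_mean) * (-lambda_g)).exp()
    return (gradient_map_t(i) * weight).mean()


def loss_reconstruction_t(r_abnormal: Tensor, i_abnormal: Tensor,
                          r_normal: Tensor, i_normal: Tensor,
                          s_abnormal: Tensor, s_normal: Tensor,
                          lambda_cross: float = LAMBDA_CROSS) -> Tensor:
    total = None
    for r, own in ((r_abnormal, "abnormal"), (r_normal, "normal")):
        for i, s, name in ((i_abnormal, s_abnormal, "abnormal"),
                           (i_normal, s_normal, "normal")):
            weight = 1.0 if own == name else lambda_cross
            term = _mean_l1_t(r * i, s) * weight
            total = term if total is None else total + term
    return total


def loss_decom_total_t(recon: Tensor, smooth: Tensor, invariable: Tensor) -> Tensor:
    return recon + WEIGHT_SMOOTHNESS * smooth + WEIGHT_INVARIABLE * invariable


def _t3(x: np.ndarray) -> Tensor:
    """(H, W, C) float array -> (1, C, H, W) float64 Tensor."""
    return Tensor(imaging.to_nchw(np.asarray(x, dtype=np.float64), dtype=np.float64))


def _check_same_shape(*arrays: np.ndarray) -> None:
    shapes = {np.asarray(a).shape for a in arrays}
    if len(shapes) > 1:
        raise ValueError(f"shape mismatch between loss inputs: {sorted(shapes)}")


def loss_invariable_reflectance(r_abnormal: np.ndarray, r_normal: np.ndarray) -> float:
    """Mean absolute difference between paired reflectance maps."""
    _check_same_shape(r_abnormal, r_normal)
    return loss_invariable_reflectance_t(_t3(r_abnormal), _t3(r_normal)).item()


def loss_illumination_smoothness(illumination: np.ndarray, reflectance: np.ndarray,
                                 lambda_g: float = LAMBDA_G) -> float:
    """Edge-aware total variation of a single illumination map."""
    i = imaging.as_single_channel(illumination)
    r = np.asarray(reflectance, dtype=np.float64)
    if i.shape[:2] != r.shape[:2]:
        raise ValueError(f"shape mismatch: {i.shape[:2]} vs {r.shape[:2]}")
    return loss_illumination_smoothness_t(_t3(i), _t3(r), lambda_g).item()


def loss_illumination_smoothness_pair(i_abnormal, r_abnormal, i_normal, r_normal,
                                      lambda_g: float = LAMBDA_G) -> float:
    """Smoothness term summed over both members of a training pair."""
    return (loss_illumination_smoothness(i_abnormal, r_abnormal, lambda_g)
            + loss_illumination_smoothness(i_normal, r_normal, lambda_g))


def loss_reconstruction(r_abnormal, i_abnormal, r_normal, i_normal,
                        s_abnormal, s_normal,
                        lambda_cross: float = LAMBDA_CROSS) -> float:
    """Four-term cross-reconstruction loss of a decomposed pair."""
    _check_same_shape(r_abnormal, r_normal, s_abnormal, s_normal)
    return loss_reconstruction_t(
        _t3(r_abnormal), _t3(imaging.as_single_channel(i_abnormal)),
        _t3(r_normal), _t3(imaging.as_single_channel(i_normal)),
        _t3(s_abnormal), _t3(s_normal), lambda_cross).item()


def loss_decom_total(recon: float, smooth: float, invariable: float) -> float:
    """Total decomposition loss: recon + 0.1 * smooth + 0.01 * invariable."""
    return recon + WEIGHT_SMOOTHNESS * smooth + WEIGHT_INVARIABLE * invariable


def model_storage_megabytes(net: Module) -> float:
    """Float32 storage of all learnable scalars, in MB (4 bytes each)."""
    return net.parameter_count() * 4 / 1e6
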