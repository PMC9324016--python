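"""Closed-form reflection component enhancement (RCE).

Vessels absorb green and blue light much more strongly than red, so
vascular detail concentrates in the G and B channels of an endoscopic
image while the mucosal layer blurs it.  RCE sharpens that detail without
a learned model:

1. adaptive stretching of the G and B channels of the reflectance:
   ``(I_c - mu_c) / (sigma_c + tau)`` with per-channel mean ``mu_c`` and
   population standard deviation ``sigma_c`` — blurrier channels (small
   sigma) are stretched harder; the R channel is kept unchanged;
2. weighted fusion with the original reflectance,
   ``R_out = ((sigma_G + sigma_B) / 2) * R_c + R``, which restores colour
   fidelity while keeping the stretched vessel contrast; ``sigma_G`` and
   ``sigma_B`` are taken from the original reflectance.

``tau`` (default 0.5) trades contrast for brightness: raising it shrinks
the stretched values, so the fused image gets brighter and flatter.
The fused result is clipped to [0, 1].
"""

from __future__ import annotations

import numpy as np

from . import imaging

__all__ = [
    "DEFAULT_TAU",
    "stretch_channel",
    "enhance_reflection",
    "stretch_all_channels",
]

#: Contrast/brightness trade-off of the adaptive stretch.
DEFAULT_TAU = 0.5


def stretch_channel(channel: np.ndarray, tau: float = DEFAULT_TAU) -> np.ndarray:
    """Adaptive mean/std stretch of one channel: (x - mu) / (sigma + tau).

    ``sigma`` is the population standard deviation.  The output has zero
    mean; a constant channel maps to all zeros.  Accepts (H, W) or
    (H, W, 1) and preserves the shape.
    """
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    arr = np.asarray(channel, dtype=np.float64)
    mu = arr.mean()
    sigma = arr.std()
    return (arr - mu) / (sigma + tau)


def _stretched(reflectance: np.ndarray, tau: float, channels: tuple[int, ...]) -> np.ndarray:
    rc = np.asarray(reflectance, dtype=np.float64).copy()
    for c in channels:
        rc[:, :, c] = stretch_channel(rc[:, :, c], tau)
    return rc


def _fuse(reflectance: np.ndarray, rc: np.ndarray) -> np.ndarray:
    sigma_g = reflectance[:, :, 1].std()
    sigma_b = reflectance[:, :, 2].std()
    fused = ((sigma_g + sigma_b) / 2.0) * rc + reflectance
    return np.clip(fused, 0.0, 1.0)


def enhance_reflection(reflectance: np.ndarray, tau: float = DEFAULT_TAU) -> np.ndarray:
    """Stretch G and B of a [0, 1] reflectance map and fuse with the original.

    Constant maps are fixed points (zero numerator and zero fusion
    weight).  The result is clipped to [0, 1].
    """
    r = imaging.validate_rgb(reflectance, name="reflectance")
    return _fuse(r, _stretched(r, tau, channels=(1, 2)))


def stretch_all_channels(reflectance: np.ndarray, tau: float = DEFAULT_TAU) -> np.ndarray:
    """Ablation variant stretching R as well as G and B before fusion.

    Kept for side-by-side comparison; stretching the red channel distorts
    tissue colour, which is why the default enhancement leaves it alone.
    """
    r = imaging.validate_rgb(reflectance, name="reflectance")
    return _fuse(r, _stretched(r, tau, channels=(0, 1, 2)))
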