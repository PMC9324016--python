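"""Full-reference image quality metrics: PSNR, SSIM and GMSD.

All metrics operate on [0, 1] float images (dynamic range 1); PSNR is
therefore reported on the same dB scale as an 8-bit computation.  SSIM
uses the standard 11x11 Gaussian window (sigma 1.5, K1 = 0.01,
K2 = 0.03) and averages colour channels.  GMSD computes Prewitt gradient
magnitudes of the BT.601 luminance and reports the standard deviation of
the per-pixel gradient-magnitude similarity map; its stabiliser is the
canonical 170 on the 255^2 scale, i.e. 0.0026 on [0, 1] data.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import correlate, gaussian_filter

__all__ = ["psnr", "ssim", "gmsd", "score_report"]

_LUMA = np.array([0.299, 0.587, 0.114])

#: SSIM window and stabilisers.
_SSIM_SIGMA = 1.5
_SSIM_TRUNCATE = 3.5  # radius int(3.5 * 1.5 + 0.5) = 5 -> 11x11 window
_SSIM_PAD = 5
_K1, _K2 = 0.01, 0.03

#: GMSD stabiliser on the [0, 1] intensity scale (170 / 255^2).
_GMSD_C = 0.0026

# 3x3 Prewitt derivative kernels, 1/3-scaled as in the GMSD definition.
_PREWITT_X = np.array([[1.0, 0.0, -1.0]] * 3) / 3.0
_PREWITT_Y = _PREWITT_X.T


def _check_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"image shapes disagree: {x.shape} vs {y.shape}")
    return x, y


def psnr(x: np.ndarray, y: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB, MAX = 1; identical images -> inf."""
    x, y = _check_pair(x, y)
    mse = float(np.mean((x - y) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(1.0 / mse)


def _ssim_single(x: np.ndarray, y: np.ndarray) -> float:
    """Mean local SSIM of one channel over valid (non-border) windows."""

    def f(img):
        return gaussian_filter(img, sigma=_SSIM_SIGMA, truncate=_SSIM_TRUNCATE)

    ux, uy = f(x), f(y)
    vxx = f(x * x) - ux * ux
    vyy = f(y * y) - uy * uy
    vxy = f(x * y) - ux * uy
    c1 = _K1 ** 2
    c2 = _K2 ** 2
    s = ((2 * ux * uy + c1) * (2 * vxy + c2)) / ((ux ** 2 + uy ** 2 + c1) * (vxx + vyy + c2))
    p = _SSIM_PAD
    return float(s[p:-p, p:-p].mean())


def ssim(x: np.ndarray, y: np.ndarray) -> float:
    """Mean structural similarity; colour images average over channels."""
    x, y = _check_pair(x, y)
    if min(x.shape[0], x.shape[1]) < 2 * _SSIM_PAD + 1:
        raise ValueError(f"images must be at least {2 * _SSIM_PAD + 1} per side for SSIM")
    if x.ndim == 2:
        return _ssim_single(x, y)
    return float(np.mean([_ssim_single(x[:, :, c], y[:, :, c]) for c in range(x.shape[2])]))


def _gradient_magnitude(lum: np.ndarray) -> np.ndarray:
    gx = correlate(lum, _PREWITT_X, mode="reflect")
    gy = correlate(lum, _PREWITT_Y, mode="reflect")
    return np.sqrt(gx * gx + gy * gy)


def gmsd(x: np.ndarray, y: np.ndarray) -> float:
    """Gradient magnitude similarity deviation; 0 for identical images."""
    x, y = _check_pair(x, y)
    lx = x @ _LUMA if x.ndim == 3 else x
    ly = y @ _LUMA if y.ndim == 3 else y
    gx = _gradient_magnitude(lx)
    gy = _gradient_magnitude(ly)
    gms = (2.0 * gx * gy + _GMSD_C) / (gx * gx + gy * gy + _GMSD_C)
    return float(gms.std())


def score_report(x: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """PSNR/SSIM/GMSD of one image pair as a plain dict."""
    return {"psnr": psnr(x, y), "ssim": ssim(x, y), "gmsd": gmsd(x, y)}
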