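"""Shared image containers, Retinex recomposition and the gradient operator.

Images are float64 numpy arrays in [0, 1]:

* RGB images: (H, W, 3), channel order R, G, B;
* illumination maps: (H, W, 1) (or (H, W), accepted and normalised);
* reflectance maps: (H, W, 3).

8-bit files are divided by 255 on read and rounded back on write.  The
observed image S is modelled as the element-wise product of a reflectance
map R (intrinsic tissue colour, vessels) and a broadcast single-channel
illumination map I.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np

__all__ = [
    "MIN_SIZE",
    "validate_rgb",
    "as_single_channel",
    "recompose",
    "gradient_map",
    "mean_luminance",
    "load_image",
    "save_image",
    "save_components",
    "load_components",
    "to_nchw",
    "from_nchw",
]

#: Smallest spatial size the networks accept (two rounds of halving).
MIN_SIZE = 8

_LUMA = np.array([0.299, 0.587, 0.114])  # BT.601 weights


def validate_rgb(image: np.ndarray, name: str = "image") -> np.ndarray:
    """Check an (H, W, 3) image in [0, 1]; returns it as float64."""
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"{name} must have shape (H, W, 3), got {arr.shape}")
    if arr.shape[0] < MIN_SIZE or arr.shape[1] < MIN_SIZE:
        raise ValueError(f"{name} must be at least {MIN_SIZE}x{MIN_SIZE}, got {arr.shape[:2]}")
    if not np.isfinite(arr).all():
        raise ValueError(f"{name} contains non-finite values")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError(f"{name} values must lie in [0, 1]")
    return arr


def as_single_channel(values: np.ndarray, name: str = "illumination") -> np.ndarray:
    """Coerce (H, W) or (H, W, 1) to (H, W, 1) float64."""
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if arr.ndim != 3 or arr.shape[2] != 1:
        raise ValueError(f"{name} must have shape (H, W, 1), got {arr.shape}")
    return arr


def recompose(reflectance: np.ndarray, illumination: np.ndarray) -> np.ndarray:
    """Element-wise product S = R o I, the Retinex image formation model.

    The single illumination channel is broadcast over the three colour
    channels; the result is clipped to [0, 1].
    """
    r = np.asarray(reflectance, dtype=np.float64)
    i = as_single_channel(illumination)
    if r.ndim != 3 or r.shape[2] != 3:
        raise ValueError(f"reflectance must have shape (H, W, 3), got {r.shape}")
    if r.shape[:2] != i.shape[:2]:
        raise ValueError(f"shape mismatch: reflectance {r.shape[:2]} vs illumination {i.shape[:2]}")
    return np.clip(r * i, 0.0, 1.0)


def gradient_map(x: np.ndarray) -> np.ndarray:
    """|horizontal| + |vertical| forward differences, replicate-padded.

    Accepts (H, W), (H, W, 1) or (H, W, 3); the output has the input's
    shape.  Replicate padding makes the difference zero at the last
    row/column, so constants map to zero everywhere.
    """
    arr = np.asarray(x, dtype=np.float64)
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[:, :, None]
    if arr.ndim != 3 or arr.shape[2] not in (1, 3):
        raise ValueError(f"expected (H, W), (H, W, 1) or (H, W, 3), got {np.asarray(x).shape}")
    out = np.zeros_like(arr)
    out[:-1, :, :] += np.abs(arr[1:, :, :] - arr[:-1, :, :])
    out[:, :-1, :] += np.abs(arr[:, 1:, :] - arr[:, :-1, :])
    return out[:, :, 0] if squeeze else out


def mean_luminance(image: np.ndarray) -> float:
    """Mean BT.601 luma of an RGB image."""
    return float((np.asarray(image, dtype=np.float64) * _LUMA).sum(axis=-1).mean())


def load_image(path: str | os.PathLike) -> np.ndarray:
    """Read an 8-bit PNG/JPEG as an (H, W, 3) float image in [0, 1]."""
    raw = iio.imread(path)
    if raw.ndim == 2:
        raw = np.stack([raw] * 3, axis=-1)
    if raw.shape[2] == 4:  # drop alpha
        raw = raw[:, :, :3]
    return validate_rgb(raw.astype(np.float64) / 255.0)


def save_image(image: np.ndarray, path: str | os.PathLike) -> None:
    """Write a [0, 1] float image as 8-bit (round, clip)."""
    arr = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(path, np.round(arr * 255.0).astype(np.uint8))


def save_components(path: str | os.PathLike, reflectance: np.ndarray,
                    illumination: np.ndarray) -> None:
    """Persist a decomposition losslessly as a compressed NPZ archive."""
    np.savez_compressed(path, reflectance=np.asarray(reflectance, dtype=np.float32),
                        illumination=np.asarray(as_single_channel(illumination), dtype=np.float32))


def load_components(path: str | os.PathLike) -> tuple[np.ndarray, np.ndarray]:
    with np.load(path) as data:
        return data["reflectance"].astype(np.float64), data["illumination"].astype(np.float64)


def to_nchw(image: np.ndarray, dtype=np.float32) -> np.ndarray:
    """(H, W, C) -> (1, C, H, W) for the networks."""
    arr = np.asarray(image)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    return arr.transpose(2, 0, 1)[None].astype(dtype)


def from_nchw(batch: np.ndarray) -> np.ndarray:
    """(1, C, H, W) -> (H, W, C) float64."""
    return np.asarray(batch)[0].transpose(1, 2, 0).astype(np.float64)
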