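"""Seeded generator of paired endoscope-like phantom images.

Real paired endoscopic datasets are private, so training and testing here
run on synthetic phantoms that reproduce the properties the method's
losses rely on:

* a pinkish tissue base with low-frequency texture;
* dark curvilinear vessels rendered as Gaussian-profile random-walk
  strokes, attenuating mainly the green and blue channels (hemoglobin
  absorbs G/B far more than R);
* a smooth uneven illumination field (off-centre spotlight with
  vignetting), multiplied onto the tissue;
* a paired capture: the *normal* image uses the field as is, the
  *abnormal* image uses the same scene under the gamma-darkened field, so
  the two members share reflectance content and differ by a smooth
  multiplicative field — exactly the Retinex assumption.

A luminance-gamma augmentation (Y channel of YCrCb raised to gamma = 0.5)
produces over-exposed counterparts so the abnormal class contains both
low- and high-light images, mirroring how the real training set was
extended.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from . import imaging

__all__ = [
    "PhantomConfig",
    "generate_pair",
    "generate_components",
    "gamma_luminance_augment",
    "make_dataset",
]

# Full-range BT.601 RGB -> YCrCb (rows: Y, Cr, Cb); inverse is the exact
# matrix inverse so the round trip is lossless up to clipping.
_RGB_TO_YCRCB = np.array([
    [0.299, 0.587, 0.114],
    [0.5, -0.418688, -0.081312],
    [-0.168736, -0.331264, 0.5],
])
_YCRCB_TO_RGB = np.linalg.inv(_RGB_TO_YCRCB)


@dataclass(frozen=True)
class PhantomConfig:
    """Generation parameters of one phantom pair.

    ``exposure_gamma`` > 1 darkens the abnormal member (the illumination
    field, already <= 1, is raised to this power).  ``illumination_sigma``
    is the spotlight radius as a fraction of the image's short side.
    """

    height: int = 128
    width: int = 128
    n_vessels: int = 12
    vessel_contrast: float = 0.5
    illumination_sigma: float = 0.35
    exposure_gamma: float = 2.5
    noise_sd: float = 0.01
    seed: int = 0


def _vessel_mask(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """[0, 1] map of Gaussian-profile strokes along seeded random walks."""
    h, w = cfg.height, cfg.width
    canvas = np.zeros((h, w))
    n_steps = int(1.5 * (h + w))
    for _ in range(cfg.n_vessels):
        y = rng.uniform(0, h)
        x = rng.uniform(0, w)
        angle = rng.uniform(0, 2 * np.pi)
        for _ in range(n_steps):
            angle += rng.normal(0.0, 0.15)
            y = (y + np.sin(angle)) % h
            x = (x + np.cos(angle)) % w
            canvas[int(y), int(x)] = 1.0
    blurred = gaussian_filter(canvas, sigma=1.0)
    peak = blurred.max()
    return blurred / peak if peak > 0 else blurred


def generate_components(cfg: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth reflectance (H, W, 3) and illumination field (H, W)."""
    if cfg.height < imaging.MIN_SIZE or cfg.width < imaging.MIN_SIZE:
        raise ValueError(f"phantoms must be at least {imaging.MIN_SIZE} per side, "
                         f"got {cfg.height}x{cfg.width}")
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.height, cfg.width

    # Pinkish mucosa with correlated low-frequency texture.
    base = np.array([0.82, 0.54, 0.52])
    texture = gaussian_filter(rng.standard_normal((h, w)), sigma=min(h, w) / 12.0)
    spread = texture.std() or 1.0
    texture = texture / spread * 0.05
    reflectance = base[None, None, :] * (1.0 + texture[:, :, None] * np.array([0.6, 1.0, 0.8]))

    # Vessels darken G and B strongly, R mildly (hemoglobin absorption).
    mask = _vessel_mask(cfg, rng) * cfg.vessel_contrast
    attenuation = 1.0 - mask[:, :, None] * np.array([0.25, 1.0, 0.85])
    reflectance = np.clip(reflectance * attenuation, 0.0, 1.0)

    # Smooth off-centre spotlight with a dim floor (vignetting).
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    cy = h * (0.5 + rng.uniform(-0.2, 0.2))
    cx = w * (0.5 + rng.uniform(-0.2, 0.2))
    sigma = cfg.illumination_sigma * min(h, w)
    dist2 = (yy - cy) ** 2 + (xx - cx) ** 2
    field = 0.25 + 0.75 * np.exp(-dist2 / (2.0 * sigma ** 2))
    return reflectance, field


def generate_pair(cfg: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """(abnormal, normal) phantom pair, each (H, W, 3) in [0, 1].

    Both members share the reflectance scene; the abnormal member sees
    the illumination field raised to ``exposure_gamma``.  Bit-identical
    under the same config (the determinism contract of the generator).
    """
    rng = np.random.default_rng(cfg.seed + 1)  # noise stream, separate from scene
    reflectance, field = generate_components(cfg)
    normal = reflectance * field[:, :, None]
    abnormal = reflectance * (field ** cfg.exposure_gamma)[:, :, None]
    shape = normal.shape
    abnormal = abnormal + rng.normal(0.0, cfg.noise_sd, shape)
    normal = normal + rng.normal(0.0, cfg.noise_sd, shape)
    return np.clip(abnormal, 0.0, 1.0), np.clip(normal, 0.0, 1.0)


def gamma_luminance_augment(image: np.ndarray, gamma: float) -> np.ndarray:
    """Raise the YCrCb luminance channel to ``gamma``; chroma untouched.

    ``gamma`` < 1 brightens (0.5 emulates the over-exposed class); 1 is
    the identity up to clipping.
    """
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    s = imaging.validate_rgb(image)
    ycrcb = s @ _RGB_TO_YCRCB.T
    ycrcb[:, :, 0] = np.clip(ycrcb[:, :, 0], 0.0, 1.0) ** gamma
    return np.clip(ycrcb @ _YCRCB_TO_RGB.T, 0.0, 1.0)


def make_dataset(n_pairs: int, cfg: PhantomConfig, out_dir: str | Path,
                 augment_fraction: float = 0.25) -> dict:
    """Write ``n_pairs`` phantom pairs as PNGs plus a JSON manifest.

    Pair *k* uses seed ``cfg.seed + k``.  A deterministic
    ``augment_fraction`` of pairs replaces the abnormal member with the
    gamma-0.5 brightened normal member, forming the high-light class.
    Returns the manifest dict (also written to ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stride = int(round(1.0 / augment_fraction)) if augment_fraction > 0 else 0
    records = []
    for k in range(n_pairs):
        pair_cfg = replace(cfg, seed=cfg.seed + k)
        abnormal, normal = generate_pair(pair_cfg)
        augmented = stride > 0 and k % stride == stride - 1
        if augmented:
            abnormal = gamma_luminance_augment(normal, 0.5)
        a_path = out / f"abnormal_{k:04d}.png"
        n_path = out / f"normal_{k:04d}.png"
        imaging.save_image(abnormal, a_path)
        imaging.save_image(normal, n_path)
        records.append({"abnormal": a_path.name, "normal": n_path.name,
                        "seed": pair_cfg.seed, "augmented": augmented})
    manifest = {"config": asdict(cfg), "n_pairs": n_pairs, "pairs": records}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
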