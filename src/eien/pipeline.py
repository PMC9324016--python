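"""Two-stage training, checkpointing and end-to-end enhancement.

Training is sequential: the decomposition network is fitted first on
paired abnormal/normal images; the illumination-correction network (ICN)
is then trained with the decomposition weights frozen, so the combined
objective is minimised stage by stage.  The correction stage supervises
``R_abnormal o I_hat`` against the normal member of the pair, i.e. the
ICN learns the abnormal-to-normal illumination mapping.

Checkpoints are NPZ archives holding every parameter array plus a JSON
metadata record with an architecture fingerprint; loading verifies the
fingerprint before restoring weights.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import illumination as icn_mod
from . import imaging, reflection
from .autodiff import Tensor
from .decomposition import (DecompositionNet, loss_decom_total_t,
                            loss_illumination_smoothness_t,
                            loss_invariable_reflectance_t, loss_reconstruction_t)
from .illumination import (ICNConfig, IlluminationCorrectionNet,
                           loss_icn_recon_t, WEIGHT_ICN_SMOOTHNESS)
from .nn import Adam, bilinear_matrix

__all__ = [
    "TrainConfig",
    "load_pairs",
    "train_decom",
    "train_icn",
    "save_checkpoint",
    "load_checkpoint",
    "enhance",
    "report_model_sizes",
]


@dataclass
class TrainConfig:
    """Optimisation settings shared by both stages.

    Defaults are the method's published protocol: Adam at 1e-4, batches
    of 8, inputs resized to 224x224, 30 epochs per stage.  ``max_steps``
    caps the number of optimisation steps for smoke runs regardless of
    the epoch count.
    """

    learning_rate: float = 1e-4
    batch_size: int = 8
    crop_size: int = 224
    epochs: int = 30
    seed: int = 0
    max_steps: int | None = None
    use_attention: bool = True
    icn: ICNConfig = field(default_factory=ICNConfig)


def _resize(image: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resize of (H, W, C) to (size, size)."""
    h, w = image.shape[:2]
    if (h, w) == (size, size):
        return image
    mh = bilinear_matrix(h, size, dtype=np.float64)
    mw = bilinear_matrix(w, size, dtype=np.float64)
    return np.einsum("oh,hwc,pw->opc", mh, image, mw, optimize=True)


def load_pairs(manifest_dir: str | Path, crop_size: int | None = None
               ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Read (abnormal, normal) image pairs listed by a dataset manifest."""
    root = Path(manifest_dir)
    manifest_path = root / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json under {root}")
    manifest = json.loads(manifest_path.read_text())
    pairs = []
    for rec in manifest["pairs"]:
        ab = imaging.load_image(root / rec["abnormal"])
        nm = imaging.load_image(root / rec["normal"])
        if crop_size:
            ab, nm = _resize(ab, crop_size), _resize(nm, crop_size)
        pairs.append((ab, nm))
    return pairs


def _batches(pairs, batch_size: int, epochs: int, max_steps: int | None,
             rng: np.random.Generator):
    """Yield (abnormal, normal) float32 NCHW batches, reshuffled per epoch."""
    step = 0
    for _ in range(epochs):
        order = rng.permutation(len(pairs))
        for start in range(0, len(pairs), batch_size):
            idx = order[start:start + batch_size]
            ab = np.stack([pairs[i][0].transpose(2, 0, 1) for i in idx]).astype(np.float32)
            nm = np.stack([pairs[i][1].transpose(2, 0, 1) for i in idx]).astype(np.float32)
            yield ab, nm
            step += 1
            if max_steps is not None and step >= max_steps:
                return


def _write_log(log_path, rows) -> None:
    if log_path is not None:
        with open(log_path, "w") as fh:
            for row in rows:
                fh.write(json.dumps(row) + "\n")


def train_decom(pairs, config: TrainConfig, log_path: str | Path | None = None
                ) -> tuple[DecompositionNet, list[dict]]:
    """Fit the decomposition network; returns (net, per-step loss log)."""
    if not pairs:
        raise ValueError("no training pairs")
    net = DecompositionNet(seed=config.seed)
    opt = Adam([p for _, p in net.parameters()], lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    log: list[dict] = []
    t0 = time.perf_counter()
    for step, (ab, nm) in enumerate(
            _batches(pairs, config.batch_size, config.epochs, config.max_steps, rng)):
        s_ab, s_nm = Tensor(ab), Tensor(nm)
        r_ab, i_ab = net(s_ab)
        r_nm, i_nm = net(s_nm)
        recon = loss_reconstruction_t(r_ab, i_ab, r_nm, i_nm, s_ab, s_nm)
        smooth = (loss_illumination_smoothness_t(i_ab, r_ab)
                  + loss_illumination_smoothness_t(i_nm, r_nm))
        invariable = loss_invariable_reflectance_t(r_ab, r_nm)
        total = loss_decom_total_t(recon, smooth, invariable)
        opt.zero_grad()
        total.backward()
        opt.step()
        log.append({"step": step, "loss": total.item(), "recon": recon.item(),
                    "smooth": smooth.item(), "invariable": invariable.item(),
                    "seconds": round(time.perf_counter() - t0, 3)})
    _write_log(log_path, log)
    return net, log


def train_icn(pairs, config: TrainConfig, decom_net: DecompositionNet,
              log_path: str | Path | None = None
              ) -> tuple[IlluminationCorrectionNet, list[dict]]:
    """Fit the ICN with the decomposition network frozen.

    The decomposition outputs enter as constants, so no gradient reaches
    (or modifies) the decomposition weights.
    """
    if not pairs:
        raise ValueError("no training pairs")
    net = IlluminationCorrectionNet(config.icn, seed=config.seed + 1)
    opt = Adam([p for _, p in net.parameters()], lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    log: list[dict] = []
    t0 = time.perf_counter()
    for step, (ab, nm) in enumerate(
            _batches(pairs, config.batch_size, config.epochs, config.max_steps, rng)):
        r_ab_t, i_ab_t = decom_net(Tensor(ab))
        # Detach: the decomposition stage stays exactly as trained.
        r_ab = Tensor(r_ab_t.data)
        i_ab = Tensor(i_ab_t.data)
        i_hat = net(i_ab, Tensor(ab), use_attention=config.use_attention)
        recon = loss_icn_recon_t(i_hat, r_ab, Tensor(nm))
        smooth = loss_illumination_smoothness_t(i_hat, r_ab)
        total = recon + WEIGHT_ICN_SMOOTHNESS * smooth
        opt.zero_grad()
        total.backward()
        opt.step()
        log.append({"step": step, "loss": total.item(), "recon": recon.item(),
                    "smooth": smooth.item(),
                    "seconds": round(time.perf_counter() - t0, 3)})
    _write_log(log_path, log)
    return net, log


# -- checkpoints ----------------------------------------------------------


def _fingerprint(state: dict[str, np.ndarray]) -> str:
    return ";".join(f"{k}:{'x'.join(map(str, v.shape))}" for k, v in sorted(state.items()))


def save_checkpoint(path: str | Path, net, kind: str, meta: dict | None = None) -> None:
    """Write all parameters plus architecture metadata to an NPZ archive."""
    state = net.state_dict()
    record = {"kind": kind, "fingerprint": _fingerprint(state)}
    if kind == "icn":
        record["icn_config"] = asdict(net.config)
    if meta:
        record.update(meta)
    np.savez_compressed(path, __meta__=np.frombuffer(
        json.dumps(record).encode(), dtype=np.uint8), **state)


def load_checkpoint(path: str | Path):
    """Restore a network from :func:`save_checkpoint`; returns (net, meta)."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    if meta["kind"] == "decom":
        net = DecompositionNet()
    elif meta["kind"] == "icn":
        net = IlluminationCorrectionNet(ICNConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in meta["icn_config"].items()}))
    else:
        raise ValueError(f"unknown checkpoint kind {meta['kind']!r}")
    if _fingerprint(net.state_dict()) != meta["fingerprint"]:
        raise ValueError("checkpoint fingerprint does not match the architecture")
    net.load_state_dict(state)
    return net, meta


# -- inference ------------------------------------------------------------


def enhance(image: np.ndarray, decom_net: DecompositionNet,
            icn_net: IlluminationCorrectionNet, tau: float = reflection.DEFAULT_TAU,
            use_rce: bool = True, use_attention: bool = True,
            stretch_all: bool = False, return_components: bool = False):
    """Full enhancement: decompose, correct illumination, enhance
    reflectance, recompose.  Accepts any size >= 8x8.

    ``use_rce=False`` bypasses the reflection enhancement entirely, so
    the output is exactly ``recompose(R, I_hat)``; ``stretch_all``
    switches the RCE to the all-channel ablation variant.
    """
    from .decomposition import decompose

    s = imaging.validate_rgb(image)
    r, i = decompose(s, decom_net)
    i_hat = icn_mod.correct_illumination(i, s, icn_net, use_attention=use_attention)
    if use_rce:
        r_out = (reflection.stretch_all_channels(r, tau) if stretch_all
                 else reflection.enhance_reflection(r, tau))
    else:
        r_out = r
    out = imaging.recompose(r_out, i_hat)
    if return_components:
        return out, {"reflectance": r, "illumination": i,
                     "illumination_corrected": i_hat, "reflectance_enhanced": r_out}
    return out


def report_model_sizes(decom_net: DecompositionNet | None = None,
                       icn_net: IlluminationCorrectionNet | None = None) -> dict[str, dict]:
    """Parameter counts and float32 megabytes per module and in total."""
    from .decomposition import model_storage_megabytes

    decom_net = decom_net or DecompositionNet(seed=0)
    icn_net = icn_net or IlluminationCorrectionNet(seed=0)
    rows = {
        "decomposition": {"parameters": decom_net.parameter_count(),
                          "megabytes": round(model_storage_megabytes(decom_net), 3)},
        "illumination_correction": {"parameters": icn_net.parameter_count(),
                                    "megabytes": round(model_storage_megabytes(icn_net), 3)},
    }
    rows["total"] = {"parameters": sum(r["parameters"] for r in rows.values()),
                     "megabytes": round(sum(r["megabytes"] for r in rows.values()), 3)}
    return rows
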