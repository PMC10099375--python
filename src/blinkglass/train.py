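"""Training and evaluation harness for the LGN keypoint regressor.

Frames are resized and normalized, their keypoints encoded as Gaussian
probability maps, and the network is fit with plain stochastic gradient
descent (momentum 0.9): the learning rate starts at 0.001 and is reduced by
a factor of 0.1 every 10 epochs.  Everything — weight initialization, data
order — flows from a single seed, so runs are bit-reproducible.

Evaluation decodes the predicted maps back to image coordinates and reports
the mean Euclidean keypoint error plus PCK (the fraction of keypoints within
a threshold expressed as a fraction of the ground-truth eye width).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .lgn import LGN, KeypointSet, SGD, decode_keypoints, encode_heatmaps, mse_heatmap_loss
from .synthgen import load_manifest

__all__ = [
    "TrainConfig",
    "preprocess",
    "lr_at_epoch",
    "load_split",
    "train_lgn",
    "evaluate_keypoints",
]


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one training run.

    The learning-rate schedule (initial 0.001, ×0.1 every 10 epochs) and the
    SGD optimizer follow the published recipe; momentum and the epoch count
    are unstated there and default to 0.9 and 30.
    """

    initial_lr: float = 0.001
    lr_decay_factor: float = 0.1
    decay_every_epochs: int = 10
    epochs: int = 30
    batch_size: int = 16
    seed: int = 0
    sigma: float = 3.0
    momentum: float = 0.9
    max_grad_norm: float = 50.0
    input_size: int = 128
    depth: int = 4
    width: int = 12

    def __post_init__(self) -> None:
        if self.initial_lr <= 0 or self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("initial_lr, epochs and batch_size must be positive")
        if not 0.0 < self.lr_decay_factor < 1.0:
            raise ValueError("lr_decay_factor must be in (0, 1)")
        if self.decay_every_epochs <= 0:
            raise ValueError("decay_every_epochs must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def lr_at_epoch(epoch: int, config: TrainConfig) -> float:
    """Closed-form stepped schedule: lr = lr0 * decay^floor(epoch / every)."""
    return config.initial_lr * config.lr_decay_factor ** (epoch // config.decay_every_epochs)


def preprocess(
    image: np.ndarray,
    target_size: int = 128,
    mean: float = 0.5,
    sd: float = 0.25,
) -> np.ndarray:
    """Resize a grayscale frame and map it to a standardized float tensor.

    Intensities are scaled to [0, 1] and standardized with the dataset mean
    and standard deviation; the output is a (1, target, target) float32
    tensor.  Raises on an empty image.
    """
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("empty image")
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if img.shape != (target_size, target_size):
        img = np.asarray(
            Image.fromarray(img.astype(np.uint8)).resize(
                (target_size, target_size), Image.BILINEAR
            )
        )
    x = img.astype(np.float32)
    if x.max() > 1.0:
        x = x / 255.0
    return ((x - mean) / sd)[None]


def _load_entry(root: Path, entry: dict, image_size: int) -> tuple[np.ndarray, np.ndarray]:
    img = np.asarray(Image.open(root / entry["frame"]).convert("L"))
    ann = json.loads((root / entry["annotation"]).read_text())
    kps = np.asarray(ann["keypoints"], dtype=np.float64)
    return img, kps


def load_split(
    manifest: dict | str | Path, split: str, root: str | Path | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Load one manifest split as (frames (n, H, W) uint8, keypoints (n, 6, 2))."""
    if not isinstance(manifest, dict):
        root = Path(manifest).parent if Path(manifest).is_file() else Path(manifest)
        manifest = load_manifest(manifest)
    elif root is None:
        raise ValueError("root directory required when passing a manifest dict")
    root = Path(root)
    entries = [e for e in manifest["entries"] if e["split"] == split]
    if not entries:
        raise ValueError(f"manifest has no '{split}' entries")
    size = manifest["image_size"][0]
    frames = np.empty((len(entries), size, size), dtype=np.uint8)
    kps = np.empty((len(entries), 6, 2), dtype=np.float64)
    for i, entry in enumerate(entries):
        frames[i], kps[i] = _load_entry(root, entry, size)
    return frames, kps


def _norm_stats(frames: np.ndarray) -> tuple[float, float]:
    x = frames.astype(np.float64) / 255.0
    return float(x.mean()), float(x.std())


def train_lgn(
    manifest: dict | str | Path,
    config: TrainConfig = TrainConfig(),
    root: str | Path | None = None,
    verbose: bool = False,
) -> tuple[LGN, list[dict]]:
    """Fit an LGN on the manifest's train split.

    Returns the trained model and a per-epoch history of
    ``{"epoch", "lr", "train_loss"}`` records.  The model stores the
    normalization statistics of the training set so inference matches.
    """
    frames, kps = load_split(manifest, "train", root)
    n = len(frames)
    mean, sd = _norm_stats(frames)

    size = config.input_size
    hm_size = (size // 2, size // 2)
    x = np.stack([preprocess(f, size, mean, sd) for f in frames]).astype(np.float32)
    y = np.stack(
        [
            encode_heatmaps(
                KeypointSet(k), sigma=config.sigma, map_size=hm_size, image_size=(size, size)
            ).maps
            for k in kps
        ]
    ).astype(np.float32)

    model = LGN(
        input_size=size,
        depth=config.depth,
        width=config.width,
        sigma=config.sigma,
        seed=config.seed,
    )
    model.norm_mean, model.norm_sd = mean, sd
    opt = SGD(
        model.params(),
        lr=config.initial_lr,
        momentum=config.momentum,
        max_grad_norm=config.max_grad_norm,
    )
    order_rng = np.random.default_rng(config.seed + 1)

    history: list[dict] = []
    for epoch in range(config.epochs):
        opt.lr = lr_at_epoch(epoch, config)
        perm = order_rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            pred = model.forward(x[idx], train=True)
            losses.append(mse_heatmap_loss(pred, y[idx]))
            opt.zero_grad()
            # per-image loss gradients are summed over the batch ("sum"
            # reduction); the clip in SGD bounds the resulting step
            model.backward((2.0 / pred.shape[1]) * (pred - y[idx]).astype(np.float32))
            opt.step()
        rec = {"epoch": epoch, "lr": opt.lr, "train_loss": float(np.mean(losses))}
        history.append(rec)
        if verbose:
            print(f"epoch {epoch:3d}  lr {opt.lr:.2e}  loss {rec['train_loss']:.4f}")
    return model, history


def predict_keypoints(
    model: LGN, frames: np.ndarray, batch_size: int = 32
) -> np.ndarray:
    """Decode predicted keypoints, (n, 6, 2) in image coordinates."""
    mean = getattr(model, "norm_mean", 0.5)
    sd = getattr(model, "norm_sd", 0.25)
    size = model.input_size
    out = np.empty((len(frames), 6, 2), dtype=np.float64)
    for start in range(0, len(frames), batch_size):
        batch = frames[start : start + batch_size]
        x = np.stack([preprocess(f, size, mean, sd) for f in batch]).astype(np.float32)
        maps = model.forward(x, train=False)
        for j in range(len(batch)):
            out[start + j] = decode_keypoints(maps[j], image_size=(size, size)).points
    return out


def keypoint_metrics(
    pred: np.ndarray, gt: np.ndarray, pck_threshold: float = 0.1
) -> dict:
    """Mean Euclidean error (px) and PCK for predicted vs true keypoints.

    PCK counts a keypoint as correct when its error is within
    ``pck_threshold`` times the ground-truth eye width (corner distance) of
    its frame.
    """
    pred = np.asarray(pred, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    err = np.linalg.norm(pred - gt, axis=-1)  # (n, 6)
    widths = np.linalg.norm(gt[:, 0] - gt[:, 1], axis=-1)  # (n,)
    pck = float((err <= pck_threshold * widths[:, None]).mean())
    return {
        "mean_error_px": float(err.mean()),
        "pck": pck,
        "per_keypoint_error_px": err.mean(axis=0).tolist(),
        "n_frames": int(len(pred)),
    }


def evaluate_keypoints(
    model: LGN,
    frames: np.ndarray,
    keypoints: np.ndarray,
    pck_threshold: float = 0.1,
) -> dict:
    """Decode the model's predictions on an evaluation set and score them."""
    if len(frames) == 0:
        raise ValueError("empty evaluation split")
    pred = predict_keypoints(model, frames)
    return keypoint_metrics(pred, keypoints, pck_threshold)
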