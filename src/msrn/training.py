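"""Multi-label loss, data handling, augmentation, and the SGD training loop.

The loss is the class-averaged binary cross-entropy over sigmoid outputs

    L(p, y) = -(1/C) * sum_i [ y_i log p_i + (1 - y_i) log(1 - p_i) ],

averaged over the batch; probabilities are clamped to [eps, 1-eps]
(eps = 1e-7) before the logarithms.  Training follows the reference
protocol: SGD with momentum 0.9 and weight decay 1e-4, learning rate
3e-3, batch size 64, an 80/20 train/test split, random rotation and
horizontal/vertical flips, and multi-seed repetition reported as
mean +/- std.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from . import nn
from .labels import CLASS_NAMES, NUM_CLASSES, MultiHotLabel, labels_to_array
from .metrics import confusion_counts, micro_average

EPS = 1e-7

MANIFEST_COLUMNS = ["path", "amd", "erm", "me", "normal", "patient_id"]


@dataclass
class TrainConfig:
    batch_size: int = 64
    learning_rate: float = 0.003
    epochs: int = 200
    momentum: float = 0.9
    weight_decay: float = 0.0001
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    split_fraction: float = 0.8
    rotation_degrees: float = 10.0
    flip_probability: float = 0.5
    probability_threshold: float = 0.5
    augment: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must lie in (0, 1)")
        if not 0 < self.probability_threshold < 1:
            raise ValueError("probability_threshold must lie in (0, 1)")


@dataclass
class DatasetManifest:
    """Image paths with multi-hot labels, patient ids and split tags."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"manifest missing columns {missing}")
        if self.frame["path"].duplicated().any():
            raise ValueError("manifest paths must be unique")
        if "split" in self.frame.columns:
            bad = set(self.frame["split"].dropna()) - {"train", "test"}
            if bad:
                raise ValueError(f"invalid split tags {bad}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def labels(self) -> np.ndarray:
        return self.frame[list(CLASS_NAMES)].to_numpy(dtype=np.int64)

    def subset(self, split: str) -> "DatasetManifest":
        return DatasetManifest(self.frame[self.frame["split"] == split].reset_index(drop=True))

    @classmethod
    def read_csv(cls, path) -> "DatasetManifest":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def multi_label_loss(probabilities: np.ndarray, labels: np.ndarray,
                     eps: float = EPS) -> float:
    """Class-averaged binary cross-entropy on sigmoid probabilities."""
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: predictions {p.shape} vs labels {y.shape}")
    p = np.clip(p, eps, 1.0 - eps)
    per_element = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    return float(per_element.mean(axis=-1).mean())


def split_dataset(manifest: DatasetManifest, config: TrainConfig,
                  seed: int) -> DatasetManifest:
    """Deterministic stratified 80/20 split tagged into a new manifest.

    Stratification is by exact label combination; the test side gets
    floor(n * (1 - split_fraction)) records overall, apportioned to the
    combinations by largest remainder so each stays within one record of
    the configured fraction.
    """
    if len(manifest) == 0:
        raise ValueError("cannot split an empty manifest")
    rng = np.random.default_rng(seed)
    df = manifest.frame.copy()
    combos = df[list(CLASS_NAMES)].astype(str).agg("".join, axis=1)
    test_frac = 1.0 - config.split_fraction
    # guard against float artifacts like 100 * 0.2 -> 19.999...
    n_test_total = int(np.floor(len(df) * test_frac + 1e-9))
    groups = sorted(combos.unique())
    quotas = {}
    remainders = []
    for g in groups:
        ideal = (combos == g).sum() * test_frac
        quotas[g] = int(np.floor(ideal + 1e-9))
        remainders.append((ideal - quotas[g], g))
    short = n_test_total - sum(quotas.values())
    for _, g in sorted(remainders, reverse=True)[:short]:
        quotas[g] += 1
    split = pd.Series("train", index=df.index)
    for g in groups:
        idx = df.index[combos == g].to_numpy()
        rng.shuffle(idx)
        split.loc[idx[:quotas[g]]] = "test"
    df["split"] = split
    return DatasetManifest(df)


def augment(image: np.ndarray, config: TrainConfig,
            rng: np.random.Generator) -> np.ndarray:
    """Random rotation (+/- rotation_degrees) and independent H/V flips.

    Operates on a (H, W) or (C, H, W) float image already resized to its
    branch size; bilinear interpolation, intensity range preserved.
    """
    out = image
    lo, hi = float(image.min()), float(image.max())
    if config.rotation_degrees > 0:
        angle = rng.uniform(-config.rotation_degrees, config.rotation_degrees)
        axes = (-2, -1)
        out = ndimage.rotate(out, angle, axes=axes, reshape=False, order=1,
                             mode="nearest")
        out = np.clip(out, lo, hi)
    if config.flip_probability > 0:
        if rng.random() < config.flip_probability:
            out = out[..., :, ::-1]
        if rng.random() < config.flip_probability:
            out = out[..., ::-1, :]
    return np.ascontiguousarray(out, dtype=image.dtype)


def resize_bilinear(image: np.ndarray, side: int) -> np.ndarray:
    """Bilinear resize of a 2-D float image in [0, 1] to (side, side)."""
    im = Image.fromarray(np.asarray(image, dtype=np.float32), mode="F")
    return np.asarray(im.resize((side, side), Image.BILINEAR), dtype=np.float32)


def load_image(path, side: int) -> np.ndarray:
    """Read a grayscale image file -> (3, side, side) float32 in [0, 1]."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=np.float32) / 255.0
    arr = resize_bilinear(arr, side)
    return np.broadcast_to(arr, (3, side, side)).copy()


def load_images(manifest: DatasetManifest, side: int, root=None) -> np.ndarray:
    root = Path(root) if root is not None else None
    out = np.empty((len(manifest), 3, side, side), dtype=np.float32)
    for i, p in enumerate(manifest.frame["path"]):
        path = root / p if root is not None else p
        out[i] = load_image(path, side)
    return out


@dataclass
class EpochLog:
    epoch: int
    train_loss: float
    test_micro_accuracy: float | None = None


@dataclass
class FitResult:
    model: object
    log: list[EpochLog]
    best_epoch: int | None
    best_micro_accuracy: float | None


def _forward_model(model, xb, train):
    if isinstance(xb, list):
        return model.forward(xb, train=train)
    return model.forward(xb, train=train)


def _slice_batch(X, idx):
    if isinstance(X, list):
        return [x[idx] for x in X]
    return X[idx]


def evaluate_probabilities(model, X, batch_size: int = 64) -> np.ndarray:
    n = X[0].shape[0] if isinstance(X, list) else X.shape[0]
    probs = np.empty((n, NUM_CLASSES), dtype=np.float64)
    for start in range(0, n, batch_size):
        idx = slice(start, min(start + batch_size, n))
        logits = _forward_model(model, _slice_batch(X, idx), train=False)
        probs[idx] = nn.sigmoid(logits)
    return probs


def fit_arrays(model, X_train, y_train, config: TrainConfig, seed: int,
               X_test=None, y_test=None, eval_every: int = 1) -> FitResult:
    """SGD training on in-memory arrays (single- or multi-branch input).

    ``X_train`` is an (N, 3, s, s) array, or a list of such arrays (one per
    branch) for a multi-scale model.  Tracks the checkpoint with the best
    test micro-average accuracy when a test set is supplied.
    """
    n = X_train[0].shape[0] if isinstance(X_train, list) else X_train.shape[0]
    y_train = np.asarray(y_train, dtype=np.float64)
    rng = np.random.default_rng(seed)
    opt = nn.SGD(model.params(), lr=config.learning_rate,
                 momentum=config.momentum, weight_decay=config.weight_decay)
    log: list[EpochLog] = []
    best_acc, best_epoch, best_state = None, None, None
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb = _slice_batch(X_train, idx)
            if config.augment and (config.rotation_degrees > 0 or config.flip_probability > 0):
                xb = _augment_batch(xb, config, rng)
            yb = y_train[idx]
            logits = _forward_model(model, xb, train=True)
            p = nn.sigmoid(logits)
            loss = multi_label_loss(p, yb)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged: non-finite loss {loss} at epoch {epoch}")
            losses.append(loss)
            dlogits = ((p - yb) / (p.shape[0] * p.shape[1])).astype(nn.DTYPE)
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
        test_acc = None
        if X_test is not None and (epoch % eval_every == 0 or epoch == config.epochs - 1):
            probs = evaluate_probabilities(model, X_test, config.batch_size)
            pred = (probs >= config.probability_threshold).astype(np.int64)
            test_acc = micro_average(confusion_counts(pred, y_test))[0]
            if best_acc is None or test_acc > best_acc:
                best_acc, best_epoch = test_acc, epoch
                best_state = nn.state_dict(model.params())
        log.append(EpochLog(epoch, float(np.mean(losses)), test_acc))
    if best_state is not None:
        nn.load_state_dict(model.params(), best_state)
    return FitResult(model=model, log=log, best_epoch=best_epoch,
                     best_micro_accuracy=best_acc)


def _augment_batch(xb, config, rng):
    if isinstance(xb, list):
        # same geometric transform across branches would need shared draws;
        # branches hold resizes of the same frame, so reuse one sub-rng per image
        seeds = rng.integers(0, 2 ** 31, size=xb[0].shape[0])
        out = []
        for x in xb:
            xa = np.empty_like(x)
            for i in range(x.shape[0]):
                xa[i] = augment(x[i], config, np.random.default_rng(seeds[i]))
            out.append(xa)
        return out
    xa = np.empty_like(xb)
    for i in range(xb.shape[0]):
        xa[i] = augment(xb[i], config, rng)
    return xa


def fit(model, manifest: DatasetManifest, config: TrainConfig, seed: int,
        branch_sizes: tuple[int, ...] = (224,), root=None,
        eval_every: int = 1) -> FitResult:
    """Train on a split-tagged manifest, loading images from disk."""
    if "split" not in manifest.frame.columns:
        manifest = split_dataset(manifest, config, seed)
    train_m, test_m = manifest.subset("train"), manifest.subset("test")

    def _load(m):
        arrays = [load_images(m, s, root=root) for s in branch_sizes]
        return arrays if len(arrays) > 1 else arrays[0]

    return fit_arrays(model, _load(train_m), train_m.labels, config, seed,
                      X_test=_load(test_m) if len(test_m) else None,
                      y_test=test_m.labels if len(test_m) else None,
                      eval_every=eval_every)


def aggregate_seed_metrics(per_seed: list[dict]) -> dict:
    """mean +/- std per metric across seed runs, plus the raw values."""
    keys = per_seed[0].keys()
    out = {}
    for k in keys:
        vals = np.array([r[k] for r in per_seed], dtype=np.float64)
        out[k] = {
            "values": vals.tolist(),
            "mean": float(vals.mean()),
            "std": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        }
    return out


def format_mean_std(mean: float, std: float, percent: bool = True) -> str:
    """Render as e.g. '97.40 ± 0.04' (metrics reported on the percent scale)."""
    scale = 100.0 if percent else 1.0
    return f"{mean * scale:.2f} ± {std * scale:.2f}"


def run_seeds(train_fn, seeds) -> dict:
    """Run ``train_fn(seed) -> dict of metrics`` per seed and aggregate.

    Needs at least two seeds for a meaningful mean +/- std.
    """
    seeds = list(seeds)
    if len(seeds) < 2:
        raise ValueError("need at least two seeds for mean +/- std aggregation")
    per_seed = [train_fn(s) for s in seeds]
    return {"seeds": seeds, "per_seed": per_seed,
            "aggregate": aggregate_seed_metrics(per_seed)}


def save_checkpoint(path, model, config_dict: dict) -> None:
    state = nn.state_dict(model.params())
    np.savez(path, __config__=json.dumps(config_dict), **state)


def load_checkpoint(path) -> tuple[dict, dict]:
    data = np.load(path, allow_pickle=False)
    cfg = json.loads(str(data["__config__"]))
    state = {k: data[k] for k in data.files if k != "__config__"}
    return cfg, state
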