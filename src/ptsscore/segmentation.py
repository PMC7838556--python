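"""Tissue segmentation: patch preparation, U-Net training, and evaluation.

The segmenter maps an RGB tile to a per-pixel probability map over the
seven tissue classes and an argmax label map.  Training uses Adam on
softmax cross-entropy with an 80/10/10 train/validation/test split and a
Dice-based stopping rule: training stops once the validation mean Dice
similarity coefficient (DSC) has not improved by at least a minimum
relative gain (default 0.1%) for a patience window (default 10 epochs)
after its best epoch; the returned weights are those of the best epoch,
not the last.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .tissue import BACKGROUND, FOREGROUND_CLASSES, N_CLASSES, TissueClass
from .unet import AdamOptimizer, UNet, softmax_cross_entropy

__all__ = [
    "UnetConfig",
    "DscReport",
    "reflect_pad",
    "split_dataset",
    "dice_coefficient",
    "early_stop_epoch",
    "train_segmenter",
    "predict_labelmap",
    "segment_image",
    "evaluate_dsc",
    "summarize_dice",
    "tissue_threshold",
]


@dataclass(frozen=True)
class UnetConfig:
    """Hyper-parameters of the segmenter and its training loop."""

    input_size: int = 512
    depth: int = 4
    base_filters: int = 16
    learning_rate: float = 1e-3
    batch_size: int = 8
    max_epochs: int = 100
    patience: int = 10
    min_rel_gain: float = 0.001  # relative validation-DSC improvement
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_size % (2 ** self.depth):
            raise ValueError(
                f"input_size {self.input_size} must be divisible by 2^depth = {2 ** self.depth}"
            )
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.min_rel_gain < 0:
            raise ValueError("min_rel_gain must be >= 0")


# ---------------------------------------------------------------------------
# patch preparation
# ---------------------------------------------------------------------------


def _reflect_axis(arr: np.ndarray, axis: int, before: int, after: int) -> np.ndarray:
    """Reflect-pad one axis, iterating when the pad exceeds size - 1."""
    while before > 0 or after > 0:
        n = arr.shape[axis]
        if n == 1:  # a single row/column can only be repeated
            b, a = before, after
            pads = [(0, 0)] * arr.ndim
            pads[axis] = (b, a)
            return np.pad(arr, pads, mode="edge")
        b = min(before, n - 1)
        a = min(after, n - 1)
        pads = [(0, 0)] * arr.ndim
        pads[axis] = (b, a)
        arr = np.pad(arr, pads, mode="reflect")
        before -= b
        after -= a
    return arr


def reflect_pad(tile: np.ndarray, target: int) -> np.ndarray:
    """Mirror-pad a tile (or label map) to ``target`` x ``target`` pixels.

    Padding is split as evenly as possible with the extra pixel on the
    bottom/right; mirrored values do not repeat the edge pixel.  Raises if
    the tile already exceeds the target (larger images must be tiled).
    """
    tile = np.asarray(tile)
    h, w = tile.shape[:2]
    if h > target or w > target:
        raise ValueError(f"tile {h}x{w} larger than target {target}; tile the image first")
    py, px = target - h, target - w
    out = _reflect_axis(tile, 0, py // 2, py - py // 2)
    out = _reflect_axis(out, 1, px // 2, px - px // 2)
    return out


def _majority_class(labels: np.ndarray) -> int:
    vals, counts = np.unique(labels, return_counts=True)
    fg = vals != BACKGROUND
    if fg.any():
        vals, counts = vals[fg], counts[fg]
    return int(vals[np.argmax(counts)])


def split_dataset(
    pairs: list,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[list, list, list]:
    """Stratified train/validation/test split.

    Stratification is by the majority tissue class of each tile's label
    map.  Splits are disjoint and exhaustive; global split sizes follow the
    fractions by largest remainder; reproducible under the seed.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    n = len(pairs)
    if n < 10:
        raise ValueError("need at least 10 pairs to split")
    rng = np.random.default_rng(seed)

    # exact global targets by largest remainder
    ideal = np.array(fractions) * n
    targets = np.floor(ideal).astype(int)
    for k in np.argsort(-(ideal - targets))[: n - targets.sum()]:
        targets[k] += 1

    strata: dict[int, list[int]] = {}
    for i, (_, labels) in enumerate(pairs):
        strata.setdefault(_majority_class(np.asarray(labels)), []).append(i)

    assigned: list[list[int]] = [[], [], []]
    deficits = targets.copy()
    leftovers: list[tuple[float, int, int]] = []  # (remainder, stratum order, split)
    for key in sorted(strata):
        idx = np.array(strata[key])
        rng.shuffle(idx)
        ideal_s = np.array(fractions) * len(idx)
        base = np.floor(ideal_s).astype(int)
        # never assign more than the remaining global deficit
        base = np.minimum(base, deficits)
        pos = 0
        for s in range(3):
            assigned[s].extend(idx[pos : pos + base[s]].tolist())
            pos += base[s]
        deficits -= base
        rema = ideal_s - base
        for j in idx[pos:]:
            leftovers.append((int(j), rema.copy()))
    # place leftover items where the stratum remainder is largest among
    # splits that still have a global deficit
    for j, rema in leftovers:
        order = np.argsort(-rema)
        s = next((int(s) for s in order if deficits[s] > 0), int(np.argmax(deficits)))
        assigned[s].append(j)
        deficits[s] -= 1
    train, val, test = (sorted(a) for a in assigned)
    return [pairs[i] for i in train], [pairs[i] for i in val], [pairs[i] for i in test]


# ---------------------------------------------------------------------------
# Dice
# ---------------------------------------------------------------------------


def dice_coefficient(pred: np.ndarray, truth: np.ndarray, cls: int) -> float:
    """Dice similarity 2|P∩T| / (|P| + |T|) for one class.

    When the class is absent from both masks the overlap is vacuously
    perfect and 1.0 is returned (callers exclude such pairs from per-class
    averaging).
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    p = pred == int(cls)
    t = truth == int(cls)
    denom = int(p.sum()) + int(t.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & t).sum()) / denom


def summarize_dice(values_by_class: dict[int, list[float]]) -> "DscReport":
    """Aggregate per-(patch, class) Dice values into a report.

    Per class: mean, sample SD, and normal-approximation 95% CI
    (mean ± 1.96·SD/√n) over the patches where the class occurs; the
    overall row pools all (patch, class) values.
    """
    rows: dict[str, dict] = {}
    pooled: list[float] = []
    for cls in FOREGROUND_CLASSES:
        vals = values_by_class.get(int(cls), [])
        pooled.extend(vals)
        rows[cls.name.lower()] = _dsc_row(vals)
    rows["overall"] = _dsc_row(pooled)
    return DscReport(rows)


def _dsc_row(vals: list[float]) -> dict:
    n = len(vals)
    if n == 0:
        return {"mean": float("nan"), "sd": float("nan"),
                "ci_lower": float("nan"), "ci_upper": float("nan"), "n": 0}
    arr = np.asarray(vals, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if n > 1 else 0.0
    half = 1.96 * sd / np.sqrt(n)
    return {"mean": mean, "sd": sd,
            "ci_lower": max(mean - half, 0.0), "ci_upper": min(mean + half, 1.0), "n": n}


@dataclass(frozen=True)
class DscReport:
    """Per-class and overall Dice statistics over an evaluation set."""

    rows: dict[str, dict] = field(default_factory=dict)

    @property
    def overall_mean(self) -> float:
        return self.rows["overall"]["mean"]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rows).T

    def to_dict(self) -> dict:
        return {k: dict(v) for k, v in self.rows.items()}


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def early_stop_epoch(
    dsc_values: list[float], patience: int = 10, min_rel_gain: float = 0.001
) -> tuple[int, int]:
    """Apply the stopping rule to a validation-DSC sequence.

    Returns ``(stop_epoch, best_epoch)`` (1-based).  The anchor epoch
    advances whenever the DSC improves on it by at least ``min_rel_gain``
    relatively; training stops at the first epoch ``patience`` epochs past
    the anchor, or at the end of the sequence.  ``best_epoch`` is the raw
    maximum (the epoch whose weights are kept).
    """
    anchor_val, anchor_epoch = -np.inf, 0
    best_val, best_epoch = -np.inf, 0
    stop = len(dsc_values)
    for e, v in enumerate(dsc_values, start=1):
        if v > best_val:
            best_val, best_epoch = v, e
        improved = v > anchor_val and (
            anchor_val <= 0 or (v - anchor_val) >= min_rel_gain * anchor_val
        )
        if improved:
            anchor_val, anchor_epoch = v, e
        elif e - anchor_epoch >= patience:
            stop = e
            break
    return stop, best_epoch


def _prepare_batch(
    pairs: list, input_size: int
) -> tuple[np.ndarray, np.ndarray]:
    """Stack (tile, labels) pairs into NCHW inputs and index targets.

    Tiles are reflect-padded to the network input size; labels become
    0-based class indices with background mapped to the ignore index -1.
    """
    xs, ys = [], []
    for tile, labels in pairs:
        t = reflect_pad(np.asarray(tile), input_size).astype(np.float32) / 255.0
        l = reflect_pad(np.asarray(labels), input_size).astype(np.int64)
        xs.append(t.transpose(2, 0, 1))
        ys.append(np.where(l == BACKGROUND, -1, l - 1))
    return np.stack(xs), np.stack(ys)


def _validation_mean_dsc(model: UNet, val_pairs: list, input_size: int) -> float:
    """Mean over patches of the mean Dice over classes present per patch."""
    per_patch = []
    for tile, labels in val_pairs:
        _, pred = predict_labelmap(model, np.asarray(tile), input_size=input_size)
        truth = np.asarray(labels)
        dices = []
        for cls in FOREGROUND_CLASSES:
            if (truth == int(cls)).any() or (pred == int(cls)).any():
                dices.append(dice_coefficient(pred, truth, int(cls)))
        per_patch.append(float(np.mean(dices)) if dices else 1.0)
    return float(np.mean(per_patch))


def train_segmenter(
    train_pairs: list,
    val_pairs: list,
    config: UnetConfig,
) -> tuple[UNet, dict]:
    """Train a U-Net on labeled tiles with Dice-based early stopping.

    Returns the model restored to its best-validation-DSC epoch and a
    history dict with per-epoch ``loss`` and ``val_dsc`` plus the
    ``best_epoch`` and ``stopped_epoch`` indices (1-based).
    """
    if not train_pairs or not val_pairs:
        raise ValueError("train and validation sets must be nonempty")
    model = UNet(
        in_channels=3, n_classes=N_CLASSES, depth=config.depth,
        base_filters=config.base_filters, seed=config.seed,
    )
    opt = AdamOptimizer(lr=config.learning_rate)
    layers = model.layers()
    rng = np.random.default_rng(config.seed)
    x, y = _prepare_batch(train_pairs, config.input_size)

    history: dict = {"loss": [], "val_dsc": []}
    anchor_val, anchor_epoch = -np.inf, 0
    best_val, best_epoch, best_state = -np.inf, 0, None
    stopped_epoch = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(train_pairs))
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            sel = order[start : start + config.batch_size]
            logits = model.forward(x[sel], train=True)
            loss, grad = softmax_cross_entropy(logits, y[sel])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {start // config.batch_size}: "
                    f"loss={loss}; lower the learning rate"
                )
            model.backward(grad)
            opt.step(layers)
            epoch_losses.append(loss)
        val_dsc = _validation_mean_dsc(model, val_pairs, config.input_size)
        history["loss"].append(float(np.mean(epoch_losses)))
        history["val_dsc"].append(val_dsc)

        if val_dsc > best_val:
            best_val, best_epoch = val_dsc, epoch
            best_state = model.get_state()
        improved = val_dsc > anchor_val and (
            anchor_val <= 0 or (val_dsc - anchor_val) >= config.min_rel_gain * anchor_val
        )
        if improved:
            anchor_val, anchor_epoch = val_dsc, epoch
        elif epoch - anchor_epoch >= config.patience:
            stopped_epoch = epoch
            break
    if stopped_epoch == 0:
        stopped_epoch = len(history["val_dsc"])
    if best_state is not None:
        model.set_state(best_state)
    history["best_epoch"] = best_epoch
    history["stopped_epoch"] = stopped_epoch
    return model, history


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def predict_labelmap(
    model: UNet, tile: np.ndarray, input_size: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Segment one tile: (probability map H x W x 7, label map H x W).

    The tile is reflect-padded to the network input size (or the next
    multiple of ``2**depth``), the padding is cropped back, and the label
    map is the per-pixel argmax mapped onto the tissue-class values.
    """
    tile = np.asarray(tile)
    h, w = tile.shape[:2]
    step = 2 ** model.depth
    if input_size is None:
        input_size = max(-(-h // step) * step, -(-w // step) * step)
    padded = reflect_pad(tile, input_size)
    py, px = (input_size - h) // 2, (input_size - w) // 2
    x = (padded.astype(np.float32) / 255.0).transpose(2, 0, 1)[None]
    prob = model.predict_proba(x)[0]  # (K, S, S)
    prob = prob[:, py : py + h, px : px + w].transpose(1, 2, 0)
    idx = prob.argmax(axis=-1)
    labels = (idx + 1).astype(np.uint8)  # foreground classes are 1..7
    return prob, labels


def segment_image(
    model: UNet, image: np.ndarray, window: int = 64
) -> np.ndarray:
    """Segment an image of arbitrary size by tiling into windows.

    Windows at the right/bottom edges are reflect-padded before prediction
    and cropped after.  Returns the stitched label map.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    out = np.zeros((h, w), dtype=np.uint8)
    for y0 in range(0, h, window):
        for x0 in range(0, w, window):
            patch = image[y0 : y0 + window, x0 : x0 + window]
            _, labels = predict_labelmap(model, patch, input_size=window)
            out[y0 : y0 + patch.shape[0], x0 : x0 + patch.shape[1]] = labels[
                : patch.shape[0], : patch.shape[1]
            ]
    return out


def evaluate_dsc(model: UNet, test_pairs: list, input_size: int | None = None) -> DscReport:
    """Per-class and overall Dice statistics of the model on a test set.

    A (patch, class) value enters the statistics when the class occurs in
    the truth or the prediction of that patch; classes absent from both are
    excluded (their vacuous Dice of 1 would inflate the mean).
    """
    if not test_pairs:
        raise ValueError("test set must be nonempty")
    values: dict[int, list[float]] = {int(c): [] for c in FOREGROUND_CLASSES}
    for tile, labels in test_pairs:
        _, pred = predict_labelmap(model, np.asarray(tile), input_size=input_size)
        truth = np.asarray(labels)
        for cls in FOREGROUND_CLASSES:
            if (truth == int(cls)).any() or (pred == int(cls)).any():
                values[int(cls)].append(dice_coefficient(pred, truth, int(cls)))
    return summarize_dice(values)


# ---------------------------------------------------------------------------
# tissue/background pre-mask
# ---------------------------------------------------------------------------


def tissue_threshold(tile: np.ndarray, levels: int = 2) -> np.ndarray:
    """Multi-level histogram thresholding into a binary tissue mask.

    The grayscale histogram is split into ``levels`` strata by maximizing
    between-class variance (multi-Otsu); the brightest stratum is treated
    as background (glass), everything darker as tissue.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    from skimage.color import rgb2gray
    from skimage.filters import threshold_multiotsu

    tile = np.asarray(tile)
    gray = rgb2gray(tile) * 255.0 if tile.ndim == 3 else tile.astype(float)
    if np.unique(np.rint(gray)).size < levels + 1:
        # degenerate histogram: fall back to a fixed white cutoff
        return gray < 220.0
    thresholds = threshold_multiotsu(gray, classes=levels)
    return gray < thresholds[-1]
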