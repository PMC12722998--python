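"""Training of channel-patched backbones on pooled windows.

Covers the full recipe: group-stratified 80/20 subject split, temporally
consistent per-window augmentation (random resized crop, brightness/contrast
jitter, horizontal flip), Adam with early stopping on validation loss, and
checkpointing. Subject disjointness between train and validation is asserted
on every split — leakage is impossible by construction.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .nn import TinyCNN, Adam, build_backbone, cross_entropy, softmax
from .windows import Window, window_to_tensor_stack

log = logging.getLogger(__name__)

LABEL_TO_INDEX = {"negative": 0, "positive": 1}


@dataclass(frozen=True)
class TrainConfig:
    """Optimization recipe.

    Defaults follow the standard setup for this task: batch 32, Adam at 1e-3,
    early stopping after 10 non-improving epochs, at most 100 epochs (200 when
    training from scratch with Kaiming initialization, which needs longer).
    """

    architecture: str = "tiny_cnn"
    in_channels: int = 150
    init: str = "kaiming_scratch"
    batch_size: int = 32
    learning_rate: float = 1e-3
    max_epochs: int = 100
    early_stop_patience: int = 10
    split_fraction: float = 0.8
    input_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.early_stop_patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")

    @property
    def effective_max_epochs(self) -> int:
        # scratch-initialized weights are allowed to train twice as long
        return self.max_epochs * 2 if (self.init == "kaiming_scratch"
                                       and self.max_epochs == 100) else self.max_epochs


@dataclass(frozen=True)
class AugmentConfig:
    crop_scale_range: tuple[float, float] = (0.8, 1.0)
    crop_aspect_range: tuple[float, float] = (3.0 / 4.0, 4.0 / 3.0)
    brightness_jitter: float = 0.20
    contrast_jitter: float = 0.10
    saturation_jitter: float = 0.10   # no-op on single-intensity channels
    hflip_probability: float = 0.5

    def __post_init__(self) -> None:
        for name in ("crop_scale_range", "crop_aspect_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"{name} must be a well-ordered positive range")
        if not 0.0 <= self.hflip_probability <= 1.0:
            raise ValueError("hflip_probability must lie in [0, 1]")


# ---------------------------------------------------------------------------
# subject split

def split_by_subject(manifest: pd.DataFrame, fraction: float = 0.8,
                     seed: int = 0) -> tuple[list[str], list[str]]:
    """Group-stratified subject split: within each capture group, subjects are
    shuffled (deterministically under ``seed``) and divided as close to
    ``fraction`` as rounding allows. No subject ever appears in both halves.
    """
    subjects = manifest[["subject_id", "group_tag"]].drop_duplicates()
    if subjects["subject_id"].nunique() < 2:
        raise ValueError("need at least 2 subjects to split")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    val: list[str] = []
    for group in sorted(subjects["group_tag"].unique()):
        members = sorted(subjects.loc[subjects["group_tag"] == group, "subject_id"])
        if len(members) == 1:
            log.warning("group %r has a single subject; assigning it to training",
                        group)
            train.extend(members)
            continue
        perm = rng.permutation(len(members))
        n_train = min(len(members) - 1, max(1, int(round(fraction * len(members)))))
        train.extend(members[i] for i in perm[:n_train])
        val.extend(members[i] for i in perm[n_train:])
    assert not set(train) & set(val), "subject leakage in split"
    return sorted(train), sorted(val)


def kfold_subject_splits(manifest: pd.DataFrame, k: int, seed: int = 0
                         ) -> list[tuple[list[str], list[str]]]:
    """Group-stratified k-fold subject splits (optional cross-validation
    driver around the 80/20 split): each fold holds out roughly 1/k of the
    subjects of every capture group; no subject appears in two holdouts."""
    if k < 2:
        raise ValueError("k must be >= 2")
    subjects = manifest[["subject_id", "group_tag"]].drop_duplicates()
    rng = np.random.default_rng(seed)
    folds: list[list[str]] = [[] for _ in range(k)]
    for group in sorted(subjects["group_tag"].unique()):
        members = sorted(subjects.loc[subjects["group_tag"] == group,
                                      "subject_id"])
        perm = rng.permutation(len(members))
        for i, j in enumerate(perm):
            folds[i % k].append(members[j])
    all_subjects = set(subjects["subject_id"])
    out = []
    for fold in folds:
        holdout = sorted(fold)
        out.append((sorted(all_subjects - set(holdout)), holdout))
    return out


# ---------------------------------------------------------------------------
# augmentation

def _bilinear_resize(stack: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Channel-wise bilinear resize of an (n, h, w) stack (half-pixel centers)."""
    n, h, w = stack.shape
    if (h, w) == (out_h, out_w):
        return stack
    ry = (np.arange(out_h) + 0.5) * h / out_h - 0.5
    rx = (np.arange(out_w) + 0.5) * w / out_w - 0.5
    y0 = np.clip(np.floor(ry).astype(int), 0, h - 1)
    x0 = np.clip(np.floor(rx).astype(int), 0, w - 1)
    y1 = np.clip(y0 + 1, 0, h - 1)
    x1 = np.clip(x0 + 1, 0, w - 1)
    wy = np.clip(ry - y0, 0.0, 1.0).astype(np.float32)[None, :, None]
    wx = np.clip(rx - x0, 0.0, 1.0).astype(np.float32)[None, None, :]
    top = stack[:, y0][:, :, x0] * (1 - wx) + stack[:, y0][:, :, x1] * wx
    bot = stack[:, y1][:, :, x0] * (1 - wx) + stack[:, y1][:, :, x1] * wx
    return top * (1 - wy) + bot * wy


def augment_window(stack: np.ndarray, cfg: AugmentConfig,
                   rng: np.random.Generator, out_size: int = 64) -> np.ndarray:
    """Augment one window: a single crop rectangle, jitter triple, and flip
    decision is drawn per window and applied identically to every channel, so
    the temporal structure pooling relies on is preserved.
    """
    stack = np.asarray(stack, dtype=np.float32)
    n, h, w = stack.shape
    scale = rng.uniform(*cfg.crop_scale_range)
    log_ratio = rng.uniform(np.log(cfg.crop_aspect_range[0]),
                            np.log(cfg.crop_aspect_range[1]))
    ratio = np.exp(log_ratio)
    ch = min(h, max(1, int(round(np.sqrt(scale * h * w / ratio)))))
    cw = min(w, max(1, int(round(np.sqrt(scale * h * w * ratio)))))
    top = int(rng.integers(0, h - ch + 1))
    left = int(rng.integers(0, w - cw + 1))
    out = stack[:, top:top + ch, left:left + cw]
    out = _bilinear_resize(out, out_size, out_size)

    brightness = 1.0 + rng.uniform(-cfg.brightness_jitter, cfg.brightness_jitter)
    contrast = 1.0 + rng.uniform(-cfg.contrast_jitter, cfg.contrast_jitter)
    rng.uniform(-cfg.saturation_jitter, cfg.saturation_jitter)  # drawn, unused: gray input
    out = out * brightness
    out = (out - out.mean()) * contrast + out.mean()
    if rng.uniform() < cfg.hflip_probability:
        out = out[:, :, ::-1]
    return np.ascontiguousarray(np.clip(out, 0.0, 1.0), dtype=np.float32)


def _prepare_eval_stack(window: Window, out_size: int) -> np.ndarray:
    stack = window_to_tensor_stack(window)
    return np.ascontiguousarray(
        _bilinear_resize(stack, out_size, out_size), dtype=np.float32)


# ---------------------------------------------------------------------------
# training loop

@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    val_video_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


def _evaluate(model: TinyCNN, stacks: np.ndarray, labels: np.ndarray,
              video_ids: np.ndarray, batch_size: int
              ) -> tuple[float, float, float]:
    """Window loss/accuracy plus the video-level validation loss.

    The video-level loss — cross-entropy of the mean positive confidence per
    video against the video label — is the early-stopping monitor: window
    loss is dominated by cue-free windows of positive videos, whose labels
    are inherently noisy, and punishes exactly the models that learned the
    cue. The video score is what the pipeline ultimately thresholds.
    """
    losses, correct = [], 0
    p_pos = np.empty(len(stacks))
    for i in range(0, len(stacks), batch_size):
        xb = stacks[i:i + batch_size]
        yb = labels[i:i + batch_size]
        logits = model.forward(xb, train=False)
        loss, _ = cross_entropy(logits, yb)
        losses.append(loss * len(xb))
        correct += int((logits.argmax(axis=1) == yb).sum())
        p = softmax(logits)[:, 1]
        p_pos[i:i + batch_size] = p
    video_losses = []
    for vid in np.unique(video_ids):
        sel = video_ids == vid
        score = float(np.clip(p_pos[sel].mean(), 1e-7, 1 - 1e-7))
        y = labels[sel][0]
        video_losses.append(-np.log(score if y == 1 else 1.0 - score))
    return (float(np.sum(losses) / len(stacks)), correct / len(stacks),
            float(np.mean(video_losses)))


def train_model(train_windows: list[Window], val_windows: list[Window],
                cfg: TrainConfig, aug: AugmentConfig | None = None,
                source_first_conv: np.ndarray | None = None
                ) -> tuple[TinyCNN, TrainingHistory]:
    """Train a channel-patched backbone on pooled windows.

    Minimizes 2-class cross-entropy with Adam; records train/validation loss
    and accuracy each epoch; stops when validation loss has not improved for
    ``early_stop_patience`` epochs or at the epoch cap; returns the weights of
    the best-validation-loss epoch. Deterministic under ``cfg.seed``.
    """
    if not train_windows or not val_windows:
        raise ValueError("train and validation window sets must be non-empty")
    aug = aug or AugmentConfig()
    y_train = np.array([LABEL_TO_INDEX[w.label] for w in train_windows])
    y_val = np.array([LABEL_TO_INDEX[w.label] for w in val_windows])
    if len(np.unique(y_val)) < 2:
        log.warning("validation set contains a single class; early stopping "
                    "still monitors validation loss")

    model = build_backbone(cfg.architecture, cfg.in_channels, cfg.init,
                           seed=cfg.seed, source_first_conv=source_first_conv)
    optimizer = Adam(model, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    val_stacks = np.stack([_prepare_eval_stack(w, cfg.input_size)
                           for w in val_windows])
    val_video_ids = np.array([w.video_id for w in val_windows])
    history = TrainingHistory()
    best_loss = np.inf
    best_state = model.state_dict()
    since_best = 0
    tail_states: list[dict] = []  # last epochs' weights for tail averaging

    for epoch in range(cfg.effective_max_epochs):
        order = rng.permutation(len(train_windows))
        epoch_loss, correct = 0.0, 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xb = np.stack([
                augment_window(window_to_tensor_stack(train_windows[j]), aug,
                               rng, out_size=cfg.input_size)
                for j in idx])
            yb = y_train[idx]
            logits = model.forward(xb, train=True)
            loss, dlogits = cross_entropy(logits, yb)
            model.backward(dlogits)
            optimizer.step()
            epoch_loss += loss * len(idx)
            correct += int((logits.argmax(axis=1) == yb).sum())
        val_loss, val_acc, val_video_loss = _evaluate(
            model, val_stacks, y_val, val_video_ids, cfg.batch_size)
        history.train_loss.append(epoch_loss / len(train_windows))
        history.train_acc.append(correct / len(train_windows))
        history.val_loss.append(val_loss)
        history.val_acc.append(val_acc)
        history.val_video_loss.append(val_video_loss)
        tail_states.append(model.state_dict())
        if len(tail_states) > 10:
            tail_states.pop(0)
        if val_video_loss < best_loss - 1e-9:
            best_loss = val_video_loss
            best_state = model.state_dict()
            history.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.early_stop_patience:
                break

    # tail-averaged weights (mean of the last epochs) are often more stable
    # than any single epoch on small data; keep whichever of best-epoch and
    # tail average has the lower validation video loss
    candidates = [best_state]
    if len(tail_states) > 1:
        avg = {k: np.mean([s[k] for s in tail_states], axis=0
                          ).astype(np.float32)
               for k in tail_states[-1]}
        candidates.append(avg)
    best_cand, best_cand_loss = None, np.inf
    for state in candidates:
        model.load_state_dict(state)
        _recalibrate_batchnorm(model, train_windows, cfg)
        _, _, loss = _evaluate(model, val_stacks, y_val, val_video_ids,
                               cfg.batch_size)
        if loss < best_cand_loss:
            best_cand, best_cand_loss = model.state_dict(), loss
    model.load_state_dict(best_cand)
    return model, history


def _recalibrate_batchnorm(model: TinyCNN, windows: list[Window],
                           cfg: TrainConfig, max_batches: int = 12) -> None:
    """Re-estimate BatchNorm running statistics on unaugmented inputs.

    Training batches are augmented (brightness/contrast jitter, crops), so
    running statistics collected during training are biased relative to the
    clean windows seen at inference; a few forward passes over unaugmented
    training windows remove that shift. No parameters are updated.
    """
    from .nn import BatchNorm2d
    bns = [l for l in model.layers if isinstance(l, BatchNorm2d)]
    saved = [bn.momentum for bn in bns]
    for bn in bns:
        bn.momentum = 0.3
    try:
        for _ in range(2):
            for i in range(0, min(len(windows), max_batches * cfg.batch_size),
                           cfg.batch_size):
                batch = windows[i:i + cfg.batch_size]
                if len(batch) < 2:
                    continue
                xb = np.stack([_prepare_eval_stack(w, cfg.input_size)
                               for w in batch])
                model.forward(xb, train=True)
    finally:
        for bn, m in zip(bns, saved):
            bn.momentum = m


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(path: str | Path, model: TinyCNN, train_cfg: TrainConfig,
                    aug_cfg: AugmentConfig, window_size: int, stride: int) -> None:
    """Weights plus every config needed to rebuild the model, in one .npz."""
    meta = dict(train=asdict(train_cfg), augment=asdict(aug_cfg),
                windowing=dict(window_size=window_size, stride=stride),
                widths=list(model.widths))
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> tuple[TinyCNN, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k[len("param/"):]: data[k] for k in data.files
                 if k.startswith("param/")}
    tc = meta["train"]
    model = TinyCNN(tc["in_channels"], seed=tc["seed"],
                    widths=tuple(meta["widths"]))
    model.load_state_dict(state)
    return model, meta
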