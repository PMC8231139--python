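"""Symmetric U-Net bone segmentation: architecture, losses, training.

The network is a classic symmetric U-Net: the contracting path applies
repeated pairs of 3x3 convolutions, each followed by batch normalization
and ReLU, with 2x2 stride-2 max-pooling between levels; the expanding
path mirrors it with nearest-neighbour upsampling and skip concatenation,
and a final 1x1 convolution maps the 64-feature (at default width) output
to the class channels.  Eight bone classes are segmented; a ninth
background channel is added so a per-pixel softmax covers every pixel,
while the losses are computed over foreground classes only.

Training follows the reference protocol: Adam (initial learning rate 0.1,
weight decay 1e-8), 500 epochs, batch size 4, multi-step learning-rate
schedule with gamma 0.1 at epochs {10, 50, 100, 150, 250}, and a sum loss
of the soft Dice error and the distance-transform Hausdorff surrogate.
A desk-scale configuration (depth 2, base 16 channels, learning rate
1e-3) is provided for CPU-sized experiments on phantom data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import distance_transform_edt

from .core import N_CLASSES
from .nn import Adam, BatchNorm2d, Conv2d, MaxPool2x2, MultiStepLR, ReLU, \
    UpsampleNearest2x, softmax

__all__ = [
    "UNetSpec",
    "TrainConfig",
    "UNet",
    "build_unet",
    "dice_loss",
    "hausdorff_loss",
    "train",
    "predict_sequence",
    "save_model",
    "load_model",
]

#: Smoothing constant of the soft Dice loss.
DICE_SMOOTH = 1e-6


@dataclass
class UNetSpec:
    """Architecture hyper-parameters of the symmetric U-Net."""

    in_channels: int = 1
    n_classes: int = N_CLASSES  # foreground classes; +1 background channel
    depth: int = 4
    base_channels: int = 64

    @property
    def out_channels(self) -> int:
        return self.n_classes + 1

    @classmethod
    def desk_scale(cls) -> "UNetSpec":
        """Reduced network for CPU-sized phantom experiments."""
        return cls(depth=2, base_channels=16)


@dataclass
class TrainConfig:
    """Optimization protocol (defaults follow the reference training recipe)."""

    lr: float = 0.1
    weight_decay: float = 1e-8
    epochs: int = 500
    batch_size: int = 4
    milestones: tuple[int, ...] = (10, 50, 100, 150, 250)
    gamma: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        ms = list(self.milestones)
        if ms != sorted(set(ms)) or (ms and ms[-1] >= self.epochs and self.epochs > 0):
            raise ValueError("milestones must be strictly increasing and < epochs")

    @classmethod
    def desk_scale(cls, epochs: int = 16, seed: int = 0) -> "TrainConfig":
        """Stable CPU recipe: lr 1e-2 with one late 10x drop (documented
        alternative to the aggressive 0.1 default)."""
        return cls(lr=1e-2, epochs=epochs, milestones=(max(1, int(epochs * 0.75)),),
                   seed=seed)


# ---------------------------------------------------------------------------
# Architecture
# ---------------------------------------------------------------------------


def _conv_block(c_in: int, c_out: int, rng) -> list:
    return [Conv2d(c_in, c_out, 3, rng), BatchNorm2d(c_out), ReLU(),
            Conv2d(c_out, c_out, 3, rng), BatchNorm2d(c_out), ReLU()]


def _run_block(block, x, train):
    for layer in block:
        x = layer.forward(x, train)
    return x


def _back_block(block, g):
    for layer in reversed(block):
        g = layer.backward(g)
    return g


class UNet:
    """Symmetric encoder-decoder network; (N,1,H,W) -> (N,C+1,H,W) logits."""

    def __init__(self, spec: UNetSpec, rng: np.random.Generator):
        self.spec = spec
        ch = [spec.base_channels * 2 ** l for l in range(spec.depth + 1)]
        self.enc = []
        c_in = spec.in_channels
        for l in range(spec.depth):
            self.enc.append(_conv_block(c_in, ch[l], rng))
            c_in = ch[l]
        self.pools = [MaxPool2x2() for _ in range(spec.depth)]
        self.bottleneck = _conv_block(ch[spec.depth - 1] if spec.depth else spec.in_channels,
                                      ch[spec.depth], rng)
        self.ups = [UpsampleNearest2x() for _ in range(spec.depth)]
        self.dec = []
        for l in reversed(range(spec.depth)):
            self.dec.append(_conv_block(ch[l + 1] + ch[l], ch[l], rng))
        self.head = Conv2d(ch[0] if spec.depth else ch[-1], spec.out_channels, 1, rng)

    @property
    def layers(self):
        out = []
        for b in self.enc:
            out.extend(b)
        out.extend(self.pools)
        out.extend(self.bottleneck)
        out.extend(self.ups)
        for b in self.dec:
            out.extend(b)
        out.append(self.head)
        return out

    @property
    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params)
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.params)

    def _check_size(self, x: np.ndarray) -> None:
        h, w = x.shape[2:]
        f = 2 ** self.spec.depth
        if h % f or w % f:
            raise ValueError(f"input size {h}x{w} not divisible by 2^depth = {f}")

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """(N, C_in, H, W) -> (N, C_out, H, W) logits.

        Internally activations are channels-last; the public contract
        stays channels-first.
        """
        x = np.asarray(x)
        if x.dtype != np.float64:  # float64 inputs propagate at full precision
            x = x.astype(np.float32)
        if x.ndim != 4 or x.shape[1] != self.spec.in_channels:
            raise ValueError("expected (N, C_in, H, W) input")
        self._check_size(x)
        x = np.ascontiguousarray(x.transpose(0, 2, 3, 1))
        skips = []
        for block, pool in zip(self.enc, self.pools):
            x = _run_block(block, x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = _run_block(self.bottleneck, x, train)
        self._skip_ch = []
        for up, block, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x, train)
            self._skip_ch.append((x.shape[-1], skip.shape[-1]))
            x = np.concatenate([x, skip], axis=-1)
            x = _run_block(block, x, train)
        out = self.head.forward(x, train)
        return out.transpose(0, 3, 1, 2)

    def backward(self, glogits: np.ndarray) -> None:
        g = self.head.backward(np.ascontiguousarray(glogits.transpose(0, 2, 3, 1)))
        gskips = []
        for up, block, (c_up, c_skip) in zip(reversed(self.ups), reversed(self.dec),
                                             reversed(self._skip_ch)):
            g = _back_block(block, g)
            gskips.append(g[..., c_up:])
            g = up.backward(np.ascontiguousarray(g[..., :c_up]))
        g = _back_block(self.bottleneck, g)
        for block, pool, gskip in zip(reversed(self.enc), reversed(self.pools),
                                      reversed(gskips)):
            g = pool.backward(g) + gskip
            g = _back_block(block, g)


def build_unet(spec: UNetSpec, seed: int = 0) -> UNet:
    """Instantiate the U-Net with He-initialized weights."""
    return UNet(spec, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# Losses (foreground classes only; scores are softmax probabilities with
# channel 0 = background, channel c = bone class c)
# ---------------------------------------------------------------------------


def _as_batch(scores: np.ndarray, target: np.ndarray):
    scores = np.asarray(scores, dtype=np.float64)
    target = np.asarray(target)
    if scores.ndim == 3:
        scores, target = scores[None], target[None]
    if scores.shape[0] != target.shape[0] or scores.shape[2:] != target.shape[1:]:
        raise ValueError("scores and target shapes are not congruent")
    return scores, target


def _dice_loss_grad(scores: np.ndarray, target: np.ndarray):
    scores, target = _as_batch(scores, target)
    n = scores.shape[0]
    grad = np.zeros_like(scores)
    total = 0.0
    for i in range(n):
        present = [c for c in range(1, scores.shape[1]) if (target[i] == c).any()]
        if not present:
            continue
        acc = 0.0
        for c in present:
            t = (target[i] == c).astype(np.float64)
            p = scores[i, c]
            inter = (p * t).sum()
            sums = p.sum() + t.sum()
            acc += 1.0 - (2.0 * inter + DICE_SMOOTH) / (sums + DICE_SMOOTH)
            dnum = 2.0 * t * (sums + DICE_SMOOTH)
            dden = 2.0 * inter + DICE_SMOOTH
            grad[i, c] += -(dnum - dden) / (sums + DICE_SMOOTH) ** 2 / len(present)
        total += acc / len(present)
    return total / n, grad / n


def dice_loss(scores: np.ndarray, target: np.ndarray) -> float:
    """Soft Dice error averaged over the foreground classes present in the
    target: 1 - (2|P.T| + eps) / (|P| + |T| + eps) per class.  0 for a
    perfect one-hot match, 1 for disjoint hard predictions."""
    return float(_dice_loss_grad(scores, target)[0])


def _boundary_dt(binary: np.ndarray) -> np.ndarray:
    """Unsigned distance (px) of every pixel to the region boundary."""
    if binary.any():
        if binary.all():
            return np.zeros_like(binary, dtype=np.float64)
        return distance_transform_edt(binary) + distance_transform_edt(~binary)
    return np.zeros_like(binary, dtype=np.float64)


def _hausdorff_loss_grad(scores: np.ndarray, target: np.ndarray, alpha: float = 2.0):
    scores, target = _as_batch(scores, target)
    n = scores.shape[0]
    hard = scores.argmax(axis=1)
    grad = np.zeros_like(scores)
    total = 0.0
    for i in range(n):
        present = [c for c in range(1, scores.shape[1]) if (target[i] == c).any()]
        if not present:
            continue
        acc = 0.0
        for c in present:
            t = target[i] == c
            p_hard = hard[i] == c
            w = _boundary_dt(t) ** alpha + _boundary_dt(p_hard) ** alpha
            diff = scores[i, c] - t
            acc += (diff * diff * w).mean()
            grad[i, c] += 2.0 * diff * w / diff.size / len(present)
        total += acc / len(present)
    return total / n, grad / n


def hausdorff_loss(scores: np.ndarray, target: np.ndarray) -> float:
    """Distance-transform surrogate of the Hausdorff distance loss.

    Per foreground class present in the target, the squared soft error of
    every pixel is weighted by the squared distance transforms of the
    target and of the hard prediction, so mistakes far from the true
    boundary dominate.  Zero for a perfect one-hot match; the weight of a
    misplaced pixel grows with the square of its distance to the boundary.
    The hard-prediction distance map is treated as a constant in the
    gradient.
    """
    return float(_hausdorff_loss_grad(scores, target)[0])


def combined_loss_grad(logits: np.ndarray, target: np.ndarray):
    """Unweighted sum of Dice and Hausdorff losses; returns (loss, dlogits)."""
    probs = softmax(np.asarray(logits, dtype=np.float64), axis=1)
    ld, gd = _dice_loss_grad(probs, target)
    lh, gh = _hausdorff_loss_grad(probs, target)
    gprobs = gd + gh
    # backprop through the per-pixel softmax
    dot = (gprobs * probs).sum(axis=1, keepdims=True)
    dlogits = probs * (gprobs - dot)
    return ld + lh, dlogits.astype(np.float32)


# ---------------------------------------------------------------------------
# Training and inference
# ---------------------------------------------------------------------------


def train(train_set: tuple[np.ndarray, np.ndarray],
          val_set: tuple[np.ndarray, np.ndarray] | None,
          unet: UNetSpec | UNet,
          cfg: TrainConfig,
          augment_cfg=None,
          verbose: bool = False) -> tuple[UNet, dict]:
    """Train the U-Net on (frames, masks) arrays of shape (n,H,W).

    Online augmentation (``preprocess.augment``) is applied per sample when
    an ``AugmentConfig`` is given.  Returns the trained model and a history
    dict with per-epoch learning rate, training loss and validation DSC.
    Raises ``RuntimeError`` on divergence (non-finite loss).
    """
    x_tr, y_tr = train_set
    if len(x_tr) == 0:
        raise ValueError("empty training set")
    model = unet if isinstance(unet, UNet) else build_unet(unet, seed=cfg.seed)
    history: dict = {"epoch": [], "lr": [], "train_loss": [], "val_dsc": []}
    if cfg.epochs == 0:
        return model, history

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.params, lr=cfg.lr, weight_decay=cfg.weight_decay)
    sched = MultiStepLR(cfg.lr, cfg.milestones, cfg.gamma)

    from .preprocess import Frame, augment as _augment

    for epoch in range(1, cfg.epochs + 1):
        opt.lr = sched.lr_at(epoch)
        order = rng.permutation(len(x_tr))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = x_tr[idx].astype(np.float32)
            yb = y_tr[idx].astype(np.int64)
            if augment_cfg is not None:
                xs, ys = [], []
                for xi, yi in zip(xb, yb):
                    fa, ma = _augment(Frame(xi), yi, augment_cfg, rng=rng)
                    xs.append(fa.intensities.astype(np.float32))
                    ys.append(ma)
                xb, yb = np.stack(xs), np.stack(ys)
            logits = model.forward(xb[:, None], train=True)
            loss, dlogits = combined_loss_grad(logits, yb)
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged at epoch {epoch} (loss={loss})")
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        val_dsc = float("nan")
        if val_set is not None and len(val_set[0]):
            val_dsc = _mean_foreground_dsc(model, val_set, cfg.batch_size)
        history["epoch"].append(epoch)
        history["lr"].append(opt.lr)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_dsc"].append(val_dsc)
        if verbose:
            print(f"epoch {epoch:3d}  lr {opt.lr:.2e}  loss {np.mean(losses):.4f}"
                  f"  val DSC {val_dsc:.4f}")
    return model, history


def _mean_foreground_dsc(model: UNet, dataset, batch_size: int) -> float:
    from .evalstats import dice_similarity
    x, y = dataset
    vals = []
    for start in range(0, len(x), batch_size):
        logits = model.forward(x[start:start + batch_size][:, None], train=False)
        pred = logits.argmax(axis=1)
        for p, t in zip(pred, y[start:start + batch_size]):
            classes = np.unique(t[t > 0])
            vals.extend(dice_similarity(p, t, c) for c in classes)
    return float(np.mean(vals)) if vals else float("nan")


def predict_sequence(model: UNet, frames: np.ndarray, batch_size: int = 4
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame class scores and argmax labels for an (n,H,W) stack.

    Frames are processed independently (temporal coupling is left to the
    post-processing stage).  Scores are per-pixel softmax probabilities
    over background + 8 bone classes, shape (n, 9, H, W).
    """
    frames = np.asarray(frames, dtype=np.float32)
    scores, labels = [], []
    for start in range(0, len(frames), batch_size):
        logits = model.forward(frames[start:start + batch_size][:, None], train=False)
        p = softmax(logits, axis=1)
        scores.append(p.astype(np.float32))
        labels.append(p.argmax(axis=1).astype(np.uint8))
    return np.concatenate(scores), np.concatenate(labels)


# ---------------------------------------------------------------------------
# Checkpoints: npz weights + JSON architecture spec
# ---------------------------------------------------------------------------


def save_model(model: UNet, path: str | Path) -> None:
    path = Path(path)
    arrays = {}
    for i, layer in enumerate(model.layers):
        for j, (p, _) in enumerate(layer.params):
            arrays[f"p_{i}_{j}"] = p
        if isinstance(layer, BatchNorm2d):
            arrays[f"rm_{i}"] = layer.run_mean
            arrays[f"rv_{i}"] = layer.run_var
    np.savez(path.with_suffix(".npz"), **arrays)
    path.with_suffix(".json").write_text(json.dumps(model.spec.__dict__))


def load_model(path: str | Path) -> UNet:
    path = Path(path)
    spec = UNetSpec(**json.loads(path.with_suffix(".json").read_text()))
    model = build_unet(spec)
    data = np.load(path.with_suffix(".npz"))
    for i, layer in enumerate(model.layers):
        for j, (p, _) in enumerate(layer.params):
            p[...] = data[f"p_{i}_{j}"]
        if isinstance(layer, BatchNorm2d):
            layer.run_mean = data[f"rm_{i}"]
            layer.run_var = data[f"rv_{i}"]
    return model
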