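"""Translated multichannel segmentation (TMS).

Two copies of the given-modality image plus one translated-modality image
fill the three input channels of a fully convolutional segmenter (the slots
conventionally used for RGB); the baseline fills all three channels with
the given image.  The network follows the FCN-8s pattern: a convolutional
encoder with three pooling stages whose final stream is fused with score
maps from the last two pooling stages before upsampling back to full
resolution; per-pixel classes come from a softmax head,
P(l = k | x) = s_k(h(x, theta*)).

Training is SGD with momentum on per-pixel cross-entropy; the capacity is
scaled to phantom resolution and initialization is random (no external
pre-trained weights).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import SGD, Conv2d, ConvTranspose2d, Module, Tensor
from .nn import autograd as ag
from .synthio import ImageSlice, LabelMap

__all__ = [
    "ChannelStack",
    "SegModelSpec",
    "SegResult",
    "FCNSegmenter",
    "assemble_channels",
    "predict_seg",
    "predict_probs",
    "train_seg",
    "compare_tms",
    "split_parts",
]


@dataclass
class ChannelStack:
    """Three aligned channels (given, given, translated) and their label."""

    channels: tuple[ImageSlice, ImageSlice, ImageSlice]
    label: LabelMap

    def __post_init__(self):
        shapes = {c.pixels.shape for c in self.channels}
        if len(shapes) != 1:
            raise ValueError("channels must share one shape")
        if self.label.classes.shape != self.channels[0].pixels.shape:
            raise ValueError("label shape must match channels")
        if not np.array_equal(self.channels[0].pixels, self.channels[1].pixels):
            raise ValueError("channels 1 and 2 must be pixel-identical")

    def array(self) -> np.ndarray:
        return np.stack([c.pixels for c in self.channels], axis=0)


@dataclass
class SegModelSpec:
    class_count: int = 2
    stage_filters: tuple[int, int, int] = (16, 32, 64)
    seed: int = 0

    def __post_init__(self):
        if self.class_count < 2:
            raise ValueError("need k >= 2 classes")
        if len(self.stage_filters) != 3:
            raise ValueError("three pooling stages required")


@dataclass
class SegResult:
    """Per-class test Dice for TMS and its baseline, with the relative
    increment Delta = (tms - baseline) / baseline (percent)."""

    dice_tms: dict[str, float]
    dice_baseline: dict[str, float]
    delta_percent: dict[str, float]
    accuracy_tms: dict[str, float] = field(default_factory=dict)
    accuracy_baseline: dict[str, float] = field(default_factory=dict)
    history_tms: list[float] = field(default_factory=list)
    history_baseline: list[float] = field(default_factory=list)


def assemble_channels(x: ImageSlice, x_hat: ImageSlice | None,
                      label: LabelMap, baseline: bool = False) -> ChannelStack:
    """Build the (x, x, x_hat) stack, or (x, x, x) in baseline mode."""
    third = x if baseline or x_hat is None else x_hat
    if third.pixels.shape != x.pixels.shape:
        raise ValueError("translated channel shape mismatch")
    return ChannelStack(channels=(x, x, third), label=label)


class FCNSegmenter(Module):
    """Three-stage convolutional encoder with FCN-8s-style skip fusion."""

    def __init__(self, spec: SegModelSpec, seed: int | None = None):
        rng = np.random.default_rng(spec.seed if seed is None else seed)
        f1, f2, f3 = spec.stage_filters
        k = spec.class_count
        self.spec = spec
        # He-scaled encoder, zero-initialized score layers, bilinear
        # upsampling: the standard fully-convolutional initialization,
        # standing in for the staged pretrained init of the original recipe
        self.conv1 = Conv2d(3, f1, 3, 1, 1, rng, init="he")
        self.conv2 = Conv2d(f1, f2, 3, 1, 1, rng, init="he")
        self.conv3 = Conv2d(f2, f3, 3, 1, 1, rng, init="he")
        self.conv_final = Conv2d(f3, f3, 3, 1, 1, rng, init="he")
        self.score_final = Conv2d(f3, k, 1, 1, 0, rng, init="he")
        self.score_pool2 = Conv2d(f2, k, 1, 1, 0, rng, init="zero")
        self.score_pool1 = Conv2d(f1, k, 1, 1, 0, rng, init="zero")
        self.up1 = ConvTranspose2d(k, k, 4, 2, 1, rng, init="bilinear")
        self.up2 = ConvTranspose2d(k, k, 4, 2, 1, rng, init="bilinear")
        self.up3 = ConvTranspose2d(k, k, 4, 2, 1, rng, init="bilinear")

    def forward(self, x: Tensor) -> Tensor:
        h1 = ag.max_pool2d(ag.relu(self.conv1(x)), 2)          # 1/2
        h2 = ag.max_pool2d(ag.relu(self.conv2(h1)), 2)         # 1/4
        h3 = ag.max_pool2d(ag.relu(self.conv3(h2)), 2)         # 1/8
        hf = ag.relu(self.conv_final(h3))
        s = self.score_final(hf)
        s = ag.add(self.up1(s), self.score_pool2(h2))          # fuse pool2
        s = ag.add(self.up2(s), self.score_pool1(h1))          # fuse pool1
        return self.up3(s)                                     # full res logits

    def logits(self, stack: ChannelStack) -> np.ndarray:
        return self.forward(Tensor(stack.array()[None])).data[0]


def predict_probs(model: FCNSegmenter, stack: ChannelStack) -> np.ndarray:
    """Softmax class probabilities, shape (K, H, W); sums to 1 per pixel."""
    z = model.logits(stack)
    z = z - z.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


def predict_seg(model: FCNSegmenter, stack: ChannelStack) -> LabelMap:
    """Per-pixel argmax of the softmax output."""
    if stack.array().shape[1] % 8 != 0:
        raise ValueError("stack side must be divisible by 8")
    probs = predict_probs(model, stack)
    names = stack.label.class_names
    if len(names) != model.spec.class_count:
        names = tuple(f"class{i}" for i in range(model.spec.class_count))
    return LabelMap(classes=np.argmax(probs, axis=0).astype(np.int64),
                    class_names=names)


def train_seg(stacks: list[ChannelStack], spec: SegModelSpec, epochs: int,
              lr: float = 1e-4, momentum: float = 0.99,
              weight_decay: float = 5e-4,
              class_weighted: bool = False) -> FCNSegmenter:
    """Train the segmenter with SGD (lr 1e-4, momentum 0.99, weight decay
    5e-4) on per-pixel cross-entropy, batch size 1, seeded by the spec.

    As in the original fully-convolutional recipe these hyperparameters go
    with an unnormalized loss: the per-pixel cross-entropy is summed over
    the image, not averaged (the recorded history stores the per-pixel
    mean for readability).  Because heavy momentum makes the loss
    oscillate, the returned model is the snapshot from the epoch with the
    lowest mean training loss, not the final epoch.  ``class_weighted``
    switches to inverse-frequency class weights for imbalanced problems
    (off by default).
    """
    if not stacks:
        raise ValueError("training set is empty")
    shapes = {s.array().shape for s in stacks}
    if len(shapes) != 1:
        raise ValueError("stacks must share one shape")
    model = FCNSegmenter(spec)
    opt = SGD(model.parameters(), lr=lr, momentum=momentum,
              weight_decay=weight_decay, max_grad_norm=1.0)
    order_rng = np.random.default_rng(spec.seed + 17)

    weights = None
    if class_weighted:
        counts = np.zeros(spec.class_count)
        for s in stacks:
            counts += np.bincount(s.label.classes.ravel(),
                                  minlength=spec.class_count)
        weights = counts.sum() / np.maximum(counts, 1.0)
        weights /= weights.mean()

    history = []
    best_loss, best_state = np.inf, None
    for _epoch in range(epochs):
        total = 0.0
        for i in order_rng.permutation(len(stacks)):
            x = Tensor(stacks[i].array()[None])
            logits = model.forward(x)
            labels = stacks[i].label.classes[None]
            pw = None if weights is None else weights[labels]
            mean_ce = ag.softmax_cross_entropy(logits, labels, pixel_weights=pw)
            loss = ag.affine_sum([mean_ce], [float(labels.size)])  # summed loss
            if not np.isfinite(loss.data):
                raise RuntimeError(f"non-finite segmentation loss at epoch {_epoch}")
            model.zero_grad()
            loss.backward()
            opt.step()
            total += float(mean_ce.data)
        epoch_loss = total / len(stacks)
        history.append(epoch_loss)
        if epoch_loss < best_loss:
            best_loss = epoch_loss
            best_state = {k: v.copy() for k, v in model.state_dict().items()}
    if best_state is not None:
        model.load_state_dict(best_state)
    model.loss_history = history
    return model


def split_parts(train_subjects: list, test_subjects: list):
    """The three-way split protocol: the training set divides 1:1 into
    PartA (trains the translator) and PartB (translated by it, then trains
    the segmenter); the untouched test set is PartC.  Raises on subject
    overlap."""
    ids = [id(s) for s in train_subjects + test_subjects]
    if len(set(ids)) != len(ids):
        raise ValueError("train/test subject overlap (split leakage)")
    half = len(train_subjects) // 2
    return train_subjects[:half], train_subjects[half:], list(test_subjects)


def _dice_block(model, stacks, class_names):
    from .metrics import dice
    k = len(class_names)
    vals = {c: [] for c in class_names[1:]}
    acc_all, acc_n = 0, 0
    for s in stacks:
        pred = predict_seg(model, s)
        acc_all += int((pred.classes == s.label.classes).sum())
        acc_n += s.label.classes.size
        for c in range(1, k):
            vals[class_names[c]].append(dice(pred, s.label, c))
    return ({c: float(np.mean(v)) for c, v in vals.items()},
            {"all": acc_all / acc_n})


def compare_tms(train_baseline: list[ChannelStack], train_tms: list[ChannelStack],
                test_baseline: list[ChannelStack], test_tms: list[ChannelStack],
                spec: SegModelSpec, epochs: int,
                class_weighted: bool = False) -> SegResult:
    """Train the segmenter in baseline and TMS modes on identical splits
    and seeds, evaluate test Dice per class, and report the relative
    increment Delta (percent) of TMS over the baseline."""
    for a, b in ((train_baseline, train_tms), (test_baseline, test_tms)):
        if len(a) != len(b):
            raise ValueError("modes must use identical splits")
        for sa, sb in zip(a, b):
            if not np.array_equal(sa.label.classes, sb.label.classes):
                raise ValueError("modes must use identical labels")
    train_labels = {sa.label.classes.tobytes() for sa in train_baseline}
    for s in test_baseline:
        if s.label.classes.tobytes() in train_labels:
            raise ValueError("train/test subject overlap (split leakage)")

    names = train_baseline[0].label.class_names
    model_b = train_seg(train_baseline, spec, epochs, class_weighted=class_weighted)
    model_t = train_seg(train_tms, spec, epochs, class_weighted=class_weighted)
    dice_b, acc_b = _dice_block(model_b, test_baseline, names)
    dice_t, acc_t = _dice_block(model_t, test_tms, names)
    delta = {c: (100.0 * (dice_t[c] - dice_b[c]) / dice_b[c]
                 if dice_b[c] > 0 else float("inf"))
             for c in dice_t}
    return SegResult(dice_tms=dice_t, dice_baseline=dice_b, delta_percent=delta,
                     accuracy_tms=acc_t, accuracy_baseline=acc_b,
                     history_tms=model_t.loss_history,
                     history_baseline=model_b.loss_history)
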