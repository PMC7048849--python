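"""Evaluation metrics for cross-modality synthesis, registration and
segmentation.

MAE, PSNR, mutual information and SSIM quantify how close a translated
image is to its real target; Dice and mean landmark distance evaluate
registration; the FCN-score harness measures how well a segmenter trained
on real target-modality images segments synthesized ones, relative to real
test images (the gap is the score).

Conventions: SSIM uses whole-image statistics by default (a windowed
variant is available behind a flag for comparability with common
libraries); mutual information is reported in nats from a joint histogram
with ``mi_bins`` bins per axis; PSNR's MAX defaults to the maximum pixel
value over the two images ("pair_max"), with a "dynamic_range" mode
available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity as _sk_ssim

from .synthio import ImageSlice, LabelMap, LandmarkSet

__all__ = [
    "MetricConfig",
    "MetricReport",
    "mae",
    "psnr",
    "mutual_information",
    "ssim",
    "dice",
    "landmark_dist",
    "fcn_score",
    "evaluate_pairs",
]


@dataclass
class MetricConfig:
    mi_bins: int = 64
    psnr_max_mode: str = "pair_max"  # or "dynamic_range"
    ssim_k1: float = 0.01
    ssim_k2: float = 0.03
    ssim_windowed: bool = False

    def __post_init__(self):
        if self.mi_bins < 2:
            raise ValueError("mi_bins must be >= 2")
        if self.psnr_max_mode not in ("pair_max", "dynamic_range"):
            raise ValueError("psnr_max_mode must be pair_max or dynamic_range")
        if self.ssim_k1 <= 0 or self.ssim_k2 <= 0:
            raise ValueError("SSIM constants must be strictly positive")


@dataclass
class MetricReport:
    """Per-image metric lists and their cohort means (arithmetic)."""

    per_image: dict[str, list[float]] = field(default_factory=dict)
    fcn: dict | None = None

    def mean(self, key: str) -> float:
        return float(np.mean(self.per_image[key]))

    def as_row(self) -> dict[str, float]:
        return {k: self.mean(k) for k in ("mae", "psnr", "mi", "ssim")
                if k in self.per_image}


def _px(a) -> np.ndarray:
    arr = a.pixels if isinstance(a, ImageSlice) else np.asarray(a)
    return arr.astype(np.float64)


def _check_same_shape(y, y_hat):
    a, b = _px(y), _px(y_hat)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    return a, b


def mae(y, y_hat) -> float:
    """Mean absolute error (1/(m*n)) * sum |yhat - y|."""
    a, b = _check_same_shape(y, y_hat)
    return float(np.abs(b - a).mean())


def psnr(y, y_hat, cfg: MetricConfig | None = None) -> float:
    """Peak signal-to-noise ratio 10*log10(MAX^2 / MSE) in dB.

    Identical images have zero MSE; +inf is returned.
    """
    cfg = cfg or MetricConfig()
    a, b = _check_same_shape(y, y_hat)
    mse = float(((b - a) ** 2).mean())
    if mse == 0:
        return float("inf")
    if cfg.psnr_max_mode == "pair_max":
        mx = float(max(a.max(), b.max()))
    else:
        mx = float(max(a.max(), b.max()) - min(a.min(), b.min()))
    return float(10.0 * np.log10(mx * mx / mse))


def mutual_information(y, y_hat, cfg: MetricConfig | None = None) -> float:
    """Histogram mutual information I(y; yhat) in nats.

    The joint histogram covers each image's own intensity range with
    ``mi_bins`` bins per axis; empty cells are skipped.
    """
    cfg = cfg or MetricConfig()
    a, b = _check_same_shape(y, y_hat)
    joint, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=cfg.mi_bins)
    p = joint / joint.sum()
    pm = p.sum(axis=1, keepdims=True)
    pn = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float((p[nz] * np.log(p[nz] / (pm @ pn)[nz])).sum())


def ssim(y, y_hat, cfg: MetricConfig | None = None) -> float:
    """Structural similarity from whole-image statistics:

        SSIM = (2 mu_x mu_y + c1)(2 sigma_xy + c2)
               / ((mu_x^2 + mu_y^2 + c1)(sigma_x^2 + sigma_y^2 + c2))

    with c1 = (K1*L)^2, c2 = (K2*L)^2, L the pair's dynamic range.  With
    ``ssim_windowed`` the common sliding-window mean is computed instead.
    """
    cfg = cfg or MetricConfig()
    a, b = _check_same_shape(y, y_hat)
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    drange = float(hi - lo) if hi > lo else 1.0
    if cfg.ssim_windowed:
        return float(_sk_ssim(a, b, data_range=drange, K1=cfg.ssim_k1, K2=cfg.ssim_k2))
    c1 = (cfg.ssim_k1 * drange) ** 2
    c2 = (cfg.ssim_k2 * drange) ** 2
    mu_x, mu_y = a.mean(), b.mean()
    var_x, var_y = a.var(), b.var()
    cov = ((a - mu_x) * (b - mu_y)).mean()
    return float(((2 * mu_x * mu_y + c1) * (2 * cov + c2))
                 / ((mu_x ** 2 + mu_y ** 2 + c1) * (var_x + var_y + c2)))


def dice(h: LabelMap, g: LabelMap, cls: int) -> float:
    """Dice overlap 2|H∩G| / (|H| + |G|) of one class's binary masks.

    Both masks empty counts as perfect agreement (1.0): absence correctly
    predicted.
    """
    if h.classes.shape != g.classes.shape:
        raise ValueError("label shape mismatch")
    hm = h.classes == cls
    gm = g.classes == cls
    denom = int(hm.sum()) + int(gm.sum())
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(hm, gm).sum() / denom)


def landmark_dist(warped: LandmarkSet, fixed: LandmarkSet,
                  spacing=(1.0, 1.0, 1.0)) -> float:
    """Mean 3-D Euclidean distance between corresponding named landmarks,
    in spacing units (slices are assumed stacked into a volume)."""
    wn, fn = set(warped.points), set(fixed.points)
    if wn != fn:
        raise ValueError(f"unpaired landmark names: {sorted(wn ^ fn)}")
    sp = np.asarray(spacing, dtype=np.float64)
    dists = [
        float(np.linalg.norm((np.asarray(warped.points[n]) - np.asarray(fixed.points[n])) * sp))
        for n in sorted(wn)
    ]
    return float(np.mean(dists))


# ---------------------------------------------------------------------------
# FCN-score harness
# ---------------------------------------------------------------------------

def _accuracy_block(preds: list[LabelMap], truths: list[LabelMap],
                    class_names: tuple[str, ...]) -> dict:
    """Pixel accuracies ("all" + per class) and per-class Dice over a set."""
    all_correct = all_total = 0
    k = len(class_names)
    cls_correct = np.zeros(k)
    cls_total = np.zeros(k)
    dice_vals: dict[str, list[float]] = {c: [] for c in class_names[1:]}
    for p, t in zip(preds, truths):
        ok = p.classes == t.classes
        all_correct += int(ok.sum())
        all_total += ok.size
        for c in range(k):
            m = t.classes == c
            cls_total[c] += int(m.sum())
            cls_correct[c] += int((ok & m).sum())
        for c in range(1, k):
            dice_vals[class_names[c]].append(dice(p, t, c))
    out = {"all": all_correct / all_total if all_total else 1.0}
    for c in range(1, k):
        out[class_names[c]] = (float(cls_correct[c] / cls_total[c])
                               if cls_total[c] else 1.0)
    return {"accuracy": out,
            "dice": {c: float(np.mean(v)) if v else 1.0 for c, v in dice_vals.items()}}


def fcn_score(seg_model, real: list[tuple[ImageSlice, LabelMap]],
              synth: list[tuple[ImageSlice, LabelMap]]) -> MetricReport:
    """Score synthesized images by segmenter discriminability.

    ``seg_model`` must have been trained on real target-modality images
    only.  Both sets are segmented (single-modality channel stacks); the
    report carries accuracy/Dice blocks for each set and their gap
    (real - synth), the FCN-score proper.
    """
    from .tms import ChannelStack, predict_seg

    def run(pairs):
        preds, truths = [], []
        for img, lab in pairs:
            stack = ChannelStack(channels=(img, img, img), label=lab)
            preds.append(predict_seg(seg_model, stack))
            truths.append(lab)
        return preds, truths

    names = real[0][1].class_names
    preds_r, truth_r = run(real)
    preds_s, truth_s = run(synth)
    block_r = _accuracy_block(preds_r, truth_r, names)
    block_s = _accuracy_block(preds_s, truth_s, names)
    gap = {
        "accuracy": {k: block_r["accuracy"][k] - block_s["accuracy"][k]
                     for k in block_r["accuracy"]},
        "dice": {k: block_r["dice"][k] - block_s["dice"][k]
                 for k in block_r["dice"]},
    }
    return MetricReport(per_image={}, fcn={"real": block_r, "synth": block_s,
                                           "gap": gap})


def evaluate_pairs(reals: list[ImageSlice], synths: list[ImageSlice],
                   cfg: MetricConfig | None = None) -> MetricReport:
    """Per-image MAE/PSNR/MI/SSIM over aligned (real, synthesized) lists."""
    cfg = cfg or MetricConfig()
    rep = MetricReport(per_image={"mae": [], "psnr": [], "mi": [], "ssim": []})
    for y, yh in zip(reals, synths):
        rep.per_image["mae"].append(mae(y, yh))
        rep.per_image["psnr"].append(psnr(y, yh, cfg))
        rep.per_image["mi"].append(mutual_information(y, yh, cfg))
        rep.per_image["ssim"].append(ssim(y, yh, cfg))
    return rep
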