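"""Translated-modality-augmented multi-atlas registration.

The pipeline has four steps: (1) augment the fixed-image space with a
translated modality, (2) register each atlas to the fixed space once per
modality (given->given and other->translated), (3) fuse the two deformation
fields as a convex combination ``w*phi_translated + (1-w)*phi_given``, and
(4) propagate the atlas labels through the fused fields and average the n
one-hot warped labels into per-class probabilities (final label = argmax).

Deformation fields are backward-warping displacement maps on the fixed
image grid: ``disp[r, c] = (dy, dx)`` such that the warped image samples
the moving image at ``(r + dy, c + dx)``.

The builtin registration backend is multi-resolution (3 levels)
Gaussian-regularized demons on histogram-matched intensities, preceded by a
center-of-mass + exhaustive-rotation rigid initialization.  Adapters for
external tools (ANTs/Elastix style command templates) can be registered on
the same seam.
"""

from __future__ import annotations

import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .synthio import ImageSlice, LabelMap, LandmarkSet

__all__ = [
    "DeformationField",
    "save_deformation",
    "load_deformation",
    "FixedSpace",
    "AtlasSubject",
    "AtlasSet",
    "FusionConfig",
    "register_pair",
    "warp_image",
    "fuse_deformations",
    "propagate_and_average",
    "select_weight",
    "register_backend",
    "CommandTemplateBackend",
]


@dataclass
class DeformationField:
    """Per-pixel displacement vectors (dy, dx) on the fixed-image grid."""

    disp: np.ndarray  # (H, W, 2)

    def __post_init__(self):
        self.disp = np.asarray(self.disp, dtype=np.float64)
        if self.disp.ndim != 3 or self.disp.shape[-1] != 2:
            raise ValueError("displacement field must have shape (H, W, 2)")
        if not np.all(np.isfinite(self.disp)):
            raise ValueError("displacement field must be finite")

    @property
    def side(self) -> int:
        return self.disp.shape[0]

    def norms(self) -> np.ndarray:
        return np.sqrt((self.disp ** 2).sum(axis=-1))


@dataclass
class FixedSpace:
    """The fixed-image space: the acquired given modality plus its
    translated counterpart, with optional ground truth."""

    given: ImageSlice
    translated: ImageSlice
    labels: LabelMap | None = None
    landmarks: LandmarkSet | None = None

    def __post_init__(self):
        if self.given.pixels.shape != self.translated.pixels.shape:
            raise ValueError("given and translated images must share shape")


@dataclass
class AtlasSubject:
    given: ImageSlice
    other: ImageSlice
    label: LabelMap
    landmarks: LandmarkSet | None = None


@dataclass
class AtlasSet:
    subjects: list[AtlasSubject]

    def __post_init__(self):
        if len(self.subjects) < 1:
            raise ValueError("atlas set needs n >= 1 subjects")
        shapes = {s.given.pixels.shape for s in self.subjects}
        if len(shapes) != 1:
            raise ValueError("atlas shapes must be homogeneous")


@dataclass
class FusionConfig:
    """w weights the translated-modality deformation; 1-w the given one."""

    w: float = 0.5
    backend: str = "builtin"
    cv_folds: int = 5
    backend_options: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("fusion weight must lie in [0, 1]")


def save_deformation(phi: DeformationField, path, spacing=(1.0, 1.0)) -> None:
    """Write a field as a raw .npy (H, W, 2) with a JSON sidecar."""
    import json

    path = Path(path)
    np.save(path, phi.disp)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({"side": phi.side, "spacing": list(spacing),
                                   "order": "dy,dx"}))


def load_deformation(path) -> DeformationField:
    return DeformationField(disp=np.load(Path(path)))


# ---------------------------------------------------------------------------
# Warping
# ---------------------------------------------------------------------------

def warp_image(img, phi: DeformationField):
    """Backward-warp an ImageSlice (bilinear) or LabelMap (nearest).

    Out-of-domain samples map to background (-1 for normalized intensity
    images, 0 otherwise/labels).
    """
    h, w = phi.disp.shape[:2]
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    coords = [rr + phi.disp[..., 0], cc + phi.disp[..., 1]]
    if isinstance(img, LabelMap):
        if img.classes.shape != (h, w):
            raise ValueError("image/field shape mismatch")
        out = ndimage.map_coordinates(img.classes, coords, order=0, mode="constant",
                                      cval=0)
        return LabelMap(classes=out.astype(img.classes.dtype),
                        class_names=img.class_names)
    if img.pixels.shape != (h, w):
        raise ValueError("image/field shape mismatch")
    cval = -1.0 if img.normalized else 0.0
    out = ndimage.map_coordinates(img.pixels.astype(np.float64), coords, order=1,
                                  mode="constant", cval=cval)
    return replace(img, pixels=out)


def fuse_deformations(phi_given: DeformationField, phi_translated: DeformationField,
                      cfg: FusionConfig) -> DeformationField:
    """Convex combination of displacement fields, pointwise:
    phi = w * phi_translated + (1 - w) * phi_given."""
    if phi_given.disp.shape != phi_translated.disp.shape:
        raise ValueError("deformation field shape mismatch")
    return DeformationField(disp=cfg.w * phi_translated.disp
                            + (1.0 - cfg.w) * phi_given.disp)


# ---------------------------------------------------------------------------
# Builtin registration backend
# ---------------------------------------------------------------------------

def _to_unit(img: ImageSlice) -> np.ndarray:
    px = img.pixels.astype(np.float64)
    if img.normalized:
        return (px + 1.0) / 2.0
    lo, hi = px.min(), px.max()
    return (px - lo) / (hi - lo) if hi > lo else np.zeros_like(px)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    return float((a * b).sum() / denom) if denom > 0 else 0.0


def _rigid_params(moving: np.ndarray, fixed: np.ndarray,
                  angle_range: float = 45.0, coarse_step: float = 3.0):
    """Center-of-mass shift + exhaustive rotation search (coarse grid then
    1-degree refinement), scored by normalized cross-correlation at quarter
    resolution.  Returns (theta_rad, com_fixed, com_moving)."""
    com_f = np.array(ndimage.center_of_mass(fixed - fixed.min() + 1e-12))
    com_m = np.array(ndimage.center_of_mass(moving - moving.min() + 1e-12))
    small_f = ndimage.zoom(fixed, 0.25, order=1)
    small_m = ndimage.zoom(moving, 0.25, order=1)

    def score(theta_deg: float) -> float:
        rot = _apply_rigid(small_m, np.deg2rad(theta_deg), com_f * 0.25, com_m * 0.25)
        return _ncc(rot, small_f)

    coarse = sorted(np.arange(-angle_range, angle_range + 1e-9, coarse_step),
                    key=abs)
    best_a, best_s = 0.0, -np.inf
    for a in coarse:
        s = score(a)
        if s > best_s + 1e-12:
            best_a, best_s = a, s
    for a in sorted(np.arange(best_a - coarse_step, best_a + coarse_step + 1e-9, 1.0),
                    key=lambda t: abs(t - best_a)):
        s = score(a)
        if s > best_s + 1e-12:
            best_a, best_s = a, s
    return np.deg2rad(best_a), com_f, com_m


def _rigid_map(shape, theta: float, com_f: np.ndarray, com_m: np.ndarray,
               offset: np.ndarray | None = None):
    """Map fixed coords p (+ optional per-pixel offset) into moving coords:
    q = R(p + offset - com_f) + com_m."""
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    if offset is not None:
        rr = rr + offset[..., 0]
        cc = cc + offset[..., 1]
    dy, dx = rr - com_f[0], cc - com_f[1]
    cos, sin = np.cos(theta), np.sin(theta)
    qr = cos * dy - sin * dx + com_m[0]
    qc = sin * dy + cos * dx + com_m[1]
    return qr, qc


def _apply_rigid(moving: np.ndarray, theta: float, com_f, com_m) -> np.ndarray:
    qr, qc = _rigid_map(moving.shape, theta, np.asarray(com_f), np.asarray(com_m))
    return ndimage.map_coordinates(moving, [qr, qc], order=1, mode="constant", cval=0.0)


def _demons_multilevel(fixed: np.ndarray, moving: np.ndarray,
                       shrinks=(4, 2, 1), iters=(60, 40, 20),
                       smooth_sd: float = 1.5):
    """Gaussian-regularized symmetric-forces demons over a 3-level pyramid.

    Returns the displacement array (H, W, 2) in (dy, dx) order.  If the
    post-level similarity worsens on two consecutive levels the best field
    seen so far is returned with a warning.
    """
    f_img = sitk.GetImageFromArray(fixed.astype(np.float64))
    m_img = sitk.GetImageFromArray(moving.astype(np.float64))
    matcher = sitk.HistogramMatchingImageFilter()
    matcher.SetNumberOfHistogramLevels(128)
    matcher.SetNumberOfMatchPoints(7)
    matcher.ThresholdAtMeanIntensityOn()
    m_img = matcher.Execute(m_img, f_img)

    demons = sitk.FastSymmetricForcesDemonsRegistrationFilter()
    demons.SetSmoothDisplacementField(True)
    demons.SetStandardDeviations(smooth_sd)

    field = None
    best_field, best_mse, worse = None, np.inf, 0
    for shrink, n_it in zip(shrinks, iters):
        if shrink > 1:
            f_l = sitk.Shrink(sitk.DiscreteGaussian(f_img, float(shrink) / 2.0),
                              [shrink, shrink])
            m_l = sitk.Shrink(sitk.DiscreteGaussian(m_img, float(shrink) / 2.0),
                              [shrink, shrink])
        else:
            f_l, m_l = f_img, m_img
        if field is None:
            field = sitk.Image(f_l.GetSize(), sitk.sitkVectorFloat64, 2)
            field.CopyInformation(f_l)
        else:
            field = sitk.Resample(field, f_l)
        demons.SetNumberOfIterations(int(n_it))
        field = demons.Execute(f_l, m_l, field)

        full = sitk.GetArrayFromImage(sitk.Resample(field, f_img))  # (H,W,(dx,dy))
        disp = full[..., ::-1]
        h, w = fixed.shape
        rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
        warped = ndimage.map_coordinates(moving, [rr + disp[..., 0], cc + disp[..., 1]],
                                         order=1, mode="constant", cval=0.0)
        mse = float(((warped - fixed) ** 2).mean())
        if mse < best_mse - 1e-12:
            best_mse, best_field, worse = mse, disp, 0
        else:
            worse += 1
            if worse >= 2:
                warnings.warn("demons similarity worsened on two consecutive "
                              "levels; returning best field so far", stacklevel=2)
                return best_field
    return best_field


def _builtin_backend(moving: ImageSlice, fixed: ImageSlice, **opts) -> DeformationField:
    mov = _to_unit(moving)
    fix = _to_unit(fixed)
    if mov.shape != fix.shape:
        raise ValueError("moving/fixed shape mismatch")
    theta, com_f, com_m = _rigid_params(
        mov, fix,
        angle_range=opts.get("angle_range", 45.0),
        coarse_step=opts.get("coarse_step", 3.0),
    )
    mov_r = _apply_rigid(mov, theta, com_f, com_m)
    disp_d = _demons_multilevel(
        fix, mov_r,
        shrinks=opts.get("shrinks", (4, 2, 1)),
        iters=opts.get("iters", (60, 40, 20)),
        smooth_sd=opts.get("smooth_sd", 1.5),
    )
    # total field: fixed coords -> moving coords through demons then rigid
    qr, qc = _rigid_map(fix.shape, theta, com_f, com_m, offset=disp_d)
    h, w = fix.shape
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    return DeformationField(disp=np.stack([qr - rr, qc - cc], axis=-1))


class CommandTemplateBackend:
    """Adapter seam for external registration tools (ANTs/Elastix style).

    The template is formatted with ``{moving}``, ``{fixed}`` and ``{field}``
    paths; the command must write the displacement field as a raw ``.npy``
    array of shape (H, W, 2) in (dy, dx) order.
    """

    def __init__(self, template: str):
        self.template = template

    def __call__(self, moving: ImageSlice, fixed: ImageSlice, **opts) -> DeformationField:
        from .synthio import write_slice_png

        with tempfile.TemporaryDirectory() as td:
            mp, fp, op = (Path(td) / n for n in ("moving.png", "fixed.png", "field.npy"))
            write_slice_png(moving, mp)
            write_slice_png(fixed, fp)
            cmd = self.template.format(moving=mp, fixed=fp, field=op)
            subprocess.run(cmd, shell=True, check=True)
            return DeformationField(disp=np.load(op))


_BACKENDS = {"builtin": _builtin_backend}


def register_backend(name: str, fn) -> None:
    """Register a registration backend under ``name``."""
    _BACKENDS[name] = fn


def register_pair(moving: ImageSlice, fixed: ImageSlice, backend: str = "builtin",
                  **opts) -> DeformationField:
    """Compute the deformation field aligning ``moving`` to ``fixed``."""
    if moving.pixels.shape != fixed.pixels.shape:
        raise ValueError("moving/fixed shape mismatch")
    try:
        fn = _BACKENDS[backend]
    except KeyError:
        raise ValueError(f"unknown registration backend {backend!r}; "
                         f"known: {sorted(_BACKENDS)}") from None
    return fn(moving, fixed, **opts)


# ---------------------------------------------------------------------------
# Multi-atlas propagation
# ---------------------------------------------------------------------------

def propagate_and_average(atlases: AtlasSet, fixed: FixedSpace, cfg: FusionConfig):
    """Register every atlas to the fixed space in both modalities, fuse the
    fields, warp the atlas labels, and average the one-hot warped labels.

    Returns (final LabelMap, per-class probability array (K, H, W)).  The
    final label is the per-pixel argmax; ties break to the lowest class.
    """
    names = atlases.subjects[0].label.class_names
    k = len(names)
    h, w = fixed.given.pixels.shape
    votes = np.zeros((k, h, w))
    for sub in atlases.subjects:
        phi_g = register_pair(sub.given, fixed.given, backend=cfg.backend,
                              **cfg.backend_options)
        phi_t = register_pair(sub.other, fixed.translated, backend=cfg.backend,
                              **cfg.backend_options)
        fused = fuse_deformations(phi_g, phi_t, cfg)
        warped = warp_image(sub.label, fused)
        for c in range(k):
            votes[c] += warped.classes == c
    probs = votes / len(atlases.subjects)
    final = LabelMap(classes=np.argmax(probs, axis=0).astype(np.int64),
                     class_names=names)
    return final, probs


WEIGHT_GRID = np.round(np.arange(0.0, 1.0 + 1e-9, 0.05), 2)


def select_weight(train_cohort, cfg: FusionConfig, translate_fn,
                  given: str, other: str, target_class: int = 1) -> float:
    """Cross-validated grid search for the fusion weight.

    Each fold holds out one group of subjects as fixed targets; the rest act
    as atlases.  For every held-out subject both per-atlas fields are
    computed once, then every candidate weight on the grid {0, 0.05, ..., 1}
    is scored by the Dice of the propagated ``target_class`` against the
    subject's own label; the weight maximizing the mean Dice is returned.

    ``translate_fn`` maps a given-modality ImageSlice to its translated
    counterpart (typically ``lambda s: imt.translate(t, s)``).
    """
    from .metrics import dice as _dice

    subjects = train_cohort.subjects
    folds = max(1, min(cfg.cv_folds, len(subjects)))
    if len(subjects) < folds:
        raise ValueError("cohort smaller than cv_folds")
    targets = list(range(len(subjects)))[:: max(1, len(subjects) // folds)][:folds]
    scores = np.zeros(len(WEIGHT_GRID))
    counts = 0
    for i in targets:
        fix_sub = subjects[i]
        atl = [s for j, s in enumerate(subjects) if j != i]
        fixed = FixedSpace(given=fix_sub.images[given],
                           translated=translate_fn(fix_sub.images[given]),
                           labels=fix_sub.label)
        pairs = []
        for sub in atl:
            phi_g = register_pair(sub.images[given], fixed.given,
                                  backend=cfg.backend, **cfg.backend_options)
            phi_t = register_pair(sub.images[other], fixed.translated,
                                  backend=cfg.backend, **cfg.backend_options)
            pairs.append((phi_g, phi_t, sub.label))
        for wi, wt in enumerate(WEIGHT_GRID):
            k = len(fix_sub.label.class_names)
            hgt, wid = fixed.given.pixels.shape
            votes = np.zeros((k, hgt, wid))
            wcfg = FusionConfig(w=float(wt), backend=cfg.backend, cv_folds=cfg.cv_folds)
            for phi_g, phi_t, lab in pairs:
                warped = warp_image(lab, fuse_deformations(phi_g, phi_t, wcfg))
                for c in range(k):
                    votes[c] += warped.classes == c
            pred = LabelMap(classes=np.argmax(votes, axis=0).astype(np.int64),
                            class_names=fix_sub.label.class_names)
            scores[wi] += _dice(pred, fix_sub.label, target_class)
        counts += 1
    scores /= max(counts, 1)
    return float(WEIGHT_GRID[int(np.argmax(scores))])
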