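"""Synthetic multi-modal brain phantoms.

Every subject is one shared anatomy (nested ellipses: a gray-matter ring, a
white-matter core, a pair of ventricles, optionally a tumor blob) rendered
under two or more contrast profiles.  Because the renderings share the
anatomy pixel-for-pixel, the cohorts behave like spatially aligned paired
modalities: distinct per-tissue contrasts, a smooth multiplicative bias
field emulating acquisition inhomogeneity, and additive Gaussian noise.

The generator is the test bed for the whole toolkit: translation pairs,
labels for segmentation, seven ventricle landmarks, and ground-truth
deformations for registration all come from here, deterministically from a
single integer seed.

What it does not emulate: MR physics (no Bloch equations, no k-space
artifacts), partial-volume mixtures at tissue borders, or real anatomical
variability beyond ellipse jitter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .register import DeformationField
from .synthio import (
    ImageSlice,
    LabelMap,
    LandmarkSet,
    read_landmarks_csv,
    read_slice_png,
    write_landmarks_csv,
    write_slice_png,
)

__all__ = [
    "TISSUES",
    "AnatomyMap",
    "ContrastProfile",
    "Subject",
    "SyntheticCohort",
    "make_anatomy",
    "render_modality",
    "make_deformation",
    "make_cohort",
    "default_profiles",
    "linear_contrast_profiles",
    "low_contrast_profiles",
    "faint_tumor_profiles",
    "save_cohort",
    "load_cohort",
]

#: tissue class ids used in AnatomyMap.tissues
TISSUES = ("background", "wm", "gm", "csf", "tumor")
BG, WM, GM, CSF, TUMOR = range(5)


@dataclass
class AnatomyMap:
    """Per-pixel tissue classes of one subject; reproducible from ``seed``."""

    tissues: np.ndarray
    seed: int

    @property
    def side(self) -> int:
        return self.tissues.shape[0]


@dataclass
class ContrastProfile:
    """Modality rendering recipe: per-tissue mean intensity in [0, 1],
    additive Gaussian noise sd, and multiplicative bias-field amplitude."""

    means: dict[str, float]
    noise_sd: float = 0.02
    bias_amp: float = 0.05
    name: str = ""

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        vals = sorted(self.means.values())
        for a, b in zip(vals, vals[1:]):
            if b - a < 0.05 - 1e-12:
                raise ValueError("per-tissue means must be pairwise distinct by >= 0.05")


@dataclass
class Subject:
    anatomy: AnatomyMap
    images: dict[str, ImageSlice]
    label: LabelMap
    landmarks: LandmarkSet
    seed: int


@dataclass
class SyntheticCohort:
    subjects: list[Subject]
    seed: int
    task: str = "structure"
    modalities: tuple[str, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.subjects)


def _ellipse(side: int, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    yy, xx = np.mgrid[0:side, 0:side]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def make_anatomy(seed: int, side: int, with_tumor: bool = False) -> AnatomyMap:
    """Randomized nested-ellipse brain-like map with a ventricle pair.

    Layout (outside-in): gray-matter ellipse, white-matter ellipse strictly
    inside it, two CSF ventricles inside the white matter.  The optional
    tumor blob is painted only where it overlaps wm/gm.  Deterministic for a
    given seed.
    """
    if side < 32:
        raise ValueError("side must be >= 32")
    rng = np.random.default_rng(seed)
    c = side / 2.0
    jit = lambda s: rng.uniform(-s, s) * side  # noqa: E731

    cy, cx = c + jit(0.02), c + jit(0.02)
    gm_ry, gm_rx = side * rng.uniform(0.38, 0.44), side * rng.uniform(0.32, 0.38)
    wm_ry, wm_rx = gm_ry * rng.uniform(0.68, 0.74), gm_rx * rng.uniform(0.68, 0.74)

    tissues = np.zeros((side, side), dtype=np.int64)
    tissues[_ellipse(side, cy, cx, gm_ry, gm_rx)] = GM
    tissues[_ellipse(side, cy, cx, wm_ry, wm_rx)] = WM

    # ventricle pair: tall narrow ellipses flanking the midline, inside wm
    v_ry = side * rng.uniform(0.09, 0.12)
    v_rx = side * rng.uniform(0.035, 0.05)
    v_dx = side * rng.uniform(0.07, 0.10)
    v_cy = cy + jit(0.01)
    for sgn in (-1, 1):
        vent = _ellipse(side, v_cy, cx + sgn * v_dx, v_ry, v_rx)
        tissues[vent & (tissues == WM)] = CSF

    if with_tumor:
        ang = rng.uniform(0, 2 * np.pi)
        rad = side * rng.uniform(0.16, 0.22)
        t_cy, t_cx = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
        t_r = side * rng.uniform(0.06, 0.09)
        blob = _ellipse(side, t_cy, t_cx, t_r, t_r * rng.uniform(0.8, 1.2))
        tissues[blob & ((tissues == WM) | (tissues == GM))] = TUMOR

    return AnatomyMap(tissues=tissues, seed=seed)


def render_modality(a: AnatomyMap, p: ContrastProfile, seed: int) -> ImageSlice:
    """Render one modality of an anatomy.

    intensity = tissue mean x (1 + bias) + N(0, noise_sd), clipped to [0, 1],
    then mapped to [-1, 1].  The bias field is unit-mean: Gaussian-blurred
    white noise (blur sigma = side/8) scaled to sd ``bias_amp``.
    """
    rng = np.random.default_rng(seed)
    side = a.side
    present = np.unique(a.tissues)
    means = np.zeros(len(TISSUES))
    for t in present:
        name = TISSUES[t]
        if name not in p.means:
            raise ValueError(f"profile missing mean for tissue {name!r}")
        means[t] = p.means[name]
    img = means[a.tissues]

    if p.bias_amp > 0:
        b = gaussian_filter(rng.standard_normal((side, side)), sigma=side / 8.0)
        sd = b.std()
        if sd > 0:
            b = b / sd * p.bias_amp
        img = img * (1.0 + b)
    if p.noise_sd > 0:
        img = img + rng.normal(0.0, p.noise_sd, size=(side, side))
    img = np.clip(img, 0.0, 1.0)
    return ImageSlice(pixels=(img - 0.5) / 0.5, modality=p.name or "synthetic",
                      normalized=True)


def make_deformation(seed: int, side: int, max_disp: float,
                     angle: float | None = None) -> DeformationField:
    """Smooth random displacement field with max vector norm <= max_disp,
    or (``angle`` given, degrees) the exact displacement field of a rotation
    about the image center.

    Fields are backward-warping: ``disp[r, c]`` is the (dy, dx) offset added
    to fixed-space coordinates to sample the moving image.
    """
    if angle is not None:
        th = np.deg2rad(angle)
        c = (side - 1) / 2.0
        yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
        dy = np.cos(th) * (yy - c) - np.sin(th) * (xx - c) + c - yy
        dx = np.sin(th) * (yy - c) + np.cos(th) * (xx - c) + c - xx
        return DeformationField(disp=np.stack([dy, dx], axis=-1))
    if max_disp < 0:
        raise ValueError("max_disp must be >= 0")
    rng = np.random.default_rng(seed)
    disp = gaussian_filter(rng.standard_normal((side, side, 2)),
                           sigma=(side / 8.0, side / 8.0, 0.0))
    norms = np.sqrt((disp ** 2).sum(axis=-1))
    peak = norms.max()
    if peak > 0:
        disp = disp * (max_disp / peak)
    else:
        disp = np.zeros_like(disp)
    return DeformationField(disp=disp)


# ---------------------------------------------------------------------------
# Contrast presets
# ---------------------------------------------------------------------------

def default_profiles() -> tuple[ContrastProfile, ContrastProfile]:
    """A T1-like (wm-bright) and a T2-like (fluid-bright) profile pair."""
    a = ContrastProfile(
        means={"background": 0.02, "wm": 0.75, "gm": 0.55, "csf": 0.15, "tumor": 0.40},
        noise_sd=0.02, bias_amp=0.05, name="A")
    b = ContrastProfile(
        means={"background": 0.02, "wm": 0.35, "gm": 0.50, "csf": 0.90, "tumor": 0.80},
        noise_sd=0.02, bias_amp=0.05, name="B")
    return a, b


def linear_contrast_profiles(slope: float = 0.6, intercept: float = 0.2,
                             noise_sd: float = 0.01) -> tuple[ContrastProfile, ContrastProfile]:
    """Pair where modality B's tissue means are an affine map of modality A's
    (B = slope*A + intercept before noise); used for parameter-recovery
    checks of the translator."""
    means_a = {"background": 0.05, "wm": 0.70, "gm": 0.45, "csf": 0.20}
    means_b = {k: slope * v + intercept for k, v in means_a.items()}
    a = ContrastProfile(means=means_a, noise_sd=noise_sd, bias_amp=0.0, name="A")
    b = ContrastProfile(means=means_b, noise_sd=0.0, bias_amp=0.0, name="B")
    return a, b


def low_contrast_profiles() -> tuple[ContrastProfile, ContrastProfile]:
    """Given modality with weak wm/gm boundary contrast, second modality with
    strong boundary contrast: the registration-fusion scenario."""
    a = ContrastProfile(
        means={"background": 0.02, "wm": 0.50, "gm": 0.44, "csf": 0.15},
        noise_sd=0.06, bias_amp=0.05, name="A")
    b = ContrastProfile(
        means={"background": 0.02, "wm": 0.80, "gm": 0.40, "csf": 0.60},
        noise_sd=0.02, bias_amp=0.05, name="B")
    return a, b


def faint_tumor_profiles() -> tuple[ContrastProfile, ContrastProfile]:
    """Given modality where the tumor is barely above the noise floor,
    second modality where it is bright: the multichannel-segmentation
    scenario."""
    a = ContrastProfile(
        means={"background": 0.02, "wm": 0.50, "gm": 0.40, "csf": 0.15, "tumor": 0.56},
        noise_sd=0.04, bias_amp=0.05, name="A")
    b = ContrastProfile(
        means={"background": 0.02, "wm": 0.35, "gm": 0.45, "csf": 0.70, "tumor": 0.95},
        noise_sd=0.02, bias_amp=0.03, name="B")
    return a, b


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def _ventricle_landmarks(tissues: np.ndarray) -> LandmarkSet:
    """Seven landmarks on the ventricles (superior/inferior/lateral extrema
    of each side plus the middle), stored as (x, y, z) with z = 0."""
    rows, cols = np.nonzero(tissues == CSF)
    cx = tissues.shape[1] / 2.0
    right = cols > cx  # image-right half
    pts: dict[str, tuple[float, float, float]] = {}

    def extreme(mask, key, minimize):
        r, c = rows[mask], cols[mask]
        idx = np.argmin(key(r, c)) if minimize else np.argmax(key(r, c))
        return float(c[idx]), float(r[idx]), 0.0

    pts["L1"] = extreme(right, lambda r, c: r, True)       # right superior
    pts["L2"] = extreme(~right, lambda r, c: r, True)      # left superior
    pts["L3"] = extreme(right, lambda r, c: r, False)      # right inferior
    pts["L4"] = extreme(~right, lambda r, c: r, False)     # left inferior
    # middle: csf pixel nearest the csf centroid (centroid itself falls
    # between the two ventricles, outside csf)
    cen_r, cen_c = rows.mean(), cols.mean()
    k = np.argmin((rows - cen_r) ** 2 + (cols - cen_c) ** 2)
    pts["L5"] = (float(cols[k]), float(rows[k]), 0.0)
    pts["L6"] = extreme(right, lambda r, c: c, False)      # right lateral/posterior
    pts["L7"] = extreme(~right, lambda r, c: c, True)      # left lateral/posterior
    return LandmarkSet(points=pts)


def _label_for_task(tissues: np.ndarray, task: str) -> LabelMap:
    if task == "tumor":
        return LabelMap(classes=(tissues == TUMOR).astype(np.int64),
                        class_names=("background", "tumor"))
    if task == "structure":
        out = np.zeros_like(tissues)
        out[tissues == WM] = 1
        out[tissues == GM] = 2
        out[tissues == CSF] = 3
        return LabelMap(classes=out, class_names=("background", "wm", "gm", "csf"))
    raise ValueError(f"unknown task {task!r}")


def make_cohort(seed: int, n_subjects: int, side: int,
                profiles: tuple[ContrastProfile, ContrastProfile] | None = None,
                task: str = "structure") -> SyntheticCohort:
    """Generate ``n_subjects`` subjects, each with one anatomy, a rendering
    per profile, a task label map, and the L1..L7 ventricle landmarks."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if profiles is None:
        profiles = default_profiles()
    with_tumor = task == "tumor"
    subjects = []
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_subjects):
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        anat = make_anatomy(sub_seed, side, with_tumor=with_tumor)
        images = {}
        for j, prof in enumerate(profiles):
            name = prof.name or f"mod{j}"
            images[name] = render_modality(anat, prof, seed=sub_seed + 1000 + j)
        subjects.append(Subject(
            anatomy=anat, images=images, label=_label_for_task(anat.tissues, task),
            landmarks=_ventricle_landmarks(anat.tissues), seed=sub_seed))
    mods = tuple(p.name or f"mod{j}" for j, p in enumerate(profiles))
    return SyntheticCohort(subjects=subjects, seed=seed, task=task, modalities=mods)


# ---------------------------------------------------------------------------
# On-disk layout: PNG renderings + CSV landmarks + NIfTI-free label PNGs
# ---------------------------------------------------------------------------

def save_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Write a cohort as a directory tree: one subdirectory per subject with
    16-bit PNG renderings, an 8-bit PNG label/anatomy map, landmarks CSV and
    a JSON metadata file."""
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    meta = {"seed": cohort.seed, "task": cohort.task,
            "modalities": list(cohort.modalities),
            "n_subjects": len(cohort.subjects),
            "label_names": list(cohort.subjects[0].label.class_names)}
    (root / "cohort.json").write_text(json.dumps(meta, indent=1))
    for i, sub in enumerate(cohort.subjects):
        d = root / f"subject_{i:03d}"
        d.mkdir(exist_ok=True)
        for name, img in sub.images.items():
            write_slice_png(img, d / f"{name}.png", bits=16)
        Image_label = sub.label.classes.astype(np.uint8)
        from PIL import Image as _PIL
        _PIL.fromarray(Image_label).save(d / "label.png")
        _PIL.fromarray(sub.anatomy.tissues.astype(np.uint8)).save(d / "anatomy.png")
        write_landmarks_csv(sub.landmarks, d / "landmarks.csv")
        (d / "subject.json").write_text(json.dumps({"seed": sub.seed}))


def load_cohort(in_dir) -> SyntheticCohort:
    root = Path(in_dir)
    meta = json.loads((root / "cohort.json").read_text())
    label_names = tuple(meta["label_names"])
    subjects = []
    from PIL import Image as _PIL
    for d in sorted(root.glob("subject_*")):
        images = {m: read_slice_png(d / f"{m}.png", modality=m)
                  for m in meta["modalities"]}
        label = LabelMap(classes=np.asarray(_PIL.open(d / "label.png")).astype(np.int64),
                         class_names=label_names)
        tissues = np.asarray(_PIL.open(d / "anatomy.png")).astype(np.int64)
        sub_seed = json.loads((d / "subject.json").read_text())["seed"]
        subjects.append(Subject(
            anatomy=AnatomyMap(tissues=tissues, seed=sub_seed), images=images,
            label=label, landmarks=read_landmarks_csv(d / "landmarks.csv"),
            seed=sub_seed))
    return SyntheticCohort(subjects=subjects, seed=meta["seed"], task=meta["task"],
                           modalities=tuple(meta["modalities"]))
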