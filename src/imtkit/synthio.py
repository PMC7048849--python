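"""Domain types and the preprocessing pipeline for paired-modality slices.

Raw 3-D volumes are reduced to normalized 2-D training material in three
steps: tumor sub-label merging, z-axis slicing, and square resize followed by
min-max scaling to [0, 1] and the affine map v -> (v - 0.5)/0.5 so every
network input lives in [-1, 1].

Coordinate conventions: volumes are indexed ``voxels[x, y, z]``; slices are
``pixels[row, col]`` with row = y, col = x; landmarks are stored in voxel
units as (x, y, z), 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize as _sk_resize

__all__ = [
    "Volume",
    "ImageSlice",
    "LabelMap",
    "LandmarkSet",
    "slice_z",
    "stack_slices",
    "resize_slice",
    "resize_label",
    "normalize",
    "merge_tumor_labels",
    "crop_and_cube",
    "read_volume",
    "write_volume",
    "read_slice_png",
    "write_slice_png",
    "read_landmarks_csv",
    "write_landmarks_csv",
]

#: BraTS-style tumor sub-classes merged into one "tumor" class:
#: necrosis, edema, non-enhancing tumor, enhancing tumor.
DEFAULT_TUMOR_SUBCLASSES = (1, 2, 3, 4)


@dataclass
class Volume:
    """A 3-D scalar image with physical spacing and a modality tag."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    modality: str = ""

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError("volume must be 3-D with all dims >= 1")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")


@dataclass
class ImageSlice:
    """One 2-D single-channel image; ``normalized`` means pixels in [-1, 1]."""

    pixels: np.ndarray
    modality: str = ""
    normalized: bool = False
    depth_index: int = 0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("slice pixels must be 2-D")
        if self.normalized:
            lo, hi = float(self.pixels.min()), float(self.pixels.max())
            if lo < -1.0 - 1e-9 or hi > 1.0 + 1e-9:
                raise ValueError("normalized slice must lie in [-1, 1]")


@dataclass
class LabelMap:
    """Integer class map per pixel; value i means ``class_names[i]``."""

    classes: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self):
        self.classes = np.asarray(self.classes)
        if self.classes.ndim != 2:
            raise ValueError("label map must be 2-D")
        if not np.issubdtype(self.classes.dtype, np.integer):
            self.classes = self.classes.astype(np.int64)
        if self.classes.size and self.classes.max() >= len(self.class_names):
            raise ValueError("label value exceeds number of class names")
        if self.classes.size and self.classes.min() < 0:
            raise ValueError("label values must be non-negative")

    def mask(self, cls: int) -> np.ndarray:
        return self.classes == cls


@dataclass
class LandmarkSet:
    """Named 3-D points in voxel units, e.g. the L1..L7 ventricle scheme."""

    points: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.points)) != len(self.points):
            raise ValueError("landmark names must be unique")

    def names(self) -> list[str]:
        return list(self.points)


# ---------------------------------------------------------------------------
# Preprocessing operations
# ---------------------------------------------------------------------------

def slice_z(v: Volume) -> list[ImageSlice]:
    """Slice a volume along z into ordered 2-D slices (depth_index = z)."""
    return [
        ImageSlice(pixels=v.voxels[:, :, k].T.copy(), modality=v.modality,
                   depth_index=k)
        for k in range(v.voxels.shape[2])
    ]


def stack_slices(slices: list[ImageSlice], spacing=(1.0, 1.0, 1.0),
                 modality: str = "") -> Volume:
    """Inverse of :func:`slice_z`: restack slices (ordered by depth_index)."""
    ordered = sorted(slices, key=lambda s: s.depth_index)
    vox = np.stack([s.pixels.T for s in ordered], axis=2)
    return Volume(voxels=vox, spacing=spacing, modality=modality or ordered[0].modality)


def resize_slice(s: ImageSlice, side: int) -> ImageSlice:
    """Bilinear resize of an intensity slice to side x side."""
    if side < 8:
        raise ValueError("side must be >= 8")
    out = _sk_resize(s.pixels.astype(np.float64), (side, side), order=1,
                     mode="edge", anti_aliasing=False, preserve_range=True)
    return replace(s, pixels=out)


def resize_label(lm: LabelMap, side: int) -> LabelMap:
    """Nearest-neighbor resize of a label map (classes never interpolate)."""
    if side <= 0:
        raise ValueError("side must be positive")
    out = _sk_resize(lm.classes, (side, side), order=0, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return LabelMap(classes=out.astype(lm.classes.dtype), class_names=lm.class_names)


def normalize(s: ImageSlice) -> ImageSlice:
    """Min-max scale to [0, 1], then map v -> (v - 0.5)/0.5 into [-1, 1].

    A constant slice has zero range; it is mapped to all zeros (mid-gray)
    with a warning so background-only slices survive batch pipelines.
    """
    px = s.pixels.astype(np.float64)
    if not np.all(np.isfinite(px)):
        raise ValueError("slice contains non-finite pixels")
    lo, hi = px.min(), px.max()
    if hi - lo == 0:
        warnings.warn("constant slice normalized to all zeros", stacklevel=2)
        out = np.zeros_like(px)
    else:
        out = ((px - lo) / (hi - lo) - 0.5) / 0.5
    return replace(s, pixels=out, normalized=True)


def merge_tumor_labels(
    raw: LabelMap,
    tumor_subclasses: tuple[int, ...] = DEFAULT_TUMOR_SUBCLASSES,
    keep: dict[int, int] | None = None,
) -> LabelMap:
    """Merge tumor sub-classes (necrosis, edema, non-enhancing, enhancing)
    into a single "tumor" class.

    ``keep`` maps non-tumor input indices to output indices (background 0 is
    always kept; gm/wm style classes pass through it). Any input value not in
    the mapping table raises, naming the offending index.
    """
    mapping: dict[int, int] = {0: 0}
    if keep:
        mapping.update(keep)
    tumor_out = max(mapping.values()) + 1
    for c in tumor_subclasses:
        mapping[c] = tumor_out
    out = np.zeros_like(raw.classes)
    present = np.unique(raw.classes)
    for c in present:
        if int(c) not in mapping:
            raise ValueError(f"unknown class index {int(c)} in label map")
        out[raw.classes == c] = mapping[int(c)]
    names = ["background"] + [f"class{i}" for i in range(1, tumor_out)] + ["tumor"]
    kept_names = {v: raw.class_names[k] for k, v in (keep or {}).items()
                  if k < len(raw.class_names)}
    for v, nm in kept_names.items():
        names[v] = nm
    return LabelMap(classes=out, class_names=tuple(names))


def crop_and_cube(v: Volume, side: int) -> Volume:
    """Crop the tight bounding box of nonzero voxels, resize to side^3."""
    nz = np.nonzero(v.voxels)
    if len(nz[0]) == 0:
        raise ValueError("volume has no nonzero foreground")
    lo = [int(a.min()) for a in nz]
    hi = [int(a.max()) + 1 for a in nz]
    block = v.voxels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].astype(np.float64)
    out = _sk_resize(block, (side, side, side), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return Volume(voxels=out, spacing=v.spacing, modality=v.modality)


# ---------------------------------------------------------------------------
# File formats: NIfTI volumes/labels, PNG slices, CSV landmarks
# ---------------------------------------------------------------------------

def read_volume(path, modality: str = "") -> Volume:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    return Volume(voxels=np.asanyarray(img.dataobj), spacing=tuple(float(z) for z in zooms),
                  modality=modality)


def write_volume(v: Volume, path) -> None:
    affine = np.diag(list(v.spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(v.voxels), affine), str(path))


def write_slice_png(s: ImageSlice, path, bits: int = 16) -> None:
    """Write a slice as 8- or 16-bit grayscale PNG (intensities rescaled
    from [-1, 1] if normalized, else min-max)."""
    px = s.pixels.astype(np.float64)
    if s.normalized:
        unit = (px + 1.0) / 2.0
    else:
        rng = px.max() - px.min()
        unit = (px - px.min()) / rng if rng > 0 else np.zeros_like(px)
    if bits == 8:
        arr = np.round(unit * 255).astype(np.uint8)
    elif bits == 16:
        arr = np.round(unit * 65535).astype(np.uint16)
    else:
        raise ValueError("bits must be 8 or 16")
    Image.fromarray(arr).save(str(path))


def read_slice_png(path, modality: str = "", normalized: bool = True,
                   depth_index: int = 0) -> ImageSlice:
    """Read a grayscale PNG; if ``normalized`` map intensities to [-1, 1]."""
    arr = np.asarray(Image.open(str(path)))
    if arr.ndim != 2:
        raise ValueError("expected single-channel grayscale PNG")
    maxval = 255.0 if arr.dtype == np.uint8 else 65535.0
    px = arr.astype(np.float64) / maxval
    if normalized:
        px = (px - 0.5) / 0.5
    return ImageSlice(pixels=px, modality=modality, normalized=normalized,
                      depth_index=depth_index)


def write_landmarks_csv(lms: LandmarkSet, path) -> None:
    rows = [{"name": n, "x": p[0], "y": p[1], "z": p[2]}
            for n, p in lms.points.items()]
    pd.DataFrame(rows, columns=["name", "x", "y", "z"]).to_csv(str(path), index=False)


def read_landmarks_csv(path) -> LandmarkSet:
    df = pd.read_csv(str(path))
    return LandmarkSet(points={
        str(r["name"]): (float(r["x"]), float(r["y"]), float(r["z"]))
        for _, r in df.iterrows()
    })
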