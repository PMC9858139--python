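"""Image and mask containers, file I/O, intensity normalization, resizing.

Every processing module in :mod:`brainmr` consumes the two carriers defined
here: :class:`Image2D`, a 2-D grayscale intensity matrix with a declared
range, and :class:`BinaryMask`, a same-shaped {0,1} matrix.  MR slices are
treated as single-channel; color inputs are collapsed by unweighted channel
averaging.  Pixels are indexed row-major, 0-based, ``(i, j) = (row, col)``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from PIL import Image as PILImage
from skimage.transform import resize as _sk_resize


class BrainMRError(Exception):
    """Base class for all package errors."""


class DegenerateInputError(BrainMRError):
    """An input is constant/empty where a split or threshold is required."""


class EmptyMaskError(BrainMRError):
    """A refinement step removed every foreground pixel."""


class UnsupportedInputError(BrainMRError):
    """The file is readable but not a supported 2-D grayscale input."""


@dataclass(frozen=True)
class Image2D:
    """An H x W matrix of real intensities with a declared intensity range.

    Parameters
    ----------
    pixels : ndarray, shape (H, W)
        Finite real intensities.
    range : (float, float)
        Declared closed intensity interval, e.g. ``(0, 255)`` or ``(0, 1)``.
        All pixels must lie within it.
    name : str
        Provenance string (file path, generator tag, ...).
    """

    pixels: np.ndarray
    range: tuple[float, float] = (0.0, 255.0)
    name: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"Image2D needs a 2-D HxW matrix, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("Image2D pixels must be finite")
        lo, hi = self.range
        if not (lo < hi):
            raise ValueError(f"invalid intensity range {self.range}")
        if px.min() < lo - 1e-9 or px.max() > hi + 1e-9:
            raise ValueError(
                f"pixels [{px.min()}, {px.max()}] outside declared range {self.range}"
            )
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "range", (float(lo), float(hi)))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class BinaryMask:
    """An H x W matrix over {0, 1}."""

    pixels: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"BinaryMask needs a 2-D matrix, got shape {px.shape}")
        vals = np.unique(px)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"BinaryMask values must be 0/1, got {vals[:10]}")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def area(self) -> int:
        return int(self.pixels.sum())


NORMAL = "normal"
ABNORMAL = "abnormal"


@dataclass
class LabeledDataset:
    """Parallel images / {normal, abnormal} labels / optional truth masks."""

    images: list[Image2D]
    labels: list[str]
    masks: list[BinaryMask | None] = field(default_factory=list)
    #: index of the original sample each image derives from (augmentation
    #: bookkeeping; identity when the dataset holds only originals).
    groups: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels must be parallel")
        bad = set(self.labels) - {NORMAL, ABNORMAL}
        if bad:
            raise ValueError(f"labels must be normal/abnormal, got {bad}")
        if not self.masks:
            self.masks = [None] * len(self.images)
        if len(self.masks) != len(self.images):
            raise ValueError("masks must parallel images")
        if not self.groups:
            self.groups = list(range(len(self.images)))
        if len(self.groups) != len(self.images):
            raise ValueError("groups must parallel images")

    def __len__(self) -> int:
        return len(self.images)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def load_image(path: str | os.PathLike) -> Image2D:
    """Read a PNG/JPEG/TIFF or single-slice NIfTI file as a grayscale image.

    Multi-channel inputs are collapsed by unweighted channel averaging.  The
    declared range follows the storage dtype: [0, 255] for 8-bit data,
    [0, 65535] for 16-bit.
    """
    spath = os.fspath(path)
    if not os.path.exists(spath):
        raise IOError(f"no such image file: {spath}")
    if spath.endswith(_NIFTI_SUFFIXES):
        return _load_nifti(spath)
    try:
        with PILImage.open(spath) as im:
            arr = np.asarray(im)
    except Exception as exc:  # pragma: no cover - format-specific messages
        raise IOError(f"could not read image {spath}: {exc}") from exc
    if arr.ndim == 3:
        arr = arr.astype(np.float64).mean(axis=2)
    elif arr.ndim != 2:
        raise UnsupportedInputError(f"{spath}: expected 2-D image, got {arr.shape}")
    hi = 65535.0 if arr.max() > 255 or np.asarray(arr).dtype.itemsize > 1 else 255.0
    return Image2D(arr.astype(np.float64), range=(0.0, hi), name=spath)


def _load_nifti(path: str) -> Image2D:
    import nibabel as nib

    vol = np.asanyarray(nib.load(path).dataobj)
    vol = np.squeeze(vol)
    if vol.ndim != 2:
        raise UnsupportedInputError(
            f"{path}: volumetric NIfTI with shape {vol.shape}; only single slices supported"
        )
    vol = vol.astype(np.float64)
    lo = min(0.0, float(vol.min()))
    hi = max(255.0, float(vol.max()))
    return Image2D(vol, range=(lo, hi), name=path)


def save_image(img: Image2D, path: str | os.PathLike) -> None:
    """Write an image to 8-bit PNG (lossless for integer [0,255] data)."""
    arr = np.clip(np.round(img.pixels), 0, 255).astype(np.uint8)
    try:
        PILImage.fromarray(arr, mode="L").save(os.fspath(path))
    except OSError as exc:
        raise IOError(f"cannot write image to {os.fspath(path)}: {exc}") from exc


def save_mask(mask: BinaryMask, path: str | os.PathLike) -> None:
    """Write a mask as 8-bit PNG with {0,1} mapped to {0,255}."""
    try:
        PILImage.fromarray(mask.pixels * 255, mode="L").save(os.fspath(path))
    except OSError as exc:
        raise IOError(f"cannot write mask to {os.fspath(path)}: {exc}") from exc


def load_mask(path: str | os.PathLike) -> BinaryMask:
    """Read an 8-bit PNG mask, mapping {0,255} back to {0,1}."""
    img = load_image(path)
    return BinaryMask((img.pixels > 127).astype(np.uint8), name=img.name)


# ---------------------------------------------------------------------------
# Intensity and geometry plumbing
# ---------------------------------------------------------------------------

def normalize(img: Image2D, target: tuple[float, float] = (0.0, 1.0)) -> Image2D:
    """Affinely map ``[min(img), max(img)]`` onto ``target``.

    A constant image maps to the target lower bound.
    """
    px = img.pixels
    if px.size == 0:
        raise DegenerateInputError("cannot normalize an empty image")
    lo, hi = float(px.min()), float(px.max())
    tlo, thi = float(target[0]), float(target[1])
    if hi == lo:
        out = np.full_like(px, tlo)
    else:
        out = (px - lo) * ((thi - tlo) / (hi - lo)) + tlo
        out = np.clip(out, min(tlo, thi), max(tlo, thi))
    return Image2D(out, range=(tlo, thi), name=img.name)


def rescale_range(img: Image2D, target: tuple[float, float] = (0.0, 1.0)) -> Image2D:
    """Map the *declared* range onto ``target`` (not the observed min/max).

    This is the scale change processing modules use (e.g. an 8-bit slice to
    the [0,1] scale by dividing by 255) — it preserves absolute contrast,
    unlike :func:`normalize` which stretches the observed range.
    """
    lo, hi = img.range
    tlo, thi = float(target[0]), float(target[1])
    out = (img.pixels - lo) * ((thi - tlo) / (hi - lo)) + tlo
    return Image2D(out, range=(tlo, thi), name=img.name)


def resize(img: Image2D, h: int, w: int) -> Image2D:
    """Bilinear resample to ``h x w`` (pixel-center aligned sampling)."""
    if h < 1 or w < 1:
        raise ValueError(f"target size must be positive, got {(h, w)}")
    if (h, w) == img.shape:
        return img
    out = _sk_resize(
        img.pixels, (h, w), order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    out = np.clip(out, img.range[0], img.range[1])
    return Image2D(out, range=img.range, name=img.name)


def to_gray_stack(img: Image2D, size: int) -> np.ndarray:
    """Resize and replicate a slice to ``(size, size, 3)`` float32 in [0,1].

    The CNN input contract is 3-channel; MR slices are single-channel, so the
    gray plane is replicated.
    """
    r = resize(img, size, size)
    plane = rescale_range(r, (0.0, 1.0)).pixels.astype(np.float32)
    return np.repeat(plane[:, :, None], 3, axis=2)


def labels_to_int(labels: Sequence[str]) -> np.ndarray:
    """Map normal->0, abnormal->1 (abnormal is the positive class)."""
    return np.array([1 if lb == ABNORMAL else 0 for lb in labels], dtype=np.int64)
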