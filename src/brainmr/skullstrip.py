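"""Skull-stripping by separability thresholding plus morphological refinement.

The slice is split into a dark region R1 and a bright region R2 at Otsu's
threshold; their separability

    H = (m1 - m2)^2 / (s1^2 + s2^2)

(population variances, with a small guard added to the denominator) sets the
binarization level ``Topt = clamp((H + min(I))/2 / 255, 0, 1)``.  The binary
head mask is then refined: area opening, hole filling, erosion by a disk,
and largest-component selection.  Because the skull ring is separated from
the parenchyma by a dark rim (CSF/meninges on T2), the largest surviving
component is the brain, and masking the original with it zeroes all
non-brain matter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion, binary_fill_holes
from skimage.measure import label
from skimage.morphology import disk

from .core_io import (
    BinaryMask,
    DegenerateInputError,
    EmptyMaskError,
    Image2D,
)
from .flmscm import otsu_threshold

logger = logging.getLogger(__name__)

#: reference area the default morphology parameters were chosen for
_REF_AREA = 256 * 256


@dataclass(frozen=True)
class SkullStripConfig:
    """Morphology settings; defaults suit ~256x256 slices and scale with area."""

    se_radius: int = 5     # disk structuring-element radius for erosion (px)
    min_area: int = 300    # area-opening threshold (px) at 256x256
    eps: float = 1e-6      # variance guard in the separability ratio
    scale_with_area: bool = True

    def __post_init__(self) -> None:
        if self.se_radius < 1:
            raise ValueError("se_radius must be >= 1")
        if self.min_area < 0:
            raise ValueError("min_area must be >= 0")
        if self.eps <= 0:
            raise ValueError("eps must be positive")

    def scaled(self, shape: tuple[int, int]) -> "SkullStripConfig":
        if not self.scale_with_area:
            return self
        factor = (shape[0] * shape[1]) / _REF_AREA
        return SkullStripConfig(
            se_radius=max(1, int(round(self.se_radius * np.sqrt(factor)))),
            min_area=int(round(self.min_area * factor)),
            eps=self.eps,
            scale_with_area=False,
        )


@dataclass(frozen=True)
class ThresholdReport:
    t_split: float   # the R1/R2 split intensity (Otsu)
    m1: float
    m2: float
    s1sq: float
    s2sq: float
    H: float         # separability (m1-m2)^2/(s1^2+s2^2+eps)
    T: float         # raw threshold (H + min(I))/2
    Topt: float      # normalized threshold, clamped to [0, 1]


@dataclass(frozen=True)
class SkullStripResult:
    brain_mask: BinaryMask
    stripped: Image2D
    report: ThresholdReport


def compute_threshold(img: Image2D, eps: float = 1e-6) -> ThresholdReport:
    """Separability threshold on a [0,255]-scale image."""
    px = img.pixels
    if float(px.max()) == float(px.min()):
        raise DegenerateInputError("separability threshold undefined on a constant image")
    t = otsu_threshold(px)
    r1 = px[px < t]
    r2 = px[px >= t]
    if r1.size == 0 or r2.size == 0:  # pragma: no cover - Otsu always splits
        raise DegenerateInputError("threshold produced an empty region")
    m1, m2 = float(r1.mean()), float(r2.mean())
    s1sq, s2sq = float(r1.var()), float(r2.var())     # population variances
    H = (m1 - m2) ** 2 / (s1sq + s2sq + eps)
    T = (H + float(px.min())) / 2.0
    topt = float(np.clip(T / 255.0, 0.0, 1.0))
    rep = ThresholdReport(t_split=t, m1=m1, m2=m2, s1sq=s1sq, s2sq=s2sq,
                          H=H, T=T, Topt=topt)
    logger.info("skullstrip t_split=%.3f m1=%.3f m2=%.3f H=%.3f T=%.3f Topt=%.4f",
                t, m1, m2, H, T, topt)
    return rep


def binarize(img: Image2D, topt: float) -> BinaryMask:
    """Head mask: 1 where ``img/255 > Topt``."""
    if not 0.0 <= topt <= 1.0:
        raise ValueError(f"Topt must lie in [0, 1], got {topt}")
    return BinaryMask((img.pixels / 255.0 > topt).astype(np.uint8), name=img.name)


def refine_mask(mask: BinaryMask, cfg: SkullStripConfig | None = None) -> BinaryMask:
    """Area opening -> hole filling -> disk erosion -> keep largest component.

    8-connectivity throughout.  Raises :class:`EmptyMaskError` if nothing
    survives (failed stripping).
    """
    cfg = (cfg or SkullStripConfig()).scaled(mask.shape)
    m = mask.pixels.astype(bool)
    if cfg.min_area > 0:
        lab, ncomp = label(m, connectivity=2, return_num=True)
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        m = (sizes >= cfg.min_area)[lab]
    m = binary_fill_holes(m, structure=np.ones((3, 3), dtype=bool))
    m = binary_erosion(m, structure=disk(cfg.se_radius).astype(bool))
    if not m.any():
        raise EmptyMaskError("mask refinement removed every pixel")
    lab, ncomp = label(m, connectivity=2, return_num=True)
    if ncomp > 1:
        sizes = np.bincount(lab.ravel())[1:]
        m = lab == (int(np.argmax(sizes)) + 1)
    return BinaryMask(m.astype(np.uint8), name=mask.name)


def skull_strip(img: Image2D, cfg: SkullStripConfig | None = None) -> SkullStripResult:
    """Full pipeline: threshold -> binarize -> refine -> zero outside mask."""
    cfg = cfg or SkullStripConfig()
    report = compute_threshold(img, cfg.eps)
    head = binarize(img, report.Topt)
    if head.area == 0:
        raise EmptyMaskError("binarization produced an empty head mask")
    brain = refine_mask(head, cfg)
    stripped = Image2D(img.pixels * brain.pixels, range=img.range, name=img.name)
    return SkullStripResult(brain_mask=brain, stripped=stripped, report=report)
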