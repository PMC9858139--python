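"""Synthetic T2-like brain phantoms with exact ground-truth masks.

A phantom is a 2-D slice with four intensity classes painted on a dark
background: an elliptical brain disc of mid intensity, a bright skull ring
separated from the brain by a dark rim (the CSF/meninges gap seen on T2),
and — for abnormal samples — a hyperintense elliptical tumor blob strictly
interior to the brain.  Gaussian noise (clipped to the intensity range) is
added after painting, so the skull/brain/tumor masks remain exact by
construction.  Phantoms stand in for T2-weighted axial slices in every test:
they reproduce the intensity ordering (tumor brighter than parenchyma,
skull brightest) and the ring/disc topology the pipeline relies on, but none
of the anatomy, texture or MR noise statistics of real acquisitions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core_io import ABNORMAL, NORMAL, BinaryMask, Image2D, LabeledDataset


@dataclass(frozen=True)
class PhantomConfig:
    size: tuple[int, int] = (256, 256)
    background_intensity: float = 0.0
    brain_intensity: float = 110.0
    tumor_intensity: float = 200.0
    skull_intensity: float = 230.0
    brain_radius: float | None = None      # default: 0.31 * min(size)
    skull_gap: float | None = None         # dark rim width; default 3% of min(size)
    skull_thickness: float | None = None   # default 2.5% of min(size)
    skull_break_deg: float = 30.0          # angular opening in the ring (foramen)
    tumor_radius_range: tuple[float, float] | None = None  # default (6%, 10%) of min(size)
    tumor_present: bool = True
    noise_sigma: float = 3.0               # on the 0-255 scale
    jitter: float = 0.10                   # relative geometry jitter
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tumor_intensity > self.brain_intensity:
            raise ValueError("tumor must be hyperintense relative to brain (T2)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    def resolved(self) -> "PhantomConfig":
        s = min(self.size)
        return replace(
            self,
            brain_radius=self.brain_radius if self.brain_radius is not None else 0.31 * s,
            skull_gap=self.skull_gap if self.skull_gap is not None else 0.03 * s,
            skull_thickness=(self.skull_thickness if self.skull_thickness is not None
                             else 0.025 * s),
            tumor_radius_range=(self.tumor_radius_range if self.tumor_radius_range
                                is not None else (0.06 * s, 0.10 * s)),
        )


@dataclass(frozen=True)
class PhantomSample:
    image: Image2D
    skull_mask: BinaryMask
    brain_mask: BinaryMask
    tumor_mask: BinaryMask
    label: str


def _ellipse(shape: tuple[int, int], center: tuple[float, float],
             radii: tuple[float, float], theta: float = 0.0) -> np.ndarray:
    ii, jj = np.mgrid[0:shape[0], 0:shape[1]].astype(np.float64)
    di, dj = ii - center[0], jj - center[1]
    c, s = np.cos(theta), np.sin(theta)
    u = c * di + s * dj
    v = -s * di + c * dj
    return (u / radii[0]) ** 2 + (v / radii[1]) ** 2 <= 1.0


def make_phantom(cfg: PhantomConfig | None = None,
                 rng: np.random.Generator | None = None) -> PhantomSample:
    """Paint one phantom; deterministic under ``cfg.seed`` when ``rng`` is None."""
    cfg = (cfg or PhantomConfig()).resolved()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    H, W = cfg.size
    j = cfg.jitter

    def jit(x: float) -> float:
        return float(x * (1.0 + rng.uniform(-j, j)))

    center = (H / 2 + rng.uniform(-j, j) * H * 0.05,
              W / 2 + rng.uniform(-j, j) * W * 0.05)
    br = (jit(cfg.brain_radius), jit(cfg.brain_radius * 0.88))
    theta = rng.uniform(0, np.pi)
    brain = _ellipse((H, W), center, br, theta)

    gap = jit(cfg.skull_gap)
    thick = jit(cfg.skull_thickness)
    inner = _ellipse((H, W), center, (br[0] + gap, br[1] + gap), theta)
    outer = _ellipse((H, W), center, (br[0] + gap + thick, br[1] + gap + thick), theta)
    skull = outer & ~inner
    if cfg.skull_break_deg > 0:
        # angular opening (foramen-like) so the ring is not a closed curve
        ii, jj = np.mgrid[0:H, 0:W].astype(np.float64)
        ang = np.arctan2(ii - center[0], jj - center[1])
        a0 = rng.uniform(-np.pi, np.pi)
        half = np.deg2rad(cfg.skull_break_deg) / 2.0
        diff = np.angle(np.exp(1j * (ang - a0)))
        skull &= np.abs(diff) > half

    tumor = np.zeros((H, W), dtype=bool)
    if cfg.tumor_present:
        r_lo, r_hi = cfg.tumor_radius_range
        tr = (rng.uniform(r_lo, r_hi), rng.uniform(r_lo, r_hi))
        margin = max(tr) + 2.0
        # place the tumor center so the whole blob stays inside the brain disc
        rad = rng.uniform(0, 1.0) * (min(br) - margin)
        ang = rng.uniform(0, 2 * np.pi)
        tc = (center[0] + rad * np.cos(ang), center[1] + rad * np.sin(ang))
        tumor = _ellipse((H, W), tc, tr, rng.uniform(0, np.pi)) & brain

    img = np.full((H, W), cfg.background_intensity, dtype=np.float64)
    img[brain] = cfg.brain_intensity
    img[tumor] = cfg.tumor_intensity
    img[skull] = cfg.skull_intensity
    if cfg.noise_sigma > 0:
        img = img + rng.normal(0.0, cfg.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 255.0)

    label = ABNORMAL if cfg.tumor_present else NORMAL
    return PhantomSample(
        image=Image2D(img, range=(0.0, 255.0), name=f"phantom-{label}"),
        skull_mask=BinaryMask(skull.astype(np.uint8)),
        brain_mask=BinaryMask(brain.astype(np.uint8)),
        tumor_mask=BinaryMask(tumor.astype(np.uint8)),
        label=label,
    )


def make_dataset(n_normal: int, n_abnormal: int,
                 cfg: PhantomConfig | None = None) -> LabeledDataset:
    """A labeled phantom cohort with per-sample jittered geometry.

    Ground-truth tumor masks are retained for abnormal samples (None for
    normal ones).  Deterministic under ``cfg.seed``.
    """
    cfg = cfg or PhantomConfig()
    rng = np.random.default_rng(cfg.seed)
    images: list[Image2D] = []
    labels: list[str] = []
    masks: list[BinaryMask | None] = []
    for k in range(n_normal + n_abnormal):
        tumor = k >= n_normal
        sample = make_phantom(replace(cfg, tumor_present=tumor), rng=rng)
        images.append(sample.image)
        labels.append(sample.label)
        masks.append(sample.tumor_mask if tumor else None)
    return LabeledDataset(images=images, labels=labels, masks=masks)
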