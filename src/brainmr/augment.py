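"""Seeded geometric augmentation: rotation, translation, reflection, scaling,
shear — expanding a dataset by a fixed per-image multiplicity.

Each output is either the original or a random affine warp whose parameters
are drawn uniformly from the configured intervals; the operators compose in
the fixed order reflect -> rotate -> shear -> scale -> translate, about the
image center.  Warps are bilinear with zero (background) fill.  With the
default multiplicity of 9, 60 normal / 125 abnormal originals expand to
540 / 1125 images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import affine_transform

from .core_io import Image2D, LabeledDataset


@dataclass(frozen=True)
class AugmentConfig:
    rotation_deg: tuple[float, float] = (-30.0, 30.0)
    translate_px: tuple[float, float] = (-10.0, 10.0)   # per axis
    reflect_prob: float = 0.5                           # per axis
    scale: tuple[float, float] = (0.5, 4.0)             # uniform zoom
    shear_deg: tuple[float, float] = (0.0, 30.0)        # per axis
    per_image: int = 9        # outputs per original, counting the original
    seed: int = 0
    single_op: bool = False   # draw exactly one operator per output instead

    def __post_init__(self) -> None:
        if self.per_image < 1:
            raise ValueError("per_image must be >= 1")
        if not 0.0 <= self.reflect_prob <= 1.0:
            raise ValueError("reflect_prob must lie in [0, 1]")


@dataclass(frozen=True)
class AffineTransform2D:
    """Forward map ``p_out = A (p_in - c) + c + t`` in (x=col, y=row) coords."""

    A: np.ndarray                       # 2x2 linear part
    t: tuple[float, float] = (0.0, 0.0)  # (tx, ty) pixels
    reflect_x: bool = False
    reflect_y: bool = False
    params: dict = field(default_factory=dict)

    @property
    def matrix(self) -> np.ndarray:
        """2x3 matrix [A | t] in (x, y) convention."""
        return np.hstack([self.A, np.asarray(self.t, dtype=np.float64)[:, None]])


def _rot(deg: float) -> np.ndarray:
    r = np.deg2rad(deg)
    c, s = np.cos(r), np.sin(r)
    return np.array([[c, -s], [s, c]])


def _shear(deg_x: float, deg_y: float) -> np.ndarray:
    return np.array([[1.0, np.tan(np.deg2rad(deg_x))],
                     [np.tan(np.deg2rad(deg_y)), 1.0]])


def _reflect(fx: bool, fy: bool) -> np.ndarray:
    return np.diag([-1.0 if fx else 1.0, -1.0 if fy else 1.0])


def random_transform(cfg: AugmentConfig, rng: np.random.Generator) -> AffineTransform2D:
    """Draw one transform; parameters uniform over the configured intervals."""
    if cfg.single_op:
        op = rng.integers(5)
        rot = rng.uniform(*cfg.rotation_deg) if op == 0 else 0.0
        tx, ty = (rng.uniform(*cfg.translate_px, size=2) if op == 1 else (0.0, 0.0))
        fx, fy = ((rng.random() < cfg.reflect_prob,
                   rng.random() < cfg.reflect_prob) if op == 2 else (False, False))
        sc = rng.uniform(*cfg.scale) if op == 3 else 1.0
        shx, shy = (rng.uniform(*cfg.shear_deg, size=2) if op == 4 else (0.0, 0.0))
    else:
        rot = rng.uniform(*cfg.rotation_deg)
        tx, ty = rng.uniform(*cfg.translate_px, size=2)
        fx = bool(rng.random() < cfg.reflect_prob)
        fy = bool(rng.random() < cfg.reflect_prob)
        sc = rng.uniform(*cfg.scale)
        shx, shy = rng.uniform(*cfg.shear_deg, size=2)
    # fixed composition order: reflect -> rotate -> shear -> scale -> translate
    A = (sc * np.eye(2)) @ _shear(shx, shy) @ _rot(rot) @ _reflect(fx, fy)
    return AffineTransform2D(
        A=A, t=(float(tx), float(ty)), reflect_x=fx, reflect_y=fy,
        params=dict(rotation_deg=float(rot), translate=(float(tx), float(ty)),
                    reflect=(fx, fy), scale=float(sc),
                    shear_deg=(float(shx), float(shy))),
    )


def identity_transform() -> AffineTransform2D:
    return AffineTransform2D(A=np.eye(2))


def apply_transform(img: Image2D, t: AffineTransform2D) -> Image2D:
    """Bilinear warp; same output shape, out-of-frame pixels filled with 0."""
    H, W = img.shape
    # convert the (x, y) linear part to (row, col) index convention
    P = np.array([[0.0, 1.0], [1.0, 0.0]])
    A_rc = P @ t.A @ P
    c = np.array([(H - 1) / 2.0, (W - 1) / 2.0])
    shift = np.array([t.t[1], t.t[0]])          # (ty, tx) -> (row, col)
    Ainv = np.linalg.inv(A_rc)
    # inverse map: p_in = Ainv @ p_out + (c - Ainv @ (c + shift))
    out = affine_transform(
        img.pixels, matrix=Ainv, offset=c - Ainv @ (c + shift),
        order=1, mode="constant", cval=0.0,
    )
    out = np.clip(out, img.range[0], img.range[1])
    return Image2D(out, range=img.range, name=img.name)


def augment_dataset(ds: LabeledDataset, cfg: AugmentConfig) -> LabeledDataset:
    """Expand every image to ``per_image`` outputs (original + warps).

    Labels are copied; ground-truth masks are kept on the originals only
    (augmented variants serve classification, not segmentation evaluation).
    ``groups`` records the original index of every output so cross-validation
    can keep all variants of one original in the same fold.
    """
    if len(ds) == 0:
        raise ValueError("cannot augment an empty dataset")
    rng = np.random.default_rng(cfg.seed)
    images: list[Image2D] = []
    labels: list[str] = []
    masks: list = []
    groups: list[int] = []
    for idx, (img, lab, msk) in enumerate(zip(ds.images, ds.labels, ds.masks)):
        images.append(img)
        labels.append(lab)
        masks.append(msk)
        groups.append(ds.groups[idx])
        for _ in range(cfg.per_image - 1):
            images.append(apply_transform(img, random_transform(cfg, rng)))
            labels.append(lab)
            masks.append(None)
            groups.append(ds.groups[idx])
    return LabeledDataset(images=images, labels=labels, masks=masks, groups=groups)
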