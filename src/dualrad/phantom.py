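"""Synthetic breast-ultrasound phantoms.

Generates speckled grayscale images with hypoechoic lesions and paired binary
masks, emulating the statistical structure of a clinical breast-ultrasound
cohort (benign / malignant / normal classes): benign lesions are smooth
ellipses, malignant lesions carry a spiculated (radially perturbed) boundary
and optional posterior shadowing, normal images contain no lesion.

The speckle model is first-order: a smooth tissue background modulated by a
multiplicative Rayleigh field.  This is not an acoustic simulation; it is
sufficient for intensity and texture radiomics to be nondegenerate and for a
segmentation model to learn the task at desktop scale.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

LABELS = ("benign", "malignant", "normal")
_LABEL_CODE = {"benign": 1, "malignant": 2, "normal": 3}


class PhantomError(ValueError):
    """Raised for invalid phantom configuration or labels."""


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the synthetic cohort.

    Default class counts mirror a 780-image clinical cohort
    (437 benign / 210 malignant / 133 normal).
    """

    image_size: int = 512
    n_benign: int = 437
    n_malignant: int = 210
    n_normal: int = 133
    speckle_scale: float = 0.4
    lesion_area_range: Tuple[float, float] = (0.02, 0.20)
    spiculation_amplitude: float = 0.25
    lesion_contrast: float = 0.5    # multiplier on background inside lesion (hypoechoic)
    center_jitter: float = 1.0      # 0 = always centered, 1 = anywhere within margins
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise PhantomError(f"image_size must be >= 32, got {self.image_size}")
        for name in ("n_benign", "n_malignant", "n_normal"):
            if getattr(self, name) < 0:
                raise PhantomError(f"{name} must be nonnegative")
        if self.speckle_scale <= 0:
            raise PhantomError("speckle_scale must be positive")
        lo, hi = self.lesion_area_range
        if not (0.0 < lo <= hi < 1.0):
            raise PhantomError(
                f"lesion_area_range must be ordered and within (0, 1), got {self.lesion_area_range}"
            )
        if self.spiculation_amplitude < 0:
            raise PhantomError("spiculation_amplitude must be nonnegative")

    def replace(self, **kw) -> "PhantomConfig":
        return dataclasses.replace(self, **kw)

    @classmethod
    def easy_segmentation(cls, n_benign: int = 30, n_malignant: int = 30,
                          seed: int = 0) -> "PhantomConfig":
        """A deliberately easy configuration used for desk-scale segmentation
        benchmarks: small images, large central high-contrast lesions, mild
        speckle.  Lesion geometry still differs between classes."""
        return cls(
            image_size=64,
            n_benign=n_benign,
            n_malignant=n_malignant,
            n_normal=0,
            speckle_scale=0.2,
            lesion_area_range=(0.10, 0.22),
            spiculation_amplitude=0.15,
            lesion_contrast=0.35,
            center_jitter=0.15,
            seed=seed,
        )


@dataclass
class UltrasoundSample:
    """One grayscale image with its lesion mask and diagnosis label."""

    id: str
    image: np.ndarray   # float32 in [0, 1], shape (H, W)
    mask: np.ndarray    # uint8 in {0, 1}, shape (H, W)
    label: str

    def validate(self) -> None:
        if self.mask.shape != self.image.shape:
            raise PhantomError(f"{self.id}: mask shape {self.mask.shape} != image shape")
        vals = np.unique(self.mask)
        if not np.all(np.isin(vals, [0, 1])):
            raise PhantomError(f"{self.id}: mask values must be binary")
        if self.label == "normal":
            if self.mask.any():
                raise PhantomError(f"{self.id}: normal sample must have empty mask")
        else:
            if not self.mask.any():
                raise PhantomError(f"{self.id}: abnormal sample must have a lesion")


def _case_rng(cfg: PhantomConfig, case_index: int, label: str) -> np.random.Generator:
    ss = np.random.SeedSequence([cfg.seed, case_index, _LABEL_CODE[label]])
    return np.random.default_rng(ss)


def _background(size: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth tissue base: mean level + depth gradient + large-scale variation."""
    depth = np.linspace(0.0, 1.0, size)[:, None]
    base = 0.55 + 0.08 * (0.5 - depth)          # slight attenuation with depth
    field = rng.standard_normal((size, size))
    field = gaussian_filter(field, sigma=size / 8.0, mode="reflect")
    sd = field.std()
    if sd > 0:
        base = base + 0.06 * field / sd
    return base.astype(np.float64)


def _lesion_mask(size: int, rng: np.random.Generator, cfg: PhantomConfig,
                 spiculated: bool) -> np.ndarray:
    """Star-convex lesion support: ellipse, optionally with a radial sinusoidal
    boundary perturbation.  The perturbation is renormalized so the enclosed
    area is preserved in expectation."""
    area_frac = rng.uniform(*cfg.lesion_area_range)
    target_area = area_frac * size * size
    ratio = rng.uniform(0.55, 0.95)             # minor/major axis ratio
    a = np.sqrt(target_area / (np.pi * ratio))  # semi-major (pixels)
    b = a * ratio
    theta0 = rng.uniform(0, np.pi)

    amp = cfg.spiculation_amplitude if spiculated else 0.0
    n_spic = rng.integers(7, 13)
    phase = rng.uniform(0, 2 * np.pi)
    norm = np.sqrt(1.0 + amp * amp / 2.0)       # keeps area at target under perturbation

    margin = a * (1 + amp) / norm + 2.0
    lo = margin
    hi = size - margin
    if hi <= lo:          # lesion nearly fills the frame; pin to center
        cx = cy = size / 2.0
    else:
        mid = size / 2.0
        half = (hi - lo) / 2.0 * cfg.center_jitter
        cx = rng.uniform(mid - half, mid + half)
        cy = rng.uniform(mid - half, mid + half)

    yy, xx = np.mgrid[0:size, 0:size]
    dx = xx - cx
    dy = yy - cy
    ct, st = np.cos(theta0), np.sin(theta0)
    u = ct * dx + st * dy
    v = -st * dx + ct * dy
    phi = np.arctan2(v, u)
    # elliptical boundary radius at angle phi (polar form about the center)
    r_ell = (a * b) / np.sqrt((b * np.cos(phi)) ** 2 + (a * np.sin(phi)) ** 2)
    r_bound = r_ell * (1.0 + amp * np.sin(n_spic * phi + phase)) / norm
    dist = np.sqrt(dx * dx + dy * dy)
    return (dist <= r_bound).astype(np.uint8)


def generate_phantom(label: str, cfg: PhantomConfig, case_index: int) -> UltrasoundSample:
    """Generate one phantom, fully determined by (cfg.seed, case_index, label)."""
    if label not in LABELS:
        raise PhantomError(f"invalid label {label!r}; must be one of {LABELS}")
    rng = _case_rng(cfg, case_index, label)
    size = cfg.image_size
    base = _background(size, rng)

    if label == "normal":
        mask = np.zeros((size, size), dtype=np.uint8)
    else:
        mask = _lesion_mask(size, rng, cfg, spiculated=(label == "malignant"))
        soft = gaussian_filter(mask.astype(np.float64), sigma=1.5, mode="constant")
        base = base * (1.0 - (1.0 - cfg.lesion_contrast) * np.clip(soft, 0, 1))
        if label == "malignant" and rng.uniform() < 0.5:
            # posterior acoustic shadowing below the lesion
            cols = mask.any(axis=0)
            rows = np.where(mask.any(axis=1))[0]
            bottom = rows[-1]
            shadow = np.ones((size, size))
            fade = np.clip((np.arange(size) - bottom) / 6.0, 0, 1)[:, None]
            shadow -= 0.12 * fade * cols[None, :]
            base = base * shadow

    speckle = rng.rayleigh(scale=np.sqrt(2.0 / np.pi), size=(size, size))
    speckle = gaussian_filter(speckle, sigma=0.7, mode="reflect")
    speckle /= speckle.mean()
    img = base * ((1.0 - cfg.speckle_scale) + cfg.speckle_scale * speckle)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)

    sample = UltrasoundSample(
        id=f"{label}_{case_index:04d}", image=img, mask=mask, label=label
    )
    sample.validate()
    return sample


def generate_cohort(cfg: PhantomConfig) -> Tuple[List[UltrasoundSample], pd.DataFrame]:
    """Generate the full cohort plus a manifest (id, label, area_fraction)."""
    total = cfg.n_benign + cfg.n_malignant + cfg.n_normal
    if total == 0:
        raise PhantomError("cohort is empty: all class counts are zero")
    samples: List[UltrasoundSample] = []
    rows = []
    case_index = 0
    for label, count in (("benign", cfg.n_benign),
                         ("malignant", cfg.n_malignant),
                         ("normal", cfg.n_normal)):
        for _ in range(count):
            s = generate_phantom(label, cfg, case_index)
            samples.append(s)
            rows.append({
                "id": s.id,
                "label": s.label,
                "area_fraction": float(s.mask.mean()),
            })
            case_index += 1
    manifest = pd.DataFrame(rows, columns=["id", "label", "area_fraction"])
    return samples, manifest


def boundary_roughness(mask: np.ndarray) -> float:
    """perimeter^2 / area of a binary mask; larger for spiculated boundaries."""
    from skimage.measure import perimeter as _perimeter

    area = float(mask.sum())
    if area == 0:
        raise PhantomError("boundary_roughness of an empty mask is undefined")
    p = float(_perimeter(mask, neighborhood=8))
    return p * p / area


def write_cohort(samples: List[UltrasoundSample], manifest: pd.DataFrame,
                 root: str) -> None:
    """Write BUSI-style layout: per-class folders with <id>.png / <id>_mask.png
    pairs (8-bit grayscale) and a manifest.csv at the root."""
    for label in LABELS:
        os.makedirs(os.path.join(root, label), exist_ok=True)
    for s in samples:
        folder = os.path.join(root, s.label)
        img8 = np.clip(np.round(s.image * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(img8, mode="L").save(os.path.join(folder, f"{s.id}.png"))
        Image.fromarray((s.mask * 255).astype(np.uint8), mode="L").save(
            os.path.join(folder, f"{s.id}_mask.png"))
    manifest.to_csv(os.path.join(root, "manifest.csv"), index=False)
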