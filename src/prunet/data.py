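"""Synthetic image/mask generation and paired-folder loading.

Three generator profiles emulate the statistical character of common
binary-segmentation settings at a configurable square size:

``skin_like``
    one large, irregular, bright lesion on a smoothly textured background
    (dermoscopy-style);
``breast_like``
    one low-contrast dark lesion under multiplicative speckle noise
    (ultrasound-style);
``lung_like``
    two large, smooth, bright regions on a dark background (CT-style),
    always exactly two connected foreground components.

Lesion shapes are perturbed ellipses: the boundary radius is modulated by a
small random Fourier series over the polar angle, which yields smooth
irregular blobs whose roughness one scalar controls. Images are single
intensities in [0, 1] replicated to three channels (with a mild per-channel
tint), so the same tensors feed an RGB-input network regardless of
modality. Every sample is generated from a per-sample child of one seed
sequence, so a dataset is a pure function of (profile, n, size, seed).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage as ndi
from skimage.transform import resize

logger = logging.getLogger(__name__)

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}


class DataError(Exception):
    """Invalid or inconsistent input data."""


@dataclass
class SegmentationSample:
    image: np.ndarray          # (H, W, 3) float32 in [0, 1]
    mask: np.ndarray           # (H, W) uint8 in {0, 1}
    profile: str = "unknown"
    source: str = ""

    def validate(self) -> "SegmentationSample":
        if self.image.ndim != 3 or self.image.shape[:2] != self.mask.shape:
            raise DataError(
                f"image {self.image.shape} and mask {self.mask.shape} disagree")
        if self.image.shape[0] != self.image.shape[1]:
            raise DataError("samples must be square")
        if not np.isfinite(self.image).all():
            raise DataError("image contains non-finite values")
        if not np.isin(np.unique(self.mask), (0, 1)).all():
            raise DataError("mask must be strictly binary")
        return self


@dataclass(frozen=True)
class GeneratorProfile:
    """Distributional description of one synthetic modality."""

    name: str
    n_lesions: int = 1
    bg_level: float = 0.35
    fg_offset: float = 0.30          # signed intensity offset of the lesion
    declared_contrast: float = 0.15  # promised |fg mean - bg mean| margin (signed)
    texture_amplitude: float = 0.08
    noise_sigma: float = 0.03
    speckle_sigma: float = 0.0       # multiplicative speckle (ultrasound-like)
    blur_sigma: float = 0.8          # edge softness of the lesion in the image
    irregularity: float = 0.25       # Fourier boundary roughness
    radius_range: tuple = (0.17, 0.30)   # semi-axis range, fraction of size
    fg_range: tuple = (0.04, 0.50)   # admissible foreground fraction
    tint: tuple = (1.0, 0.92, 0.85)


PROFILES: dict[str, GeneratorProfile] = {
    "skin_like": GeneratorProfile(
        name="skin_like", bg_level=0.35, fg_offset=0.32, declared_contrast=0.15,
        texture_amplitude=0.08, noise_sigma=0.03, irregularity=0.25,
        radius_range=(0.17, 0.30), fg_range=(0.04, 0.50),
        tint=(1.0, 0.88, 0.78)),
    "breast_like": GeneratorProfile(
        name="breast_like", bg_level=0.50, fg_offset=-0.20,
        declared_contrast=-0.08, texture_amplitude=0.05, noise_sigma=0.02,
        speckle_sigma=0.18, blur_sigma=1.5, irregularity=0.15,
        radius_range=(0.10, 0.22), fg_range=(0.02, 0.30),
        tint=(1.0, 1.0, 1.0)),
    "lung_like": GeneratorProfile(
        name="lung_like", n_lesions=2, bg_level=0.22, fg_offset=0.50,
        declared_contrast=0.30, texture_amplitude=0.05, noise_sigma=0.03,
        irregularity=0.08, radius_range=(0.10, 0.16), fg_range=(0.05, 0.35),
        tint=(1.0, 1.0, 1.0)),
}


def _check_size(size: int) -> None:
    if size < 16 or size % 16:
        raise DataError(f"size must be a positive multiple of 16, got {size}")


def _blob_mask(rng, size: int, center, rx: float, ry: float,
               irregularity: float) -> np.ndarray:
    """Rasterise one perturbed ellipse."""
    theta = rng.uniform(0, np.pi)
    cy, cx = center
    y, x = np.mgrid[0:size, 0:size]
    dx, dy = x - cx, y - cy
    xr = np.cos(theta) * dx + np.sin(theta) * dy
    yr = -np.sin(theta) * dx + np.cos(theta) * dy
    r = np.sqrt((xr / rx) ** 2 + (yr / ry) ** 2)
    angle = np.arctan2(yr, xr)
    rho = np.ones_like(angle)
    for k in range(2, 6):
        rho += (irregularity / k) * rng.normal() * np.cos(k * angle + rng.uniform(0, 2 * np.pi))
    return r <= np.maximum(rho, 0.3)


def _single_lesion_mask(rng, size: int, profile: GeneratorProfile) -> np.ndarray:
    lo, hi = profile.fg_range
    mask = None
    for _ in range(12):
        rx = rng.uniform(*profile.radius_range) * size
        ry = rng.uniform(*profile.radius_range) * size
        cy = size * (0.5 + rng.uniform(-0.12, 0.12))
        cx = size * (0.5 + rng.uniform(-0.12, 0.12))
        mask = _blob_mask(rng, size, (cy, cx), rx, ry, profile.irregularity)
        if lo <= mask.mean() <= hi:
            return mask
    # rescale the last draw toward the middle of the admissible range
    frac = max(mask.mean(), 1.0 / size ** 2)
    s = np.sqrt(0.5 * (lo + hi) / frac)
    rx, ry = np.clip(rx * s, 2, 0.45 * size), np.clip(ry * s, 2, 0.45 * size)
    return _blob_mask(rng, size, (cy, cx), rx, ry, profile.irregularity)


def _lung_mask(rng, size: int, profile: GeneratorProfile) -> np.ndarray:
    """Two smooth regions confined to the left/right halves (2 components)."""
    mask = np.zeros((size, size), dtype=bool)
    for cx_frac in (0.27, 0.73):
        rx = rng.uniform(*profile.radius_range) * size
        ry = rng.uniform(1.4 * profile.radius_range[0],
                         1.6 * profile.radius_range[1]) * size
        cy = size * (0.5 + rng.uniform(-0.06, 0.06))
        cx = size * (cx_frac + rng.uniform(-0.02, 0.02))
        blob = _blob_mask(rng, size, (cy, cx), rx, ry, profile.irregularity)
        half = slice(0, size // 2 - 1) if cx_frac < 0.5 else slice(size // 2 + 1, size)
        keep = np.zeros_like(blob)
        keep[:, half] = blob[:, half]
        mask |= keep
    return mask


def _render_sample(rng, size: int, profile: GeneratorProfile,
                   source: str) -> SegmentationSample:
    if profile.n_lesions == 2:
        mask = _lung_mask(rng, size, profile)
    else:
        mask = _single_lesion_mask(rng, size, profile)

    texture = ndi.gaussian_filter(rng.normal(size=(size, size)), size / 16.0)
    texture *= profile.texture_amplitude / max(texture.std(), 1e-8)
    img = profile.bg_level + texture
    soft = ndi.gaussian_filter(mask.astype(float), profile.blur_sigma)
    img = img + profile.fg_offset * soft
    img += profile.noise_sigma * rng.normal(size=(size, size))
    if profile.speckle_sigma:
        img *= 1.0 + profile.speckle_sigma * rng.normal(size=(size, size))
    img = np.clip(img, 0.0, 1.0)
    rgb = img[..., None] * np.asarray(profile.tint)[None, None, :]
    return SegmentationSample(
        image=np.clip(rgb, 0.0, 1.0).astype(np.float32),
        mask=mask.astype(np.uint8),
        profile=profile.name,
        source=source,
    ).validate()


def generate_dataset(profile, n: int, size: int = 256,
                     seed: int = 0) -> list[SegmentationSample]:
    """Generate ``n`` reproducible image/mask pairs for one profile.

    ``profile`` may be a profile name or a :class:`GeneratorProfile`.
    ``size`` must be a multiple of 16 so the samples satisfy the network's
    spatial-divisibility constraint at five levels.
    """
    if isinstance(profile, str):
        try:
            profile = PROFILES[profile]
        except KeyError:
            raise DataError(
                f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")
    if n < 1:
        raise DataError("n must be >= 1")
    _check_size(size)
    children = np.random.SeedSequence(seed).spawn(n)
    return [
        _render_sample(np.random.default_rng(child), size, profile,
                       source=f"synthetic:{profile.name}:{seed}:{i}")
        for i, child in enumerate(children)
    ]


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

AUGMENT_OPS = ("hflip", "vflip", "rot90", "rot180", "rot270")


def transform_pair(sample: SegmentationSample, op: str) -> SegmentationSample:
    """Apply one named geometric transform identically to image and mask."""
    img, mask = sample.image, sample.mask
    if op == "hflip":
        img, mask = img[:, ::-1], mask[:, ::-1]
    elif op == "vflip":
        img, mask = img[::-1], mask[::-1]
    elif op in ("rot90", "rot180", "rot270"):
        k = {"rot90": 1, "rot180": 2, "rot270": 3}[op]
        img, mask = np.rot90(img, k, axes=(0, 1)), np.rot90(mask, k, axes=(0, 1))
    else:
        raise ValueError(f"unknown augmentation op {op!r}")
    return replace(sample, image=np.ascontiguousarray(img),
                   mask=np.ascontiguousarray(mask))


def augment_pair(sample: SegmentationSample, ratio: float,
                 rng: np.random.Generator) -> SegmentationSample:
    """With probability ``ratio``, apply one random flip/right-angle rotation."""
    if not 0.0 <= ratio <= 1.0:
        raise ValueError("ratio must lie in [0, 1]")
    if ratio > 0.0 and rng.random() < ratio:
        return transform_pair(sample, AUGMENT_OPS[rng.integers(len(AUGMENT_OPS))])
    return sample


# ---------------------------------------------------------------------------
# disk IO
# ---------------------------------------------------------------------------

def save_dataset(samples: list[SegmentationSample], out_dir,
                 manifest_name: str = "manifest.csv") -> Path:
    """Write 8-bit PNG image/mask pairs plus a manifest CSV."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rows = ["path,profile,source"]
    for i, s in enumerate(samples):
        stem = f"sample_{i:04d}"
        iio.imwrite(out / "images" / f"{stem}.png",
                    (np.clip(s.image, 0, 1) * 255).round().astype(np.uint8))
        iio.imwrite(out / "masks" / f"{stem}.png", s.mask * np.uint8(255))
        rows.append(f"images/{stem}.png,{s.profile},{s.source}")
    (out / manifest_name).write_text("\n".join(rows) + "\n")
    return out


def load_folder_dataset(images_dir, masks_dir, size: int,
                        channels: int = 3) -> list[SegmentationSample]:
    """Load paired image/mask folders, matched by file stem.

    Images are resized with bilinear interpolation; masks with
    nearest-neighbour and then thresholded at half their maximum, which
    keeps them strictly binary through the resize.
    """
    _check_size(size)
    images_dir, masks_dir = Path(images_dir), Path(masks_dir)
    if not images_dir.is_dir() or not masks_dir.is_dir():
        raise DataError(f"missing folder: {images_dir} or {masks_dir}")

    def index(folder: Path) -> dict[str, Path]:
        files = {}
        for p in sorted(folder.iterdir()):
            if not p.is_file():
                continue
            if p.suffix.lower() not in IMAGE_EXTENSIONS:
                logger.info("skipping non-image file %s", p)
                continue
            files[p.stem] = p
        return files

    imgs, masks = index(images_dir), index(masks_dir)
    unmatched = sorted(set(imgs) ^ set(masks))
    if unmatched:
        raise DataError(f"unmatched image/mask stems: {unmatched}")
    if not imgs:
        raise DataError(f"no image files found in {images_dir}")

    samples = []
    for stem in sorted(imgs):
        img = np.asarray(iio.imread(imgs[stem]), dtype=np.float64)
        if img.max() > 1.0:
            img /= 255.0
        if img.ndim == 2:
            img = np.repeat(img[..., None], channels, axis=2)
        elif img.shape[2] > channels:
            img = img[..., :channels]
        img = resize(img, (size, size), order=1, anti_aliasing=True,
                     preserve_range=True)
        m = np.asarray(iio.imread(masks[stem]), dtype=np.float64)
        if m.ndim == 3:
            m = m[..., 0]
        m = resize(m, (size, size), order=0, anti_aliasing=False,
                   preserve_range=True)
        binary = (m >= 0.5 * m.max()).astype(np.uint8) if m.max() > 0 \
            else np.zeros((size, size), np.uint8)
        samples.append(SegmentationSample(
            image=np.clip(img, 0, 1).astype(np.float32), mask=binary,
            profile="folder", source=str(imgs[stem])).validate())
    return samples


def dataset_hash(samples: list[SegmentationSample]) -> str:
    """Content hash of a dataset, for run manifests."""
    h = hashlib.sha256()
    for s in samples:
        h.update(np.ascontiguousarray(s.image).tobytes())
        h.update(np.ascontiguousarray(s.mask).tobytes())
    return h.hexdigest()


def samples_to_arrays(samples: list[SegmentationSample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack samples into network tensors (N,C,H,W) and (N,1,H,W)."""
    x = np.stack([s.image.transpose(2, 0, 1) for s in samples]).astype(np.float32)
    y = np.stack([s.mask[None].astype(np.float32) for s in samples])
    return x, y
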