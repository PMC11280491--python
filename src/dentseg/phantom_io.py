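"""Synthetic dental phantoms, PNG I/O, augmentation and dataset splitting.

Phantom images emulate the difficult properties of panoramic radiographs:
elongated, partially overlapping tooth-like shapes, a low-contrast
root/bone boundary near the lower third of every tooth, and additive
Gaussian noise.  Everything is a pure function of its configuration
(including the seed), so the full pipeline is testable without any
external data.

Coordinate convention throughout the package: (row, col), 0-based,
top-left origin.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "ImageSample", "PhantomConfig", "AugmentSpec", "PlacementError",
    "generate_phantom", "write_dataset", "read_sample", "load_manifest",
    "augment", "random_augment_spec", "split_dataset", "root_contrast",
]

MASK_THRESHOLD = 127  # on-disk masks are {0, 255}; >127 decodes to 1


class PlacementError(RuntimeError):
    """Raised when the requested teeth cannot be placed on the canvas."""


@dataclass
class ImageSample:
    """A 3-channel image in [0, 1] with a binary mask of equal spatial size."""

    image: np.ndarray  # (3, H, W) float in [0, 1]
    mask: np.ndarray   # (H, W) uint8 in {0, 1}
    id: str = "sample"

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float64)
        self.mask = np.asarray(self.mask)
        if self.image.ndim != 3 or self.image.shape[0] != 3:
            raise ValueError(f"image must be (3, H, W), got {self.image.shape}")
        if self.image.shape[1:] != self.mask.shape:
            raise ValueError(
                f"image spatial dims {self.image.shape[1:]} != mask dims {self.mask.shape}")
        vals = np.unique(self.mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"mask must be binary, found values {vals}")
        self.mask = self.mask.astype(np.uint8)


@dataclass(frozen=True)
class PhantomConfig:
    canvas: tuple[int, int] = (64, 128)   # (height, width)
    n_teeth: int = 6
    contrast_gap: float = 0.15
    noise_sigma: float = 0.02
    overlap_prob: float = 0.3
    seed: int = 0

    def __post_init__(self):
        h, w = self.canvas
        if h < 16 or w < 16:
            raise ValueError("canvas dimensions must be >= 16")
        if not 0.0 <= self.contrast_gap <= 1.0:
            raise ValueError("contrast_gap must be in [0, 1]")
        if not 0.0 <= self.overlap_prob <= 1.0:
            raise ValueError("overlap_prob must be in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_teeth < 0:
            raise ValueError("n_teeth must be >= 0")


@dataclass(frozen=True)
class AugmentSpec:
    """Augmentation magnitudes; all ranges are sampled from ``seed``.

    Photometric ops (brightness, gamma, noise) touch the image only;
    geometric ops (scale, mirror, affine) hit image and mask identically,
    with nearest-neighbour resampling for the mask.
    """

    brightness_delta: tuple[float, float] = (0.0, 0.0)
    gamma: tuple[float, float] = (1.0, 1.0)
    gaussian_noise_sigma: float = 0.0
    scale: tuple[float, float] = (1.0, 1.0)
    mirror: bool = False
    rotate_deg: tuple[float, float] = (0.0, 0.0)
    translate_px: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self):
        if self.gamma[0] <= 0 or self.gamma[1] <= 0:
            raise ValueError("gamma range must be strictly positive")
        if self.scale[0] <= 0 or self.scale[1] <= 0:
            raise ValueError("scale range must be strictly positive")


# --------------------------------------------------------------------------
# phantom generation
# --------------------------------------------------------------------------

_BACKGROUND = 0.40
_CROWN_LIFT = 0.35


def _capsule_mask(h: int, w: int, p0: tuple[float, float],
                  p1: tuple[float, float], radius: float) -> np.ndarray:
    """Pixels within ``radius`` of the segment p0-p1 (a capsule shape)."""
    rr, cc = np.mgrid[0:h, 0:w]
    p0 = np.asarray(p0, dtype=float)
    d = np.asarray(p1, dtype=float) - p0
    denom = float(d @ d) or 1.0
    t = np.clip(((rr - p0[0]) * d[0] + (cc - p0[1]) * d[1]) / denom, 0.0, 1.0)
    dist2 = (rr - (p0[0] + t * d[0])) ** 2 + (cc - (p0[1] + t * d[1])) ** 2
    return dist2 <= radius ** 2


def _draw_tooth(h: int, w: int, cx: float, top: float, length: float,
                width: float, n_roots: int, rng: np.random.Generator) -> np.ndarray:
    """A tooth = crown capsule + 1-2 narrower root capsules below it."""
    crown_len = 0.55 * length
    crown = _capsule_mask(h, w, (top, cx), (top + crown_len, cx), width / 2)
    roots = np.zeros((h, w), dtype=bool)
    root_top = top + crown_len * 0.8
    root_bot = top + length
    if n_roots == 1:
        roots |= _capsule_mask(h, w, (root_top, cx), (root_bot, cx), width / 3.2)
    else:
        spread = width / 3.0
        for s in (-spread, spread):
            tip_dx = s * (1.0 + 0.3 * rng.random())
            roots |= _capsule_mask(h, w, (root_top, cx + s * 0.5),
                                   (root_bot, cx + tip_dx), width / 4.0)
    return crown | roots


def generate_phantom(config: PhantomConfig) -> ImageSample:
    """Render a deterministic tooth-row phantom from ``config``.

    Raises :class:`PlacementError` if the canvas cannot hold ``n_teeth``
    non-overlapping teeth after bounded shrinking retries (overlap
    requested via ``overlap_prob`` relaxes the space requirement).
    """
    h, w = config.canvas
    rng = np.random.default_rng(config.seed)
    image = np.full((h, w), _BACKGROUND)
    mask = np.zeros((h, w), dtype=bool)

    if config.n_teeth > 0:
        margin = 2
        tooth_w = float(min(max(6, h // 4), 18, (w - 2 * margin) / max(config.n_teeth, 1) * 1.4))
        placed = False
        for _ in range(6):  # bounded retries, shrinking teeth each time
            overlaps = rng.random(config.n_teeth) < config.overlap_prob
            # step between tooth centres: overlap -> guaranteed intersection
            steps = np.where(overlaps, 0.6 * tooth_w, 1.25 * tooth_w)
            steps[0] = 0.0
            centers = margin + tooth_w / 2 + np.cumsum(steps)
            if centers[-1] + tooth_w / 2 + margin <= w and tooth_w >= 4:
                placed = True
                break
            tooth_w *= 0.8
        if not placed:
            raise PlacementError(
                f"cannot place {config.n_teeth} teeth on a {h}x{w} canvas")
        length = min(0.62 * h, h - 8)
        top = max(2.0, (h - length) / 2)
        root_level = _BACKGROUND + 0.8 * config.contrast_gap
        for cx in centers:
            n_roots = 1 + int(rng.random() < 0.4)
            jitter = rng.uniform(-1.5, 1.5)
            tooth = _draw_tooth(h, w, cx + jitter, top + rng.uniform(-1, 1),
                                length, tooth_w, n_roots, rng)
            mask |= tooth
            rr = np.nonzero(tooth)[0]
            if rr.size:
                split = rr.min() + 2 * (rr.max() - rr.min()) // 3
                crown_part = tooth & (np.arange(h)[:, None] < split)
                root_part = tooth & ~crown_part
                image[crown_part] = _BACKGROUND + _CROWN_LIFT
                image[root_part] = root_level

    image = ndimage.gaussian_filter(image, sigma=1.0)
    if config.noise_sigma > 0:
        image = image + rng.normal(0.0, config.noise_sigma, size=image.shape)
    image = np.clip(image, 0.0, 1.0)
    tri = np.repeat(image[None], 3, axis=0)
    return ImageSample(image=tri, mask=mask.astype(np.uint8),
                       id=f"phantom_{config.seed:06d}")


def root_contrast(sample: ImageSample) -> float:
    """|mean intensity of root-region tooth pixels - 3-px background collar|.

    The root region is the lower third of the mask's row extent; the collar
    is the 3-pixel dilation ring around the mask restricted to those rows.
    """
    mask = sample.mask.astype(bool)
    if not mask.any():
        return 0.0
    rows = np.nonzero(mask.any(axis=1))[0]
    split = rows.min() + 2 * (rows.max() - rows.min()) // 3
    band = np.zeros_like(mask)
    band[split:] = True
    root = mask & band
    collar = ndimage.binary_dilation(mask, iterations=3) & ~mask & band
    if not root.any() or not collar.any():
        return 0.0
    img = sample.image[0]
    return abs(float(img[root].mean()) - float(img[collar].mean()))


# --------------------------------------------------------------------------
# disk I/O
# --------------------------------------------------------------------------

def write_dataset(samples: list[ImageSample], directory: str | Path) -> Path:
    """Write samples as PNG pairs plus a ``manifest.csv``; returns its path.

    Images are 8-bit 3-channel PNG; masks are 8-bit single-channel PNG
    with values {0, 255}.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "image_path", "mask_path"])
        for sample in samples:
            img8 = np.clip(np.round(sample.image * 255), 0, 255).astype(np.uint8)
            img_path = directory / f"{sample.id}_image.png"
            mask_path = directory / f"{sample.id}_mask.png"
            Image.fromarray(img8.transpose(1, 2, 0)).save(img_path)
            Image.fromarray((sample.mask * 255).astype(np.uint8)).save(mask_path)
            writer.writerow([sample.id, img_path.name, mask_path.name])
    return manifest


def read_sample(image_path: str | Path, mask_path: str | Path,
                sample_id: str | None = None) -> ImageSample:
    """Read a PNG image/mask pair; image scaled to [0,1], mask binarised >127."""
    img = np.asarray(Image.open(image_path), dtype=np.float64) / 255.0
    if img.ndim == 2:  # grayscale file: replicate to three channels
        img = np.repeat(img[None], 3, axis=0)
    else:
        img = img.transpose(2, 0, 1)[:3]
        if img.shape[0] == 1:
            img = np.repeat(img, 3, axis=0)
    raw_mask = np.asarray(Image.open(mask_path))
    if raw_mask.ndim == 3:  # collapse channels before binarising
        raw_mask = raw_mask.max(axis=2)
    mask = (raw_mask > MASK_THRESHOLD).astype(np.uint8)
    if img.shape[1:] != mask.shape:
        raise ValueError(
            f"image shape {img.shape[1:]} does not match mask shape {mask.shape}")
    if sample_id is None:
        sample_id = Path(image_path).stem.removesuffix("_image")
    return ImageSample(image=img, mask=mask, id=sample_id)


def load_manifest(manifest_path: str | Path) -> list[ImageSample]:
    """Load every image/mask pair listed in a ``write_dataset`` manifest."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    samples = []
    with open(manifest_path, newline="") as fh:
        for row in csv.DictReader(fh):
            samples.append(read_sample(base / row["image_path"],
                                       base / row["mask_path"], row["id"]))
    return samples


# --------------------------------------------------------------------------
# augmentation
# --------------------------------------------------------------------------

def augment(sample: ImageSample, spec: AugmentSpec) -> ImageSample:
    """Apply the augmentation suite; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    img = sample.image.copy()
    mask = sample.mask.copy()
    h, w = mask.shape

    # -- geometric: one affine (scale + rotation + translation) + mirror ----
    scale = rng.uniform(*spec.scale)
    angle = np.deg2rad(rng.uniform(*spec.rotate_deg))
    tr = rng.uniform(-spec.translate_px[0], spec.translate_px[0]) if spec.translate_px[0] else 0.0
    tc = rng.uniform(-spec.translate_px[1], spec.translate_px[1]) if spec.translate_px[1] else 0.0
    if scale != 1.0 or angle != 0.0 or tr != 0.0 or tc != 0.0:
        cosa, sina = np.cos(angle), np.sin(angle)
        # output->input map about the image centre
        lin = np.array([[cosa, -sina], [sina, cosa]]) / scale
        center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
        offset = center - lin @ (center + np.array([tr, tc]))
        img = np.stack([
            ndimage.affine_transform(ch, lin, offset=offset, order=1, mode="constant",
                                     cval=float(ch.mean()))
            for ch in img])
        mask = ndimage.affine_transform(mask, lin, offset=offset, order=0,
                                        mode="constant", cval=0).astype(np.uint8)
    if spec.mirror:
        img = img[:, :, ::-1].copy()
        mask = mask[:, ::-1].copy()

    # -- photometric: image only --------------------------------------------
    gamma = rng.uniform(*spec.gamma)
    if gamma != 1.0:
        img = np.clip(img, 0.0, 1.0) ** gamma
    delta = rng.uniform(*spec.brightness_delta)
    if delta != 0.0:
        img = img + delta
    if spec.gaussian_noise_sigma > 0:
        img = img + rng.normal(0.0, spec.gaussian_noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    return ImageSample(image=img, mask=mask, id=sample.id)


def random_augment_spec(rng: np.random.Generator,
                        base: AugmentSpec | None = None) -> AugmentSpec:
    """Draw a fresh augmentation seed (and mirror coin) from ``rng``."""
    base = base or AugmentSpec()
    return replace(base, mirror=bool(rng.random() < 0.5) if base.mirror else False,
                   seed=int(rng.integers(0, 2 ** 31)))


# --------------------------------------------------------------------------
# splitting
# --------------------------------------------------------------------------

def split_dataset(samples: list, ratio: float = 0.9,
                  seed: int = 0) -> tuple[list, list]:
    """Disjoint, exhaustive, seeded train/val split (train fraction = ratio)."""
    if not samples:
        raise ValueError("cannot split an empty dataset")
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    order = np.random.default_rng(seed).permutation(len(samples))
    n_train = int(round(ratio * len(samples)))
    train = [samples[i] for i in order[:n_train]]
    val = [samples[i] for i in order[n_train:]]
    return train, val
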