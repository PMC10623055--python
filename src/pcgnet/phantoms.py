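"""Synthetic CT-like organ phantoms.

Real head-and-neck CT collections used for organ-at-risk segmentation are
private; what matters for exercising the model is (a) a spread of structure
sizes from large (brainstem/mandible-like, a few percent of pixels) down to
very small (optic-nerve/chiasm-like, well under 0.5%), (b) HU-like grayscale
contrast between structures and background, and (c) systematic cross-site
intensity shifts between the unlabeled pretraining pool and the labeled
fine-tuning set.  The generator emulates exactly those three properties.

Each phantom slice contains five (by default) pairwise non-overlapping
randomised superellipses with per-structure intensity bands, a smooth
background texture field, an affine+gamma "institution shift", and additive
Gaussian noise.  A single integer seed fully determines a sample.

Structure semi-axes are calibrated from the exact superellipse area
A = 4ab * Gamma(1+1/p)^2 / Gamma(1+2/p) so realised pixel counts track the
configured area fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import gamma as _gamma

logger = logging.getLogger(__name__)

#: gain, bias, gamma triples emulating scanner/protocol differences between
#: sites; id 0 is the identity (the "local" institution).
SHIFT_TABLE = (
    (1.00, 0.00, 1.00),
    (1.18, 0.06, 0.92),
    (0.85, 0.10, 1.12),
    (1.10, -0.04, 1.25),
    (0.90, 0.08, 0.85),
)

SPLITS = ("pretrain", "train", "val", "test")
_SPLIT_OFFSET = {"pretrain": 10_000_000, "train": 0, "val": 20_000_000, "test": 30_000_000}


@dataclass
class PhantomConfig:
    """Generation parameters; defaults are the desk-scale study conditions."""

    image_size: int = 128
    num_structures: int = 5
    size_fractions: tuple = (0.04, 0.06, 0.03, 0.004, 0.002)
    intensity_means: tuple = (0.10, 0.40, 0.75, 0.55, 0.90, 0.25)  # background first
    noise_sd: float = 0.04
    texture_sd: float = 0.02
    institution_shift: int = 0
    seed: int = 0

    def __post_init__(self):
        if len(self.size_fractions) != self.num_structures:
            raise ValueError("size_fractions length must equal num_structures")
        if len(self.intensity_means) != self.num_structures + 1:
            raise ValueError("intensity_means must list background + one mean per structure")
        for f in self.size_fractions:
            if not (0.0 < f < 0.25):
                raise ValueError(f"size fraction {f} outside (0, 0.25)")
        if self.num_structures >= 2:
            two_smallest = sorted(self.size_fractions)[:2]
            if any(f >= 0.01 for f in two_smallest):
                raise ValueError(
                    "the two smallest size fractions must be < 0.01 "
                    "(the generator must include very small structures)"
                )


@dataclass
class PhantomSample:
    image: np.ndarray  # float32 (H, W) in [0, 1]
    label: np.ndarray | None  # int16 (H, W) in {0..M-1}; None for unlabeled samples
    meta: dict = field(default_factory=dict)

    def require_label(self) -> np.ndarray:
        """Tripwire accessor: unlabeled (pretraining) samples raise here."""
        if self.label is None:
            raise ValueError(
                "this sample belongs to the unlabeled pretraining split; "
                "its labels are withheld by construction"
            )
        return self.label


def _superellipse_field(size, cy, cx, a, b, theta, p):
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    u = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
    v = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
    g = (np.abs(u / a) ** p + np.abs(v / b) ** p) ** (1.0 / p)
    return g


def _axes_from_area(area, aspect, p):
    # exact superellipse area: 4ab * Gamma(1+1/p)^2 / Gamma(1+2/p)
    shape_factor = 4.0 * _gamma(1.0 + 1.0 / p) ** 2 / _gamma(1.0 + 2.0 / p)
    ab = area / shape_factor
    b = np.sqrt(ab / aspect)
    return aspect * b, b


def generate_phantom(config: PhantomConfig) -> PhantomSample:
    """Generate one slice; identical config gives a bit-identical sample."""
    size = config.image_size
    rng = np.random.default_rng(config.seed)
    label = np.zeros((size, size), dtype=np.int16)
    image = np.full((size, size), config.intensity_means[0], dtype=np.float64)

    for idx, frac in enumerate(config.size_fractions):
        if frac * size * size < 1.0:
            raise ValueError(
                f"structure {idx + 1}: target fraction {frac} is below one pixel "
                f"at image size {size}"
            )

    # place big structures first; tiny ones slot into the remaining space
    order = sorted(range(config.num_structures), key=lambda i: -config.size_fractions[i])
    occupied = np.zeros((size, size), dtype=bool)
    meta_structures = {}
    for idx in order:
        frac = config.size_fractions[idx]
        area = frac * size * size
        placed = False
        for _ in range(300):
            p = rng.uniform(1.6, 3.0)
            aspect = rng.uniform(2.5, 4.5) if frac < 0.01 and idx == 3 else rng.uniform(1.1, 2.2)
            a, b = _axes_from_area(area, aspect, p)
            if b < 0.8:
                aspect = max(1.1, aspect * 0.5)
                a, b = _axes_from_area(area, aspect, p)
            theta = rng.uniform(0, np.pi)
            margin = max(a, b) + 2.0
            if 2 * margin >= size:
                continue
            cy = rng.uniform(margin, size - margin)
            cx = rng.uniform(margin, size - margin)
            g = _superellipse_field(size, cy, cx, a, b, theta, p)
            mask = g <= 1.0
            if mask.sum() < 1:
                continue
            grown = ndimage.binary_dilation(mask, iterations=2)
            if np.any(grown & occupied):
                continue
            coverage = np.clip((1.0 - g) * min(a, b) + 0.5, 0.0, 1.0)
            image = image * (1.0 - coverage) + config.intensity_means[idx + 1] * coverage
            label[mask] = idx + 1
            occupied |= grown
            meta_structures[idx + 1] = {
                "center": (float(cy), float(cx)),
                "axes": (float(a), float(b)),
                "theta": float(theta),
                "exponent": float(p),
                "pixels": int(mask.sum()),
            }
            placed = True
            break
        if not placed:
            raise RuntimeError(f"could not place structure {idx + 1} without overlap")

    if config.texture_sd > 0:
        field_noise = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (size, size)), sigma=8.0)
        image = image + config.texture_sd * field_noise / max(field_noise.std(), 1e-9)

    image = apply_institution_shift(image, config.institution_shift)
    if config.noise_sd > 0:
        image = image + rng.normal(0.0, config.noise_sd, (size, size))
    image = np.clip(image, 0.0, 1.0).astype(np.float32)

    meta = {
        "seed": config.seed,
        "institution_shift": config.institution_shift,
        "structures": meta_structures,
        "spacing_mm": 1.0,
    }
    return PhantomSample(image=image, label=label, meta=meta)


def apply_institution_shift(image, shift_id: int):
    """Affine intensity transform (gain, bias) plus mild gamma, by site id."""
    gain, bias, gam = SHIFT_TABLE[shift_id % len(SHIFT_TABLE)]
    return np.clip(image * gain + bias, 0.0, 1.0) ** gam


def generate_dataset(n: int, config: PhantomConfig, split: str) -> list[PhantomSample]:
    """Generate ``n`` samples for one split.

    Pretraining samples carry images only (labels withheld) and draw their
    institution shift from the non-identity entries of the shift table,
    emulating a heterogeneous multi-site unlabeled pool; the labeled splits
    use the config's own institution shift.
    """
    if split not in SPLITS:
        raise ValueError(f"unknown split {split!r}; expected one of {SPLITS}")
    if n < 0:
        raise ValueError("n must be >= 0")
    out = []
    for i in range(n):
        cfg_i = PhantomConfig(
            image_size=config.image_size,
            num_structures=config.num_structures,
            size_fractions=config.size_fractions,
            intensity_means=config.intensity_means,
            noise_sd=config.noise_sd,
            texture_sd=config.texture_sd,
            institution_shift=(1 + i % (len(SHIFT_TABLE) - 1))
            if split == "pretrain"
            else config.institution_shift,
            seed=config.seed + _SPLIT_OFFSET[split] + i,
        )
        sample = generate_phantom(cfg_i)
        if split == "pretrain":
            sample = PhantomSample(image=sample.image, label=None, meta=sample.meta)
        out.append(sample)
    return out


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


def _geom_pair(image, label, fn_image, fn_label):
    image = fn_image(image)
    if label is not None:
        label = fn_label(label)
    return image, label


def augment(sample: PhantomSample, ops, seed: int | None = None) -> PhantomSample:
    """Apply a sequence of augmentation ops; geometry hits image and label
    identically (nearest-neighbour for labels), intensity ops hit the image only.

    ``ops`` is a sequence of names or ``(name, kwargs)`` pairs drawn from
    {mirror, rotate, translate, affine, gray_float}.
    """
    rng = np.random.default_rng(seed)
    image = sample.image.astype(np.float32).copy()
    label = None if sample.label is None else sample.label.copy()

    for op in ops:
        name, kw = op if isinstance(op, (tuple, list)) else (op, {})
        if name == "mirror":
            axis = kw.get("axis")
            if axis is None:
                axis = int(rng.integers(0, 2))
            image, label = _geom_pair(
                image, label, lambda im: np.flip(im, axis=axis).copy(), lambda lb: np.flip(lb, axis=axis).copy()
            )
        elif name == "rotate":
            angle = kw.get("angle")
            if angle is None:
                lo, hi = kw.get("range", (-15.0, 15.0))
                angle = float(rng.uniform(lo, hi))
            if angle % 90 == 0:
                k = int(angle // 90) % 4
                image, label = _geom_pair(
                    image, label, lambda im: np.rot90(im, k).copy(), lambda lb: np.rot90(lb, k).copy()
                )
            else:
                image, label = _geom_pair(
                    image,
                    label,
                    lambda im: ndimage.rotate(im, angle, reshape=False, order=1, mode="nearest"),
                    lambda lb: ndimage.rotate(lb, angle, reshape=False, order=0, mode="constant", cval=0),
                )
        elif name == "translate":
            shift = kw.get("shift")
            if shift is None:
                m = kw.get("max_fraction", 0.08) * image.shape[0]
                shift = (float(rng.uniform(-m, m)), float(rng.uniform(-m, m)))
            image, label = _geom_pair(
                image,
                label,
                lambda im: ndimage.shift(im, shift, order=1, mode="nearest"),
                lambda lb: ndimage.shift(lb, shift, order=0, mode="constant", cval=0),
            )
        elif name == "affine":
            jitter = kw.get("jitter", 0.06)
            mat = np.eye(2) + rng.uniform(-jitter, jitter, (2, 2))
            center = (np.array(image.shape) - 1) / 2.0
            offset = center - mat @ center
            image, label = _geom_pair(
                image,
                label,
                lambda im: ndimage.affine_transform(im, mat, offset=offset, order=1, mode="nearest"),
                lambda lb: ndimage.affine_transform(lb, mat, offset=offset, order=0, mode="constant", cval=0),
            )
        elif name == "gray_float":
            sd = kw.get("sd", 0.03)
            if sd > 0:
                image = np.clip(image + rng.normal(0.0, sd, image.shape), 0.0, 1.0).astype(
                    np.float32
                )
        else:
            raise ValueError(f"unknown augmentation op {name!r}")

    return PhantomSample(image=image.astype(np.float32), label=label, meta=dict(sample.meta))


def contrastive_view(image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One random view for Siamese pretraining.

    The view cluster composes a random resized crop (0.6-1.0 of the area),
    mirrors, a small rotation, affine jitter, grayscale float noise and a
    random intensity gain/bias.
    """
    size = image.shape[0]
    scale = float(rng.uniform(0.6, 1.0))
    crop = max(8, int(round(size * np.sqrt(scale))))
    y0 = int(rng.integers(0, size - crop + 1))
    x0 = int(rng.integers(0, size - crop + 1))
    view = image[y0 : y0 + crop, x0 : x0 + crop]
    view = ndimage.zoom(view, size / crop, order=1)[:size, :size]
    if view.shape != image.shape:  # guard rounding
        pad_y, pad_x = size - view.shape[0], size - view.shape[1]
        view = np.pad(view, ((0, pad_y), (0, pad_x)), mode="edge")
    if rng.random() < 0.5:
        view = np.flip(view, axis=0)
    if rng.random() < 0.5:
        view = np.flip(view, axis=1)
    angle = float(rng.uniform(-15, 15))
    view = ndimage.rotate(view, angle, reshape=False, order=1, mode="nearest")
    gain = float(rng.uniform(0.9, 1.1))
    bias = float(rng.uniform(-0.05, 0.05))
    view = view * gain + bias
    view = view + rng.normal(0.0, 0.03, view.shape)
    return np.clip(view, 0.0, 1.0).astype(np.float32)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def preprocess(
    image: np.ndarray,
    spacing: float,
    target_spacing: float = 1.0,
    pad_to: int = 512,
    is_label: bool = False,
    pad_value: float = 0.0,
) -> np.ndarray:
    """Resample to the target pixel spacing and symmetrically pad/crop.

    Linear interpolation for images, nearest-neighbour for labels; padding
    uses ``pad_value`` (background intensity for images, 0 for labels).  If
    the resampled content exceeds ``pad_to`` it is centre-cropped with a
    logged warning.
    """
    if spacing <= 0 or target_spacing <= 0:
        raise ValueError("spacings must be > 0")
    factor = spacing / target_spacing
    out = image
    if factor != 1.0:
        out = ndimage.zoom(image, factor, order=0 if is_label else 1)
    h, w = out.shape
    if h > pad_to or w > pad_to:
        logger.warning("resampled content %dx%d exceeds pad_to=%d; centre-cropping", h, w, pad_to)
        y0 = max(0, (h - pad_to) // 2)
        x0 = max(0, (w - pad_to) // 2)
        out = out[y0 : y0 + pad_to, x0 : x0 + pad_to]
        h, w = out.shape
    fill = 0 if is_label else pad_value
    canvas = np.full((pad_to, pad_to), fill, dtype=out.dtype)
    y0 = (pad_to - h) // 2
    x0 = (pad_to - w) // 2
    canvas[y0 : y0 + h, x0 : x0 + w] = out
    return canvas
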