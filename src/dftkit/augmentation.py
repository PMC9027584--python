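"""Image augmentation: Gaussian blur, gamma shift, small rotation, white
noise, a seeded random pipeline, and random minority oversampling.

Each transform maps a [0, 1] grayscale image to a [0, 1] image of the same
shape.  Mirroring is deliberately absent from the registry: breast imagery
is chiral (left/right anatomy matters), so flips would corrupt labels'
anatomical meaning.  The pipeline draws, per emitted image, one source
image (with replacement), one transform, and one parameter vector from the
configured ranges; exact duplicates are rejected by content hash.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .data import ImageSet, to_uint8

__all__ = [
    "TransformParams",
    "AugmentationPlan",
    "gaussian_kernel",
    "gaussian_blur",
    "gamma_shift",
    "rotate_small",
    "add_white_noise",
    "augment_dataset",
    "oversample_minority",
    "DEFAULT_RANGES",
]

MAX_ANGLE = 25.0  # degrees; small-angle regime


@dataclass(frozen=True)
class TransformParams:
    """One sampled parameter vector (only the active transform's field is used)."""

    blur_variance: float = 1.0   # px^2
    gamma_c: float = 1.0         # scale constant, > 0
    gamma_exp: float = 1.0       # exponent, > 0
    angle: float = 0.0           # degrees, |angle| <= 25
    noise_sigma: float = 0.01    # intensity units, >= 0


#: Default sampling ranges: visually mild distortions.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "blur_variance": (0.25, 4.0),
    "gamma_c": (0.8, 1.2),
    "gamma_exp": (0.7, 1.5),
    "angle_abs": (2.0, 15.0),
    "noise_sigma": (0.005, 0.02),
}


def _check_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"image must be 2-D, got shape {img.shape}")
    if not np.isfinite(img).all():
        raise ValueError("image contains non-finite intensities")
    return img


def gaussian_kernel(v: float) -> np.ndarray:
    """Square Gaussian kernel of variance ``v`` (px^2), radius ceil(3*sqrt(v)).

    Entries are proportional to exp(-(x^2 + y^2) / (2v)) and normalized to
    sum exactly 1.
    """
    if v <= 0:
        raise ValueError(f"blur variance must be > 0, got {v}")
    radius = int(np.ceil(3.0 * np.sqrt(v)))
    ax = np.arange(-radius, radius + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    k = np.exp(-(xx**2 + yy**2) / (2.0 * v))
    return k / k.sum()


def gaussian_blur(img: np.ndarray, v: float) -> np.ndarray:
    """Convolve with :func:`gaussian_kernel`, reflect-padded borders."""
    img = _check_image(img)
    out = ndimage.convolve(img, gaussian_kernel(v), mode="reflect")
    return np.clip(out, 0.0, 1.0)


def gamma_shift(img: np.ndarray, c: float, gamma: float) -> np.ndarray:
    """Power-law intensity shift I' = clip(c * I**gamma, 0, 1)."""
    if c <= 0 or gamma <= 0:
        raise ValueError(f"c and gamma must be > 0, got c={c}, gamma={gamma}")
    img = _check_image(img)
    return np.clip(c * np.power(img, gamma), 0.0, 1.0)


def rotate_small(img: np.ndarray, angle: float) -> np.ndarray:
    """Rotate by ``angle`` degrees about the image center.

    Bilinear interpolation; pixels rotated in from outside the frame are
    filled with 0 (background).  Restricted to |angle| <= 25 degrees so the
    anatomy stays within frame.
    """
    if abs(angle) > MAX_ANGLE:
        raise ValueError(f"|angle| must be <= {MAX_ANGLE} deg, got {angle}")
    img = _check_image(img)
    if angle == 0.0:
        return img.copy()
    phi = np.deg2rad(angle)
    c, s = np.cos(phi), np.sin(phi)
    center = (np.asarray(img.shape, dtype=float) - 1.0) / 2.0
    # inverse map: output (r', c') samples input R(-phi) @ (r'-ctr) + ctr
    rot = np.array([[c, -s], [s, c]])
    offset = center - rot @ center
    out = ndimage.affine_transform(
        img, rot, offset=offset, order=1, mode="constant", cval=0.0
    )
    return np.clip(out, 0.0, 1.0)


def add_white_noise(
    img: np.ndarray, noise_sigma: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Add zero-mean Gaussian pixel noise of sd ``noise_sigma``; clip to [0, 1]."""
    if noise_sigma < 0:
        raise ValueError(f"noise_sigma must be >= 0, got {noise_sigma}")
    img = _check_image(img)
    if noise_sigma == 0:
        return img.copy()
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    return np.clip(img + rng.normal(0.0, noise_sigma, size=img.shape), 0.0, 1.0)


# -- random pipeline ---------------------------------------------------------

def _apply(name: str, img: np.ndarray, p: TransformParams,
           rng: np.random.Generator) -> np.ndarray:
    if name == "identity":
        return img.copy()
    if name == "blur":
        return gaussian_blur(img, p.blur_variance)
    if name == "gamma":
        return gamma_shift(img, p.gamma_c, p.gamma_exp)
    if name == "rotate":
        return rotate_small(img, p.angle)
    if name == "noise":
        return add_white_noise(img, p.noise_sigma, rng)
    raise ValueError(f"unknown transform {name!r}")


def _draw_params(rng: np.random.Generator,
                 ranges: dict[str, tuple[float, float]]) -> TransformParams:
    lo, hi = ranges["angle_abs"]
    angle = rng.choice([-1.0, 1.0]) * rng.uniform(lo, hi)
    return TransformParams(
        blur_variance=rng.uniform(*ranges["blur_variance"]),
        gamma_c=rng.uniform(*ranges["gamma_c"]),
        gamma_exp=rng.uniform(*ranges["gamma_exp"]),
        angle=float(angle),
        noise_sigma=rng.uniform(*ranges["noise_sigma"]),
    )


@dataclass(frozen=True)
class AugmentationPlan:
    """Transform registry, parameter ranges, target size and seed.

    One transform is drawn per emitted image; set ``chain=True`` to apply
    every registered transform in sequence instead.
    """

    transforms: tuple[str, ...] = ("blur", "gamma", "rotate", "noise")
    param_ranges: dict = field(default_factory=lambda: dict(DEFAULT_RANGES))
    n_target: int = 0
    seed: int = 0
    chain: bool = False

    def __post_init__(self) -> None:
        if not self.transforms:
            raise ValueError("transform registry must be non-empty")
        if "mirror" in self.transforms or "flip" in self.transforms:
            raise ValueError("mirroring is not permitted (chirality preservation)")


def _content_hash(img: np.ndarray) -> bytes:
    return hashlib.sha1(to_uint8(img).tobytes()).digest()


def augment_dataset(source: ImageSet, plan: AugmentationPlan):
    """Emit ``plan.n_target`` augmented images by repeated random draws.

    Per emission: draw a source image with replacement, a transform from the
    registry, and its parameters from the ranges; the label is inherited.
    Exact duplicates (8-bit content hash) of already-emitted images are
    redrawn.  Fully reproducible under ``plan.seed``.  Returns the augmented
    :class:`ImageSet` and a provenance list of (source index, transform,
    params) records.
    """
    if len(source) == 0:
        raise ValueError("source dataset is empty")
    if plan.n_target < len(source):
        raise ValueError(
            f"n_target ({plan.n_target}) must be >= source size ({len(source)})"
        )
    rng = np.random.default_rng(plan.seed)
    images, labels, provenance = [], [], []
    seen: set[bytes] = set()
    attempts_left = 100 * plan.n_target
    while len(images) < plan.n_target:
        if attempts_left <= 0:
            raise RuntimeError(
                "could not emit enough distinct images; widen parameter ranges"
            )
        attempts_left -= 1
        i = int(rng.integers(len(source)))
        img = source.images[i]
        params = _draw_params(rng, plan.param_ranges)
        if plan.chain:
            names = list(plan.transforms)
        else:
            names = [plan.transforms[int(rng.integers(len(plan.transforms)))]]
        for name in names:
            img = _apply(name, img, params, rng)
        h = _content_hash(img)
        if h in seen:
            continue
        seen.add(h)
        images.append(img)
        labels.append(int(source.labels[i]))
        provenance.append(
            {"source": source.names[i], "transforms": names,
             "params": {k: getattr(params, k) for k in
                        ("blur_variance", "gamma_c", "gamma_exp",
                         "angle", "noise_sigma")}}
        )
    return ImageSet(np.stack(images), np.asarray(labels)), provenance


def oversample_minority(labels, seed: int) -> np.ndarray:
    """Indices that balance every class up to the majority count.

    Original indices are kept; the top-up indices are drawn uniformly with
    replacement from each minority class's own indices.  Already-balanced
    input comes back unchanged.
    """
    labels = np.asarray(labels)
    if len(labels) == 0:
        raise ValueError("labels must be non-empty")
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(labels, return_counts=True)
    majority = counts.max()
    out = [np.arange(len(labels))]
    for cls, cnt in zip(classes, counts):
        deficit = majority - cnt
        if deficit:
            pool = np.flatnonzero(labels == cls)
            out.append(rng.choice(pool, size=deficit, replace=True))
    return np.concatenate(out)
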