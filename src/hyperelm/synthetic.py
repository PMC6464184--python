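"""Synthetic multichannel ridge-texture datasets and noise corruptions.

The generator emulates registered multispectral palmprint regions of
interest: each identity (class) is defined by a random mixture of oriented
sinusoidal ridge components, each spectral channel sees a blend of that
shared class structure with channel-specific texture (controlled by the
coupling ``gamma``), and individual acquisitions of the same palm differ by
a small random translation and pixelwise Gaussian jitter.  Pixels live on
the 8-bit [0, 255] scale so that the three standard robustness corruptions
— additive Gaussian noise, salt & pepper and multiplicative speckle — act
on the scale their conventional parameter values assume.

All randomness flows from the configuration seed; rerunning any operation
with the same seed is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image

from .dataset import MultichannelDataset
from .preprocessing import intensity_normalize, vectorize_image

__all__ = [
    "SynthConfig",
    "generate_images",
    "images_to_dataset",
    "generate_dataset",
    "write_dataset_images",
    "add_gaussian_noise",
    "add_salt_pepper",
    "add_speckle",
    "apply_noise",
    "NOISE_MODELS",
]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic multichannel benchmark.

    Defaults define the package's standard benchmark: 20 identities, 10
    acquisitions each, four registered 32 x 32 channels.  ``channel_coupling``
    is the fraction of a channel's texture shared with the class template
    (1 = all channels identical, 0 = unrelated); ``jitter_std`` is the
    within-class pixel noise on the 8-bit scale and ``max_shift`` the
    largest per-acquisition translation in pixels.
    """

    n_classes: int = 20
    samples_per_class: int = 10
    n_channels: int = 4
    image_size: int = 32
    texture_components: int = 6
    channel_coupling: float = 0.65
    jitter_std: float = 20.0
    max_shift: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2 or self.samples_per_class < 2:
            raise ValueError("need at least 2 classes and 2 samples per class")
        if self.n_channels < 1 or self.image_size < 8:
            raise ValueError("need >= 1 channel and image size >= 8")
        if not 0.0 <= self.channel_coupling <= 1.0:
            raise ValueError("channel_coupling must lie in [0, 1]")
        if self.jitter_std < 0 or self.max_shift < 0:
            raise ValueError("jitter_std and max_shift must be non-negative")

    def with_seed(self, seed: int) -> "SynthConfig":
        return replace(self, seed=seed)


def _ridge_texture(rng: np.random.Generator, size: int, components: int) -> np.ndarray:
    """A zero-mean mixture of oriented sinusoids, the ridge-like template."""
    y, x = np.mgrid[0:size, 0:size] / size
    tex = np.zeros((size, size))
    for _ in range(components):
        freq = rng.uniform(2.0, 6.0)            # cycles across the image
        theta = rng.uniform(0.0, np.pi)
        phase = rng.uniform(0.0, 2 * np.pi)
        amp = rng.uniform(0.5, 1.0)
        tex += amp * np.sin(
            2 * np.pi * freq * (x * np.cos(theta) + y * np.sin(theta)) + phase
        )
    return tex


def generate_images(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Generate raw 8-bit-scale images: (N, n_channels, H, W) plus labels.

    Per class a base template is drawn; per channel the template is
    ``gamma * base + (1 - gamma) * channel-specific texture`` mapped
    linearly onto [0, 255]; per acquisition the channel image is shifted by
    a common random translation (channels stay registered) and perturbed by
    Gaussian jitter, then clipped back to [0, 255].
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    size = cfg.image_size
    gamma = cfg.channel_coupling
    n_total = cfg.n_classes * cfg.samples_per_class
    images = np.empty((n_total, cfg.n_channels, size, size))
    labels = np.empty(n_total, dtype=int)

    i = 0
    for cls in range(cfg.n_classes):
        base = _ridge_texture(rng, size, cfg.texture_components)
        templates = []
        for _ in range(cfg.n_channels):
            variant = _ridge_texture(rng, size, cfg.texture_components)
            tpl = gamma * base + (1.0 - gamma) * variant
            lo, hi = tpl.min(), tpl.max()
            templates.append(255.0 * (tpl - lo) / (hi - lo) if hi > lo else
                             np.full_like(tpl, 127.5))
        for _ in range(cfg.samples_per_class):
            dy, dx = rng.integers(-cfg.max_shift, cfg.max_shift + 1, size=2)
            for j, tpl in enumerate(templates):
                img = np.roll(tpl, (dy, dx), axis=(0, 1))
                img = img + rng.normal(0.0, cfg.jitter_std, size=img.shape)
                images[i, j] = np.clip(img, 0.0, 255.0)
            labels[i] = cls
            i += 1
    return images, labels


def images_to_dataset(
    images: np.ndarray,
    labels: np.ndarray,
    channel_names=None,
) -> MultichannelDataset:
    """Normalize and vectorize raw (N, C, H, W) images into a dataset."""
    images = np.asarray(images, dtype=float)
    n, c = images.shape[:2]
    channels = [
        np.vstack([
            vectorize_image(intensity_normalize(images[i, j])) for i in range(n)
        ])
        for j in range(c)
    ]
    if channel_names is None:
        channel_names = [f"band{j}" for j in range(c)]
    return MultichannelDataset(channels, labels, list(channel_names))


def generate_dataset(cfg: SynthConfig) -> MultichannelDataset:
    """Generate, normalize and vectorize the synthetic benchmark in one call."""
    images, labels = generate_images(cfg)
    return images_to_dataset(images, labels)


def write_dataset_images(images, labels, root, channel_names=None) -> None:
    """Write raw images to the per-channel folder layout the loader reads.

    Files are named ``subject<label>_<index>.png``; pixel values are rounded
    to 8-bit grayscale PNG.
    """
    images = np.asarray(images)
    root = Path(root)
    n, c = images.shape[:2]
    if channel_names is None:
        channel_names = [f"band{j}" for j in range(c)]
    counters: dict[int, int] = {}
    for name in channel_names:
        (root / name).mkdir(parents=True, exist_ok=True)
    for i in range(n):
        lab = int(labels[i])
        idx = counters.get(lab, 0)
        counters[lab] = idx + 1
        for j, name in enumerate(channel_names):
            img = np.clip(np.round(images[i, j]), 0, 255).astype(np.uint8)
            Image.fromarray(img, mode="L").save(
                root / name / f"subject{lab:03d}_{idx}.png"
            )


# ---------------------------------------------------------------------------
# noise corruptions (8-bit scale; applied before intensity normalization)
# ---------------------------------------------------------------------------

def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def add_gaussian_noise(img, mean: float = 0.0, std: float = 36.0, seed=0) -> np.ndarray:
    """Additive Gaussian white noise on the [0, 255] scale, clipped."""
    img = np.asarray(img, dtype=float)
    if std == 0.0 and mean == 0.0:
        return img.copy()
    out = img + _rng(seed).normal(mean, std, size=img.shape)
    return np.clip(out, 0.0, 255.0)


def add_salt_pepper(img, density: float = 0.10, seed=0) -> np.ndarray:
    """Salt & pepper: a ``density`` fraction of pixels forced to 0 or 255."""
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must lie in [0, 1]")
    img = np.asarray(img, dtype=float).copy()
    if density == 0.0:
        return img
    rng = _rng(seed)
    hit = rng.random(img.shape) < density
    salt = rng.random(img.shape) < 0.5
    img[hit & salt] = 255.0
    img[hit & ~salt] = 0.0
    return img


def add_speckle(img, variance: float = 0.05, seed=0) -> np.ndarray:
    """Multiplicative speckle ``I * (1 + u)`` with zero-mean uniform ``u``.

    ``u`` is uniform on ``[-a, a]`` with ``a = sqrt(3 * variance)`` so that
    Var(u) equals ``variance`` — the convention of the common imaging
    toolboxes.  Output is clipped to [0, 255].
    """
    if variance < 0:
        raise ValueError("variance must be non-negative")
    img = np.asarray(img, dtype=float)
    if variance == 0.0:
        return img.copy()
    half_width = np.sqrt(3.0 * variance)
    u = _rng(seed).uniform(-half_width, half_width, size=img.shape)
    return np.clip(img * (1.0 + u), 0.0, 255.0)


NOISE_MODELS = {
    "gaussian": add_gaussian_noise,
    "saltpepper": add_salt_pepper,
    "speckle": add_speckle,
}


def apply_noise(images: np.ndarray, kind: str, seed=0) -> np.ndarray:
    """Apply one named corruption (at its standard parameters) to a stack."""
    if kind in (None, "none"):
        return np.asarray(images, dtype=float).copy()
    try:
        fn = NOISE_MODELS[kind]
    except KeyError:
        raise ValueError(
            f"unknown noise model {kind!r}; expected one of {sorted(NOISE_MODELS)}"
        ) from None
    return fn(images, seed=seed)
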