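"""Image normalization, dataset loading/splitting and model persistence.

Datasets on disk follow a per-channel folder layout::

    root/
      <channel>/<subject>_<index>.png      (PNG/BMP/JPEG, grayscale)

Every sample must be present in every channel folder under the same
``<subject>_<index>`` stem.  Loading applies per-image global min-max
intensity normalization (removing global illumination differences between
acquisitions) and row-major vectorization, producing a
:class:`~hyperelm.dataset.MultichannelDataset` whose labels are a contiguous
relabeling of the sorted subject ids.

Models (plain ELM or HELM) are persisted as a single ``.npz`` archive of
named real arrays plus a JSON config block; hypercomplex matrices are stored
as their component matrices ``comp0 .. compd``.
"""

from __future__ import annotations

import json
import warnings
import zipfile
from pathlib import Path

import numpy as np
from PIL import Image

from .dataset import MultichannelDataset
from .elm import ELMModel
from .helm import FusionStats, HELMModel
from .hypercomplex import HCMatrix

__all__ = [
    "intensity_normalize",
    "vectorize_image",
    "unvectorize_image",
    "load_multichannel_dataset",
    "split_dataset",
    "stratified_split_indices",
    "save_model",
    "load_model",
    "ModelFormatError",
]

MODEL_FORMAT_VERSION = 1

IMAGE_EXTENSIONS = (".png", ".bmp", ".jpg", ".jpeg")


def intensity_normalize(img: np.ndarray) -> np.ndarray:
    """Rescale an image to [0, 1] by its own global min and max.

    ``(I - min) / (max - min)``; a constant image maps to all zeros (it
    carries no structure, so the neutral vector is returned rather than
    dividing by zero).
    """
    img = np.asarray(img, dtype=float)
    lo = img.min()
    hi = img.max()
    if hi == lo:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def vectorize_image(img: np.ndarray) -> np.ndarray:
    """Flatten an H x W image to a 1 x (H*W) row vector, row-major."""
    img = np.asarray(img, dtype=float)
    return img.reshape(1, -1)


def unvectorize_image(vec: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Inverse of :func:`vectorize_image` given the original (H, W)."""
    return np.asarray(vec, dtype=float).reshape(shape)


def _read_gray(path: Path, resize: int | None) -> np.ndarray:
    with Image.open(path) as im:
        im = im.convert("L")
        if resize is not None:
            im = im.resize((resize, resize), Image.BILINEAR)
        return np.asarray(im, dtype=float)


def _sample_key(stem: str) -> tuple[str, int]:
    """Split ``<subject>_<index>`` at the last underscore."""
    subject, _, idx = stem.rpartition("_")
    if not subject:
        raise ValueError(
            f"file stem {stem!r} does not follow the <subject>_<index> pattern"
        )
    return subject, int(idx)


def load_multichannel_dataset(
    root,
    channel_names,
    resize: int | None = None,
) -> MultichannelDataset:
    """Load a per-channel image folder tree into a dataset.

    Channel order in ``channel_names`` fixes the channel-to-hypercomplex-unit
    mapping downstream (first name -> real slot).  All channels must contain
    the same sample stems; images must share one size unless ``resize`` is
    given (bilinear square resize).
    """
    root = Path(root)
    channel_names = list(channel_names)
    if not channel_names:
        raise ValueError("at least one channel name is required")
    first_dir = root / channel_names[0]
    if not first_dir.is_dir():
        raise FileNotFoundError(f"channel folder not found: {first_dir}")

    stems = sorted(
        (p.stem for p in first_dir.iterdir() if p.suffix.lower() in IMAGE_EXTENSIONS),
        key=_sample_key,
    )
    if not stems:
        raise FileNotFoundError(f"no images found under {first_dir}")

    def find(channel: str, stem: str) -> Path:
        for ext in IMAGE_EXTENSIONS:
            p = root / channel / f"{stem}{ext}"
            if p.exists():
                return p
        raise FileNotFoundError(
            f"sample {stem!r} missing from channel folder {root / channel}"
        )

    subjects = sorted({_sample_key(s)[0] for s in stems})
    label_of = {s: i for i, s in enumerate(subjects)}

    channels: list[list[np.ndarray]] = [[] for _ in channel_names]
    labels = []
    shape = None
    for stem in stems:
        labels.append(label_of[_sample_key(stem)[0]])
        for j, name in enumerate(channel_names):
            img = _read_gray(find(name, stem), resize)
            if shape is None:
                shape = img.shape
            elif img.shape != shape:
                raise ValueError(
                    f"image size {img.shape} of {stem!r}/{name} differs from "
                    f"{shape}; pass resize= to force a common size"
                )
            channels[j].append(vectorize_image(intensity_normalize(img))[0])

    return MultichannelDataset(
        [np.vstack(rows) for rows in channels],
        np.asarray(labels, dtype=int),
        channel_names,
    )


def stratified_split_indices(
    labels,
    train_fraction: float | None = 0.5,
    per_class: int | None = None,
    seed=0,
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test index split, stratified per class.

    Either a train fraction (rounded per class) or an absolute per-class
    train count may be given; shuffling within each class is driven by the
    seed alone.
    """
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        if per_class is not None:
            k = per_class
            if not 0 < k <= len(idx):
                raise ValueError(
                    f"cannot take {k} training samples from class {cls} "
                    f"with {len(idx)} samples"
                )
        else:
            if len(idx) < 2:
                raise ValueError(
                    f"class {cls} has {len(idx)} sample(s); fractional splits "
                    "need at least 2 per class"
                )
            k = int(round(train_fraction * len(idx)))
            if not 0 < k < len(idx):
                raise ValueError(
                    f"train fraction {train_fraction} leaves an empty partition "
                    f"for class {cls} ({len(idx)} samples)"
                )
        train_idx.append(idx[:k])
        test_idx.append(idx[k:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def split_dataset(
    ds: MultichannelDataset,
    train_fraction: float | None = 0.5,
    per_class: int | None = None,
    seed=0,
) -> tuple[MultichannelDataset, MultichannelDataset]:
    """Stratified, seed-reproducible train/test split of a dataset."""
    tr, te = stratified_split_indices(
        ds.labels, train_fraction=train_fraction, per_class=per_class, seed=seed
    )
    return ds.subset(tr), ds.subset(te)


# ---------------------------------------------------------------------------
# model persistence
# ---------------------------------------------------------------------------

class ModelFormatError(RuntimeError):
    """Raised for unreadable, corrupt or incompatible model files."""


def save_model(model, path) -> None:
    """Serialize an :class:`ELMModel` or :class:`HELMModel` to ``.npz``."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    if isinstance(model, HELMModel):
        config = {
            "format_version": MODEL_FORMAT_VERSION,
            "kind": "helm",
            "activation": model.activation,
            "ridge": model.ridge,
            "solver": model.solver,
            "n_classes": model.n_classes,
            "channel_names": model.channel_names,
            "seed": model.seed,
        }
        for j, a in enumerate(model.alphas):
            arrays[f"alpha{j}"] = a
        for k in range(model.d + 1):
            arrays[f"beta_comp{k}"] = model.beta.components[k]
        if model.fusion_stats is not None:
            arrays["fusion_min_t"] = model.fusion_stats.min_t
            arrays["fusion_max_t"] = model.fusion_stats.max_t
    elif isinstance(model, ELMModel):
        config = {
            "format_version": MODEL_FORMAT_VERSION,
            "kind": "elm",
            "activation": model.activation,
            "ridge": model.ridge,
            "n_classes": model.n_classes,
        }
        arrays["alpha"] = model.alpha
        arrays["beta"] = model.beta
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    arrays["config_json"] = np.frombuffer(
        json.dumps(config).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_model(path):
    """Load a model saved by :func:`save_model`; raises on corrupt files."""
    path = Path(path)
    try:
        with np.load(path) as npz:
            data = {k: npz[k] for k in npz.files}
    except (OSError, ValueError, zipfile.BadZipFile, KeyError) as exc:
        raise ModelFormatError(f"cannot read model file {path}: {exc}") from exc
    if "config_json" not in data:
        raise ModelFormatError(f"{path} is not a model file (missing config)")
    try:
        config = json.loads(bytes(data["config_json"].tobytes()).decode())
    except (UnicodeDecodeError, json.JSONDecodeError) as exc:
        raise ModelFormatError(f"corrupt config block in {path}: {exc}") from exc
    version = config.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"unsupported model format version {version!r} in {path}"
        )
    try:
        if config["kind"] == "helm":
            alphas = []
            while f"alpha{len(alphas)}" in data:
                alphas.append(data[f"alpha{len(alphas)}"])
            comps = []
            while f"beta_comp{len(comps)}" in data:
                comps.append(data[f"beta_comp{len(comps)}"])
            stats = None
            if "fusion_min_t" in data:
                stats = FusionStats(data["fusion_min_t"], data["fusion_max_t"])
            return HELMModel(
                alphas=alphas,
                beta=HCMatrix(np.stack(comps)),
                fusion_stats=stats,
                activation=config["activation"],
                ridge=config["ridge"],
                solver=config["solver"],
                n_classes=config["n_classes"],
                channel_names=config["channel_names"],
                seed=config.get("seed"),
            )
        if config["kind"] == "elm":
            return ELMModel(
                alpha=data["alpha"],
                beta=data["beta"],
                activation=config["activation"],
                ridge=config["ridge"],
                n_classes=config["n_classes"],
            )
    except (KeyError, ValueError) as exc:
        raise ModelFormatError(f"corrupt model file {path}: {exc}") from exc
    raise ModelFormatError(f"unknown model kind {config.get('kind')!r} in {path}")
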