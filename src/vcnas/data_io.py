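"""Dataset containers, format readers, splitting and synthetic images.

Three real-data formats are supported: IDX image/label pairs (the MNIST
container), CIFAR-10 binary batches, and folders of labelled RGB image
patches with a CSV manifest (the layout used for 64×64 histopathology
mitosis patches).  All readers return the same in-memory container, a
:class:`DatasetBundle` of float images in ``[0, 1]`` with integer labels.

A seeded synthetic generator renders class-dependent Gaussian blob patterns
so that every downstream component (training, the two-step structure
search, analytics) can be exercised end-to-end without downloads.
"""

from __future__ import annotations

import csv
import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "DatasetBundle",
    "SplitSpec",
    "FormatError",
    "read_idx",
    "write_idx",
    "read_cifar_batches",
    "read_patch_folder",
    "subsample_split",
    "generate_synthetic",
    "save_bundle_npz",
    "load_bundle_npz",
]

_IDX_IMAGES_MAGIC = 0x00000803
_IDX_LABELS_MAGIC = 0x00000801


class FormatError(ValueError):
    """A file does not conform to its declared binary format."""


@dataclass
class DatasetBundle:
    """Images (N, H, W, C) in [0, 1] plus integer class labels in [0, K)."""

    images: np.ndarray
    labels: np.ndarray
    n_classes: int
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.images.ndim != 4:
            raise ValueError("images must be a (N, H, W, C) array")
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels must have equal length")
        if len(self.labels) and (
            self.labels.min() < 0 or self.labels.max() >= self.n_classes
        ):
            raise ValueError("labels must lie in [0, n_classes)")
        if len(self.images) and (
            self.images.min() < 0.0 or self.images.max() > 1.0
        ):
            raise ValueError("pixel values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def image_shape(self) -> tuple[int, int, int]:
        return tuple(self.images.shape[1:])

    def take(self, indices: np.ndarray, provenance: str | None = None) -> "DatasetBundle":
        return DatasetBundle(
            self.images[indices],
            self.labels[indices],
            self.n_classes,
            provenance or self.provenance,
        )


@dataclass(frozen=True)
class SplitSpec:
    """Sizes of the disjoint train/validation/test subsets, plus the seed."""

    train_n: int
    val_n: int
    test_n: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.train_n, self.val_n, self.test_n) < 0:
            raise ValueError("split sizes must be non-negative")

    @property
    def total(self) -> int:
        return self.train_n + self.val_n + self.test_n


def read_idx(images_path, labels_path) -> DatasetBundle:
    """Read an IDX image/label file pair (big-endian, MNIST layout)."""
    images_path, labels_path = Path(images_path), Path(labels_path)
    with open(images_path, "rb") as fh:
        header = fh.read(16)
        if len(header) < 16:
            raise FormatError(f"{images_path}: truncated IDX header")
        magic, n, rows, cols = struct.unpack(">IIII", header)
        if magic != _IDX_IMAGES_MAGIC:
            raise FormatError(f"{images_path}: bad IDX magic {magic:#010x}")
        raw = fh.read(n * rows * cols)
        if len(raw) != n * rows * cols:
            raise FormatError(f"{images_path}: truncated IDX pixel data")
    images = np.frombuffer(raw, dtype=np.uint8).reshape(n, rows, cols, 1)
    with open(labels_path, "rb") as fh:
        header = fh.read(8)
        if len(header) < 8:
            raise FormatError(f"{labels_path}: truncated IDX header")
        magic, n_labels = struct.unpack(">II", header)
        if magic != _IDX_LABELS_MAGIC:
            raise FormatError(f"{labels_path}: bad IDX magic {magic:#010x}")
        raw = fh.read(n_labels)
        if len(raw) != n_labels:
            raise FormatError(f"{labels_path}: truncated IDX label data")
    if n_labels != n:
        raise FormatError(
            f"label count {n_labels} does not match image count {n}"
        )
    labels = np.frombuffer(raw, dtype=np.uint8).astype(np.int64)
    n_classes = int(labels.max()) + 1 if n else 10
    return DatasetBundle(images / 255.0, labels, max(n_classes, 2), "mnist")


def write_idx(bundle: DatasetBundle, images_path, labels_path) -> None:
    """Write a single-channel bundle as an IDX image/label pair."""
    if bundle.image_shape[2] != 1:
        raise ValueError("IDX image files hold single-channel images")
    n, rows, cols, _ = bundle.images.shape
    pixels = np.round(bundle.images[..., 0] * 255.0).astype(np.uint8)
    with open(images_path, "wb") as fh:
        fh.write(struct.pack(">IIII", _IDX_IMAGES_MAGIC, n, rows, cols))
        fh.write(pixels.tobytes())
    with open(labels_path, "wb") as fh:
        fh.write(struct.pack(">II", _IDX_LABELS_MAGIC, n))
        fh.write(bundle.labels.astype(np.uint8).tobytes())


def read_cifar_batches(directory) -> DatasetBundle:
    """Read CIFAR-10 binary batches (3073-byte rows: label + 3072 pixels).

    Every file in ``directory`` matching ``*_batch*.bin`` or ``*.bin`` is
    read, in sorted order.  Pixels are stored planar R, G, B, row-major.
    """
    directory = Path(directory)
    files = sorted(directory.glob("*.bin"))
    if not files:
        raise FileNotFoundError(f"no CIFAR .bin batches in {directory}")
    images, labels = [], []
    row_bytes = 1 + 3072
    for path in files:
        raw = path.read_bytes()
        if len(raw) % row_bytes:
            raise FormatError(f"{path}: size {len(raw)} not a multiple of {row_bytes}")
        rows = np.frombuffer(raw, dtype=np.uint8).reshape(-1, row_bytes)
        labels.append(rows[:, 0].astype(np.int64))
        # planar RGB -> (N, 32, 32, 3)
        images.append(rows[:, 1:].reshape(-1, 3, 32, 32).transpose(0, 2, 3, 1))
    images_arr = np.concatenate(images) / 255.0
    labels_arr = np.concatenate(labels)
    return DatasetBundle(images_arr, labels_arr, 10, "cifar10")


def read_patch_folder(directory, manifest_csv) -> DatasetBundle:
    """Read labelled RGB image patches (PNG/TIFF) via a CSV manifest.

    The manifest has columns ``filename,label``; labels are mapped to
    contiguous integer ids in sorted label order.
    """
    from PIL import Image

    directory = Path(directory)
    rows = []
    with open(manifest_csv, newline="") as fh:
        for rec in csv.DictReader(fh):
            rows.append((rec["filename"], rec["label"]))
    if not rows:
        raise FormatError(f"{manifest_csv}: empty manifest")
    label_names = sorted({label for _, label in rows})
    label_ids = {name: i for i, name in enumerate(label_names)}
    images, labels = [], []
    for filename, label in rows:
        path = directory / filename
        if not path.exists():
            raise FileNotFoundError(f"manifest entry not found: {path}")
        with Image.open(path) as img:
            arr = np.asarray(img.convert("RGB"), dtype=np.float64) / 255.0
        images.append(arr)
        labels.append(label_ids[label])
    return DatasetBundle(
        np.stack(images), np.asarray(labels), len(label_names), "patches"
    )


def subsample_split(
    bundle: DatasetBundle, sizes: SplitSpec, stratify: bool = False
) -> tuple[DatasetBundle, DatasetBundle, DatasetBundle]:
    """Seeded uniform subsample of ``bundle`` into disjoint train/val/test.

    Sampling is uniform without replacement over the whole bundle
    (class-stratification is available but off by default).
    """
    if sizes.total > len(bundle):
        raise ValueError(
            f"requested {sizes.total} samples from a bundle of {len(bundle)}"
        )
    rng = np.random.default_rng(sizes.seed)
    if stratify:
        order = []
        for cls in range(bundle.n_classes):
            cls_idx = np.flatnonzero(bundle.labels == cls)
            order.append(rng.permutation(cls_idx))
        # interleave classes so any prefix is near-balanced
        interleaved = []
        for chunk in zip(*[iter(o) for o in order]):
            interleaved.extend(chunk)
        idx = np.asarray(interleaved)
        if len(idx) < sizes.total:  # ragged class sizes: fall back to the rest
            rest = np.setdiff1d(np.arange(len(bundle)), idx, assume_unique=False)
            idx = np.concatenate([idx, rng.permutation(rest)])
    else:
        idx = rng.permutation(len(bundle))
    a, b = sizes.train_n, sizes.train_n + sizes.val_n
    c = b + sizes.test_n
    return bundle.take(idx[:a]), bundle.take(idx[a:b]), bundle.take(idx[b:c])


def _blob(size: int, cx: float, cy: float, sx: float, sy: float, theta: float) -> np.ndarray:
    """One anisotropic Gaussian bump on a size×size grid, peak value 1."""
    y, x = np.mgrid[0:size, 0:size].astype(np.float64)
    xr = (x - cx) * np.cos(theta) + (y - cy) * np.sin(theta)
    yr = -(x - cx) * np.sin(theta) + (y - cy) * np.cos(theta)
    return np.exp(-0.5 * ((xr / sx) ** 2 + (yr / sy) ** 2))


def generate_synthetic(
    n_classes: int,
    n_per_class: int | list[int],
    size: int = 28,
    channels: int = 1,
    noise_sd: float = 0.05,
    seed: int = 0,
    jitter: float = 0.03,
) -> DatasetBundle:
    """Seeded synthetic image classes built from Gaussian blob motifs.

    Each class is assigned a deterministic template — position, scale and
    orientation of one or two Gaussian bumps drawn from a class-keyed RNG —
    so classes are distinct local 2-D motifs.  Per-sample variation is a
    small spatial jitter of the template plus i.i.d. additive pixel noise
    of standard deviation ``noise_sd`` (clipped back into [0, 1]).  With
    ``noise_sd=0`` the classes are exactly separable.

    ``n_per_class`` may be a single count or a per-class list, which is how
    class imbalance (e.g. the 1:2 positive:negative mitosis ratio) is
    emulated.
    """
    if size < 8:
        raise ValueError("size must be at least 8")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    counts = (
        [int(n_per_class)] * n_classes
        if np.isscalar(n_per_class)
        else list(n_per_class)
    )
    if len(counts) != n_classes:
        raise ValueError("n_per_class list must have one entry per class")

    rng = np.random.default_rng(seed)
    images, labels = [], []
    for cls in range(n_classes):
        template_rng = np.random.default_rng(10_000 + cls)  # class identity, not noise
        n_bumps = 1 + cls % 2
        params = [
            (
                template_rng.uniform(0.25 * size, 0.75 * size),
                template_rng.uniform(0.25 * size, 0.75 * size),
                template_rng.uniform(0.08 * size, 0.2 * size),
                template_rng.uniform(0.08 * size, 0.2 * size),
                template_rng.uniform(0, np.pi),
            )
            for _ in range(n_bumps)
        ]
        channel_gain = template_rng.uniform(0.5, 1.0, size=channels)
        for _ in range(counts[cls]):
            dx, dy = rng.normal(0.0, jitter * size, size=2)
            canvas = np.zeros((size, size))
            for cx, cy, sx, sy, theta in params:
                canvas += _blob(size, cx + dx, cy + dy, sx, sy, theta)
            canvas = np.clip(canvas, 0.0, 1.0)
            img = canvas[:, :, None] * channel_gain[None, None, :]
            if noise_sd > 0:
                img = img + rng.normal(0.0, noise_sd, size=img.shape)
            images.append(np.clip(img, 0.0, 1.0))
            labels.append(cls)
    order = rng.permutation(len(labels))
    return DatasetBundle(
        np.stack(images)[order], np.asarray(labels)[order], n_classes, "synthetic"
    )


def save_bundle_npz(bundle: DatasetBundle, path) -> None:
    np.savez_compressed(
        path,
        images=bundle.images,
        labels=bundle.labels,
        n_classes=bundle.n_classes,
        provenance=bundle.provenance,
    )


def load_bundle_npz(path) -> DatasetBundle:
    with np.load(path, allow_pickle=False) as data:
        return DatasetBundle(
            data["images"],
            data["labels"],
            int(data["n_classes"]),
            str(data["provenance"]),
        )
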