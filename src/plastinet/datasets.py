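"""Labelled image-like datasets: IDX readers, zero-mean preprocessing, synthetic data.

The IDX format is the big-endian container MNIST and fashionMNIST are
distributed in: a 4-byte magic word (``0x00000803`` for uint8 image tensors,
``0x00000801`` for uint8 label vectors), one big-endian uint32 per dimension,
then raw bytes.  :func:`read_idx` loads a matching images/labels pair into a
:class:`LabeledImageSet`; :func:`write_idx_images` / :func:`write_idx_labels`
exist so tests and exports can round-trip the format.

Zero-meaning subtracts the per-feature mean of the *training* set from every
set, which removes exactly-zero inputs (a zero input freezes all plasticity on
its outgoing synapses, confounding update counts).

Synthetic datasets place one Gaussian prototype per class and add isotropic
noise; they are shaped like flattened image data so the full training pipeline
is exercisable without any download.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

IDX_MAGIC_IMAGES = 0x00000803
IDX_MAGIC_LABELS = 0x00000801


class IdxFormatError(ValueError):
    """Raised when an IDX file has the wrong magic number or is truncated."""


class DataInconsistencyError(ValueError):
    """Raised when paired data files or datasets disagree on sample counts/shapes."""


@dataclass
class LabeledImageSet:
    """Feature matrix with integer labels and one-hot targets.

    Attributes
    ----------
    features : ndarray, shape (n_samples, n_features)
        Real-valued inputs (pixel intensities scaled to [0, 1] before any
        centering, or synthetic feature vectors).
    labels : ndarray, shape (n_samples,)
        Integer class labels in ``[0, n_classes)``.
    targets : ndarray, shape (n_samples, n_classes)
        One-hot encoding of ``labels``.
    zero_meaned : bool
        Whether per-feature training means have been subtracted.
    column_means : ndarray or None
        The means that were subtracted (recorded for reuse on held-out sets).
    """

    features: np.ndarray
    labels: np.ndarray
    targets: np.ndarray
    zero_meaned: bool = False
    column_means: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.targets = np.asarray(self.targets, dtype=np.float64)
        if self.features.ndim != 2:
            raise DataInconsistencyError("features must be 2-D (n_samples, n_features)")
        if self.features.shape[0] != self.labels.shape[0]:
            raise DataInconsistencyError(
                f"{self.features.shape[0]} feature rows but {self.labels.shape[0]} labels"
            )
        if self.targets.shape != (self.labels.shape[0], self.n_classes) or not (
            np.all(np.isin(self.targets, (0.0, 1.0)))
            and np.all(self.targets.sum(axis=1) == 1.0)
        ):
            raise DataInconsistencyError("targets must be a one-hot matrix matching labels")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_classes(self) -> int:
        return self.targets.shape[1] if self.targets.ndim == 2 else int(self.labels.max()) + 1


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    return np.eye(n_classes, dtype=np.float64)[np.asarray(labels, dtype=np.int64)]


def make_labeled_set(features: np.ndarray, labels: np.ndarray, n_classes: int | None = None) -> LabeledImageSet:
    """Build a :class:`LabeledImageSet` from features and integer labels."""
    labels = np.asarray(labels, dtype=np.int64)
    if n_classes is None:
        n_classes = int(labels.max()) + 1
    return LabeledImageSet(np.asarray(features, dtype=np.float64), labels, _one_hot(labels, n_classes))


# ---------------------------------------------------------------------------
# IDX I/O
# ---------------------------------------------------------------------------

def _read_idx_array(path: str | Path, expected_magic: int) -> np.ndarray:
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 4:
        raise IdxFormatError(f"{path}: file too short for an IDX header")
    (magic,) = struct.unpack(">I", raw[:4])
    if magic != expected_magic:
        raise IdxFormatError(
            f"{path}: bad IDX magic 0x{magic:08x} (expected 0x{expected_magic:08x})"
        )
    ndim = magic & 0xFF
    header_len = 4 + 4 * ndim
    if len(raw) < header_len:
        raise IdxFormatError(f"{path}: truncated IDX dimension header")
    dims = struct.unpack(f">{ndim}I", raw[4:header_len])
    n_expected = int(np.prod(dims, dtype=np.int64))
    body = np.frombuffer(raw, dtype=np.uint8, offset=header_len)
    if body.size != n_expected:
        raise IdxFormatError(
            f"{path}: payload has {body.size} bytes, header promises {n_expected}"
        )
    return body.reshape(dims)


def read_idx(images_path: str | Path, labels_path: str | Path) -> LabeledImageSet:
    """Read an IDX images/labels file pair into a :class:`LabeledImageSet`.

    Pixel bytes are scaled to ``[0, 1]``; the result is not zero-meaned.
    """
    images = _read_idx_array(images_path, IDX_MAGIC_IMAGES)
    labels = _read_idx_array(labels_path, IDX_MAGIC_LABELS).astype(np.int64)
    if images.shape[0] != labels.shape[0]:
        raise DataInconsistencyError(
            f"{images.shape[0]} images but {labels.shape[0]} labels"
        )
    features = images.reshape(images.shape[0], -1).astype(np.float64) / 255.0
    return make_labeled_set(features, labels)


def write_idx_images(path: str | Path, images: np.ndarray) -> None:
    """Write a uint8 tensor of shape (n, rows, cols) as an IDX image file."""
    images = np.ascontiguousarray(images, dtype=np.uint8)
    if images.ndim != 3:
        raise ValueError("images must have shape (n, rows, cols)")
    with open(path, "wb") as fh:
        fh.write(struct.pack(">IIII", IDX_MAGIC_IMAGES, *images.shape))
        fh.write(images.tobytes())


def write_idx_labels(path: str | Path, labels: np.ndarray) -> None:
    """Write a uint8 label vector as an IDX label file."""
    labels = np.ascontiguousarray(labels, dtype=np.uint8)
    if labels.ndim != 1:
        raise ValueError("labels must be 1-D")
    with open(path, "wb") as fh:
        fh.write(struct.pack(">II", IDX_MAGIC_LABELS, labels.shape[0]))
        fh.write(labels.tobytes())


# ---------------------------------------------------------------------------
# Zero-meaning
# ---------------------------------------------------------------------------

def zero_mean(
    train: LabeledImageSet, others: tuple[LabeledImageSet, ...] | list[LabeledImageSet] = ()
) -> tuple[LabeledImageSet, ...]:
    """Subtract per-feature *training* means from the train set and every other set.

    Returns ``(train', *others')``.  Held-out sets are shifted by the training
    means, so their own column means need not be zero afterwards.
    """
    if train.zero_meaned:
        raise ValueError("training set is already zero-meaned")
    for other in others:
        if other.n_features != train.n_features:
            raise DataInconsistencyError(
                f"feature dimension mismatch: {other.n_features} != {train.n_features}"
            )
    means = train.features.mean(axis=0)
    out = [
        replace(train, features=train.features - means, zero_meaned=True, column_means=means.copy())
    ]
    for other in others:
        out.append(
            replace(other, features=other.features - means, zero_meaned=True, column_means=means.copy())
        )
    return tuple(out)


# ---------------------------------------------------------------------------
# Synthetic data
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the prototype-plus-noise synthetic generator."""

    n_classes: int = 10
    n_features: int = 784
    n_train: int = 2000
    n_valid: int = 500
    prototype_scale: float = 1.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2 or self.n_features < 2:
            raise ValueError("need n_classes >= 2 and n_features >= 2")
        if self.n_train < self.n_classes:
            raise ValueError("n_train must be at least n_classes")
        if not (np.isfinite(self.noise_sd) and self.noise_sd >= 0):
            raise ValueError("noise_sd must be finite and >= 0")
        if not (np.isfinite(self.prototype_scale) and self.prototype_scale > 0):
            raise ValueError("prototype_scale must be finite and > 0")


def make_synthetic(spec: SyntheticSpec) -> tuple[LabeledImageSet, LabeledImageSet]:
    """Generate a zero-meaned (train, valid) pair from a :class:`SyntheticSpec`.

    Each class has a fixed Gaussian prototype (sd ``prototype_scale``); samples
    are prototype plus isotropic Gaussian noise (sd ``noise_sd``).  Output is
    deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    protos = rng.normal(0.0, spec.prototype_scale, size=(spec.n_classes, spec.n_features))

    def draw(n: int) -> LabeledImageSet:
        labels = rng.integers(0, spec.n_classes, size=n)
        feats = protos[labels]
        if spec.noise_sd > 0:
            feats = feats + rng.normal(0.0, spec.noise_sd, size=(n, spec.n_features))
        else:
            feats = feats.copy()
        return make_labeled_set(feats, labels, spec.n_classes)

    train = draw(spec.n_train)
    valid = draw(spec.n_valid)
    train, valid = zero_mean(train, [valid])
    return train, valid


# ---------------------------------------------------------------------------
# CSV export / import (plain-text persistence of generated datasets)
# ---------------------------------------------------------------------------

def save_csv(dataset: LabeledImageSet, features_path: str | Path, labels_path: str | Path) -> None:
    np.savetxt(features_path, dataset.features, delimiter=",")
    np.savetxt(labels_path, dataset.labels, fmt="%d")


def load_csv(features_path: str | Path, labels_path: str | Path, n_classes: int | None = None) -> LabeledImageSet:
    features = np.atleast_2d(np.loadtxt(features_path, delimiter=","))
    labels = np.atleast_1d(np.loadtxt(labels_path, dtype=np.int64))
    return make_labeled_set(features, labels, n_classes)


def load_mnist(directory: str | Path, kind: str = "train") -> LabeledImageSet:
    """Load MNIST/fashionMNIST IDX files from ``directory``.

    Expects the standard file names (``train-images-idx3-ubyte`` /
    ``train-labels-idx1-ubyte``, or the ``t10k-`` pair for ``kind='test'``),
    optionally gzip-compressed (``.gz`` suffix).  See the README for the
    manual download step.
    """
    import gzip
    import shutil
    import tempfile

    prefix = {"train": "train", "test": "t10k"}[kind]
    directory = Path(directory)
    paths = []
    for stem in (f"{prefix}-images-idx3-ubyte", f"{prefix}-labels-idx1-ubyte"):
        plain = directory / stem
        gz = directory / f"{stem}.gz"
        if plain.exists():
            paths.append(plain)
        elif gz.exists():
            tmp = Path(tempfile.mkdtemp()) / stem
            with gzip.open(gz, "rb") as src, open(tmp, "wb") as dst:
                shutil.copyfileobj(src, dst)
            paths.append(tmp)
        else:
            raise FileNotFoundError(f"missing {plain} (or {gz})")
    return read_idx(paths[0], paths[1])
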