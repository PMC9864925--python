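"""Synthetic dataset generation, SMOTE balancing, splitting and client partitioning.

The federated protocol in this package assumes a multi-class, imbalanced image
corpus partitioned across clients (the motivating application is chest-X-ray
classification into six disease categories).  This module supplies that
statistical structure without any external download:

* :func:`generate_synthetic_dataset` draws class-templated grayscale images —
  each class is a Gaussian blob at a class-specific location and scale, plus
  i.i.d. pixel noise, with a single ``separability`` knob controlling how far
  apart the class templates sit relative to the noise.
* :func:`smote_oversample` balances classes with SMOTE: synthetic minority
  samples are linear interpolations between a sample and one of its k nearest
  same-class neighbours in flattened pixel space.
* :func:`stratified_split` performs the per-class train/validation/test split
  (default 80/10/10) with floor rounding and the remainder assigned to train.
* :func:`partition_clients` distributes a dataset across clients either IID or
  with Dirichlet-controlled class skew (non-IID).

All operations are deterministic given their seed.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._rng import child_rng

__all__ = [
    "ImageSample",
    "LabeledDataset",
    "SplitSpec",
    "ClientPartition",
    "generate_synthetic_dataset",
    "smote_oversample",
    "stratified_split",
    "partition_clients",
    "save_image_directory",
    "load_image_directory",
    "save_archive",
    "load_archive",
]

PROVENANCES = ("original", "synthetic_smote", "generated")

# noise level of the generator; the separability knob scales the template
# amplitude relative to this
_NOISE_SIGMA = 0.15


@dataclass(frozen=True)
class ImageSample:
    """One labeled grayscale image.

    Parameters
    ----------
    id : unique string within a dataset.
    pixels : 2-D float array, intensities in [0, 1].
    label : class index in ``{0..K-1}``.
    provenance : one of ``original``, ``synthetic_smote``, ``generated``.
    """

    id: str
    pixels: np.ndarray
    label: int
    provenance: str = "original"

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if px.size and (px.min() < -1e-12 or px.max() > 1 + 1e-12):
            raise ValueError("pixel intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)


@dataclass
class LabeledDataset:
    """Ordered collection of :class:`ImageSample` with a per-class manifest."""

    samples: list[ImageSample]
    class_names: list[str]

    def __post_init__(self) -> None:
        if len(self.class_names) < 2:
            raise ValueError("a labeled dataset needs at least K=2 classes")
        seen: set[str] = set()
        for s in self.samples:
            if s.label < 0 or s.label >= len(self.class_names):
                raise ValueError(f"label {s.label} out of range for K={self.num_classes}")
            if s.id in seen:
                raise ValueError(f"duplicate sample id {s.id!r}")
            seen.add(s.id)

    @property
    def num_classes(self) -> int:
        return len(self.class_names)

    @property
    def manifest(self) -> dict[int, int]:
        """Observed per-class sample counts, keyed by class index."""
        counts = dict.fromkeys(range(self.num_classes), 0)
        for s in self.samples:
            counts[s.label] += 1
        return counts

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def ids(self) -> list[str]:
        return [s.id for s in self.samples]

    def pixels_array(self) -> np.ndarray:
        """Stack all images into an (n, H, W) float64 array."""
        return np.stack([s.pixels for s in self.samples]) if self.samples else np.empty((0, 0, 0))

    def labels_array(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=np.int64)

    def subset(self, indices: Iterable[int]) -> "LabeledDataset":
        return LabeledDataset([self.samples[i] for i in indices], list(self.class_names))

    def by_class(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {k: [] for k in range(self.num_classes)}
        for i, s in enumerate(self.samples):
            out[s.label].append(i)
        return out


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test fractions; must sum to 1."""

    train_fraction: float = 0.8
    validation_fraction: float = 0.1
    test_fraction: float = 0.1

    def __post_init__(self) -> None:
        fracs = (self.train_fraction, self.validation_fraction, self.test_fraction)
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("split fractions must lie in [0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {sum(fracs)}")


@dataclass
class ClientPartition:
    """One client's local data: disjoint train/validation/test datasets."""

    client_id: str
    train: LabeledDataset
    validation: LabeledDataset
    test: LabeledDataset

    def __post_init__(self) -> None:
        ids = [set(self.train.ids()), set(self.validation.ids()), set(self.test.ids())]
        for a in range(3):
            for b in range(a + 1, 3):
                if ids[a] & ids[b]:
                    raise ValueError("client partition members must be pairwise disjoint")

    @property
    def size(self) -> int:
        return len(self.train) + len(self.validation) + len(self.test)


def _class_template(k: int, num_classes: int, image_size: tuple[int, int]) -> np.ndarray:
    """Deterministic spatial pattern for class k: a Gaussian blob on a ring.

    The blob centre moves around a ring with the class index and its width
    cycles through three scales, so between-class templates differ in both
    location and extent.
    """
    H, W = image_size
    r = 0.30 * min(H, W)
    ang = 2.0 * math.pi * k / num_classes
    cy = (H - 1) / 2.0 + r * math.sin(ang)
    cx = (W - 1) / 2.0 + r * math.cos(ang)
    sigma = 0.10 * min(H, W) * (1.0 + 0.3 * (k % 3))
    yy, xx = np.mgrid[0:H, 0:W]
    tpl = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2)))
    return tpl / tpl.max()


def generate_synthetic_dataset(
    class_counts: Sequence[int],
    image_size: tuple[int, int] = (32, 32),
    separability: float = 3.0,
    seed: int = 0,
    class_names: Sequence[str] | None = None,
    id_prefix: str = "gen",
) -> LabeledDataset:
    """Generate a K-class grayscale image dataset with controllable separability.

    Each class k is drawn as ``clip(0.25 + separability * sigma * template_k +
    noise, 0, 1)`` with pixel noise ``N(0, sigma^2)``, ``sigma = 0.15``.  At
    ``separability=0`` all classes share one distribution (pure noise), so any
    classifier performs at chance; larger values push the class templates
    apart relative to the noise.

    Identical arguments (including ``seed``) yield an identical dataset.
    """
    class_counts = [int(c) for c in class_counts]
    K = len(class_counts)
    if K < 2:
        raise ValueError("need at least 2 classes")
    if any(c < 0 for c in class_counts):
        raise ValueError("class counts must be nonnegative")
    if sum(class_counts) == 0:
        raise ValueError("total sample count must be positive")
    if separability < 0:
        raise ValueError("separability must be nonnegative")
    H, W = image_size
    if H < 8 or W < 8:
        raise ValueError("image size must be at least 8x8")
    if class_names is None:
        class_names = [f"class{k}" for k in range(K)]
    elif len(class_names) != K:
        raise ValueError("class_names length must match class_counts")

    amp = separability * _NOISE_SIGMA
    samples: list[ImageSample] = []
    for k, n in enumerate(class_counts):
        rng = child_rng(seed, "generate", k)
        tpl = amp * _class_template(k, K, (H, W))
        for i in range(n):
            noise = rng.normal(0.0, _NOISE_SIGMA, size=(H, W))
            px = np.clip(0.25 + tpl + noise, 0.0, 1.0)
            samples.append(
                ImageSample(f"{id_prefix}-c{k}-{i:06d}", px, k, provenance="generated")
            )
    return LabeledDataset(samples, list(class_names))


def smote_oversample(
    dataset: LabeledDataset,
    target_per_class: int,
    k_neighbors: int = 5,
    seed: int = 0,
) -> LabeledDataset:
    """Balance every class to exactly ``target_per_class`` samples with SMOTE.

    New samples are ``x_new = x_i + u * (x_nn - x_i)`` on flattened pixel
    vectors, with ``u ~ Uniform(0, 1)`` and ``x_nn`` one of the ``k_neighbors``
    nearest same-class neighbours of ``x_i`` (Euclidean).  Originals are kept
    unchanged and appear before the synthetic samples of their class; outputs
    are clipped to [0, 1] and flagged ``synthetic_smote``.
    """
    from sklearn.neighbors import NearestNeighbors

    if target_per_class < 1:
        raise ValueError("target_per_class must be positive")
    manifest = dataset.manifest
    max_count = max(manifest.values())
    if target_per_class < max_count:
        raise ValueError(
            f"target_per_class={target_per_class} is below the largest class count {max_count}"
        )
    by_class = dataset.by_class()
    for k, idxs in by_class.items():
        if len(idxs) < 2:
            raise ValueError(
                f"class {dataset.class_names[k]!r} has {len(idxs)} sample(s); "
                "SMOTE needs at least 2 per class"
            )

    out = list(dataset.samples)
    shape = dataset.samples[0].pixels.shape
    for k in range(dataset.num_classes):
        idxs = by_class[k]
        deficit = target_per_class - len(idxs)
        if deficit == 0:
            continue
        rng = child_rng(seed, "smote", k)
        X = np.stack([dataset.samples[i].pixels.ravel() for i in idxs])
        n_nbrs = min(k_neighbors + 1, len(idxs))  # +1: query point is its own 1-NN
        nn = NearestNeighbors(n_neighbors=n_nbrs).fit(X)
        nbr_idx = nn.kneighbors(X, return_distance=False)[:, 1:]
        base = rng.integers(0, len(idxs), size=deficit)
        pick = rng.integers(0, nbr_idx.shape[1], size=deficit)
        u = rng.uniform(0.0, 1.0, size=deficit)
        for j in range(deficit):
            xi = X[base[j]]
            xn = X[nbr_idx[base[j], pick[j]]]
            xnew = np.clip(xi + u[j] * (xn - xi), 0.0, 1.0)
            out.append(
                ImageSample(
                    f"smote-c{k}-{j:06d}",
                    xnew.reshape(shape),
                    k,
                    provenance="synthetic_smote",
                )
            )
    return LabeledDataset(out, list(dataset.class_names))


def _split_class_sizes(n: int, spec: SplitSpec) -> tuple[int, int, int]:
    """Floor allocation for validation and test; remainder to train."""
    n_val = math.floor(spec.validation_fraction * n)
    n_test = math.floor(spec.test_fraction * n)
    return n - n_val - n_test, n_val, n_test


def stratified_split(
    dataset: LabeledDataset,
    spec: SplitSpec = SplitSpec(),
    seed: int = 0,
) -> tuple[LabeledDataset, LabeledDataset, LabeledDataset]:
    """Per-class train/validation/test split.

    Per-class validation and test sizes are ``floor(fraction * n)``; all
    leftover samples go to train (so 7000 samples at 0.8/0.1/0.1 give exactly
    5600/700/700).  The three outputs partition the input by sample id.
    Raises if a nonzero fraction would receive zero samples for some class.
    """
    by_class = dataset.by_class()
    train_idx: list[int] = []
    val_idx: list[int] = []
    test_idx: list[int] = []
    for k in range(dataset.num_classes):
        idxs = by_class[k]
        n = len(idxs)
        n_train, n_val, n_test = _split_class_sizes(n, spec)
        for frac, got, name in (
            (spec.train_fraction, n_train, "train"),
            (spec.validation_fraction, n_val, "validation"),
            (spec.test_fraction, n_test, "test"),
        ):
            if frac > 0 and got == 0:
                raise ValueError(
                    f"class {dataset.class_names[k]!r} has {n} samples; too few to give "
                    f">=1 to the nonzero {name} fraction {frac}"
                )
        rng = child_rng(seed, "split", k)
        perm = rng.permutation(n)
        shuffled = [idxs[i] for i in perm]
        train_idx.extend(shuffled[:n_train])
        val_idx.extend(shuffled[n_train : n_train + n_val])
        test_idx.extend(shuffled[n_train + n_val :])
    return (
        dataset.subset(sorted(train_idx)),
        dataset.subset(sorted(val_idx)),
        dataset.subset(sorted(test_idx)),
    )


def _lenient_split(
    dataset: LabeledDataset, spec: SplitSpec, seed: int
) -> tuple[LabeledDataset, LabeledDataset, LabeledDataset]:
    # per-class floor split without the >=1 error: classes too small to feed a
    # nonzero fraction keep everything in train (used inside client partitions,
    # where skewed clients may hold only a handful of some class)
    by_class = dataset.by_class()
    train_idx: list[int] = []
    val_idx: list[int] = []
    test_idx: list[int] = []
    for k in range(dataset.num_classes):
        idxs = by_class[k]
        n = len(idxs)
        n_train, n_val, n_test = _split_class_sizes(n, spec)
        rng = child_rng(seed, "split", k)
        perm = rng.permutation(n)
        shuffled = [idxs[i] for i in perm]
        train_idx.extend(shuffled[:n_train])
        val_idx.extend(shuffled[n_train : n_train + n_val])
        test_idx.extend(shuffled[n_train + n_val :])
    return (
        dataset.subset(sorted(train_idx)),
        dataset.subset(sorted(val_idx)),
        dataset.subset(sorted(test_idx)),
    )


def partition_clients(
    dataset: LabeledDataset,
    sizes: Sequence[int | float],
    mode: str = "iid",
    seed: int = 0,
    concentration: float = 0.5,
    split: SplitSpec = SplitSpec(),
) -> list[ClientPartition]:
    """Distribute a dataset across clients.

    ``sizes`` are absolute counts (ints) or fractions of the dataset (floats
    in (0, 1]).  ``iid`` mode samples clients uniformly without replacement;
    ``by_class_skew`` draws each client's class proportions from a symmetric
    Dirichlet with the given ``concentration`` (smaller = more skewed, i.e.
    more non-IID).  Each client's share is then split per-class into
    train/validation/test with a lenient floor rule.
    """
    n_total = len(dataset)
    counts: list[int] = []
    for s in sizes:
        if isinstance(s, float) and 0 < s <= 1:
            counts.append(int(round(s * n_total)))
        else:
            counts.append(int(s))
    if any(c <= 0 for c in counts):
        raise ValueError("client sizes must be positive")
    if sum(counts) > n_total:
        raise ValueError(f"requested {sum(counts)} samples but only {n_total} available")
    if mode not in ("iid", "by_class_skew"):
        raise ValueError(f"unknown partition mode {mode!r}")

    rng = child_rng(seed, "partition")
    partitions: list[ClientPartition] = []
    if mode == "iid":
        order = rng.permutation(n_total)
        start = 0
        for c, size in enumerate(counts):
            chunk = sorted(int(i) for i in order[start : start + size])
            start += size
            tr, va, te = _lenient_split(dataset.subset(chunk), split, seed=seed * 31 + c)
            partitions.append(ClientPartition(f"client{c + 1}", tr, va, te))
    else:
        if concentration <= 0:
            raise ValueError("concentration must be positive")
        pools = {k: list(idxs) for k, idxs in dataset.by_class().items()}
        for k in pools:
            rng.shuffle(pools[k])
        K = dataset.num_classes
        for c, size in enumerate(counts):
            p = rng.dirichlet(np.full(K, concentration))
            want = np.floor(p * size).astype(int)
            # top up to the exact size in order of largest fractional remainder
            rem = p * size - want
            for k in np.argsort(-rem):
                if want.sum() >= size:
                    break
                want[k] += 1
            chunk: list[int] = []
            for k in range(K):
                take = min(int(want[k]), len(pools[k]))
                chunk.extend(pools[k][:take])
                pools[k] = pools[k][take:]
            # backfill from whatever classes still have samples
            k = 0
            while len(chunk) < size:
                if pools[k]:
                    chunk.append(pools[k].pop(0))
                k = (k + 1) % K
            tr, va, te = _lenient_split(dataset.subset(sorted(chunk)), split, seed=seed * 31 + c)
            partitions.append(ClientPartition(f"client{c + 1}", tr, va, te))
    return partitions


# ---------------------------------------------------------------------------
# External interfaces: image directories and array archives


def save_image_directory(dataset: LabeledDataset, path: str | Path) -> Path:
    """Write the dataset as one subdirectory per class of 8-bit grayscale PNGs,
    plus a ``manifest.csv`` (id, path, class, provenance)."""
    from PIL import Image

    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in dataset.samples:
        cls = dataset.class_names[s.label]
        sub = root / cls
        sub.mkdir(exist_ok=True)
        img = Image.fromarray(np.round(s.pixels * 255).astype(np.uint8), mode="L")
        rel = f"{cls}/{s.id}.png"
        img.save(root / rel)
        rows.append((s.id, rel, cls, s.provenance))
    with open(root / "manifest.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "path", "class", "provenance"])
        w.writerows(rows)
    return root


def load_image_directory(path: str | Path) -> LabeledDataset:
    """Read a dataset written by :func:`save_image_directory` (or any directory
    of per-class PNG subfolders; a manifest.csv is used when present)."""
    from PIL import Image

    root = Path(path)
    manifest = root / "manifest.csv"
    samples: list[ImageSample] = []
    if manifest.exists():
        with open(manifest, newline="") as fh:
            rows = list(csv.DictReader(fh))
        class_names = sorted({r["class"] for r in rows})
        cls_idx = {c: i for i, c in enumerate(class_names)}
        for r in rows:
            px = np.asarray(Image.open(root / r["path"]).convert("L"), dtype=np.float64) / 255.0
            samples.append(ImageSample(r["id"], px, cls_idx[r["class"]], r["provenance"]))
    else:
        class_names = sorted(p.name for p in root.iterdir() if p.is_dir())
        cls_idx = {c: i for i, c in enumerate(class_names)}
        for c in class_names:
            for f in sorted((root / c).glob("*.png")):
                px = np.asarray(Image.open(f).convert("L"), dtype=np.float64) / 255.0
                samples.append(ImageSample(f"{c}/{f.stem}", px, cls_idx[c], "original"))
    return LabeledDataset(samples, class_names)


def save_archive(dataset: LabeledDataset, path: str | Path) -> Path:
    """Write the dataset to one compressed ``.npz`` container."""
    path = Path(path)
    np.savez_compressed(
        path,
        pixels=dataset.pixels_array(),
        labels=dataset.labels_array(),
        ids=np.array(dataset.ids()),
        provenance=np.array([s.provenance for s in dataset.samples]),
        class_names=np.array(dataset.class_names),
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_archive(path: str | Path) -> LabeledDataset:
    with np.load(path, allow_pickle=False) as z:
        samples = [
            ImageSample(str(i), p, int(l), str(v))
            for i, p, l, v in zip(z["ids"], z["pixels"], z["labels"], z["provenance"])
        ]
        return LabeledDataset(samples, [str(c) for c in z["class_names"]])
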