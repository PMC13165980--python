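"""Dataset I/O, train/test splitting and class-balancing augmentation.

The pipeline mirrors standard preparation for lesion-image classifiers:

1. resize every RGB image to a fixed square input size (default 224,
   direct bilinear resize — no aspect preservation);
2. randomly reserve a test fraction (default 20%) of the *original*
   images, optionally grouping by patient so no patient spans both sides;
3. expand every training class to a fixed count (default 3500) by
   repeated augmentation of that class's originals: random rescale to
   80–110% of the input size, random horizontal/vertical reflection,
   centered placement on a zero-filled canvas (center crop on overflow);
4. check for leakage: duplicate image ids, pixel-identical images and
   shared patients across the two sides.

The test side is never augmented.  Datasets live on disk as one
directory per class of PNG/JPG files plus a manifest CSV
(image_id, label, source, patient_id, is_augmented).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "ImageRecord",
    "SplitSpec",
    "AugmentationConfig",
    "LeakageReport",
    "DataError",
    "resize_image",
    "split_dataset",
    "augment_image",
    "balance_classes",
    "check_leakage",
    "save_dataset",
    "load_dataset",
    "class_histogram",
]


class DataError(ValueError):
    """Raised for malformed records, splits or balancing configurations."""


@dataclass
class ImageRecord:
    """One labelled RGB image with provenance metadata."""

    image_id: str
    pixels: np.ndarray  # H x W x 3 uint8
    label: str
    source: str = "unknown"
    patient_id: str | None = None
    is_augmented: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise DataError(
                f"{self.image_id}: expected H x W x 3 RGB pixels, got {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise DataError(f"{self.image_id}: empty image")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise DataError(f"{self.image_id}: channel values outside [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)

    def content_hash(self) -> str:
        h = hashlib.sha1()
        h.update(str(self.pixels.shape).encode())
        h.update(self.pixels.tobytes())
        return h.hexdigest()


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split: fraction reserved for test, seed, grouping unit."""

    test_fraction: float = 0.20
    seed: int = 0
    grouping: str = "image"  # or "patient"

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise DataError("test_fraction must be in (0, 1)")
        if self.grouping not in ("image", "patient"):
            raise DataError(f"unknown grouping {self.grouping!r}")


@dataclass(frozen=True)
class AugmentationConfig:
    """Random-rescale / random-reflection augmentation with zero fill."""

    scale_min: float = 0.80
    scale_max: float = 1.10
    reflect_probability: float = 0.5  # per axis
    fill_value: int = 0
    output_size: int = 224
    target_per_class: int = 3500

    def __post_init__(self) -> None:
        if not 0 < self.scale_min <= self.scale_max:
            raise DataError("require 0 < scale_min <= scale_max")
        if self.output_size < 1 or self.target_per_class < 1:
            raise DataError("output_size and target_per_class must be >= 1")
        if not 0 <= self.reflect_probability <= 1:
            raise DataError("reflect_probability must be in [0, 1]")


def resize_image(record: ImageRecord, size: int) -> ImageRecord:
    """Bilinear resize to ``size x size x 3``; metadata preserved.

    A same-size input is returned pixel-identical (no resampling pass).
    """
    h, w, _ = record.pixels.shape
    if (h, w) == (size, size):
        return replace(record, pixels=record.pixels.copy())
    img = Image.fromarray(record.pixels, mode="RGB")
    out = img.resize((size, size), resample=Image.BILINEAR)
    return replace(record, pixels=np.asarray(out, dtype=np.uint8))


def split_dataset(records: Sequence[ImageRecord], spec: SplitSpec) -> tuple:
    """Randomly reserve ``test_fraction`` of the originals for testing.

    The test count is ``round-half-up(fraction * N)`` under image
    grouping.  Under patient grouping whole patients are moved to the
    test side (in shuffled order) until the target count is reached, so
    no patient contributes to both sides.  Deterministic given the seed.
    """
    records = list(records)
    if any(r.is_augmented for r in records):
        raise DataError("split operates on original (unaugmented) records only")
    n = len(records)
    if n < 2:
        raise DataError("need at least 2 records to split")
    n_test = int(np.floor(spec.test_fraction * n + 0.5))
    n_test = min(max(n_test, 1), n - 1)
    rng = np.random.default_rng(spec.seed)

    if spec.grouping == "image":
        order = rng.permutation(n)
        test_idx = set(order[:n_test].tolist())
    else:
        if any(r.patient_id is None for r in records):
            raise DataError("patient grouping requires patient_id on every record")
        patients = sorted({r.patient_id for r in records})
        rng.shuffle(patients)
        test_patients: set = set()
        count = 0
        for p in patients:
            if count >= n_test:
                break
            test_patients.add(p)
            count += sum(1 for r in records if r.patient_id == p)
        test_idx = {i for i, r in enumerate(records) if r.patient_id in test_patients}
        if len(test_idx) == n:  # never empty the training side
            drop = next(iter(test_patients))
            test_idx = {i for i in test_idx if records[i].patient_id != drop}

    train = [r for i, r in enumerate(records) if i not in test_idx]
    test = [r for i, r in enumerate(records) if i in test_idx]
    return train, test


def augment_image(
    record: ImageRecord, config: AugmentationConfig, rng: np.random.Generator,
    new_id: str | None = None,
) -> ImageRecord:
    """One random transform draw: rescale, reflect, center on zero canvas.

    The input is expected at ``config.output_size``.  The scale factor is
    drawn uniformly from [scale_min, scale_max]; each axis is reflected
    independently with ``reflect_probability``; the rescaled image is
    placed centered on an ``output_size`` canvas, cropping overflow and
    filling uncovered area with ``fill_value``.  Label, source and
    patient identity are preserved; the output is flagged as augmented.
    """
    size = config.output_size
    scale = float(rng.uniform(config.scale_min, config.scale_max))
    new_side = max(1, int(round(scale * size)))
    img = Image.fromarray(record.pixels, mode="RGB")
    if new_side != record.pixels.shape[0]:
        img = img.resize((new_side, new_side), resample=Image.BILINEAR)
    arr = np.asarray(img, dtype=np.uint8)
    if rng.random() < config.reflect_probability:
        arr = arr[:, ::-1]  # horizontal reflection
    if rng.random() < config.reflect_probability:
        arr = arr[::-1, :]  # vertical reflection

    canvas = np.full((size, size, 3), config.fill_value, dtype=np.uint8)
    if new_side <= size:
        off = (size - new_side) // 2
        canvas[off : off + new_side, off : off + new_side] = arr
    else:
        off = (new_side - size) // 2
        canvas = arr[off : off + size, off : off + size].copy()
    return replace(
        record,
        image_id=new_id or f"{record.image_id}~aug",
        pixels=canvas,
        is_augmented=True,
    )


def class_histogram(records: Iterable[ImageRecord]) -> dict:
    counts: dict = {}
    for r in records:
        counts[r.label] = counts.get(r.label, 0) + 1
    return counts


def balance_classes(
    train: Sequence[ImageRecord], config: AugmentationConfig, seed: int = 0
) -> list:
    """Expand every class to exactly ``target_per_class`` records.

    Originals are all retained; the deficit of each class is filled with
    augmented copies of that class's originals taken in round-robin
    order (first original first), each with a fresh seeded transform
    draw.  A class already at the target is passed through unchanged; a
    class above the target is a configuration error — the pipeline never
    downsamples.
    """
    train = list(train)
    if not train:
        raise DataError("training set is empty")
    hist = class_histogram(train)
    over = {c: n for c, n in hist.items() if n > config.target_per_class}
    if over:
        raise DataError(
            f"classes exceed target_per_class={config.target_per_class}: {over}"
        )
    out = list(train)
    for ci, code in enumerate(sorted(hist)):
        originals = [r for r in train if r.label == code]
        rng = np.random.default_rng([seed, ci])
        deficit = config.target_per_class - len(originals)
        for k in range(deficit):
            parent = originals[k % len(originals)]
            out.append(
                augment_image(parent, config, rng, new_id=f"{parent.image_id}~aug{k:05d}")
            )
    return out


@dataclass
class LeakageReport:
    """Cross-split overlap: ids, identical pixel content, shared patients."""

    duplicate_ids: list = field(default_factory=list)
    content_collisions: list = field(default_factory=list)  # (train_id, test_id)
    patient_overlaps: list = field(default_factory=list)

    @property
    def is_clean(self) -> bool:
        return not (self.duplicate_ids or self.content_collisions or self.patient_overlaps)

    def summary(self) -> str:
        if self.is_clean:
            return "leakage check: clean"
        return (
            f"leakage check: {len(self.duplicate_ids)} duplicate ids, "
            f"{len(self.content_collisions)} identical-content pairs, "
            f"{len(self.patient_overlaps)} shared patients"
        )


def check_leakage(train: Sequence[ImageRecord], test: Sequence[ImageRecord]) -> LeakageReport:
    """Automated analogue of an image-level leakage inspection."""
    train_ids = {r.image_id for r in train}
    dup_ids = sorted(train_ids & {r.image_id for r in test})

    train_hashes: dict = {}
    for r in train:
        train_hashes.setdefault(r.content_hash(), []).append(r.image_id)
    collisions = []
    for r in test:
        for tid in train_hashes.get(r.content_hash(), []):
            collisions.append((tid, r.image_id))

    train_pat = {r.patient_id for r in train if r.patient_id is not None}
    test_pat = {r.patient_id for r in test if r.patient_id is not None}
    return LeakageReport(
        duplicate_ids=dup_ids,
        content_collisions=sorted(collisions),
        patient_overlaps=sorted(train_pat & test_pat),
    )


# -- disk layout -----------------------------------------------------------

def save_dataset(records: Sequence[ImageRecord], root: Path | str) -> Path:
    """Write one directory per class plus ``manifest.csv``; returns root."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in records:
        cdir = root / r.label
        cdir.mkdir(exist_ok=True)
        path = cdir / f"{r.image_id}.png"
        Image.fromarray(r.pixels, mode="RGB").save(path)
        rows.append(
            {
                "image_id": r.image_id,
                "label": r.label,
                "source": r.source,
                "patient_id": "" if r.patient_id is None else r.patient_id,
                "is_augmented": int(r.is_augmented),
            }
        )
    pd.DataFrame(rows).to_csv(root / "manifest.csv", index=False)
    return root


def load_dataset(root: Path | str) -> list:
    """Read a directory-per-class dataset back into records.

    Uses ``manifest.csv`` when present (restoring source/patient
    metadata); otherwise walks the class directories.
    """
    root = Path(root)
    manifest = root / "manifest.csv"
    records = []
    if manifest.exists():
        df = pd.read_csv(manifest, keep_default_na=False)
        for row in df.itertuples(index=False):
            path = root / row.label / f"{row.image_id}.png"
            if not path.exists():  # alternate extensions
                matches = list((root / row.label).glob(f"{row.image_id}.*"))
                if not matches:
                    raise DataError(f"missing image file for {row.image_id}")
                path = matches[0]
            pixels = np.asarray(Image.open(path).convert("RGB"), dtype=np.uint8)
            records.append(
                ImageRecord(
                    image_id=str(row.image_id),
                    pixels=pixels,
                    label=str(row.label),
                    source=str(row.source) or "unknown",
                    patient_id=str(row.patient_id) or None,
                    is_augmented=bool(row.is_augmented),
                )
            )
        return records
    for cdir in sorted(p for p in root.iterdir() if p.is_dir()):
        for path in sorted(cdir.glob("*")):
            if path.suffix.lower() not in (".png", ".jpg", ".jpeg"):
                continue
            pixels = np.asarray(Image.open(path).convert("RGB"), dtype=np.uint8)
            records.append(
                ImageRecord(image_id=path.stem, pixels=pixels, label=cdir.name)
            )
    return records
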