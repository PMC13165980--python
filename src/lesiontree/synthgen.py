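"""Seeded synthetic lesion-like image generator.

Real dermatology collections have a property the hierarchical classifier
exploits: the benign classes look more like each other than like the
malignant classes and vice versa.  The generator encodes that structure
explicitly — each class is a parametric "lesion" (an irregular ellipse
on a skin-tone background) whose hue sits in its group's hue band:
within a group base hues lie within a +/-20 degree window, across groups
they are at least 90 degrees apart.  Within-group discrimination relies
on subtler cues (lesion size, border irregularity, texture frequency,
lightness), so a small classifier separates the groups more easily than
it separates classes inside a group.

Images are nothing like photorealistic dermoscopy (no hair, rulers,
illumination gradients, camera noise correlations); they exist so the
full pipeline is exercisable and testable without any download.  All
randomness flows from an integer seed; identical seeds give bit-identical
pixels.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .datapipe import ImageRecord

__all__ = [
    "SynthClassSpec",
    "SynthError",
    "DEFAULT_CLASS_SPECS",
    "DEFAULT_IMBALANCED_COUNTS",
    "generate_image",
    "generate_dataset",
    "generate_imbalanced",
]


class SynthError(ValueError):
    pass


@dataclass(frozen=True)
class SynthClassSpec:
    """Parametric appearance of one synthetic lesion class."""

    class_code: str
    group: str
    base_hue: float  # degrees
    lesion_radius_fraction: float  # of image side
    border_irregularity: float  # radial modulation amplitude
    texture_frequency: float  # cycles per image
    noise_sd: float  # channel-value std dev
    lightness: float = 0.55  # HSV value of the lesion fill


# Benign hues sit in a warm brown band (20-40 deg), malignant in a
# cool band (200-224 deg): within-group spread 20 deg, across-group
# separation ~160 deg.  Shape/texture parameters carry the within-group
# signal; noise_sd keeps separation imperfect for small classifiers.
DEFAULT_CLASS_SPECS = (
    SynthClassSpec("ACK", "Benign", 20.0, 0.22, 0.25, 0.0, 45.0, lightness=0.64),
    SynthClassSpec("NEV", "Benign", 30.0, 0.30, 0.05, 0.0, 45.0, lightness=0.50),
    SynthClassSpec("SEK", "Benign", 40.0, 0.26, 0.10, 6.0, 45.0, lightness=0.58),
    SynthClassSpec("MEL", "Malignant", 200.0, 0.28, 0.30, 0.0, 45.0, lightness=0.38),
    SynthClassSpec("BCC", "Malignant", 212.0, 0.24, 0.08, 5.0, 45.0, lightness=0.56),
    SynthClassSpec("SCC", "Malignant", 224.0, 0.32, 0.15, 2.0, 45.0, lightness=0.46),
)

#: Distinct, unequal per-class counts with max/min ratio > 3 (NEV-heavy,
#: mirroring the dominance of nevi in public lesion collections).
DEFAULT_IMBALANCED_COUNTS = {
    "NEV": 100,
    "ACK": 70,
    "SEK": 49,
    "BCC": 34,
    "MEL": 24,
    "SCC": 17,
}

_SKIN_TONE = np.array([224.0, 172.0, 147.0])


def _hsv_to_rgb255(h_deg: float, s: float, v: float) -> np.ndarray:
    r, g, b = colorsys.hsv_to_rgb((h_deg % 360.0) / 360.0, s, v)
    return np.array([r, g, b]) * 255.0


def generate_image(
    spec: SynthClassSpec, size: int, rng: np.random.Generator
) -> tuple:
    """One synthetic lesion image.

    Returns ``(pixels, geometry)`` where geometry holds the lesion's
    center, nominal radius and axis-aligned bounding box (row0, row1,
    col0, col1) — ground truth for localization checks.
    """
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cx = size / 2 + rng.uniform(-0.08, 0.08) * size
    cy = size / 2 + rng.uniform(-0.08, 0.08) * size
    r0 = spec.lesion_radius_fraction * size * rng.uniform(0.85, 1.15)

    theta = np.arctan2(yy - cy, xx - cx)
    lobes = int(rng.integers(3, 7))
    phase = rng.uniform(0, 2 * np.pi)
    radius = r0 * (1.0 + spec.border_irregularity * np.sin(lobes * theta + phase))
    dist = np.hypot(yy - cy, xx - cx)
    inside = dist <= radius

    hue = spec.base_hue + rng.uniform(-6.0, 6.0)
    fill = _hsv_to_rgb255(hue, 0.75, spec.lightness)
    img = np.empty((size, size, 3))
    img[:] = _SKIN_TONE * rng.uniform(0.95, 1.05)
    img[inside] = fill
    if spec.texture_frequency > 0:
        f = spec.texture_frequency
        tex = 0.18 * np.sin(2 * np.pi * f * xx / size) * np.sin(2 * np.pi * f * yy / size)
        img[inside] *= (1.0 + tex[inside])[:, None]
    img += rng.normal(0.0, spec.noise_sd, img.shape)
    pixels = np.clip(img, 0, 255).astype(np.uint8)

    rmax = r0 * (1.0 + spec.border_irregularity)
    geometry = {
        "center": (cy, cx),
        "radius": r0,
        "bbox": (
            max(0, int(np.floor(cy - rmax))),
            min(size, int(np.ceil(cy + rmax)) + 1),
            max(0, int(np.floor(cx - rmax))),
            min(size, int(np.ceil(cx + rmax)) + 1),
        ),
    }
    return pixels, geometry


def generate_dataset(
    specs: Sequence[SynthClassSpec] = DEFAULT_CLASS_SPECS,
    per_class_counts: Mapping[str, int] | int = 10,
    image_size: int = 64,
    seed: int = 0,
    return_geometry: bool = False,
):
    """Generate a labelled synthetic dataset.

    ``per_class_counts`` is either one count for every class or a mapping
    class code -> count.  Patient ids are assigned in runs of 2, 3 and 1
    images, so some patients contribute several images (as in clinical
    collections where one patient has multiple lesion photographs).
    Deterministic given the seed.
    """
    by_code = {s.class_code: s for s in specs}
    if isinstance(per_class_counts, int):
        per_class_counts = {s.class_code: per_class_counts for s in specs}
    unknown = set(per_class_counts) - set(by_code)
    if unknown:
        raise SynthError(f"counts requested for unknown classes: {sorted(unknown)}")
    if any(n <= 0 for n in per_class_counts.values()):
        raise SynthError("per-class counts must be positive")

    records, geometries = [], {}
    patient_pattern = (2, 3, 1)
    for ci, code in enumerate(sorted(per_class_counts)):
        spec = by_code[code]
        rng = np.random.default_rng([seed, ci, image_size])
        n = per_class_counts[code]
        pat_sizes: list = []
        while sum(pat_sizes) < n:
            pat_sizes.append(patient_pattern[len(pat_sizes) % len(patient_pattern)])
        pat_of: list = []
        for pi, sz in enumerate(pat_sizes):
            pat_of.extend([pi] * sz)
        for i in range(n):
            pixels, geom = generate_image(spec, image_size, rng)
            image_id = f"{code.lower()}_{seed}_{i:04d}"
            records.append(
                ImageRecord(
                    image_id=image_id,
                    pixels=pixels,
                    label=code,
                    source="synthetic",
                    patient_id=f"{code.lower()}_pat{pat_of[i]:03d}",
                )
            )
            geometries[image_id] = geom
    if return_geometry:
        return records, geometries
    return records


def generate_imbalanced(seed: int = 0, image_size: int = 64) -> list:
    """Six-class set with distinct, unequal counts for balancing tests."""
    return generate_dataset(
        DEFAULT_CLASS_SPECS, DEFAULT_IMBALANCED_COUNTS, image_size=image_size, seed=seed
    )
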