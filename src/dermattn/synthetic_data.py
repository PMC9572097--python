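"""Synthetic imbalanced lesion-image benchmark.

Real dermoscopy archives are severely imbalanced (in HAM10000 the largest
class outnumbers the smallest ~58:1) and carry class-correlated patient
metadata with missing values.  This generator emulates that structure at
desk scale so the full pipeline — loader, attention model, weighted loss,
metadata fusion, metrics — is exercisable with no download and no GPU:

* images are a noisy skin-tone background plus one elliptical lesion blob
  whose color, radius and border irregularity are drawn from per-class
  ranges (classes separable by construction, but overlapping, so the Bayes
  error is positive);
* per-class counts are exact and default to the HAM10000 class ratios
  scaled by 0.1;
* ages are drawn from class-shifted normals, sites from per-class
  preference lists, and any metadata field goes missing with a configurable
  rate ("unknown" is kept as a level, mirroring the loader contract).

It does NOT attempt photorealism: no hair, rulers, gel bubbles, vignetting
or multi-lesion frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .data_io import DX_TYPES, HAM10000_CLASSES, MetadataSchema, REQUIRED_COLUMNS

__all__ = [
    "ClassAppearance",
    "ClassMetadataEffect",
    "SyntheticDatasetSpec",
    "ham_like_spec",
    "imbalanced_triplet_spec",
    "weak_image_strong_meta_spec",
    "generate_image",
    "generate_arrays",
    "generate_dataset",
]

SKIN_TONE = np.array([224.0, 172.0, 150.0])


@dataclass(frozen=True)
class ClassAppearance:
    """Per-class lesion appearance ranges."""

    color: tuple[float, float, float]          # mean lesion RGB, 0-255
    color_sd: float = 18.0                     # per-image color jitter
    radius: tuple[float, float] = (0.18, 0.32)  # ellipse semi-axes, fraction of min(h,w)
    irregularity: float = 0.15                 # radial border perturbation amplitude


@dataclass(frozen=True)
class ClassMetadataEffect:
    """Per-class metadata distributions."""

    age_mean: float = 50.0
    age_sd: float = 15.0
    sites: tuple[str, ...] = ("back", "trunk", "lower extremity")


# HAM10000-flavoured per-class appearance: brown nevi, dark melanomas,
# red vascular lesions, pale basal cell carcinomas, etc.
_HAM_APPEARANCE = {
    "akiec": ClassAppearance((196, 122, 108), radius=(0.14, 0.26)),
    "bcc": ClassAppearance((186, 142, 132), radius=(0.12, 0.24)),
    "bkl": ClassAppearance((146, 98, 72)),
    "df": ClassAppearance((122, 82, 72), radius=(0.10, 0.20)),
    "mel": ClassAppearance((62, 42, 36), irregularity=0.35, radius=(0.20, 0.38)),
    "nv": ClassAppearance((112, 72, 56), irregularity=0.08),
    "vasc": ClassAppearance((182, 62, 72), radius=(0.10, 0.22)),
}

_HAM_META = {
    "akiec": ClassMetadataEffect(67, 10, ("face", "scalp", "hand")),
    "bcc": ClassMetadataEffect(65, 12, ("face", "back", "neck")),
    "bkl": ClassMetadataEffect(62, 12, ("back", "trunk", "face")),
    "df": ClassMetadataEffect(47, 13, ("lower extremity", "upper extremity")),
    "mel": ClassMetadataEffect(58, 14, ("back", "trunk", "lower extremity")),
    "nv": ClassMetadataEffect(42, 14, ("back", "trunk", "abdomen", "lower extremity")),
    "vasc": ClassMetadataEffect(48, 18, ("trunk", "abdomen", "chest")),
}

# HAM10000 per-class counts scaled by 0.1 (akiec..vasc order)
HAM_SCALED_COUNTS = (33, 51, 110, 12, 111, 670, 14)


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Full recipe for one reproducible synthetic dataset."""

    class_names: tuple[str, ...] = HAM10000_CLASSES
    class_counts: tuple[int, ...] = HAM_SCALED_COUNTS
    image_size: tuple[int, int] = (64, 64)
    appearance: tuple[ClassAppearance, ...] = tuple(_HAM_APPEARANCE[c] for c in HAM10000_CLASSES)
    metadata_effect: tuple[ClassMetadataEffect, ...] = tuple(_HAM_META[c] for c in HAM10000_CLASSES)
    missing_rate: float = 0.05
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.class_names)
        if not (len(self.class_counts) == len(self.appearance) == len(self.metadata_effect) == n):
            raise ValueError("class_names, class_counts, appearance and metadata_effect must align")
        if any(c < 1 for c in self.class_counts):
            raise ValueError("every class count must be >= 1")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError(f"missing_rate must be in [0,1], got {self.missing_rate}")
        if min(self.image_size) < 8:
            raise ValueError(f"degenerate image size {self.image_size}")

    @property
    def schema(self) -> MetadataSchema:
        return MetadataSchema(classes=tuple(self.class_names))


def ham_like_spec(scale: float = 0.1, seed: int = 0, image_size=(64, 64)) -> SyntheticDatasetSpec:
    """The default benchmark: 7 classes at HAM10000 ratios scaled by ``scale``."""
    base = (327, 514, 1099, 115, 1113, 6705, 142)
    counts = tuple(max(1, int(round(c * scale))) for c in base)
    return SyntheticDatasetSpec(class_counts=counts, seed=seed, image_size=image_size)


def imbalanced_triplet_spec(counts: tuple[int, int, int] = (600, 60, 20), seed: int = 0,
                            image_size=(24, 24)) -> SyntheticDatasetSpec:
    """Three-class set with a majority and two minority classes — the standing
    benchmark for weighted-loss imbalance mitigation.  Lesion colors overlap
    between neighbouring classes so an unweighted model profits from
    neglecting the minorities."""
    names = ("maj", "min1", "min2")
    appearance = (
        ClassAppearance((120, 78, 60), color_sd=26.0),
        ClassAppearance((96, 62, 50), color_sd=26.0),
        ClassAppearance((150, 96, 74), color_sd=26.0),
    )
    meta = (
        ClassMetadataEffect(45, 15, ("back", "trunk")),
        ClassMetadataEffect(55, 15, ("back", "trunk")),
        ClassMetadataEffect(50, 15, ("back", "trunk")),
    )
    return SyntheticDatasetSpec(class_names=names, class_counts=counts,
                                image_size=image_size, appearance=appearance,
                                metadata_effect=meta, missing_rate=0.0, seed=seed)


def weak_image_strong_meta_spec(per_class: int = 120, seed: int = 0,
                                image_size=(24, 24)) -> SyntheticDatasetSpec:
    """Balanced three-class set where lesion appearance barely separates the
    classes but age does — the benchmark for the metadata-fusion benefit."""
    names = ("a", "b", "c")
    appearance = (
        ClassAppearance((118, 76, 58), color_sd=30.0),
        ClassAppearance((112, 72, 56), color_sd=30.0),
        ClassAppearance((124, 80, 60), color_sd=30.0),
    )
    meta = (
        ClassMetadataEffect(20, 6, ("back", "trunk")),
        ClassMetadataEffect(50, 6, ("back", "trunk")),
        ClassMetadataEffect(80, 6, ("back", "trunk")),
    )
    return SyntheticDatasetSpec(class_names=names, class_counts=(per_class,) * 3,
                                image_size=image_size, appearance=appearance,
                                metadata_effect=meta, missing_rate=0.0, seed=seed)


def generate_image(class_index: int, spec: SyntheticDatasetSpec,
                   rng: np.random.Generator) -> np.ndarray:
    """One uint8 (h, w, 3) image: noisy skin background + one class-styled blob."""
    if not 0 <= class_index < len(spec.class_names):
        raise ValueError(f"class_index {class_index} out of range")
    h, w = spec.image_size
    app = spec.appearance[class_index]

    img = np.broadcast_to(SKIN_TONE, (h, w, 3)).copy()
    lo, hi = app.radius
    if hi > 0:
        scale = min(h, w)
        rx = rng.uniform(lo, hi) * scale
        ry = rng.uniform(lo, hi) * scale
        cy = h / 2 + rng.uniform(-0.1, 0.1) * h
        cx = w / 2 + rng.uniform(-0.1, 0.1) * w
        theta = rng.uniform(0, np.pi)

        yy, xx = np.mgrid[0:h, 0:w]
        dy, dx = yy - cy, xx - cx
        u = (np.cos(theta) * dx + np.sin(theta) * dy) / max(rx, 1e-9)
        v = (-np.sin(theta) * dx + np.cos(theta) * dy) / max(ry, 1e-9)
        r = np.sqrt(u ** 2 + v ** 2)
        # irregular border: low-order radial harmonics perturb the unit circle
        ang = np.arctan2(v, u)
        boundary = np.ones_like(r)
        for m in (2, 3, 5):
            boundary += app.irregularity * rng.uniform(-1, 1) / m * np.cos(m * ang + rng.uniform(0, 2 * np.pi))
        mask = np.clip((boundary - r) / 0.15 + 0.5, 0.0, 1.0)  # soft edge

        color = np.asarray(app.color) + rng.normal(0.0, app.color_sd, size=3)
        img = img * (1 - mask[..., None]) + color * mask[..., None]

    img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def _make_metadata(spec: SyntheticDatasetSpec, labels: np.ndarray,
                   rng: np.random.Generator) -> pd.DataFrame:
    n = len(labels)
    rows = []
    for i in range(n):
        k = int(labels[i])
        eff = spec.metadata_effect[k]
        age = float(np.clip(rng.normal(eff.age_mean, eff.age_sd), 0, 100))
        age = 5.0 * round(age / 5.0)  # archives record age in 5-year bins
        sex = "male" if rng.random() < 0.5 else "female"
        site = eff.sites[rng.integers(len(eff.sites))]
        if rng.random() < spec.missing_rate:
            age = np.nan
        if rng.random() < spec.missing_rate:
            sex = "unknown"
        if rng.random() < spec.missing_rate:
            site = "unknown"
        rows.append({
            "lesion_id": f"SYN_{i:07d}",
            "image_id": f"SYNISIC_{i:07d}",
            "dx": spec.class_names[k],
            "dx_type": DX_TYPES[rng.integers(len(DX_TYPES))],
            "age": age,
            "sex": sex,
            "localization": site,
        })
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


def generate_arrays(spec: SyntheticDatasetSpec) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """In-memory dataset: (images uint8 (N,h,w,3), labels int (N,), metadata table).

    Fully deterministic in ``spec.seed``; per-class counts are exact.
    """
    rng = np.random.default_rng(spec.seed)
    labels = np.concatenate([
        np.full(c, k, dtype=np.int64) for k, c in enumerate(spec.class_counts)
    ])
    labels = rng.permutation(labels)
    h, w = spec.image_size
    images = np.empty((len(labels), h, w, 3), dtype=np.uint8)
    for i, k in enumerate(labels):
        images[i] = generate_image(int(k), spec, rng)
    meta = _make_metadata(spec, labels, rng)
    return images, labels, meta


def generate_dataset(spec: SyntheticDatasetSpec, out_dir) -> pd.DataFrame:
    """Write the dataset to disk: one PNG per image plus ``metadata.csv``.

    File stems equal the image_id, matching the loader contract.  The same
    seed produces a byte-identical CSV and identical PNGs.
    """
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    try:
        img_dir.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create output directory {img_dir}: {e}") from e
    images, labels, meta = generate_arrays(spec)
    for i, image_id in enumerate(meta["image_id"]):
        Image.fromarray(images[i]).save(img_dir / f"{image_id}.png")
    meta.to_csv(out_dir / "metadata.csv", index=False)
    return meta
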