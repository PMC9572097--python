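"""Reading and writing lesion images and HAM10000-dialect metadata tables.

The metadata dialect is a CSV with columns ``lesion_id, image_id, dx,
dx_type, age, sex, localization``.  Missing age/sex/localization values are
kept as explicit sentinel levels (``unknown`` for the categoricals, NaN plus
a downstream missing-indicator for age) rather than dropped or imputed, so a
record is never lost to incomplete metadata.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "MetadataSchema",
    "MetadataRecord",
    "HAM10000_CLASSES",
    "HAM10000_SITES",
    "IMAGENET_MEAN",
    "IMAGENET_STD",
    "IMAGENET_BGR_MEAN",
    "load_metadata",
    "write_metadata",
    "class_counts",
    "records",
    "load_images",
    "preprocess_pixels",
    "split_dataset",
]

HAM10000_CLASSES = ("akiec", "bcc", "bkl", "df", "mel", "nv", "vasc")
HAM10000_SITES = (
    "abdomen", "acral", "back", "chest", "ear", "face", "foot", "genital",
    "hand", "lower extremity", "neck", "scalp", "trunk", "upper extremity",
)
SEX_LEVELS = ("male", "female", "unknown")
DX_TYPES = ("histo", "follow_up", "consensus", "confocal")
UNKNOWN = "unknown"

REQUIRED_COLUMNS = ("lesion_id", "image_id", "dx", "dx_type", "age", "sex", "localization")

# ImageNet channel statistics (RGB order, unit scale) and the BGR pixel-scale
# means used by the caffe-style preprocessing convention.
IMAGENET_MEAN = np.array([0.485, 0.456, 0.406])
IMAGENET_STD = np.array([0.229, 0.224, 0.225])
IMAGENET_BGR_MEAN = np.array([103.939, 116.779, 123.68])


@dataclass(frozen=True)
class MetadataSchema:
    """Configured label and site vocabularies for a dataset."""

    classes: tuple[str, ...] = HAM10000_CLASSES
    sites: tuple[str, ...] = HAM10000_SITES

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def class_index(self, dx: str) -> int:
        return self.classes.index(dx)


@dataclass
class MetadataRecord:
    """One row of the metadata table with sentinel levels materialized."""

    image_id: str
    dx: str
    age: float = np.nan  # years; NaN when unknown
    sex: str = UNKNOWN
    localization: str = UNKNOWN
    dx_type: str = UNKNOWN
    lesion_id: str = ""

    @property
    def age_missing(self) -> bool:
        return bool(np.isnan(self.age))


def load_metadata(path: str | os.PathLike, schema: MetadataSchema | None = None) -> pd.DataFrame:
    """Load and validate a HAM10000-dialect metadata CSV.

    Returns a DataFrame with the required columns in canonical order, missing
    categorical cells mapped to ``unknown`` and missing ages kept as NaN.
    Raises ``ValueError`` for a missing required column or a ``dx`` label
    outside the schema, naming the offending row.
    """
    schema = schema or MetadataSchema()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"lesion_id": str, "image_id": str})
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"metadata file {path} is missing required columns {missing_cols}")
    df = df.loc[:, list(REQUIRED_COLUMNS)].copy()
    for col in ("sex", "localization", "dx_type", "dx"):
        df[col] = df[col].astype("string").str.strip().str.lower()
        df[col] = df[col].fillna(UNKNOWN).replace("", UNKNOWN)
    df["age"] = pd.to_numeric(df["age"], errors="coerce")
    if (df["age"].dropna() < 0).any():
        bad = df.index[df["age"] < 0][0]
        raise ValueError(f"row {bad}: negative age {df.at[bad, 'age']}")
    bad_dx = ~df["dx"].isin(schema.classes)
    if bad_dx.any():
        row = int(df.index[bad_dx][0])
        raise ValueError(
            f"row {row} (image_id={df.at[row, 'image_id']}): unknown dx label "
            f"{df.at[row, 'dx']!r}; expected one of {list(schema.classes)}"
        )
    bad_site = ~(df["localization"].isin(schema.sites) | (df["localization"] == UNKNOWN))
    if bad_site.any():
        row = int(df.index[bad_site][0])
        raise ValueError(
            f"row {row}: unknown localization {df.at[row, 'localization']!r}"
        )
    return df


def write_metadata(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a metadata table back to CSV (the loader's round-trip partner)."""
    df.loc[:, list(REQUIRED_COLUMNS)].to_csv(path, index=False)


def class_counts(df: pd.DataFrame, schema: MetadataSchema | None = None) -> pd.Series:
    """Per-class record counts in schema order; ``.sum()`` gives the total."""
    schema = schema or MetadataSchema()
    counts = df["dx"].value_counts()
    return pd.Series([int(counts.get(c, 0)) for c in schema.classes],
                     index=list(schema.classes), name="count")


def records(df: pd.DataFrame) -> list[MetadataRecord]:
    """Materialize the table as typed records."""
    out = []
    for row in df.itertuples(index=False):
        out.append(MetadataRecord(
            image_id=row.image_id, dx=row.dx,
            age=float(row.age) if pd.notna(row.age) else np.nan,
            sex=row.sex, localization=row.localization,
            dx_type=row.dx_type, lesion_id=row.lesion_id,
        ))
    return out


def load_images(image_dir: str | os.PathLike, image_ids, size: tuple[int, int] = (128, 128)) -> np.ndarray:
    """Load PNG/JPEG images by image_id stem, bilinear-resized to ``size`` (h, w).

    Returns a uint8 array of shape (N, h, w, 3).
    """
    image_dir = Path(image_dir)
    h, w = size
    out = np.empty((len(image_ids), h, w, 3), dtype=np.uint8)
    for i, image_id in enumerate(image_ids):
        path = None
        for ext in (".png", ".jpg", ".jpeg"):
            cand = image_dir / f"{image_id}{ext}"
            if cand.exists():
                path = cand
                break
        if path is None:
            raise FileNotFoundError(f"no image file for id {image_id!r} under {image_dir}")
        with Image.open(path) as im:
            im = im.convert("RGB")
            if im.size != (w, h):
                im = im.resize((w, h), Image.BILINEAR)
            out[i] = np.asarray(im)
    return out


def preprocess_pixels(pixels: np.ndarray, mode: str = "symmetric") -> np.ndarray:
    """Map raw 0–255 RGB pixels to the scale a backbone convention expects.

    Modes
    -----
    ``symmetric``     x/127.5 − 1, range [−1, 1] (MobileNet/NasNet/Inception).
    ``unit_imagenet`` x/255 then per-channel ImageNet mean/std normalization
                      (DenseNet).
    ``bgr_centered``  RGB→BGR channel reversal, then per-channel ImageNet mean
                      subtraction on the 0–255 scale, no scaling (ResNet).

    Input must be raw integer-valued pixels in 0–255; already-scaled float
    input is rejected so the transform cannot be applied twice.
    """
    x = np.asarray(pixels)
    if x.ndim < 1 or x.shape[-1] != 3:
        raise ValueError(f"expected a trailing RGB channel axis of size 3, got shape {x.shape}")
    if x.min() < 0 or x.max() > 255:
        raise ValueError("pixel values must lie in 0..255")
    if np.issubdtype(x.dtype, np.floating) and x.size and float(x.max()) <= 1.0:
        raise ValueError("input looks already scaled (float max <= 1); expected raw 0-255 pixels")
    x = x.astype(np.float64)
    if mode == "symmetric":
        return x / 127.5 - 1.0
    if mode == "unit_imagenet":
        return (x / 255.0 - IMAGENET_MEAN) / IMAGENET_STD
    if mode == "bgr_centered":
        return x[..., ::-1] - IMAGENET_BGR_MEAN
    raise ValueError(f"unknown pixel mode {mode!r}")


def split_dataset(items, fractions: tuple[float, float] = (0.9, 0.1), seed: int = 0,
                  stratify_labels=None):
    """Shuffle and split into train/validation subsets.

    ``train`` gets floor(n · f_train) items; when the fractions sum to 1 the
    remainder goes to validation, otherwise validation gets floor(n · f_val).
    Pass ``stratify_labels`` to split each class separately with the same
    rule, which protects rare classes from ending up absent in one side.
    ``items`` may be an integer n (index arrays are returned), a sequence, or
    a DataFrame.
    """
    ft, fv = fractions
    if not (0.0 < ft < 1.0 and 0.0 < fv < 1.0 and ft + fv <= 1.0 + 1e-12):
        raise ValueError(f"fractions must be in (0,1) and sum to <= 1, got {fractions}")
    if isinstance(items, int):
        n = items
    else:
        n = len(items)
    if n < 2:
        raise ValueError("need at least 2 items to split")
    rng = np.random.default_rng(seed)

    def _split_indices(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        idx = rng.permutation(idx)
        n_train = int(np.floor(len(idx) * ft))
        if abs(ft + fv - 1.0) <= 1e-12:
            n_val = len(idx) - n_train
        else:
            n_val = int(np.floor(len(idx) * fv))
        return idx[:n_train], idx[n_train:n_train + n_val]

    if stratify_labels is not None:
        labels = np.asarray(stratify_labels)
        if len(labels) != n:
            raise ValueError("stratify_labels length must match items")
        train_parts, val_parts = [], []
        for lab in np.unique(labels):
            tr, va = _split_indices(np.flatnonzero(labels == lab))
            train_parts.append(tr)
            val_parts.append(va)
        train_idx = rng.permutation(np.concatenate(train_parts))
        val_idx = rng.permutation(np.concatenate(val_parts))
    else:
        train_idx, val_idx = _split_indices(np.arange(n))

    if isinstance(items, int):
        return train_idx, val_idx
    if isinstance(items, pd.DataFrame):
        return items.iloc[train_idx], items.iloc[val_idx]
    if isinstance(items, np.ndarray):
        return items[train_idx], items[val_idx]
    return [items[i] for i in train_idx], [items[i] for i in val_idx]
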