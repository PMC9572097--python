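"""Encoding of patient metadata and fusion with image features.

Age, sex and anatomical site carry diagnostic signal of their own (e.g.
actinic keratoses skew old and sun-exposed sites, nevi skew young), so the
classifier accepts them as a second input branch.  Sex and site are one-hot
encoded with an explicit ``unknown`` level each — missing metadata is a
category, not a dropped record.  Age is divided by a fixed scale of 100
years (so the slot lies in [0, 1] for the ages that occur in dermoscopy
archives) and accompanied by a missing-indicator bit; a missing age encodes
as slot 0 with the indicator set.  The encoded vector feeds a single dense
layer (default 4096 units) whose output is concatenated after the image
feature vector.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_io import SEX_LEVELS, UNKNOWN, MetadataRecord, MetadataSchema
from .nn import Dense

__all__ = [
    "AGE_SCALE",
    "encoded_length",
    "encode_metadata",
    "encode_metadata_frame",
    "MetadataHead",
    "metadata_head_forward",
    "fuse",
]

AGE_SCALE = 100.0  # years; fixed so the encoding is split-independent


def encoded_length(schema: MetadataSchema) -> int:
    """Length of the encoded vector: sex levels + sites(+unknown) + age + missing bit."""
    return len(SEX_LEVELS) + len(schema.sites) + 1 + 2


def encode_metadata(record: MetadataRecord, schema: MetadataSchema | None = None) -> np.ndarray:
    """Deterministic fixed-length encoding of one record.

    Layout: [one-hot sex (male, female, unknown) | one-hot site (schema order,
    then unknown) | age / 100 | age-missing bit].
    """
    schema = schema or MetadataSchema()
    sex_vec = np.zeros(len(SEX_LEVELS))
    sex = record.sex if record.sex in SEX_LEVELS else None
    if sex is None:
        raise ValueError(f"sex level {record.sex!r} not in {SEX_LEVELS}")
    sex_vec[SEX_LEVELS.index(sex)] = 1.0

    site_vec = np.zeros(len(schema.sites) + 1)
    if record.localization == UNKNOWN:
        site_vec[-1] = 1.0
    elif record.localization in schema.sites:
        site_vec[schema.sites.index(record.localization)] = 1.0
    else:
        raise ValueError(
            f"localization {record.localization!r} not in schema sites and not {UNKNOWN!r}"
        )

    if record.age_missing:
        age_part = np.array([0.0, 1.0])
    else:
        age_part = np.array([float(record.age) / AGE_SCALE, 0.0])
    return np.concatenate([sex_vec, site_vec, age_part])


def encode_metadata_frame(df: pd.DataFrame, schema: MetadataSchema | None = None) -> np.ndarray:
    """Encode every row of a validated metadata table; shape (N, encoded_length)."""
    schema = schema or MetadataSchema()
    out = np.empty((len(df), encoded_length(schema)))
    for i, (_, row) in enumerate(df.iterrows()):
        rec = MetadataRecord(
            image_id=str(row["image_id"]), dx=str(row["dx"]),
            age=float(row["age"]) if pd.notna(row["age"]) else np.nan,
            sex=str(row["sex"]), localization=str(row["localization"]),
        )
        out[i] = encode_metadata(rec, schema)
    return out


class MetadataHead(Dense):
    """Single dense layer mapping the encoded metadata vector to a wide
    feature vector (default 4096 units, linear — the downstream classifier
    head supplies the nonlinearity)."""

    def __init__(self, in_dim: int, units: int = 4096,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__(in_dim, units, rng=rng, name="meta_head")
        self.units = units


def metadata_head_forward(encoded: np.ndarray, head: MetadataHead) -> np.ndarray:
    """Dense-layer forward for one encoded vector or a batch."""
    x = np.asarray(encoded, dtype=np.float64)
    single = x.ndim == 1
    out = head.forward(x[None] if single else x)
    return out[0] if single else out


def fuse(image_features: np.ndarray, meta_features: np.ndarray | None) -> np.ndarray:
    """Concatenate image features (first) with metadata features.

    ``meta_features`` may be None or empty when the metadata branch is
    disabled, in which case the image features pass through unchanged.
    Works on single vectors or aligned batches.
    """
    img = np.asarray(image_features, dtype=np.float64)
    if not np.isfinite(img).all():
        raise ValueError("image features must be finite")
    if meta_features is None or np.asarray(meta_features).size == 0:
        return img
    meta = np.asarray(meta_features, dtype=np.float64)
    if not np.isfinite(meta).all():
        raise ValueError("metadata features must be finite")
    return np.concatenate([img, meta], axis=-1)
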