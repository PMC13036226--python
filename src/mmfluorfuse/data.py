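"""Fluorescence-image and parameter-table handling.

This module covers the imaging side of the phenotyping pipeline: reading
FluorCam-style exports (1024x768 pseudo-colored PNG/TIFF) and their
80-parameter tables, assigning the five ordinal salt-tolerance levels from
QY_max (= Fv/Fm), center-cropping and resizing, the fixed six-fold
rotation/mirror augmentation, and stratified 8:1:1 splitting.

Level semantics: level 1 is a healthy plant (QY_max >= 0.79), level 5 is
severe salt damage.  The level bins are half-open and total on the real
line; values below the lowest observed QY_max clamp to level 5.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize as _sk_resize

from .errors import DataError, DimensionError, ParseError, SchemaError

#: the five parameters every record must carry (the physiological anchors)
REQUIRED_PARAMS = ("Fm", "QY_max", "NPQ_Lss", "qP_Lss", "Rfd_Lss")
#: number of fluorescence parameters per sample
N_PARAMS = 80
#: identifier columns of a parameter table, in order
ID_COLUMNS = ("sample_id", "variety_id", "treatment")

#: upper QY_max edges of levels 1..4; below the last edge is level 5
LEVEL_EDGES = (0.79, 0.61, 0.46, 0.31)

#: fixed augmentation order (identity, rotations CCW, horizontal and
#: vertical mirror) so manifests and caches are reproducible
AUGMENT_NAMES = ("orig", "rot90", "rot180", "rot270", "mirror_h", "mirror_v")


@dataclass
class ParameterRecord:
    """One sample's 80 named chlorophyll-fluorescence parameters."""

    sample_id: str
    variety_id: str
    treatment: str  # "control" or "salt"
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.values) != N_PARAMS:
            raise SchemaError(
                f"record {self.sample_id!r} has {len(self.values)} parameters, "
                f"expected {N_PARAMS}")
        missing = [p for p in REQUIRED_PARAMS if p not in self.values]
        if missing:
            raise SchemaError(
                f"record {self.sample_id!r} missing required parameters {missing}")
        for name, v in self.values.items():
            if not math.isfinite(v):
                raise ParseError(
                    f"record {self.sample_id!r}: parameter {name!r} is not finite")

    @property
    def qy_max(self) -> float:
        return self.values["QY_max"]

    def as_array(self, order: list[str] | None = None) -> np.ndarray:
        names = list(self.values) if order is None else order
        return np.array([self.values[n] for n in names], dtype=float)


@dataclass
class FluorImage:
    """An H x W x 3 float image with values in [0, 1]."""

    pixels: np.ndarray
    source_size: tuple[int, int] | None = None  # (width, height)

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise DimensionError(f"expected HxWx3 pixels, got shape {px.shape}")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("pixel values must lie in [0, 1]")
        self.pixels = px
        if self.source_size is None:
            self.source_size = (px.shape[1], px.shape[0])

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class LabeledSample:
    """Image + parameter record + salt-tolerance level in 1..5."""

    image: FluorImage | None
    params: ParameterRecord
    level: int

    def __post_init__(self):
        expected = assign_level(self.params.qy_max)
        if self.level != expected:
            raise DataError(
                f"sample {self.params.sample_id!r}: level {self.level} "
                f"inconsistent with QY_max={self.params.qy_max} (expect {expected})")


@dataclass
class DatasetSplit:
    train: list[str]
    val: list[str]
    test: list[str]
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)

    def __post_init__(self):
        sets = [set(self.train), set(self.val), set(self.test)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise DataError("split lists are not pairwise disjoint")


# ------------------------------------------------------------------- tables

def load_parameter_table(path) -> list[ParameterRecord]:
    """Read a CSV of ``sample_id, variety_id, treatment`` + 80 parameters.

    Raises :class:`SchemaError` on missing columns and :class:`ParseError`
    (naming the row) on non-numeric parameter values.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in ID_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"parameter table missing columns {missing}")
    param_cols = [c for c in df.columns if c not in ID_COLUMNS]
    if len(param_cols) != N_PARAMS:
        raise SchemaError(
            f"parameter table has {len(param_cols)} parameter columns, "
            f"expected {N_PARAMS}")
    missing_req = [p for p in REQUIRED_PARAMS if p not in param_cols]
    if missing_req:
        raise SchemaError(f"parameter table missing required columns {missing_req}")

    numeric = df[param_cols].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        col = numeric.columns[numeric.iloc[row].isna().to_numpy()][0]
        raise ParseError(f"row {row}: parameter {col!r} is not numeric "
                         f"(value {df.iloc[row][col]!r})")

    records = []
    for i in range(len(df)):
        records.append(ParameterRecord(
            sample_id=str(df.iloc[i]["sample_id"]),
            variety_id=str(df.iloc[i]["variety_id"]),
            treatment=str(df.iloc[i]["treatment"]),
            values={c: float(numeric.iloc[i][c]) for c in param_cols},
        ))
    return records


def write_parameter_table(records: list[ParameterRecord], path) -> None:
    rows = []
    for r in records:
        row = {"sample_id": r.sample_id, "variety_id": r.variety_id,
               "treatment": r.treatment}
        row.update(r.values)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ------------------------------------------------------------------- levels

def assign_level(qy_max: float) -> int:
    """Map QY_max (Fv/Fm) to the ordinal salt-tolerance level 1..5.

    Bins are half-open: [0.79, inf) -> 1, [0.61, 0.79) -> 2,
    [0.46, 0.61) -> 3, [0.31, 0.46) -> 4, (-inf, 0.31) -> 5.
    """
    if not math.isfinite(qy_max):
        raise ValueError(f"QY_max must be finite, got {qy_max}")
    for lvl, edge in enumerate(LEVEL_EDGES, start=1):
        if qy_max >= edge:
            return lvl
    return 5


# ------------------------------------------------------------------- images

def read_image(path) -> FluorImage:
    """Read a PNG or TIFF image as float RGB in [0, 1]."""
    with Image.open(path) as im:
        rgb = im.convert("RGB")
        px = np.asarray(rgb, dtype=float) / 255.0
    return FluorImage(px)


def write_image(img: FluorImage, path) -> None:
    arr = np.clip(np.round(img.pixels * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(path)


def center_crop(img: FluorImage, side: int) -> FluorImage:
    """Crop a centered ``side x side`` window (0-based, half-open)."""
    h, w = img.height, img.width
    if side > min(h, w):
        raise DimensionError(f"crop side {side} exceeds image size {h}x{w}")
    top = (h - side) // 2
    left = (w - side) // 2
    return FluorImage(img.pixels[top:top + side, left:left + side].copy(),
                      source_size=img.source_size)


def resize(img: FluorImage, side: int) -> FluorImage:
    """Bilinear resize to ``side x side``; values stay in [0, 1]."""
    if side < 1:
        raise DimensionError(f"resize side must be >= 1, got {side}")
    if side == img.height == img.width:
        return FluorImage(img.pixels.copy(), source_size=img.source_size)
    out = _sk_resize(img.pixels, (side, side), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return FluorImage(np.clip(out, 0.0, 1.0), source_size=img.source_size)


def augment_six_fold(img: FluorImage) -> list[FluorImage]:
    """The fixed six-transform augmentation of a square image.

    Order: identity, rot90, rot180, rot270 (counter-clockwise), horizontal
    mirror (left-right), vertical mirror (up-down).
    """
    if img.height != img.width:
        raise DimensionError(
            f"six-fold augmentation needs a square image, got {img.height}x{img.width}")
    px = img.pixels
    variants = [px.copy(),
                np.rot90(px, 1, axes=(0, 1)).copy(),
                np.rot90(px, 2, axes=(0, 1)).copy(),
                np.rot90(px, 3, axes=(0, 1)).copy(),
                px[:, ::-1].copy(),
                px[::-1, :].copy()]
    return [FluorImage(v, source_size=img.source_size) for v in variants]


# -------------------------------------------------------------------- split

def _apportion(quotas: np.ndarray, total: int, caps: np.ndarray) -> np.ndarray:
    """Integer allocation by largest remainder, respecting per-item caps."""
    base = np.minimum(np.floor(quotas).astype(int), caps)
    rem = total - base.sum()
    frac = quotas - np.floor(quotas)
    order = np.argsort(-frac, kind="stable")
    i = 0
    while rem > 0 and i < 10 * len(base):
        j = order[i % len(base)]
        if base[j] < caps[j]:
            base[j] += 1
            rem -= 1
        i += 1
    if rem != 0:
        raise DataError("cannot apportion split sizes under per-level caps")
    return base


def split_dataset(ids: list[str], levels: dict[str, int] | list[int],
                  ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
                  seed: int = 0) -> DatasetSplit:
    """Stratified train/val/test split of raw sample ids.

    Sizes are floor(r_train*n) / floor(r_val*n) / remainder overall, with
    per-level proportions within one sample of the global ratios.  The
    split is computed on raw ids; augmentation happens afterwards within
    each split, so augmented copies of one plant never cross splits.
    """
    ids = list(ids)
    n = len(ids)
    if n < 10:
        raise DataError(f"need at least 10 ids to split, got {n}")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    if not isinstance(levels, dict):
        levels = dict(zip(ids, levels))
    lvl_ids: dict[int, list[str]] = {}
    for sid in ids:
        lvl_ids.setdefault(levels[sid], []).append(sid)
    if n < len(lvl_ids):
        raise DataError("fewer ids than classes; cannot stratify")

    keys = sorted(lvl_ids)
    counts = np.array([len(lvl_ids[k]) for k in keys])
    n_train = int(np.floor(ratios[0] * n))
    n_val = int(np.floor(ratios[1] * n))

    t_alloc = _apportion(ratios[0] * counts, n_train, counts)
    v_alloc = _apportion(ratios[1] * counts, n_val, counts - t_alloc)

    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    for k, t_k, v_k in zip(keys, t_alloc, v_alloc):
        pool = list(lvl_ids[k])
        rng.shuffle(pool)
        train.extend(pool[:t_k])
        val.extend(pool[t_k:t_k + v_k])
        test.extend(pool[t_k + v_k:])
    return DatasetSplit(train=train, val=val, test=test, ratios=tuple(ratios))


# ----------------------------------------------------------------- manifest

def dataset_manifest(samples: list[LabeledSample]) -> dict:
    """Per-level counts and total, keyed ``{"per_level": {1..5}, "total"}``."""
    counts = Counter(s.level for s in samples)
    per_level = {lvl: int(counts.get(lvl, 0)) for lvl in range(1, 6)}
    return {"per_level": per_level, "total": int(sum(per_level.values()))}
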