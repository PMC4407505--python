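"""Reading images and writing the pipeline's interchange tables.

CSV is the interchange format between stages (fixed headers, UTF-8, "."
decimal); model fits are written as JSON reports.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .image_features import FEATURE_NAMES, validate_image

FEATURE_HEADER = ["image_id", *FEATURE_NAMES]
RATINGS_HEADER = ["participant_id", "image_id", "preference", "naturalness", "rt", "group"]

IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit RGB PNG/JPEG raster (alpha dropped with a warning)."""
    arr = iio.imread(path)
    if arr.ndim == 2:  # grayscale file: replicate to RGB
        arr = np.stack([arr] * 3, axis=-1)
    return validate_image(arr)


def iter_image_paths(directory: str | Path) -> list[Path]:
    directory = Path(directory)
    return sorted(
        p for p in directory.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES
    )


def write_feature_table(features: pd.DataFrame, path: str | Path) -> None:
    """Write features.csv with the canonical header; missing DER is empty."""
    features[FEATURE_HEADER].to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(FEATURE_HEADER) - set(df.columns)
    if missing:
        raise ValueError(f"feature table {path} lacks columns {sorted(missing)}")
    return df


def write_ratings(ratings: pd.DataFrame, path: str | Path) -> None:
    ratings[RATINGS_HEADER].to_csv(path, index=False)


def read_ratings(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(RATINGS_HEADER) - set(df.columns)
    if missing:
        raise ValueError(f"ratings table {path} lacks columns {sorted(missing)}")
    return df


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def save_edge_map(weights: np.ndarray, path: str | Path) -> None:
    """Save an edge-weight map as PNG with weights {0, 0.5, 1} -> {0, 128, 255}."""
    img = np.zeros(weights.shape, dtype=np.uint8)
    img[weights == 0.5] = 128
    img[weights == 1.0] = 255
    iio.imwrite(path, img)


def save_scene(pixels: np.ndarray, path: str | Path) -> None:
    iio.imwrite(path, pixels)
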