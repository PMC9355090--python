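"""Dataset manifests, stratified splitting and image augmentation.

A manifest is a CSV with header ``path,label,split``; labels follow the
fixed class order (healthy, unhealthy, none), mirroring the Y / N2 / N1
folder convention for healthy, unhealthy and blank frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.transform import AffineTransform, warp

from ..evaluation import LABELS

__all__ = [
    "FOLDER_CODES",
    "AugmentationConfig",
    "read_manifest",
    "write_manifest",
    "split_dataset",
    "hflip",
    "augment",
]

#: Folder naming convention: Y = healthy, N2 = unhealthy, N1 = no seedling.
FOLDER_CODES = {"Y": "healthy", "N2": "unhealthy", "N1": "none"}

SPLITS = ("train", "val", "test")


@dataclass(frozen=True)
class AugmentationConfig:
    """Random-augmentation magnitudes (shear 25°, rotation 20°, horizontal
    flip, shifts of 0.3 of each dimension)."""

    shear_degrees: float = 25.0
    rotation_degrees: float = 20.0
    horizontal_flip: bool = True
    width_shift_fraction: float = 0.3
    height_shift_fraction: float = 0.3

    def __post_init__(self) -> None:
        if not (0 <= self.width_shift_fraction <= 1 and 0 <= self.height_shift_fraction <= 1):
            raise ValueError("shift fractions must lie in [0, 1]")
        if self.shear_degrees < 0 or self.rotation_degrees < 0:
            raise ValueError("angles must be nonnegative")

    @property
    def is_identity(self) -> bool:
        return (
            self.shear_degrees == 0
            and self.rotation_degrees == 0
            and not self.horizontal_flip
            and self.width_shift_fraction == 0
            and self.height_shift_fraction == 0
        )


def read_manifest(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"path", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    bad = set(df["label"]) - set(LABELS)
    if bad:
        raise ValueError(f"unknown labels in manifest: {sorted(bad)}")
    return df


def write_manifest(df: pd.DataFrame, path: str) -> None:
    cols = [c for c in ("path", "label", "split") if c in df.columns]
    df.to_csv(path, index=False, columns=cols)


def split_dataset(
    manifest: pd.DataFrame,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> pd.DataFrame:
    """Per-class stratified train/val/test assignment.

    Within each class the rows are shuffled and cut by the requested
    fractions using floor-then-distribute rounding (largest fractional
    remainder first), so every class deviates from the exact fractions by
    at most one image per split. Deterministic under ``seed``.
    """
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise ValueError("fractions must sum to 1")
    if manifest["path"].duplicated().any():
        raise ValueError("manifest paths must be unique")
    rng = np.random.default_rng(seed)
    out = manifest.copy()
    out["split"] = ""
    for label in LABELS:
        idx = out.index[out["label"] == label].to_numpy()
        if len(idx) == 0:
            raise ValueError(f"class {label!r} has no rows to split")
        rng.shuffle(idx)
        n = len(idx)
        exact = [f * n for f in fractions]
        sizes = [int(math.floor(e)) for e in exact]
        remainder = n - sum(sizes)
        order = np.argsort([-(e - s) for e, s in zip(exact, sizes)], kind="stable")
        for k in range(remainder):
            sizes[order[k]] += 1
        start = 0
        for split_name, size in zip(SPLITS, sizes):
            out.loc[idx[start : start + size], "split"] = split_name
            start += size
    return out


def hflip(image: np.ndarray) -> np.ndarray:
    """Horizontal mirror (an involution)."""
    return np.ascontiguousarray(np.asarray(image)[:, ::-1])


def augment(
    image: np.ndarray,
    config: AugmentationConfig = AugmentationConfig(),
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """One random augmentation draw: shear, rotation, optional horizontal
    flip and shifts, composed about the image centre.

    Vacated pixels are filled with white to match the extracted-image
    background. Output dtype/shape equal the input; a zero-magnitude
    config returns the image unchanged. Bit-reproducible for a fixed seed.
    """
    image = np.asarray(image, dtype=np.uint8)
    if config.is_identity:
        return image.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h, w = image.shape[:2]
    shear = math.radians(rng.uniform(-config.shear_degrees, config.shear_degrees))
    rotation = math.radians(rng.uniform(-config.rotation_degrees, config.rotation_degrees))
    flip = bool(config.horizontal_flip and rng.random() < 0.5)
    tx = rng.uniform(-config.width_shift_fraction, config.width_shift_fraction) * w
    ty = rng.uniform(-config.height_shift_fraction, config.height_shift_fraction) * h

    if flip:
        image = hflip(image)
    centre = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    to_origin = AffineTransform(translation=-centre)
    distort = AffineTransform(rotation=rotation, shear=shear)
    back = AffineTransform(translation=centre + np.array([tx, ty]))
    tform = to_origin + distort + back
    warped = warp(
        image.astype(np.float64) / 255.0,
        tform.inverse,
        order=1,
        cval=1.0,  # white fill
        preserve_range=True,
    )
    return np.clip(np.round(warped * 255.0), 0, 255).astype(np.uint8)
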