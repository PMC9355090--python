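"""RGB→HSV conversion and HSV box masking in the half-range encoding.

Hue is stored halved (0–180) and saturation/value scaled to 0–255 so that
integer threshold tables fit in 8 bits. All conversions are vectorised and
bit-reproducible: scaling uses round-half-away-from-zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ColorRange",
    "rgb_to_hsv",
    "in_range",
    "union_masks",
    "load_color_table",
    "get_color_range",
]


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (values here are nonnegative)."""
    return np.floor(x + 0.5)


@dataclass(frozen=True)
class ColorRange:
    """An inclusive HSV box; hue may carry several intervals (red wraps).

    Bounds use the half-range encoding: hue in [0, 180], saturation and
    value in [0, 255].
    """

    name: str
    hue_ranges: tuple[tuple[int, int], ...]
    s_min: int
    s_max: int
    v_min: int
    v_max: int

    def __post_init__(self) -> None:
        for lo, hi in self.hue_ranges:
            if not (0 <= lo <= hi <= 180):
                raise ValueError(f"invalid hue interval ({lo}, {hi}) for {self.name!r}")
        if not (0 <= self.s_min <= self.s_max <= 255):
            raise ValueError(f"invalid saturation bounds for {self.name!r}")
        if not (0 <= self.v_min <= self.v_max <= 255):
            raise ValueError(f"invalid value bounds for {self.name!r}")

    @classmethod
    def from_bounds(
        cls,
        name: str,
        h_min: int,
        h_max: int,
        s_min: int,
        s_max: int,
        v_min: int,
        v_max: int,
    ) -> "ColorRange":
        return cls(name, ((h_min, h_max),), s_min, s_max, v_min, v_max)


def _validate_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an H×W×3 RGB array, got shape {image.shape}")
    if image.shape[0] < 1 or image.shape[1] < 1:
        raise ValueError("empty image")
    return image


def rgb_to_hsv(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to half-range HSV.

    Per pixel the channels are first scaled to unit range (R', G', B'),
    then Cmax, Cmin and the chroma Δ = Cmax − Cmin are formed.  Hue is
    piecewise over which channel attains Cmax (0° when Δ = 0), with the
    red branch wrapped into [0°, 360°); saturation is Δ/Cmax (0 for black)
    and value is Cmax.  The result stores (H/2, 255·S, 255·V) rounded
    half-away-from-zero, as uint8-compatible integers in a uint8 array
    with H ≤ 180.
    """
    image = _validate_rgb(image)
    rgb = image.astype(np.float64) / 255.0
    rp, gp, bp = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    cmax = np.max(rgb, axis=-1)
    cmin = np.min(rgb, axis=-1)
    delta = cmax - cmin

    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.select(
            [delta == 0, cmax == rp, cmax == gp, cmax == bp],
            [
                0.0,
                60.0 * ((gp - bp) / delta),
                60.0 * ((bp - rp) / delta + 2.0),
                60.0 * ((rp - gp) / delta + 4.0),
            ],
        )
    h = np.where(h < 0, h + 360.0, h)  # wrap the Cmax=R' branch into [0, 360)
    s = np.where(cmax == 0, 0.0, np.divide(delta, cmax, out=np.zeros_like(delta), where=cmax != 0))

    out = np.empty(image.shape, dtype=np.uint8)
    out[..., 0] = _round_half_away(h / 2.0)
    out[..., 1] = _round_half_away(s * 255.0)
    out[..., 2] = _round_half_away(cmax * 255.0)
    return out


def in_range(hsv: np.ndarray, crange: ColorRange) -> np.ndarray:
    """Binary mask (0/255 uint8): 255 where all three channels fall inside
    the box; hue passes if it lies in any of the range's hue intervals."""
    hsv = np.asarray(hsv)
    if hsv.ndim != 3 or hsv.shape[2] != 3:
        raise ValueError(f"expected an H×W×3 HSV array, got shape {hsv.shape}")
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    h_ok = np.zeros(h.shape, dtype=bool)
    for lo, hi in crange.hue_ranges:
        h_ok |= (h >= lo) & (h <= hi)
    ok = (
        h_ok
        & (s >= crange.s_min)
        & (s <= crange.s_max)
        & (v >= crange.v_min)
        & (v <= crange.v_max)
    )
    return np.where(ok, 255, 0).astype(np.uint8)


def union_masks(masks: Iterable[np.ndarray]) -> np.ndarray:
    """Pixelwise union of 0/255 masks (the "summed" mask composition)."""
    masks = [np.asarray(m) for m in masks]
    if not masks:
        raise ValueError("need at least one mask")
    shape = masks[0].shape
    for m in masks[1:]:
        if m.shape != shape:
            raise ValueError(f"mask shape mismatch: {m.shape} vs {shape}")
    out = np.zeros(shape, dtype=np.uint8)
    for m in masks:
        out |= (m > 0).astype(np.uint8)
    return out * 255


def load_color_table(path: str | None = None) -> dict[str, ColorRange]:
    """Load the versioned HSV threshold table (packaged JSON by default).

    Users may pass a path to an override file with the same schema.
    """
    if path is None:
        raw = resources.files("seedlingscreen.data").joinpath("hsv_color_table.json").read_text()
    else:
        with open(path) as fh:
            raw = fh.read()
    doc = json.loads(raw)
    table: dict[str, ColorRange] = {}
    for name, spec in doc["colors"].items():
        table[name] = ColorRange(
            name=name,
            hue_ranges=tuple((int(lo), int(hi)) for lo, hi in spec["h"]),
            s_min=int(spec["s"][0]),
            s_max=int(spec["s"][1]),
            v_min=int(spec["v"][0]),
            v_max=int(spec["v"][1]),
        )
    for alias, target in doc.get("aliases", {}).items():
        table[alias] = table[target]
    return table


_DEFAULT_TABLE: dict[str, ColorRange] | None = None


def get_color_range(name: str) -> ColorRange:
    """Look up a color in the packaged threshold table."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_color_table()
    try:
        return _DEFAULT_TABLE[name]
    except KeyError:
        raise KeyError(f"unknown color {name!r}; known: {sorted(_DEFAULT_TABLE)}") from None
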