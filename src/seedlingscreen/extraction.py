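"""Background removal and per-station cropping of captured frames.

A captured frame shows several seedlings side by side against a light
neutral background. Extraction keeps pixels inside the plant-color union
(orange, yellow, green, cyan, blue) or the black substrate range and paints
everything else white, then frames are cut into equal-width station crops
and resized for the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

from .colorspace import ColorRange, get_color_range, in_range, rgb_to_hsv, union_masks

__all__ = [
    "PLANT_COLORS",
    "NET_INPUT_SIZE",
    "SeedlingCrop",
    "plant_mask",
    "substrate_mask",
    "seedling_mask",
    "extract_seedling",
    "black_background",
    "crop_frame",
    "resize_for_net",
    "read_image",
    "write_image",
    "write_mask",
]

#: Colors whose union forms the plant-extraction threshold. The background is
#: white/gray, so these five chromatic ranges keep the seedling foliage.
PLANT_COLORS: tuple[str, ...] = ("orange", "yellow", "green", "cyan", "blue")

#: Side length expected by the residual-network classifiers.
NET_INPUT_SIZE = 224

WHITE = np.array([255, 255, 255], dtype=np.uint8)


@dataclass(frozen=True)
class SeedlingCrop:
    """One station's slice of a frame; ``index`` runs 1..n left to right."""

    image: np.ndarray
    index: int


def plant_mask(hsv: np.ndarray) -> np.ndarray:
    """Union of the orange/yellow/green/cyan/blue in-range masks."""
    return union_masks([in_range(hsv, get_color_range(c)) for c in PLANT_COLORS])


def substrate_mask(hsv: np.ndarray) -> np.ndarray:
    """The black in-range mask (dark substrate plug)."""
    return in_range(hsv, get_color_range("black"))


def seedling_mask(image: np.ndarray) -> np.ndarray:
    """Full extraction mask: plant colors ∪ black substrate, from RGB."""
    hsv = rgb_to_hsv(image)
    return union_masks([plant_mask(hsv), substrate_mask(hsv)])


def extract_seedling(image: np.ndarray) -> np.ndarray:
    """White-background seedling image.

    Pixels inside the extraction mask keep their values; the rest become
    white. Composing the mask once and overlaying onto white is
    algebraically identical to the two-step black-background/transparency
    composition and idempotent, because pure white falls in no extraction
    range.
    """
    mask = seedling_mask(image)
    out = np.where(mask[..., None] > 0, image, WHITE)
    return out.astype(np.uint8)


def black_background(image: np.ndarray) -> np.ndarray:
    """Debugging intermediate: masked pixels kept, background black."""
    mask = seedling_mask(image)
    return np.where(mask[..., None] > 0, image, 0).astype(np.uint8)


def crop_frame(image: np.ndarray, n: int) -> list[SeedlingCrop]:
    """Cut a frame into ``n`` equal-width vertical slices, left to right.

    Remainder pixels go to the rightmost slice; concatenating the slices
    reconstructs the frame exactly.
    """
    image = np.asarray(image)
    width = image.shape[1]
    if n < 1:
        raise ValueError("station count must be >= 1")
    if n > width:
        raise ValueError(f"cannot cut {width}-px-wide frame into {n} slices")
    base = width // n
    crops = []
    for i in range(n):
        lo = i * base
        hi = (i + 1) * base if i < n - 1 else width
        crops.append(SeedlingCrop(image=image[:, lo:hi], index=i + 1))
    return crops


def resize_for_net(image: np.ndarray, size: int = NET_INPUT_SIZE) -> np.ndarray:
    """Direct bilinear resize to the square network input (no aspect
    preservation)."""
    image = np.asarray(image, dtype=np.uint8)
    if image.shape[0] == size and image.shape[1] == size:
        return image.copy()
    pil = Image.fromarray(image)
    return np.asarray(pil.resize((size, size), Image.BILINEAR))


def read_image(path: str) -> np.ndarray:
    """Read a PNG/JPEG as an H×W×3 uint8 RGB array."""
    with Image.open(path) as img:
        return np.asarray(img.convert("RGB"))


def write_image(image: np.ndarray, path: str) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)


def write_mask(mask: np.ndarray, path: str) -> None:
    """Write a binary mask as a single-channel PNG."""
    Image.fromarray(np.asarray(mask, dtype=np.uint8), mode="L").save(path)
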