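"""Rule-based seedling screening from leaf and substrate pixel areas.

Leaf pixels (yellow ∪ green ranges) and substrate pixels (black range) are
masked in HSV, denoised by morphological closing followed by Gaussian
smoothing with re-thresholding, counted, and compared against pixel-area
thresholds: a seedling is healthy when leaf area ≥ 2,300 px AND substrate
area ≥ 1,300 px, absent when both measured areas are zero, and unhealthy
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import dilation, disk, erosion

from .colorspace import get_color_range, in_range, rgb_to_hsv, union_masks

__all__ = [
    "LEAF_COLORS",
    "ScreeningThresholds",
    "DenoiseConfig",
    "ScreeningResult",
    "denoise",
    "measure_areas",
    "classify_physical",
    "screen_image",
]

#: The leaf-area measurement uses the narrower yellow-green set, not the
#: five-color extraction union: foliage is yellow-green, and the wider set
#: would count stray chromatic noise into the area.
LEAF_COLORS: tuple[str, ...] = ("yellow", "green")

HEALTHY = "healthy"
UNHEALTHY = "unhealthy"
NONE = "none"


@dataclass(frozen=True)
class ScreeningThresholds:
    """Pixel-area screening index (inclusive lower bounds)."""

    leaf_min: int = 2300
    substrate_min: int = 1300

    def __post_init__(self) -> None:
        if self.leaf_min < 0 or self.substrate_min < 0:
            raise ValueError("thresholds must be nonnegative")


@dataclass(frozen=True)
class DenoiseConfig:
    """Morphology + Gaussian denoising settings.

    ``selem_radius=1`` gives the minimal 3×3 elliptical (cross) structuring
    element; ``gaussian_sigma=1.0`` with ``truncate=2.0`` is a 5×5 kernel.
    Re-thresholding at mid-level (>127 on a 0–255 mask) restores binarity
    and suppresses isolated single-pixel noise.
    """

    selem_radius: int = 1
    dilate_iterations: int = 1
    erode_iterations: int = 1
    gaussian_sigma: float = 1.0
    gaussian_truncate: float = 2.0
    rethreshold: int = 127


@dataclass(frozen=True)
class ScreeningResult:
    label: str
    leaf_area: int
    substrate_area: int


def denoise(mask: np.ndarray, config: DenoiseConfig = DenoiseConfig()) -> np.ndarray:
    """Dilation, then erosion, then Gaussian blur + mid-level re-threshold."""
    binary = np.asarray(mask) > 0
    footprint = disk(config.selem_radius)
    for _ in range(config.dilate_iterations):
        binary = dilation(binary, footprint)
    for _ in range(config.erode_iterations):
        binary = erosion(binary, footprint)
    blurred = ndimage.gaussian_filter(
        binary.astype(np.float64) * 255.0,
        sigma=config.gaussian_sigma,
        truncate=config.gaussian_truncate,
    )
    return np.where(blurred > config.rethreshold, 255, 0).astype(np.uint8)


def measure_areas(
    image: np.ndarray, config: DenoiseConfig = DenoiseConfig()
) -> tuple[int, int]:
    """(leaf_area, substrate_area) in pixels, counted after denoising."""
    hsv = rgb_to_hsv(image)
    leaf = denoise(
        union_masks([in_range(hsv, get_color_range(c)) for c in LEAF_COLORS]), config
    )
    substrate = denoise(in_range(hsv, get_color_range("black")), config)
    return int(np.count_nonzero(leaf)), int(np.count_nonzero(substrate))


def classify_physical(
    leaf_area: int,
    substrate_area: int,
    thresholds: ScreeningThresholds = ScreeningThresholds(),
    zero_epsilon: int = 0,
) -> ScreeningResult:
    """Total three-way rule on the measured areas.

    Both areas ≤ ``zero_epsilon`` (default 0, strict) → no seedling; both
    at or above their thresholds → healthy; anything else → unhealthy.
    """
    if leaf_area < 0 or substrate_area < 0:
        raise ValueError("areas must be nonnegative")
    if leaf_area <= zero_epsilon and substrate_area <= zero_epsilon:
        return ScreeningResult(NONE, 0, 0)
    if leaf_area >= thresholds.leaf_min and substrate_area >= thresholds.substrate_min:
        return ScreeningResult(HEALTHY, leaf_area, substrate_area)
    return ScreeningResult(UNHEALTHY, leaf_area, substrate_area)


def screen_image(
    image: np.ndarray,
    thresholds: ScreeningThresholds = ScreeningThresholds(),
    config: DenoiseConfig = DenoiseConfig(),
) -> ScreeningResult:
    """Measure areas on an image and classify in one step."""
    leaf, substrate = measure_areas(image, config)
    return classify_physical(leaf, substrate, thresholds)
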