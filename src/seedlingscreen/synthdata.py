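"""Synthetic side-view seedling frames with ground-truth labels and areas.

Each render emulates the capture geometry the pipeline expects: a light
neutral (gray) background with per-pixel brightness jitter, a dark
substrate plug drawn as a rectangle at the bottom centre, and a fan of
green elliptical leaf blobs above it. The blob count is an explicit proxy
for the "three leaves and one heart" maturity criterion; unhealthy
seedlings are rendered either with wilted (flattened, undersized) foliage
or with substrate loss (an undersized plug), and absent seedlings as
blank frames.

Ground truth is exact: the record stores the rendered leaf/substrate
pixel counts from the drawing masks, and the label follows the area rule
(healthy iff leaf ≥ 2,300 px and substrate ≥ 1,300 px and ≥ 3 blobs;
none iff the frame is empty; otherwise unhealthy).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .extraction import write_image
from .cnn_screen.data import split_dataset, write_manifest

__all__ = ["SynthParams", "SynthRecord", "render_seedling", "generate_dataset"]

LEAF_MIN = 2300
SUBSTRATE_MIN = 1300
MIN_BLOBS = 3

# Upright vs wilted leaf shape: vertical/horizontal semi-axis ratio.
UPRIGHT_RATIO = 1.6
WILT_RATIO = 0.45

BACKGROUND_RGB = (210, 210, 205)
SUBSTRATE_RGB = (32, 26, 20)
LEAF_RGB = (48, 150, 60)


@dataclass(frozen=True)
class SynthParams:
    """Generator knobs for one rendered frame (areas in pixels)."""

    target_leaf_area: int = 3000
    target_substrate_area: int = 1500
    leaf_blob_count: int = 3
    frame_size: tuple[int, int] = (640, 480)  # (width, height)
    wilt: bool = False
    background_rgb: tuple[int, int, int] = BACKGROUND_RGB
    background_jitter: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.leaf_blob_count < 0:
            raise ValueError("blob count must be nonnegative")
        if self.target_leaf_area < 0 or self.target_substrate_area < 0:
            raise ValueError("target areas must be nonnegative")


@dataclass(frozen=True)
class SynthRecord:
    """Ground truth for one render."""

    label: str
    leaf_area: int
    substrate_area: int
    blob_count: int
    wilt: bool
    path: str = ""


def _rule_label(leaf_area: int, substrate_area: int, blob_count: int) -> str:
    if blob_count == 0 and leaf_area == 0 and substrate_area == 0:
        return "none"
    if leaf_area >= LEAF_MIN and substrate_area >= SUBSTRATE_MIN and blob_count >= MIN_BLOBS:
        return "healthy"
    return "unhealthy"


def _ellipse_mask(shape: tuple[int, int], cx: float, cy: float, ax: float, ay: float) -> np.ndarray:
    h, w = shape
    y0, y1 = max(0, int(cy - ay) - 1), min(h, int(cy + ay) + 2)
    x0, x1 = max(0, int(cx - ax) - 1), min(w, int(cx + ax) + 2)
    mask = np.zeros(shape, dtype=bool)
    if y0 >= y1 or x0 >= x1:
        return mask
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask[y0:y1, x0:x1] = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0
    return mask


def render_seedling(
    params: SynthParams, return_masks: bool = False
):
    """Render one frame; returns (image, record[, leaf_mask, substrate_mask]).

    Rendered leaf and substrate areas land within 5% of their targets
    (rectangles are exact; ellipses get one corrective rescale after pixel
    counting). Raises ``ValueError`` when the requested areas cannot fit
    the frame.
    """
    width, height = params.frame_size
    rng = np.random.default_rng(params.seed)

    # light neutral background: one jitter value per pixel keeps it gray
    base = np.array(params.background_rgb, dtype=np.int32)
    jitter = rng.integers(
        -params.background_jitter, params.background_jitter + 1, size=(height, width, 1)
    )
    image = np.clip(base[None, None, :] + jitter, 0, 255).astype(np.uint8)

    substrate_mask = np.zeros((height, width), dtype=bool)
    leaf_mask = np.zeros((height, width), dtype=bool)

    # substrate plug: bottom-centre rectangle, ~2:1 wide aspect, exact area
    if params.target_substrate_area > 0:
        sub_h = max(1, round(math.sqrt(params.target_substrate_area / 2.0)))
        sub_w = max(1, round(params.target_substrate_area / sub_h))
        if sub_w > width or sub_h > height:
            raise ValueError("substrate area does not fit the frame")
        x0 = (width - sub_w) // 2
        substrate_mask[height - sub_h :, x0 : x0 + sub_w] = True

    # leaf blobs: a horizontal fan of disjoint ellipses above the plug
    if params.leaf_blob_count > 0 and params.target_leaf_area > 0:
        per_blob = params.target_leaf_area / params.leaf_blob_count
        ratio = WILT_RATIO if params.wilt else UPRIGHT_RATIO
        ax = math.sqrt(per_blob / (math.pi * ratio))
        ay = ratio * ax
        spacing = 2.0 * ax + 4.0
        span = spacing * (params.leaf_blob_count - 1)
        if span + 2 * ax >= width or 2 * ay >= height:
            raise ValueError("leaf area does not fit the frame")
        sub_top = height - (substrate_mask.any(axis=1).sum())
        cy = sub_top - ay - 12.0
        if cy - ay < 0:
            raise ValueError("leaf area does not fit above the substrate")
        cx0 = width / 2.0 - span / 2.0
        scale = 1.0
        for _ in range(3):  # corrective rescale toward the target pixel count
            trial = np.zeros((height, width), dtype=bool)
            for b in range(params.leaf_blob_count):
                trial |= _ellipse_mask(
                    (height, width), cx0 + b * spacing, cy, ax * scale, ay * scale
                )
            count = int(trial.sum())
            if abs(count - params.target_leaf_area) <= 0.02 * params.target_leaf_area:
                break
            scale *= math.sqrt(params.target_leaf_area / max(count, 1))
        leaf_mask = trial

    sub_color = np.array(SUBSTRATE_RGB, dtype=np.int32)
    leaf_color = np.array(LEAF_RGB, dtype=np.int32)
    if substrate_mask.any():
        n = int(substrate_mask.sum())
        image[substrate_mask] = np.clip(
            sub_color[None, :] + rng.integers(-5, 6, size=(n, 3)), 0, 45
        ).astype(np.uint8)
    if leaf_mask.any():
        n = int(leaf_mask.sum())
        image[leaf_mask] = np.clip(
            leaf_color[None, :] + rng.integers(-8, 9, size=(n, 3)), 0, 255
        ).astype(np.uint8)

    leaf_area = int(leaf_mask.sum())
    substrate_area = int(substrate_mask.sum())
    blob_count = params.leaf_blob_count if leaf_area > 0 else 0
    record = SynthRecord(
        label=_rule_label(leaf_area, substrate_area, blob_count),
        leaf_area=leaf_area,
        substrate_area=substrate_area,
        blob_count=blob_count,
        wilt=params.wilt,
    )
    if return_masks:
        return image, record, leaf_mask, substrate_mask
    return image, record


def _sample_params(label: str, rng: np.random.Generator, frame_size, seed: int) -> SynthParams:
    """Class-conditional parameter draws, margin-separated from the
    screening thresholds by at least 20% on the deciding criterion."""
    if label == "none":
        return SynthParams(0, 0, 0, frame_size=frame_size, seed=seed)
    if label == "healthy":
        return SynthParams(
            target_leaf_area=int(rng.integers(2760, 5501)),
            target_substrate_area=int(rng.integers(1560, 3001)),
            leaf_blob_count=int(rng.integers(3, 6)),
            frame_size=frame_size,
            wilt=False,
            seed=seed,
        )
    # unhealthy: wilt (undersized, flattened foliage) or substrate loss
    if rng.random() < 0.5:
        return SynthParams(
            target_leaf_area=int(rng.integers(900, 1841)),
            target_substrate_area=int(rng.integers(1560, 3001)),
            leaf_blob_count=3,
            frame_size=frame_size,
            wilt=True,
            seed=seed,
        )
    return SynthParams(
        target_leaf_area=int(rng.integers(2760, 5501)),
        target_substrate_area=int(rng.integers(400, 1041)),
        leaf_blob_count=3,
        frame_size=frame_size,
        wilt=False,
        seed=seed,
    )


def generate_dataset(
    n_per_class: int,
    seed: int,
    out_dir: str | Path,
    frame_size: tuple[int, int] = (640, 480),
    split: bool = True,
) -> pd.DataFrame:
    """Write ``3 × n_per_class`` PNG frames plus manifest and ground truth.

    Produces ``manifest.csv`` (path,label[,split]) and
    ``ground_truth.json`` under ``out_dir``; byte-identical outputs for
    identical seeds. Returns the manifest as a DataFrame.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    records = []
    for label in ("healthy", "unhealthy", "none"):
        for i in range(n_per_class):
            child_seed = int(rng.integers(0, 2**31 - 1))
            params = _sample_params(label, rng, frame_size, child_seed)
            image, record = render_seedling(params)
            if record.label != label:
                raise RuntimeError(
                    f"generator drew parameters whose rule label {record.label!r} "
                    f"contradicts the requested class {label!r}"
                )
            name = f"{label}_{i:04d}.png"
            write_image(image, str(out_dir / name))
            rows.append({"path": name, "label": label})
            records.append({**asdict(record), "path": name, "params_seed": child_seed})
    manifest = pd.DataFrame(rows)
    if split:
        manifest = split_dataset(manifest, seed=seed)
    write_manifest(manifest, str(out_dir / "manifest.csv"))
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(records, fh, indent=1)
    return manifest
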