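"""Frame-level screening: crop → background removal → classify per station.

A captured frame holds several seedlings side by side (six on the
reference rig). The pipeline cuts the frame into station crops, removes
the background, and classifies each crop with either the rule-based
physical screen or a trained network; each station gets a verdict whose
``remove_flag`` tells the transplanting actuator whether to discard that
seedling. Both methods consume the identical preprocessed crops.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .cnn_screen.layers import Module
from .cnn_screen.train import predict
from .extraction import crop_frame, extract_seedling, resize_for_net
from .physical_screen import (
    DenoiseConfig,
    ScreeningThresholds,
    classify_physical,
    measure_areas,
)

__all__ = ["StationVerdict", "preprocess_frame", "screen_frame", "write_verdict_log"]

DEFAULT_STATIONS = 6


@dataclass(frozen=True)
class StationVerdict:
    """Outcome for one station (1-based, left to right)."""

    station: int
    label: str
    method: str
    remove_flag: bool
    leaf_area: int | None = None
    substrate_area: int | None = None
    scores: tuple[float, float, float] | None = None


def preprocess_frame(frame: np.ndarray, stations: int = DEFAULT_STATIONS) -> list[np.ndarray]:
    """Shared preprocessing: station crops with the background removed."""
    return [extract_seedling(crop.image) for crop in crop_frame(frame, stations)]


def screen_frame(
    frame: np.ndarray,
    method: str = "physical",
    model: Module | None = None,
    stations: int = DEFAULT_STATIONS,
    thresholds: ScreeningThresholds = ScreeningThresholds(),
    denoise_config: DenoiseConfig = DenoiseConfig(),
) -> list[StationVerdict]:
    """One verdict per station, in left-to-right order.

    ``method`` is "physical" (area rule) or "cnn" (requires ``model``).
    A station is flagged for removal whenever its label is not healthy.
    """
    if method not in ("physical", "cnn"):
        raise ValueError(f"unknown method {method!r}")
    if method == "cnn" and model is None:
        raise ValueError("method 'cnn' requires a trained model")
    verdicts = []
    for i, extracted in enumerate(preprocess_frame(frame, stations), start=1):
        if method == "physical":
            leaf, substrate = measure_areas(extracted, denoise_config)
            result = classify_physical(leaf, substrate, thresholds)
            verdicts.append(
                StationVerdict(
                    station=i,
                    label=result.label,
                    method=method,
                    remove_flag=result.label != "healthy",
                    leaf_area=result.leaf_area,
                    substrate_area=result.substrate_area,
                )
            )
        else:
            label, probs = predict(model, resize_for_net(extracted))
            verdicts.append(
                StationVerdict(
                    station=i,
                    label=label,
                    method=method,
                    remove_flag=label != "healthy",
                    scores=tuple(float(p) for p in probs),
                )
            )
    return verdicts


def write_verdict_log(
    verdicts: list[StationVerdict], path: str | Path, row_index: int = 0
) -> None:
    """Append verdicts as JSON lines; carries station/row counters so a
    downstream replanting step can reconstruct trough positions."""
    with open(path, "a") as fh:
        for v in verdicts:
            entry = asdict(v)
            entry["row"] = row_index
            fh.write(json.dumps(entry) + "\n")
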