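"""Per-frame hue extraction: one 8-bit hue value per well per image.

Pixels inside each well's ROI disc are averaged in RGB space and the mean
color is converted to hue.  Averaging in RGB rather than averaging per-pixel
hues avoids the ill-defined circular mean near the red wrap, exactly where
phenol red operates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .color import rgb_to_hue8
from .plate import WellID, WellROI

__all__ = ["Frame", "PlateFrameHues", "extract_frame", "extract_well_hue"]


@dataclass
class Frame:
    """One acquisition: an RGB raster plus its ordinal and time stamp.

    ``index`` starts at 1 (matching the Image_1, Image_2, ... file naming);
    ``time_min`` is minutes since run start, so frame 1 is t = 0.
    """

    raster: np.ndarray
    index: int
    time_min: float

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster)
        if self.raster.ndim != 3 or self.raster.shape[2] != 3:
            raise ValueError("frame raster must have shape (height, width, 3)")
        if self.index < 1:
            raise ValueError("frame index starts at 1")


@dataclass
class PlateFrameHues:
    """Hue of every well in one frame."""

    index: int
    hues: dict[WellID, float] = field(default_factory=dict)


def _disc_mask(shape: tuple[int, int], roi: WellROI) -> np.ndarray:
    ys, xs = np.ogrid[: shape[0], : shape[1]]
    return (xs - roi.center_x) ** 2 + (ys - roi.center_y) ** 2 <= roi.radius**2


def extract_well_hue(frame: Frame, roi: WellROI) -> float:
    """Mean-RGB hue of one well's disc in one frame.

    Raises ValueError (naming the well) if the disc extends outside the
    raster.
    """
    h, w = frame.raster.shape[:2]
    if (
        roi.center_x - roi.radius < 0
        or roi.center_y - roi.radius < 0
        or roi.center_x + roi.radius > w
        or roi.center_y + roi.radius > h
    ):
        raise ValueError(f"ROI for well {roi.well} lies outside the {w}x{h} raster")
    mask = _disc_mask((h, w), roi)
    mean_rgb = frame.raster[mask].reshape(-1, 3).mean(axis=0)
    return rgb_to_hue8(mean_rgb)


def extract_frame(frame: Frame, rois: list[WellROI]) -> PlateFrameHues:
    """One hue per well; independent of the ROI processing order."""
    out = PlateFrameHues(index=frame.index)
    for roi in rois:
        out.hues[roi.well] = extract_well_hue(frame, roi)
    return out
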