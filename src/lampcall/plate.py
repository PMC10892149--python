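"""Plate geometry: the 12x8 tube array and its image-space regions of interest.

The instrument images a rigidly mounted 96-well (12 columns x 8 rows) plate
from a fixed camera, so well positions are modeled as a parametric grid
rather than detected per frame.  An optional centroid refinement absorbs
small registration drift.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PlateLayout",
    "WellID",
    "WellROI",
    "all_rois",
    "refine_rois",
    "standard_layout",
]

log = logging.getLogger(__name__)

#: Default ROI radius as a fraction of the smaller center-to-center pitch.
#: Kept well under 1/4 so a disc fits inside the centroid search window.
DEFAULT_RADIUS_FRACTION = 0.20


@dataclass(frozen=True, order=True)
class WellID:
    """A well address: row letter (A-H) and 1-based column (1-12)."""

    row: str
    col: int

    def __post_init__(self) -> None:
        if len(self.row) != 1 or self.row not in string.ascii_uppercase:
            raise ValueError(f"row must be a single letter A-Z, got {self.row!r}")
        if self.col < 1:
            raise ValueError(f"column must be >= 1, got {self.col}")

    def __str__(self) -> str:
        return f"{self.row}{self.col}"

    @classmethod
    def parse(cls, text: str) -> "WellID":
        text = text.strip()
        if len(text) < 2 or not text[0].isalpha():
            raise ValueError(f"cannot parse well id {text!r}")
        return cls(row=text[0].upper(), col=int(text[1:]))

    def to_index(self, n_cols: int = 12) -> int:
        """Row-major index: A1 -> 0, A12 -> 11, B1 -> 12, ... H12 -> 95."""
        return (ord(self.row) - ord("A")) * n_cols + (self.col - 1)

    @classmethod
    def from_index(cls, index: int, n_cols: int = 12) -> "WellID":
        row, col = divmod(index, n_cols)
        return cls(row=chr(ord("A") + row), col=col + 1)


@dataclass(frozen=True)
class WellROI:
    """A circular region of interest for one well, in pixel coordinates."""

    well: WellID
    center_x: float
    center_y: float
    radius: float


@dataclass(frozen=True)
class PlateLayout:
    """Geometry of the tube array within the camera frame.

    The grid is defined by the pixel center of well A1 (``origin_x``,
    ``origin_y``), the center-to-center pitches, and a common ROI disc
    radius.  Invariants: all discs lie within the image and adjacent
    discs do not overlap (``2 * roi_radius < min(pitch)``).
    """

    n_rows: int
    n_cols: int
    image_width: int
    image_height: int
    origin_x: float
    origin_y: float
    pitch_x: float
    pitch_y: float
    roi_radius: float

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("plate must have at least one row and column")
        if self.roi_radius <= 0:
            raise ValueError("roi_radius must be positive")
        if 2 * self.roi_radius >= min(self.pitch_x, self.pitch_y):
            raise ValueError(
                "ROIs overlap: 2*roi_radius must be smaller than the pitch "
                f"(radius {self.roi_radius}, pitch {self.pitch_x}x{self.pitch_y})"
            )
        last_x = self.origin_x + (self.n_cols - 1) * self.pitch_x
        last_y = self.origin_y + (self.n_rows - 1) * self.pitch_y
        if (
            self.origin_x - self.roi_radius < 0
            or self.origin_y - self.roi_radius < 0
            or last_x + self.roi_radius > self.image_width
            or last_y + self.roi_radius > self.image_height
        ):
            raise ValueError("ROI discs extend beyond the image bounds")

    @property
    def n_wells(self) -> int:
        return self.n_rows * self.n_cols

    def well_ids(self) -> list[WellID]:
        """All wells in row-major order (A1 ... A12, B1 ... H12)."""
        return [WellID.from_index(i, self.n_cols) for i in range(self.n_wells)]

    def to_config(self) -> dict[str, str]:
        return {
            f"layout_{k}": str(getattr(self, k))
            for k in (
                "n_rows", "n_cols", "image_width", "image_height",
                "origin_x", "origin_y", "pitch_x", "pitch_y", "roi_radius",
            )
        }

    @classmethod
    def from_config(cls, config: dict[str, str]) -> "PlateLayout":
        kw = {}
        for k in ("n_rows", "n_cols", "image_width", "image_height"):
            kw[k] = int(float(config[f"layout_{k}"]))
        for k in ("origin_x", "origin_y", "pitch_x", "pitch_y", "roi_radius"):
            kw[k] = float(config[f"layout_{k}"])
        return cls(**kw)


def standard_layout(
    image_width: int,
    image_height: int,
    margin_fraction: float = 0.05,
    n_rows: int = 8,
    n_cols: int = 12,
    radius_fraction: float = DEFAULT_RADIUS_FRACTION,
) -> PlateLayout:
    """Evenly spaced grid centered in the image with fractional margins.

    Each well occupies one cell of the inner region left after removing
    ``margin_fraction`` of each dimension on every side; ROI radius is
    ``radius_fraction`` of the smaller pitch.
    """
    if not 0 <= margin_fraction < 0.5:
        raise ValueError("margin_fraction must lie in [0, 0.5)")
    inner_w = image_width * (1 - 2 * margin_fraction)
    inner_h = image_height * (1 - 2 * margin_fraction)
    pitch_x = inner_w / n_cols
    pitch_y = inner_h / n_rows
    radius = radius_fraction * min(pitch_x, pitch_y)
    if radius < 1.0:
        raise ValueError(
            f"image {image_width}x{image_height} too small: ROI radius would be "
            f"{radius:.2f} px (< 1 px); non-overlapping discs need a larger image"
        )
    return PlateLayout(
        n_rows=n_rows,
        n_cols=n_cols,
        image_width=image_width,
        image_height=image_height,
        origin_x=image_width * margin_fraction + pitch_x / 2,
        origin_y=image_height * margin_fraction + pitch_y / 2,
        pitch_x=pitch_x,
        pitch_y=pitch_y,
        roi_radius=radius,
    )


def all_rois(layout: PlateLayout) -> list[WellROI]:
    """ROIs for every well in deterministic row-major order."""
    rois = []
    for well in layout.well_ids():
        r = ord(well.row) - ord("A")
        c = well.col - 1
        rois.append(
            WellROI(
                well=well,
                center_x=layout.origin_x + c * layout.pitch_x,
                center_y=layout.origin_y + r * layout.pitch_y,
                radius=layout.roi_radius,
            )
        )
    return rois


def _window_centroid(
    lum: np.ndarray, cx: float, cy: float, half: float
) -> tuple[float, float] | None:
    """Centroid of |luminance - window median| within a square window.

    Returns None when the window is flat (no contrast to localize on).
    """
    h, w = lum.shape
    x0 = max(0, int(round(cx - half)))
    x1 = min(w, int(round(cx + half)) + 1)
    y0 = max(0, int(round(cy - half)))
    y1 = min(h, int(round(cy + half)) + 1)
    win = lum[y0:y1, x0:x1]
    weight = np.abs(win - np.median(win))
    total = weight.sum()
    if total < 1e-9:
        return None
    ys, xs = np.mgrid[y0:y1, x0:x1]
    return float((weight * xs).sum() / total), float((weight * ys).sum() / total)


def refine_rois(
    calibration_frame: np.ndarray,
    layout: PlateLayout,
    rois: list[WellROI] | None = None,
    max_iter: int = 8,
) -> list[WellROI]:
    """Snap nominal ROI centers onto a calibration frame of a loaded plate.

    Each center is moved to the intensity centroid within a search window
    of half-width pitch/4, iterated to convergence; the total displacement
    from the nominal center is clamped to pitch/4, so gross mislocation is
    impossible.  A contrast-free (flat) window keeps the nominal center
    and logs a warning.  Idempotent: refining its own output is a no-op.
    """
    raster = np.asarray(calibration_frame, dtype=float)
    if raster.ndim == 3:
        lum = raster.mean(axis=2)
    else:
        lum = raster
    half = min(layout.pitch_x, layout.pitch_y) / 4.0
    refined = []
    for roi in (rois if rois is not None else all_rois(layout)):
        cx, cy = roi.center_x, roi.center_y
        degenerate = False
        for _ in range(max_iter):
            cent = _window_centroid(lum, cx, cy, half)
            if cent is None:
                degenerate = True
                break
            nx, ny = cent
            # clamp total displacement from the nominal center
            dx = np.clip(nx - roi.center_x, -half, half)
            dy = np.clip(ny - roi.center_y, -half, half)
            nx, ny = roi.center_x + dx, roi.center_y + dy
            if abs(nx - cx) < 0.5 and abs(ny - cy) < 0.5:
                cx, cy = nx, ny
                break
            cx, cy = nx, ny
        if degenerate:
            log.warning("well %s: flat search window, keeping nominal center", roi.well)
            refined.append(roi)
        else:
            refined.append(
                WellROI(
                    well=roi.well,
                    center_x=float(round(cx)),
                    center_y=float(round(cy)),
                    radius=roi.radius,
                )
            )
    return refined
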