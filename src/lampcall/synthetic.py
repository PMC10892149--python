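"""Ground-truthed synthetic runs: per-well color trajectories and rendered
plate frames.

The generator emulates what the analysis layer assumes about a colorimetric
LAMP run: positive wells interpolate sigmoidally between the dye's negative
and positive endpoint colors, negatives stay flat, per-channel Gaussian
noise jitters pixel intensities, and a smooth illumination field (linear
gradient plus vignette) emulates imperfect lighting.  The transition is a
logistic in RGB space — physical color mixing is closer to linear in
reflectance than in hue, and for phenol red the resulting hue path then
crosses the red wrap naturally, exercising the circular arithmetic.

Defaults mirror the standard assay: 60-min run, 60-s interval, 96 wells,
phenol red, with sharp transitions (tau = 0.5 min, so 10-90% of the color
change happens within ~2.2 min, matching the step-like curves real
amplification produces).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .color import DyeProfile
from .extraction import Frame
from .plate import PlateLayout, WellID, WellROI, all_rois, standard_layout
from .run_io import PARAMS_NAME, RunConfig, write_params

__all__ = [
    "IlluminationModel",
    "NoiseModel",
    "WellTruth",
    "generate_run",
    "random_truths",
    "read_truths",
    "render_frame",
    "trajectory",
    "write_truths",
]

TRUTH_CSV_NAME = "truth.csv"

#: Default matte background color (slightly off-white, achromatic).
BACKGROUND_RGB = (235.0, 235.0, 235.0)

DEFAULT_TAU_MIN = 0.5


@dataclass(frozen=True)
class WellTruth:
    """Ground truth for one well: amplification state and transition timing.

    ``t_amp_min`` is the transition midpoint (the logistic's center) and
    ``tau_min`` its time scale; both are ignored for negative wells.
    """

    well: WellID
    is_positive: bool
    t_amp_min: float = 20.0
    tau_min: float = DEFAULT_TAU_MIN

    def __post_init__(self) -> None:
        if self.tau_min <= 0:
            raise ValueError("tau_min must be positive")


@dataclass(frozen=True)
class NoiseModel:
    """Independent per-channel Gaussian pixel noise, in intensity units."""

    rgb_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rgb_sd < 0:
            raise ValueError("rgb_sd must be non-negative")


@dataclass(frozen=True)
class IlluminationModel:
    """Smooth multiplicative lighting field: a left-to-right linear
    gradient of fractional amplitude plus corner vignetting."""

    gradient_amplitude: float = 0.0
    vignette_strength: float = 0.0


def _logistic(t: np.ndarray, t0: float, tau: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(t - t0) / tau))


def trajectory(
    dye: DyeProfile,
    truth: WellTruth,
    times: Sequence[float],
    noise: NoiseModel = NoiseModel(rgb_sd=0.0),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-frame well color, shape (n_times, 3), float in [0, 255].

    Positive wells follow c(t) = negative + s(t) * (positive - negative)
    per channel with s the logistic centered at ``t_amp_min``; negative
    wells have s = 0 throughout.  Gaussian noise (sd ``rgb_sd``) is added
    per channel per time point and the result clipped to [0, 255].
    """
    t = np.asarray(times, dtype=float)
    neg = np.asarray(dye.negative_color, dtype=float)
    pos = np.asarray(dye.positive_color, dtype=float)
    if truth.is_positive:
        s = _logistic(t, truth.t_amp_min, truth.tau_min)[:, None]
    else:
        s = np.zeros((t.size, 1))
    colors = neg + s * (pos - neg)
    if noise.rgb_sd > 0:
        if rng is None:
            rng = np.random.default_rng(noise.seed)
        colors = colors + rng.normal(0.0, noise.rgb_sd, colors.shape)
    return np.clip(colors, 0.0, 255.0)


def _illumination_field(shape: tuple[int, int], model: IlluminationModel) -> np.ndarray:
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    fx = xs / max(w - 1, 1) - 0.5
    field = 1.0 + model.gradient_amplitude * fx
    if model.vignette_strength:
        r2 = fx**2 + (ys / max(h - 1, 1) - 0.5) ** 2
        field = field * (1.0 - model.vignette_strength * r2 / 0.5)
    return field


def render_frame(
    layout: PlateLayout,
    well_colors: Mapping[WellID, Sequence[float]],
    illumination: IlluminationModel = IlluminationModel(),
    noise: NoiseModel = NoiseModel(rgb_sd=0.0),
    frame_index: int = 1,
    time_min: float | None = None,
    background: Sequence[float] = BACKGROUND_RGB,
) -> Frame:
    """Render one plate image: colored ROI discs on a matte background.

    The illumination field multiplies all channels (so it is hue-neutral
    up to clipping/quantization); pixel noise is then added.  Rendering is
    deterministic given the noise seed and frame index.
    """
    h, w = layout.image_height, layout.image_width
    img = np.empty((h, w, 3), dtype=float)
    img[:] = np.asarray(background, dtype=float)
    ys, xs = np.ogrid[0:h, 0:w]
    for roi in all_rois(layout):
        if roi.well not in well_colors:
            continue
        mask = (xs - roi.center_x) ** 2 + (ys - roi.center_y) ** 2 <= roi.radius**2
        img[mask] = np.asarray(well_colors[roi.well], dtype=float)
    if illumination.gradient_amplitude or illumination.vignette_strength:
        img = img * _illumination_field((h, w), illumination)[:, :, None]
    if noise.rgb_sd > 0:
        rng = np.random.default_rng([noise.seed, frame_index])
        img = img + rng.normal(0.0, noise.rgb_sd, img.shape)
    raster = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return Frame(raster=raster, index=frame_index,
                 time_min=(frame_index - 1) if time_min is None else time_min)


def frames_for_run(
    config: RunConfig,
    truths: Sequence[WellTruth],
    dye: DyeProfile,
    layout: PlateLayout,
    noise: NoiseModel = NoiseModel(),
    illumination: IlluminationModel = IlluminationModel(),
):
    """Yield the rendered Frame sequence for a whole synthetic run.

    Well-color noise (the in-tube color jitter) and pixel noise share
    ``noise.rgb_sd`` but use distinct seed streams, so the run is fully
    reproducible from ``noise.seed``.
    """
    times = config.frame_times()
    color_rng = np.random.default_rng([noise.seed, 7919])
    trajs = {
        t.well: trajectory(dye, t, times, noise=noise, rng=color_rng)
        for t in truths
    }
    for i, t in enumerate(times, start=1):
        colors = {w: traj[i - 1] for w, traj in trajs.items()}
        yield render_frame(layout, colors, illumination=illumination,
                           noise=noise, frame_index=i, time_min=float(t))


def random_truths(
    config: RunConfig,
    n_positive: int,
    rng: np.random.Generator | int | None = None,
    tau_min: float = DEFAULT_TAU_MIN,
) -> list[WellTruth]:
    """Random positive set with transition midpoints uniform between 30%
    and 75% of the run, safely after the baseline window."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    wells = [WellID.from_index(i) for i in range(96)]
    positive = set(rng.choice(96, size=n_positive, replace=False).tolist())
    lo = max(0.30 * config.total_assay_min, 4.0)
    hi = max(0.75 * config.total_assay_min, lo)
    return [
        WellTruth(
            well=w,
            is_positive=(i in positive),
            t_amp_min=float(rng.uniform(lo, hi)),
            tau_min=tau_min,
        )
        for i, w in enumerate(wells)
    ]


def write_truths(path: Path, truths: Sequence[WellTruth]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["well", "is_positive", "t_amp_min", "tau_min"])
        for t in truths:
            writer.writerow([str(t.well), int(t.is_positive), t.t_amp_min, t.tau_min])


def read_truths(path: Path) -> list[WellTruth]:
    truths = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            truths.append(
                WellTruth(
                    well=WellID.parse(row["well"]),
                    is_positive=bool(int(row["is_positive"])),
                    t_amp_min=float(row["t_amp_min"]),
                    tau_min=float(row["tau_min"]),
                )
            )
    return truths


def generate_run(
    config: RunConfig,
    truths: Sequence[WellTruth],
    dye: DyeProfile,
    noise: NoiseModel = NoiseModel(),
    illumination: IlluminationModel = IlluminationModel(),
    path: Path | str | None = None,
    layout: PlateLayout | None = None,
    image_size: tuple[int, int] = (480, 320),
    image_format: str = "png",
    overwrite: bool = False,
):
    """Write a complete synthetic run folder plus its ground-truth CSV.

    The folder contains a params file and Image_1..Image_N in run-folder
    dialect; frames default to lossless PNG so generated fixtures are
    byte-reproducible from the seed.  Returns the layout used (and the
    folder path when one was written).
    """
    import imageio.v3 as iio

    if layout is None:
        layout = standard_layout(*image_size)
    if path is None:
        raise ValueError("generate_run requires an output path")
    folder = Path(path)
    if folder.exists():
        if not overwrite:
            raise FileExistsError(f"{folder} exists; pass overwrite=True")
        import shutil

        shutil.rmtree(folder)
    folder.mkdir(parents=True)
    write_params(folder / PARAMS_NAME, config, layout)
    for frame in frames_for_run(config, truths, dye, layout, noise, illumination):
        iio.imwrite(folder / f"Image_{frame.index}.{image_format}", frame.raster)
    write_truths(folder / TRUTH_CSV_NAME, truths)
    return folder, layout
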