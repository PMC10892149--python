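"""Run-folder I/O and the frame-by-frame processing pipeline.

A run folder mirrors the instrument's output: a key=value params ``.txt``
written at run initiation, one image per acquisition named ``Image_1``,
``Image_2``, ... at the configured interval (default 60 s), a raw-hue CSV
and an averaged-hue CSV (rows = frames, columns = wells A1...H12), and a
calls CSV.  Processing is streaming-capable: frames can be fed one at a
time as they are acquired, and the final state is identical to batch
processing of the same frames.
"""

from __future__ import annotations

import logging
import shutil
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import imageio.v3 as iio
import numpy as np

from .calling import (
    DEFAULT_BASELINE_WINDOW,
    DEFAULT_MIN_DELTA,
    CallResult,
    HueSeries,
    baseline_stats,
    call_well,
)
from .color import DyeProfile, builtin_dye
from .extraction import Frame, extract_frame
from .plate import PlateLayout, WellID, all_rois, standard_layout

__all__ = [
    "RunConfig",
    "RunRecord",
    "RunProcessor",
    "analyze_folder",
    "discover_frames",
    "load_frames",
    "process_run",
    "read_run_folder",
    "write_run_folder",
]

log = logging.getLogger(__name__)

PARAMS_NAME = "params.txt"
RAW_CSV_NAME = "raw_hue.csv"
AVG_CSV_NAME = "averaged_hue.csv"
CALLS_CSV_NAME = "calls.csv"

_CONFIG_FIELDS = (
    ("run_name", str),
    ("total_assay_min", float),
    ("interval_s", float),
    ("assay_temperature_C", float),
    ("n_reactions", int),
    ("dye", str),
)


@dataclass(frozen=True)
class RunConfig:
    """User-set run parameters: total time, acquisition interval,
    temperature, reaction count and dye."""

    run_name: str = "run"
    total_assay_min: float = 60.0
    interval_s: float = 60.0
    assay_temperature_C: float = 65.0
    n_reactions: int = 96
    dye: str = "PR"

    def __post_init__(self) -> None:
        if self.interval_s <= 0 or self.total_assay_min <= 0:
            raise ValueError("interval and total time must be positive")
        total_s = self.total_assay_min * 60.0
        n_intervals = total_s / self.interval_s
        if abs(n_intervals - round(n_intervals)) > 1e-9:
            raise ValueError(
                f"interval {self.interval_s}s does not divide the total assay "
                f"time of {self.total_assay_min} min evenly"
            )
        if not 1 <= self.n_reactions <= 96:
            raise ValueError("n_reactions must lie in 1..96")

    @property
    def n_frames(self) -> int:
        """Frames per run, including the frame at t = 0."""
        return int(round(self.total_assay_min * 60.0 / self.interval_s)) + 1

    def frame_times(self) -> np.ndarray:
        """Acquisition times in minutes: 0, interval, 2*interval, ..."""
        return np.arange(self.n_frames) * (self.interval_s / 60.0)

    def to_params(self) -> dict[str, str]:
        return {name: str(getattr(self, name)) for name, _ in _CONFIG_FIELDS}

    @classmethod
    def from_params(cls, params: dict[str, str]) -> "RunConfig":
        kw = {}
        for name, typ in _CONFIG_FIELDS:
            if name in params:
                kw[name] = typ(params[name])
        return cls(**kw)


@dataclass
class RunRecord:
    """A complete run: parameters, geometry, frame references, per-well
    series and calls, and the output-file manifest."""

    config: RunConfig
    layout: PlateLayout
    frames: list  # Frame objects or Path references to image files
    series: dict[WellID, HueSeries]
    calls: dict[WellID, CallResult]
    manifest: list[str] = field(default_factory=list)
    call_history: list[frozenset] = field(default_factory=list)


def write_params(path: Path, config: RunConfig, layout: PlateLayout | None = None) -> None:
    lines = [f"{k}={v}" for k, v in config.to_params().items()]
    if layout is not None:
        lines += [f"{k}={v}" for k, v in layout.to_config().items()]
    path.write_text("\n".join(lines) + "\n")


def read_params(path: Path) -> tuple[RunConfig, PlateLayout | None, dict[str, str]]:
    """Parse a key=value params file; unknown keys are kept and warned about."""
    params: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
        key, _, value = line.partition("=")
        params[key.strip()] = value.strip()
    known = {name for name, _ in _CONFIG_FIELDS}
    layout = None
    if any(k.startswith("layout_") for k in params):
        layout = PlateLayout.from_config(params)
        known |= set(layout.to_config())
    unknown = set(params) - known
    if unknown:
        warnings.warn(f"{path}: ignoring unknown parameter keys {sorted(unknown)}")
    return RunConfig.from_params(params), layout, params


def _csv_header(wells: Sequence[WellID]) -> str:
    return "time_min," + ",".join(str(w) for w in wells)


def _write_hue_csv(path: Path, times: np.ndarray, wells: Sequence[WellID],
                   values: dict[WellID, np.ndarray]) -> None:
    lines = [_csv_header(wells)]
    for i, t in enumerate(times):
        row = [f"{t:.2f}"] + [f"{values[w][i]:.2f}" for w in wells]
        lines.append(",".join(row))
    path.write_text("\n".join(lines) + "\n")


def _read_hue_csv(path: Path) -> tuple[np.ndarray, list[WellID], dict[WellID, np.ndarray]]:
    lines = path.read_text().splitlines()
    header = lines[0].split(",")
    if header[0] != "time_min":
        raise ValueError(f"{path}: first CSV column must be time_min")
    wells = [WellID.parse(h) for h in header[1:]]
    data = np.array([[float(x) for x in line.split(",")] for line in lines[1:]])
    times = data[:, 0]
    return times, wells, {w: data[:, j + 1] for j, w in enumerate(wells)}


def _write_calls_csv(path: Path, wells: Sequence[WellID],
                     calls: dict[WellID, CallResult]) -> None:
    lines = ["well,status,crossing_time_min,threshold"]
    for w in wells:
        c = calls[w]
        cross = "" if c.crossing_time_min is None else f"{c.crossing_time_min:.2f}"
        lines.append(f"{w},{c.status},{cross},{c.threshold_delta:.2f}")
    path.write_text("\n".join(lines) + "\n")


def discover_frames(folder: Path) -> list[Path]:
    """Find Image_<i>.jpg/.png files; indices must run 1..N without gaps."""
    folder = Path(folder)
    found: dict[int, Path] = {}
    for p in folder.iterdir():
        if p.stem.startswith("Image_") and p.suffix.lower() in (".jpg", ".jpeg", ".png"):
            try:
                idx = int(p.stem.split("_", 1)[1])
            except ValueError:
                continue
            found[idx] = p
    if not found:
        raise FileNotFoundError(f"no Image_<index> frames found in {folder}")
    n = max(found)
    missing = sorted(set(range(1, n + 1)) - set(found))
    if missing:
        raise FileNotFoundError(
            f"frame numbering has gaps in {folder}: missing Image_{missing[0]} "
            f"(and {len(missing) - 1} more)" if len(missing) > 1 else
            f"frame numbering has gaps in {folder}: missing Image_{missing[0]}"
        )
    return [found[i] for i in range(1, n + 1)]


def load_frames(folder: Path, interval_s: float) -> Iterator[Frame]:
    """Lazily read frames from a run folder in acquisition order."""
    for i, path in enumerate(discover_frames(Path(folder)), start=1):
        raster = iio.imread(path)
        if raster.ndim == 3 and raster.shape[2] == 4:
            raster = raster[:, :, :3]
        yield Frame(raster=raster, index=i, time_min=(i - 1) * interval_s / 60.0)


class RunProcessor:
    """Incremental per-frame pipeline.

    Feed frames in acquisition order; the processor extracts hues, keeps
    unwrapped per-well series, freezes the baseline threshold once the
    window has closed, and latches positives as they cross.  ``finalize``
    returns a :class:`RunRecord` identical to batch processing.
    """

    def __init__(
        self,
        config: RunConfig,
        layout: PlateLayout,
        dye: DyeProfile | None = None,
        window_minutes: tuple[float, float] = DEFAULT_BASELINE_WINDOW,
        min_delta: float = DEFAULT_MIN_DELTA,
        k_sd: float | None = None,
    ) -> None:
        self.config = config
        self.layout = layout
        self.dye = dye if dye is not None else builtin_dye(config.dye)
        self.window_minutes = window_minutes
        self.min_delta = min_delta
        self.k_sd = k_sd
        self.rois = all_rois(layout)
        self.wells = [r.well for r in self.rois]
        self._times: list[float] = []
        self._raw: dict[WellID, list[float]] = {w: [] for w in self.wells}
        self._positive: dict[WellID, tuple[int, float]] = {}
        self.call_history: list[frozenset] = []
        self._n_fed = 0

    def feed(self, frame: Frame) -> frozenset:
        """Process one frame; returns the current latched positive set."""
        h, w = frame.raster.shape[:2]
        if (w, h) != (self.layout.image_width, self.layout.image_height):
            raise ValueError(
                f"frame {frame.index}: raster {w}x{h} does not match the "
                f"layout's {self.layout.image_width}x{self.layout.image_height}"
            )
        hues = extract_frame(frame, self.rois)
        self._times.append(frame.time_min)
        for well in self.wells:
            self._raw[well].append(hues.hues[well])
        self._n_fed += 1
        self._update_calls(frame.index, frame.time_min)
        positives = frozenset(self._positive)
        self.call_history.append(positives)
        return positives

    def _update_calls(self, index: int, time_min: float) -> None:
        if time_min <= self.window_minutes[1]:
            return  # baseline window still open; no calls yet
        for well in self.wells:
            if well in self._positive:
                continue
            series = HueSeries(well=well, times=np.array(self._times),
                               raw=np.array(self._raw[well]))
            stats = baseline_stats(series, self.window_minutes)
            k = self.dye.k_sd if self.k_sd is None else self.k_sd
            threshold = max(k * stats.sd, self.min_delta)
            deviation = self.dye.direction * (series.smoothed[-1] - stats.mean)
            if deviation > threshold:
                self._positive[well] = (index, time_min)

    def finalize(self) -> RunRecord:
        if self._n_fed != self.config.n_frames:
            raise ValueError(
                f"fed {self._n_fed} frames but the configuration implies "
                f"{self.config.n_frames}"
            )
        times = np.array(self._times)
        series = {
            w: HueSeries(well=w, times=times, raw=np.array(self._raw[w]))
            for w in self.wells
        }
        calls = {
            w: call_well(series[w], self.dye, min_delta=self.min_delta,
                         window_minutes=self.window_minutes, k_sd=self.k_sd)
            for w in self.wells
        }
        return RunRecord(
            config=self.config,
            layout=self.layout,
            frames=[],
            series=series,
            calls=calls,
            call_history=list(self.call_history),
        )


def process_run(
    config: RunConfig,
    frame_source: Iterable[Frame],
    dye: DyeProfile | None = None,
    layout: PlateLayout | None = None,
    window_minutes: tuple[float, float] = DEFAULT_BASELINE_WINDOW,
    min_delta: float = DEFAULT_MIN_DELTA,
    k_sd: float | None = None,
) -> RunRecord:
    """Batch-process an ordered frame sequence into a full RunRecord.

    Equivalent to feeding every frame through a :class:`RunProcessor`;
    streaming and batch runs over the same frames produce identical
    series, calls and CSV output.
    """
    frames = iter(frame_source)
    first = next(frames)
    if layout is None:
        h, w = first.raster.shape[:2]
        layout = standard_layout(w, h)
    proc = RunProcessor(config, layout, dye=dye, window_minutes=window_minutes,
                        min_delta=min_delta, k_sd=k_sd)
    proc.feed(first)
    for frame in frames:
        proc.feed(frame)
    return proc.finalize()


def write_run_folder(record: RunRecord, path, overwrite: bool = False,
                     image_format: str = "jpg") -> list[str]:
    """Write a complete run folder; returns the manifest of file names.

    Contents: ``params.txt`` (key=value echo of every run parameter plus
    the plate layout), ``Image_1``...``Image_N``, the raw-hue and
    averaged-hue CSVs (one row per frame, one column per well, 2 decimal
    places), and the calls CSV.  Refuses to touch an existing folder
    unless ``overwrite`` is set.
    """
    folder = Path(path)
    if folder.exists():
        if not overwrite:
            raise FileExistsError(f"{folder} exists; pass overwrite=True to replace it")
        shutil.rmtree(folder)
    folder.mkdir(parents=True)
    manifest: list[str] = []

    write_params(folder / PARAMS_NAME, record.config, record.layout)
    manifest.append(PARAMS_NAME)

    for i, frame in enumerate(record.frames, start=1):
        name = f"Image_{i}.{image_format}"
        if isinstance(frame, (str, Path)):
            src = Path(frame)
            name = f"Image_{i}{src.suffix}"
            shutil.copyfile(src, folder / name)
        else:
            iio.imwrite(folder / name, np.asarray(frame.raster, dtype=np.uint8))
        manifest.append(name)

    wells = record.layout.well_ids()
    if record.series:
        any_series = next(iter(record.series.values()))
        times = any_series.times
        _write_hue_csv(folder / RAW_CSV_NAME, times, wells,
                       {w: s.raw for w, s in record.series.items()})
        _write_hue_csv(folder / AVG_CSV_NAME, times, wells,
                       {w: s.smoothed for w, s in record.series.items()})
        manifest += [RAW_CSV_NAME, AVG_CSV_NAME]
    if record.calls:
        called = [w for w in wells if w in record.calls]
        _write_calls_csv(folder / CALLS_CSV_NAME, called, record.calls)
        manifest.append(CALLS_CSV_NAME)
    record.manifest = manifest
    return manifest


def read_run_folder(path) -> RunRecord:
    """Reconstruct a RunRecord from a run folder.

    Frames are kept as file references; series are read back from the raw
    CSV when present (nothing is recomputed).  Calls are re-derived from
    the stored series and params only when a calls CSV exists; otherwise
    the record carries empty calls.
    """
    folder = Path(path)
    params_path = folder / PARAMS_NAME
    if not params_path.exists():
        raise FileNotFoundError(f"missing {PARAMS_NAME} in {folder}")
    config, layout, _ = read_params(params_path)
    try:
        frame_paths = discover_frames(folder)
    except FileNotFoundError as err:
        # a data-only folder (CSVs without images) is valid; numbering
        # gaps in an image sequence are not
        if "gaps" in str(err):
            raise
        frame_paths = []
    if layout is None:
        if not frame_paths:
            raise ValueError(f"{folder}: no layout in params and no frames to infer it")
        raster = iio.imread(frame_paths[0])
        layout = standard_layout(raster.shape[1], raster.shape[0])

    series: dict[WellID, HueSeries] = {}
    if (folder / RAW_CSV_NAME).exists():
        times, wells, raw = _read_hue_csv(folder / RAW_CSV_NAME)
        if set(wells) != set(layout.well_ids()):
            raise ValueError(f"{RAW_CSV_NAME}: well columns do not match the layout")
        series = {w: HueSeries(well=w, times=times, raw=raw[w]) for w in wells}

    calls: dict[WellID, CallResult] = {}
    if (folder / CALLS_CSV_NAME).exists() and series:
        dye = builtin_dye(config.dye)
        calls = {w: call_well(s, dye) for w, s in series.items()}

    return RunRecord(
        config=config,
        layout=layout,
        frames=list(frame_paths),
        series=series,
        calls=calls,
        manifest=[p.name for p in sorted(folder.iterdir())],
    )


def analyze_folder(
    path,
    dye: DyeProfile | str | None = None,
    out: Path | None = None,
    window_minutes: tuple[float, float] = DEFAULT_BASELINE_WINDOW,
    min_delta: float = DEFAULT_MIN_DELTA,
    k_sd: float | None = None,
    layout: PlateLayout | None = None,
) -> RunRecord:
    """End-to-end analysis of a run folder of images.

    Reads params and frames, extracts hues, calls every well, and (when
    ``out`` is given) writes the raw/averaged/calls CSVs there.
    """
    folder = Path(path)
    config, stored_layout, _ = read_params(folder / PARAMS_NAME)
    if layout is None:
        layout = stored_layout
    if isinstance(dye, str):
        dye = builtin_dye(dye)
    elif dye is None:
        dye = builtin_dye(config.dye)
    record = process_run(
        config,
        load_frames(folder, config.interval_s),
        dye=dye,
        layout=layout,
        window_minutes=window_minutes,
        min_delta=min_delta,
        k_sd=k_sd,
    )
    record.frames = discover_frames(folder)
    if out is not None:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        wells = record.layout.well_ids()
        times = next(iter(record.series.values())).times
        _write_hue_csv(out / RAW_CSV_NAME, times, wells,
                       {w: s.raw for w, s in record.series.items()})
        _write_hue_csv(out / AVG_CSV_NAME, times, wells,
                       {w: s.smoothed for w, s in record.series.items()})
        _write_calls_csv(out / CALLS_CSV_NAME, wells, record.calls)
        record.manifest = [RAW_CSV_NAME, AVG_CSV_NAME, CALLS_CSV_NAME]
    return record
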