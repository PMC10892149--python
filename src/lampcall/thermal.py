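"""Lumped-parameter thermal model of the convective heating system.

Three coupled first-order compartments — the heated air chamber, the
metal plate seated on it, and the liquid inside an inserted tube — plus a
bang-bang (on/off with hysteresis) controller on the chamber heater.  The
model reproduces the qualitative behavior of the instrument: a fast
chamber ramp, a slower plate equilibration (reaching the working
temperature in ~20 min and settling within ~45 min of pre-heat), a
steady-state drop from chamber to plate/tube, sub-minute tube ramp after
insertion, and a stability band bounded by the controller hysteresis.

Plate heat loss is folded into the steady-state offset: the plate relaxes
toward ``ambient + (1 - offset/(setpoint - ambient)) * (chamber - ambient)``,
which equals ``setpoint - offset`` when the chamber holds its setpoint and
decays to ambient when the heater is off.  An ``open_port_coupling``
coefficient models unfilled sample ports venting chamber air through the
plate, which speeds chamber-plate equilibration.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "TempTrace",
    "ThermalParams",
    "plate_fixed_point",
    "simulate_preheat",
    "simulate_tube_insertion",
    "stability_band",
]


@dataclass(frozen=True)
class ThermalParams:
    """Model parameters.

    Defaults are calibrated to the qualitative instrument behavior: a
    77 degC chamber setpoint yielding a ~68 degC plate/tube temperature,
    the plate passing 65 degC near 20 min and settling by 45 min.
    """

    ambient_C: float = 22.0
    chamber_setpoint_C: float = 77.0
    heater_rate_C_per_min: float = 20.0
    tau_chamber_min: float = 5.0
    tau_plate_min: float = 6.0
    tau_tube_s: float = 10.0
    hysteresis_C: float = 0.5
    plate_tube_offset_C: float = 9.0
    open_port_coupling: float = 0.0

    def __post_init__(self) -> None:
        if min(self.tau_chamber_min, self.tau_plate_min, self.tau_tube_s) <= 0:
            raise ValueError("all time constants must be positive")
        if self.hysteresis_C < 0:
            raise ValueError("hysteresis must be non-negative")

    @property
    def tau_plate_effective_min(self) -> float:
        """Plate time constant shortened by open-port convective coupling."""
        return self.tau_plate_min / (1.0 + self.open_port_coupling)

    def plate_target(self, chamber_C: float | np.ndarray) -> float | np.ndarray:
        """Temperature the plate relaxes toward for a given chamber temp."""
        span = self.chamber_setpoint_C - self.ambient_C
        k = self.plate_tube_offset_C / span if span > 0 else 0.0
        return self.ambient_C + (1.0 - k) * (np.asarray(chamber_C) - self.ambient_C)


@dataclass
class TempTrace:
    """Time series of the three compartment temperatures, in minutes/degC."""

    times: np.ndarray
    chamber_C: np.ndarray
    plate_C: np.ndarray
    tube_C: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.chamber_C) == len(self.plate_C) == len(self.tube_C) == n):
            raise ValueError("all trace series must have equal length")

    def to_csv(self, path: Path) -> None:
        lines = ["time_min,chamber_C,plate_C,tube_C"]
        for t, c, p, u in zip(self.times, self.chamber_C, self.plate_C, self.tube_C):
            lines.append(f"{t:.4f},{c:.4f},{p:.4f},{u:.4f}")
        Path(path).write_text("\n".join(lines) + "\n")


def plate_fixed_point(params: ThermalParams) -> float:
    """Closed-form plate steady state with the chamber held at setpoint."""
    return float(params.plate_target(params.chamber_setpoint_C))


def tube_fixed_point(params: ThermalParams) -> float:
    """Closed-form tube steady state (tube tracks the plate)."""
    return plate_fixed_point(params)


def simulate_preheat(
    params: ThermalParams, duration_min: float, dt_s: float = 1.0
) -> TempTrace:
    """Explicit-Euler pre-heat simulation from ambient.

    The chamber integrates heater input (bang-bang with hysteresis around
    the setpoint; with zero hysteresis the heater modulates to hold the
    setpoint exactly once reached) against first-order loss to ambient;
    the plate lags toward its chamber-dependent target.  No tube is
    present, so the tube series stays at ambient.

    Raises ValueError when ``dt_s`` exceeds 1/20 of the smallest
    compartment time constant (Euler stability guard).
    """
    dt_min = dt_s / 60.0
    tau_min = min(params.tau_chamber_min, params.tau_plate_effective_min)
    if dt_min > tau_min / 20.0:
        raise ValueError(
            f"dt of {dt_s} s is too coarse for time constants of ~{tau_min} min; "
            f"use dt <= {tau_min * 3.0:.2f} s"
        )
    n = int(round(duration_min / dt_min)) + 1
    times = np.arange(n) * dt_min
    chamber = np.empty(n)
    plate = np.empty(n)
    chamber[0] = plate[0] = params.ambient_C
    heater_on = True
    half = params.hysteresis_C / 2.0
    for i in range(1, n):
        tc = chamber[i - 1]
        if params.hysteresis_C > 0:
            if tc >= params.chamber_setpoint_C + half:
                heater_on = False
            elif tc <= params.chamber_setpoint_C - half:
                heater_on = True
            heat = params.heater_rate_C_per_min if heater_on else 0.0
            tc_new = tc + dt_min * (heat - (tc - params.ambient_C) / params.tau_chamber_min)
        else:
            # zero hysteresis: heater modulates, holding the setpoint exactly
            # once it is reachable against the loss to ambient
            heat = params.heater_rate_C_per_min
            tc_new = tc + dt_min * (heat - (tc - params.ambient_C) / params.tau_chamber_min)
            loss_rate = (params.chamber_setpoint_C - params.ambient_C) / params.tau_chamber_min
            if tc_new > params.chamber_setpoint_C and params.heater_rate_C_per_min >= loss_rate:
                tc_new = params.chamber_setpoint_C
        chamber[i] = tc_new
        target = params.plate_target(chamber[i - 1])
        plate[i] = plate[i - 1] + dt_min * (target - plate[i - 1]) / params.tau_plate_effective_min
    tube = np.full(n, params.ambient_C)
    return TempTrace(times=times, chamber_C=chamber, plate_C=plate, tube_C=tube)


def simulate_tube_insertion(
    params: ThermalParams,
    plate_trace: TempTrace,
    insert_time_min: float,
) -> TempTrace:
    """Add a tube inserted at ``insert_time_min`` to an existing trace.

    The liquid starts at ambient and follows a first-order lag (time
    constant ``tau_tube_s``) toward the plate temperature.  Returns a new
    trace with the tube series filled in; before insertion the tube is at
    ambient.
    """
    times = plate_trace.times
    if insert_time_min < times[0] or insert_time_min > times[-1]:
        raise ValueError("insertion time must lie within the plate trace")
    tau_min = params.tau_tube_s / 60.0
    tube = np.full(times.shape, params.ambient_C)
    prev_t = None
    for i, t in enumerate(times):
        if t < insert_time_min:
            continue
        if prev_t is None:
            prev_t = t
            continue
        dt = t - prev_t
        steps = max(1, int(np.ceil(dt / (tau_min / 20.0))))
        h = dt / steps
        temp = tube[i - 1]
        target = plate_trace.plate_C[i]
        for _ in range(steps):
            temp = temp + h * (target - temp) / tau_min
        tube[i] = temp
        prev_t = t
    return TempTrace(
        times=times,
        chamber_C=plate_trace.chamber_C.copy(),
        plate_C=plate_trace.plate_C.copy(),
        tube_C=tube,
    )


def stability_band(
    trace: TempTrace, window: tuple[float, float], series: str = "tube"
) -> float:
    """Half-width of a temperature excursion over a time window: the
    maximum absolute deviation from the window mean.  ``series`` selects
    the compartment ("tube" by default; "chamber" or "plate" for
    controller diagnostics)."""
    lo, hi = window
    mask = (trace.times >= lo) & (trace.times <= hi)
    if not mask.any():
        raise ValueError(f"no samples in window [{lo}, {hi}] min")
    vals = getattr(trace, f"{series}_C")[mask]
    return float(np.max(np.abs(vals - vals.mean())))
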