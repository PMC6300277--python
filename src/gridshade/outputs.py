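"""Shade/energy composition, temporal aggregation, units, and raster export.

Per timestep, the walking engine delivers an object light fraction grid
O_LD (product of encountered transmittances) and a terrain shade grid
T_SHADE (inverse-distance topographic shade).  These compose into:

    O_SHADE     = 1 - O_LD
    L           = O_LD * (1 - T_SHADE)      (ground light fraction)
    Shade_TOTAL = 1 - L
    Energy_RES  = L * EI_cos                (ground-level incident energy)

so an unshaded cell (O_LD = 1, T_SHADE = 0) keeps the full clear-sky
incident energy and shade fractions run from 0 (no shade) to 1 (complete
shade).  Aggregation averages shade over daylight timesteps only (shade is
undefined without incident light) and reports energy either as the window
mean (W/m^2) or accumulated (J/m^2 = W/m^2 x s).  Energy can be converted
to PAR photon flux with a full-spectrum shortwave -> PAR factor,
default 2.02 umol s^-1 W^-1.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from pathlib import Path

import numpy as np

from .engine import TimestepResult
from .grids import GridRaster, write_ascii_grid
from .sun import SunState

__all__ = [
    "ShadeFields",
    "AggregatedOutputs",
    "compose_shade_energy",
    "aggregate",
    "convert_energy_units",
    "export_outputs",
    "WATTS_TO_UMOL",
    "OUTPUT_LAYERS",
]

WATTS_TO_UMOL = 2.02  # umol m^-2 s^-1 per W m^-2, shortwave -> PAR default

OUTPUT_LAYERS = ("energy", "total-shade", "object-shade", "terrain-shade")


@dataclass
class ShadeFields:
    """One timestep's composed shade and energy grids (NaN off-origin)."""

    o_ld: np.ndarray
    o_shade: np.ndarray
    t_shade: np.ndarray
    shade_total: np.ndarray
    energy: np.ndarray
    timestamp: datetime
    is_night: bool
    ei_cos: float


@dataclass
class AggregatedOutputs:
    """Time-aggregated grids for one output window."""

    start: datetime
    end: datetime
    o_shade: np.ndarray
    t_shade: np.ndarray
    shade_total: np.ndarray
    energy: np.ndarray
    energy_mode: str            # "mean-energy" | "accumulated-energy"
    energy_units: str           # "W/m^2", "J/m^2", or PAR equivalents
    n_daylight: int
    n_timesteps: int


def compose_shade_energy(o_ld: np.ndarray, terrain_shade: np.ndarray,
                         sun: SunState, timestamp: datetime | None = None,
                         is_night: bool | None = None) -> ShadeFields:
    """Compose a timestep's shade and ground-energy grids.

    Accepts either raw grids + sun or, more conveniently, a
    TimestepResult via :func:`compose_timestep`.
    """
    o_ld = np.asarray(o_ld, dtype=float)
    terrain_shade = np.asarray(terrain_shade, dtype=float)
    if o_ld.shape != terrain_shade.shape:
        raise ValueError(
            f"grid shapes differ: {o_ld.shape} vs {terrain_shade.shape}")
    night = (sun.altitude <= 0) if is_night is None else is_night
    light = o_ld * (1.0 - terrain_shade)
    return ShadeFields(
        o_ld=o_ld,
        o_shade=1.0 - o_ld,
        t_shade=terrain_shade,
        shade_total=1.0 - light,
        energy=light * sun.ei_cos,
        timestamp=timestamp if timestamp is not None else sun.timestamp,
        is_night=night,
        ei_cos=sun.ei_cos,
    )


def compose_timestep(result: TimestepResult) -> ShadeFields:
    """ShadeFields from a raw engine timestep result."""
    return compose_shade_energy(result.o_ld, result.terrain_shade_grid,
                                result.sun, is_night=result.is_night)


def aggregate(fields: list[ShadeFields], mode: str = "mean-energy",
              grain_seconds: float = 3600.0) -> AggregatedOutputs:
    """Aggregate a window of timestep fields.

    Shade grids are averaged over daylight timesteps only; night
    timesteps contribute zero energy.  In accumulated mode each timestep's
    energy is weighted by its duration in seconds.  A window that is
    entirely night yields NaN shade grids and zero energy.
    """
    if not fields:
        raise ValueError("cannot aggregate an empty window")
    if mode not in ("mean-energy", "accumulated-energy"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    shape = fields[0].o_ld.shape
    for f in fields:
        if f.o_ld.shape != shape:
            raise ValueError("all fields in a window must share geometry")
    day = [f for f in fields if not f.is_night]
    if day:
        o_shade = np.mean([f.o_shade for f in day], axis=0)
        t_shade = np.mean([f.t_shade for f in day], axis=0)
        shade_total = np.mean([f.shade_total for f in day], axis=0)
    else:
        o_shade = np.full(shape, np.nan)
        t_shade = np.full(shape, np.nan)
        shade_total = np.full(shape, np.nan)
    energies = [np.where(np.isnan(f.energy), np.nan, f.energy)
                if not f.is_night else np.zeros(shape) for f in fields]
    # keep nodata footprint of the origin mask on the energy grid
    nodata_mask = np.isnan(fields[0].o_ld) if day or fields else None
    if mode == "mean-energy":
        energy = np.mean(energies, axis=0)
        units = "W/m^2"
    else:
        energy = np.sum(energies, axis=0) * grain_seconds
        units = "J/m^2"
    if nodata_mask is not None:
        energy = np.where(nodata_mask, np.nan, energy)
    return AggregatedOutputs(
        start=fields[0].timestamp, end=fields[-1].timestamp,
        o_shade=o_shade, t_shade=t_shade, shade_total=shade_total,
        energy=energy, energy_mode=mode, energy_units=units,
        n_daylight=len(day), n_timesteps=len(fields),
    )


def convert_energy_units(grid: np.ndarray | float,
                         factor: float = WATTS_TO_UMOL,
                         inverse: bool = False) -> np.ndarray | float:
    """Convert W/m^2 to umol/m^2/s PAR photon flux (or back with inverse).

    The default factor 2.02 is the generalized full-spectrum shortwave to
    PAR conversion; it is configurable because the proper factor depends
    on sky condition and sensor.
    """
    if factor <= 0:
        raise ValueError(f"conversion factor must be > 0, got {factor}")
    if inverse:
        return grid / factor
    return grid * factor


_LAYER_ATTR = {
    "energy": "energy",
    "total-shade": "shade_total",
    "object-shade": "o_shade",
    "terrain-shade": "t_shade",
}


def export_outputs(agg: AggregatedOutputs, which: list[str] | tuple[str, ...],
                   directory: str | Path, geometry: GridRaster,
                   decimals: int = 4) -> list[Path]:
    """Write one ESRI ASCII grid per requested layer for one window.

    File names are deterministic (layer name + window start timestamp), so
    re-running an export overwrites byte-identically.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    stamp = agg.start.strftime("%Y%m%d_%H%M")
    for layer in which:
        if layer not in _LAYER_ATTR:
            raise ValueError(
                f"unknown output layer {layer!r}; expected one of {OUTPUT_LAYERS}")
        values = getattr(agg, _LAYER_ATTR[layer])
        grid = geometry.like(np.where(np.isnan(values),
                                      geometry.nodata_value, values))
        paths.append(write_ascii_grid(grid, directory / f"{layer}_{stamp}.asc",
                                      decimals=decimals))
    return paths
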