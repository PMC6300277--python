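"""Configuration-driven simulation runs.

A run iterates civil timesteps at the configured temporal grain between a
start and stop Julian day/year, computes the solar state at the landscape
centroid for each timestep, walks every origin cell, aggregates the
per-timestep grids into output windows, and exports the requested layers
as ESRI ASCII rasters plus an optional probe-cell time series and a run
log.  Identical configuration and inputs produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from datetime import datetime, timedelta
from pathlib import Path

import yaml

from .calibration import CalibrationParams
from .engine import simulate_timestep
from .grids import LandscapeStack, build_landscape_stack, read_ascii_grid
from .outputs import (OUTPUT_LAYERS, ShadeFields, aggregate, compose_timestep,
                      convert_energy_units, export_outputs)
from .sun import SolarContext, sun_state

__all__ = ["RunConfig", "load_config", "run_simulation"]


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    """Everything a simulation run needs.

    Times are civil clock times at the configured UTC offset; latitude and
    longitude describe the landscape centroid, at which the solar state is
    evaluated for the whole grid (the single-distant-source assumption).
    """

    latitude: float
    longitude: float
    utc_offset: float = 0.0
    start_julian_day: int = 1
    start_year: int = 2000
    stop_julian_day: int = 1
    stop_year: int = 2000
    daily_grain: int = 60                  # minutes between solar updates
    aggregation: int | str = "daily"       # minutes, or "daily"
    forced_start: str | None = None        # "HH:MM" daily window start
    forced_stop: str | None = None         # "HH:MM" daily window stop
    dem: str | None = None
    ndsm: str | None = None
    otm: str | None = None
    understory_height: str | None = None
    understory_otm: str | None = None
    mask: str | None = None
    cs_cali: float = 1.0
    tr_cali: float = 1.0
    gr_cali: float = 0.5
    cloud_fraction: float | dict[int, float] | None = None
    outputs: tuple[str, ...] = ("energy", "total-shade")
    energy_mode: str = "mean-energy"
    energy_units: str = "W/m^2"            # or "umol/m^2/s"
    par_factor: float = 2.02
    v: float | None = None                 # walk step override, metres
    probe_cell: tuple[int, int] | None = None
    sensor_height: float = 0.0
    output_dir: str = "outputs"
    output_decimals: int = 4
    seed: int = 0

    def validate(self) -> None:
        if not 1 <= self.daily_grain <= 1440:
            raise ConfigError(
                f"daily_grain must be in [1, 1440] minutes, got {self.daily_grain}")
        if self.aggregation != "daily":
            agg = int(self.aggregation)
            if agg <= 0 or agg % self.daily_grain != 0:
                raise ConfigError(
                    f"aggregation ({agg} min) must be a positive multiple of "
                    f"daily_grain ({self.daily_grain} min)")
        if (self.start_year, self.start_julian_day) > (self.stop_year,
                                                       self.stop_julian_day):
            raise ConfigError("start Julian day/year must not exceed stop")
        for d in (self.start_julian_day, self.stop_julian_day):
            if not 1 <= d <= 366:
                raise ConfigError(f"Julian day {d} outside [1, 366]")
        if self.energy_mode not in ("mean-energy", "accumulated-energy"):
            raise ConfigError(f"unknown energy mode {self.energy_mode!r}")
        for layer in self.outputs:
            if layer not in OUTPUT_LAYERS:
                raise ConfigError(f"unknown output layer {layer!r}")
        if self.energy_units not in ("W/m^2", "umol/m^2/s"):
            raise ConfigError(f"unknown energy units {self.energy_units!r}")
        for name in ("forced_start", "forced_stop"):
            value = getattr(self, name)
            if value is not None:
                _parse_clock(value)

    def calibration_params(self) -> CalibrationParams:
        return CalibrationParams(cs_cali=self.cs_cali, tr_cali=self.tr_cali,
                                 gr_cali=self.gr_cali)

    def solar_context(self) -> SolarContext:
        return SolarContext(latitude=self.latitude, longitude=self.longitude,
                            utc_offset=self.utc_offset)


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Load a YAML run configuration file, with keyword overrides."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: configuration must be a mapping")
    data.update(overrides)
    known = {f.name for f in RunConfig.__dataclass_fields__.values()}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"{path}: unknown configuration keys: {sorted(unknown)}")
    for key in ("outputs",):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    if "probe_cell" in data and isinstance(data["probe_cell"], list):
        data["probe_cell"] = tuple(data["probe_cell"])
    config = RunConfig(**data)
    config.validate()
    return config


def _parse_clock(text: str) -> tuple[int, int]:
    try:
        hh, mm = text.split(":")
        hh, mm = int(hh), int(mm)
    except ValueError as exc:
        raise ConfigError(f"clock time {text!r} is not HH:MM") from exc
    if not (0 <= hh <= 24 and 0 <= mm < 60):
        raise ConfigError(f"clock time {text!r} out of range")
    return hh, mm


def load_stack(config: RunConfig) -> LandscapeStack:
    """Read and co-register the raster layers a configuration names."""
    def read(attr):
        path = getattr(config, attr)
        if path is None:
            return None
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"{attr} raster not found: {path}")
        return read_ascii_grid(path)

    return build_landscape_stack(
        dem=read("dem"), ndsm=read("ndsm"), otm=read("otm"),
        understory_height=read("understory_height"),
        understory_otm=read("understory_otm"), mask=read("mask"))


def iter_days(config: RunConfig):
    """Yield the calendar dates covered by the configured day/year range."""
    date = datetime(config.start_year, 1, 1) + timedelta(
        days=config.start_julian_day - 1)
    stop = datetime(config.stop_year, 1, 1) + timedelta(
        days=config.stop_julian_day - 1)
    while date <= stop:
        yield date
        date += timedelta(days=1)


def day_timesteps(config: RunConfig, day: datetime) -> list[datetime]:
    """Civil timestamps simulated within one day, honoring the forced
    start/stop clock window."""
    h0, m0 = _parse_clock(config.forced_start) if config.forced_start else (0, 0)
    if config.forced_stop:
        h1, m1 = _parse_clock(config.forced_stop)
        end = day + timedelta(hours=h1, minutes=m1)
    else:
        end = day + timedelta(days=1)
    t = day + timedelta(hours=h0, minutes=m0)
    out = []
    while t < end:
        out.append(t)
        t += timedelta(minutes=config.daily_grain)
    return out


def _cloud_for_day(config: RunConfig, day: datetime) -> float | None:
    cloud = config.cloud_fraction
    if cloud is None or isinstance(cloud, (int, float)):
        return cloud
    return cloud.get(day.timetuple().tm_yday)


def run_simulation(config: RunConfig,
                   stack: LandscapeStack | None = None) -> list[Path]:
    """Execute a full configured run; returns the written file paths.

    A pre-built stack may be supplied (e.g. a generated fixture); otherwise
    the configured raster paths are read.
    """
    config.validate()
    if stack is None:
        stack = load_stack(config)
    ctx = config.solar_context()
    params = config.calibration_params()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    geometry = stack.geometry
    grain_seconds = config.daily_grain * 60.0

    written: list[Path] = []
    probe_rows: list[str] = []
    log_lines = [
        "# simulation run log",
        f"config: {json.dumps(asdict(config), default=str, sort_keys=True)}",
        f"config_hash: {_config_hash(config)}",
    ]

    for day in iter_days(config):
        t0 = time.perf_counter()
        cloud = _cloud_for_day(config, day)
        fields: list[ShadeFields] = []
        for ts in day_timesteps(config, day):
            sun = sun_state(ctx, ts, cs_cali=params.cs_cali,
                            cloud_fraction=cloud)
            result = simulate_timestep(stack, sun, params, v=config.v)
            sf = compose_timestep(result)
            if config.energy_units == "umol/m^2/s":
                sf.energy = convert_energy_units(sf.energy, config.par_factor)
            fields.append(sf)
            if config.probe_cell is not None:
                r, c = config.probe_cell
                probe_rows.append("\t".join([
                    ts.isoformat(),
                    f"{sf.energy[r, c]:.4f}",
                    f"{sf.shade_total[r, c]:.4f}",
                    f"{sf.o_shade[r, c]:.4f}",
                    f"{sf.t_shade[r, c]:.4f}",
                ]))
        for window in _windows(config, fields):
            agg = aggregate(window, mode=config.energy_mode,
                            grain_seconds=grain_seconds)
            written.extend(export_outputs(agg, config.outputs, out_dir,
                                          geometry,
                                          decimals=config.output_decimals))
            log_lines.append(
                f"window {agg.start.isoformat()}..{agg.end.isoformat()}: "
                f"{agg.n_daylight}/{agg.n_timesteps} daylight timesteps")
        log_lines.append(
            f"day {day.date().isoformat()}: "
            f"{time.perf_counter() - t0:.2f} s")

    if config.probe_cell is not None:
        probe_path = out_dir / "probe_series.tsv"
        header = "timestamp\tenergy\ttotal_shade\tobject_shade\tterrain_shade"
        probe_path.write_text("\n".join([header] + probe_rows) + "\n")
        written.append(probe_path)

    log_path = out_dir / "run_log.txt"
    log_path.write_text("\n".join(log_lines) + "\n")
    written.append(log_path)
    return written


def _windows(config: RunConfig,
             fields: list[ShadeFields]) -> list[list[ShadeFields]]:
    if not fields:
        return []
    if config.aggregation == "daily":
        return [fields]
    per = int(config.aggregation) // config.daily_grain
    return [fields[i:i + per] for i in range(0, len(fields), per)]


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), default=str, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
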