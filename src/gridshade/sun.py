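"""Per-timestep solar geometry and clear-sky incident energy.

For each simulation timestep the model needs the sun's azimuth (degrees
clockwise from north), its altitude above the horizon, the top-of-atmosphere
clear-sky irradiance EI for the day, and the cosine-corrected, calibrated
incident energy EI_cos that actually drives the landscape:

    declination  delta = 23.45 sin(2 pi (284 + n) / 365)          [degrees]
    hour angle   Omega = 15 (t_solar - 12)                        [degrees]
    altitude     gamma = arcsin(cos phi cos delta cos Omega
                                + sin phi sin delta)
    EI     = S_sun (1 + 0.034 cos(2 pi n / 365.25))               [W/m^2]
    EI_cos = sin(gamma) * EI * CS_CALI * (1 - cloud_fraction)     [W/m^2]

where phi is latitude, n the day of year and t_solar the local solar time
obtained from civil clock time via the site longitude, the UTC offset and
the equation of time.  The sin(gamma) factor is the cosine of the zenith
angle (90 deg - altitude): overhead sun passes the full EI, a sun on the
horizon passes none.  CS_CALI folds all atmospheric losses into a single
calibrated multiplier; cloud_fraction is an optional flat daily reduction.

Azimuth is resolved to the correct quadrant with a two-argument arctangent
of the sun's horizontal direction components rather than an arccos form,
so it is continuous through 0-360 degrees clockwise from north.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from datetime import datetime

__all__ = [
    "SolarContext",
    "SunState",
    "declination",
    "equation_of_time",
    "solar_position",
    "clear_sky_irradiance",
    "incident_clear_sky",
    "sun_state",
]

SOLAR_CONSTANT = 1367.0  # W/m^2


@dataclass(frozen=True)
class SolarContext:
    """Geo-temporal context shared by all timesteps of a run.

    latitude in degrees (north positive), longitude in degrees (east
    positive), utc_offset in hours (e.g. -8 for Pacific Standard Time).
    """

    latitude: float
    longitude: float
    utc_offset: float = 0.0
    solar_constant: float = SOLAR_CONSTANT

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")


@dataclass(frozen=True)
class SunState:
    """One timestep's solar angles and incident energy."""

    timestamp: datetime
    azimuth: float   # degrees clockwise from north, [0, 360)
    altitude: float  # degrees above horizon, [-90, 90]
    ei: float        # clear-sky (top of atmosphere) irradiance, W/m^2
    ei_cos: float    # cosine-corrected, calibrated incident energy, W/m^2

    @property
    def is_daylight(self) -> bool:
        return self.altitude > 0.0


def declination(day_of_year: int) -> float:
    """Solar declination in degrees for a day of year (1..366).

    Standard 23.45-degree sinusoidal model; the sun is over the equator at
    the equinoxes and reaches +/-23.45 degrees at the solstices.
    """
    if not 1 <= day_of_year <= 366:
        raise ValueError(f"day of year {day_of_year} outside [1, 366]")
    return 23.45 * math.sin(math.radians(360.0 * (284 + day_of_year) / 365.0))


def equation_of_time(day_of_year: int) -> float:
    """Equation of time in minutes (apparent minus mean solar time).

    Spencer's Fourier expansion; accurate to about 30 seconds, ample for
    angle work at minute-scale temporal grain.
    """
    b = 2.0 * math.pi * (day_of_year - 1) / 365.0
    return 229.18 * (
        0.000075
        + 0.001868 * math.cos(b)
        - 0.032077 * math.sin(b)
        - 0.014615 * math.cos(2 * b)
        - 0.040849 * math.sin(2 * b)
    )


def _solar_time_hours(ctx: SolarContext, timestamp: datetime) -> float:
    """Local solar time in hours from civil clock time.

    Corrects clock time for the offset between the site longitude and the
    time-zone standard meridian (15 deg * utc_offset) and for the equation
    of time.
    """
    n = timestamp.timetuple().tm_yday
    clock = (timestamp.hour + timestamp.minute / 60.0
             + timestamp.second / 3600.0)
    meridian = 15.0 * ctx.utc_offset
    correction_min = 4.0 * (ctx.longitude - meridian) + equation_of_time(n)
    return clock + correction_min / 60.0


def hour_angle(ctx: SolarContext, timestamp: datetime) -> float:
    """Hour angle in degrees: 0 at solar noon, 15 degrees per hour."""
    return 15.0 * (_solar_time_hours(ctx, timestamp) - 12.0)


def solar_position(ctx: SolarContext, timestamp: datetime) -> tuple[float, float]:
    """(azimuth, altitude) in degrees for a civil timestamp.

    Azimuth is clockwise from north in [0, 360); altitude is above the
    horizon (negative at night).
    """
    n = timestamp.timetuple().tm_yday
    delta = math.radians(declination(n))
    phi = math.radians(ctx.latitude)
    omega = math.radians(hour_angle(ctx, timestamp))

    sin_alt = (math.cos(phi) * math.cos(delta) * math.cos(omega)
               + math.sin(phi) * math.sin(delta))
    altitude = math.degrees(math.asin(max(-1.0, min(1.0, sin_alt))))

    # horizontal direction of the sun: atan2 form is quadrant-safe and
    # avoids the unbounded arccos argument of the naive formulation
    az_from_south = math.atan2(
        math.sin(omega),
        math.cos(omega) * math.sin(phi) - math.tan(delta) * math.cos(phi),
    )
    azimuth = (math.degrees(az_from_south) + 180.0) % 360.0
    return azimuth, altitude


def clear_sky_irradiance(day_of_year: int,
                         solar_constant: float = SOLAR_CONSTANT) -> float:
    """Top-of-atmosphere clear-sky irradiance EI (W/m^2) for a day of year.

    Earth-Sun distance (eccentricity) correction: EI peaks ~3.4% above the
    solar constant near perihelion (early January) and dips symmetrically
    near aphelion (early July).
    """
    if not 1 <= day_of_year <= 366:
        raise ValueError(f"day of year {day_of_year} outside [1, 366]")
    return solar_constant * (
        1.0 + 0.034 * math.cos(2.0 * math.pi * day_of_year / 365.25))


def incident_clear_sky(ei: float, altitude: float, cs_cali: float = 1.0,
                       cloud_fraction: float | None = None) -> float:
    """Cosine-corrected, calibrated incident energy EI_cos (W/m^2).

    EI_cos = sin(altitude) * EI * CS_CALI * (1 - cloud_fraction), floored
    at zero; a sun at or below the horizon yields zero.  CS_CALI values
    above 1 are permitted (they arise from peak calibration against an
    under-predicted observation) but flagged with a warning.
    """
    if ei < 0:
        raise ValueError(f"clear-sky irradiance must be >= 0, got {ei}")
    if cs_cali > 1.0 + 1e-9:
        warnings.warn(
            f"CS_CALI {cs_cali} exceeds 1; nominal range is (0, 1]",
            stacklevel=2)
    if cloud_fraction is not None and not 0.0 <= cloud_fraction <= 1.0:
        raise ValueError(f"cloud fraction {cloud_fraction} outside [0, 1]")
    if altitude <= 0.0:
        return 0.0
    cloud = 0.0 if cloud_fraction is None else cloud_fraction
    return max(0.0, math.sin(math.radians(altitude)) * ei * cs_cali
               * (1.0 - cloud))


def sun_state(ctx: SolarContext, timestamp: datetime, cs_cali: float = 1.0,
              cloud_fraction: float | None = None) -> SunState:
    """Full solar state (angles + energies) for one timestep."""
    azimuth, altitude = solar_position(ctx, timestamp)
    ei = clear_sky_irradiance(timestamp.timetuple().tm_yday,
                              ctx.solar_constant)
    ei_cos = incident_clear_sky(ei, altitude, cs_cali, cloud_fraction)
    return SunState(timestamp=timestamp, azimuth=azimuth, altitude=altitude,
                    ei=ei, ei_cos=ei_cos)
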