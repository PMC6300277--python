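"""Independent cross-checks: a fine-step light-transport march and a
Meeus/NOAA-style solar ephemeris.

Both implementations deliberately share no code with the model modules
they validate, so agreement between them and the model is evidence rather
than tautology:

* :func:`brute_force_light_fraction` marches a 3-D point from a cell
  center along the exact sun direction vector in small horizontal
  increments (default cellsize/50), with none of the walking algorithm's
  per-timestep rise/run caching or quarter-cell stepping.  Each distinct
  cell the ray traverses is assessed at the midpoint of the ray's chord
  through that cell (which coincides with the cell center on full
  crossings and differs only for corner-grazing chords).

* :func:`ephemeris_position` computes solar azimuth/altitude from the
  NOAA solar-calculator formulation (Julian centuries, mean/true solar
  longitude, obliquity, equation of time from orbital elements) — an
  entirely different derivation from the model's day-of-year declination
  and Spencer equation of time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime

from .grids import LandscapeStack
from .sun import SunState

__all__ = ["brute_force_light_fraction", "ephemeris_position", "OracleResult"]


@dataclass(frozen=True)
class OracleResult:
    object_light_fraction: float
    terrain_hit: bool
    cells_to_terrain: int | None


def brute_force_light_fraction(
    stack: LandscapeStack, sun: SunState, origin: tuple[int, int],
    step: float | None = None, origin_height_offset: float = 0.0,
) -> OracleResult:
    """Fine-step continuous ray march from one origin cell toward the sun.

    step is the horizontal increment in metres (default cellsize/50; must
    be well below the cell size).  Returns the accumulated object light
    fraction, whether the ray hit terrain, and if so after how many
    distinct cells.
    """
    if sun.altitude <= 0:
        raise ValueError("the sun must be above the horizon")
    cellsize = stack.cellsize
    if step is None:
        step = cellsize / 50.0
    if step <= 0:
        raise ValueError(f"step must be > 0, got {step}")

    az = math.radians(sun.azimuth)
    tan_alt = math.tan(math.radians(sun.altitude))
    # horizontal direction in grid (col, row) coordinates; row grows south
    dx = math.sin(az) * step / cellsize
    dr = -math.cos(az) * step / cellsize

    nrows, ncols = stack.shape
    dem = stack.dem_array()
    ndsm = stack.ndsm_array()
    otm = stack.otm_array()
    uh = stack.understory_height_array()
    uo = stack.understory_otm_array()
    has_dem = stack.dem is not None
    ceiling = stack.ceiling

    row0, col0 = origin
    z0 = (dem[row0][col0] if has_dem else 0.0) + origin_height_offset
    if z0 != z0:
        raise ValueError(f"origin cell {origin} has nodata elevation")

    x = col0 + 0.5
    r = row0 + 0.5
    o_ld = 1.0
    cells = 0
    cur_row, cur_col = row0, col0

    def assess(ri: int, ci: int) -> str:
        """Assess one crossed cell at the ray height over the horizontal
        origin-center -> cell-center distance; "terrain", "blocked"
        (transmittance applied) or "clear"."""
        nonlocal o_ld
        dist = math.hypot(ci - col0, ri - row0) * cellsize
        height = z0 + tan_alt * dist
        elev = dem[ri][ci]
        if has_dem and elev != elev:  # nodata terrain: transparent
            return "clear"
        if not has_dem:
            elev = 0.0
        if has_dem and height < elev:
            return "terrain"
        top = elev + ndsm[ri][ci]
        if height < top:
            if uh is not None and uo is not None and height < elev + uh[ri][ci]:
                o_ld *= max(0.0, min(1.0, uo[ri][ci]))
            else:
                o_ld *= max(0.0, min(1.0, otm[ri][ci]))
            return "blocked"
        return "clear"

    # edge-tie handling mirrors the walk convention: a point exactly on a
    # boundary belongs to the cell ahead in the travel direction
    tie_x = 1e-12 if dx < 0 else 0.0
    tie_r = 1e-12 if dr < 0 else 0.0
    max_steps = int((nrows + ncols) * cellsize / step) * 2 + 100
    for _ in range(max_steps):
        px, pr = x, r
        x += dx
        r += dr
        t = None
        ci = math.floor(x - tie_x)
        ri = math.floor(r - tie_r)
        if ci == cur_col and ri == cur_row:
            continue
        if ci != cur_col and ri != cur_row:
            # resolve crossing order; exact corner hits pass diagonally
            bx = cur_col + 1 if dx > 0 else cur_col
            br = cur_row + 1 if dr > 0 else cur_row
            tx = (bx - px) / dx
            ty = (br - pr) / dr
            if tx < ty:
                crossed = ((cur_row, ci), (ri, ci))
            elif ty < tx:
                crossed = ((ri, cur_col), (ri, ci))
            else:
                crossed = ((ri, ci),)
        else:
            crossed = ((ri, ci),)
        for ri, ci in crossed:
            if not (0 <= ci < ncols and 0 <= ri < nrows):
                return OracleResult(o_ld, False, None)
            cur_row, cur_col = ri, ci
            cells += 1
            outcome = assess(ri, ci)
            if outcome == "terrain":
                return OracleResult(o_ld, True, cells)
        # once the ray height at the current center exceeds the landscape
        # ceiling nothing further can intercept it
        dist = math.hypot(cur_col - col0, cur_row - row0) * cellsize
        if z0 + tan_alt * dist >= ceiling:
            return OracleResult(o_ld, False, None)
    raise RuntimeError("oracle march failed to terminate (internal error)")


# --- NOAA/Meeus solar ephemeris -----------------------------------------


def _julian_day(timestamp: datetime, utc_offset: float) -> float:
    """Julian day number (UT) for a local civil timestamp."""
    frac = (timestamp.hour + timestamp.minute / 60.0
            + timestamp.second / 3600.0 - utc_offset) / 24.0
    return timestamp.toordinal() + 1721424.5 + frac


def ephemeris_position(latitude: float, longitude: float, utc_offset: float,
                       timestamp: datetime) -> tuple[float, float]:
    """(azimuth, altitude) in degrees from the NOAA calculator formulation.

    Geometric altitude (no atmospheric refraction); azimuth clockwise from
    north.  Accurate to a small fraction of a degree over 1900-2100.
    """
    jd = _julian_day(timestamp, utc_offset)
    jc = (jd - 2451545.0) / 36525.0

    gmls = (280.46646 + jc * (36000.76983 + 0.0003032 * jc)) % 360.0
    gmas = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    eeo = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    eqctr = (math.sin(math.radians(gmas))
             * (1.914602 - jc * (0.004817 + 0.000014 * jc))
             + math.sin(math.radians(2 * gmas)) * (0.019993 - 0.000101 * jc)
             + math.sin(math.radians(3 * gmas)) * 0.000289)
    true_long = gmls + eqctr
    app_long = (true_long - 0.00569
                - 0.00478 * math.sin(math.radians(125.04 - 1934.136 * jc)))
    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = mean_obliq + 0.00256 * math.cos(math.radians(125.04 - 1934.136 * jc))
    decl = math.degrees(math.asin(
        math.sin(math.radians(obliq)) * math.sin(math.radians(app_long))))

    var_y = math.tan(math.radians(obliq / 2.0)) ** 2
    eq_time = 4.0 * math.degrees(
        var_y * math.sin(2.0 * math.radians(gmls))
        - 2.0 * eeo * math.sin(math.radians(gmas))
        + 4.0 * eeo * var_y * math.sin(math.radians(gmas))
        * math.cos(2.0 * math.radians(gmls))
        - 0.5 * var_y * var_y * math.sin(4.0 * math.radians(gmls))
        - 1.25 * eeo * eeo * math.sin(2.0 * math.radians(gmas)))

    clock_min = (timestamp.hour * 60.0 + timestamp.minute
                 + timestamp.second / 60.0)
    tst = (clock_min + eq_time + 4.0 * longitude - 60.0 * utc_offset) % 1440.0
    ha = tst / 4.0 - 180.0 if tst / 4.0 >= 0 else tst / 4.0 + 180.0
    if ha < -180.0:
        ha += 360.0

    phi = math.radians(latitude)
    d = math.radians(decl)
    h = math.radians(ha)
    cos_zen = (math.sin(phi) * math.sin(d)
               + math.cos(phi) * math.cos(d) * math.cos(h))
    cos_zen = max(-1.0, min(1.0, cos_zen))
    zenith = math.degrees(math.acos(cos_zen))
    altitude = 90.0 - zenith

    sin_zen = math.sin(math.radians(zenith))
    if sin_zen < 1e-9:
        return 180.0, altitude  # sun at zenith: azimuth indeterminate
    cos_az = ((math.sin(phi) * cos_zen) - math.sin(d)) / (math.cos(phi) * sin_zen)
    cos_az = max(-1.0, min(1.0, cos_az))
    if ha > 0:
        azimuth = (math.degrees(math.acos(cos_az)) + 180.0) % 360.0
    else:
        azimuth = (540.0 - math.degrees(math.acos(cos_az))) % 360.0
    return azimuth, altitude
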