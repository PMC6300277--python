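"""The walking algorithm: backward ray marching over the landscape grid.

For every origin cell, a ray is traced from the cell center toward the
sun in fixed horizontal increments (the step length v defaults to a
quarter of the cell resolution).  Each time the ray enters a NEW cell the
ray height there is compared against that cell's terrain elevation and
object top:

    Solar_VRC = |tan(gamma)| * X_TOTAL        (vertical rise, m)
    Solar_AH  = origin_elevation + Solar_VRC  (absolute ray height, m)
    O_DH      = Solar_AH - (elevation + object height)
    T_DH      = Solar_AH - elevation

A negative O_DH means the ray passes through the cell's object voxel and
that cell's transmittance (times TR_CALI) multiplies into the accumulated
object light fraction O_LD.  A negative T_DH means the ray hit terrain:
the walk terminates and the origin receives terrain shade
GR_CALI / cells_walked — full effect when the blocking ridge is adjacent,
weakening with distance to account for indirect-light scattering.  A walk
also terminates on leaving the data extent or on climbing above the
precomputed ceiling (the landscape's maximum elevation + object height),
above which nothing can intercept the ray.

The per-step trigonometry is computed once per timestep and shared by all
origins.  Cells are DISCOVERED by the quarter-cell march, but each new
cell is ASSESSED at the horizontal distance from the origin center to
that cell's center, so the result is independent of the step length for
any v <= cellsize/4 and transmittance is applied exactly once per cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .grids import LandscapeStack
from .params import CalibrationParams
from .sun import SunState

__all__ = [
    "StepVector",
    "CellResult",
    "step_vector",
    "ray_height",
    "assess_object",
    "assess_terrain",
    "terrain_shade",
    "walk_cell",
    "simulate_timestep",
    "TimestepResult",
]

# sample points landing exactly on a cell edge belong to the cell ahead
# in the walk direction; the nudge resolves the floor() tie that way
_EDGE_TIE_EPS = 1e-9


@dataclass(frozen=True)
class StepVector:
    """Per-step displacement toward the sun, in metres.

    run is the east-positive component, rise the north-positive component;
    run^2 + rise^2 = v^2.
    """

    run: float
    rise: float
    v: float


@dataclass(frozen=True)
class CellResult:
    """Outcome of one origin cell's walk."""

    object_light_fraction: float  # O_LD, accumulated product of transmittances
    terrain_shade: float          # GR_CALI / cells_walked if terrain hit, else 0
    terminated_by: str            # "terrain" | "edge" | "ceiling"
    cells_walked: int


def step_vector(azimuth: float, v: float) -> StepVector:
    """Displacement per walk step toward a sun at the given azimuth.

    run = sin(azimuth) * v (east), rise = cos(azimuth) * v (north); the
    continuous form covers all four quadrants with one expression and is
    computed once per timestep, then reused for every origin cell.
    """
    if not 0.0 <= azimuth < 360.0:
        azimuth = azimuth % 360.0
    if v <= 0:
        raise ValueError(f"step length v must be > 0, got {v}")
    a = math.radians(azimuth)
    return StepVector(run=math.sin(a) * v, rise=math.cos(a) * v, v=v)


def ray_height(origin_elevation: float, altitude: float,
               x_total: float) -> tuple[float, float]:
    """(Solar_VRC, Solar_AH) at horizontal distance x_total from the origin."""
    if x_total < 0:
        raise ValueError("x_total must be >= 0")
    vrc = abs(math.tan(math.radians(altitude))) * x_total
    return vrc, origin_elevation + vrc


def assess_object(solar_ah: float, dem_elev: float, ndsm_height: float,
                  otm: float, understory_height: float | None = None,
                  understory_otm: float | None = None,
                  tr_cali: float = 1.0) -> float:
    """Transmittance factor contributed by one encountered cell.

    O_DH = Solar_AH - (elevation + object height); a non-negative O_DH
    means the ray clears the object (factor 1).  Otherwise the factor is
    the effective transmittance of the voxel containing the ray: the
    understory voxel when an understory layer exists and the ray is below
    its top, the canopy voxel otherwise.  Factors outside [0, 1] after
    TR_CALI scaling are clamped.
    """
    o_dh = solar_ah - (dem_elev + ndsm_height)
    if o_dh >= 0:
        return 1.0
    if (understory_height is not None and understory_otm is not None
            and solar_ah < dem_elev + understory_height):
        factor = understory_otm * tr_cali
    else:
        factor = otm * tr_cali
    return min(1.0, max(0.0, factor))


def assess_terrain(solar_ah: float, dem_elev: float) -> str:
    """"penetrated" if the ray is below ground (T_DH < 0), else "above".

    T_DH = 0 (ray grazing the surface) counts as above: grazing rays do
    not terminate walks.
    """
    return "penetrated" if solar_ah - dem_elev < 0 else "above"


def terrain_shade(cells_walked: int, gr_cali: float) -> float:
    """Terrain shade for a walk terminated by terrain after cells_walked cells.

    GR_CALI at one cell walked (maximum topographic shade, the blocking
    terrain is adjacent), weakening inversely with distance.
    """
    if cells_walked < 1:
        raise RuntimeError(
            "terrain cannot terminate a walk before any cell is entered")
    return gr_cali / cells_walked


class _WalkContext:
    """Per-timestep state shared by every origin's walk (plain-Python
    containers: the inner loop is scalar and tight)."""

    def __init__(self, stack: LandscapeStack, sun: SunState,
                 params: CalibrationParams, v: float | None):
        self.cellsize = stack.cellsize
        self.v = self.cellsize / 4.0 if v is None else v
        if self.v <= 0:
            raise ValueError("step length v must be > 0")
        sv = step_vector(sun.azimuth, self.v)
        # grid row index grows southward, so a northward rise lowers it
        self.dx = sv.run / self.cellsize
        self.dr = -sv.rise / self.cellsize
        self.tan_alt = abs(math.tan(math.radians(sun.altitude)))
        self.nrows, self.ncols = stack.shape
        self.ceiling = stack.ceiling
        self.has_dem = stack.dem is not None
        self.has_objects = stack.ndsm is not None
        dem = stack.dem_array()
        self.dem = dem.tolist()
        self.dem_ok = (~np.isnan(dem)).tolist()
        self.ndsm = stack.ndsm_array().tolist()
        self.otm = stack.otm_array().tolist()
        uh = stack.understory_height_array()
        uo = stack.understory_otm_array()
        self.has_understory = uh is not None and uo is not None
        self.uh = uh.tolist() if uh is not None else None
        self.uo = uo.tolist() if uo is not None else None
        self.tr_cali = params.tr_cali
        self.gr_cali = params.gr_cali
        # nudges implementing the edge-tie rule per axis
        self.ex = _EDGE_TIE_EPS if self.dx < 0 else 0.0
        self.er = _EDGE_TIE_EPS if self.dr < 0 else 0.0

    def walk(self, row: int, col: int,
             origin_height_offset: float = 0.0) -> CellResult:
        cellsize = self.cellsize
        dx, dr = self.dx, self.dr
        ex, er = self.ex, self.er
        tan_alt = self.tan_alt
        nrows, ncols = self.nrows, self.ncols
        dem, dem_ok = self.dem, self.dem_ok
        ndsm, otm = self.ndsm, self.otm
        ceiling = self.ceiling
        has_dem, has_objects = self.has_dem, self.has_objects
        has_under = self.has_understory
        tr = self.tr_cali

        ox = col + 0.5
        orow = row + 0.5
        z0 = (dem[row][col] if has_dem else 0.0) + origin_height_offset
        if z0 != z0:  # NaN origin elevation: caller should have excluded it
            raise ValueError(f"origin cell ({row}, {col}) has nodata elevation")

        x, r = ox, orow
        cur_col, cur_row = col, row
        o_ld = 1.0
        cells_walked = 0
        # hard cap: the walk must leave the grid within this many steps
        max_steps = int(4 * (nrows + ncols) / min(abs(dx) + abs(dr), 2.0)) + 16 \
            if (dx or dr) else 0
        if max_steps == 0:
            raise ValueError("degenerate step vector")
        for _ in range(max_steps):
            px, pr = x, r
            x += dx
            r += dr
            c_i = math.floor(x - ex)
            r_i = math.floor(r - er)
            if c_i == cur_col and r_i == cur_row:
                continue
            # a step may cross a column boundary, a row boundary, or both;
            # visit the crossed cells in their order along the segment (an
            # exact lattice-corner hit passes diagonally, touching neither
            # off-diagonal neighbor)
            if c_i != cur_col and r_i != cur_row:
                bx = cur_col + 1 if dx > 0 else cur_col
                br = cur_row + 1 if dr > 0 else cur_row
                tx = (bx - px) / dx
                tr_ = (br - pr) / dr
                if tx < tr_:
                    entered = ((cur_row, c_i), (r_i, c_i))
                elif tr_ < tx:
                    entered = ((r_i, cur_col), (r_i, c_i))
                else:
                    entered = ((r_i, c_i),)
            else:
                entered = ((r_i, c_i),)
            for r_i, c_i in entered:
                if c_i < 0 or c_i >= ncols or r_i < 0 or r_i >= nrows:
                    return CellResult(o_ld, 0.0, "edge", cells_walked)
                cur_col, cur_row = c_i, r_i
                cells_walked += 1
                ddx = (c_i + 0.5) - ox
                ddr = (r_i + 0.5) - orow
                x_total = math.hypot(ddx, ddr) * cellsize
                solar_ah = z0 + tan_alt * x_total
                cell_elev = dem[r_i][c_i] if has_dem else 0.0
                if has_dem and not dem_ok[r_i][c_i]:
                    # unknown terrain: transparent and non-blocking
                    if solar_ah >= ceiling:
                        return CellResult(o_ld, 0.0, "ceiling", cells_walked)
                    continue
                if has_dem and solar_ah - cell_elev < 0:
                    return CellResult(
                        o_ld, self.gr_cali / cells_walked, "terrain",
                        cells_walked)
                if has_objects:
                    h = ndsm[r_i][c_i]
                    if h > 0 and solar_ah - (cell_elev + h) < 0:
                        if has_under and solar_ah < cell_elev + self.uh[r_i][c_i]:
                            factor = self.uo[r_i][c_i] * tr
                        else:
                            factor = otm[r_i][c_i] * tr
                        if factor < 0.0:
                            factor = 0.0
                        elif factor > 1.0:
                            factor = 1.0
                        o_ld *= factor
                if solar_ah >= ceiling:
                    return CellResult(o_ld, 0.0, "ceiling", cells_walked)
        raise RuntimeError("walk failed to terminate (internal error)")


def walk_cell(origin: tuple[int, int], sun: SunState, stack: LandscapeStack,
              params: CalibrationParams | None = None, v: float | None = None,
              origin_height_offset: float = 0.0) -> CellResult:
    """Walk a single origin cell toward the sun and return its shade result.

    origin is a (row, col) index; origin_height_offset raises the walk's
    starting elevation above the ground surface (e.g. a sensor height).
    The sun must be above the horizon.
    """
    if sun.altitude <= 0:
        raise ValueError("walks require a sun above the horizon")
    ctx = _WalkContext(stack, sun, params or CalibrationParams(), v)
    return ctx.walk(origin[0], origin[1], origin_height_offset)


@dataclass
class TimestepResult:
    """Raw per-timestep walk output before shade/energy composition.

    Grids are NaN outside eligible origin cells.  Night timesteps carry
    O_LD = 1 and terrain shade 0 by convention and are flagged.
    """

    o_ld: np.ndarray
    terrain_shade_grid: np.ndarray
    sun: SunState
    is_night: bool


def simulate_timestep(stack: LandscapeStack, sun: SunState,
                      params: CalibrationParams | None = None,
                      v: float | None = None) -> TimestepResult:
    """Walk every eligible origin cell for one timestep.

    Eligible origins are non-nodata DEM cells inside the area-of-interest
    mask; ineligible cells carry NaN.  At night (altitude <= 0) no walks
    are performed.
    """
    params = params or CalibrationParams()
    origins = stack.origin_mask()
    o_ld = np.full(stack.shape, np.nan)
    t_shade = np.full(stack.shape, np.nan)
    if sun.altitude <= 0:
        o_ld[origins] = 1.0
        t_shade[origins] = 0.0
        return TimestepResult(o_ld, t_shade, sun, is_night=True)
    ctx = _WalkContext(stack, sun, params, v)
    for row, col in np.argwhere(origins):
        res = ctx.walk(int(row), int(col))
        o_ld[row, col] = res.object_light_fraction
        t_shade[row, col] = res.terrain_shade
    return TimestepResult(o_ld, t_shade, sun, is_night=False)
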