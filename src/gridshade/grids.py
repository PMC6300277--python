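"""ESRI ASCII Grid I/O and the co-registered landscape stack.

The simulator consumes three co-registered rasters: a digital elevation
model (DEM, bare-earth elevation in metres), a normalized digital surface
model (nDSM, object height above ground in metres) and an object
transmittance model (OTM, the fraction of light each cell's object lets
through, 0 = opaque, 1 = transparent).  An optional understory layer pair
splits each object column into two stacked voxels (canopy over understory)
with distinct transmittances, and an optional 0/1 mask restricts which
cells are reported.

All rasters travel as ESRI ASCII Grid text files: a short key/value header
(ncols, nrows, xllcorner/xllcenter, yllcorner/yllcenter, cellsize, optional
NODATA_value) followed by nrows x ncols whitespace-separated values in
top-down row order (row 0 = northernmost).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "GridRaster",
    "LandscapeStack",
    "read_ascii_grid",
    "write_ascii_grid",
    "build_landscape_stack",
    "GridFormatError",
    "CoRegistrationError",
]

DEFAULT_NODATA = -9999.0


class GridFormatError(ValueError):
    """Malformed ESRI ASCII grid file or invalid header field."""


class CoRegistrationError(ValueError):
    """Layers of a landscape stack do not share the same geometry."""


@dataclass
class GridRaster:
    """A georeferenced 2-D cell array.

    ``values`` is ordered north-to-south by row (row 0 = northernmost) and
    west-to-east by column, matching the ESRI ASCII top-down convention.
    """

    ncols: int
    nrows: int
    xllcorner: float
    yllcorner: float
    cellsize: float
    values: np.ndarray
    nodata_value: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.ncols < 1 or self.nrows < 1:
            raise GridFormatError("ncols and nrows must be >= 1")
        if not (self.cellsize > 0):
            raise GridFormatError("cellsize must be > 0")
        if self.values.shape != (self.nrows, self.ncols):
            raise GridFormatError(
                f"values shape {self.values.shape} does not match "
                f"(nrows, ncols) = ({self.nrows}, {self.ncols})"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def is_nodata(self) -> np.ndarray:
        """Boolean mask of nodata cells."""
        return np.isclose(self.values, self.nodata_value) | np.isnan(self.values)

    def data_values(self) -> np.ndarray:
        """Values with nodata cells replaced by NaN."""
        out = self.values.astype(float).copy()
        out[self.is_nodata()] = np.nan
        return out

    def same_geometry(self, other: "GridRaster") -> list[str]:
        """Names of geometry fields on which the two grids differ."""
        bad = []
        if self.ncols != other.ncols:
            bad.append("ncols")
        if self.nrows != other.nrows:
            bad.append("nrows")
        if not math.isclose(self.cellsize, other.cellsize, rel_tol=1e-9):
            bad.append("cellsize")
        if not math.isclose(self.xllcorner, other.xllcorner, rel_tol=0, abs_tol=1e-6):
            bad.append("xllcorner")
        if not math.isclose(self.yllcorner, other.yllcorner, rel_tol=0, abs_tol=1e-6):
            bad.append("yllcorner")
        return bad

    def like(self, values: np.ndarray, nodata: float | None = None) -> "GridRaster":
        """New raster with this grid's geometry and the given values."""
        return GridRaster(
            ncols=self.ncols,
            nrows=self.nrows,
            xllcorner=self.xllcorner,
            yllcorner=self.yllcorner,
            cellsize=self.cellsize,
            values=values,
            nodata_value=self.nodata_value if nodata is None else nodata,
        )


_HEADER_KEYS = {"ncols", "nrows", "xllcorner", "xllcenter",
                "yllcorner", "yllcenter", "cellsize", "nodata_value"}


def read_ascii_grid(path: str | Path) -> GridRaster:
    """Read an ESRI ASCII grid file.

    Both the ``xllcorner``/``yllcorner`` and ``xllcenter``/``yllcenter``
    header dialects are accepted; centers are converted to corners.  A
    missing NODATA_value header defaults the sentinel to -9999.
    """
    path = Path(path)
    header: dict[str, float] = {}
    body_tokens: list[str] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if not parts:
            continue
        key = parts[0].lower()
        if key in _HEADER_KEYS:
            if len(parts) != 2:
                raise GridFormatError(
                    f"{path}: malformed header line {i + 1}: {line.strip()!r}")
            try:
                header[key] = float(parts[1])
            except ValueError as exc:
                raise GridFormatError(
                    f"{path}: non-numeric header value on line {i + 1}: "
                    f"{parts[1]!r}") from exc
        else:
            break
    else:
        i += 1  # file was all header

    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise GridFormatError(f"{path}: missing required header key {key!r}")
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    cellsize = header["cellsize"]
    if cellsize <= 0:
        raise GridFormatError(f"{path}: cellsize must be > 0, got {cellsize}")

    if "xllcorner" in header:
        xll = header["xllcorner"]
    elif "xllcenter" in header:
        xll = header["xllcenter"] - cellsize / 2.0
    else:
        raise GridFormatError(f"{path}: missing xllcorner/xllcenter header")
    if "yllcorner" in header:
        yll = header["yllcorner"]
    elif "yllcenter" in header:
        yll = header["yllcenter"] - cellsize / 2.0
    else:
        raise GridFormatError(f"{path}: missing yllcorner/yllcenter header")
    nodata = header.get("nodata_value", DEFAULT_NODATA)

    for j in range(i, len(lines)):
        body_tokens.extend(lines[j].split())
    expected = nrows * ncols
    if len(body_tokens) != expected:
        raise GridFormatError(
            f"{path}: expected {expected} cell values, found {len(body_tokens)}")
    values = np.empty(expected, dtype=float)
    for k, tok in enumerate(body_tokens):
        try:
            values[k] = float(tok)
        except ValueError as exc:
            raise GridFormatError(
                f"{path}: non-numeric cell token {tok!r} at position {k}") from exc
    return GridRaster(
        ncols=ncols, nrows=nrows, xllcorner=xll, yllcorner=yll,
        cellsize=cellsize, values=values.reshape(nrows, ncols),
        nodata_value=nodata,
    )


def _fmt_exact(x: float) -> str:
    """Shortest exact decimal form: integers without a decimal point,
    everything else via the float's round-tripping repr."""
    if math.isfinite(x) and x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(float(x))


def _fmt(x: float, decimals: int, nodata: float) -> str:
    if np.isnan(x) or np.isclose(x, nodata):
        # write the sentinel verbatim, never as formatted data
        return _fmt_exact(nodata)
    return f"{x:.{decimals}f}"


def write_ascii_grid(grid: GridRaster, path: str | Path, decimals: int = 6) -> Path:
    """Write ``grid`` as an ESRI ASCII grid file (corner-form header).

    Round-trips: re-reading reproduces the header exactly and the values to
    the written decimal precision.  Nodata cells are written as the sentinel
    verbatim.
    """
    path = Path(path)
    lines = [
        f"ncols {grid.ncols}",
        f"nrows {grid.nrows}",
        f"xllcorner {_fmt_exact(grid.xllcorner)}",
        f"yllcorner {_fmt_exact(grid.yllcorner)}",
        f"cellsize {_fmt_exact(grid.cellsize)}",
        f"NODATA_value {_fmt_exact(grid.nodata_value)}",
    ]
    for row in grid.values:
        lines.append(" ".join(_fmt(v, decimals, grid.nodata_value) for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path


@dataclass
class LandscapeStack:
    """Validated, co-registered landscape layers with a precomputed ceiling.

    ``ceiling`` is the maximum over non-nodata cells of (elevation + object
    height), a missing layer contributing zero; a ray above the ceiling can
    never be intercepted, so it terminates the walk.
    """

    dem: GridRaster | None = None
    ndsm: GridRaster | None = None
    otm: GridRaster | None = None
    understory_height: GridRaster | None = None
    understory_otm: GridRaster | None = None
    mask: GridRaster | None = None
    ceiling: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        layers = self.layers()
        if self.dem is None and self.ndsm is None:
            raise CoRegistrationError("at least one of dem, ndsm must be provided")
        if self.ndsm is not None and self.otm is None:
            raise CoRegistrationError("an OTM layer is required when nDSM is present")
        ref_name, ref = layers[0]
        for name, layer in layers[1:]:
            bad = ref.same_geometry(layer)
            if bad:
                raise CoRegistrationError(
                    f"layer {name!r} geometry differs from {ref_name!r} "
                    f"on fields: {', '.join(bad)}")
        if self.otm is not None:
            vals = self.otm.data_values()
            out = np.argwhere((vals < 0) | (vals > 1))
            if out.size:
                r, c = out[0]
                raise ValueError(
                    f"OTM value {vals[r, c]} outside [0, 1] at cell ({r}, {c})")
        if self.understory_otm is not None:
            vals = self.understory_otm.data_values()
            if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
                raise ValueError("understory OTM values must lie in [0, 1]")
        if self.ndsm is not None:
            nd = self.ndsm.data_values()
            if np.nanmin(nd) < -1e-12:
                bad = np.argwhere(nd < 0)[0]
                raise ValueError(f"negative nDSM height at cell {tuple(bad)}")
        if self.understory_height is not None and self.ndsm is not None:
            uh = self.understory_height.data_values()
            nd = self.ndsm.data_values()
            both = ~np.isnan(uh) & ~np.isnan(nd)
            if np.any(uh[both] < 0) or np.any(uh[both] > nd[both] + 1e-9):
                raise ValueError(
                    "understory height must satisfy 0 <= height <= nDSM")
        self.ceiling = self._compute_ceiling()

    def layers(self) -> list[tuple[str, GridRaster]]:
        out = []
        for name in ("dem", "ndsm", "otm", "understory_height",
                     "understory_otm", "mask"):
            layer = getattr(self, name)
            if layer is not None:
                out.append((name, layer))
        return out

    @property
    def geometry(self) -> GridRaster:
        """A reference layer carrying the shared geometry."""
        return self.layers()[0][1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.geometry.shape

    @property
    def cellsize(self) -> float:
        return self.geometry.cellsize

    def _compute_ceiling(self) -> float:
        dem = self.dem.data_values() if self.dem is not None else 0.0
        ndsm = self.ndsm.data_values() if self.ndsm is not None else 0.0
        if self.dem is None:
            dem = np.zeros(self.shape)
        if self.ndsm is None:
            ndsm = np.zeros(self.shape)
        # nodata object height blocks nothing
        ndsm = np.where(np.isnan(ndsm), 0.0, ndsm)
        elev = dem + ndsm
        if np.all(np.isnan(elev)):
            return 0.0
        return float(np.nanmax(elev))

    # --- arrays used by the walking engine ------------------------------

    def dem_array(self) -> np.ndarray:
        """Elevation with NaN at nodata; zeros when no DEM layer exists."""
        if self.dem is None:
            return np.zeros(self.shape)
        return self.dem.data_values()

    def ndsm_array(self) -> np.ndarray:
        if self.ndsm is None:
            return np.zeros(self.shape)
        nd = self.ndsm.data_values()
        return np.where(np.isnan(nd), 0.0, nd)

    def otm_array(self) -> np.ndarray:
        if self.otm is None:
            return np.ones(self.shape)
        ot = self.otm.data_values()
        return np.where(np.isnan(ot), 1.0, ot)

    def understory_height_array(self) -> np.ndarray | None:
        if self.understory_height is None:
            return None
        uh = self.understory_height.data_values()
        return np.where(np.isnan(uh), 0.0, uh)

    def understory_otm_array(self) -> np.ndarray | None:
        if self.understory_otm is None:
            return None
        uo = self.understory_otm.data_values()
        return np.where(np.isnan(uo), 1.0, uo)

    def origin_mask(self) -> np.ndarray:
        """Cells eligible as walk origins.

        Nodata DEM cells are excluded (their outputs carry nodata) and the
        optional area-of-interest mask restricts origins further; masked-out
        cells still participate as shade casters during walks.
        """
        ok = np.ones(self.shape, dtype=bool)
        if self.dem is not None:
            ok &= ~self.dem.is_nodata()
        if self.mask is not None:
            ok &= self.mask.values > 0.5
        return ok


def build_landscape_stack(
    dem: GridRaster | None = None,
    ndsm: GridRaster | None = None,
    otm: GridRaster | None = None,
    understory_height: GridRaster | None = None,
    understory_otm: GridRaster | None = None,
    mask: GridRaster | None = None,
) -> LandscapeStack:
    """Assemble and validate a co-registered landscape stack.

    With only a DEM, object shading is disabled (topographic-only mode);
    with only an nDSM+OTM, terrain is treated as flat at elevation zero
    (object-only mode).
    """
    return LandscapeStack(
        dem=dem, ndsm=ndsm, otm=otm,
        understory_height=understory_height,
        understory_otm=understory_otm, mask=mask,
    )
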