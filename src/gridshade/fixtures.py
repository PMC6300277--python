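"""Synthetic test landscapes.

Every landscape the test-suite and validation scripts use is generated
here, deterministically, from a small declarative spec: flat plains,
single blocks (one tree/building), terrain ridges, uniform slopes, and
seeded random canopies.  Generated stacks satisfy all landscape-stack
invariants, and identical seeds reproduce identical stacks bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import GridRaster, LandscapeStack, build_landscape_stack

__all__ = ["FixtureSpec", "make_fixture"]

KINDS = ("flat", "block", "ridge", "slope", "random-canopy")


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of a synthetic landscape.

    parameters (by kind):
      flat:          elevation (default 0)
      block:         position (row, col), height, transmittance,
                     elevation, size (cells, default 1)
      ridge:         axis ("col" or "row"), index, height, elevation,
                     width (cells, default 1)
      slope:         gradient (m per cell, rising northward for axis
                     "row", eastward for "col"), axis, elevation
      random-canopy: density (fraction of vegetated cells), height_range,
                     transmittance_range, elevation, seed
    """

    shape: tuple[int, int]
    cellsize: float = 10.0
    kind: str = "flat"
    parameters: dict = field(default_factory=dict)
    xllcorner: float = 0.0
    yllcorner: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(
                f"unknown fixture kind {self.kind!r}; expected one of {KINDS}")


def _grid(spec: FixtureSpec, values: np.ndarray) -> GridRaster:
    nrows, ncols = spec.shape
    return GridRaster(ncols=ncols, nrows=nrows, xllcorner=spec.xllcorner,
                      yllcorner=spec.yllcorner, cellsize=spec.cellsize,
                      values=values)


def make_fixture(spec: FixtureSpec) -> LandscapeStack:
    """Build the landscape stack a fixture spec describes."""
    nrows, ncols = spec.shape
    p = dict(spec.parameters)
    elevation = float(p.pop("elevation", 0.0))
    dem = np.full((nrows, ncols), elevation)

    if spec.kind == "flat":
        if p:
            raise ValueError(f"unexpected flat parameters: {sorted(p)}")
        return build_landscape_stack(dem=_grid(spec, dem))

    if spec.kind == "block":
        row, col = p.pop("position")
        height = float(p.pop("height"))
        transmittance = float(p.pop("transmittance"))
        size = int(p.pop("size", 1))
        if p:
            raise ValueError(f"unexpected block parameters: {sorted(p)}")
        ndsm = np.zeros((nrows, ncols))
        otm = np.ones((nrows, ncols))
        ndsm[row:row + size, col:col + size] = height
        otm[row:row + size, col:col + size] = transmittance
        return build_landscape_stack(dem=_grid(spec, dem),
                                     ndsm=_grid(spec, ndsm),
                                     otm=_grid(spec, otm))

    if spec.kind == "ridge":
        axis = p.pop("axis", "col")
        index = int(p.pop("index"))
        height = float(p.pop("height"))
        width = int(p.pop("width", 1))
        if p:
            raise ValueError(f"unexpected ridge parameters: {sorted(p)}")
        if axis == "col":
            dem[:, index:index + width] += height
        elif axis == "row":
            dem[index:index + width, :] += height
        else:
            raise ValueError(f"ridge axis must be 'row' or 'col', got {axis!r}")
        return build_landscape_stack(dem=_grid(spec, dem))

    if spec.kind == "slope":
        axis = p.pop("axis", "row")
        gradient = float(p.pop("gradient"))
        if p:
            raise ValueError(f"unexpected slope parameters: {sorted(p)}")
        if axis == "row":  # rising northward (toward row 0)
            ramp = gradient * np.arange(nrows - 1, -1, -1, dtype=float)
            dem += ramp[:, None]
        elif axis == "col":  # rising eastward
            dem += gradient * np.arange(ncols, dtype=float)[None, :]
        else:
            raise ValueError(f"slope axis must be 'row' or 'col', got {axis!r}")
        return build_landscape_stack(dem=_grid(spec, dem))

    # random-canopy
    density = float(p.pop("density", 0.4))
    h_lo, h_hi = p.pop("height_range", (5.0, 30.0))
    t_lo, t_hi = p.pop("transmittance_range", (0.2, 0.9))
    seed = p.pop("seed", 0)
    if p:
        raise ValueError(f"unexpected random-canopy parameters: {sorted(p)}")
    rng = np.random.default_rng(seed)
    vegetated = rng.random((nrows, ncols)) < density
    heights = rng.uniform(h_lo, h_hi, (nrows, ncols))
    trans = rng.uniform(t_lo, t_hi, (nrows, ncols))
    ndsm = np.where(vegetated, heights, 0.0)
    otm = np.where(vegetated, trans, 1.0)
    return build_landscape_stack(dem=_grid(spec, dem),
                                 ndsm=_grid(spec, ndsm),
                                 otm=_grid(spec, otm))
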