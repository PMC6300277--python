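"""Shared fixture landscapes and sun states for the test suite."""

from __future__ import annotations

from datetime import datetime

import numpy as np
import pytest

from gridshade.grids import GridRaster, build_landscape_stack
from gridshade.sun import SunState


def grid(values, cellsize=10.0, xll=0.0, yll=0.0, nodata=-9999.0):
    values = np.asarray(values, dtype=float)
    return GridRaster(ncols=values.shape[1], nrows=values.shape[0],
                      xllcorner=xll, yllcorner=yll, cellsize=cellsize,
                      values=values, nodata_value=nodata)


def sun(azimuth, altitude, ei=1300.0, ei_cos=None, when=None):
    """A hand-set solar state (angles chosen by the test, not computed)."""
    if ei_cos is None:
        ei_cos = max(0.0, np.sin(np.radians(altitude))) * ei
    return SunState(timestamp=when or datetime(2008, 7, 6, 12),
                    azimuth=float(azimuth), altitude=float(altitude),
                    ei=float(ei), ei_cos=float(ei_cos))


@pytest.fixture
def block_row_stack():
    """1x16 row of 10 m cells: flat ground, a 20 m object with
    transmittance 0.4 at column 6."""
    dem = np.zeros((1, 16))
    ndsm = np.zeros((1, 16))
    otm = np.ones((1, 16))
    ndsm[0, 6] = 20.0
    otm[0, 6] = 0.4
    return build_landscape_stack(dem=grid(dem), ndsm=grid(ndsm), otm=grid(otm))


@pytest.fixture
def ridge_row_stack():
    """1x16 row of 10 m cells: flat ground with a 30 m ridge at column 7."""
    dem = np.zeros((1, 16))
    dem[0, 7] = 30.0
    return build_landscape_stack(dem=grid(dem))


@pytest.fixture
def flat_stack():
    return build_landscape_stack(dem=grid(np.zeros((8, 8))))


def recovery_landscape(n=30, cellsize=10.0):
    """Calibration test landscape: flat 100 m plateau, a 60 m ridge one
    column west of the probe (full-strength terrain shade in the
    afternoon), and a 25 m half-transmissive canopy band to the east
    (morning object shade).  Probe cell (15, 15), solar noon unshaded."""
    dem = np.full((n, n), 100.0)
    dem[:, 14] += 60.0
    ndsm = np.zeros((n, n))
    otm = np.ones((n, n))
    ndsm[5:26, 17:20] = 25.0
    otm[5:26, 17:20] = 0.5
    return build_landscape_stack(dem=grid(dem, cellsize=cellsize),
                                 ndsm=grid(ndsm, cellsize=cellsize),
                                 otm=grid(otm, cellsize=cellsize))
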