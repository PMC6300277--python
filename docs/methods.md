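# Methods

## Model

gridshade estimates ground-level incident solar energy on a raster
landscape by direct reduction: clear-sky energy arrives from a single
distant source (parallel rays, spatially uniform over the grid), and each
cell's share is reduced by whatever the ray from that cell toward the sun
passes through. Two reduction pathways are tracked simultaneously but
independently — partial attenuation through object voxels (canopies,
buildings) and binary interception by terrain — and are composed at the
end into shade fractions and energy.

Assumptions worth stating explicitly:

* **Single distant source.** Solar angles and clear-sky energy are
  evaluated once per timestep at the landscape centroid and applied to
  every cell. Fine for plot-to-watershed extents; wrong for extents where
  solar position varies meaningfully across the grid.
* **Voxel objects.** A cell's object is a column of uniform transmittance
  (optionally two stacked columns, canopy over understory). There is no
  within-crown structure, no gap dappling, no soft shadow edges, no
  reflected or diffuse-sky light. All atmospheric loss is folded into one
  calibrated multiplier.
* **Backward ray marching.** One ray per origin cell per timestep, traced
  from the ground toward the sun. Complexity is O(cells × path length),
  a deliberate middle ground between station extrapolation and full ray
  tracing.

## Solar geometry

Declination uses the standard 23.45° day-of-year sinusoid; hour angle
comes from civil time via the site longitude, the configured UTC offset
and Spencer's equation of time; altitude is the usual spherical-astronomy
arcsine and azimuth a quadrant-safe two-argument arctangent (an arccos
form is numerically treacherous near noon and cannot distinguish morning
from afternoon). Clear-sky energy applies the Earth–Sun eccentricity
correction, EI = S_sun(1 + 0.034 cos(2πn/365.25)) with S_sun = 1367 W/m².
Incident energy multiplies by the cosine of the zenith angle, i.e.
sin(altitude): an overhead sun transmits everything, a rising sun almost
nothing. Altitude at or below zero yields zero energy and no walks.

The geometry is validated against a second, independently implemented
ephemeris (Meeus/NOAA formulation: Julian centuries, orbital elements,
apparent longitude, obliquity) kept deliberately free of any code shared
with the model; hourly daylight agreement is checked as r² in the test
suite and the acceptance script.

## The walking algorithm

Per timestep the step vector (run = sin α·v east, rise = cos α·v north,
v defaulting to cellsize/4) is computed once and shared by all origins.
Cells are *discovered* by marching the sampling point; they are *assessed*
at the ray height over the horizontal distance from the origin center to
the entered cell's center. Consequences of that split:

* transmittance applies exactly once per distinct cell entered, so the
  result is independent of v (for v ≤ cellsize/4) — per-step application
  would raise a canopy's transmittance to the ~4th power;
* the quantity driving object/terrain tests at a cell is the same no
  matter how the sampling lands within the cell, which makes cast-shadow
  extents exactly the analytic ⌊h/tanγ/cellsize⌋ for a column of height h.

Two distances are therefore tracked: metres from the origin feed the ray
height; the count of distinct cells entered feeds the terrain-shade
denominator.

Numerical and boundary choices:

* A sampling point landing exactly on a cell edge belongs to the cell
  ahead in the walk direction; a ray grazing the ground (T_DH = 0) does
  not terminate.
* A single march step can cross a column boundary and a row boundary at
  once; the two crossings are visited in their order along the step
  segment, so no crossed cell is ever skipped (the march enumerates the
  ray's supercover, in the marching-squares sense). An exact lattice-corner
  hit passes diagonally and touches neither off-diagonal neighbor.
* The walk starts at the origin's ground elevation (plus any configured
  sensor height) and never assesses the origin's own cell — a vegetated
  cell does not shade itself.
* Termination: terrain penetration, leaving the data extent, or ray
  height reaching the landscape ceiling max(DEM + nDSM), above which
  nothing can intercept. The terminating terrain cell contributes terrain
  shade; its object (if any) is not additionally applied.
* Nodata DEM cells are excluded as origins (outputs carry nodata there)
  and are transparent and non-blocking when encountered mid-walk:
  fabricating shade from unknown terrain would bias energy downward.
  Cells outside the area-of-interest mask are excluded as origins only —
  they still cast shade, so reported physics does not depend on the
  reporting region.
* Stacked voxels are sampled at a single height per cell: whichever voxel
  contains the ray height (canopy, or understory below its top)
  contributes its transmittance.

## Outputs

Object and terrain shade compose through the ground light fraction
L = O_LD·(1 − T_SHADE): Shade_TOTAL = 1 − L and Energy = L·EI_cos, so 0
means no shade and an unshaded cell keeps the full incident energy, and
the decomposition identity 1 − Shade_TOTAL = (1−O_SHADE)(1−T_SHADE) holds
cell-wise by construction. Shade averages over an aggregation window use
daylight timesteps only (shade is undefined without incident light);
night timesteps contribute zero energy. Accumulated energy is
Σ energy × timestep seconds (J/m²). PAR conversion uses a configurable
full-spectrum shortwave → photon-flux factor, default 2.02 µmol s⁻¹ W⁻¹ —
a generic conversion; the proper factor depends on sky state and sensor.

## Calibration

The workflow is: baseline run (cs = 1, tr = 1, gr = 0.5); CS_CALI from
the peak-energy relation cs = 1 − (PSE_sim − PSE_obs)/PSE_obs; then
TR_CALI and GR_CALI by a deterministic grid search (default step 0.005
over (0, 1], order configurable — calibrate the dominant influence
first) minimizing RMSE at a single probe cell, with the configured sensor
height added to the probe's walk origin. A grid search replaces manual
visual fitting so the workflow is reproducible and testable.

Properties of the peak relation worth knowing:

* It is a first-order correction, not a ratio match: a relative peak
  mismatch ε leaves a residual of about ε² after recalibration. The
  acceptance test asserts exactly this second-order bound.
* That residual propagates into the GR search roughly in proportion to
  the cells_walked of the terrain hits at the probe. The parameter-recovery
  experiment therefore places blocking terrain adjacent to the probe
  (terrain shade at full strength), where recovery is sharp: measured
  errors ~0.004 (cs), 0.000 (tr), 0.005 (gr) at the 0.005 search
  resolution, for true values (0.94, 0.945, 0.2).
* For a peak over-prediction of 2× or more the relation goes non-positive;
  the workflow floors CS_CALI at the search resolution with a warning.

Fit statistics are mean error (sim − obs), RMSE, and percent agreement
defined as Σobs/Σsim, so systematic over-prediction gives values below
one. Percent agreement has no single established definition; this ratio
was chosen for interpretability and is reported alongside RMSE, never
alone. Values of CS/TR_CALI above 1 (observed peak above simulation) are
warned about but not clamped.

## Synthetic landscapes and the transport oracle

All test landscapes are generated programmatically: flat plains, single
blocks, terrain ridges, uniform slopes, and seeded random canopies
(vegetation density 0.4, heights uniform 5–30 m, transmittances uniform
0.2–0.9 — magnitudes typical of conifer stands on 10 m cells). They
emulate the geometry the model reasons about — heights, transmittances,
terrain relief — and nothing else: no spatial autocorrelation of real
canopies, no correlated height/transmittance structure, no sensor noise
in "observed" series (calibration observations are the simulator's own
output). Passing tests therefore demonstrate the light-transport and
calibration machinery, not field accuracy against instruments.

The brute-force transport oracle marches a 3-D point along the exact sun
direction at a fine horizontal step (default cellsize/50, with none of
the engine's per-timestep rise/run caching or quarter-cell stepping),
enumerates every crossed cell at its own resolution, and assesses each at
the model-defined center-distance height. Agreement (≥ 99 % of cells
required; measured 100 %) is evidence because the traversal code paths
are disjoint; residual disagreement is expected only for rays grazing
cell corners. Halving the oracle's step changes no result on the
reference fixtures.

## Problem sizes

The validation suite uses 20×20-cell random canopies (20 landscapes × 10
sun positions for oracle equivalence), 21×21 shadow-geometry fixtures, a
30×30 calibration landscape at 30-minute grain over one day, and hourly
one-day end-to-end runs on 8×8 grids — sizes at which every property is
checked exhaustively per cell while the whole suite stays fast.

## Known limitations

* Direct beam only: no diffuse-sky fraction, no reflected light, no
  soft shadow edges; cloud cover is a flat daily multiplier (1 − cloud_fraction),
  the minimal defensible reading of a daily percentage input.
* Strict co-registration is required; there is no reprojection or
  resampling, and only the ESRI ASCII grid format is read and written.
* Runtime grows with grid size × ray length; the pure-Python engine is
  sized for plot-to-small-watershed experiments, not regional 1 m rasters.
* Calibration is single-probe; multi-site joint calibration and parameter
  uncertainty are out of scope.
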