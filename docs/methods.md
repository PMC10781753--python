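# Methods

`coastsqueeze` implements a transect-based accounting of *coastal
squeeze*: the loss of the space available to sandy-coast ecosystems,
trapped between rising seas on the seaward side and fixed human
infrastructure on the landward side. This note describes the measurement
model, the conventions the package fixes where the method leaves choices
open, what the synthetic-world generator does and does not emulate, and
the known limitations.

## The measurement model

**Transects.** Straight sampling lines of fixed length *L* (default
25 km) are cast landward, perpendicular to the shoreline, at fixed
arc-length interspacing (default 1 km), only where the coast is
classified as sandy. Perpendicularity on a discretized polyline is not
unique; the package uses the segment direction inside a segment and the
angle bisector of adjacent segments at a vertex (preceding segment on a
180° reversal). Origins sit at arc multiples measured from each part's
start, endpoints included; both conventions are configurable.

**Infrastructure-free width.** Two proxies are measured per transect as
the distance along the transect to the first crossing of a structure:

* *all* — buildings, freeways, car roads, paved bike/pedestrian paths;
* *heavy* — buildings and freeways only.

Distance is along the transect line: a structure that does not cross the
transect contributes nothing however close it is. Building interiors
count (a transect starting inside a building has width 0); roads are
crossed at their centerline, road width ignored. A transect with no
qualifying structure within *L* is *censored*: the flag is explicit and
the censor limit (= *L*) is carried with the record, never a sentinel
width.

**Censoring rule for medians.** Censored records enter order statistics
at their censor limit. A group median is reported as a value only when
it falls below the limit; otherwise only the lower bound "median >
limit" is known and the record is flagged. Because realistic medians
(hundreds of meters) sit far below a 25-km limit, censoring cannot bias
them; the rule makes that explicit. Below-threshold fractions are
unaffected for any threshold below the limit.

**Natural obstructions.** A transect is excluded when a natural barrier
precedes the first structure:

* *cliff* — the maximum seaward slope before the structure exceeds the
  angle of repose of dry sand, 34°, strictly. Slopes are finite
  differences of bilinearly interpolated elevations at a 30-m step
  (typical coastal-DEM cell size; configurable), `atan(Δz/step)` per
  interval, positive when the terrain rises landward. A numerical guard
  of 10⁻⁹ degrees keeps a ramp at exactly the threshold angle from being
  flagged by floating-point rounding.
* *shoreline re-intersection* — the transect crosses the shoreline again
  (narrow strip, island) before the structure. Crossings within 1 m of
  the origin are the transect's own start and are ignored.
* *DEM latitude limit* — coastal elevation models lose validity at high
  northern latitudes; transects above 60°N (northern hemisphere only by
  default, symmetric on request) cannot be slope-checked and are
  excluded outright.

Precedence is DEM limit > re-intersection > cliff, and the cliff test is
evaluated per width category: a cliff between the first paved path and
the first building excludes the *all* record while the *heavy* record
stands. "Maximum seaward slope" is read as the maximum seaward of the
first structure (consistent with "barrier before structure"); the
whole-transect maximum is also reported in the profile.

**Aggregation conventions.** Lower median on even counts, nearest-rank
percentiles, strict `<` for below-threshold fractions, half-open
latitude bands `[b, b+Δ)`. Latitudinal band profiles expose both mean
and median since zonal bar summaries conventionally use the mean while
squeeze comparisons use the median.

**Socio-economic regression.** Population density is sampled
nearest-cell along the full transect from a ~1-km raster (coarser than
the station spacing, so interpolation would be spurious), reduced to a
per-transect median (standard interpolated median, matching the
continuous density field) and then to country medians. The country-level
model is OLS of median width (meters, untransformed) on log₁₀ median
density and log₁₀ GDP per capita; only the explanatory variables are
log-transformed, a log-response variant sits behind a flag for
sensitivity. Base-10 logs are recorded in the fit report; the base moves
coefficients, not R². Countries with non-positive predictors or a
censoring-bound median are rejected with a count.

**Protection comparison.** A transect is *protected* when its first
2 km (closed interval — touching at exactly 2,000 m counts) intersect a
protected-area polygon, and *urban* when its median transect density is
≥ 300 persons/km² (the European urban-cluster threshold; the ≥ side is a
convention, configurable). Protected vs non-protected widths are
compared with a two-sided Wilcoxon rank-sum test — normal approximation
with tie correction and 0.5 continuity correction, reporting Z — and the
four urban/protection groups with a Kruskal-Wallis test (tie-corrected
χ², df = groups − 1) followed by pairwise rank-sum posthocs at the
Bonferroni level α/6. For pooled samples of ≤ 10 values both tests
switch to exhaustive permutation enumeration, where the normal and
chi-square approximations are visibly inaccurate; every realistic sample
size uses the asymptotic path.

**Sea-level-rise exposure.** Each transect is matched to the nearest
point of a shoreline-retreat projection field (RCP 4.5 / RCP 8.5, 2100,
50th percentile) within 0.05° (~5.6 km): great-circle distance in the
geographic frame, the equatorial-meter equivalent (plain Euclidean) in
the planar frame; a per-axis box metric is available by flag; distance
ties break toward the lowest point id. The residual accommodation space
is width − retreat; *lost* means residual ≤ 0 (boundary inclusive).
Shoreline advance (negative retreat) is not clamped. A censored width
stands at its censor limit, so it is never lost under any retreat below
that limit — a documented consequence of the censoring convention.

## The synthetic-world generator

Real inputs at global scale (coastlines, building footprints, coastal
DEMs, population rasters, protected-area polygons, retreat projections)
are not reproducible at desk scale, so the pipeline is validated on
generated worlds whose truth is known *by construction*: infrastructure
is placed on the landward side at a perpendicular offset drawn from the
width distribution, so the true width equals the placed offset; cliffs,
protection rectangles, urban density bands and retreat values are
likewise recorded as placed.

Default conditions emulate the global study's statistical structure: a
positively skewed log-normal width with median 392 m and log-sd 1.2; 7%
of stations with no structure within reach; a class mix of 40%
buildings, 10% freeways, 35% car roads, 15% paved paths; heavy widths a
median 4× beyond a light first structure (multiplier clamped at 1 so the
heavy structure never precedes the first structure); 4% cliff-limited
stations at 45° ramps; 16% protected shore whose widths are 4× larger;
urban patches of 1,500 /km² against a rural 50 /km² (straddling the
300 /km² threshold); fixed 2100 retreats of 161 m (RCP 4.5) and 209 m
(RCP 8.5), consistent with roughly a quarter of a median-392-m
log-normal shore losing its free space. GDP per capita is log-uniform
over 10³–10⁵ per synthetic country. One seed drives every draw;
identical specs serialize byte-identically.

Exactness depends on the coastline shape. On a *straight* coast every
truth column is exact: shore-perpendicular transects are parallel, so
alongshore bands (cliff ramps, density columns, protection rectangles,
±400 m around each 1-km station) can never interfere across transects,
and DEM ramp breakpoints are snapped to cell centers so bilinear
sampling reproduces the ramp exactly. A *sinusoidal* coast (300 m
amplitude, 20 km wavelength) keeps widths exact — the curvature bound
guarantees neighbouring transects stay separated beyond the feature
half-width over 25 km — but carries no cliffs, protection or urban
bands. *Island* and *peninsula* shapes exist for re-intersection
geometry (known crossing distances 2R and the strip width) and place no
infrastructure, because a structure on one shore could be nearer to a
transect from the opposite shore than its own placed offset. The
pseudo-geographic mode maps the alongshore axis to latitude (coast along
a meridian, transects cast east with a per-transect cos-latitude
scaling) for exercising the 60°N limit and degree-based retreat
matching; rasters on degree grids cannot carry exact per-station bands,
so that mode runs without cliffs or urban patches.

What passing tests on these worlds show — and do not show. They show
the measurement, exclusion, labelling, matching and statistical
machinery is correct against known geometry and known distributions.
They do not show anything about real coastlines: fractal shoreline
geometry, structures not centered on transects, road networks crossing
many transects obliquely, DEM noise and datum error, misregistered
rasters, or tagging errors in real infrastructure data have no synthetic
counterpart here.

## Numerical choices

* Geodesy: per-transect local equirectangular frames (east scaled by
  cos φ of the origin); over 25 km the distortion is negligible relative
  to the 0.1-m geometric tolerance, and planar worlds remove projection
  error from ground truth entirely.
* Geometric tolerances: perpendicularity to 10⁻⁹, spacing to 10⁻⁶ m,
  oracle agreement to 0.1 m (the stepping resolution), re-intersection
  origin guard 1 m.
* Degenerate inputs: zero-length tangents raise; parts shorter than one
  vertex pair are skipped with a warning; invalid geometries are skipped
  per feature with a logged warning; all-nodata elevation profiles mark
  the transect as beyond DEM coverage; empty groups yield flagged
  rows (n = 0), not errors.
* Problem sizes: the default validation world uses ~1,100 transects
  (1,100 km of coast), the distribution-level checks 3,000–10,000
  stations with a coarsened (300 m) DEM — sizes at which Monte-Carlo
  tolerances (binomial bounds, 3σ of a sample fraction) are already
  tight while the full suite runs in about a minute.

## Limitations

* Road width is ignored (centerline crossing), dikes and unpaved
  seawalls are out of scope, and there is no handling of real-world
  attribute schemas beyond the four-class mapping.
* The regression is correlative; no spatial autocorrelation structure is
  modelled, and country medians inherit the censoring convention.
* Retreat projections enter as given point values; no shoreline-change
  modelling, sediment budgets, or uncertainty propagation beyond the
  50th-percentile scenario values.
* The synthetic generator has no width–density or width–GDP coupling;
  regression behaviour is validated on purpose-built country tables with
  known coefficients rather than through the world generator.
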