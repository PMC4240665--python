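# Methods

## The measurement problem

Percussive use turns the struck face of a stone into a field of
microscopic conchoidal fractures — dense small-scale peaks and ridges —
while fluvial abrasion produces rounded cupules with smooth deep bases and
rounded high bosses. `percmorph` quantifies this contrast by analysing the
scanned surface as a micro-landscape: rugosity is mapped with a
topographic position index (TPI), spatially coherent rugosity is isolated
with the Getis-Ord Gi* hot-spot statistic, and the geometry of the
significant clusters is summarised in two shape metrics that are compared
across specimen groups nonparametrically.

## Pipeline stages and their assumptions

**TIN → DEM.** Scan meshes (PLY/OBJ/STL, assumed millimetres; unit
metadata in files is ignored) are projected along one coordinate axis —
by default the axis of smallest bounding-box extent, i.e. the surface
normal of a roughly planar patch — onto a regular grid. Each covered cell
centre receives the barycentric linear interpolation of the covering
triangle; where a folded or closed mesh covers a centre more than once
the triangle nearest the viewer wins, so closed scans need no
pre-cropping. Cell values are point samples at cell centres (the standard
linear TIN-to-raster rule), and the default pitch is the mesh's median
unique-edge length, matching the information content of the scan. The
projection assumes the analysed patch is single-valued along the chosen
axis; strongly curved whole-object scans should be cropped to the damaged
face first.

**TPI.** `TPI_i = z_i − mean(z_j)` over a moving window, excluding the
focal cell by default. The default window is a 7×7 square (radius 3
cells); an annulus window is available. TPI is insensitive to adding a
constant and scales linearly with the field; broad convex curvature of
the specimen enters only weakly at this window size, which is what makes
the index usable on domed cobble faces. Cells whose window is not fully
covered by data are **masked, not computed**: a truncated asymmetric
window on a sloped or domed surface yields a biased TPI, and at the
default per-cell significance of 0.001 that bias alone would paint a
spurious significant ring along the raster border. The coverage threshold
`min_coverage` therefore defaults to 1.0 (full window); lowering it trades
a wider usable margin against edge bias.

**Gi\*.** Binary symmetric weights over the valid cells: queen3x3
(8 neighbours + self, the default — the smallest self-inclusive
neighbourhood, maximising spatial resolution of damage patches) or a
Euclidean distance band in cell units. The statistic uses the population
standard deviation and excludes invalid cells from `n`, `X̄`, `S` and all
neighbour sums. z-scores are converted to two-tailed normal p-values; a
cell is hot (cold) when z ≥ z_crit (≤ −z_crit) with z_crit ≈ 3.29 at the
default alpha = 0.001. No correction across cells is applied: the
published procedure this implements thresholds each cell at p < 0.001.
A cell whose neighbourhood covers every valid cell has zero variance term
and is marked invalid with a warning.

**Polygons.** Significant cells of one class are grouped by 8-connectivity
(4 available); components smaller than `min_cells = 3` are dropped as
significance speckle. The outer boundary is traced along cell edges —
deliberately un-smoothed, because the staircase perimeter of a jagged
cluster *is* the signal; smoothing would systematically shrink it.
Interior hole rims are not added to the perimeter. Area is
`cell_count × cell_size²`; maximum length is the largest pairwise
boundary-vertex distance and maximum width the extent perpendicular to
that axis. **Volume** is defined against a least-squares plane fitted to
the ring of unmasked cells immediately surrounding the polygon — the
local undamaged reference surface: material above the plane for hot
polygons, void below it for cold ones, summed over the polygon's cells.
Fitting to the exterior ring (rather than the polygon's own rim) is what
makes a flat-topped plateau of height h and footprint A measure h·A, a
hemispherical pit measure (2/3)πr³ in the fine-grid limit, and any
polygon on a tilted plane measure zero. The ratio `perimeter²/volume`
squares the perimeter to cancel the allometric advantage of volume
(three growth dimensions) over perimeter (two): under uniform scaling by
k the ratio goes as 1/k, so shape, not size, dominates. It is undefined
(and the polygon flagged) below a volume floor of `0.01 cell_size³`. The
per-specimen hot/cold area ratio defaults to the ratio of mean polygon
areas; a total-area mode is available.

**Statistics.** Two-sided Mann-Whitney U via midranks, reported as
min(U_a, U_b). With both samples ≤ 10 and no ties the exact
(enumeration) null distribution is used; otherwise the normal
approximation with tie and continuity corrections. Bonferroni multiplies
by the number of pairwise comparisons actually tested per metric (logged
in the output). For perimeter²/volume the observations are hot polygons
pooled across a group's specimens — this follows the published analysis
design, and the within-specimen clustering it ignores is noted as a
caveat in the comparison metadata; for the hot/cold ratio observations
are per-specimen.

## The synthetic surface model

The simulator exists to validate the discrimination end to end with known
ground truth, emulating the study design of roughly twenty experimental
hammerstones versus a dozen naturally pitted cobbles.

All classes share one base surface: a 15×15 mm patch at 0.1 mm pitch, a
1 mm convex dome (water-worn cobble curvature), a faint correlated polish
texture (s.d. 0.8 µm, correlation length 0.2 mm) and uncorrelated scanner
measurement noise (s.d. 8 µm, the dominant texture term at this pitch for
a triangulation laser scanner). Because the damage generators differ only
in feature construction, any detected class difference is attributable to
damage morphology.

*Natural* surfaces carry three cupules with a Gaussian depth profile
(radius 2.0–2.6 mm, depth 0.6–0.9 mm) — the profile blends tangentially
into the surface, encoding rounded perimeters and smooth deep bases
without any rim discontinuity — plus five smooth rounded bosses
(spherical caps, radius 0.5–0.8 mm, height 0.18–0.28 mm), the rounded
knobs abrasion leaves standing proud. The bosses matter: they are the
"limited hot spots" of an abraded surface, compact and genuinely
voluminous, which is what gives natural hot polygons their low
perimeter²/volume.

*Anthropogenic* surfaces carry three circular patches (radius 2 mm) of
crushed texture: a correlated ridge-and-hollow bed (amplitude 0.04 mm,
correlation length 0.25 mm) whose negative side is damped to 20% —
crushed debris partly fills the hollows, the reason percussive damage
rarely forms coherent cold spots — overlaid with sharp sub-cell peaks
(half-normal, scale 0.08 mm) and shallow notches (scale 0.025 mm) at
8 per mm², on a faint 0.05 mm basin. The `rim_smoothing` parameter
(0.3 mm) smooths that basin's edges.

Every surface returns a ground-truth damage mask, so sensitivity and
specificity of the full pipeline are measurable per parameter setting.

### What the defaults deliver (and do not)

With default pipeline settings the frozen generator gives: zero
significant polygons on ≈96% of undamaged surfaces; complete per-surface
separation of median hot-polygon perimeter²/volume (anthropogenic
≈650–1250 mm⁻¹ vs natural ≈150–350 mm⁻¹); hot/cold area ratios of
≈1.0–2.0 (anthropogenic) vs ≈0.3–1.0 (natural); and every damage patch
overlapping detected polygons, with 15–30% of truly damaged cells
individually flagged. That last figure is a deliberate trade-off: at a
per-cell threshold of |z| ≥ 3.29 with a small window, only the locally
coherent extremes of a crushed patch clear the bar. Pushing per-cell
sensitivity toward one-half would require damage dense and strong enough
to saturate the texture, which destroys the very shape contrasts the
method measures and the specificity on undamaged stone. Detection here is
patch-level, not cell-level.

What passing the synthetic benchmark does **not** show: that the
discrimination holds on real scans with registration error, lithology
dependent texture (quartz vs basalt), weathering, or damage classes
outside the two modelled morphologies. The generator's parameters are
calibrated to qualitative descriptions of such surfaces, not to measured
roughness spectra.

## Numerical choices

- Degenerate mesh faces (area < 1e-12 mm²) are dropped, never repaired.
- TPI neighbour counts from convolution are rounded to integers before
  thresholding, so coverage masks are exact.
- Gi* denominators use the population s.d.; p-values via `erfc` for
  precision in the far tail.
- Polygon extraction orders components row-major by topmost-leftmost
  cell; all CSV output uses a fixed float format, so outputs are
  byte-stable across runs.
- Plane fits with fewer than three ring cells (or rank-deficient
  geometry) fall back to the mean ring elevation, logged.
- Mann-Whitney with all observations identical returns p = 1 with a
  warning rather than dividing by a zero tie-corrected variance.
- All randomness flows from `numpy.random.default_rng` seeds; benchmark
  per-surface seeds derive deterministically from the master seed.

## Known limitations

- Volume is measured relative to the polygon's immediate surroundings, so
  a broad smooth swell detected only at its crest reports the crest's
  prominence, not the landform's full bulk. The two study metrics were
  designed around this behaviour.
- 3D (mesh) surface area of polygons is not computed; planar area is
  reported, with perimeter/area emitted alongside perimeter²/volume.
- Polygon-level pooling understates uncertainty when specimens contribute
  many polygons; a mixed-model treatment is out of scope.
- The per-cell p < 0.001 rule performs no multiple-testing correction
  across cells, staying faithful to the published procedure; an optional
  Benjamini-Hochberg mode (`classify_cells(..., fdr=True)`) is available
  for sensitivity analysis and is off everywhere by default.
- Gi* p-values rely on the normal approximation, which is accurate for
  the window sizes used (tested against a Monte-Carlo null) but degrades
  for windows covering a large fraction of the raster.
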