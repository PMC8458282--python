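# Methods

`rdmorph` quantifies regional photoreceptor loss in the murine
retinal-detachment (RD) model from axial whole-eye cryosections.  This note
describes the measurement models, the synthetic phantom that stands in for
real cryosections, the statistical procedures, and the numerical choices
behind them.

## The measurement problem

Subretinal injection of sodium hyaluronate lifts the neurosensory retina off
the retinal pigment epithelium (RPE) as a bullous dome roughly 1.1 mm high.
Photoreceptor death is read out in the outer nuclear layer (ONL) through
three quantities: the ONL nucleus count in a 400 µm segment, the ONL
thickness, and the ONL/INL thickness ratio (the inner nuclear layer is
largely spared, so dividing by it corrects for oblique sectioning).  Because
cell loss differs sharply between the top of the dome (detached apex) and
the stretched region near the injection site (detached base), all
measurements are reported per region, with regions defined by arc length
along the ONL relative to the detachment peak.

## Layer thickness: perpendicular callipers

`morphometry.thickness_profile` measures a band-shaped layer mask the way
calliper-style plugins do:

1. The band's two long boundaries are recovered by ordering its skeleton
   (double-BFS diameter of the skeleton pixel graph; cycle traversal for
   closed bands such as annuli), trimming twice the median half-width at
   open ends, and casting rays from each skeleton point along both normals
   to the sub-pixel 0.5-crossing of the mask.
2. Stations are resampled along the outer (scleral-side) boundary at the
   calliper interval (1 px by default, matching 1 µm at the default scale).
3. At each station the tangent is a least-squares fit over a 7-point
   window; the thickness is the chord along the inward normal to the point
   where bilinear interpolation of the mask drops below 0.5, marched at
   0.25 px steps with linear refinement of the crossing.

Stations whose chord leaves the image, or whose normals are undefined, are
dropped and counted, never interpolated.  On an axis-aligned rectangle the
procedure is exact; on a 100/150 px annulus every station is within 1 px of
the analytic width.  An independent cross-check used only in tests is twice
the maximum medial-axis inscribed radius, which equals the band width for
uniform bands and is immune to skeleton end spurs.

Mask-traced profiles start their arc at the first valid station.  Region
intervals live on the tile's ONL outer boundary, so
`morphometry.align_profile_arc` reprojects each station onto that reference
curve before region statistics are computed.

## Detachment height and peak

`morphometry.rd_height` implements a straight calliper from an RPE station
to the outer ONL boundary, perpendicular to both layers: the ray is first
cast along the RPE normal, then re-aimed along the average of the RPE
normal and the ONL normal at the actual hit point (two fixed-point
iterations).  If the final direction is within 10° of both layer normals
the chord length is reported; otherwise the nearest distance to the ONL
curve is used and the measurement flagged as non-perpendicular.  On the
bullous dome the perpendicular solution exists near the peak and over the
attached retina; on the steep flanks the fallback fires by design.

`regions.locate_rd_peak` scans RPE stations (8 µm coarse grid, ≤1 µm
refinement), calls a specimen detached where the height exceeds three times
the attached ONL-to-RPE gap (10th percentile of heights unless given), and
returns the height maximum.  Exact ties form a plateau and the plateau
centroid is returned, so a flat-topped dome yields its centre.  The peak is
reported in both arc coordinates — along the RPE (where the calliper
stations live) and along the ONL (where the regions live).

## Regions of interest

Four 400 µm ONL-arc segments: detached apex (edge touching the peak on the
peripheral/sclerotomy side), detached base (near edge 500 µm peripheral of
the peak), attached central (anchored at the posterior end of the attached
arc) and attached paracentral (adjacent, toward the detachment).  The
100 µm transition zone flanking the detachment edge is excluded from every
ROI; which side is peripheral is a configuration flag, not inferred from
anatomy.  ROI crop outlines are parallel offsets of the ONL outer boundary;
nuclei cut by the outline are attributed by centroid position, which keeps
counts unbiased under small ROI translations.

## Automated ONL counting

`nuclei.count_onl_nuclei` is a deterministic, phantom-verifiable stand-in
for the automated DAPI counters used in this literature:

rolling-ball background subtraction (radius 50 px; the image is first
scaled to an 8-bit-like range so the ball's intensity radius — and hence
the count — is invariant under intensity rescaling, and large balls run on
a downsampled copy as in the classic implementation) → light Gaussian
denoise (σ 0.5 px) → Otsu threshold inside the ONL mask → hole filling →
watershed of the distance transform.  Watershed seeds are local maxima of
the background-subtracted DAPI signal smoothed at σ 0.8 px; maxima closer
than half the expected nucleus diameter (4 µm by default) merge into one
seed, and every thresholded component receives at least one.  Finally,
watershed regions smaller than 25% of the median nucleus area are
discarded, and clumps larger than 2.5× the median contribute
`round(area / a_pair)` nuclei.

The divisor `a_pair` is self-calibrated per image as the median area of
watershed regions living in components the watershed did split.  Touching
nuclei occupy visibly more thresholded area each than isolated ones (their
union dilates at the threshold), so dividing clump areas by the global
median systematically overestimates multiplicity; the self-calibrated
divisor removes that bias and is stable against the ±1 px² quantisation of
the median at this pixel scale.  Seeding on the DAPI signal rather than on
the distance map is what separates heavily overlapping pairs: their
intensity maxima stay distinct down to about 2 px separation, where the
smoothed distance map has long since fused.

On phantoms at the study's packing density the counter stays within ~1% of
ground truth at overlap fraction 0.10 and within ~2% at 0.25; the tested
guarantees are 3% and 8% respectively.

## Relative ONL-thickness heatmap

Station thicknesses divided by a reference — an explicit value or the
median ONL thickness over the attached central ROI (the default, since all
regional comparisons are normalized to that region).  The overlay paints
ONL pixels by their nearest station's value through a viridis ramp clipped
to [0.4, 1.2]; the clip makes the apex/base contrast visible while the
serialized CSV keeps full precision (round-trips bit-identically).  The
display is qualitative by design; only relative ordering is asserted in
tests.

## The synthetic phantom

`phantom.generate_phantom_tile` builds a cryosection stand-in with known
ground truth:

* **Geometry.**  The RPE is a shallow circular arc (radius 12 mm).  The
  outer ONL boundary rides at a 20 µm subretinal gap, elevated over the
  detached footprint by a cosine bell whose peak puts the RPE→ONL distance
  at 1126.75 µm.  The ONL (94.20 µm) and INL (47.10 µm) bands are *normal
  offsets* (parallel curves) of that deformed boundary, so
  perpendicular-calliper thickness equals the constructed value on the
  steep flanks too; radial offsets would not have that property.  The
  construction is valid while the bell's curvature radius exceeds the total
  band depth, which the spec validator enforces.
* **Stretch.**  A multiplier on both nuclear linear density and band
  thickness ramps from 1 to `base_stretch` (default 0.81) between 450 and
  500 µm peripheral of the peak — the detached base is stretched, the apex
  spared, mimicking the mechanical stretching toward the sclerotomy.
* **Nuclei.**  Radii ~N(2.0, 0.2) µm; arc positions drawn from the density
  profile (312.5 nuclei per 100 µm of ONL arc, i.e. ≈1250 per 400 µm
  attached segment); dart-throwing placement with hard-core separation
  1.02× the radius sum, relaxed to a uniform 0.6–1.0× for a fraction of
  candidates equal to the overlap fraction (default 0.10).  Placement
  failures after 80 attempts are dropped, which at the study density costs
  ≈2% of the Poisson target — counts are therefore always compared against
  the recorded ground truth, not the nominal expectation.  INL nuclei are
  placed at matched areal density.  Rendering: 2-D Gaussian blobs
  (σ = radius/2, amplitude 6000·N(1, 0.15²)) on a background of 200 with
  read-noise SD 8, 16-bit.
* **Ground truth.**  Every centroid with its ONL-arc position, per-region
  counts and analytic band thicknesses, the peak position in both arc
  systems, and the layer boundary curves.  Identical (spec, seed) pairs are
  bit-identical.

What the phantom does **not** emulate: optics (PSF, vignetting, uneven
illumination), chromatin texture within nuclei, 3-D sectioning effects,
rod/cone subtypes, staining variability, and tissue folds.  Passing tests
therefore demonstrate correctness of the measurement chain on idealised
geometry and realistic packing density, not robustness to real-world
acquisition artefacts; the counting parameters would need re-validation on
real DAPI tiles.

The default scale is 1 µm/px (configurable); acquisition scale is otherwise
unconstrained, so all defaults are stated in µm.

## Cohort simulation

`phantom.generate_cohort_table` draws cross-sectional cohorts: each animal
is euthanised at one timepoint (days 0, 1, 7, 14) and contributes one tile
with all four regions; per (region, day) cell the ONL count and ONL/INL
ratio are truncated-Gaussian (resampled below zero) with the cell's mean
and SD.  `published_cohort_design` carries the published group statistics,
with two documented choices: the attached regions, reported as unchanged
over time, keep their day-0 statistics at later days; and where the
baseline and longitudinal figures print slightly different day-0 ratio
values the longitudinal series is used, keeping each region's time course
internally consistent.  The default n is 6 animals per day, inside the
published 4–7 range.

## Statistics

* **Normalization (RD/AR).**  Each tile's regional values divided by the
  same tile's attached-central values; the reference region is exactly 1.
* **Cell-death rate.**  OLS of the metric on day over per-sample
  observations; the p-value is the regression F-test, identical to the
  slope's two-sided t-test for one regressor.  With equal n per day the
  per-sample slope equals the slope on day means (asserted numerically).
* **Group comparisons.**  One-way ANOVA with Tukey HSD (Tukey–Kramer for
  unequal n) for multi-group designs; Student t-tests for two groups, Welch
  behind a flag; Shapiro–Wilk normality reported but never used to switch
  the test family; α = 0.050 throughout.  The Tukey p-values are computed
  directly on `scipy.stats.studentized_range` and cross-checked against
  statsmodels in the tests; inside the replicate simulations pass/fail
  decisions use a cached critical value and exact p-values are evaluated
  only for reported contrasts, which keeps a 500-replicate run near 100 s.
* **Degeneration criteria.**  Per detached region, eight sub-criteria:
  (1/2) at day 0 no significant reduction of the count/ratio relative to
  either attached region, and (3/4) progressive reduction over time — a
  significant day-0 vs day-14 Tukey contrast in the decreasing direction
  with no significant increase between any earlier and later timepoint.
  Each is scored on absolute (a) and tile-normalized (b) values; a region
  is fit to demonstrate progressive degeneration iff all eight pass.
  "Progressive" is deliberately *not* operationalised as monotone sample
  means: small non-significant upticks (the apex ratio rises from 1.05 to
  1.08 between days 7 and 14 in the source data) must not veto an
  otherwise unambiguous decline.
* **Case studies.**  (1) per-region ANOVA of normalized metrics across
  days; (2) two-group t-tests day 0 vs day 7/14; (3) apex and base tiles
  pooled at a timepoint and shuffled into two groups with a seeded
  generator (sizes differ by at most one for odd pools) — the design that
  masks regional differences.  Non-detections where the model truly
  degenerates are annotated as type II errors.

## Problem sizes

The default full phantom is 1480×3960 px (≈3.9 mm of arc, ~14,500 ONL
nuclei) and generates in ~10 s; counting experiments use a compact
fully-attached phantom (280×840 px, one 400 µm segment of ~1250 nuclei).
The replicate simulations in the test suite use 500 cohorts (n = 6/day) for
the criteria and case-2 rates and 1000 seeded shuffles for the case-3 null;
`scripts/acceptance.py` reports the same quantities at 200/400 replicates,
sizes at which the binomial standard error of every reported rate is
already below two percentage points.

## Known limitations

* Boundary tracing assumes a band-like mask; masks with branches, holes or
  extreme curvature (bell curvature radius approaching the band depth)
  raise topology or validation errors rather than returning degraded
  numbers.
* Stations within roughly two band-widths of a cut section edge are
  trimmed or dropped; profiles of very short segments are correspondingly
  sparse.
* The ONL/INL ratio divides means over the same ONL-arc interval; the INL
  profile's own arc differs slightly on the steep flanks, a second-order
  effect at the reported precision.
* Counting accuracy is validated against the phantom's blob model only;
  the published counter it stands in for is not redistributed here, and no
  claim of equivalence to it is made.
* The criteria evaluation treats animals as independent (the source design
  is cross-sectional); longitudinal correlation modelling is out of scope.
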