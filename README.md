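# rdmorph

Regional photoreceptor-degeneration morphometry for the murine
retinal-detachment model.

## The problem

Subretinal injection of sodium hyaluronate detaches the mouse neurosensory
retina from the RPE as a bullous dome ~1.1 mm high, and photoreceptors in
the outer nuclear layer (ONL) die at rates that differ sharply across the
detached retina: the region at the top of the dome (detached apex) loses
cells progressively, while the stretched region near the injection site
(detached base) starts ~20% thinner at day 0 and then barely changes.  An
analysis that ignores this regional structure — or samples the wrong
region — fails to detect true degeneration (a type II error).

`rdmorph` implements the full regional analysis for axial whole-eye
cryosections, for researchers quantifying photoreceptor death in this
model:

* **morphometry** — layer thickness by perpendicular callipers at a 1 px
  interval, ONL/INL thickness ratio, straight-calliper detachment height;
* **heatmap** — relative ONL-thickness overlay across attached and
  detached retina;
* **regions** — RD-peak location and the four 400 µm regions of interest
  (attached central, attached paracentral, detached apex, detached base at
  500 µm from the peak);
* **nuclei** — automated DAPI nucleus counting
  (rolling-ball → Otsu → distance-transform watershed → area cleanup);
* **stats** — RD/AR normalization, cell-death-rate regression, ANOVA +
  Tukey HSD / t-test comparisons, the a-priori degeneration criteria
  1a–4b, and three cautionary case studies;
* **phantom** — synthetic cryosection tiles with known ground truth and
  replicate cohort tables from the published group statistics, so the
  whole pipeline is testable without any image download.

## The quantities

For a region *r* and timepoint *t*, the pipeline reports the ONL cell
count *N<sub>r</sub>(t)* per 400 µm segment, mean layer thicknesses
*T<sub>ONL</sub>*, *T<sub>INL</sub>* and their ratio
*T<sub>ONL</sub>/T<sub>INL</sub>*, the tile-normalized values
RD/AR = *x<sub>r</sub>* / *x*<sub>attached central</sub>, and the
cell-death rate as the OLS slope of a metric on day,

&nbsp;&nbsp;&nbsp;&nbsp;rate = Σ(t−t̄)(y−ȳ) / Σ(t−t̄)²,

with the regression F-test for significance (α = 0.050).  A region is
*fit to demonstrate progressive degeneration* iff it shows no significant
day-0 deficit versus the attached retina (criteria 1–2, count and ratio,
absolute and normalized) **and** a significant, progressive decline over
14 days (criteria 3–4).

## Worked example

```python
from rdmorph import (PhantomSpec, generate_phantom_tile, BoundaryCurve,
                     thickness_profile, onl_inl_ratio, locate_rd_peak,
                     published_cohort_design, generate_cohort_table,
                     fit_rate, evaluate_criteria)
from rdmorph.morphometry import align_profile_arc

# 1. a synthetic cryosection with a ~1.1 mm bullous detachment
image, labels, gt = generate_phantom_tile(PhantomSpec(), seed=1)
onl_outer = BoundaryCurve(gt.onl_outer_curve)
rpe = BoundaryCurve(gt.rpe_curve)

# 2. calliper morphometry and the RD peak
onl = align_profile_arc(thickness_profile(labels == 2, layer="onl"), onl_outer)
inl = align_profile_arc(thickness_profile(labels == 3, layer="inl"), onl_outer)
peak = locate_rd_peak(rpe, onl_outer)
ac = gt.region_intervals_um["attached_central"]
print(f"attached central ONL: {onl.mean_um(ac):.2f} um, "
      f"ONL/INL {onl_inl_ratio(onl, inl, ac):.2f}")
print(f"RD peak at {peak.onl_arc_um:.0f} um, height {peak.height_um:.2f} um")

# 3. a replicate cohort from the published group statistics
cohort = generate_cohort_table(published_cohort_design(n=6), seed=1)
rate = fit_rate(cohort, "detached_apex", "onl_count")
print(f"apex cell-death rate: {rate.slope_per_day:+.2f} cells/day "
      f"(p={rate.p_value:.2g}, n={rate.n_obs})")
report = evaluate_criteria(cohort)
print("fit to show progressive degeneration:", report.verdicts)
```

prints

```
attached central ONL: 94.66 um, ONL/INL 2.00
RD peak at 3133 um, height 1126.75 um
apex cell-death rate: -34.08 cells/day (p=4.1e-06, n=24)
fit to show progressive degeneration: {'detached_apex': True, 'detached_base': False}
```

The phantom was built with a 94.20 µm ONL, ratio 2.0 and an 1126.75 µm
detachment, so the first two lines read the construction back within a
fraction of a percent.  The simulated cohort reproduces the study's
substantive findings: an apex death rate near −33.4 cells/day, and only
the detached apex passing all eight degeneration criteria — the detached
base is disqualified by its day-0 deficit and flat time course.

A command-line interface mirrors the library
(`rdmorph simulate tile|cohort`, `measure`, `regions`, `heatmap`, `count`,
`analyze`, `case-study`); every command reads and writes plain
TIFF/CSV/JSON/YAML.

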