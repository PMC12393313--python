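# Methods

This note documents the measurement models implemented in
`centmorph`, the conventions and tunable parameters that matter, what
the synthetic generators do and do not emulate, and the design choices
made where the underlying manual workflow left the procedure open.

## Coordinate and calibration conventions

Pixel coordinates are 0-based `(x, y)`; a pixel occupies the unit
square centered on its integer index. Polygon-ROI membership is
evaluated at pixel centers, boundary inclusive, so clockwise and
counter-clockwise traces are equivalent and results are deterministic.
Physical calibration is a single isotropic pixel edge length with an
explicit unit; FIB-SEM panels are calibrated by the scale-bar rule
(length per marked pixel run, e.g. 11 px = 100 nm → 9.09 nm/px).
Every measurement is logged with a content hash of its ROI for
provenance.

## Ring morphometry

**Line scans.** A scan samples bilinearly interpolated intensity every
0.5 px along the line and averages across the stated perpendicular
width. The diameter of an annular structure is the distance between
the highest local maximum on each side of the profile midpoint
(plateaus collapse to their middle sample; ties break toward the
sample farthest from the midpoint), and the reported diameter is
(d₁+d₂)/2 over two perpendicular scans. One bias is worth knowing:
averaging across a *wide* scan line (e.g. 1 µm) on a *curved* ring
pulls the apparent peak inward, because off-axis sample points cross
the ring at larger radii. On a noiseless 2-µm ring this bias reaches
1.5 px. The synthetic validations therefore scan with a one-pixel
line width, where recovery is exact; with acquired data the width is
an explicit parameter (`line_width`), and the original workflow's "7"
(pixels or µm — ambiguous in the source protocol) is simply whatever
the user passes.

**Thresholds.** All threshold rules are closed intervals
`[lower, upper]` with `upper` the maximum intensity of the traced
region, so a perfectly uniform region is fully selected:

| rule | lower threshold | used for |
|---|---|---|
| torus | (mean+min)/2 of the torus region | centriculum / tubulin ring |
| void | (mean+max)/2 of the traced void | inner edge of the tubulin ring |
| background | mean + max of a background patch | PCM (SPD-5, γ-tubulin) |

The PCM mask keeps only the 8-connected in-range component containing
a seed (the global intensity maximum unless a seed point is given) —
the automated equivalent of a wand-tool click.

**Void area.** The void is the 4-connected background component
containing the declared center, bounded by the thresholded ring
(foreground implicitly 8-connected by complementarity; the mixed
connectivity avoids topological paradoxes at diagonal contacts). If
that component reaches the raster border the ring is not closed and
the measurement fails loudly rather than silently filling the break.

**Ring widths.** The threshold estimator converts the areas enclosed
by the outer and inner ring edges to circle-equivalent radii
(R = √(A/π)) and reports R₁ − R₂. The circle assumption is applied
exactly as stated even to non-circular masks; for elongated masks it
biases both radii toward the geometric mean of the axes. When a
spindle-exclusion wedge removes part of the ring, the outer edge is
reconstructed across the wedge by the convex closure of the surviving
mask. The line-scan estimator normalizes each of the four profile
peaks to its own maximum and reads the width at 90% of it (crossings
by linear interpolation between samples; 90% because the trough
between the two peaks of a tubulin scan typically sits near 85% of
max, so lower fractions would merge the peaks). On an ideal
rectangular-profile ring the two estimators agree to within two pixel
sizes; on Gaussian profiles the 90% width is systematically narrower
than the generator's full width (0.918 σ for an isolated Gaussian
peak) — the estimators are consistent with each other, not unbiased
estimates of any one "true" width.

**Gap area.** gap = void − PCM area, computed from co-registered
channels. Negative gaps are legitimate (fluorescence overlap) and
flagged, not clipped.

## Membrane porosity

Holes are 4-connected background components of a binary membrane
panel; the membrane is 8-connected, preventing diagonal leaks from
merging distinct openings. Border-touching holes are excluded by
default since their extent in a cropped panel is unknown. No minimum
size is applied at detection: single-pixel holes stay in the
distribution, and passability filtering is a separate step using the
π·(d/2)² cutoff (490 nm² for a 25-nm microtubule, truncated for
display). Binning uses right-closed bins (0,500], (500,1000],
(1000,2000] … (9000,10000], (10000,∞) nm², and percentages are
reported both by hole count and by open-area contribution. The
viewing-angle check converts the center-to-edge fiducial line to its
inclination against the central plane (arcsin of the normalized dot
product with the plane normal) and passes below 30°.

## Microtubule angle classification

Boundary lines are infinite lines (point + unit direction); the
interior edge doubles as the local tangent, taken as given input —
the curvature of the membrane edge is not re-estimated at trace
scale. A trace must cross the interior edge; it is *continuing* if
either endpoint reaches the far side of the exterior edge (an
endpoint exactly on the line, tolerance 1e-9, counts as continuing —
"continued beyond" read inclusively), *excluded* if flagged present
in an adjacent slab (that 3-D check is data preparation, supplied as
boolean flags), otherwise *stopped*. The angle to the radial vector
is 90° minus the acute trace-to-tangent angle, always in [0, 90]; it
is invariant to endpoint swap, to reversing either direction vector,
and to global rotation. Output tables round to 0.1°.

## Synthetic generators

The generators define the conditions under which the pipelines are
validated; all are deterministic in (spec, seed).

- **Rings/scenes**: radially symmetric annuli (rectangular or
  Gaussian radial profile) centered slightly off the pixel lattice so
  lattice-aligned rasterization can never flatter a measurement.
  Default scene geometry emulates the metaphase 1-cell configuration:
  3.4-µm centriculum ring of 0.4-µm width (void radius 1.5 µm) at
  0.05 µm/px, PCM disk nested inside, 2.6-µm tubulin ring. Optional
  noise applies Poisson shot noise then additive Gaussian read noise,
  in that order; the default is noise-free so exact-geometry checks
  stay exact. Rough ROI traces (torus outer/inner, background patch,
  tubulin void) are emitted with each scene so pipelines run
  unattended.
- **Panels**: non-overlapping discs with lognormal areas packed until
  the rasterized open fraction is within 0.5 pp of target. Centers
  keep a separation of the two radii plus 1.5 px, guaranteeing a full
  membrane pixel between holes so detection recovers the truth areas
  exactly. The packing bound counts rejected placements (10⁴ by
  default). Cortical defaults: 2×2 µm at 100/11 nm/px, 7.85% open,
  median hole 400 nm² (σ_log = 1.2, ~60% of holes below 500 nm²);
  pronuclear conditions use 20.66% open with much larger holes
  (median 2500 nm², σ_log = 1.5, 3×3 µm panel). The co-variation is
  not cosmetic: the separation overhead scales with hole perimeter,
  so high open fractions are geometrically unpackable from sub-500
  nm² holes — as in the real panels, where the high-porosity side is
  dominated by holes above 10,000 nm².
- **Slabs**: interior edge along the x-axis, exterior parallel at the
  slab width (default 1 µm, the metaphase membrane thickness); angles
  drawn as |Normal(0, σ)| truncated below 90° (half-normal, because
  only angle magnitudes in [0, 90] are meaningful); default mixture
  106 stopped / 21 continuing with σ = 25° / 8°.

What the generators do **not** emulate: optical blur (no PSF
convolution), spatially varying background, clustered or irregular
hole shapes beyond discs, curved membrane edges, and trace
localization error. Passing tests therefore demonstrate that the
estimators are correct and self-consistent on known geometry — not
that they are unbiased on acquired microscopy data, where threshold
placement interacts with the PSF.

## Statistics

Two-group comparisons dispatch automatically: Shapiro-Wilk on both
groups at α = 0.05 (the qualitative "normally distributed" rule made
explicit); the unpaired t-test only when both pass, otherwise
two-tailed Mann-Whitney (exact null for combined n ≤ 20 without ties,
tie-corrected normal approximation otherwise; all-tied samples return
p = 1 by convention). Multi-group comparisons use Kruskal-Wallis with
Dunn pairwise z-tests on pooled ranks (tie-corrected) and Holm
adjustment — the multiple-comparison correction was unspecified in
the source workflow, and Holm is the conservative, assumption-light
default (selectable). Under the two-stage auto dispatch the realized
type-I error on Gaussian nulls sits slightly below the nominal 5%
(≈4–6% over seeds at n = 15/group, 1000 replicates) — a known,
benign property of normality pre-testing. Regression is ordinary
least squares with the standard t-test of slope ≠ 0. Summaries are
mean ± SD; significance is p < 0.05 throughout.

## Problem sizes and tolerances

Validation runs use 128–160 px images (0.05–0.1 µm/px), 220–330 px
panels, slabs of 127 traces, 200 slab replicates for the
narrower-spread contrast, and 1000 replicates for type-I calibration;
the full suite completes in seconds. Numeric tolerances: diameter
recovery within 1 px on noiseless annuli; threshold ring width within
1 px of the designed width on the 1.0/1.5 µm annulus; gap recovery
within 5% (0.1 µm² absolute at zero gap); panel open fraction within
1 pp of target with exact per-hole recovery; angle recovery to
~1e-10° on noiseless slabs; OLS against the normal-equation oracle to
1e-10.

## Known limitations

- The circle-equivalence width estimator is biased for non-circular
  rings; no ellipse fitting is offered by design.
- Wide line scans underestimate diameters of small rings (curvature
  bias above); use narrow scans or report the width used.
- The PCM "wand" seed defaults to the global intensity maximum, which
  on multi-centrosome fields requires an explicit seed point.
- Panel generation cannot reach open fractions near the disc-packing
  jamming limit for a given hole-size distribution; it fails with the
  achieved fraction rather than silently under-delivering.
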