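# Methods

This note records the models, conventions and numerical choices behind
`lungmorph`, and what its synthetic validation does and does not show
about real histology.

## Geometry on pixel regions

All measurements operate on 8-connected sets of pixels with an isotropic
physical pixel size (µm); anisotropic input is an error, not a silent
approximation.  Two conventions matter everywhere downstream:

**Feret diameter on pixel corners.**  A region's Feret (maximum caliper)
diameter is the largest pairwise distance over the convex hull of its
pixels' *corner* points, times the pixel size.  Treating pixels as unit
squares rather than points gives a nonzero, resolution-consistent diameter
for thin and single-pixel regions (one pixel has Feret √2 px) and keeps
the estimate stable as resolution changes.  The cost is a ~+½ px offset
relative to the underlying continuous shape, which the generators cancel
(below).

**Perimeter as max(hull, smoothed contour).**  Boundary length is the
larger of (a) the convex-hull perimeter of the corner points and (b) the
length of the marching-squares 0.5-level contour after two passes of a
3-point circular moving average on its vertices.  Naive pixel-edge
counting overestimates circle perimeters by ~27 % and would corrupt
circularity; the raw marching-squares polygon still overshoots by ~5 %
from its half-pixel staircase, and smoothing it enough to fix that erodes
the corners of small squares.  The hull perimeter is a lower bound for
every closed curve and exact for convex regions, so the maximum of the two
is exact for the convex shapes that dominate this morphometry (discs,
ellipses, squares: errors ≤ 0.5 %) while the smoothed contour takes over
for concave shapes (a 6-lobed star: +1.9 %).  Known residual bias: for a
single pixel the contour estimate degenerates and the hull gives exactly
4 px; for rasterised discs under ~15 px radius the hull perimeter runs
2–3 % high, which slightly depresses small-disc circularity.

Circularity is 4π·area/perimeter²; no formula beyond this standard one is
assumed, and absolute circularity values are therefore not a validation
surface — only orderings and limits (discs → 1 with growing radius,
elongated shapes ≪ 1) are asserted.

## Segmentation

Binary masks pass through unchanged.  Grayscale images are thresholded by
Otsu.  RGB input is converted with fixed published H&E stain vectors
(skimage's rgb2hed); the hematoxylin + eosin optical densities are summed
and thresholded by Otsu, clamped to [0.01, 0.6] so a pathological
histogram cannot push the threshold into the background or saturate it.
There is no training step; re-running on the same image and config is
bit-identical.

The *section mask* is the hole-filled morphological closing (default
radius 10 µm, edge-padded so tissue touching the frame is not eroded) of
the tissue mask: every airspace enclosed by tissue belongs to the section.
*Airspaces* are 8-connected components of section ∧ ¬tissue.  Components
below 20 µm² are treated as staining noise — far below any alveolar
cross-section at these resolutions.  Components touching the image border
or adjacent to non-section background are flagged `border_touching`: they
are truncated by the field of view and cannot be measured, so they are
excluded from Lm ("closed" airspaces only).  By default they still count
toward the airspace area fraction; a config switch
(`exclude_border_airspaces_from_fraction`) removes them from both
numerator and denominator instead, and the partition identity below holds
either way.

**Large-structure removal.**  The criteria by which conducting airways and
vessels are removed before parenchymal analysis are a genuine design
opening; this implementation flags non-tissue components with Feret
≥ 100 µm — the lower bound of the bronchiole detection window, which keeps
the parenchyma and bronchiole analyses disjoint by construction.  A
secondary rule (circularity ≥ threshold ∧ area ≥ threshold, for round
vessel lumina below 100 µm) is implemented but **disabled by default**:
smooth ellipses are geometrically indistinguishable from vessel circles by
circularity alone (an aspect-0.85 ellipse has circularity ≈ 0.99), so on
the generator's smooth shapes the rule cannot discriminate and would
wrongly exclude large round alveoli.  On real H&E, where alveoli are
crinkly and vessels smooth, it can be enabled via config.

## Parenchyma metrics

Airspace area fraction and alveolar tissue density are computed by pixel
counting over the section with flagged-large pixels removed from both
numerator and denominator, so

    airspace_area_fraction + tissue_density = 1

holds exactly (not approximately) on every image.  Lm is the *unweighted*
mean Feret diameter over closed, non-excluded airspaces — per-airspace
averaging, not area weighting, matching the definition of a mean over the
airspaces of the section.  Per-image values are averaged per mouse before
any group statistics.

## Bronchiole morphometry

A candidate bronchiole is a closed non-tissue component (the lumen)
enclosed by a connected tissue annulus.  The annulus is the tissue
component adjacent to the lumen, trimmed to a configurable thickness cap
(default 60 µm) around the lumen so that alveolar walls attached to the
outside of the ring are not annexed when the bronchiole is embedded in
parenchyma.  Candidates whose whole region (lumen ∪ ring) has Feret
outside [100, 500] µm, or that touch the image border (truncated geometry),
are rejected; the window test is inclusive at both bounds and the
generators place 99/501 µm rings outside and 101/499 µm rings inside it.

The inner and outer epithelial limits are the smoothed marching-squares
contours of the lumen and whole region.  Wall thickness is measured
one-directionally: for every outer-contour point, the Euclidean distance
to the nearest inner-contour point, averaged.  At 0.452 µm/px a 240 µm
bronchiole yields ≈ 2 000 boundary samples.  One-directional sampling
avoids double-counting; for an annulus the symmetric variant is identical,
and for mildly eccentric rings the difference is far below the pixel.
Areas are pixel counts, so whole = lumen + wall is exact per bronchiole.

## Cell classification and normalisation

Channels are binary label masks (nuclei, Lamp3, Hopx, CC10, acetylated
tubulin, E-cadherin, EdU).  Nuclei are labelled 8-connected; each nucleus
yields at most one cell record.

*Alveolar*: a cell is Type II if Lamp3 covers ≥ 10 % of a peri-nuclear
ring (nucleus dilated by 1.2 µm, nucleus removed) — vesicular, cytoplasmic
staining; Type I if Hopx covers ≥ 30 % of the nucleus — nuclear staining.
Cells positive for both are dropped and counted (`n_ambiguous`): the two
markers are lineage-specific, so a double-positive indicates a
segmentation collision, and no tie-break rule would be defensible.
Count conservation (records + dropped = nuclei) is asserted in tests.

*Bronchiolar*: cell territories are obtained by flooding the epithelial
band from each nucleus with the E-cadherin borders as watershed barriers —
this is the computational reading of "cells delineated by lateral
E-cadherin".  The band mask is the closing (default 6 µm) of the union of
all epithelial channels, which bridges the unstained gap between a
ciliated cell's basal nucleus and its apical tubulin without crossing
borders.  A territory containing acetylated tubulin (≥ 2 px) is ciliated;
CC10 makes it club; both → ambiguous, dropped.

*EdU*: positive when EdU covers ≥ 30 % of the nucleus
(`edu_overlap_frac`); the threshold stands in for an unstated "EdU+
nucleus" rule and is config-exposed.

*Basement membrane*: each E-cadherin component is one lateral border; its
basal endpoint is the principal-axis extreme nearer the nuclear layer
(nuclei sit basally in this columnar epithelium).  If the band encloses a
lumen (a hole > 100 µm² in its filled mask) the basal points are ordered
by angle and the polyline closed; otherwise they are ordered along the
band's principal axis.  The polyline length, in mm, is the denominator for
club/ciliated densities.  Edge cells are counted by nucleus centroid.

*Normalisation*: alveolar densities divide by (field area × tissue
density), using the same mouse's mean tissue density from the parenchyma
pipeline — the most granular pairing available; this reports cells per mm²
of alveolar *tissue*, insulating the count from septal rarefaction.

## Statistics

Technical replicates are combined to an unweighted mean per mouse;
biological replicates enter a two-tailed two-sample t-test, pooled
variance by default (df = n₁+n₂−2), Welch as an option — with n = 4 per
group both variants give p = 0.03 for the Type I density comparison from
the published summary statistics, so the unstated choice is immaterial
there.  Degenerate input (zero variance in both groups) returns p = 1 at
equal means rather than NaN.  No multiple-testing correction is applied
across metrics; each metric is tested independently, which mirrors the
study design and is a documented caveat, not a recommendation.  Percent
change is 100·(young − old)/young, positive for a reduction, rounded
half-away-from-zero when quoted as an integer.

`simulate_power` runs the full generate → aggregate → test chain on the
hierarchical sampler; at the null its rejection rate is ≈ 0.05
(1000 reps, seeded), which validates the pipeline's calibration
end-to-end.

## Synthetic histology

**Half-pixel footprint convention.**  All analytic boundaries are drawn at
radius − ½ px in pixel-centre coordinates.  The pixel squares of the
rasterised shape then span exactly the nominal diameter, so the
corner-hull Feret of the generated region matches the specification to
sub-pixel accuracy; without this every rasterised diameter would carry a
systematic +1 px bias that would consume the entire max(2 %, 1 px)
recovery band.

**Parenchyma** fields place non-overlapping ellipses (major axis = the
drawn Feret; aspect ratio uniform in [0.65, 0.95]; orientation uniform)
into a tissue sheet by dart throwing with a ≥ 2 px septal margin.  When
rejection sampling stalls, every admissible centre is enumerated exactly
by convolving the occupancy mask with the candidate footprint — placement
fails only when the field is genuinely saturated, and the error is
explicit.  In density-targeted mode, placement stops when the airspace
fraction reaches the target (realised tissue density within ±0.01 or
error); a draw too large to fit near saturation is re-drawn (≤ 200
times), so very dense fields carry a slight small-airspace bias in the
upper tail — the realised Feret list, not the nominal distribution, is the
ground truth that recovery is measured against.  Airspace Feret
diameters default to normal with CV 0.25, a typical dispersion for
adult alveolar profiles.  Ellipses are a stated simplification: real
airspace sections are crinkled polygons, so segmentation robustness to
boundary irregularity is only partially exercised.

**Bronchioles** are annuli with optional sinusoidal boundary wobble
(identical phase on both limits, so the radial gap stays at the nominal
wall thickness) and optional lumen-centre eccentricity.  Truth areas are
analytic (π(R² + A²/2) for wobble amplitude A); truth wall statistics are
computed on 2048-point analytic polygons, independent of rasterisation.

**IF fields** plant cells with disc nuclei (1.5 µm radius alveolar;
pitch-limited in the bronchiolar band, floor 0.7 µm) and type-appropriate
marker geometry: Lamp3 as a 1.1 µm peri-nuclear annulus, Hopx on the
nucleus, CC10 filling the mid-cytoplasm, acetylated tubulin as an apical
band, E-cadherin as radial/vertical lateral borders, EdU on the nucleus.
Alveolar placement keeps a 6 µm centre-to-centre floor so that no probe
ring can reach a neighbour's markers (reaches sum to 5.3 µm);
classification on noiseless masks is therefore exact by construction, and
the tests verify that it is.  Per-type counts are Poisson at the planted
expectation by default (`count_model="expected"` rounds instead); EdU
flags are per-cell Bernoulli draws by default, while
`edu_model="expected"` plants the rounded count at random positions —
used when the measurement chain rather than sampling noise is under
test.  Default output is noiseless label masks; the pseudo-H&E renderer
(blur σ 0.6 px, 1.5 % sensor noise, eosin-toned tissue on slide white)
exists for segmentation robustness checks only, where the stain-density
pipeline recovers the mask at Dice ≥ 0.98.  None of this emulates real IF
artefacts — out-of-focus light, spectral bleed-through, nuclear crowding
with true overlap — so passing tests certify the analysis contract, not
robustness to degraded optics.

**Cohorts** draw mouse-level metric values from group normals
(between-mouse SD) and field-level values from mouse normals (within-mouse
SD).  Each mouse's stream is keyed by (group, index) via
`SeedSequence(seed, spawn_key=...)`, so enlarging a cohort never perturbs
earlier mice.  The study driver (`analysis/01`) clips draws to generator
feasibility (tissue density ∈ [0.57, 0.88]; total planted cell density
below the 2-D packing ceiling of ~15 500 nuclei/mm² of field and
260 cells/mm of membrane), since a 2-D section cannot hold arbitrarily
many non-overlapping nuclei; the clipped values are recorded as that
mouse's truth.

## Problem sizes

Validation uses 20 parenchyma fields of ≥ 100 closed airspaces for Lm
recovery (|Lm − truth| ≤ max(2 %, 1 px) at mean Ferets 30–60 µm), 50
random annuli (diameters 120–450 µm, walls 10–30 µm) for bronchiole
recovery at the same tolerance, ≥ 950 planted alveolar cells and > 200
bronchiolar cells per replicate for density (±5 %) and EdU (exact binomial
95 % CI) recovery, 200 random blobs (up to 10⁴ px) for the brute-force
Feret oracle, and 1000 Monte-Carlo replicates for the null type-I error.
These sizes were chosen to keep each property suite well-resolved while
the whole validation remains a few minutes of computation.

## Known limitations

- Lm-by-Feret is the implemented definition; it is not numerically
  comparable to grid-intercept Lm on the same tissue, and no conversion is
  attempted.
- Circularity's absolute scale inherits the perimeter estimator's
  small-shape bias (discs < 15 px radius read ~3–5 % low).
- Segmentation of real, stain-variable whole-slide H&E is out of scope;
  the stain-separation path is validated only against the package's own
  renderer.
- The wall-thickness cap (60 µm) is a heuristic for embedded bronchioles;
  severely oblique cross-sections violate the annulus model and are not
  modelled by the generator.
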