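# Methods

This note documents the models, conventions and design choices behind
phenoplate: what each stage computes, which parameters matter, what the
synthetic-data generator does and does not emulate, and the numerical
details a maintainer would need to reproduce or change behavior.

## Color space and pixel rules

All imagery is 8-bit RGB. Hue, saturation and brightness (HSB) are the
standard HSV transform rescaled to the integer range [0, 255] (hue by
255/360), the convention of 8-bit imaging software, which is also the only
scale on which the segmentation constants (49, 74, 20, 50, 23, 127, 138)
are coherent — several exceed 100, so they cannot be percentages. The hue
of achromatic pixels (S = 0) is defined as 0 and such pixels are counted in
hue histograms; an exclusion flag exists for sensitivity checks.

Grayscale defaults to the unweighted channel mean (no weighting is implied
by the segmentation constants); Rec.601 luma weights are available via
`to_gray(..., weights="luma")`.

Pixel rules are AND-combinations of clauses over R, G, B, H, S, Bri, gray
and the normalized red–blue index (R − B)/(R + B). Every printed comparison
is strict (`<`, `>`) exactly as typeset; the salt gray-band filter keeps
gray ∈ [0, 140] ∪ [150, 255] with both printed endpoints included, i.e. the
excluded band is the open interval (140, 150). Rules are monotone:
tightening any clause constant can only remove foreground (property-tested).

## Local-mean thresholding and grid removal (phosphate)

Dark objects on the backlit field are segmented by
`gray(p) < localmean(p, radius) − offset` with the square window clipped at
image borders. Window means use an exact integral image so a constant
raster yields an exactly empty mask under the strict inequality; defaults
are radius 15 px and offset 0 (the algorithm's name is fixed by the method;
the radius is a free parameter and configurable). If the radius exceeds
both image dimensions, the global mean is used (logged).

Embossed plate-grid lines are removed by run-length scanning rather than
morphological opening, because the removal criterion is stated directly as
run lengths: horizontal foreground runs strictly longer than 50 px are
cleared, then vertical runs longer than 240 px, then one binary erosion
(4-neighbor cross), then the inclusive 0-based row bands (50, 260) and
(1698, 1798) are cleared. The operation never adds pixels. Coordinates are
0-based, origin top-left, x rightward, y downward.

## Connected components and contours

Components are maximal connected regions (default 8-connectivity, matching
contour-tracing labelers; 4-connectivity available), delegated to
`scipy.ndimage.label` and verified against an independent flood-fill oracle.
The outer contour of each component is traced with Moore-neighbor tracing
and Jacob's stopping criterion; the perimeter is the polygonal length of
that contour through border-pixel centers (axis steps 1, diagonal steps √2),
interior holes ignored. A filled 20 × 10 rectangle therefore has perimeter
2·(19 + 9) = 56 exactly. Plants with fewer than 4 pixels get a degenerate,
flagged profile instead of an exception (a single pixel has perimeter 0 and
undefined ratio features).

## Morpho-colorimetric features

Eight features per digital plant:

| feature | definition | unit |
|---|---|---|
| area | pixel count | px |
| perimeter | outer-contour polygon length | px |
| circularity | 4πA/P² (normalized; disk → 1) | – |
| compactness | A/P | px |
| major/minor axis | equivalent-ellipse axis lengths, 4·√λ of the second-central-moment eigenvalues (+1/12 per-pixel unit-square term) | px |
| eccentricity | major/minor | – |
| hisgreypeak | modal gray intensity of plant pixels (lowest wins ties) | [0, 255] |

Circularity as a *ratio of the squared circumference to the area* (P²/A)
does not match a filter like "circularity lower than 0.70" for selecting
elongated roots — on that raw scale elongated objects have *large* values.
Features and filters therefore use the normalized form 4πA/P² (disk = 1,
elongated → 0); the raw ratio is still emitted as `raw_circularity`.

The equivalent-ellipse axes are the moment-of-inertia definition (the axis
about which the body is easiest to rotate). A consequence worth noting: for
a uniform rod of length L the major axis is 4·√(L²/12) ≈ 1.155·L, about 15 %
longer than the rod's extent. The phosphate root-length proxy (major axis
of the merged shoot+root plant) is therefore proportional to, not equal to,
the drawn root length; the tests assert the proportionality (r > 0.9, ratio
within (1.0, 1.4)) and that the line contrast is detected by ANOVA, which is
what the screen consumes.

Hue-class histograms assign pixel class ⌊H·K/256⌋ with K = 16 per modality
(salt/arsenic; VIS and FLUO vectors concatenated to length 32) and K = 32
for freezing. The printed yellowish damage classes "4, 12, 20, 28, 36"
exceed a 0–31 index range, so they are read as the *centers* of width-8 hue
bins on [0, 255] — i.e. the five lowest-hue bins covering H ∈ [0, 40),
red-through-yellow tones. The class set is configurable. A seedling is
damaged iff its yellow fraction strictly exceeds 0.5.

## Object filtering, cell assignment, shoot–root merge

Object filters apply strict bounds on area, normalized circularity and the
Euclidean distance from the component centroid to the nearest grid-cell
center (the anchor point is not specified more precisely by the method;
the centroid is the natural choice). Survivors are annotated with that
cell; per cell only the largest object is kept, ties broken by the lowest
component label for determinism.

On vertical phosphate plates each shoot is paired with at most one root in
the same grid column whose topmost pixel lies nearest below the shoot
centroid; the merged plant is the pixel-set union. Unpaired shoots become
shoot-only plants; unpaired roots are dropped (they cannot be attributed to
a seedling).

## Statistics

* **Two-group call.** Euclidean distances on the joined color vectors,
  agglomerative clustering with average linkage (the distance is fixed by
  the method, the linkage is not; average is the default and configurable),
  tree cut at exactly two groups. The group with the larger mean mass in
  the green VIS hue classes (bins 4–7 of 16, ≈ 90–180°) is labeled
  alive/germinated — an automated stand-in for inspecting the most
  representative members of each group. Identical profiles yield a flagged
  single-group degenerate result and no test.
* **Fisher's exact test** (scipy) on [[line_g1, wt_g1], [line_g2, wt_g2]],
  two-sided by the minimum-likelihood rule; verified exactly against
  rational hypergeometric enumeration for all tables with row sums ≤ 12.
  Zero-margin tables return p = 1 with a warning.
* **One-way ANOVA** (scipy) on the major axis for phosphate; degenerate
  inputs (zero within-group variance) are mapped to F = 0, p = 1 when the
  means agree and p = 0 with a warning when they do not.
* **BH FDR** (statsmodels step-up) across all mutant lines of one
  condition/assay run — that is the multiple-testing family; significance
  is p_adj < 0.05, and the stringent filter's strong threshold is
  p_adj < 0.01 *within the qualifying stress*.
* **Multi-trait clustering.** The eight features are z-scored within the
  condition (constant features dropped with a warning), plants clustered
  with Ward linkage (common practice for z-scored features) and cut at five
  groups, relabeled C1–C5 by order of first appearance for determinism.
  Lines are then clustered (average linkage) on their density vectors over
  C1–C5; the density rows sum to 1 by construction. Plants are pooled
  across lines within a condition before clustering (the grouping is
  per-condition; a per-line option exists).

## Gene triage

Per gene, from its per-line, per-stress adjusted p-values:

* **Category tree** (most to least allele support): ≥ 2 lines significant in
  the same stress → Category 6; else ≥ 2 usable alleles each significant
  somewhere → Category 5; else one supporting allele significant in more
  than one condition → Category 3; else Category 1. Categories 2
  (multi-condition) and 4 (multi-allele) are carried as flags. The tree is
  reconstructed from the category definitions and validated against the
  published labels; two loci (At2g27110, At1g79740) do not follow it and
  are carried as metadata-driven exceptions (`category_reported`), not
  silently forced.
* **Stringent filter**: pass iff some stress has ≥ 2 significant lines
  (p_adj < 0.05) and min p_adj < 0.01 within that same stress. Freezing
  screening years (2011/2013) pool as one stress for both criteria.
* The bundled screen tables use per-stress line ranks as line identities
  for multi-allele genes, because the pairing of alleles across stresses is
  not published; this leaves every per-stress count, the filter and the
  tree unchanged. Single-allele genes keep one line id across stresses.

## Synthetic plate generator

The generator emulates the study's plate formats — 6 × 6 square grids with
36 seedlings (salt, arsenic; VIS + FLUO), round plates with 60 large
seedlings (freezing), and backlit vertical 6-seed plates with embossed grid
lines (phosphate) — at 1800 × 1800 px (the phosphate crop bands reach row
1798, which fixes the frame size; smaller sides are supported for fast
tests). Designs default to the study sizes: 36 × 3 replicates (salt,
arsenic), 60 × 3 (freezing), 6 × 2 (phosphate), one line per plate.

Per-line effect parameters: survival/germination probability (wild type
0.65, matching the semi-lethal stress design), per-seedling damage fraction
(Beta with configurable mean and concentration), root length (Normal, mean
250 px, sd 25). Tissue colors are truncated-Normal hues on [0, 255]: alive
85 ± 8 (mid-green), dead/damaged 22 ± 6, seeds 15 ± 5 (brown). Freezing
alive tissue instead uses 72 ± 6 truncated to [48, 80] at saturation
0.82–0.95: at pure green (H = 85, 120°) the assay's own foreground index
(R − B)/(R + B) is identically 0 and above H ≈ 82 it drops below the 0.20
threshold, so healthy freezing tissue is drawn yellow-green — consistent
with the look of post-freeze recovery imagery — to keep the printed rule
sound on its own synthetic data. Backgrounds are constructed to fail each
assay's rule exactly: achromatic gray for salt (S = 0), near-white
(R ≥ 254) for arsenic, achromatic dark gray for freezing (index 0), and a
*noiseless* bright field for phosphate (with offset 0 any noise below the
local mean would become foreground). Phosphate grid lines are spaced 550 px
so horizontal lines avoid the root zone; roots are drawn as 3-px-wide wavy
polylines (amplitude 3–5 px, period 80–120 px) so no vertical run exceeds
the 240 px removal threshold, and they start just below the shoot
silhouette so the dark mask separates shoot and root objects.

Everything is deterministic: each plate's RNG stream derives from the
(experiment seed, plate index) pair, so identical configuration and seed
reproduce byte-identical images and truth tables.

What the generator does **not** emulate: seedling occlusion and touching
rosettes, lighting gradients and vignetting, condensation and reflections,
lid artifacts, agar texture, camera noise correlated across channels, and
color-calibration drift. Passing segmentation recall of ~100 % on these
clean plates therefore demonstrates that the rules, filters and geometry
are implemented faithfully — not that the pipeline is robust to real-world
image degradation.

## Problem sizes and calibration studies

The test suite and the acceptance script use: one clean plate per assay at
the study formats for segmentation recall; a 5-line end-to-end salt
mini-screen (36 seedlings per line, one replicate, 900 px plates) for the
survival-call accuracy and screen recovery; 200 simulated null lines at
survival 0.65 and n = 108 for false-positive calibration; and 100 seeded
runs of a survival 0.15 vs 0.65 contrast at n = 108 for power. The
count-level calibration studies run on simulated true statuses (binomial
draws through the same test path), not rendered images, which is the
appropriate level for calibrating the statistical layer.

## Known limitations

* The printed thresholds are taken at face value on the 8-bit scale; if a
  source pipeline used a different HSB scale or grayscale weighting, the
  configurable keys (`to_gray` weights, per-assay threshold keys) are the
  adjustment points.
* The shoot/root "circularity rate > 0.099" for shoots is assumed to be the
  same normalized quantity as the root rule's 0.70; both are configurable.
* Freezing seedlings on round plates get line identity from nearest layout
  regions, not exclusive cell assignment; overlapping rosettes would merge
  into one component and be dropped by the 40 000 px upper area bound.
* The major-axis root-length proxy is linear in, but ~15 % above, the true
  root extent (rod geometry of the moment definition); comparisons between
  lines are unaffected.
* FLUO color classes are computed identically to VIS (hue after HSB
  conversion); the method implies but does not state this.
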