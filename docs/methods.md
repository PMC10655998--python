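# Methods

This note documents the models, parameter choices, numerical conventions
and limitations behind `amyquant`. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Stain model and unmixing

Transmitted-light chromogens obey Beer–Lambert absorption: channel
intensity is `I_ch = I0_ch · exp(−D_ch)`, so stain amount is linear in
optical density `D_ch = −ln(I_ch / I0_ch)`, not in RGB intensity. We work
throughout in natural-log density, and "au" in all thresholds means this
density scale. `I0` defaults to 255 per channel because clear glass is
near-saturated in brightfield scans; a measured glass reference can be
supplied instead. Intensities are clipped to `[1, I0]` before the log so
8-bit zeros produce a large finite density rather than infinity.

Stain recognition is density-space two-stain least squares: each pixel's
3-vector of channel densities is projected onto the span of two unit
reference absorbance vectors, DAB ≈ (0.269, 0.568, 0.778) and
hematoxylin ≈ (0.650, 0.704, 0.286) (normalised; both configurable).
Negative coefficients are clamped to zero independently — stain loads are
physically non-negative, and the maps feed threshold rules rather than a
reconstruction, so a full non-negative least-squares projection would add
cost without changing any classification in practice. Brown+ve is brown
minus blue *after* clamping, so Brown+ve ≤ brown always, with equality
exactly where the blue coefficient is zero. Density-based colour models
for microscopy classify stains in a chromaticity/density representation;
projection onto reference density axes carries the same information and
is fully deterministic, which is why we chose it. We do not claim it is
byte-identical to any particular commercial implementation.

## Working resolutions

Scans are taken at a nominal ×40. No scanner µm/px is assumed: the scale
is always an explicit `mpp` input (0.25 µm/px is a common ×40 convention;
the bundled fixtures use 0.5 µm/px to keep the canonical section a
tractable problem size). Tissue detection runs at ×10-equivalent and stain
classification at ×20-equivalent. Both are produced by integer block-mean
downsampling (factors scan/10 and scan/20): a named-magnification recipe
does not pin down a resampling kernel, and the block mean is
deterministic and alias-free for factor-of-2 steps. Rasters whose
dimensions do not divide the factor are trimmed by up to factor−1
trailing rows/columns. The tissue mask is replicated (nearest-neighbour)
onto the stain grid, and stain classes outside tissue are forced to
"none", so glass-edge staining cannot seed objects; treating the tissue
mask as a hard gate for stain detection is an assumption of this
implementation.

## Tissue detection

The grey raster is the per-pixel minimum of R, G and B (the darkest
channel). The glass/tissue threshold is the 95th brightness percentile of
that raster plus an offset of −10 grey levels (both configurable), clamped
to [0, 255]; pixels strictly below the threshold are tissue. Percentiles
use linear interpolation (NumPy default). On a raster that is 90 % glass
at grey 250 and 10 % tissue at grey 100 this yields threshold 240 and a
mask equal to the planted tissue exactly, which the tests assert.

## Segmentation rules and conventions

Brown classification: a pixel enters the brown class only if brown
density > 0.15 au *and* Brown+ve > 0.1 au (both strict); brown pixels
with density ≥ 0.5 au are dark (inclusive), the rest light. Seeded
growing: each 8-connected dark component seeds a candidate; a light
component adjacent to a seed joins it, and a light component touching two
seeds merges them. Under one shared connectivity this is equivalent to
taking connected components of (dark ∪ light) that contain a dark pixel,
which is how it is computed; light components with no seed are discarded.
Connectivity is 8 by default (region growing is neighbourhood-inclusive)
and configurable to 4.

The five removal rules, with inequality directions exactly as printed in
the rule set they implement: area < 10 µm²; dark area < 1.5 µm²; mean
brown > 0.5 au AND SD < 0.25 au; area < 40 µm² AND elliptic fit below
threshold; area > 40 µm² AND dark fraction > 0.70. An object of exactly
40 µm² falls under neither of the last two rules, and exactly 10 µm² or
exactly 70 % dark is kept — the boundary-cases fixture plants objects on
each of these thresholds and the tests assert they survive. "Stain
intensity" and "standard deviation" are interpreted as the mean and
population SD of brown density over the object's pixels: the rule set
references no other per-object stain statistic.

**Elliptic fit.** "Non-elliptical" needs a concrete metric. We score each
object by intersection-over-union against a comparison ellipse with the
object's centroid, second-moment orientation and axis ratio, scaled to
the object's pixel count (area-matched). Second moments are taken over
pixel centres with eigenvalues floored at 1e-3 px², which keeps collinear
objects finite while still punishing them: a 1-px-wide line fits a very
long, very thin sliver whose overlap with the object is small (a 1×40
line scores ≈ 0.29; a disc of radius 10 px scores ≈ 1.0). A single pixel
scores 1 by convention, and a fitted semi-major axis beyond 2000 px
scores 0 outright. The acceptance threshold is 0.65, configurable; it
cleanly separates discs and mildly wobbled discs (≥ 0.85) from lines and
slivers (≤ 0.3) on the synthetic fixtures, and mirrors the elliptic-fit
feature family of rule-based segmentation platforms.

## Burden quantification

A plaque belongs to a region iff its centroid lies inside the region
polygon, boundary inclusive. The centroid rule makes counts additive over
any disjoint partition of the section — which a per-region export
implies — whereas any-overlap rules double-count straddlers. The full
plaque area is attributed to the centroid's region. Coverage percentages
divide by tissue area within the region, not polygon area, because glass
was removed before analysis. Region polygons are expressed in
full-resolution pixel coordinates (0-based, x right, y down, vertices at
pixel centres) and mapped onto the stain grid by the block-centre
transform `(v + 0.5)/f − 0.5`.

## Immunoassay calibration

The standard curve is the four-parameter logistic
`y = d + (a−d)/(1 + (x/c)^b)` (5PL optionally adds an asymmetry
exponent), the standard model of plate-reader analysis software. Fitting
is least squares over all standard replicates with deterministic,
data-derived initialisation (a at the lowest mean signal, d at the
highest, c at the geometric mid-concentration, b = 1) and box bounds
keeping c positive and b in (0, 50]. Optional 1/y or 1/y² weighting is
available (default none). Under multiplicative noise, 1/y² weighting is
the variance-matched choice, and the parameter-recovery tests run under
it; with 1 % CV noise on the canonical twelve-point duplicate layout,
a, d and c recover within 5 % (b within 10 %) on each of 100 simulated
plates. Curves whose mean signals decrease along the dilution series by
more than 5 % of the signal range are rejected as ill-posed rather than
silently fitted.

Back-interpolation uses the closed-form inverse
`x = c·((a−d)/(y−d) − 1)^(1/b)`; signals at or beyond the asymptotes are
censored ("below range"/"above range"), never extrapolated, and censored
wells never receive a numeric estimate.

**Detection and quantification limits.** The printed LOD definition
("2.5 × SD of the background") carries no blank-mean term; taken
literally it sits below the blank signal itself whenever blanks are
nonzero. We therefore anchor it at the blank mean — threshold signal =
blank mean + 2.5·SD(blanks), back-interpolated to concentration — and
expose `lod_add_blank_mean=false` to reproduce the literal form. The
third LLOQ clause as printed compares the mean blank signal to itself; the
only non-vacuous reading, implemented here, is that the *standard's* mean
signal must exceed blank mean + 9·SD(blanks). A standard passes the LLOQ
screen iff its back-interpolation is within 100 ± 20 %, its replicate CV
is ≤ 20 %, and it clears the blank gate; the LLOQ is the lowest passing
standard (undefined if none pass). Sample SDs use the n−1 denominator
throughout — replicates are duplicates, so small-sample bias matters.

## Group statistics

The omnibus test is the tie-corrected Kruskal–Wallis H with a chi-square
(k−1 df) reference; on three shifted groups of five the chi-square p sits
within 0.02 of a 10,000-permutation reference (asserted in the tests).
Dunn's pairwise z uses pooled mid-rank means with the tie-corrected
variance `[N(N+1)/12 − Σ(t³−t)/(12(N−1))]·(1/n_i + 1/n_j)`, and adjusted
p-values are Bonferroni over exactly the requested comparison set —
comparison sets are explicit inputs because studies typically test
selected contrasts (each transgenic line against its own control), not
all pairs. Fully tied data returns H = 0, p = 1 by convention (the
tie-corrected denominator vanishes; an error would be unhelpful for
degenerate-but-valid input).

Spearman correlation at n ≤ 10 without ties enumerates all n! rank
permutations (cached per n) and reports the one-sided exact p in the
direction of the observed sign: the fraction of permutations with
coefficient at least as large (positive rho) or at least as small
(negative rho), with rho = 0 treated as positive. One-sided exact p is
the default because it is the convention consistent with small-cohort
correlation values of the kind this package targets (rho = 0.9 at n = 5
gives 5/120 ≈ 0.04; rho = −0.8 at n = 4 gives 4/24 ≈ 0.17; a two-sided
convention would double both). Ties or n > 10 fall back to the asymptotic
test with an explicit warning and a `method` marker. Under independent
continuous nulls the one-sided-in-observed-direction p is calibrated at
the *achievable* exact level (≈ 0.083 at n = 5, computed by enumeration),
which the null-calibration test verifies within binomial 99 % bounds.

## Synthetic data: what it emulates, and what it does not

The slide generator paints stain densities on the ×20 analysis grid —
plaques as dark disc cores inside light halo discs (optionally wobbled by
a low-order radial cosine), artifacts as the five rule-violating designs
below, hematoxylin as a uniform tissue background — replicates them to
full resolution, adds optional density-space Gaussian noise, applies the
inverse Beer–Lambert transform and quantises to 8 bits. Painting on the
analysis grid means block-mean downsampling recovers planted densities
exactly up to quantisation (< 0.02 au), so ground truth is exact; noise
is added in density space so that margins in au translate directly to
detection margins.

Artifact designs (sizes in µm; quoted statistics hold on the canonical
1 µm analysis grid): *speck*, 3×3 with a 2×2 dark corner (area 9 µm²;
mixed loads keep its mean ≤ 0.5 so only the area rule fires);
*faint_halo*, a light disc of radius 3 with one dark pixel (dark area
1 µm²); *uniform_blob*, 6×6 uniformly at 0.8 au (mean 0.8, SD ≈ 0, area
36 so no size rule fires); *line*, 1×20 with a 3 µm dark run (elliptic
fit ≈ 0.29); *dense_blob*, 8×8 with 52/64 dark at 0.52 au (fraction
0.8125, mean 0.475 ≤ 0.5). Every design violates exactly one rule with a
margin of at least 0.02–0.06 au over quantisation error, and the
end-to-end tests assert the flag sets are exactly the designed ones.

The canonical fixtures are generated programmatically: *clean-section*
(4000×4000 px at 0.5 µm/px, 200 plaques and 50 artifacts on a jittered
16×16 grid with ≥ 26 µm clearance so no two objects touch, noiseless),
*null-section* (tissue and glass only) and *boundary-section* (objects
exactly at 10 µm², 40 µm² and 0.70 dark fraction). Plaque parameter
ranges (halo radius 4–12 µm, core at 35–50 % of the halo radius, core
0.65–0.85 au, halo 0.30–0.38 au, hematoxylin 0.12 au) are chosen so every
plaque passes all five rules with margin: e.g. the core fraction cap
keeps mean brown ≤ 0.44, well under the uniform-intensity rule. The
clean-section size keeps a full render + segmentation around 20 s on one
CPU, which is why it is the canonical end-to-end problem size.

What the generator does **not** emulate: realistic tissue texture and
nuclear detail, optics/point-spread blur, scanner compression artefacts,
stain-vector drift between slides, diffuse (core-less) plaque
morphologies, and overlapping or touching objects. Passing the recovery
tests therefore shows the rule set is implemented faithfully and the
pipeline is self-consistent — not that the thresholds are optimal for any
particular real scanner or staining batch.

Plate simulation draws `4PL(conc)·(1 + ε)`, ε ~ N(0, CV/100) truncated at
−0.99, over a twelve-point two-fold dilution in duplicate (top
500 concentration units, true parameters a = 100, d = 10000, c = 50,
b = 1.2) with duplicate blanks at the lower asymptote; default noise CV
is 2 %, a typical intra-plate figure for electrochemiluminescence
platforms. Group simulation draws lognormal (or normal) samples whose
*population* median is exactly the requested value (lognormal:
`median·exp(spread·Z)` with spread the log-scale SD); default n = 5 per
group, matching typical per-genotype cohort sizes.

## Degenerate inputs and tie-breaks

Duplicate region names are suffixed `#2`, `#3` … in file order. A region
polygon fully outside the raster is an error; empty report lists are an
error. Candidates are emitted in raster-scan order of their first pixel.
Blank sets need ≥ 2 wells for any SD-based limit; an LOD threshold at or
below the lower asymptote censors the LOD at zero. Constant vectors are
rejected by the correlation test; all-tied group data returns the null
convention described above.

## Known limitations

- Stain reference vectors are fixed defaults, not estimated per slide;
  slides with atypical chromogen batches need a calibrated config.
- The elliptic-fit metric, its 0.65 threshold, and the eigenvalue floor
  are implementation choices; any shape metric consistent with
  "non-elliptical" would pass the printed rule set equally.
- Region assignment is by centroid only; boundary-straddling objects are
  inherently ambiguous and a majority-area variant would change counts'
  additivity.
- Whole-slide pyramidal formats are out of scope; inputs are flat 8-bit
  TIFF/PNG rasters.
- The asymptotic Spearman fallback (ties, n > 10) uses the t
  approximation and is not exact.
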