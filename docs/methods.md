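# Methods

## Visual model

Spectra are resampled by linear interpolation onto the common 300–700 nm,
5 nm grid (81 points) and clamped to [0, 100] % — reflectance spectra are
smooth at the 5 nm scale, and clamping keeps instrument noise from
producing negative quantum catches. Replicate scans of one specimen-patch
are averaged at the reflectance level before modelling (configurable off);
specimen points are averaged per species × sex × patch afterwards, so the
species × sex × patch mean colour is the analysis unit.

Cone sensitivities default to Govardovskii A1 alpha-band templates
(standard published constants, beta band omitted) evaluated at
λ<sub>max</sub> = 372/456/544/609 nm (UVS type) or 419/478/542/607 nm (VS
type) — widely used averages for the two avian visual-system classes.
These are configuration, not measurements: a user-supplied CSV overrides
the templates bit-for-bit (written with 17 significant digits and parsed
with round-trip precision), and may already incorporate oil-droplet or
ocular-media filtering, which is not modelled separately.

Quantum catches use plain rectangle-rule summation on the uniform grid
(boundary terms cancel in the relative catches) and are normalised by each
cone's catch from a perfect reflector under the same illuminant. This
normalisation is deliberate: it is the standard relative quantum catch of
the visual-ecology literature, and it is what places achromatic stimuli
(white, grey, flat melanin) at the tetrahedron's centre. Without it, a
flat spectrum maps ≈ 0.087 away from the origin under unit-peak templates
and the centre/periphery structure of the space (unsaturated colours
central, saturated colours peripheral) is distorted. No receptor-noise
model, no further chromatic adaptation and no log transform are applied:
the analysis is purely geometric in linear relative-catch space.

The simplex→tetrahedron map is the canonical affine embedding, permuted so
the longwave vertex is the apex: vertices pairwise equidistant (edge
√(3/2)), circumradius 0.75, achromatic point at the origin, l vertex at
(0, 0, 0.75). Any map satisfying those constraints differs only by a
rotation/reflection; this one is fixed so coordinates are testable.

## Gamut metrics

Convex-hull volume and half-space operations use Qhull (scipy.spatial).
Degenerate inputs (< 4 points, or affinely flat) report volume 0 with a
flag rather than erroring. Hull overlap is computed exactly by stacking
both hulls' facet inequalities, locating a Chebyshev-centre interior point
by linear program, intersecting half-spaces and taking the hull volume of
the intersection vertices; a Monte-Carlo rejection-sampling estimator
(uniform in the smaller hull's bounding box, with binomial standard error)
is retained as an independent cross-check and as a fallback for
numerically fragile near-degenerate intersections.

Chromatic loci are half-open cubic cells of edge 0.022 anchored at the
achromatic origin; each point belongs to exactly one cell
(⌊(coord − origin)/0.022⌋). Direct 3D flooring is provably identical to
intersecting two 2D grids on the yz and yx planes (they share the y axis
and the cell edge); the equivalence is kept as a property test rather than
an implementation. The grid anchor is not canonical — locus counts shift
slightly under translation — so origin and cell size are explicit
parameters. Every reported percentage names its denominator: volume
fractions are relative to the full tetrahedron (≈ 0.21651) or a named
reference hull; locus fractions are relative to the whole-sample occupied
loci or a stated union.

## Mechanism classification

The six-way assignment operationalises shape criteria that are classically
applied by expert inspection. Features are extracted from a Savitzky–Golay
smoothed curve (window 7 points ≈ 35 nm, order 3): Spearman monotonicity,
relative range, interior peaks with prominences, the 400–510 nm trough,
small "fine structure" maxima inside it (prominence 0.4–6 %R), a shoulder
(maximum derivative ≥ 0.3 %/nm followed by an OLS tail slope below
0.15 %/nm beyond 640 nm — a least-squares slope because pointwise
derivatives are dominated by spectrally correlated noise), and long-wave
versus short-wave levels.

Rule precedence: pigment+structure first (a 500–600 nm discrete maximum,
fine structure in the 450 nm trough, depressed reflectance beyond the
peak, and no discrete maximum below 490 nm — the guard that separates
iridescent double bells), then carotenoid (trough + fine structure + high
long-wave plateau with ≥ 3× long/short contrast, or a monotone sigmoid
with shoulder and the same contrast and no interior maximum), then
structural (a discrete interior maximum without the carotenoid plateau, or
a global maximum below 350 nm with ≥ 1.5× UV/long ratio — bells truncated
at the grid edge), with melanin (including white) as the fall-through.
Carotenoid-shaped spectra in Psittaciformes are psittacofulvin-based; an
unknown order keeps the carotenoid label.

All thresholds are named configuration. The defaults were calibrated once
against the synthetic spectral families below — the contract is 100 %
recovery of the generating family on noise-free spectra and ≥ 95 % at the
generator's default noise — and are *not* claimed to reproduce any
particular expert's per-species assignments on real data. The
fine-structure requirement on the combined (pigment+structure) rule is a
heuristic: it is how mid-wavelength structural bells are told apart from
carotenoid+structural greens, and purple structural colours with genuine
trough texture would challenge it.

## Synthetic avifaunas

The generator emulates the structure of a museum spectral library, not its
physics: melanin = flat or monotone (linear/saturating) curves, baseline
5–35 %R; white = flat 55–85 %R (classified with melanin); carotenoid =
logistic rise (inflection 490–530 nm, width 12–22 nm) to a 39–73 %R
plateau, with optional paired absorption dips at 425/470 nm (σ 11 nm,
depth 2.2–3.6 %R) creating the ~447 nm fine-structure maximum; structural
= Gaussian bells centred 320–480 nm (σ 25–55 nm, amplitude 25–60 %R),
25 % iridescent with a second bell 170–230 nm redward at 35–60 % relative
amplitude; pigment+structure = bells centred 555–590 nm (σ 22–30 nm) with
fine structure and a small far-red tail. Bell centres for the plain
structural family sit in the UV–blue range, where structural colour
dominates in real plumage; the combined family's centres are constrained
redward of 555 nm so its 450 nm trough is flat enough to carry fine
structure — with broader bells the rising flank erases the dips and the
two families are not separable by shape, noise-free or otherwise.

Specimen noise is smoothed white noise with ≈ 25 nm correlation length
(default SD 1.5 %R): real reflectance noise is spectrally smooth, and iid
per-wavelength noise would be trivially removable by smoothing and would
defeat shape classification unrealistically. Sexual dichromatism is
implemented as substitution — with probability `dichromatism` (default
0.4) a female's ornamental (non-melanin) patch is replaced by a
melanin/white patch — rather than parameter shrinkage, reproducing the
qualitative structure of male-exclusive peripheral colour. By default both
sexes share a patch's shape parameters, so at dichromatism 0 the sexes are
exchangeable. The default avifauna has 60 species in 4 orders (30/15/10/5),
melanin-dominant mechanism frequencies, a small parrot-like order with
disproportionate structural/psittacofulvin colour, 3 specimens per sex and
17 patches.

What passing tests on this generator do **not** show: that the classifier
thresholds transfer to real spectrometer data (real families overlap more
and contain intermediates), that absolute gamut magnitudes match any real
avifauna (they are condition-dependent), or that specimen preservation,
patch homology and measurement geometry are handled — those belong to data
collection, not this pipeline.

## Bootstrap inference

The species is the exchangeable unit: a replicate draws whole species (with
their full per-patch point sets for the relevant sex); patches are never
resampled independently. The sex-ratio design draws N species with
replacement from those with both sexes measured and records the
female/male metric ratio; replicates with a degenerate (zero) male metric
are flagged, counted and redrawn. The per-order design draws the order's
species count from the entire avifauna and expresses the metric as a
percentage of the full-sample value; sampling is with replacement by
default to mirror the sex-ratio procedure, with without-replacement as an
option. Note that with-replacement draws contain duplicate species and so
carry slightly fewer distinct species than the observed order, which makes
the observed percentage sit marginally high against the null; the
without-replacement option removes this artefact and is what the
calibration tests use.

Two-tailed p-values double the smaller tail with an add-one correction,
p = min(1, 2·min((1+#{rep ≤ obs})/(B+1), (1+#{rep ≥ obs})/(B+1))), so
finite resampling never reports p = 0; the raw doubled proportion is
available by option. Quantiles use the inclusive linear-interpolation
convention (visible in the 4th decimal at B = 10000, hence fixed).
Randomness flows from a single integer seed per call (per-stage derived
seeds in the pipeline), giving byte-identical reruns. The default B is
10000 for standalone calls and 1000 in the pipeline config; calibration
checks run 200 simulations at B = 500 with 40 single-specimen species —
problem sizes chosen to make the checks routine to run while keeping
Monte-Carlo slack well below the asserted margins.

## Known limitations

No discriminability (JND) modelling, double cones or achromatic channel;
no phylogenetically structured nulls and no multiple-testing correction
across orders; no alpha-shape or density-based gamut estimators (convex
hulls overestimate occupied space and are outlier-sensitive — the locus
grid is the robust counterpart); mechanism assignment is a shape heuristic,
and melanin's contribution inside structural colours is systematically
underestimated by any such scheme.
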