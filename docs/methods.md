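# Methods

## Contour model and conventions

A vessel outline is an ordered closed polygon in image coordinates
(x = column, y = row, y increasing downward); the closing segment is
implicit. On ingest, consecutive duplicate vertices are dropped, zero-area
(collinear) records are rejected, and the traversal is re-oriented so the
shoelace area is positive — one unambiguous convention for all downstream
math. Boundary tracing from label masks follows the crack (pixel-edge)
boundary with 8-connectivity, so a filled k×k block yields area exactly k²;
holes inside an object are ignored because only the outer cross-section
shape is analyzed. How "approximately transversal" vessels are selected for
outlining is left to the user; the package analyzes whatever outlines it is
given.

Arc-length resampling places m points uniformly along the polygon
(default m = 256, comfortably above the Nyquist need of the N = 20
harmonics computed). Resampling is chordal: resampled points lie on the
original segments, so the perimeter of the resampled polygon converges to
the original from below at O(1/m²) and is exact whenever the resample nodes
include the vertices.

## Elliptic Fourier analysis

Coefficients are computed with the closed-form segment sums for polygonal
contours (exact, no quadrature): for harmonic n,
a_n = T/(2n²π²) Σ_p (Δx_p/Δt_p)[cos(2πnt_p/T) − cos(2πnt_{p−1}/T)], b_n with
sines, c_n/d_n analogously for y, and A0/C0 from the segmentwise
first-moment integrals. The test suite checks these against an independent
dense trapezoidal quadrature of the arc-length parameterization to 1e-6.

Normalization removes everything that is not shape, via the first-harmonic
ellipse: a phase shift moves the start point to the semi-major axis, a
rigid rotation aligns that axis with x, division by the semi-major length
fixes scale (a1 = 1, b1 = c1 = 0), and if d1 < 0 the traversal direction is
reflected (b_n, d_n negated) — contour direction and mirroring are imaging
artifacts, not biology. Two genuinely open conventions were fixed as
follows:

* Either end of the major axis is a valid start point (a half-turn
  ambiguity that flips the sign of alternating harmonics). Both candidates
  are computed and the one with the lexicographically larger rounded
  coefficient sequence is kept — a shape-intrinsic rule, so the result is
  independent of the input's orientation or start index.
* "First five Fourier descriptors" is interpreted as
  D_n = sqrt(a_n² + b_n² + c_n² + d_n²) for n = 1..5 of the fully
  normalized coefficients. The originating ImageJ plugin does not document
  its exact convention; this one is scale-, rotation-, start-point- and
  chirality-invariant, which is the property the analysis requires, and is
  recorded in every descriptor table's metadata header.

Note that the arc-length parameterization of a true ellipse is not a pure
first harmonic (traversal speed modulation puts energy into odd
harmonics), so for a 2:1 ellipse D1 ≈ 1.159 rather than the
angle-parameterization value sqrt(1.25) ≈ 1.118; D1 = sqrt(2) holds exactly
for circles and decreases monotonically with elongation. Descriptor
invariance is property-tested to 1e-6 relative over randomized similarity
transforms; in practice it holds to machine precision because the
normalization is algebraic.

Defaults: N = 20 harmonics computed (so reconstruction diagnostics are
meaningful), K = 5 retained.

## Synthetic reference shapes and samples

The generator emulates the designed five-class test panel and tumor-like
samples. All classes are star-convex radial functions r(θ) about the
origin, which excludes self-intersection by construction; parameters
pushing min r below 5% of the mean radius are rejected. Class recipes
(defaults in parentheses):

* **circular** — r = R, plus the shared noise channel.
* **rectangular** — superellipse (exponent 8) of aspect ratio ≥ 1 (2.2),
  random orientation: a sharp-cornered elongated profile.
* **irregular** — random-phase radial perturbation with every angular
  order 3..6 present at mildly jittered amplitude (RMS 0.18). Order 2 is
  excluded: a dominant two-lobe dip is visually and spectrally a concavity,
  and the class is meant to be distinguishable from "concave".
* **concave** — one deep smooth Gaussian invagination (depth 0.85 of R,
  angular width 0.8 rad) at a random position.
* **indented** — sharp inward notches r = R(1 − depth·max(0, cos kθ)^q)
  (k = 4 lobes, depth 0.5, q = 4).

The shared noise channel multiplies r by 1 + noise·g(θ), where g is a
random sum of four low-order harmonics normalized to unit RMS
(noise = 0.03 by default). Class geometry and noise use separate RNG
streams derived from the seed, so degenerate class parameters (e.g.
indentation depth 0) reduce exactly to the circular recipe at the same
seed. Panel sizes vary uniformly over 40–80 px so scale invariance is
exercised end to end. These recipes were designed once for within-class
coherence and between-class separation (nearest-centroid classification of
individual shapes exceeds 95% on a 50-per-class panel; the k = 5
average-linkage cut of a 20-per-class panel is class-pure across a wide
seed sweep) and are fixed defaults, not tuning knobs.

Synthetic tumor samples draw vessels from per-group class mixtures:
normal = 0.8 circular + 0.2 mild-irregular (RMS 0.08),
indented = 0.7 indented + 0.3 circular,
angular = 0.6 rectangular + 0.4 irregular. The mixtures mirror the
qualitative description of how the three phenotype groups diverge from the
circular ideal; the exact weights are package conventions.

What the generator does **not** emulate: staining artifacts, section
thickness effects, touching/overlapping vessels, non-star-convex outlines,
and manual outlining variability. Passing tests therefore demonstrate that
the pipeline's math is correct and that it separates shape classes of this
kind at these noise levels — not that any given real tissue cohort will
separate equally cleanly.

Rendered vessel fields rasterize outlines into a label mask and paint a
perivascular stain whose intensity falls linearly from 1.0 at the vessel
surface to 0.2 at the side-specific reach, then drops to zero. The plateau
floor makes ground truth threshold-robust: any threshold below 0.2 recovers
the full reach. Overlapping vessels are an error so ground truth stays
unambiguous.

## Clustering and classification

Per-sample descriptor vectors are arithmetic means over the sample's
vessels. Samples are compared by agglomerative average linkage (UPGMA) on
Euclidean distances. The agglomeration is implemented directly (Lance–
Williams update) so the tie rule is fully specified — among equal minimal
distances, the lexicographically smallest cluster-id pair merges first —
and results are identical across platforms; scipy's implementation serves
as an independent oracle in the tests (heights agree to 1e-9). No row
scaling or centering is applied before clustering: descriptors are already
scale-normalized; a z-scoring flag is deliberately not a default.

Cutting the tree at k removes the k − 1 highest merges; ties across the cut
are resolved by merge order (earlier merges stay merged). The number of
classes k is a user input; mean silhouette widths for k = 2..6 are reported
to aid the choice.

Classification against a labeled reference panel supports two methods:

* **centroid** — nearest reference-class centroid in descriptor space.
* **cocluster** — samples and panel rows clustered jointly; the tree is cut
  at the largest k at which every cluster still contains a panel member,
  and each sample takes its cluster's majority panel label. (The finest
  such partition is the informative one — every coarser cut also
  qualifies.) A centroid fallback guards degenerate inputs and is flagged.

For three-group phenotype recovery the reference panel is a group-labeled
set of synthetic reference samples rather than the five shape-class
centroids: the angular mixture lies between the rectangular and irregular
class centroids, so mapping shape classes onto groups would be ill-posed,
whereas group-level reference samples represent each phenotype directly.

## Supply quantification

All assay operations are pure formula evaluations with explicit units:

* Evans blue (Miles assay): corrected absorbance A620 − A740 (hemoglobin is
  the only spectral correction modeled); amounts via an ordinary
  least-squares standard curve, reported as µg dye per g tissue; negative
  corrected values are returned as-is with a blank-dominated flag.
* Standard curves require ≥ 2 distinct calibration points; inversion flags
  extrapolation beyond the calibrated range.
* Tumor volume V = π/6·l·w² (mm³) with l ≥ w enforced by a warn-and-swap.
* %ID/g = 100 × (amount per gram)/(injected dose), default dose 100 µg.
* Penetration depth: stain-positive pixels (threshold: explicit, or Otsu's
  by default, recorded in the output) are assigned to the nearest vessel by
  Euclidean distance transform; each vessel's principal axis splits its
  surroundings into two sides; the per-side maximal distance-to-surface is
  taken and the per-vessel value is the mean of the two side maxima,
  aggregated as the mean over vessels. A side without stain contributes 0
  and is flagged; fields with fewer than 10 vessels are flagged. This is a
  2D automated equivalent of the manual per-side measurement on
  longitudinal vessels in z-stacks; the z-dimension is out of scope.
  On rendered fixtures the measurement recovers ground truth within 1 px
  across seeds.
* Microvessel density: objects per mm² from a count and area, or from a
  label mask plus pixel size. Positive-area fraction: positive ∧ tissue
  pixels over tissue pixels, in percent.

Pericyte-coverage scoring is deliberately not implemented: the qualitative
"degree of coverage" criterion has no operational definition precise enough
to reproduce.

## Numerical choices and limitations

* Contours with a degenerate first harmonic (magnitude < 1e-12) cannot be
  normalized and raise.
* Descriptor tolerances (1e-6 invariance, 1e-9 clustering-oracle agreement)
  are test tolerances, not runtime parameters.
* Problem sizes used by the test suite and acceptance script — 20 shapes
  per class, 8 samples per group with 20 vessels each, 100 random matrices
  up to n = 12, 20 rendered fields — keep a full run in the tens of
  seconds while exercising every code path at realistic scale.
* The crack-boundary/rasterization pair is consistent only up to the
  half-pixel boundary band; sub-pixel outline accuracy is not claimed.
* The cocluster method inherits average linkage's sensitivity to outliers;
  the centroid method is the default.
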