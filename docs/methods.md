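# Methods

## Overview

`lesionsf` quantifies the *qualitative* asymmetry of a pigmented skin
lesion. A lesion image is split in two by a line through its center of
mass; each half is reduced, per measuring function, to a vertex-filtered
graph whose **size function** — the count ℓ(x, y) of connected
components of the sublevel set {φ ≤ y} containing a point with φ ≤ x —
summarizes the half's structure. The two halves are compared with the
matching distance between the cornerpoint representations of their size
functions. Repeating over 45 equally spaced lines (4° steps over 180°)
yields a distance-versus-angle curve per measuring function; the curves
are condensed into characteristic numbers that, together with three
global shape features, feed a degree-3 polynomial-kernel SVM whose two
operating points produce a low/middle/high risk index.

Because the comparison is topological, it responds to differences in
*structure* (how many lobes, how mass and color are laid out along the
split) rather than to rigid-geometric mismatch alone.

## Size functions on graphs

A `SizeGraph` is a finite graph with a finite real value φ(v) per
vertex. Its size function is 0-dimensional persistence of the sublevel
filtration and is computed with a sorted union-find sweep: vertices in
increasing φ (ties broken by declaration order), an edge activating at
the larger endpoint value, the elder rule deciding merges. The diagram
holds proper cornerpoints (x, y), x < y (zero-persistence pairs are
dropped) and one cornerline per connected component at that component's
minimum. Correctness is checked in the test suite against a brute-force
evaluator that rebuilds the sublevel subgraph at each query point.

**Matching distance.** Proper cornerpoints are matched bijectively with
the diagonal available as a sink; the pair cost is
min(max(|Δx|, |Δy|), max(p₁/2, p₂/2)) with pᵢ the persistences, the
diagonal cost p/2, and the reported value is the minimax over
matchings — exact, via exhaustive enumeration up to 8 points and a
binary search over candidate costs with bipartite-matching feasibility
above that. Cornerlines match only cornerlines, in sorted order; if the
two halves have different component counts the distance is conceptually
infinite and a configurable cap (`cornerline_penalty`, default 2.0 — the
largest possible joint range of normalized values) is returned: a split
whose halves do not even agree topologically is maximal asymmetry
evidence. This cost rule is the standard matching distance for size
functions; it is a design choice of this package, stated here because
no single normative formula exists for the cornerline case.

**Numerical floor.** Before comparing, proper cornerpoints with
persistence ≤ `min_persistence` (default 0.005 in normalized units) are
pruned. Pruning both diagrams at level ε perturbs the matching distance
by at most ε/2 (0.0025 here) while keeping diagrams small enough for the
exact bottleneck search at 45 lines × 6 measuring functions per image.

## Segmentation and hair removal

Hairs are suppressed first: each channel is morphologically closed with
linear structuring elements (length `hair_strel_length`, default 15 px)
at 0°/45°/90°/135°, and the pixel-wise minimum over orientations is
kept. A thin dark stroke not aligned with any of the four directions is
filled by every closing; the minimum leaves everything else untouched,
and the composite is exactly idempotent (the image is edge-padded so
this holds at the frame too). Hair segments running within a few degrees
of one of the four orientations survive; they are thin and removed by
the mask morphology below.

Segmentation: Rec.601 luminance → Otsu threshold → below-threshold
pixels → opening then closing with a disk of `smooth_radius` (default
5 px) → largest 8-connected component (error `no lesion found` if none
reaches `min_area` = 500 px) → hole fill. The boundary is the sub-pixel
0.5-level marching-squares contour of the mask after Gaussian smoothing
with `contour_sigma` = 1.5 px; the smoothing removes the one-pixel
staircase ripple of a binary contour while displacing the curve by well
under a pixel. The center is the unweighted mask centroid (robust to
illumination), area the mask pixel count, perimeter the polyline arc
length.

**Bumpiness.** The boundary polyline becomes a cycle graph with
φ = distance from the centroid; bumpiness is the total persistence of
the proper cornerpoints divided by the maximal radius. Each radial lobe
contributes its depth, so a circle scores 0, a 2:1 ellipse 0.5 (one
merge at the semi-major level), and an 8-lobed star ≈ 3.2. Cornerpoints
with persistence below 0.5 px are discarded as sub-resolution contour
ripple; without this floor the sum accumulates pixelization noise along
the whole contour (≈ 0.1 for a rendered disk). The score is
scale-invariant for all lobes above the floor.

## Measuring functions

For a splitting line at angle θ ∈ [0, π) through the centroid (tangent
(sin θ, cos θ), normal (cos θ, −sin θ) in row/col coordinates):

* **boundary** — boundary points strictly on one side, connected as
  along the contour, φ = unsigned distance to the line. An arc cut from
  the contour necessarily carries one essential cornerpoint ≈ (0, max):
  its distance profile has minima at both ends. Both halves share it,
  so symmetric lesions still score ≈ 0.
* **mass** — a path graph over integer arc positions t along the line;
  φ(t) sums bilinearly interpolated grey levels at unit steps along the
  orthogonal ray into that side, restricted to the lesion mask. The 2-D
  half collapses to a 1-D profile because each orthogonal segment
  contributes a single sum.
* **color** — same path graph; φ(t) sums Euclidean RGB distances of
  consecutive ray samples (both inside the mask), i.e. the color
  variation encountered crossing the half.

The three `*_neg` variants negate φ on the same graphs, exposing
superlevel structure. For each (line, function) pair the two halves are
jointly normalized by their maximum |φ|, making φ dimensionless in
[−1, 1] and distances comparable across lesion sizes; characteristic
numbers are always computed on these normalized distances. Degenerate
halves (no vertices on a side) score `cornerline_penalty`.

## Asymmetry curves and characteristic numbers

The curve {c_k} has period π and n = 45 samples by default (90 lines
buy little and double the cost). With Δθ = π/n and cyclic forward
differences d_k = (c_{k+1} − c_k)/Δθ, the 11 characteristic numbers
are: min; max; average; min plus the value 90° from the first argmin
(the 90° offset lands between samples for odd n, so the two straddling
samples are averaged); integral Δθ Σ c_k; first moment Δθ Σ θ_k c_k
(origin at θ = 0; the moment is the one origin-dependent feature);
total variation Σ|c_{k+1} − c_k|; min and max derivative; integral of
|d|; and total variation of |d|. The variation and the integral of |d|
duplicate each other up to the Δθ factor; both are retained to keep the
published feature list intact. 11 numbers × 6 measuring functions + 
area, perimeter, bumpiness = 69 features.

## Classifier and risk index

Features are z-scored on the training set and fed to an SVC with kernel
(γ⟨u, v⟩ + 1)³, γ = 1/69, C = 1, class-balanced weights, SMO tolerance
1e-8 (reproducible decision values; duplicating the data with C halved
reproduces the decision function to 1e-6). Two operating points are
placed on the single decision axis (larger = more melanoma-like):
`threshold_high_sens` is the largest cutoff keeping ≥ 95% of training
melanomas above it, `threshold_high_spec` the smallest cutoff keeping
≥ 90% of training naevi below it (clamped so sens ≤ spec). Realizing
the "two classifiers" as two thresholds of one decision function makes
the agree/disagree logic deterministic; below both → low risk, above
both → high, between → middle. Models serialize to a documented JSON
schema (scaler, support vectors, dual coefficients, intercept,
thresholds) — no opaque binaries.

Hold-out evaluation supports scheme H (every second sample, in id
order, to the training set) and scheme R (random split with configured
per-class counts), each returning sensitivity, specificity and the full
ROC of the test scores; a stratified k-fold helper reports balanced
accuracy for recovery experiments.

## Synthetic data

The generator stands in for clinical dermoscopy frames, which are not
publicly deposited. A lesion is a star-convex region
r(θ) = R(1 + Σ a_m cos(mθ + φ_m)) on a 192² frame (R ∈ [40, 62] px in
cohorts), dark lesion on lighter skin, anti-aliased over ≈ 1 px, with
three orthogonal asymmetry dials in [0, 1]: `boundary_asym` scales the
odd harmonics (even ones deform symmetrically), `mass_asym` applies a
linear intensity gradient (up to ±45% at 1) along a random direction,
and `color_asym` displaces a fixed dark Gaussian blob (σ = R/3,
channel-weighted so it shifts hue) by 0.8·R·dial from the center.
Gaussian pixel noise (sd 1–4 in cohorts) and 0–6 dark cubic-Bézier hair
strokes of width 1–2 px complete the frame. Everything is deterministic
given the spec's seed, and the exact polar-inequality mask is returned
as ground truth.

Cohorts draw every dial from [0, 0.15] for benign and [0.4, 0.9] for
malignant lesions, with all other parameters shared. The gap is by
construction: it makes classifier recovery a well-posed end-to-end check
of the feature pipeline, not a clinical performance claim. The generator
does not model dermoscopic microstructures (pigment networks, globules),
specular highlights, vignetting, or ruler/frame artifacts, so passing
tests demonstrate that the pipeline measures what the dials control —
not that clinical hit ratios would match.

## Problem sizes and tolerances

The recovery experiment uses 100 + 100 lesions at 192² with 5-fold
stratified cross-validation (≈ 1.5 s per image end to end); oracle
checks use 200 random graphs (≤ 30 vertices, 20×20 evaluation grids)
and 200 random diagram pairs with exhaustive matching. Symmetry nulls
allow 0.05 on normalized distances (pixelization of a rendered disk);
equivariance checks allow 0.05–0.1 per entry for the combination of
resampling and re-segmentation. The exhaustive matching oracle is
limited to 8 proper points (8! assignments); the production path
switches to binary search + bipartite feasibility above that and agrees
with the oracle to 1e-9.

## Known limitations

* Star-convex synthetic lesions only; real lesion boundaries can be
  non-star-convex, where the boundary measuring function gains
  components the generator never produces (the code handles them; the
  tests do not exercise them at scale).
* The first moment depends on the image axes; rotating an input rotates
  that one feature.
* Otsu assumes a bimodal luminance histogram: very low-contrast lesions
  fail with `no lesion found` rather than degrading gracefully.
* The SVM's kernel scale/offset and C are conventional defaults, not
  tuned to any clinical data set.
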