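# Methods

## Signature model

A mass boundary is an ordered closed anticlockwise vertex sequence
`C = {p_i = (x_i, y_i), i = 1..N}` with modulo-N indexing, in pixel
coordinates (`x` = overlay column, `y` = overlay row; anticlockwise means
positive shoelace area in this frame — visual chirality is irrelevant to
every feature). The centroid is the arithmetic vertex mean, not the area
centroid: boundary files sample the contour roughly uniformly in arc
length, and the vertex mean is what the radial-signature tradition uses.

The reference ellipse is axis-aligned, centered at the centroid, with
semi-axes `D_x/2` and `D_y/2` given by the coordinate ranges. It is the
"standard" regular shape a benign mass approximates; when `D_x = D_y` it is
a circle. The ellipse-residual signature pairs each vertex `p_i` with the
point `q_i` where the ray centroid→`p_i` crosses the ellipse, at polar
radius `r_e(θ) = ab / √((b cos θ)² + (a sin θ)²)`. Ray–ellipse pairing keeps
`h` single-valued per vertex even for spiculated contours where a
nearest-point pairing would be ambiguous. The residual is unsigned,
`h(i) = |h_p(i) − r_e(θ_i)|`, with a signed variant (positive outside the
ellipse) behind a flag.

Signatures start at the right-hand crossover of the horizontal line through
the centroid. Discrete contours rarely contain the exact crossover point,
so the start vertex is chosen among vertices with `x_i > x_0` as the one
minimizing `|y_i − y_0|`, ties broken by larger `x_i`, then smaller original
index — a deterministic rule rather than sub-pixel interpolation, since the
downstream rank-ordered subsection vectors are insensitive to a one-vertex
start offset. Signatures are computed on raw vertices (unit sample spacing
of one chain-code step); no arc-length resampling is performed, because all
features either are per-sample statistics or are rank-ordered per
subsection, so contours of different N remain comparable.

## Features

All statistical averages are population moments (divide by N). Lag-based
quantities use circular indexing by default — a contour signature is a
closed loop — and linear (truncated) indexing for open segments:
subsections of a signature, and simulated fractional-Brownian profiles,
which are open paths whose wrap-around pairs would otherwise inject
O(w²) squared jumps into the small-lag power law.

* **RMS roughness** `w = √(⟨h²⟩ − ⟨h⟩²)` — vertical fluctuation scale, in
  pixels.
* **Circularity** `μ_R/σ_R` — dimensionless; large for regular contours.
  For `σ = 0` (perfectly regular synthetic contours) the ratio is capped at
  1e6 and flagged with a warning, keeping feature tables finite.
* **Height–height correlation** `H(ρ) = ⟨[h(n) − h(n+ρ)]²⟩` for
  `ρ = 1..N/2`, and normalized autocorrelation `R(ρ)` computed on
  mean-subtracted samples and normalized by `w²` so that `R(0) = 1` and R
  decays toward 0 for stationary signals (without mean subtraction R would
  plateau at `⟨h⟩²/w²`). The correlation length `ξ` is the first lag where
  R reaches `1/e`, linearly interpolated between integer lags; if R never
  gets there within `N/2` lags, `ξ = N/2` with a warning.
* **Fractal exponent** `α`: ordinary least squares on
  `(log ρ, log H(ρ))` over a small-lag window; `α = slope/2`, clipped to
  `[0, 1]` with the raw value retained for diagnostics;
  `D = 2 − α` for a planar profile. The self-affine power law holds only
  for `ρ ≪ ξ`, so the automatic fit window is
  `ρ ∈ [1, max(4, min(⌊ξ⌋, ⌊N/10⌋))]`; zero-valued H lags are excluded with
  a warning and fewer than 3 usable lags is an error. The window is
  exposed in the API for sensitivity analyses.
* **RMS slope** `s = √⟨(dh/dρ)²⟩` — forward first differences at unit lag
  (central differences behind a flag). This is the fastest-acting
  descriptor: spiculation changes the residual between *adjacent* boundary
  points, which `s` measures directly while `w` only sees the aggregated
  variance.

## Subsection ranking

The signature is split into `C` contiguous blocks (sizes differing by at
most one; the first `N mod C` blocks get the extra sample), the feature is
computed per block in linear mode, and the values are sorted ascending into
a C-vector. Ascending order is an arbitrary but fixed convention —
classifiers are insensitive to any consistent ordering. The sweep set is
`C ∈ {1, 2, 4, 6, 8, 10, 12, 14, 16, 18, 20}` (11 values); a C infeasible
for a short signature (blocks under 2 samples, or under 6 for the α fit) is
skipped with a warning and recorded, rather than failing the sweep.

## Evaluation protocol

Labels: malignant = positive. Metrics: accuracy `(TP+TN)/total`,
sensitivity `TP/(TP+FN)`, specificity `TN/(TN+FP)`; rates undefined on a
single-class test split are flagged and excluded from that repetition's
average. Splits are stratified with integer per-class quotas (largest
remainders rounded up) and seeded; one split sequence is shared across all
C values, features and signature kinds so every comparison is paired. A
single small test split has large variance, so the default protocol uses
100 repeated splits and reports means; `repetitions=1` gives a literal
single-split protocol.

Features are z-scored with training-split statistics before every
classifier — including 1-NN, which thus uses standardized Euclidean
distance — because `w`/`s` (pixels) and `μ/σ` (dimensionless, up to the 1e6
cap) differ by orders of magnitude. Classifiers are scikit-learn:
`KNeighborsClassifier(1)`, `SVC(kernel="linear", C=1)`, and
`MLPClassifier` with one hidden layer of 10 logistic units, cross-entropy
loss, at most 500 epochs with plateau-based stopping, and seeded random
initial weights (the seed varies per repetition).

## Synthetic cohorts

Both classes are polar-harmonic constructions
`r(θ) = r_e(θ)(1 + Σ_k a_k cos(kθ + φ_k))` around a random reference
ellipse with semi-axes drawn uniformly from 40–80 px, sampled at 256
angles and rounded to the pixel grid so that synthetic contours carry the
same digitization noise as chain-code input (an exact-real mode exists for
closed-form tests). The classes differ in frequency band and amplitude:

* benign — harmonic orders `k ≤ 4`, per-harmonic relative amplitude drawn
  from [0, 0.03]: a smooth, regular, near-elliptical margin;
* malignant — 4–8 harmonics with orders in [8, 30] sharing a total relative
  amplitude drawn from [0.10, 0.35], plus 2–6 narrow Gaussian spicule
  spikes (width 0.05 rad, relative height 0.05–0.15): a microlobulated,
  spiculated margin.

The non-overlapping frequency bands make class separation controllable by
a single amplitude knob, which the monotonicity tests exercise. A polar
curve is star-shaped and self-intersects only if the radius reaches zero;
the worst-case inward excursion of the harmonic sum is its total amplitude,
so totals ≥ 1 are rejected, while outward-only spicule spikes cannot cause
self-intersection and are exempt. Every generator is a pure function of
(spec, seed); cohort contours get seeds derived from one master seed and
recorded in the manifest, so any contour is independently regenerable.

What the generator does **not** emulate: pixel intensities and texture,
partial occlusion or ill-defined margins, observer variability in boundary
tracing, non-star-shaped lesions (polar construction cannot loop back on
itself), and the size/eccentricity/label correlations of real screening
populations. Passing separation tests therefore demonstrates that the
pipeline detects the geometric regularity-vs-spiculation contrast it
formalizes — not a claimed accuracy on clinical data.

fBm profiles for calibrating the α estimator are generated by circulant
embedding of fractional Gaussian noise (Davies–Harte; exact covariance up
to overall scale), cumulatively summed, mean-removed, and rescaled to the
target RMS roughness exactly; N must be a power of two ≥ 256 for the
embedding, and a spectral-synthesis fallback (with warning) covers a
non-positive-definite embedding. Because fBm has stationary increments,
the linear-mode `H(ρ)` follows `ρ^{2α}` at every lag in expectation, which
is why estimator calibration uses linear mode (see above).

## Numerical choices and degenerate inputs

* Chain codes: the default direction map is 0 = +x advancing anticlockwise
  by 45°/code, configurable because overlay dialects differ on which code
  is "up". Clockwise-traced loops are reversed on parse (start vertex kept
  first). Non-closing codes are an error reporting the terminal gap, with a
  permissive mode that appends greedy 8-connected closing steps and warns.
  Arbitrary contours export to chain codes by rounding vertices and joining
  them with greedy 8-connected walks, which reduces to exact re-encoding
  for already 8-connected input.
* Contours must have ≥ 3 vertices, no consecutive duplicates (digitization
  duplicates are dropped on construction), and positive signed area. A
  contour collapsing onto an axis-aligned line (a zero bounding diameter)
  is a degenerate-contour error.
* `polyfit` on logs for the α fit; R(ρ) via FFT in circular mode and direct
  sums in linear mode, both validated against naive double-loop references
  to 1e−9 in the test suite.

## Problem sizes

Default study conditions, used by tests and the acceptance script alike:
cohorts of 100 benign + 100 malignant contours at 256 vertices; 100
repeated splits with 23-item test sets (mirroring the classical evaluation
size for this problem); fBm calibration at N = 4096 with 20 replicates per
exponent in {0.2, 0.3, 0.5, 0.7, 0.8}; digitized-ellipse geometry checks at
720 vertices. These sizes give repetition-averaged metrics with standard
errors well below the decision margins of the associated checks.

## Known limitations

* The ellipse-residual transform assumes the centroid lies inside the
  contour and the contour is star-shaped about it; for strongly non-convex
  real lesions the ray–ellipse pairing remains single-valued but the
  radial angle ordering may fold back on itself.
* `α` from a log–log OLS is biased downward when `ξ` is small relative to
  the fit window; the automatic window mitigates but cannot eliminate this
  for very short subsections (C = 20 on N = 256 leaves ~13 samples per
  block).
* The μ/σ cap (1e6) is a pragmatic sentinel: cohorts dominated by perfectly
  regular contours would feed near-constant capped columns to the
  classifiers.
* Accuracies reported on synthetic cohorts characterize the generator's
  separation, not clinical performance.
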