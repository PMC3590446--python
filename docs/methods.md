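# Methods

## Model

A nodule is modeled as a central-symmetric Gaussian gray-level profile
`q(r) = q_max · exp(−(r/ρ)²)` truncated at radius `R`, where it reaches the
boundary gray level `q_min`.  The decay parameter is never free:
`ρ = R (ln q_max − ln q_min)^(−1/2)` follows from `q(R) = q_min`, so a
template is fully specified by (shape, R, q_max, q_min) plus the
shape-specific parameters below.  Gray levels are dimensionless window
levels on a nominal 0–255 scale; no Hounsfield calibration is performed,
inputs are assumed pre-windowed.

Four shapes: **circle** (single-slice disk), **semicircle** (half-disk for
wall-attached nodules; `angle` is the direction of the flat edge's outward
normal, counterclockwise from +x — the profile itself is isotropic, so the
angle only selects which half-plane survives), **sphere** (three stacked
layers: central layer per the radial profile, outer layers per
`q_v(r) = q_max·exp(−(r²+v²)/ρ²)` truncated at `√(R²−v²)`), and
**hollow sphere** (sphere with in-plane `r < 0.75 R` removed from the
support of every layer).  The inter-slice offset `v` (default 7 px) is a
free configuration parameter: the mapping from physical slice thickness to
`v` depends on the acquisition and is not derivable inside the package.
3D shapes require `R > v` so the outer-layer radius is real.

The gray-level distribution over a 2D template is used in the closed form
`ψ(q) = 2πR √((ln q_max − ln q)/(ln q_max − ln q_min))`, i.e. the
circumference of the iso-gray contour at `q`.  This omits the |dr/dq|
Jacobian a change-of-variables density would carry; the package implements
the printed form and treats it as an unnormalized profile, normalizing
numerically only where it is compared against empirical histograms.  The
normalized form tracks the rendered-stencil histogram to Kolmogorov
distance ≈ 0.04–0.05 for R ≥ 15, which the suite checks against a 0.1 band.

### Rasterization

A pixel belongs to the support when its center lies within the geometry
(Euclidean distance, no anti-aliasing).  Stencils are odd-sided squares
(side `2⌈R⌉+1`) or three-layer cubes so the center is a single pixel.  The
half-plane test for semicircles uses a −1e−9 tolerance so the flat-edge
line is kept whole despite trigonometric rounding.  The hollow interior is
removed from the support mask rather than filled with a background value:
matching sums run over the support only, which makes "removed" exact.

## Matching

Similarity is the normalized cross-correlation restricted to the template
support; it lies in [−1, 1] and is invariant to positive affine gray
rescaling of either input.  Windows with zero variance over the support
(or windows leaving the volume) score −∞ and can never become candidates —
clipping or padding would bias the correlation.

The search is genetic.  A chromosome packs (x, y, z, R[, angle]) in
big-endian bit fields, by default 9+9+5+5 (+4 for the semicircle
orientation, quantized to 22.5° steps).  Field widths adapt to the volume
in both directions: widening when an axis outgrows its field, narrowing
when the field vastly overshoots the axis — otherwise most offspring decode
outside the volume and the repair step piles them onto boundary voxels.
The radius gene maps `g ↦ min(R_min + g, R_max)` with the default range
5–30 px.

Defaults follow the method's stated operating point: population 100,
50 generations, single-point crossover at 0.75, per-bit mutation at 0.05,
similarity threshold 0.8, initial locations drawn uniformly from the search
space.  Where the procedure is underdetermined the package chooses:

* **Selection** — tournament of size 2: parameterless, robust to fitness
  scaling.
* **Repair** — an off-space location snaps to the Euclidean-nearest
  search-space voxel (ties broken lexicographically); radius and angle
  genes are untouched.
* **Harvesting** — every individual ever evaluated above the threshold is
  recorded, not just the final population: the goal is all above-threshold
  locations, a multimodal problem.
* **Niching** — selection fitness is derated (−0.5) near already-harvested
  peaks, and 10% of each generation are random immigrants, so the
  population keeps moving to unharvested modes instead of collapsing onto
  the single best nodule.
* **Memetic refinement** — each generation the best few distinct
  individuals take one hill step over the (±1 voxel, ±2 radius, ±1 angle
  step) neighborhood, restricted to the search space.  This matters because
  annular (hollow) templates have spike-like NCC landscapes with a weak
  halo: the GA finds the halo, the hill step finds the spike.  After
  non-maximum suppression, surviving candidates are hill-climbed to local
  optimality ("polish") for the same reason: a candidate one voxel or two
  radii off lets background into the support and corrupts the gray
  features downstream.
* **Deduplication** — greedy non-maximum suppression by descending
  similarity with suppression radius `max(R_i, R_j)`.

Matching runs separately per template shape; an exhaustive matcher
(`exhaustive_match`) enumerates every (location, radius[, angle]) and is
the oracle against which GA recall is measured on phantoms.  Since
templates are nested (a half-disk is contained in a disk, an annulus in a
sphere), different shapes can score NCC ≈ 1 on the same solid object;
detection is therefore judged by center and radius, not by shape label.

## Search space

The two upstream segmentation stages that isolate vessels, bronchi and
abnormalities are outside this package's scope; their output is consumed
either as a user-supplied binary mask or via a simple gray-threshold
stand-in.  Components smaller than `min_component` voxels are dropped
(26-connectivity).  Per-slice hole filling (on by default) returns cavity
interiors to the search space: a hollow nodule segments as an annulus whose
geometric center is background, yet the hollow template must be centered
there.

## False-positive reduction

Three features per candidate: radial nonuniformity `U` (max − min of
center-to-border distances `d(θ)` at 8 directions, computed on the
candidate-space mask slice through the candidate center; rays step 0.25 px
with bilinear lookup and stop at the first background crossing), mean gray
`q_ave` over the template support, and the 10%-tile gray `q_10` (empirical
10th percentile with lower-value interpolation, so the reported value is an
observed gray level).  `d(θ)` uses the single center slice for 3D
candidates.

Classification is naive Bayes with equiprobable priors and independent
features.  Class-conditional densities are linear combinations of Gaussians
with positive and negative components (default 2 positive, 1 negative),
fitted sequentially: standard EM for the positive components (monotone
log-likelihood, tolerance 1e−6, ≤ 500 iterations, variance floored at 1e−6
of the sample variance), then negative components placed by moment-matching
the regions where the positive model overshoots the empirical histogram,
then sign-constrained least-squares refinement of all weights, then
renormalization to unit weight sum with negative weights shrunk until the
density is non-negative over the observed range padded by 3σ.  Density
evaluations are clamped at 1e−12 in the Bayes rule; a posterior of exactly
0.5 resolves to FPN (favoring specificity).  Lung candidates use all three
features; wall (semicircular) candidates use only the gray features, since
the pleural edge makes `U` uninformative there.

## Synthetic data

The phantom generator is the package's study bench, not a fixture: nodules
are rendered with the same template stencils the matcher probes with (so
plant and probe agree exactly before noise), on a background of gray 20
with additive Gaussian noise σ = 5 by default and template gray range
`q_max = 255, q_min = 61`.  The default layout plants 10 non-overlapping
nodules — 3 circles, 2 semicircles, 3 spheres, 2 hollow spheres, radii 5–25
px — in a 128×128×9 volume, matching the in-plane resolution regime where
nodule radii span 5–30 px.  Vessel distractors are vertical tubes with
Gaussian cross-profiles (radius 2–4 px) at the same gray range, placed
clear of nodules; their cross-sections are deliberately confusable with
small circular templates.  The mask marks noiseless foreground above
background.  Everything is a pure function of config + seed.

What the phantom does **not** emulate: anatomy (lobes, pleural geometry,
airways), partial-volume and reconstruction effects, spiculated or
irregular nodule margins, gray-level inhomogeneity inside nodules, and
contact between nodules and vessels.  Passing phantom tests therefore
demonstrates the correctness of the machinery (calibration, search,
features, classification) under the model's own assumptions, not clinical
performance.

The feature-set generator draws (U, q_ave, q_10) for the three training
classes (20 false positives / 20 lung true positives / 20 wall true
positives by default).  Its class-conditional means mirror what rendered
candidates actually exhibit: for a solid template the support mean is
`(q_max − q_min)/ln(q_max/q_min) ≈ 136` (lower for 3-layer and annular
shapes, hence the wide 120 ± 20 band) and the 10%-tile sits near `q_min`;
false positives pick up background voxels (both gray features pulled down)
and have elongated borders (high U).  These are configuration defaults
describing the synthetic study, not estimates of any clinical cohort.

## Problem sizes and numerical choices

Phantom experiments run at 128×128×9 (≈ 10⁴ search-space voxels), where the
exhaustive oracle over all four shapes, 26 radii and 16 semicircle angles
completes in about a minute on one core via batched NCC (the per-template
correlation over all valid centers is one matrix product).  The GA
evaluates 100×50 individuals per shape in a few seconds.  Determinism: all
randomness flows from `numpy.random.default_rng(seed)`; the pipeline
re-run with the same seed produces byte-identical candidate CSVs.

## Known limitations

* Shape attribution of a detection is unreliable when templates nest; only
  center and radius are scored.
* The 5-bit z field covers 32 slices; longer scans rely on the automatic
  field widening, which departs from the fixed 28-bit chromosome.
* The LCG negative components refine weights only (means/variances are
  frozen after moment matching); good enough for the unimodal-per-class
  feature densities used here, but not a general density estimator.
* `U` is computed on one slice; an averaged multi-slice variant might be
  more robust for large 3D candidates.
* The GA's recall guarantee is empirical (≥ 90% of oracle-found nodules on
  the default phantom at fixed seeds), not analytic.
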