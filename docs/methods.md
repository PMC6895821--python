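# Methods

## Maxima detection

A punctum is a regional maximum of the raw intensity field: an 8-connected
set of equal-intensity pixels all of whose outside neighbours are strictly
lower. Working on raw, unaltered stored intensities (AU) is deliberate — the
acceptance criterion is *relative*, so flat-field or illumination correction
is unnecessary and would only add free parameters.

Quantized (8- or 16-bit) images produce flat-topped peaks, so plateau
handling must be explicit for counts to be well defined: by default an
equal-intensity plateau collapses to its centroid, rounded half-up to a
pixel (`plateau_policy="centroid"`); `"first"` takes the plateau pixel
first in (row, col) order. The reported intensity is the plateau value. If
two plateau representatives round to the same pixel, the more intense one
is kept, so detected points always occupy distinct pixels.

**Adjacent background.** "Adjacent" is operationalized as the annulus
`inner < d ≤ outer` (Euclidean distance between pixel centres) around the
candidate, defaults 3 and 7 px: the inner radius excludes the punctum core
(PSF sigma ≈ 1–2 px), the outer radius keeps the estimate local relative to
typical spot spacing. The statistic is the median by default — robust
against a neighbouring punctum intruding into the annulus — with the mean
available for comparison. A candidate survives when
`intensity − background ≥ delta_threshold` (default 10 AU, the criterion
the pipeline is built around).

**Edges.** Candidates closer than `edge_margin` (default = outer annulus
radius) to any border are discarded rather than scored with a truncated
annulus, which would bias the background estimate. Consequence: puncta in a
7-px border strip are never counted, in either of the two implementations
(package and brute-force oracle), so comparisons remain exact.

The implementation uses `skimage.morphology.local_maxima` for the regional
maxima mask; the test suite contains an independent pure-Python
plateau-BFS detector with explicit annulus enumeration, and the two are
required to agree point-for-point (coordinates, intensities, backgrounds)
on randomized quantized images.

## Coincidence matching

The paper-style judgement "superimposed after overlay" is made quantitative:
maxima from the two channels are paired one-to-one, accepting candidate
pairs within `match_radius` (default 2.0 px — about the registration and
localization slack of two independently detected, pixel-quantized spot
centres) in order of increasing distance. Ties in distance are broken by the
(row, col) order of the A point, then of the B point, so output is
deterministic. One-to-one matching keeps `n_coincident ≤ min(n_A, n_B)`,
which the percentage definition requires. `exact_pixel` mode (radius 0) is
retained for the strict reading of superimposed pixels.

Greedy-by-distance matching is not guaranteed optimal in cardinality; the
test suite compares it against a brute-force maximum bipartite matching
(Kuhn's algorithm) and asserts both the inequality and equality whenever
all inter-pair gaps exceed twice the radius. Percentages with empty
denominators are NA with a logged warning, never 0 or 100.

## Synthetic image model

The generator is the minimal model under which the detection criterion is
meaningful: isotropic Gaussian spots (amplitude ~ U(30, 120) AU, sigma ~
U(1, 2) px) added to a constant background (10 AU) with an optional linear
gradient, optional Gaussian or Poisson noise applied last, clipped and
rounded to the camera bit depth (default 8-bit, matching 768 × 582 RGB
acquisition geometry; bit depth is an assumption, as acquisition depth is
rarely reported). With no noise and no gradient the image minimum equals
the background level exactly.

Ground truth: exactly `round(f · n_A)` A spots (f = planted coincident
fraction) receive a B partner displaced per axis by a normal draw of
standard deviation `partner_jitter` (default 0.5 px) truncated at ±2
standard deviations. The truncation is a consistency requirement, not a
tuning: a "coincidental" pair displaced beyond the coincidence scale would
carry a geometrically false truth label. Spot centres keep a minimum
separation (default 4 × the largest sigma) between same-channel spots — so
distinct truth spots yield distinct detectable maxima — and between
non-partner spots across channels, so the planted pairing is the *only*
coincidence structure and the planted fraction is the unambiguous ground
truth. Placement is rejection sampling; an infeasible density fails
explicitly naming the constraint.

What the generator does not emulate: tissue morphology, nuclear
counterstains, autofluorescence, spatially varying PSFs, spot-shape
asymmetry, chromatic shift between channels, and clustered (non-uniform)
spot placement. Passing tests therefore demonstrate correctness of the
*measurement* given the punctate model, not robustness to every real-tissue
artefact; on real images the match radius and annulus radii are the
parameters to revisit first.

## Expression simulation and statistics

`simulate_expression` draws genes × samples values from a multivariate
normal on the log scale: covariance `diag(sd) · R · diag(sd)` with planted
correlation matrix R (validated symmetric, unit-diagonal, PSD), means and
sds per gene (defaults 8 and 1, a plausible log2-microarray scale). The
first `n_dead` samples are labelled dead and shifted additively by
`group_shift`; the last `n_unknown` are labelled unknown. Defaults mirror a
68-patient cohort split 10 dead / 57 alive / 1 undetermined.

`pearson_screen` uses `scipy.stats.pearsonr` per gene pair over
pairwise-complete samples (per-pair n reported); p-values are two-sided
from the t transform with n − 2 df. No multiple-testing correction is
applied — matching the screen it reimplements — and the report footer
states the number of tests. Star annotation uses the nested thresholds
\* p<0.05, \*\* p<0.02, \*\*\* p<0.005, showing the strictest satisfied
level. Zero-variance genes yield NA with a warning.

`group_compare` is a two-sided two-sample t test excluding unknown-status
samples, unequal-variance (Welch) by default since group variances are not
guaranteed equal at n = 10 vs 57; the pooled-variance variant is selectable.
Calibration tests use the Welch default for type-I error; the power check
uses the pooled variant, whose sampling distribution under equal variances
is exactly noncentral t with 65 df and ncp = δ/√(1/10 + 1/57), giving an
exact analytic oracle (the Welch power differs slightly through its
random degrees of freedom).

## Grading

The ordinal scale −, −/+, +, ++, +++ is embedded as {0, 0.5, 1, 2, 3} —
the minimal order-preserving embedding with the mixed grade at the midpoint
of − and +; no numeric scale is canonical, so this is a package convention
stated in the API docs. Aggregation is the arithmetic mean over observers
ignoring NA, back-mapped to the nearest symbol with ties rounded toward the
lower grade (conservative reporting). Zone qualifiers ("Only in some
zones") are annotations and never enter the numeric value. ASCII/Unicode
minus and the "+/−" spelling are normalized to one symbol set.

## Problem sizes and numerical choices

Simulation-based checks run at: 100 random 64 × 64 images for the
detector-vs-oracle comparison; 50 image pairs (10 per fraction level,
320 × 320 px, 100 spots per channel) for planted-fraction recovery; 500
point-set pairs for the matching oracle; 1000 simulations each for the
correlation-screen and t-test calibrations at n = 68. These sizes give
Monte-Carlo standard errors well inside the asserted tolerances (e.g.
±3 percentage points for recovery; 0.05 ± 0.02 for test size) while keeping
the whole suite inside a couple of minutes on one CPU. All randomness flows
from explicit integer seeds; there is no hidden global random state.

Known limitations: detection localization is pixel-level (no sub-pixel
refinement), greedy matching can be suboptimal in dense ambiguous fields
(quantified by the oracle tests), the image model is additive-Gaussian-spot
only, and probe-to-gene mapping for array data is out of scope — expression
inputs are assumed gene-level.
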