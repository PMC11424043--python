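# Methods

## The model

`tcstat` performs one-sample, two-sided cluster-extent inference for
multi-subject brain statistical maps, with the twist that the adjacency
structure used to form clusters is a *topology* `T` combining spatial
neighborhood with anatomical (white-matter) connectivity:

```
T(i,j) = 1  if  S(i,j) = 1  or  C_dist(i,j) = 1
```

where `S` is the spatial adjacency (triangle-mesh neighbors on a
cortical surface, the 26-neighborhood in a voxel grid, a 4-lattice in
the 2D phantom) and `C_dist` is a binarized group-consensus structural
connectome. Suprathreshold nodes of equal sign are grouped into
connected components of `T`; each cluster's node count (extent) is its
test statistic; family-wise error is controlled by the permutation
distribution of the maximum extent under subject-wise sign flips.
Because anatomical edges can merge spatially disjoint activations into
one cluster, small but anatomically connected effects can reach
significance that purely spatial clustering misses — the property the
ribbon phantom is designed to exhibit.

Assumptions: subject maps are exchangeable under sign flips (symmetric
null), nodes share a common geometry across subjects, and the
connectome used for clustering is meaningful at the group level.

## Building the topology

From individual streamline-count connectomes `A_s`:

1. **Consensus** `C(i,j)` = fraction of subjects with `A_s(i,j) > 0`.
2. **Distance normalization.** Consistency is strongly biased toward
   short connections. Edges are assigned to a connection class
   (interhemispheric / intrahemispheric / subcortical — any edge
   touching a subcortical node is subcortical) and, per class, split
   into equal-count distance bins (default 100). Cubic splines
   (not-a-knot boundary conditions) through the per-bin mean and sd
   give `f_mu(d)` and `f_sigma(d)`; the normalized consistency is
   `C_n = (C - f_mu(ED)) / f_sigma(ED)` with `f_sigma` floored at
   1e-6. Equal-count bins stabilize the per-bin sd estimate; not-a-knot
   ends avoid the boundary bias that natural splines introduce when the
   mean trend is curved near the shortest distances. Spline evaluation
   is clamped to the fitted bin-center range.
3. **Smoothing.** `F C_n F^T` with a row-stochastic truncated Gaussian
   kernel on Euclidean node distances (default FWHM 6 mm, truncation
   where the weight falls below 1e-6 of the peak); the product is
   re-symmetrized to absorb floating-point asymmetry.
4. **Density matching.** The smoothed matrix is thresholded to the
   average density of an individual connectome (nonzero fraction of the
   off-diagonal upper triangle) by keeping the `k` largest-weight
   edges, with deterministic tie-breaking (weight descending, then
   lexicographic node pair), then binarized to give `C_dist`.

The pipeline order is fixed: normalize, smooth, threshold, binarize,
union with `S`.

## Inference

* Per-node one-sample t statistic; Cohen's `d = t / sqrt(N)`.
  Zero-variance nodes are marked missing and can never be
  suprathreshold.
* The cluster-defining threshold (CDT) is expressed on the z scale by
  default (default 3.3, the two-sided p = 0.001 point) and converted to
  the equivalent t quantile for the sample's degrees of freedom; a
  `t`-scale mode thresholds t directly. The boundary is inclusive.
* Positive and negative suprathreshold sets are clustered separately
  (clusters never mix signs); a single pooled max-extent null across
  both signs controls the two-sided FWER. Cluster ids are dense,
  ordered by decreasing extent, ties broken by smallest member node.
* Sign flips: one `(n_perm, n_subjects)` block of independent fair
  signs from `numpy.random.default_rng(seed)`; row 0 is always the
  identity, so `p = #(null_max >= extent) / n_perm >= 1/n_perm` and the
  test is exact-level by construction. With `exhaustive=True` all
  `2^n` patterns are enumerated once (feasible for n <= 20).
* Implementation note: because squared values are invariant under sign
  flips, all permuted t maps come from a single matrix product, and
  thresholding happens on the t scale after converting the CDT once;
  this is algebraically identical to recomputing each permutation from
  scratch.

With `T = S` the procedure reduces exactly — labels, extents,
p-values — to conventional spatial cluster-extent inference; a test
verifies this against an independently coded image-space reference.

## The ribbon phantom

An 80 x 80 grid masked to an annulus between 0.55 and 0.95 of the
half-grid (~3,000 pixels) represents an axial slice; a +/-15 degree
bottom sector is the "brain stem" and each half of the remaining ring
is split into five 33 degree sectors, giving 11 atlas regions. The
ground truth is binary (peak 1, background 0) over three regions of
distinct extents: the whole right mid sector (~280 px), an angular 40%
chunk of a left sector (~110 px), and a 2 x 3 pixel patch that is the
exact mirror image of part of the large sector. Fibers: association
(deterministic near-boundary pairs between angularly adjacent sectors),
projection (seeded random stem-to-sector pairs), commissural (seeded
random mirror pairs per homotopic sector pair, always including the
small patch's mirror pairs). The small region is therefore
homotopically wired to the large one by construction.

Observations are `smooth(scale * truth + N(0, sd^2))` restricted to the
ribbon, with defaults sd 2 and Gaussian sigma 0.5 (truncated at 4
sigma, kernel renormalized inside the ribbon at its boundary). Noise is
smoothed together with the signal. An `effect_scale` of 0 gives
pure-null samples for error-rate calibration.

What the phantom does *not* emulate: realistic spatial autocorrelation
structure of BOLD noise beyond the single smoothing kernel,
between-subject anatomical variability, non-Gaussian noise, and any 3D
geometry. Passing tests on the phantom demonstrate the correctness and
calibration of the machinery, not performance on real data.

Problem sizes used in the validation suite — 200 null samples of 40
subjects at 500 permutations for the error-rate check, 100 repetitions
for the detection-contrast check, 50 for the reduction check — were
chosen to give binomial standard errors small enough for the stated
bounds while remaining desk-scale.

## Evaluation metrics

* **Sensitivity map**: per-node fraction of repetitions in which the
  node sat in a significant cluster with the ground-truth sign.
  For truth-null nodes the same bookkeeping yields the node-level
  false-positive rate.
* **Power curves**: moving-window average (default width 0.05 in d
  units, 50% overlap) of per-node power over effect size, with an
  interpolating cubic spline for a continuous curve. Descriptive, not
  inferential.
* **Bookmaker informedness** `BM = TPR + TNR - 1`. Truth-signal nodes
  are TP only when detected with the correct sign; truth-null nodes are
  FP when detected at all. Degenerate case: if the truth has no null
  nodes, the two signed classes take the binary roles so the textbook
  anchors (perfect = 1, total inversion = -1) remain exact. The
  chance-level-zero property holds for the binary significant-vs-null
  task; sign-checked scoring penalizes a random classifier below zero,
  so chance-level checks are run sign-free.
* **Threshold-free summary**: BM recomputed over a grid of binarization
  thresholds (default 21 points over 0.06-0.16, the range between the
  uncorrected and Bonferroni minimal detectable effects at N = 1000)
  and integrated to a normalized partial AUC (trapezoid / span).
* **Analytic bounds**: two-sided one-sample t-test power from the
  noncentral t distribution (noncentrality `d sqrt(N)`, df `N-1`) at
  level alpha and alpha/n_tests; the minimal detectable effect is the
  smallest grid point whose `d sqrt(N)` exceeds the two-sided critical
  t value. The noncentral-t closed form is used directly because it
  stays finite at Bonferroni-scale levels; the vanishing opposite-tail
  term is clamped to zero where scipy underflows.

## Network summaries

The anatomical matrix is filtered to edges with both endpoints
significant; downsampling to an atlas sets a region pair to 1 if any
high-resolution edge connects them (intra-region edges suppressed).
Major spatial clusters are components under `S` alone, keeping those at
least 1% (configurable) of the largest. The cluster graph weights each
anatomical link between clusters by the product of the two clusters'
maximum |d|; Kruskal's algorithm with deterministic tie-breaking
(weight descending, then node pair) extracts a maximum spanning forest
(per connected component).

## Numerical and design choices

* Matrix Market files use 1-based indices and a symmetric header
  (lower-triangle storage on disk, upper triangle in memory); 0-based
  indexing internally. Volume-mask nodes are enumerated in C order.
* Duplicate edges with conflicting weights are an error, not a silent
  merge; self-edges are rejected.
* The density threshold keeps `round(target * n(n-1)/2)` edges, so the
  achieved density matches the target within one edge.
* The smoothing kernel guarantees unit row sums to 1e-9; a
  row-stochastic kernel does not preserve the total matrix weight
  (that would require column-stochasticity), so no such invariant is
  assumed.
* All randomness flows through integer seeds into
  `numpy.random.default_rng`; every simulation and permutation result
  is bit-reproducible given (inputs, seed).

## Known limitations

* The spatial structure and geometry must be supplied or generated; no
  native-space surface processing (registration, tractography,
  streamline mapping) is performed here.
* The consensus pipeline assumes enough edges per connection class to
  fill the requested distance bins; very sparse connectomes need fewer
  bins.
* Sign-flip permutation assumes a symmetric null; skewed subject
  distributions can make the test conservative or liberal.
* TFCE-style enhancement and exchangeability-block permutation schemes
  are out of scope.
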