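# Methods

## Problem and model

`nmcoupling` quantifies how the *size* of a functional brain node shapes
the graph metrics computed on it, and turns that dependence into a
statistic — node-metric coupling (NMC) — that can be compared between
diagnostic groups.

The pipeline assumes the node-definition stage (spatially constrained ICA)
has already produced, per subject, one 3D spatial loading map per
component and a T x C table of component time courses. From there:

1. **Node size** (`nodesize`). A component's size is the number of voxels
   in its spatial map whose value strictly exceeds `k` times the map's
   standard deviation, `k = 3.5` by default. The SD is the population SD
   over all voxels of the supplied map (restricted to a brain mask when
   one is given); thresholding is one-sided on the positive tail, since
   ICA loading maps are conventionally read through positive
   participation (a `two_sided` flag counts `|v| > k*SD` instead). Ties at
   exactly `k*SD` are excluded so the count is deterministic. The size is
   a dimensionless voxel tally; no mm^3 conversion is applied.

2. **FNC graph** (`connectivity`). The functional network connectivity
   matrix is the C x C Pearson correlation of the time courses.
   Proportional thresholding retains the `round(pt * C(C-1)/2)`
   upper-triangle edges with largest |r| — magnitude ranking preserves
   strong negative coupling rather than silently discarding it — and
   zeroes the rest, keeping signed weights. Ties at the cut break by
   (row, column) index. `pt` defaults to 0.30, a mid-range density common
   for correlation networks; it is an explicit parameter everywhere and
   the CLI can sweep it. Thresholding is applied per subject (per-subject
   graphs are required for per-subject metrics).

3. **Graph metrics** (`metrics`). Six weighted metrics: node degree
   `k_i = sum_j |w_ij|`; participation coefficient
   `y_i = 1 - sum_m (k_i(m)/k_i)^2` over the functional-domain partition;
   closeness centrality `(n-1) / sum_j d_ij`; global efficiency
   (mean of `1/d_ij` over ordered pairs); characteristic path length
   (mean `d_ij` over reachable ordered pairs); and the Onnela weighted
   clustering coefficient, `t_i = (1/2) sum_{j,h} (w'_ij w'_ih w'_jh)^{1/3}`
   with weights max-normalized and `C_i = 2 t_i / (k^b_i (k^b_i - 1))`
   using the binary (neighbor-count) degree, which keeps `C_i` in [0, 1].
   Shortest paths are Dijkstra over edge lengths `1/|w|` (scipy's csgraph).
   Signed weights enter every metric through |w| (a
   `negative_weights="discard"` switch drops them instead): path lengths
   and cube roots require nonnegative weights, and magnitude is what the
   thresholding ranked by. Unreachable pairs contribute 0 to efficiency
   and are excluded (with a logged count) from the path length; an
   isolated node has closeness 0 and participation 0 by convention.

4. **NMC** (`stats`). NMC is the Pearson correlation **across subjects
   within a group** between a component's node size and a metric: for
   nodal metrics, size(·, c) against metric(·, c); for global metrics,
   size(·, c) against the subject-level global value. This orientation is
   the one under which the per-group critical correlations below follow
   from the group sizes. The grid is metrics x components (6 x 53 at the
   default layout). A single cell's significance uses the t-transform
   `t = r sqrt((n-2)/(1-r^2))`, df = n-2, two-tailed, Bonferroni-corrected
   over the grid (`alpha / 318` at 6 x 53); with the three default group
   sizes 947 / 368 / 213 this yields critical |r| of 0.12 / 0.20 / 0.26.
   Group differences in NMC use the Fisher z-test for independent
   correlations, Bonferroni over the grid. Undefined correlations
   (constant columns) propagate as missing, never as zero. Group
   differences in the three global metrics use Welch t-tests with
   Benjamini–Hochberg FDR across the metrics x group-pairs family;
   cell-wise FNC group differences use per-cell Welch t-tests on
   Fisher-z-transformed correlations with BH-FDR over the upper triangle.

## Synthetic cohorts

The generator (`synthetic`) emulates the study design the statistics are
built for — not the biophysics of BOLD data.

* **Structure.** 53 components in 7 functional domains (auditory,
  subcortical, sensorimotor, visual, cognitive control, cerebellar,
  default mode; 2/5/9/9/17/4/7 components) and three groups of 947 / 368 /
  213 subjects by default. The `desk_preset` (60 / 40 / 30 subjects, 20
  components in 5 domains, T = 120, 20^3-voxel maps) keeps replicate
  studies fast while preserving the unequal-group asymmetry.
* **Spatial maps with exact sizes.** Background voxels are standard
  normal clipped to [-3, 3]; `target_size` implant voxels get a common
  value solved (fixed-point, 10% margin) to exceed 3.5 x the finished
  map's SD. Since the map SD never drops below ~0.99, the threshold stays
  above 3.4 and no background voxel can cross it: the suprathreshold
  count equals the planted size *exactly*, giving the whole size pipeline
  an exact oracle. Planted sizes are capped at 1% of the voxel count, the
  regime where this construction is guaranteed.
* **Time courses.** T multivariate normal draws from a correlation matrix
  with within-domain blocks at 0.45, between-domain entries at 0.15, and
  per-group attenuation (1.0 / 0.95 / 0.85 for HC / MCI / AD) modelling
  globally weaker connectivity in the impaired group.
* **Planted coupling.** Row/column c of the correlation target is scaled
  by `1 + beta * z(size_c)`, z standardizing the subject's size against
  the generator's component mean and spread. Larger nodes thus carry
  stronger edges, so weighted degree — and through it the other metrics —
  correlates with size across subjects. The factor is clipped to
  [0.25, 2] and off-diagonal targets to |r| <= 0.95 so the target remains
  a valid correlation matrix at beta = 0.5; if it is still not positive
  definite it is shrunk toward the identity in steps of 0.05 (with a
  warning), erroring beyond 90% shrinkage. No generative mechanism is
  canonical here; this one is chosen because only the existence, sign and
  monotonicity of the coupling are asserted downstream, never an exact r.
* **Determinism.** Every stream derives from the master seed via
  `SeedSequence` tuples keyed by (seed, stage, subject, component);
  identical configuration gives byte-identical cohorts, and spatial maps
  are regenerated on demand rather than stored, so even the full cohort
  fits in memory.

What the generator does **not** emulate: hemodynamics, spatial
autocorrelation, motion or scanner artifacts, site effects, or realistic
per-domain effect topographies. Passing tests therefore demonstrate that
the *statistical machinery* is correct and calibrated, not that any
particular clinical effect will replicate on real data.

## Calibration and recovery studies

`experiments` packages the replicate studies used by the tests and the
reproduction script, all at the desk preset:

* **Null calibration** — 50 cohorts with `beta = 0`; the fraction of NMC
  cells crossing the Bonferroni critical r should stay near the nominal
  per-cell corrected level `alpha / (6 C)` (the test allows 2x, the usual
  binomial slack at these counts).
* **Coupling recovery** — paired-seed cohorts at beta in {0, 0.2, 0.5};
  mean degree-NMC must be positive under coupling and increase with beta
  (sign test over 20 replicates).
* **Density sweep** — thresholding honours its edge-count contract
  exactly for C in [5, 60] and pt in {0.1, ..., 1.0}.
* **Size recovery** — zero mismatches between planted and quantified
  sizes over a full desk cohort (2,600 maps).

## Numerical choices and edge cases

* Population (n) SD for map thresholds; strict `>` at the threshold.
* `round()` (banker's rounding) fixes the retained-edge count; the same
  convention is used in the contract and the tests.
* Pearson correlations are clipped to [-1, 1] after computation;
  `atanh` inputs are clipped just inside +/-1 where a transform of a
  sample r is needed.
* Constant vectors raise (single correlations) or propagate as flagged
  NaN (grid cells); degenerate zero-variance FNC cells are excluded from
  the FDR family.
* A constant spatial map has no SD threshold and is a hard error.
* `n_tests` for the Bonferroni grid defaults to metrics x components
  computed from the actual inputs (318 only at the 6 x 53 default).

## Known limitations

* The PT fraction is not identified by the study design the defaults
  mirror; conclusions can depend on it, which is why it is a required,
  sweepable parameter rather than a constant.
* Whether map SD should be computed within a brain mask is
  dataset-dependent; both modes are supported and the choice matters for
  template-level volume ratios.
* The Fisher z-test for NMC group differences assumes independent groups
  and bivariate normality within cells; no permutation alternative is
  provided (extension point only).
* Metrics are computed on |w|; networks whose negative edges carry
  distinct meaning need the `discard` policy and care in interpretation.
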