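# Methods

`nbssni` implements a case-control subnetwork-extraction framework for
node-aligned brain connectomes that tests two network representations at
once: node-level statistics on one representation (typically the structural
connectome, or anatomical per-region measures) select a set of "important
actor" nodes, and edge-level statistics on the other representation
(typically functional connectivity) select suprathreshold edges; the
extracted subnetwork is the intersection of the two, relaxed by a
neighborhood parameter `d`.  This note records the model, the defaults, the
numerical choices, and what the synthetic benchmarks do and do not show.

## Extraction model

Given groups of sizes N1 (condition) and N2 (control) on n shared nodes:

1. A node property is computed per subject: an (N, n) matrix per group.
   Built-in graph properties: closeness centrality
   `C(v) = (n-1)/Σ_u d(u,v)`, current-flow closeness
   `CFCC(v) = (n-1)/Σ_u R(u,v)` (effective resistance via the Laplacian
   pseudoinverse, weights = conductances), and the local information
   dimension (LID), minus the slope of `I_v(l) = -(n_v(l)/n) ln(n_v(l)/n)`
   against `ln l` for box radii l from the smallest distance to half the
   eccentricity of v.  Anatomical vectors (gray matter volume, intrinsic
   curvature index) attach per subject and bypass graph computation.
2. Per group, a one-sample test per node (Student t, or a one-sided
   Kolmogorov–Smirnov test for non-normal properties such as the LID);
   thresholding at `t_node` (statistic scale) or `p_node` (p scale) gives a
   suprathreshold node set per group, combined by intersection (default) or
   by taking one group's set.  A two-sample variant replaces both tests
   with one between-group test (e.g. gray-matter-volume loss).
3. A two-sample t test per functional edge, one-tailed: `hyper` tests
   condition > control, `hypo` the reverse.  The stored statistic is
   tail-signed so one `t ≥ t_edge` rule serves both tails.
4. The d-intersection: `d = 0` keeps suprathreshold edges with both
   endpoints central, `d = 1` those touching at least one central node,
   `d > 1` those within hop distance `d − 1` of the central set, distances
   measured **on the suprathreshold edge graph** (the graph on which the
   neighborhoods grow is a design choice; using only already-significant
   edges keeps the rule self-contained).

Baselines: canonical NBS (suprathreshold edges, largest connected component,
ties broken by smallest contained node index) and edge-independent BH-FDR
selection.

### Choices the underlying description leaves open

* **Null level of the one-sample node test.**  Implemented default is the
  grand mean of the property matrix, so "significant" nodes are
  significantly above-average actors within their group; `zero` and an
  explicit value are exposed.  For strictly positive properties a zero null
  would make every node significant and the node threshold vacuous.
* **KS reference distribution.**  The pooled empirical distribution of all
  values in the group's property matrix, with the one-sided D+ statistic
  (node values stochastically larger).  Parameter-free and consistent with
  the non-normality motivation for using KS at all.
* **Weighted shortest-path convention.**  Structural weights are
  affinities (fiber density), so edge traversal cost defaults to `1/w`;
  hop counting and raw-weight costs are selectable.  Which convention the
  original analyses used on weighted networks is not recoverable; it is a
  configuration knob, not a claim.
* **Vertex area in the angle-deficit curvature.**  Barycentric (one third
  of incident triangle area), which partitions the mesh area exactly and
  makes per-region intrinsic curvature `ICI_r = Σ_{v∈r}(2π − Σθ_i)/4π`
  independent of the area convention (the area cancels).  A whole closed
  sphere-topology mesh gives ICI = 1 by Gauss–Bonnet, which the tests use
  as an exact oracle.
* **LID slope fit.**  Unweighted least squares over all radii in the
  non-degenerate range; nodes with fewer than two distinct radii get LID 0
  (with a warning) so downstream statistics stay defined.
* **d = 0 connectedness.**  The claim that the d = 0 subnetwork is always a
  single connected component holds only when the central set is itself
  connected in the suprathreshold graph; it is not enforced or assumed
  anywhere.

## Synthetic data model

The generator emulates a two-group multimodal imaging cohort.

**Structural.**  Connection propensity `P(u,v) = E(d_uv) · K(u,v)` with a
three-branch distance kernel (distances in mm):
`A1·log(d−b)/(d−b)` for d < 18 with A1 = 133.49, b = −899.3;
`A2·e^{−ℓd}·d^{−η2}` for 18 ≤ d < 39 with A2 = 0.000943, ℓ = 0.2277,
η2 = −3.83; `A3·d^{−η3}` for d ≥ 39 with A3 = 275.178, η3 = 2.031.  The
long-range branch is implemented as a *decay* (`d^{−η3}`); the growing form
is available behind `printed_long_range_sign` but a connection probability
that increases without bound at long range is physically implausible and is
treated as a sign-convention slip in the source of the fitted values.
`K(u,v)` draws `1 + N(μ_nc, σ_nc)` for pairs touching the central set n_c
and `1 + N(0, σ_nc)` otherwise (σ_nc = 2 throughout; negative draws clamp
to 0, since propensities cannot be negative).  Optional robustness noise
adds folded-normal `|N(μ_x, σ_x)|` terms to every pair.  Edges are added
without replacement proportionally to P until m = 3,188 edges exist (the
default cohort scale is n = 264 nodes); the literal sequential
renormalized sampler and a Gumbel top-k sampler (the exponential-race
identity makes the two distributions equal, and a frequency test asserts
it) are both provided, the vectorized one being the default.  Edge weights
draw from a piecewise density — body `α_w e^{kw}/w + C_w` with α_w = 0.194,
k = 1.038e−6, C_w = −0.0007, and power-law tail `A_w w^{−η_w}` with
A_w = 627.78, η_w = 2.99 — via inverse-CDF sampling on a 10⁴-point grid
over support [1, 1000] (arbitrary units; the support scale is not pinned
down by the fitted constants).  The crossover defaults to the first
intersection of the two branches (≈ w = 67 under the defaults), where the
body is still positive; the body alone would go negative past w ≈ 277, so
an all-body support must end before that.

**Coordinates.**  Real atlas centroids are not bundled; a deterministic
*synthetic* 264-point cloud (uniform in a 65 × 85 × 60 mm ellipsoid, fixed
internal seed) stands in, and any 3-column mm table can be substituted.
Pairwise distances span roughly 2–170 mm, exercising all three kernel
branches.

**Functional.**  Complete symmetric matrices; every pair draws `N(0, σ)`
except planted contrast edge sets in the condition group, which draw
`N(μ_e, σ)`.  With σ = 1 the contrast-to-noise ratio (CNR) of a planted
edge equals μ_e, and the overlap coefficient with the noise density is
`OVL = 2Φ(−μ_e/2)`.

**Scenarios.**  The *embedded-contrast* scenario plants |n_c| = 5 central
nodes (μ_nc = 1.5) and, in the condition group's functional networks, 8
subcontrast edges at CNR 0.6 each touching a central node plus 11 contrast
edges at CNR 0.8 in the periphery (touching none), 30 + 30 subjects.  The
*single-contrast* scenario plants a connected 20-edge component at CNR μ_e
spanning the 5 central nodes plus exactly 2 non-central nodes.  Node
identities inside each scenario are drawn from the caller's generator;
the spatial cloud is fixed.

**What the generator does not emulate:** negative structural weights,
spatial autocorrelation of functional noise, site/motion artifacts,
hemispheric symmetry, or any coupling between structural edge weights and
functional correlations beyond the planted central-node mechanism.
Passing benchmarks therefore demonstrate correctness of the machinery and
the relative behavior of the methods under the stated model, not expected
effect sizes on real data.

## Experiments

All method comparisons are paired: within a repetition every method scores
the same generated cohort, which removes cohort-level Monte-Carlo variance
from the differences.  ROC sweeps use t_edge ∈ [0.5, 6] for the t-based
methods and q ∈ [0.001, 0.99] for FDR, with `t_node = 0.5` and `d = 1` for
the node-informed method.  The size-controlled comparison keeps the top
200 (canonical) / 300 (node-informed) t scores, takes the largest
component, applies the d = 1 intersection for the node-informed method,
and retains the top 50 edges.  Desk-scale defaults are 20 thresholds and
50–100 repetitions (the estimators are identical at the published scale of
100 thresholds and 500–1,000 repetitions; only the Monte-Carlo error
differs).  The experiments compute the node property with hop distances,
which the planted mechanism elevates just as it does the weighted variant,
at half the cost.

## Prediction

Repeated stratified K-fold classification (defaults K = 15, r = 25; the
test suite and acceptance runs use K = 5 and smaller r at its problem
sizes).  Within each training fold the configured extractor runs on
training subjects only; features are the functional weights of selected
edges (non-selected edges contribute nothing — implemented by slicing the
selected columns, which for every classifier in the zoo is equivalent to
zeroing them); accuracy is plain proportion correct (balanced accuracy
optional).  Each selected edge accumulates the fold accuracy; the
accumulated matrix averaged over all r·K folds and rescaled to max 1 is
the edge prediction-weight matrix.  Folds are stratified to avoid
single-class training splits at small N.  Node *statistics* are recomputed
per fold; the node *property values* are per-subject quantities and are
computed once (they cannot leak across subjects).  The permutation test
reassigns group labels (sizes preserved) and reruns the whole procedure;
p = #(μ_null ≥ μ_observed)/n_perm.  Classifier zoo: logistic regression,
ridge, linear SVM, decision tree, k-NN, Gaussian naive Bayes, SGD, LDA —
library defaults, no hyperparameter search.

## Numerical notes and tie-breaks

* Matrices are symmetrized by averaging when max asymmetry ≤ 1e-6 and
  rejected above that; diagonals are forced to zero.
* Zero-variance test inputs yield statistic 0 / p 1 with a warning rather
  than NaN.
* Disconnected graphs: closeness is computed per component with an
  (n_comp − 1) numerator (isolated nodes get 0); current-flow closeness
  raises, as resistance is undefined across components.
* Component-size ties (canonical NBS and the fixed-size prefilter) break
  toward the component containing the smallest node index; top-k edge
  selections sort by (−t, u, v).  All outputs are deterministic given the
  seed.
* The one-sided KS p-value uses the asymptotic bound
  `exp(−2D²·mn/(m+n))`; KS p-values are only used for p-scale node
  thresholds, never for the edge stage.

## Known limitations

* The acceptance-scale simulations use reduced repetition counts and
  threshold grids; orderings are reproduced, not curve shapes.
* The embedded-contrast recovery at `t_edge = 4` is intrinsically a
  low-power regime at CNR 0.6 with 30 subjects per group (expected edge
  t ≈ 2.3): single realizations can look far better than the average, and
  the comparison here is of *means* over seeds.
* Real-data conveniences (Fisher-z transforms, covariate adjustment,
  multi-site harmonization) are out of scope; the loader applies no
  transform to functional matrices (a hook point exists at the Subject
  level).
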