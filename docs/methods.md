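# Methods

`dcenet` detects **differentially co-expressed (DCE) gene pairs**: pairs
whose *dependency structure* — not their expression level — changes between
phenotype groups. The procedure is distribution-free and sensitive to
nonlinear dependence, where tests built on Pearson's correlation are blind.

## The two-step procedure

**Step 1 — distance-correlation screening.** A pair that is independent in
every group cannot be differentially co-expressed, so all such pairs are
removed first. Dependence is measured by the sample distance correlation:
with pairwise distances a_ij = |x_i − x_j| double-centered to
A_ij = a_ij − ā_i − ā_j + ā (and likewise B from y),

    dCov²(x, y) = (1/n²) Σ_ij A_ij B_ij,
    dCor(x, y)  = dCov(x, y) / √(dCov(x, x) · dCov(y, y)) ∈ [0, 1],

which is zero iff the variables are independent (in the population).
Significance comes from a t-approximation on the bias-corrected statistic
R*_n (U-centered inner products; under independence E[R*_n] ≈ 0):

    T_n = √(v − 1) · R*_n / √(1 − R*_n²),  v = n(n − 3)/2,  T_n ≈ t_{v−1},

one-sided in the upper tail. A label-shuffling permutation test on dCor is
available as the exact alternative (`screen_method="permutation"`).
Benjamini–Hochberg (BH) adjustment runs per group across all pairs; a pair
survives if it is significant in *any* group.

**Step 2 — graph-based edge-count testing.** For each surviving pair and
each pair of groups, the two groups' (x, y) points are pooled and a
similarity graph G is built: the union of k successive edge-disjoint
minimum spanning trees (k-MST, default k = 3) of the complete Euclidean
graph. R_k counts edges with both ends in group k. Under the permutation
null (random labels at fixed group sizes),

    μ_k = |G| n_k(n_k − 1) / (N(N − 1)),

with a covariance Σ assembled from |G|, the node degrees (through
C = ½ Σ_i deg_i² − |G|) and falling factorials of the group sizes. The
statistic S = (R − μ)ᵀ Σ⁻¹ (R − μ) is asymptotically χ² with p degrees of
freedom (p = number of groups; the classical two-group test is the p = 2
special case). If two groups differ in joint distribution, samples sit
closer to their own group and S is large. BH runs across the whole
(pair × comparison) family; a pair is DCE if any comparison is significant.

Before step 2 the matrix is quantile-normalized per group (rank-based
normal scores, Φ⁻¹((rank − 0.5)/n_g)), so every gene's marginal is
identical across groups and the test responds only to the dependency
structure (in effect a copula comparison). Screening runs *before* this
normalization: the transform exists to protect the test from differential
expression, not the screen.

Optional preprocessing removes batch and age-group effects by
median/variance matching: g* = M_i + (g − M_ij)·σ̂_i/σ̂_ij, where M_ij/σ̂_ij
are the batch median/sd of gene i and M_i/σ̂_i the overall ones. Batches
are corrected first, then age groups, as two sequential applications of
the same operation.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `kmst` | 3 | denser graphs improve the χ² approximation; 3-MST is the standard compromise |
| `fdr` | 0.05 | BH threshold for both screening and testing |
| `screen_method` | `ttest` | t-approximation; `permutation` is exact but ~10³× slower |
| `qn_reference` | `normal` | normal scores equalize marginals across unequal group sizes; `pooled` uses the gene's pooled empirical quantiles |
| `bh_scope` | `global` | one BH family over all (pair × comparison) p-values (conservative); `per_comparison` adjusts within each group pair |
| MI bins | ⌈n^{1/3}⌉ | cube-root rule for the plug-in entropy baseline |
| permutation p-values | add-one | p = (1 + #{≥ obs})/(1 + B); never zero |

## Synthetic data

`simulate` generates the study conditions used throughout the tests:

* **linear** — standard bivariate normal, correlation ρ = 0.3 in group 1
  and ρ + Δ in group 2; n = 100 per group.
* **nonlinear** — X ~ U(−2, 2), Y = X² + ε, ε ~ N(0, σ²); σ = 0.5 in
  group 1 and 0.5 + Δ in group 2. The symmetric parabola keeps the
  Pearson correlation at zero, isolating nonlinear sensitivity.
* **independence** — N(0,1) × N(0,2) and U(0,1) × U(0,2) at n = 50, for
  calibration of the screening test.
* **gene-pair panels** (`gen_pair_panel`) — 100 disjoint pairs, two groups
  of 100 samples; null pairs keep ρ = 0.3 in both groups, planted pairs
  carry a quadratic dependence in group 1 that is absent (independent,
  marginal-matched) in group 2.

These emulate the dependency structures of interest but none of the
nuisance structure of real expression data: no read-depth or library-size
variation, no heavy tails or outliers, no correlated gene blocks beyond
the planted pairs, and group sizes are balanced. Passing tests therefore
demonstrate the statistical machinery, not robustness to real-data
artifacts.

## Marginal matching and exchangeability (a warning)

The power harness matches marginals on **pooled** ranks by default rather
than normalizing each group separately. The reason is structural: mapping
each group of equal size n to its own normal-score grid places both groups
on the *identical* set of values, so every sample has an exact marginal
twin in the other group. The pooled configuration is then highly atypical
of a random labeling — between-group edges are systematically inflated —
and the permutation null that the edge-count moments (and the permutation
test itself) assume no longer holds. Measured at n = m = 100, the null
rejection rate of the nominal 5% test is ≈ 0.24 under per-group matching
and ≈ 0.04 under pooled matching, and the effect equally distorts power.
Per-group matching remains available (`matching="per_group"`) for protocol
comparison.

The pipeline's testing stage keeps per-group quantile normalization
because its purpose there is to remove genuine differential expression,
and real cohorts have unequal group sizes, which breaks the exact grid
coincidence. With equal-sized groups, however, moderate p-values from
`test_pairs` are anti-conservative for the same reason; the global BH
family keeps the false-flag rate of the full pipeline near zero in the
panel studies, but single-pair p-values near the threshold should be
interpreted cautiously (or checked with `edgecount.permutation_test`).

## Numerical choices

* MST ties are broken lexicographically by (i, j) node index, so graphs
  are deterministic; integer-valued (tie-rich) data may admit other
  equally minimal trees. The k-MST is built greedily: tree r is the
  Kruskal MST of the complete graph minus trees 1..r−1. The greedy union
  can disconnect before k trees are found even when k disjoint trees
  exist; the error names the failing round.
* A numerically singular Σ (condition number > 1e12; only tiny degenerate
  graphs) falls back to the pseudo-inverse with df = rank(Σ) and a warning.
* dCor values in (1, 1 + 1e−9] are clamped to 1; squared dCov in
  (−1e−12, 0) is clamped to 0; beyond those bands an error is raised.
* The normalized mutual information I* is clamped to ≤ 0.999999 before
  the z-transform. Entropies are plug-in estimates in natural log on
  equal-frequency (average-rank) bins, so the MI baseline is invariant to
  monotone transforms of each margin.
* The all-pairs screening is computed as Gram matrices over flattened
  centered distance matrices (two matrix products per group), which is
  what makes 20,000-pair screens take seconds; a test pins it to the
  per-pair route.

## Known limitations

* **The screening t-approximation is a high-dimension result.** In the
  univariate case used here its null distribution remains right-skewed
  (skewness ≈ 2 at n = 50): p-values are not exactly uniform and deviate
  from permutation p-values by up to ~0.1 in the mid-range, and the far
  tail is mildly anti-conservative (null P(p ≤ 0.01) ≈ 0.035). Screening
  is a search-space reduction device, not an inference guarantee; use the
  permutation screen where calibration matters. The same code on
  30-dimensional inputs is well calibrated, confirming the approximation's
  dimension dependence rather than an implementation defect.
* **The normalized-MI baseline has essentially no power** as specified:
  the z-transform of I* = I/(H(X) + H(Y)) is compared against a variance
  of 1/(n − 3), but the sampling variability of plug-in I* is an order of
  magnitude smaller at any equal-frequency bin count, so the test rejects
  (almost) never — at the null or otherwise. It is retained as a faithful
  comparison baseline; only ordering properties are asserted for it.
* The χ² approximation for the edge-count test needs min(n_k) ≳ 20;
  smaller groups should use `permutation_test`.
* Screening and testing reuse the same data; the reported FDR does not
  account for the selection step (standard practice for this pipeline
  family, but worth remembering when interpreting borderline pairs).

## Problem sizes used by the checks

The test-suite and `scripts/acceptance.py` run at the following scales,
chosen to keep Monte-Carlo error well below the asserted margins: oracle
comparisons at n ∈ [5, 40]; calibration at 10,000 replicates (n = 50);
permutation agreement at 100 replicates × 10,000 shuffles; moment checks
at 20,000 labelings (N = 40); null calibration at 1,000 replicates
(n = m = 100, 3-MST); power at 500 replicates; pipeline panels of 100
pairs (200 genes × 200 samples) over 5–20 seeds.
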