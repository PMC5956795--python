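# dcenet

Nonparametric **differential co-expression (DCE) analysis**: find gene
pairs whose *dependency structure* changes between phenotypes, including
nonlinear changes that correlation-based methods cannot see.

Differential expression asks whether a gene's *level* shifts between
conditions. Differential co-expression asks whether the *relationship*
between two genes changes — a rewiring signal that is invisible to
per-gene tests and, when the relationship is nonlinear (quadratic,
V-shaped, saturating), largely invisible to the standard approach of
comparing Pearson correlations via Fisher's z. `dcenet` is aimed at
researchers comparing co-expression across phenotype groups (e.g. tumor
subtypes) from bulk expression matrices.

## Method

Two distribution-free stages:

1. **Screening** removes pairs that are independent in every group, using
   the distance correlation

   dCor(X, Y) = dCov(X, Y) / √(dCov(X, X) dCov(Y, Y)) ∈ [0, 1],

   estimated from double-centered pairwise-distance matrices
   (dCov² = n⁻² Σ A_ij B_ij), which is zero iff X ⟂ Y. Significance uses
   the t-approximation T_n = √(v−1) R*_n / √(1 − R*_n²), v = n(n−3)/2, on
   the bias-corrected statistic R*_n (a permutation test is available).
   Benjamini–Hochberg control at FDR ≤ 0.05 per group; a pair survives if
   significant in any group.

2. **Testing** compares, for each surviving pair and each pair of groups,
   the two joint distributions after per-group quantile normalization
   (rank-based normal scores), so only the copula is compared. A 3-MST
   similarity graph over the pooled samples yields within-group edge
   counts R = (R₁, …, R_p) with closed-form permutation-null moments
   (μ, Σ); the statistic S = (R − μ)ᵀ Σ⁻¹ (R − μ) is χ²_p. BH across all
   (pair × comparison) p-values; a pair is DCE if any comparison is
   significant.

Fisher-z Pearson and normalized-mutual-information two-sample tests are
included as comparison baselines, and a simulation harness reproduces
power/type-I-error studies for all three. See `docs/methods.md` for the
formulas, design choices, and known limitations.

## Worked example

A synthetic panel of 12 gene pairs (two groups, 100 samples each), two of
which have a quadratic co-expression in group 1 that is lost in group 2:

```python
from dcenet.simulate import gen_pair_panel
from dcenet.pipeline import screen_pairs, test_pairs
from dcenet.preprocess import quantile_normalize_per_group

matrix, pairs, changed = gen_pair_panel(n_pairs=12, n_changed=2, seed=7)
screened = screen_pairs(matrix, fdr=0.05)
print(f"screening kept {len(screened.kept_pairs)} of {len(screened.pairs)} pairs")
network = test_pairs(quantile_normalize_per_group(matrix), screened, k_mst=3, fdr=0.05)
print(f"DCE pairs: {network.significant_pairs}")
print(network.table[network.table.significant].to_string(index=False))
```

prints

```
screening kept 18 of 276 pairs
DCE pairs: [('g0', 'g1'), ('g2', 'g3')]
gene_a gene_b   comparison         S        raw_p        adj_p  significant
    g0     g1 grp1_vs_grp2 34.125589 3.887967e-08 3.499170e-07         True
    g2     g3 grp1_vs_grp2 49.797351 1.536890e-11 2.766402e-10         True
```

Screening cut the 276 candidate pairs to 18 (the 12 genuinely dependent
pairs plus a few borderline keeps), and the edge-count test flagged
exactly the two planted pairs: their S values are far above the null mean
of 2, and the BH-adjusted p-values stay significant. The same analysis
runs on files via the CLI:

```sh
dcenet run --expr expr.tsv --labels labels.tsv --kmst 3 --fdr 0.05 --out-dir out/
```

writing `screening.tsv`, `network.tsv`, `dce_pairs.tsv` and a JSON run
log (optionally a GraphML export of the DCE network). The power harness
shows why the graph test earns its keep — against a quadratic dependence
change the Pearson baseline never leaves the noise floor:

```
$ dcenet simulate --setting nonlinear --deltas 0.2,0.6 --reps 100 --methods pearson,edgecount --seed 0 --out power.csv
  setting    method  delta   n  reps  rate       se  seed
nonlinear   pearson    0.2 100   100  0.21 0.040731     0
nonlinear edgecount    0.2 100   100  0.36 0.048000     0
nonlinear   pearson    0.6 100   100  0.13 0.033630     0
nonlinear edgecount    0.6 100   100  0.95 0.021794     0
```

(`rate` is the rejection fraction at α = 0.05; the nominal Pearson rate
does not grow with the effect size Δ because the quadratic is symmetric.)

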