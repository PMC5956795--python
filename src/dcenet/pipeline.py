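"""End-to-end differential co-expression (DCE) search.

The pipeline runs in two stages over a labeled expression matrix:

1. **Screening** — for every unordered gene pair and every phenotype group,
   a distance-correlation test of independence; Benjamini-Hochberg (BH)
   adjustment is applied within each group across all pairs, and a pair is
   discarded only if its adjusted p-values are above the FDR threshold in
   *every* group (an uncorrelated pair cannot be differentially
   co-expressed).  This typically shrinks the search space by an order of
   magnitude before the expensive graph tests.

2. **Testing** — for every surviving pair and every pair of groups, the
   two groups' (x, y) points are pooled, a k-MST similarity graph (default
   k = 3) is built on the quantile-normalized coordinates, and the
   two-group edge-count test compares the joint distributions.  BH is
   applied across the whole (pair x comparison) family; a pair is flagged
   DCE if any comparison is significant at the FDR threshold.

Screening runs on batch-corrected (not yet quantile-normalized) data;
quantile normalization exists to protect the *test* from marginal
differences, not the screen.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .distcorr import dcor_permutation_test, dcor
from .edgecount import KMSTError, build_kmst, two_group_test
from .preprocess import (
    ExpressionMatrix,
    load_expression,
    quantile_normalize_per_group,
    remove_batch_effect,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenResult",
    "DCENetwork",
    "RunConfig",
    "bh_adjust",
    "screen_pairs",
    "test_pairs",
    "run",
]


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sort ascending, set adj_(i) = min_{j >= i} p_(j) * m / j capped at 1,
    and map back to the input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


@dataclass
class ScreenResult:
    """Per-pair, per-group screening statistics and the keep decision."""

    table: pd.DataFrame   # gene_a, gene_b, group, dcor, raw_p, adj_p
    pairs: pd.DataFrame   # gene_a, gene_b, min_adj_p, kept
    fdr: float

    @property
    def kept_pairs(self) -> list[tuple]:
        k = self.pairs[self.pairs["kept"]]
        return list(zip(k["gene_a"], k["gene_b"]))


@dataclass
class DCENetwork:
    """Edge-count comparison results for the screened pairs."""

    table: pd.DataFrame   # gene_a, gene_b, comparison, raw_p, adj_p, significant
    pairs: pd.DataFrame   # gene_a, gene_b, min_adj_p, significant
    fdr: float
    summary: dict = field(default_factory=dict)

    @property
    def significant_pairs(self) -> list[tuple]:
        s = self.pairs[self.pairs["significant"]]
        return list(zip(s["gene_a"], s["gene_b"]))

    def graph(self):
        """The DCE network as a networkx Graph over significant pairs."""
        import networkx as nx

        g = nx.Graph()
        for a, b in self.significant_pairs:
            g.add_edge(a, b)
        return g


def _group_dcor_matrices(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs modified-dcor t-test p-values and sample dCor for one group.

    ``data`` is (G genes x n samples).  Both statistics reduce to Gram
    matrices over per-gene flattened centered distance matrices, so the
    whole G x G computation is two matrix products.  Genes constant in the
    group get p = 1 and dcor = 0 against every partner.
    """
    G, n = data.shape
    Vs = np.empty((G, n * n))     # flattened A* (bias-corrected centering)
    Ds = np.empty((G, n))         # diagonals of A*
    Wc = np.empty((G, n * n))     # flattened double-centered A
    for g in range(G):
        d = np.abs(data[g][:, None] - data[g][None, :])
        m = d.mean(axis=1)
        M = d.mean()
        A = d - m[:, None] - m[None, :] + M
        Wc[g] = A.ravel()
        A = A - d / n
        np.fill_diagonal(A, m - M)
        A *= n / (n - 1)
        Vs[g] = A.ravel()
        Ds[g] = np.diag(A)
    IP = Vs @ Vs.T - (n / (n - 2)) * (Ds @ Ds.T)
    diag = np.diag(IP).copy()
    ok = diag > 0
    denom = np.sqrt(np.outer(np.clip(diag, 0, None), np.clip(diag, 0, None)))
    with np.errstate(divide="ignore", invalid="ignore"):
        rstar = np.where(denom > 0, IP / denom, 0.0)
    dcov2 = np.clip((Wc @ Wc.T) / (n * n), 0.0, None)
    ddiag = np.diag(dcov2).copy()
    dden = np.sqrt(np.sqrt(np.outer(np.clip(ddiag, 0, None), np.clip(ddiag, 0, None))))
    with np.errstate(divide="ignore", invalid="ignore"):
        dcor_mat = np.where(dden > 0, np.sqrt(dcov2) / dden, 0.0)
    dcor_mat = np.clip(dcor_mat, 0.0, 1.0)
    df = n * (n - 3) // 2 - 1
    rc = np.clip(rstar, -1 + 1e-15, 1 - 1e-15)
    T = np.sqrt(df) * rc / np.sqrt(1.0 - rc * rc)
    P = stats.t.sf(T, df)
    bad = ~ok
    if bad.any():
        P[bad, :] = 1.0
        P[:, bad] = 1.0
        dcor_mat[bad, :] = 0.0
        dcor_mat[:, bad] = 0.0
    return P, dcor_mat


def screen_pairs(
    m: ExpressionMatrix,
    gene_set: list | None = None,
    fdr: float = 0.05,
    method: str = "ttest",
    n_perm: int = 10_000,
    seed: int = 0,
) -> ScreenResult:
    """Distance-correlation screening of all gene pairs across groups.

    A pair is kept iff its BH-adjusted independence p-value is at or below
    ``fdr`` in at least one group (BH applied per group across all pairs).
    """
    if method not in ("ttest", "permutation"):
        raise ValueError(f"unknown screening method {method!r}")
    genes = m.genes
    if gene_set is not None:
        present = [g for g in gene_set if g in m.values.index]
        absent = [g for g in gene_set if g not in m.values.index]
        if absent:
            warnings.warn(
                f"{len(absent)} gene(s) from the gene set are absent from the "
                f"matrix and were skipped: {absent[:5]}...",
                RuntimeWarning,
                stacklevel=2,
            )
        genes = present
    if len(genes) < 2:
        raise ValueError("screening requires at least 2 genes")
    pairs = list(itertools.combinations(range(len(genes)), 2))
    ia = np.array([p[0] for p in pairs])
    ib = np.array([p[1] for p in pairs])
    groups = m.group_names
    records = []
    min_adj = np.full(len(pairs), np.inf)
    rng = np.random.default_rng(seed)
    for group in groups:
        data = m.values.loc[genes, m.group_columns(group)].to_numpy()
        if method == "ttest":
            P, D = _group_dcor_matrices(data)
            raw = P[ia, ib]
            dc = D[ia, ib]
        else:
            raw = np.empty(len(pairs))
            dc = np.empty(len(pairs))
            for idx, (i, j) in enumerate(pairs):
                child = int(rng.integers(2**31))
                raw[idx] = dcor_permutation_test(data[i], data[j], n_perm=n_perm, seed=child)
                dc[idx] = dcor(data[i], data[j])
        adj = bh_adjust(raw)
        min_adj = np.minimum(min_adj, adj)
        records.append(
            pd.DataFrame(
                {
                    "gene_a": [genes[i] for i in ia],
                    "gene_b": [genes[j] for j in ib],
                    "group": group,
                    "dcor": dc,
                    "raw_p": raw,
                    "adj_p": adj,
                }
            )
        )
    table = pd.concat(records, ignore_index=True)
    pairs_df = pd.DataFrame(
        {
            "gene_a": [genes[i] for i in ia],
            "gene_b": [genes[j] for j in ib],
            "min_adj_p": min_adj,
            "kept": min_adj <= fdr,
        }
    )
    return ScreenResult(table, pairs_df, fdr)


def test_pairs(
    m: ExpressionMatrix,
    screened: ScreenResult,
    k_mst: int = 3,
    fdr: float = 0.05,
    bh_scope: str = "global",
) -> DCENetwork:
    """Edge-count tests on every screened pair for every pair of groups.

    ``m`` should be quantile-normalized per group.  With p groups each pair
    carries p(p-1)/2 comparisons; BH runs across the full
    (pair x comparison) family (``bh_scope='global'``) or within each
    comparison (``'per_comparison'``).
    """
    if bh_scope not in ("global", "per_comparison"):
        raise ValueError(f"unknown bh_scope {bh_scope!r}")
    kept = screened.kept_pairs
    groups = m.group_names
    comparisons = list(itertools.combinations(groups, 2))
    group_data = {g: m.values[m.group_columns(g)].to_numpy() for g in groups}
    gene_idx = {g: i for i, g in enumerate(m.values.index)}
    rows = []
    for a, b in kept:
        if a not in gene_idx or b not in gene_idx:
            warnings.warn(f"pair ({a}, {b}) absent from matrix; skipped",
                          RuntimeWarning, stacklevel=2)
            continue
        for g1, g2 in comparisons:
            x1 = group_data[g1][gene_idx[a]]
            y1 = group_data[g1][gene_idx[b]]
            x2 = group_data[g2][gene_idx[a]]
            y2 = group_data[g2][gene_idx[b]]
            pts = np.column_stack(
                [np.concatenate([x1, x2]), np.concatenate([y1, y2])]
            )
            if np.ptp(pts, axis=0).max() == 0:
                warnings.warn(
                    f"pair ({a}, {b}) degenerate in comparison {g1} vs {g2}; skipped",
                    RuntimeWarning, stacklevel=2,
                )
                continue
            labels = np.concatenate([np.zeros(x1.size, int), np.ones(x2.size, int)])
            try:
                graph = build_kmst(pts, k=k_mst)
            except KMSTError as exc:
                warnings.warn(
                    f"pair ({a}, {b}), comparison {g1} vs {g2}: {exc}; skipped",
                    RuntimeWarning, stacklevel=2,
                )
                continue
            res = two_group_test(graph, labels)
            rows.append((a, b, f"{g1}_vs_{g2}", res.S, res.p_value))
    table = pd.DataFrame(rows, columns=["gene_a", "gene_b", "comparison", "S", "raw_p"])
    if len(table):
        if bh_scope == "global":
            table["adj_p"] = bh_adjust(table["raw_p"].to_numpy())
        else:
            table["adj_p"] = table.groupby("comparison")["raw_p"].transform(
                lambda s: bh_adjust(s.to_numpy())
            )
        table["significant"] = table["adj_p"] <= fdr
        pair_summary = (
            table.groupby(["gene_a", "gene_b"], sort=False)
            .agg(min_adj_p=("adj_p", "min"), significant=("significant", "any"))
            .reset_index()
        )
    else:
        table = table.assign(adj_p=pd.Series(dtype=float),
                             significant=pd.Series(dtype=bool))
        pair_summary = pd.DataFrame(
            columns=["gene_a", "gene_b", "min_adj_p", "significant"]
        )
    summary = {
        "n_pairs_tested": int(pair_summary.shape[0]),
        "n_comparisons": int(table.shape[0]),
        "n_dce_pairs": int(pair_summary["significant"].sum()) if len(pair_summary) else 0,
    }
    return DCENetwork(table, pair_summary, fdr, summary)


@dataclass
class RunConfig:
    """Configuration for the end-to-end run."""

    expr: str
    labels: str
    out_dir: str
    gene_set: str | None = None
    kmst: int = 3
    fdr: float = 0.05
    screen_method: str = "ttest"
    n_perm: int = 10_000
    qn_reference: str = "normal"
    bh_scope: str = "global"
    graphml: bool = False
    seed: int = 0


def _read_gene_set(path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def run(config: RunConfig | dict) -> DCENetwork:
    """Execute load -> batch/age correction -> screen -> quantile
    normalization -> edge-count testing, writing all outputs to
    ``config.out_dir``.  Reruns with the same inputs and seed are
    byte-identical (no timestamps are written)."""
    cfg = RunConfig(**config) if isinstance(config, dict) else config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stage load: %s", cfg.expr)
    m = load_expression(cfg.expr, cfg.labels)
    if m.batches is not None:
        logger.info("stage batch-correction")
        m = remove_batch_effect(m, factor="batch")
    if m.age_groups is not None:
        logger.info("stage age-correction")
        m = remove_batch_effect(m, factor="age")

    gene_set = _read_gene_set(cfg.gene_set) if cfg.gene_set else None
    logger.info("stage screen")
    screened = screen_pairs(
        m, gene_set=gene_set, fdr=cfg.fdr, method=cfg.screen_method,
        n_perm=cfg.n_perm, seed=cfg.seed,
    )
    logger.info("stage quantile-normalization")
    mq = quantile_normalize_per_group(m, reference=cfg.qn_reference)
    logger.info("stage test")
    network = test_pairs(mq, screened, k_mst=cfg.kmst, fdr=cfg.fdr, bh_scope=cfg.bh_scope)

    screen_out = screened.table.copy()
    kept_map = dict(zip(zip(screened.pairs["gene_a"], screened.pairs["gene_b"]),
                        screened.pairs["kept"]))
    screen_out["kept"] = [
        kept_map[(a, b)] for a, b in zip(screen_out["gene_a"], screen_out["gene_b"])
    ]
    screen_out.to_csv(out / "screening.tsv", sep="\t", index=False, float_format="%.6g")
    network.table.to_csv(out / "network.tsv", sep="\t", index=False, float_format="%.6g")
    network.pairs.to_csv(out / "dce_pairs.tsv", sep="\t", index=False, float_format="%.6g")
    if cfg.graphml:
        import networkx as nx

        nx.write_graphml(network.graph(), out / "network.graphml")
    log = {
        "package": "dcenet",
        "version": __version__,
        "versions": {
            "numpy": np.__version__,
            "scipy": __import__("scipy").__version__,
            "pandas": pd.__version__,
        },
        "config": {k: getattr(cfg, k) for k in cfg.__dataclass_fields__},
        "n_genes": len(m.genes),
        "n_samples": len(m.samples),
        "groups": {g: len(m.group_columns(g)) for g in m.group_names},
        "n_pairs_screened_in": int(screened.pairs["kept"].sum()),
        **network.summary,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    return network
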