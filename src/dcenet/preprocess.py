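"""Expression-matrix loading, batch/covariate correction, marginal matching.

Two preprocessing steps protect the downstream tests from nuisance
variation:

* ``remove_batch_effect`` — median- and variance-matching within batches:
  for gene i, batch j, sample k,

      g*_ijk = M_i + (g_ijk - M_ij) * s_i / s_ij,

  where M_ij / s_ij are the batch median and standard deviation and
  M_i / s_i are the gene's overall median and standard deviation.  After
  correction every batch is re-centered on the gene's overall median.  The
  same operation with age-group labels removes age effects.

* ``quantile_normalize_per_group`` — rank-based marginal matching applied
  to each gene within each phenotype group separately, so that every
  gene's marginal distribution is identical across groups.  The
  joint-distribution test downstream then responds only to changes in the
  dependency structure (the copula), not to differential expression.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "remove_batch_effect",
    "quantile_normalize_per_group",
    "normal_scores",
    "load_expression",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples log-expression with sample group (and batch) labels.

    ``constant_flags`` records (gene, group) combinations found constant
    during quantile normalization; such genes carry no rank information in
    that group and are excluded from screening there.
    """

    values: pd.DataFrame               # index: genes, columns: samples
    groups: pd.Series                  # index: samples -> group label
    batches: pd.Series | None = None   # index: samples -> batch label
    age_groups: pd.Series | None = None
    constant_flags: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene identifiers")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        self.groups = self.groups.loc[self.values.columns]
        for attr in ("batches", "age_groups"):
            lab = getattr(self, attr)
            if lab is not None:
                absent = [s for s in self.values.columns if s not in lab.index]
                if absent:
                    raise ValueError(f"samples without a {attr} label: {absent}")
                setattr(self, attr, lab.loc[self.values.columns])

    @property
    def genes(self) -> list:
        return list(self.values.index)

    @property
    def samples(self) -> list:
        return list(self.values.columns)

    @property
    def group_names(self) -> list:
        return sorted(self.groups.unique())

    def group_columns(self, group) -> list:
        return list(self.groups.index[self.groups == group])

    def group_values(self, group) -> pd.DataFrame:
        return self.values[self.group_columns(group)]


def _match_batches(values: pd.DataFrame, batches: pd.Series) -> pd.DataFrame:
    out = values.copy()
    overall_median = values.median(axis=1)
    overall_sd = values.std(axis=1, ddof=1)
    for batch in pd.unique(batches):
        cols = list(batches.index[batches == batch])
        if len(cols) < 2:
            raise ValueError(f"batch {batch!r} has fewer than 2 samples")
        block = values[cols]
        med = block.median(axis=1)
        sd = block.std(axis=1, ddof=1)
        zero = sd == 0
        scale = overall_sd.where(~zero, 0.0) / sd.where(~zero, 1.0)
        scale = scale.where(~zero, 1.0)  # shift-only for zero-variance genes
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} gene(s) constant within batch {batch!r}; "
                "shifted without rescaling",
                RuntimeWarning,
                stacklevel=3,
            )
        out[cols] = (block.sub(med, axis=0)).mul(scale, axis=0).add(overall_median, axis=0)
    return out


def remove_batch_effect(m: ExpressionMatrix, factor: str = "batch") -> ExpressionMatrix:
    """Median/variance matching across batches (``factor='batch'``) or age
    groups (``factor='age'``).

    With a single batch the transform is the identity.  Genes with zero
    within-batch variance are shifted to the overall median but not
    rescaled.
    """
    labels = m.batches if factor == "batch" else m.age_groups
    if factor not in ("batch", "age"):
        raise ValueError(f"unknown factor {factor!r}")
    if labels is None:
        raise ValueError(f"no {factor} labels present")
    corrected = _match_batches(m.values, labels)
    return replace(m, values=corrected)


def normal_scores(v: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform: Phi^{-1}((rank - 0.5) / n).

    Ties receive average ranks.  A constant vector maps to all zeros.
    """
    v = np.asarray(v, dtype=float)
    n = v.size
    if np.all(v == v[0]):
        return np.zeros(n)
    ranks = stats.rankdata(v, method="average")
    return stats.norm.ppf((ranks - 0.5) / n)


def _pooled_scores(v: np.ndarray, pooled: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = v.size
    if np.all(v == v[0]):
        return np.zeros(n)
    ranks = stats.rankdata(v, method="average")
    return np.quantile(np.sort(pooled), (ranks - 0.5) / n)


def quantile_normalize_per_group(
    m: ExpressionMatrix, reference: str = "normal"
) -> ExpressionMatrix:
    """Quantile-normalize each gene within each group to a fixed reference.

    ``reference='normal'`` (default) maps values to normal scores, so every
    gene's within-group marginal is the same standard-normal reference
    regardless of group size.  ``reference='pooled'`` uses the gene's
    pooled empirical quantiles instead.  Genes constant within a group are
    set to zero there and recorded in ``constant_flags``.
    """
    if reference not in ("normal", "pooled"):
        raise ValueError(f"unknown reference {reference!r}")
    out = m.values.copy()
    flags: list[tuple[str, str]] = list(m.constant_flags)
    for group in m.group_names:
        cols = m.group_columns(group)
        if len(cols) < 4:
            raise ValueError(f"group {group!r} has fewer than 4 samples")
        block = m.values[cols].to_numpy()
        for gi, gene in enumerate(m.values.index):
            row = block[gi]
            if np.all(row == row[0]):
                flags.append((gene, group))
                out.loc[gene, cols] = 0.0
            elif reference == "normal":
                out.loc[gene, cols] = normal_scores(row)
            else:
                out.loc[gene, cols] = _pooled_scores(row, m.values.loc[gene].to_numpy())
    return replace(m, values=out, constant_flags=flags)


def load_expression(
    path, groups_path, batches_path=None, *, sep: str | None = None
) -> ExpressionMatrix:
    """Load an expression matrix plus sample labels from delimited text.

    The matrix file has gene IDs in the first column and a header row of
    sample IDs.  The label file has no header: ``sample_id  group
    [batch [age_group]]``.  ``batches_path`` may supply batch labels in a
    separate two-column file instead.  Genes containing missing values are
    dropped (with a logged count); samples lacking a label raise an error.
    """
    values = pd.read_csv(path, sep=sep, engine="python", index_col=0)
    n_bad = int(values.isna().any(axis=1).sum())
    if n_bad:
        logger.warning("dropping %d gene(s) with missing values", n_bad)
        values = values.dropna(axis=0)
    lab = pd.read_csv(groups_path, sep=sep, engine="python", header=None)
    lab = lab.set_index(0)
    if lab.index.has_duplicates:
        raise ValueError("duplicate sample identifiers in label file")
    groups = lab[1]
    batches = lab[2] if lab.shape[1] >= 2 else None
    ages = lab[3] if lab.shape[1] >= 3 else None
    if batches_path is not None:
        b = pd.read_csv(batches_path, sep=sep, engine="python", header=None).set_index(0)
        batches = b[1]
    missing = [s for s in values.columns if s not in groups.index]
    if missing:
        raise ValueError(f"label file is missing sample(s): {missing}")
    return ExpressionMatrix(values.astype(float), groups, batches, ages)
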