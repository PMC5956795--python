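"""Comparison methods: Fisher-z tests on Pearson correlation and on
normalized mutual information.

Both baselines test whether a gene pair's association strength differs
between two phenotypes by z-transforming a per-group association measure
and comparing the transforms with a two-sample z-test,

    p = 2 P(Z > |z_1 - z_2| / sqrt(1/(n_1 - 3) + 1/(n_2 - 3))).

For the Pearson baseline the measure is the sample correlation r and
z = arctanh(r).  For the mutual-information baseline the measure is the
normalized MI

    I* = I(X, Y) / (H(X) + H(Y)),

with plug-in entropies (natural log) on equal-frequency bins, and the same
z-transform is applied to I*.  The Pearson test only sees linear
association; the MI test sees nonlinear association but loses power to the
discretization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .distcorr import BivariateSample, _as_xy

__all__ = [
    "TwoSampleZResult",
    "fisher_z",
    "pearson_diff_test",
    "discretize_equal_freq",
    "mi_diff_test",
]

#: normalized MI is clamped below this before the z-transform
_MI_CLAMP = 0.999999


@dataclass(frozen=True)
class TwoSampleZResult:
    """Per-group z statistics and the two-sided comparison p-value."""

    stat1: float
    stat2: float
    z: float
    p_value: float
    n1: int
    n2: int


def fisher_z(r: float) -> float:
    """Fisher's z-transform, z = 1/2 log((1 + r)/(1 - r)); requires |r| < 1."""
    if abs(r) >= 1:
        raise ValueError(f"fisher_z requires |r| < 1, got {r}")
    return 0.5 * math.log((1 + r) / (1 - r))


def _two_sample_z(z1: float, z2: float, n1: int, n2: int) -> tuple[float, float]:
    denom = math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = abs(z1 - z2) / denom
    return z, float(2 * stats.norm.sf(z))


def _sample(g) -> BivariateSample:
    return g if isinstance(g, BivariateSample) else BivariateSample(*g)


def pearson_diff_test(g1, g2) -> TwoSampleZResult:
    """Two-sample Fisher-z test for equality of Pearson correlations."""
    s1, s2 = _sample(g1), _sample(g2)
    if s1.n < 4 or s2.n < 4:
        raise ValueError("pearson_diff_test requires n >= 4 in each group")
    for s in (s1, s2):
        if np.std(s.x) == 0 or np.std(s.y) == 0:
            raise ValueError("constant margin: Pearson correlation undefined")
    r1 = float(np.corrcoef(s1.x, s1.y)[0, 1])
    r2 = float(np.corrcoef(s2.x, s2.y)[0, 1])
    z1, z2 = fisher_z(r1), fisher_z(r2)
    z, p = _two_sample_z(z1, z2, s1.n, s2.n)
    return TwoSampleZResult(z1, z2, z, p, s1.n, s2.n)


def discretize_equal_freq(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency (quantile) binning by average ranks; labels 1..n_bins.

    Tied values share an average rank and therefore always land in the same
    bin, so occupancies differ only by what ties force.  The labels depend
    on ranks alone, hence are invariant to monotone transforms.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if n_bins > n:
        raise ValueError(f"n_bins={n_bins} exceeds sample size {n}")
    ranks = stats.rankdata(x, method="average")
    labels = np.ceil(ranks * n_bins / n).astype(int)
    return np.clip(labels, 1, n_bins)


def _plugin_entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def _normalized_mi(x: np.ndarray, y: np.ndarray, n_bins: int) -> float:
    bx = discretize_equal_freq(x, n_bins)
    by = discretize_equal_freq(y, n_bins)
    joint = np.zeros((n_bins, n_bins))
    np.add.at(joint, (bx - 1, by - 1), 1.0)
    hx = _plugin_entropy(joint.sum(axis=1))
    hy = _plugin_entropy(joint.sum(axis=0))
    hxy = _plugin_entropy(joint.ravel())
    if hx + hy == 0:
        raise ValueError("degenerate marginals: H(X) + H(Y) = 0")
    i = max(hx + hy - hxy, 0.0)
    return min(i / (hx + hy), _MI_CLAMP)


def default_bins(n: int) -> int:
    # cube-root rule for plug-in MI on continuous data
    return max(2, math.ceil(n ** (1 / 3)))


def mi_diff_test(g1, g2, n_bins: int | None = None) -> TwoSampleZResult:
    """Two-sample Fisher-z test on normalized mutual information I*.

    Entropies are plug-in estimates (natural log) on equal-frequency bins;
    the bin count defaults to ceil(n^(1/3)) of the smaller group.
    """
    s1, s2 = _sample(g1), _sample(g2)
    if s1.n < 16 or s2.n < 16:
        raise ValueError("mi_diff_test requires n >= 16 in each group")
    if n_bins is None:
        n_bins = default_bins(min(s1.n, s2.n))
    i1 = _normalized_mi(s1.x, s1.y, n_bins)
    i2 = _normalized_mi(s2.x, s2.y, n_bins)
    z1, z2 = fisher_z(i1), fisher_z(i2)
    z, p = _two_sample_z(z1, z2, s1.n, s2.n)
    return TwoSampleZResult(z1, z2, z, p, s1.n, s2.n)
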