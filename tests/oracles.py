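"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately written element-by-element, without
vectorized shortcuts and without importing the code paths it checks.
"""

import math

import numpy as np


def naive_dcov(x, y):
    """Triple-loop sample distance covariance (V-statistic form)."""
    n = len(x)
    a = [[abs(x[i] - x[j]) for j in range(n)] for i in range(n)]
    b = [[abs(y[i] - y[j]) for j in range(n)] for i in range(n)]

    def center(d):
        rbar = [sum(d[i]) / n for i in range(n)]
        gbar = sum(sum(row) for row in d) / (n * n)
        return [[d[i][j] - rbar[i] - rbar[j] + gbar for j in range(n)] for i in range(n)]

    A = center(a)
    B = center(b)
    s = 0.0
    for i in range(n):
        for j in range(n):
            s += A[i][j] * B[i][j]
    return math.sqrt(max(s / (n * n), 0.0))


def naive_dcor(x, y):
    num = naive_dcov(x, y)
    den = math.sqrt(naive_dcov(x, x) * naive_dcov(y, y))
    return num / den


def cramer_two_group_S(graph, labels):
    """Two-group edge-count statistic built scalar-by-scalar.

    Sigma is assembled term-by-term from the printed moment formulas and
    inverted by Cramer's rule on the 2x2 system.
    """
    edges = [tuple(e) for e in graph.edges]
    N = graph.n_nodes
    n = int(sum(1 for g in labels if g == 0))
    m = N - n
    G = len(edges)
    R1 = sum(1 for (i, j) in edges if labels[i] == 0 and labels[j] == 0)
    R2 = sum(1 for (i, j) in edges if labels[i] == 1 and labels[j] == 1)
    deg = [0] * N
    for i, j in edges:
        deg[i] += 1
        deg[j] += 1
    C = 0.5 * sum(d * d for d in deg) - G
    mu1 = G * n * (n - 1) / (N * (N - 1))
    mu2 = G * m * (m - 1) / (N * (N - 1))
    s11 = (
        mu1 * (1 - mu1)
        + 2 * C * n * (n - 1) * (n - 2) / (N * (N - 1) * (N - 2))
        + (G * (G - 1) - 2 * C)
        * n * (n - 1) * (n - 2) * (n - 3)
        / (N * (N - 1) * (N - 2) * (N - 3))
    )
    s22 = (
        mu2 * (1 - mu2)
        + 2 * C * m * (m - 1) * (m - 2) / (N * (N - 1) * (N - 2))
        + (G * (G - 1) - 2 * C)
        * m * (m - 1) * (m - 2) * (m - 3)
        / (N * (N - 1) * (N - 2) * (N - 3))
    )
    s12 = (
        (G * (G - 1) - 2 * C)
        * n * m * (n - 1) * (m - 1)
        / (N * (N - 1) * (N - 2) * (N - 3))
        - mu1 * mu2
    )
    det = s11 * s22 - s12 * s12
    d1 = R1 - mu1
    d2 = R2 - mu2
    # Cramer: Sigma^{-1} = (1/det) [[s22, -s12], [-s12, s11]]
    return (d1 * (s22 * d1 - s12 * d2) + d2 * (-s12 * d1 + s11 * d2)) / det


def naive_bh(pvals):
    """Step-up BH written from the definition, index by index."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(pvals[i] * m / rank, prev)
        adj[i] = val
        prev = val
    return np.array(adj)
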