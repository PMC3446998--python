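"""Independent oracles shared by the test suite.

Everything here is deliberately written as a separate code path from the
package: dense eigen-decomposition for stationary vectors, direct formula
correlation, brute-force set/filter/scan oracles, and an interval-based
re-derivation of Duncan's letter grouping.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import studentized_range

from prorank.network_io import InteractionNetwork


def random_directed_network(rng: np.random.Generator, n: int, p: float) -> InteractionNetwork:
    names = [f"N{i:03d}" for i in range(n)]
    edges = [
        (names[i], names[j])
        for i in range(n)
        for j in range(n)
        if i != j and rng.random() < p
    ]
    return InteractionNetwork.from_edges(edges, extra_nodes=names)


def dense_stationary(transition, alpha: float) -> np.ndarray:
    """Principal left eigenvector of the dense scaled matrix, sum-1 normalised."""
    m = transition.scaled_dense(alpha)
    eigvals, eigvecs = np.linalg.eig(m.T)
    principal = np.argmin(np.abs(eigvals - 1.0))
    vec = np.real(eigvecs[:, principal])
    vec = np.abs(vec)
    return vec / vec.sum()


def pearson_r_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """From-scratch covariance / sigma product-moment correlation."""
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))


def anova_f_oracle(groups) -> float:
    """One-way F via explicit sums of squares (no library call)."""
    all_values = [v for g in groups for v in g]
    grand = sum(all_values) / len(all_values)
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum((v - sum(g) / len(g)) ** 2 for g in groups for v in g)
    dfb = len(groups) - 1
    dfw = len(all_values) - len(groups)
    return (ssb / dfb) / (ssw / dfw)


def duncan_letters_oracle(groups, alpha: float = 0.05) -> list[str]:
    """Independent interval-merging re-derivation of Duncan's letter display.

    Walks the sorted means and, for every starting position, extends the
    homogeneous stretch as far as the step-down critical ranges allow
    (re-testing every enclosing span directly rather than via the
    acceptance list used by the implementation).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    g = len(arrays)
    sizes = np.array([len(a) for a in arrays])
    df = int(sizes.sum()) - g
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays) / df
    n_h = g / (1.0 / sizes).sum()
    means = np.array([a.mean() for a in arrays])
    order = np.argsort(-means, kind="stable")
    sm = means[order]

    def critical(span: int) -> float:
        if mse == 0.0:
            return 0.0
        q = studentized_range.ppf((1 - alpha) ** (span - 1), span, df)
        return float(q) * math.sqrt(mse / n_h)

    # homogeneous[i][j]: the span i..j (and everything inside) passes the
    # step-down test, i.e. some enclosing-or-equal span has range <= R_p.
    def span_ok(i: int, j: int) -> bool:
        for a in range(0, i + 1):
            for b in range(j, g):
                span = b - a + 1
                if span >= 2 and sm[a] - sm[b] <= critical(span):
                    return True
        return i == j

    maximal = []
    for i in range(g):
        j = i
        while j + 1 < g and span_ok(i, j + 1):
            j += 1
        maximal.append((i, j))
    # drop intervals contained in an earlier one
    kept = []
    for iv in maximal:
        if not any(c <= iv[0] and iv[1] <= d for c, d in kept):
            kept.append(iv)

    letters_sorted = ["" for _ in range(g)]
    for idx, (a, b) in enumerate(sorted(kept)):
        for pos in range(a, b + 1):
            letters_sorted[pos] += chr(ord("A") + idx)
    letters = ["" for _ in range(g)]
    for pos, orig in enumerate(order):
        letters[orig] = letters_sorted[pos]
    return letters
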