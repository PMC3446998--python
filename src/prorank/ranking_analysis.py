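"""Comparison machinery for ranking results.

Top/middle/bottom group extraction, correlation between rankings (Pearson
or Spearman, on raw scores or rank positions), top-k overlap and common
sets, and the top-vs-bottom fold ratio of mean scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from prorank.pagerank import RankingResult

CORRELATION_METHODS = ("pearson", "spearman")
CORRELATION_BASES = ("score", "position")

DEFAULT_GROUP_SIZE = 50


class AlignmentError(ValueError):
    """Ranking results cover different protein sets."""


@dataclass(frozen=True)
class RankGroups:
    """Top-k, centered middle-k and bottom-k proteins of one ranking."""

    top: tuple[str, ...]
    mid: tuple[str, ...]
    bottom: tuple[str, ...]
    k: int

    def as_dict(self) -> dict[str, tuple[str, ...]]:
        return {"top": self.top, "mid": self.mid, "bottom": self.bottom}


@dataclass(frozen=True)
class ComparisonStats:
    r: float
    p: float
    method: str
    basis: str

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.r <= 1.0 + 1e-9:
            raise ValueError(f"correlation out of range: {self.r}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p-value out of range: {self.p}")


def _common_nodes(*results: RankingResult) -> tuple[str, ...]:
    node_sets = [set(r.scores) for r in results]
    first = node_sets[0]
    for other in node_sets[1:]:
        if other != first:
            raise AlignmentError(
                "ranking results cover different protein sets "
                f"(sizes {sorted(len(s) for s in node_sets)})"
            )
    return tuple(sorted(first))


def extract_groups(result: RankingResult, k: int = DEFAULT_GROUP_SIZE) -> RankGroups:
    """Top-k, middle-k (centered window) and bottom-k proteins.

    With n proteins, top covers positions 1..k, bottom covers n−k+1..n and
    mid covers the k positions starting at floor((n−k)/2)+1. The three
    groups are pairwise disjoint whenever 3k ≤ n.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = result.n
    if n < k:
        raise ValueError(f"k={k} exceeds ranking size n={n}")
    ordered = result.by_position()
    mid_start = (n - k) // 2  # 0-based
    return RankGroups(
        top=tuple(ordered[:k]),
        mid=tuple(ordered[mid_start : mid_start + k]),
        bottom=tuple(ordered[n - k :]),
        k=k,
    )


def correlate(
    r1: RankingResult,
    r2: RankingResult,
    method: str = "pearson",
    basis: str = "score",
    exact: bool = False,
) -> ComparisonStats:
    """Correlation between two rankings over their shared protein set.

    ``basis='score'`` correlates stationary probabilities, ``'position'``
    correlates 1-based rank positions. The p-value is two-sided; for
    Pearson it comes from the t-transform with n−2 degrees of freedom,
    unless ``exact`` is set, which switches to a permutation p-value
    (exhaustive for small n) — only sensible for n < 20.
    """
    if method not in CORRELATION_METHODS:
        raise ValueError(f"unknown correlation method {method!r}")
    if basis not in CORRELATION_BASES:
        raise ValueError(f"unknown correlation basis {basis!r}")
    nodes = _common_nodes(r1, r2)
    if basis == "score":
        x = np.array([r1.scores[v] for v in nodes])
        y = np.array([r2.scores[v] for v in nodes])
    else:
        x = np.array([r1.positions[v] for v in nodes], dtype=float)
        y = np.array([r2.positions[v] for v in nodes], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance in one input")
    kwargs = {}
    if exact:
        kwargs["method"] = stats.PermutationMethod(n_resamples=9999, rng=0)
    if method == "pearson":
        res = stats.pearsonr(x, y, **kwargs)
    else:
        res = stats.spearmanr(x, y, **kwargs)
    return ComparisonStats(
        r=float(res.statistic), p=float(res.pvalue), method=method, basis=basis
    )


def top_k_overlap(
    r1: RankingResult, r2: RankingResult, k: int
) -> tuple[int, frozenset[str]]:
    """Size and identity of the intersection of two top-k sets."""
    nodes = _common_nodes(r1, r2)
    if k > len(nodes):
        raise ValueError(f"k={k} exceeds n={len(nodes)}")
    top1 = set(r1.by_position()[:k])
    top2 = set(r2.by_position()[:k])
    shared = frozenset(top1 & top2)
    return len(shared), shared


def common_top_k(results: Sequence[RankingResult], k: int) -> frozenset[str]:
    """Intersection of the top-k sets of all given rankings."""
    if len(results) < 2:
        raise ValueError("need at least two rankings")
    nodes = _common_nodes(*results)
    if k > len(nodes):
        raise ValueError(f"k={k} exceeds n={len(nodes)}")
    common: set[str] | None = None
    for result in results:
        top = set(result.by_position()[:k])
        common = top if common is None else common & top
    return frozenset(common or set())


def fold_ratio(result: RankingResult, k: int) -> float:
    """Mean top-k score divided by mean bottom-k score (≥ 1 by construction)."""
    n = result.n
    if n < 2 * k:
        raise ValueError(f"need n >= 2k (n={n}, k={k})")
    ordered = result.by_position()
    top_mean = float(np.mean([result.scores[v] for v in ordered[:k]]))
    bottom_mean = float(np.mean([result.scores[v] for v in ordered[n - k :]]))
    if bottom_mean == 0:
        raise ZeroDivisionError("bottom-k mean score is zero")
    return top_mean / bottom_mean


def comparison_rows(
    results: Sequence[RankingResult],
    k: int,
    method: str = "pearson",
    basis: str = "score",
) -> list[dict[str, object]]:
    """Pairwise comparison summary rows plus one common-top-k row.

    Used by the CLI to emit one TSV row per ranking pair (r, p, overlap@k,
    fold ratios) and a final row with the all-methods common set.
    """
    rows: list[dict[str, object]] = []
    for i in range(len(results)):
        for j in range(i + 1, len(results)):
            a, b = results[i], results[j]
            cs = correlate(a, b, method=method, basis=basis)
            count, shared = top_k_overlap(a, b, k)
            rows.append(
                {
                    "pair": f"{a.method}~{b.method}",
                    "r": cs.r,
                    "p": cs.p,
                    "method": cs.method,
                    "basis": cs.basis,
                    "overlap_k": count,
                    "k": k,
                    "fold_ratio_1": fold_ratio(a, k),
                    "fold_ratio_2": fold_ratio(b, k),
                    "shared": ";".join(sorted(shared)),
                }
            )
    if len(results) >= 2:
        common = common_top_k(results, k)
        rows.append(
            {
                "pair": "common_top_k",
                "r": "",
                "p": "",
                "method": "",
                "basis": "",
                "overlap_k": len(common),
                "k": k,
                "fold_ratio_1": "",
                "fold_ratio_2": "",
                "shared": ";".join(sorted(common)),
            }
        )
    return rows
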