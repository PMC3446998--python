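"""Direction-specific transition matrices and scaled PageRank.

Three walk directions are supported:

* ``forward`` — rows normalised by out-degree; high scores mark nodes that
  receive information from many / important sources ("authorities").
* ``reverse`` — the same construction on the edge-reversed network; high
  scores mark broad emitters / regulators ("hubs").
* ``undirected`` — the symmetrised adjacency normalised by degree; with
  no damping this reduces exactly to degree / (2·|edges|).

The stationary vector of the scaled chain ``M = α·N + (1−α)/n·J`` is found
by power iteration; a Monte-Carlo random surfer and a mean-return-time
simulator provide independent empirical checks (by Kac's identity the
stationary probability of a node is the reciprocal of its expected return
time).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import sparse

from prorank.network_io import InteractionNetwork

Direction = Literal["forward", "reverse", "undirected"]
DanglingPolicy = Literal["stay", "teleport"]

DIRECTIONS: tuple[str, ...] = ("forward", "reverse", "undirected")
DANGLING_POLICIES: tuple[str, ...] = ("stay", "teleport")

DEFAULT_ALPHA = 0.85


class ConvergenceWarning(UserWarning):
    """Power iteration failed to reach tolerance within max_iter."""


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic walk matrix for one direction, dangling rows resolved."""

    nodes: tuple[str, ...]
    walk_matrix: sparse.csr_matrix = field(repr=False)
    direction: str
    dangling_policy: str

    @property
    def n(self) -> int:
        return len(self.nodes)

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.dangling_policy not in DANGLING_POLICIES:
            raise ValueError(f"unknown dangling policy {self.dangling_policy!r}")
        if self.n < 1:
            raise ValueError("transition matrix needs at least one node")
        row_sums = np.asarray(self.walk_matrix.sum(axis=1)).ravel()
        if not np.allclose(row_sums, 1.0, atol=1e-12):
            raise ValueError("walk matrix rows must sum to 1")
        if self.walk_matrix.nnz and self.walk_matrix.data.min() < 0:
            raise ValueError("walk matrix entries must be non-negative")

    def scaled_dense(self, alpha: float = DEFAULT_ALPHA) -> np.ndarray:
        """The dense scaled matrix α·N + (1−α)/n·J (for oracles / small n)."""
        n = self.n
        return alpha * self.walk_matrix.toarray() + (1.0 - alpha) / n


@dataclass(frozen=True)
class RankingResult:
    """Stationary probabilities plus derived 1-based rank positions.

    Positions order by descending score with ties broken lexicographically
    by protein identifier, so listings are reproducible.
    """

    method: str
    scores: dict[str, float]
    positions: dict[str, int]
    percent: dict[str, float]
    iterations_used: int = 0
    converged: bool = True
    alpha: float = DEFAULT_ALPHA
    dangling_policy: str = "stay"

    @classmethod
    def from_scores(
        cls,
        method: str,
        scores: dict[str, float],
        iterations_used: int = 0,
        converged: bool = True,
        alpha: float = DEFAULT_ALPHA,
        dangling_policy: str = "stay",
    ) -> "RankingResult":
        if not scores:
            raise ValueError("empty score map")
        order = sorted(scores, key=lambda name: (-scores[name], name))
        positions = {name: rank for rank, name in enumerate(order, start=1)}
        total = float(sum(scores.values()))
        percent = {name: 100.0 * value / total for name, value in scores.items()}
        return cls(
            method=method,
            scores=dict(scores),
            positions=positions,
            percent=percent,
            iterations_used=iterations_used,
            converged=converged,
            alpha=alpha,
            dangling_policy=dangling_policy,
        )

    @property
    def n(self) -> int:
        return len(self.scores)

    def by_position(self) -> list[str]:
        """Protein identifiers ordered best rank first."""
        return sorted(self.positions, key=self.positions.get)

    def score_array(self, nodes: tuple[str, ...] | None = None) -> np.ndarray:
        names = nodes if nodes is not None else tuple(sorted(self.scores))
        return np.array([self.scores[name] for name in names])


def _direction_edges(network: InteractionNetwork, direction: str) -> set[tuple[str, str]]:
    if direction == "forward":
        return set(network.edges)
    if direction == "reverse":
        return {(v, u) for u, v in network.edges}
    if direction == "undirected":
        return set(network.edges) | {(v, u) for u, v in network.edges}
    raise ValueError(f"unknown direction {direction!r}")


def build_transition(
    network: InteractionNetwork,
    direction: str = "forward",
    dangling_policy: str = "stay",
) -> TransitionMatrix:
    """Row-stochastic walk matrix for the requested direction.

    Forward rows divide the adjacency by out-degree; reverse applies the
    identical construction to the edge-reversed network; undirected uses the
    symmetrised adjacency divided by degree. Rows with no outgoing links are
    resolved by the dangling policy: ``stay`` puts probability 1 on the node
    itself, ``teleport`` spreads a uniform 1/n row.
    """
    if network.n_nodes == 0:
        raise ValueError("network has no nodes")
    if dangling_policy not in DANGLING_POLICIES:
        raise ValueError(f"unknown dangling policy {dangling_policy!r}")
    n = network.n_nodes
    idx = network.node_index()
    edges = _direction_edges(network, direction)
    rows = np.fromiter((idx[u] for u, _ in edges), dtype=np.int64, count=len(edges))
    cols = np.fromiter((idx[v] for _, v in edges), dtype=np.int64, count=len(edges))
    out_deg = np.bincount(rows, minlength=n) if len(edges) else np.zeros(n, dtype=np.int64)
    dangling = np.flatnonzero(out_deg == 0)
    data = 1.0 / out_deg[rows] if len(edges) else np.zeros(0)
    if dangling.size:
        if dangling_policy == "stay":
            rows = np.concatenate([rows, dangling])
            cols = np.concatenate([cols, dangling])
            data = np.concatenate([data, np.ones(dangling.size)])
        else:  # teleport: uniform row
            rows = np.concatenate([rows, np.repeat(dangling, n)])
            cols = np.concatenate([cols, np.tile(np.arange(n), dangling.size)])
            data = np.concatenate([data, np.full(dangling.size * n, 1.0 / n)])
    walk = sparse.csr_matrix((data, (rows, cols)), shape=(n, n))
    return TransitionMatrix(
        nodes=network.nodes,
        walk_matrix=walk,
        direction=direction,
        dangling_policy=dangling_policy,
    )


def pagerank(
    transition: TransitionMatrix,
    alpha: float = DEFAULT_ALPHA,
    tol: float = 1e-12,
    max_iter: int = 1000,
) -> RankingResult:
    """Stationary vector of the scaled chain M = α·N + (1−α)/n·J.

    Power iteration starts from the uniform vector and stops when the L1
    change between successive iterates drops below ``tol``. The scaled
    matrix is never materialised: each step is a sparse vector-matrix
    product plus the rank-one uniform correction. With α < 1 every entry of
    the result is strictly positive and the chain has a unique stationary
    distribution; at α = 1 periodic chains may oscillate, in which case the
    result carries ``converged=False`` and a :class:`ConvergenceWarning` is
    issued.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    n = transition.n
    walk = transition.walk_matrix
    x = np.full(n, 1.0 / n)
    teleport = (1.0 - alpha) / n
    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        x_new = alpha * (x @ walk) + teleport
        x_new /= x_new.sum()  # guard against float drift
        if np.abs(x_new - x).sum() < tol:
            x = x_new
            converged = True
            break
        x = x_new
    if not converged:
        warnings.warn(
            f"power iteration did not converge in {max_iter} iterations "
            f"(direction={transition.direction}, alpha={alpha})",
            ConvergenceWarning,
            stacklevel=2,
        )
    scores = {name: float(x[i]) for i, name in enumerate(transition.nodes)}
    return RankingResult.from_scores(
        transition.direction,
        scores,
        iterations_used=iterations,
        converged=converged,
        alpha=alpha,
        dangling_policy=transition.dangling_policy,
    )


def rank_network(
    network: InteractionNetwork,
    direction: str = "forward",
    alpha: float = DEFAULT_ALPHA,
    dangling_policy: str = "stay",
    tol: float = 1e-12,
    max_iter: int = 1000,
) -> RankingResult:
    """Convenience wrapper: build the transition matrix and run pagerank."""
    transition = build_transition(network, direction, dangling_policy)
    return pagerank(transition, alpha=alpha, tol=tol, max_iter=max_iter)


def _surfer_arrays(network: InteractionNetwork, direction: str):
    """CSR-style neighbour arrays for the requested walk direction."""
    n = network.n_nodes
    idx = network.node_index()
    edges = sorted(_direction_edges(network, direction))
    targets_by_src: list[list[int]] = [[] for _ in range(n)]
    for u, v in edges:
        targets_by_src[idx[u]].append(idx[v])
    indptr = np.zeros(n + 1, dtype=np.int64)
    for i, targets in enumerate(targets_by_src):
        indptr[i + 1] = indptr[i] + len(targets)
    indices = np.fromiter(
        (t for targets in targets_by_src for t in targets),
        dtype=np.int64,
        count=int(indptr[-1]),
    )
    return indptr, indices


def _step(
    current: int,
    u_move: float,
    u_pick: float,
    alpha: float,
    n: int,
    indptr: np.ndarray,
    indices: np.ndarray,
    stay: bool,
) -> int:
    """One transition of the scaled chain."""
    if u_move >= alpha:  # teleport jump
        return int(u_pick * n)
    lo, hi = indptr[current], indptr[current + 1]
    deg = hi - lo
    if deg == 0:
        return current if stay else int(u_pick * n)
    return int(indices[lo + int(u_pick * deg)])


def random_surfer(
    network: InteractionNetwork,
    direction: str = "forward",
    alpha: float = DEFAULT_ALPHA,
    steps: int = 100_000,
    seed: int = 0,
    dangling_policy: str = "stay",
) -> dict[str, float]:
    """Empirical visit frequencies of the scaled chain.

    With probability ``alpha`` the surfer follows a uniformly random
    outgoing link (applying the dangling policy at sinks), otherwise it
    jumps to a uniformly random node. Frequencies are normalised visit
    counts over ``steps`` transitions; the output is deterministic for a
    fixed seed.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if dangling_policy not in DANGLING_POLICIES:
        raise ValueError(f"unknown dangling policy {dangling_policy!r}")
    n = network.n_nodes
    indptr, indices = _surfer_arrays(network, direction)
    rng = np.random.default_rng(seed)
    counts = np.zeros(n, dtype=np.int64)
    stay = dangling_policy == "stay"
    current = int(rng.integers(n))
    block = 1 << 16
    done = 0
    while done < steps:
        m = min(block, steps - done)
        u_move = rng.random(m)
        u_pick = rng.random(m)
        for j in range(m):
            current = _step(current, u_move[j], u_pick[j], alpha, n, indptr, indices, stay)
            counts[current] += 1
        done += m
    freq = counts / counts.sum()
    return {name: float(freq[i]) for i, name in enumerate(network.nodes)}


def mean_return_time(
    network: InteractionNetwork,
    direction: str = "forward",
    alpha: float = DEFAULT_ALPHA,
    node: str = "",
    n_returns: int = 1000,
    seed: int = 0,
    dangling_policy: str = "stay",
) -> float:
    """Simulated mean number of steps between successive visits to ``node``.

    By Kac's identity this converges to the reciprocal of the node's
    stationary probability under the same scaled chain.
    """
    if n_returns < 1:
        raise ValueError("n_returns must be >= 1")
    idx = network.node_index()
    if node not in idx:
        raise KeyError(f"node {node!r} not in network")
    target = idx[node]
    n = network.n_nodes
    indptr, indices = _surfer_arrays(network, direction)
    rng = np.random.default_rng(seed)
    stay = dangling_policy == "stay"
    current = target
    returns = 0
    total_steps = 0
    block = 1 << 16
    while returns < n_returns:
        u_move = rng.random(block)
        u_pick = rng.random(block)
        for j in range(block):
            current = _step(current, u_move[j], u_pick[j], alpha, n, indptr, indices, stay)
            total_steps += 1
            if current == target:
                returns += 1
                if returns >= n_returns:
                    break
    return total_steps / n_returns
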