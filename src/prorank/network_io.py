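"""Reading scored edge tables into directed networks, and ranking table I/O.

Edge tables are tab-separated with a ``source / target / pids`` header; an
edge is retained only when its directional score is strictly greater than
the threshold (default 2.0). Retained edges are deduplicated and unweighted:
every kept interaction contributes the same 0/1 entry to the adjacency
matrix. Ranking tables are written as ``rank / protein_id / score / percent``
with ``# key=value`` provenance headers.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping

import numpy as np
from scipy import sparse

logger = logging.getLogger(__name__)

EDGE_COLUMNS = ("source", "target", "pids")
RANKING_COLUMNS = ("rank", "protein_id", "score", "percent")

DEFAULT_PIDS_THRESHOLD = 2.0


class EmptyNetworkError(ValueError):
    """Raised when no edges survive filtering (or generation)."""


class EdgeTableFormatError(ValueError):
    """Raised for malformed edge-table rows; message carries the line number."""


@dataclass(frozen=True)
class DirectedInteraction:
    """One scored directed interaction between two proteins."""

    source: str
    target: str
    pids: float

    def __post_init__(self) -> None:
        if not self.source or not self.target:
            raise ValueError("interaction endpoints must be non-empty strings")
        if not np.isfinite(self.pids):
            raise ValueError(f"non-finite pids score for {self.source}->{self.target}")


@dataclass(frozen=True)
class InteractionNetwork:
    """Directed, unweighted interaction network.

    ``nodes`` is lexicographically sorted so that matrix row/column order,
    rank tie-breaking and output files are deterministic. ``edges`` is a
    deduplicated set of (source, target) pairs whose endpoints are all
    members of ``nodes``.
    """

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]] = field(repr=False)

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate node identifiers")
        if list(self.nodes) != sorted(self.nodes):
            raise ValueError("nodes must be lexicographically sorted")
        for u, v in self.edges:
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge endpoint not in node set: ({u}, {v})")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        extra_nodes: Iterable[str] = (),
    ) -> "InteractionNetwork":
        """Build a network from (source, target) pairs.

        Duplicates collapse to a single edge; self-edges are dropped with a
        warning because they would distort out-degree and dangling handling.
        """
        kept: set[tuple[str, str]] = set()
        n_self = 0
        for u, v in edges:
            if u == v:
                n_self += 1
                continue
            kept.add((u, v))
        if n_self:
            logger.warning("dropped %d self-edge(s)", n_self)
        nodes = {u for u, _ in kept} | {v for _, v in kept} | set(extra_nodes)
        return cls(nodes=tuple(sorted(nodes)), edges=frozenset(kept))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_index(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.nodes)}

    def reverse(self) -> "InteractionNetwork":
        """The same network with every edge direction flipped."""
        return InteractionNetwork(
            nodes=self.nodes,
            edges=frozenset((v, u) for u, v in self.edges),
        )

    def adjacency(self, directed: bool = True) -> sparse.csr_matrix:
        """0/1 adjacency matrix in node order; symmetrized if undirected."""
        idx = self.node_index()
        pairs = set(self.edges)
        if not directed:
            pairs |= {(v, u) for u, v in self.edges}
        n = self.n_nodes
        if not pairs:
            return sparse.csr_matrix((n, n))
        rows = np.fromiter((idx[u] for u, _ in pairs), dtype=np.int64, count=len(pairs))
        cols = np.fromiter((idx[v] for _, v in pairs), dtype=np.int64, count=len(pairs))
        data = np.ones(len(pairs))
        return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))

    def out_degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        idx = self.node_index()
        for u, _ in self.edges:
            deg[idx[u]] += 1
        return deg

    def in_degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        idx = self.node_index()
        for _, v in self.edges:
            deg[idx[v]] += 1
        return deg


def _open_lines(stream: str | IO[str]) -> Iterator[tuple[int, str]]:
    if isinstance(stream, str):
        handle: IO[str] = open(stream, "r", encoding="utf-8")
        close = True
    else:
        handle, close = stream, False
    try:
        for lineno, raw in enumerate(handle, start=1):
            yield lineno, raw.rstrip("\n").rstrip("\r")
    finally:
        if close:
            handle.close()


def read_edge_table(
    stream: str | IO[str],
    threshold: float = DEFAULT_PIDS_THRESHOLD,
) -> InteractionNetwork:
    """Read a scored edge table, keeping edges with score strictly > threshold.

    Parameters
    ----------
    stream
        Path or open text stream. Tab-separated, header naming at least
        ``source``, ``target`` and ``pids`` columns; ``#`` lines ignored.
    threshold
        Strict lower bound on the directional score (default 2.0). Rows at
        exactly the threshold are excluded.

    Raises
    ------
    EdgeTableFormatError
        On a malformed row; the message names the 1-based line number.
    EmptyNetworkError
        When no edge survives the filter.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    header: list[str] | None = None
    col: dict[str, int] = {}
    kept: list[tuple[str, str]] = []
    for lineno, line in _open_lines(stream):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = [h.strip().lower() for h in fields]
            missing = [c for c in EDGE_COLUMNS if c not in header]
            if missing:
                raise EdgeTableFormatError(
                    f"line {lineno}: header missing column(s) {missing}; got {header}"
                )
            col = {c: header.index(c) for c in EDGE_COLUMNS}
            continue
        if len(fields) < len(header):
            raise EdgeTableFormatError(
                f"line {lineno}: expected {len(header)} tab-separated fields, got {len(fields)}"
            )
        source = fields[col["source"]].strip()
        target = fields[col["target"]].strip()
        try:
            pids = float(fields[col["pids"]])
        except ValueError as exc:
            raise EdgeTableFormatError(f"line {lineno}: unparseable pids value") from exc
        interaction = DirectedInteraction(source, target, pids)
        if interaction.pids > threshold:
            kept.append((interaction.source, interaction.target))
    if header is None:
        raise EdgeTableFormatError("empty input: no header line found")
    network = InteractionNetwork.from_edges(kept)
    if network.n_edges == 0:
        raise EmptyNetworkError(
            f"empty network: no edge has pids > {threshold!r}"
        )
    return network


def write_ranking(result, stream: str | IO[str], header: Mapping[str, object] | None = None) -> None:
    """Write a ranking as a TSV sorted by rank ascending.

    Columns: rank, protein_id, score, percent. Scores are written with 17
    significant digits so that a write/read round trip is exact to well
    beyond 12 decimals. ``header`` entries are emitted as ``# key=value``
    provenance lines; ``method`` is always recorded.
    """
    if not result.scores:
        raise ValueError("cannot write an empty ranking")
    if isinstance(stream, str):
        with open(stream, "w", encoding="utf-8", newline="\n") as handle:
            write_ranking(result, handle, header=header)
        return
    meta = {"method": result.method}
    if header:
        meta.update(header)
    for key, value in meta.items():
        stream.write(f"# {key}={value}\n")
    stream.write("\t".join(RANKING_COLUMNS) + "\n")
    order = sorted(result.positions, key=result.positions.get)
    for name in order:
        stream.write(
            f"{result.positions[name]}\t{name}\t"
            f"{result.scores[name]:.17g}\t{result.percent[name]:.17g}\n"
        )


def read_ranking(stream: str | IO[str]):
    """Read a ranking TSV written by :func:`write_ranking`.

    Returns a :class:`~prorank.pagerank.RankingResult`; the method tag is
    recovered from the ``# method=...`` header when present.
    """
    from prorank.pagerank import RankingResult  # deferred: avoid import cycle

    method = "forward"
    scores: dict[str, float] = {}
    header_seen = False
    for lineno, line in _open_lines(stream):
        if not line.strip():
            continue
        if line.lstrip().startswith("#"):
            body = line.lstrip("# ").strip()
            if body.startswith("method="):
                method = body.split("=", 1)[1]
            continue
        fields = line.split("\t")
        if not header_seen:
            if [f.strip().lower() for f in fields[:4]] != list(RANKING_COLUMNS):
                raise EdgeTableFormatError(
                    f"line {lineno}: expected ranking header {RANKING_COLUMNS}"
                )
            header_seen = True
            continue
        if len(fields) < 4:
            raise EdgeTableFormatError(f"line {lineno}: expected 4 fields")
        scores[fields[1]] = float(fields[2])
    if not scores:
        raise EmptyNetworkError("ranking file contains no rows")
    return RankingResult.from_scores(method, scores)


def ranking_to_string(result, header: Mapping[str, object] | None = None) -> str:
    buf = io.StringIO()
    write_ranking(result, buf, header=header)
    return buf.getvalue()
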