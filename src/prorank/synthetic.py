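"""Synthetic directed networks and annotations with planted structure.

The generator plants a small set of emitters that reach the rest of the
network through relay chains (so their influence is large while their
direct out-degree stays small), gives background receivers relatively even
in-degrees, and injects short directed feedback cycles. Annotations are
drawn so that conservation (bit score) increases with planted importance
and subcellular location flags correlate with the emitter/receiver role.
Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import IO, Mapping

import numpy as np

from prorank.annotation_stats import AnnotationTable
from prorank.network_io import EmptyNetworkError, InteractionNetwork

ROLE_IMPORTANCE = {"emitter": 2, "relay": 1, "receiver": 0}

# Per-role probability of each location flag; receivers skew nuclear,
# emitters membrane/cytoplasmic.
DEFAULT_LOCATION_PROBS: dict[str, dict[str, float]] = {
    "emitter": {"nucleus": 0.10, "cytoplasm": 0.70, "membrane": 0.70},
    "relay": {"nucleus": 0.30, "cytoplasm": 0.60, "membrane": 0.40},
    "receiver": {"nucleus": 0.70, "cytoplasm": 0.40, "membrane": 0.20},
}

DEFAULT_PATHWAY_PROBS: dict[str, dict[str, float]] = {
    "emitter": {"known_pathway": 0.9, "signalling": 0.8, "MAPK": 0.4},
    "relay": {"known_pathway": 0.7, "signalling": 0.6, "MAPK": 0.3},
    "receiver": {"known_pathway": 0.4, "signalling": 0.25, "MAPK": 0.1},
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-structure network generator."""

    n_nodes: int = 500
    n_emitters: int = 5
    emitter_fanout: int = 3
    relay_depth: int = 3
    receiver_in_mean: float = 2.0
    background_edge_prob: float = 0.002
    n_feedback_motifs: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if not 0 <= self.n_emitters < self.n_nodes:
            raise ValueError("need 0 <= n_emitters < n_nodes")
        if not 0.0 <= self.background_edge_prob <= 1.0:
            raise ValueError("background_edge_prob must be in [0, 1]")
        if self.receiver_in_mean < 0:
            raise ValueError("receiver_in_mean must be >= 0")

    def with_seed(self, seed: int) -> "SyntheticSpec":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class PlantedRoles:
    """Ground-truth role per node (exactly n_emitters emitters)."""

    roles: dict[str, str] = field(repr=False)

    def of_role(self, role: str) -> tuple[str, ...]:
        return tuple(sorted(p for p, r in self.roles.items() if r == role))

    @property
    def emitters(self) -> tuple[str, ...]:
        return self.of_role("emitter")

    def importance(self, protein: str) -> int:
        return ROLE_IMPORTANCE[self.roles[protein]]


def _node_names(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"P{i:0{width}d}" for i in range(n)]


def generate_network(spec: SyntheticSpec) -> tuple[InteractionNetwork, PlantedRoles]:
    """Generate a directed network with planted emitters, relays, receivers.

    Each emitter sends ``emitter_fanout`` disjoint relay chains of length
    ``relay_depth`` whose final relay feeds a random receiver, so an
    emitter's direct out-degree is exactly ``emitter_fanout``. Receivers
    pick up Poisson(``receiver_in_mean``) further in-edges from random
    non-emitter sources, background edges between non-emitter pairs are
    added iid, and ``n_feedback_motifs`` node-disjoint directed cycles
    (length 3–5) are planted among the receivers.
    """
    rng = np.random.default_rng((spec.seed, 0x4E45))
    n = spec.n_nodes
    names = _node_names(n)

    n_relays = spec.n_emitters * spec.emitter_fanout * spec.relay_depth
    if spec.n_emitters + n_relays >= n:
        raise ValueError(
            f"capacity error: {spec.n_emitters} emitters + {n_relays} relay "
            f"slots leave no receivers among {n} nodes"
        )

    perm = rng.permutation(n)
    emitter_idx = perm[: spec.n_emitters]
    relay_idx = perm[spec.n_emitters : spec.n_emitters + n_relays]
    receiver_idx = perm[spec.n_emitters + n_relays :]

    roles = {names[i]: "receiver" for i in receiver_idx}
    roles.update({names[i]: "emitter" for i in emitter_idx})
    roles.update({names[i]: "relay" for i in relay_idx})

    edges: set[tuple[int, int]] = set()
    relay_cursor = 0
    for e in emitter_idx:
        for _ in range(spec.emitter_fanout):
            chain = relay_idx[relay_cursor : relay_cursor + spec.relay_depth]
            relay_cursor += spec.relay_depth
            prev = e
            for r in chain:
                edges.add((int(prev), int(r)))
                prev = r
            if receiver_idx.size:
                edges.add((int(prev), int(rng.choice(receiver_idx))))

    # Extra in-edges for receivers. Sources are allocated round-robin over
    # the non-emitter pool so that out-degrees stay nearly even: receiving
    # breadth varies (Poisson in-degree) while emitting breadth does not,
    # which is the planted "few key emitters, even receivers" asymmetry.
    non_emitters = np.concatenate([relay_idx, receiver_idx])
    if spec.receiver_in_mean > 0 and non_emitters.size > 1:
        in_degs = rng.poisson(spec.receiver_in_mean, size=receiver_idx.size)
        pool: list[int] = []
        while len(pool) < int(in_degs.sum()):
            pool.extend(map(int, rng.permutation(non_emitters)))
        cursor = 0
        for r, deg in zip(receiver_idx, in_degs):
            for _ in range(int(deg)):
                src = pool[cursor]
                cursor += 1
                if src != int(r):
                    edges.add((src, int(r)))

    # Sparse iid background noise between non-emitter ordered pairs.
    if spec.background_edge_prob > 0 and non_emitters.size > 1:
        m = non_emitters.size
        n_pairs = m * (m - 1)
        n_bg = rng.binomial(n_pairs, spec.background_edge_prob)
        for _ in range(n_bg):
            u, v = rng.choice(non_emitters, size=2, replace=False)
            edges.add((int(u), int(v)))

    # Node-disjoint feedback cycles among receivers.
    motif_pool = list(map(int, rng.permutation(receiver_idx)))
    for _ in range(spec.n_feedback_motifs):
        length = int(rng.integers(3, 6))
        if len(motif_pool) < length:
            break
        cycle = [motif_pool.pop() for _ in range(length)]
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            edges.add((a, b))

    if not edges:
        raise EmptyNetworkError("synthetic spec produced an empty edge set")

    network = InteractionNetwork.from_edges(
        ((names[u], names[v]) for u, v in edges),
        extra_nodes=names,
    )
    return network, PlantedRoles(roles=roles)


def generate_annotations(
    roles: PlantedRoles,
    bits_base: float = 150.0,
    bits_slope: float = 80.0,
    bits_sd: float = 20.0,
    seed: int = 0,
    length_meanlog: float = 6.3,
    length_sdlog: float = 0.35,
    location_probs: Mapping[str, Mapping[str, float]] | None = None,
    pathway_probs: Mapping[str, Mapping[str, float]] | None = None,
) -> AnnotationTable:
    """Draw an annotation table whose structure tracks the planted roles.

    Bit scores follow ``bits_base + bits_slope·importance + N(0, bits_sd)``
    truncated at zero (importance: emitter 2, relay 1, receiver 0), lengths
    are log-normal, e-values decay exponentially in the bit score, and
    location / pathway flags are Bernoulli with role-dependent
    probabilities.
    """
    if bits_sd < 0:
        raise ValueError("bits_sd must be >= 0")
    loc_probs = location_probs or DEFAULT_LOCATION_PROBS
    path_probs = pathway_probs or DEFAULT_PATHWAY_PROBS
    rng = np.random.default_rng((seed, 0xA44F))
    records = []
    for protein in sorted(roles.roles):
        role = roles.roles[protein]
        bits = max(
            0.0,
            bits_base + bits_slope * ROLE_IMPORTANCE[role] + rng.normal(0.0, bits_sd),
        )
        evalue = min(10.0, 10.0 ** (-bits / 10.0))
        length = max(1, int(round(rng.lognormal(length_meanlog, length_sdlog))))
        labels = set()
        probs = path_probs[role]
        if rng.random() < probs.get("known_pathway", 0.0):
            labels.add("known_pathway")
            if rng.random() < probs.get("signalling", 0.0):
                labels.add("signalling")
                if rng.random() < probs.get("MAPK", 0.0):
                    labels.add("MAPK")
        flags = {
            flag: bool(rng.random() < loc_probs[role][flag])
            for flag in ("nucleus", "cytoplasm", "membrane")
        }
        records.append(
            {
                "protein_id": protein,
                "blast_bits": bits,
                "evalue": evalue,
                "length_aa": length,
                "pathway_labels": frozenset(labels),
                **flags,
            }
        )
    return AnnotationTable.from_records(records)


def write_edge_table(
    network: InteractionNetwork,
    stream: str | IO[str],
    seed: int = 0,
    pids_range: tuple[float, float] = (2.5, 9.0),
) -> None:
    """Write the network as a scored edge TSV that survives the 2.0 filter.

    Scores are drawn uniformly from ``pids_range`` (strictly above the
    threshold) so that re-reading the table reproduces the network exactly.
    """
    if isinstance(stream, str):
        with open(stream, "w", encoding="utf-8", newline="\n") as handle:
            write_edge_table(network, handle, seed=seed, pids_range=pids_range)
        return
    rng = np.random.default_rng((seed, 0xED6E))
    stream.write("source\ttarget\tpids\n")
    for u, v in sorted(network.edges):
        pids = rng.uniform(*pids_range)
        stream.write(f"{u}\t{v}\t{pids:.3f}\n")


def write_roles(roles: PlantedRoles, stream: str | IO[str]) -> None:
    if isinstance(stream, str):
        with open(stream, "w", encoding="utf-8", newline="\n") as handle:
            write_roles(roles, handle)
        return
    stream.write("protein_id\trole\timportance\n")
    for protein in sorted(roles.roles):
        role = roles.roles[protein]
        stream.write(f"{protein}\t{role}\t{ROLE_IMPORTANCE[role]}\n")
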