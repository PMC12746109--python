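"""Triad-based inference of strain-strain trophic interactions.

Within an environment-restricted subnetwork, two strains connected through a
mediating compound form one of four triad motifs:

* competition (-):      s_i -DEGRADES-> c <-DEGRADES- s_j        (symmetric)
* direct_inhibition (-): s_i -PRODUCES-> c, c -INHIBITS-> s_j    (directed)
* cross_feeding (+):    s_i -PRODUCES-> c <-DEGRADES- s_j        (directed)
* resistance (+):       s_i -PRODUCES-> c, s_j -RESISTS-> c      (symmetric)

Each distinct (pair, compound, type) combination counts once regardless of
sentence multiplicity; the interaction weight of a strain pair is
``w = n_plus - n_minus``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

TRIAD_SIGNS = {
    "competition": -1,
    "direct_inhibition": -1,
    "cross_feeding": +1,
    "resistance": +1,
}

SYMMETRIC_TYPES = frozenset({"competition", "resistance"})

#: Relation types retained in an environment subnetwork.
SUBNETWORK_RELATIONS = frozenset({"PRODUCES", "DEGRADES", "RESISTS", "INHIBITS"})


@dataclass
class EnvironmentSubnetwork:
    """Strains inhabiting one environment plus their induced compound edges."""

    environment: tuple[str, str]
    strains: frozenset
    edges: tuple  # (source node, target node, relation_type), deduplicated


@dataclass(frozen=True)
class TriadMatch:
    """One matched triad.  For symmetric types the strain pair is unordered
    (stored sorted); for directed types ``strain_a`` acts on ``strain_b``."""

    type: str
    strain_a: tuple[str, str]
    strain_b: tuple[str, str]
    compound: tuple[str, str]

    @property
    def sign(self) -> int:
        return TRIAD_SIGNS[self.type]

    @property
    def pair(self) -> tuple:
        return tuple(sorted((self.strain_a, self.strain_b)))


@dataclass
class InteractionEdge:
    strain_a: tuple[str, str]
    strain_b: tuple[str, str]
    n_plus: int
    n_minus: int
    by_type: dict = field(default_factory=dict)

    @property
    def weight(self) -> int:
        return self.n_plus - self.n_minus


def extract_environment_subnetwork(
    graph: nx.MultiDiGraph, environment: tuple[str, str]
) -> EnvironmentSubnetwork:
    """Restrict the phenotype graph to strains INHABITing one environment term.

    Members are STRAIN nodes with at least one INHABITS edge to the
    environment node; the induced edges are the PRODUCES/DEGRADES/RESISTS
    edges from members and INHIBITS edges to members (compound-mediated).
    """
    if environment not in graph:
        raise ValueError(f"unknown environment term {environment!r}")
    members = frozenset(
        u
        for u, _, rel in graph.in_edges(environment, keys=True)
        if rel == "INHABITS" and u[0] == "STRAIN"
    )
    edges = set()
    for s in members:
        for _, tgt, rel in graph.out_edges(s, keys=True):
            if rel in ("PRODUCES", "DEGRADES", "RESISTS"):
                edges.add((s, tgt, rel))
        for src, _, rel in graph.in_edges(s, keys=True):
            if rel == "INHIBITS":
                edges.add((src, s, rel))
    return EnvironmentSubnetwork(
        environment=environment, strains=members, edges=tuple(sorted(edges))
    )


def enumerate_triads(sub: EnvironmentSubnetwork) -> list[TriadMatch]:
    """All distinct (pair, compound, type) triads in the subnetwork."""
    producers: dict[tuple, set] = {}
    degraders: dict[tuple, set] = {}
    resisters: dict[tuple, set] = {}
    inhibited: dict[tuple, set] = {}
    for src, tgt, rel in sub.edges:
        if rel == "PRODUCES" and src in sub.strains:
            producers.setdefault(tgt, set()).add(src)
        elif rel == "DEGRADES" and src in sub.strains:
            degraders.setdefault(tgt, set()).add(src)
        elif rel == "RESISTS" and src in sub.strains:
            resisters.setdefault(tgt, set()).add(src)
        elif rel == "INHIBITS" and tgt in sub.strains:
            inhibited.setdefault(src, set()).add(tgt)
    found: set[TriadMatch] = set()
    compounds = set(producers) | set(degraders) | set(resisters) | set(inhibited)
    for c in compounds:
        ps = producers.get(c, set())
        ds = degraders.get(c, set())
        rs = resisters.get(c, set())
        hs = inhibited.get(c, set())
        for si in ds:
            for sj in ds:
                if si < sj:
                    found.add(TriadMatch("competition", si, sj, c))
        for si in ps:
            for sj in ds:
                if si != sj:
                    found.add(TriadMatch("cross_feeding", si, sj, c))
            for sj in hs:
                if si != sj:
                    found.add(TriadMatch("direct_inhibition", si, sj, c))
            for sj in rs:
                if si != sj:
                    a, b = sorted((si, sj))
                    found.add(TriadMatch("resistance", a, b, c))
    return sorted(
        found, key=lambda t: (t.type, t.strain_a, t.strain_b, t.compound)
    )


def interaction_weights(triads) -> list[InteractionEdge]:
    """Net interaction weight per unordered strain pair.

    ``n_plus`` and ``n_minus`` sum positive/negative triads over both
    directions and all compounds; pairs with no triads are omitted.
    """
    acc: dict[tuple, InteractionEdge] = {}
    for t in triads:
        pair = t.pair
        edge = acc.get(pair)
        if edge is None:
            edge = InteractionEdge(pair[0], pair[1], 0, 0)
            acc[pair] = edge
        if t.sign > 0:
            edge.n_plus += 1
        else:
            edge.n_minus += 1
        edge.by_type[t.type] = edge.by_type.get(t.type, 0) + 1
    return [acc[p] for p in sorted(acc)]


def infer_interactions(
    graph: nx.MultiDiGraph, environment: tuple[str, str]
) -> list[InteractionEdge]:
    """Convenience wrapper: subnetwork -> triads -> weights."""
    sub = extract_environment_subnetwork(graph, environment)
    return interaction_weights(enumerate_triads(sub))
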