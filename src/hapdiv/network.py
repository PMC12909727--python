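"""Statistical-parsimony (TCS-style) haplotype networks.

The network connects haplotypes by edges labelled with mutational steps
(pairwise differences over unambiguous columns), keeps only connections up
to a parsimony-justified limit, and retains *all* tied minimal edges during
Kruskal-style construction, so reticulations (cycles) can appear — a
minimum-spanning network rather than a tree, matching what TCS/PopArt draw.

Unsampled intermediate haplotypes are not inserted as explicit nodes;
multi-step edges simply carry their step count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import networkx as nx

from .haplotypes import AMBIGUOUS, Haplotype


def pairwise_steps(hap_a: Haplotype | str, hap_b: Haplotype | str) -> int:
    """Mutational steps between two haplotypes.

    Counts columns where both bases are unambiguous (not N or -) and differ.
    """
    seq_a = hap_a.sequence if isinstance(hap_a, Haplotype) else hap_a
    seq_b = hap_b.sequence if isinstance(hap_b, Haplotype) else hap_b
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    return sum(
        1
        for a, b in zip(seq_a, seq_b)
        if a != b and a not in AMBIGUOUS and b not in AMBIGUOUS
    )


def parsimony_probability(j: int, m: int) -> float:
    """Probability that two sequences of length m differing at j sites are
    separated by exactly j mutations (i.e. that parsimony holds).

    Finite-sites Jukes–Cantor model: each site accumulates Poisson(lam)
    mutations along the path joining the two sequences, and a mutated site
    shows one of the three non-ancestral bases uniformly.  The per-site rate
    lam is profiled at its maximum-likelihood value given the observed
    fraction of differing sites, j/m = (3/4)(1 - exp(-4 lam / 3)).  Parsimony
    holds when every differing site carries exactly one mutation and every
    identical site carries none:

        P = [P(1 mutation | differs)]^j * [P(0 mutations | same)]^(m-j)

    This is the package's reconstruction of the statistical-parsimony
    probability used to set TCS connection limits; see docs/methods.md.
    """
    if m < 1:
        raise ValueError("alignment length must be positive")
    if j == 0:
        return 1.0
    if j >= 0.75 * m:
        return 0.0  # saturation: JC divergence undefined at or beyond 3/4
    d = j / m
    lam = -0.75 * math.log(1.0 - 4.0 * d / 3.0)
    p_diff = d  # (3/4)(1 - exp(-4 lam/3)) by construction
    # P(site differs & exactly one mutation) = lam*exp(-lam): one mutation
    # always lands on a non-ancestral base.
    p_one_given_diff = lam * math.exp(-lam) / p_diff
    p_same = 1.0 - p_diff
    p_zero_given_same = math.exp(-lam) / p_same
    return (p_one_given_diff ** j) * (p_zero_given_same ** (m - j))


def connection_limit(
    alignment_length: int,
    confidence: float = 0.95,
    fixed_limit: int | None = None,
) -> int:
    """Largest step count whose parsimony probability is >= confidence.

    With ``fixed_limit`` given, returns it unchanged (the estimator is
    bypassed).  The result is always >= 1 and non-decreasing in
    alignment_length at fixed confidence.
    """
    if fixed_limit is not None:
        if fixed_limit < 1:
            raise ValueError("fixed_limit must be >= 1")
        return fixed_limit
    if alignment_length < 1:
        raise ValueError("alignment length must be positive")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must lie in (0, 1)")
    limit = 1
    for j in range(1, alignment_length + 1):
        if parsimony_probability(j, alignment_length) >= confidence:
            limit = j
        else:
            break
    return limit


@dataclass
class HaplotypeNetwork:
    """Minimum-spanning network over haplotypes.

    edges are (hap_id_a, hap_id_b, steps) with steps >= 1; identity_links
    carries zero-step links between identical haplotypes of different groups
    (cross-species ties), kept distinct from mutational edges.
    """

    nodes: dict[str, Haplotype]
    edges: list[tuple[str, str, int]]
    connection_limit: int
    identity_links: list[tuple[str, str]] = field(default_factory=list)

    @property
    def components(self) -> list[set[str]]:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((a, b) for a, b, _ in self.edges)
        return [set(c) for c in nx.connected_components(g)]

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for hap_id, hap in self.nodes.items():
            g.add_node(hap_id, count=hap.count,
                       **{f"tally_{k}": ";".join(f"{a}={b}" for a, b in sorted(v.items()))
                          for k, v in hap.group_summary.items()})
        for a, b, steps in self.edges:
            g.add_edge(a, b, steps=steps, kind="mutational")
        for a, b in self.identity_links:
            g.add_edge(a, b, steps=0, kind="identity")
        return g


def build_network(haps: Sequence[Haplotype], limit: int) -> HaplotypeNetwork:
    """Minimum-spanning network by ascending-distance edge insertion.

    Candidate edges are all pairs with distance <= limit, processed in
    distance tiers.  Within each tier, every edge joining components that
    were distinct when the tier was entered is retained — ties are kept, so
    cycles can appear.  Deterministic given input order.
    """
    if not haps:
        raise ValueError("empty haplotype list")
    if limit < 1:
        raise ValueError("limit must be >= 1")
    ids = [h.hap_id for h in haps]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate hap_ids")
    dist: dict[tuple[str, str], int] = {}
    for h1, h2 in combinations(haps, 2):
        dist[(h1.hap_id, h2.hap_id)] = pairwise_steps(h1, h2)
    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges: list[tuple[str, str, int]] = []
    tiers = sorted({d for d in dist.values() if 1 <= d <= limit})
    for tier in tiers:
        comp_at_entry = {i: find(i) for i in ids}
        tier_edges = [
            (a, b) for (a, b), d in dist.items()
            if d == tier and comp_at_entry[a] != comp_at_entry[b]
        ]
        for a, b in tier_edges:
            edges.append((a, b, tier))
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra
    return HaplotypeNetwork(
        nodes={h.hap_id: h for h in haps},
        edges=edges,
        connection_limit=limit,
    )


def add_identity_links(network: HaplotypeNetwork,
                       pairs: Sequence[tuple[str, str]]) -> None:
    """Attach zero-step identity links (e.g. identical haplotypes across species)."""
    for a, b in pairs:
        if a not in network.nodes or b not in network.nodes:
            raise KeyError(f"identity link references unknown node: {(a, b)}")
        network.identity_links.append((a, b))


def write_graphml(network: HaplotypeNetwork, path: str | Path) -> None:
    nx.write_graphml(network.to_graph(), str(path))


def write_edge_list(network: HaplotypeNetwork, path: str | Path) -> None:
    """Plain edge-list TSV: hap_a, hap_b, steps (identity links have steps 0)."""
    with open(path, "w") as fh:
        fh.write("hap_a\thap_b\tsteps\n")
        for a, b, steps in network.edges:
            fh.write(f"{a}\t{b}\t{steps}\n")
        for a, b in network.identity_links:
            fh.write(f"{a}\t{b}\t0\n")
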