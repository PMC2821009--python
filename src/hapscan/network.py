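"""Statistical-parsimony haplotype networks and branch bipartitions.

Haplotypes are connected in ascending mutational-distance order up to a
parsimony connection limit; equal-length alternative connections are retained
as loops and later broken by coalescent-style priority rules so the network
becomes a tree. Each tree branch then induces a bipartition of the haplotypes
that downstream association scanning treats as a biallelic marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import lgamma, log

import networkx as nx
import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq


@dataclass
class Haplotype:
    id: str
    sequence: str
    frequency: float = 0.0
    pop_frequencies: dict[str, float] = field(default_factory=dict)


@dataclass
class MutationLabel:
    """One nucleotide change on an edge, oriented ancestral -> derived."""

    site: int  # 0-based nucleotide position
    from_base: str
    to_base: str
    aa_change: str | None = None  # e.g. "E40K" (1-based codon), None = synonymous

    def __str__(self) -> str:
        core = f"{self.from_base}{self.site + 1}{self.to_base}"
        return f"{core}({self.aa_change})" if self.aa_change else core


@dataclass
class BranchPartition:
    """The bipartition induced by removing one tree edge.

    ``side_a`` contains the root (ancestral) haplotype; ``side_b`` is the
    derived side whose allele is counted when individuals are classed AA/AB/BB.
    """

    edge: tuple[str, str]
    side_a: frozenset[str]
    side_b: frozenset[str]
    changes: tuple[MutationLabel, ...] = ()

    @property
    def branch_id(self) -> str:
        return f"{self.edge[0]}|{self.edge[1]}"

    @property
    def label(self) -> str:
        if self.changes:
            return "+".join(str(c) for c in self.changes)
        return self.branch_id


class HaplotypeNetwork:
    """Observed haplotypes as nodes; edges are parsimonious mutational paths."""

    def __init__(
        self,
        haplotypes: dict[str, Haplotype],
        graph: nx.Graph,
        connection_limit: int,
    ):
        self.haplotypes = haplotypes
        self.graph = graph
        self.connection_limit = connection_limit
        self.removed_edges: list[tuple[str, str]] = []

    @property
    def is_tree(self) -> bool:
        g = self.graph
        return nx.is_connected(g) and g.number_of_edges() == g.number_of_nodes() - 1

    @property
    def root(self) -> str:
        """Designated ancestral node: the most frequent haplotype."""
        return max(
            self.haplotypes.values(), key=lambda h: (h.frequency, h.id)
        ).id


def pairwise_differences(seqs: dict[str, str] | list[str]) -> tuple[np.ndarray, list[str]]:
    """Site-count distance matrix between aligned nucleotide sequences.

    Ambiguity handling: any two differing characters count as one difference
    (an ambiguous base mismatches every differing concrete base).
    """
    if isinstance(seqs, dict):
        ids = list(seqs)
        strings = [seqs[i] for i in ids]
    else:
        ids = [f"s{i}" for i in range(len(seqs))]
        strings = list(seqs)
    lengths = {len(s) for s in strings}
    if len(lengths) > 1:
        raise ValueError(f"sequences are not aligned: lengths {sorted(lengths)}")
    arr = np.array([list(s.upper()) for s in strings])
    n = len(strings)
    dist = np.zeros((n, n), dtype=int)
    for i in range(n):
        diff = (arr[i] != arr[i + 1 :]).sum(axis=1)
        dist[i, i + 1 :] = diff
        dist[i + 1 :, i] = diff
    return dist, ids


def parsimony_probability(steps: int, seq_length: int) -> float:
    """Probability that `steps` mutational steps over `seq_length` sites are
    homoplasy-free (each step strikes a site untouched by the others), under
    uniform and independent placement of mutations across sites.

    Computed by the recursion P_j = P_{j-1} * (1 - (j-1)/m), P_1 = 1. When all
    steps hit distinct sites the observed differences equal the true number of
    steps, i.e. the parsimonious connection is the true one.
    """
    if seq_length < 1:
        raise ValueError("seq_length must be >= 1")
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if steps > seq_length:
        return 0.0
    p = 1.0
    for i in range(1, steps):
        p *= 1.0 - i / seq_length
    return p


def parsimony_connection_limit(seq_length: int, confidence: float = 0.95) -> int:
    """Largest number of steps still considered parsimonious at `confidence`.

    Returns the largest j with parsimony probability > confidence; always >= 1
    since single steps are homoplasy-free with certainty.
    """
    if not (0.0 < confidence < 1.0):
        raise ValueError("confidence must be in (0, 1)")
    j = 1
    while j + 1 <= seq_length and parsimony_probability(j + 1, seq_length) > confidence:
        j += 1
    return j


def parsimony_probability_closed_form(steps: int, seq_length: int) -> float:
    """Closed-form route to the same probability: m! / (m-j)! / m^j."""
    if steps > seq_length:
        return 0.0
    return float(
        np.exp(lgamma(seq_length + 1) - lgamma(seq_length - steps + 1)
               - steps * log(seq_length))
    )


def build_network(
    haplotypes: dict[str, Haplotype],
    limit: int | None = None,
    confidence: float = 0.95,
) -> HaplotypeNetwork:
    """Connect haplotypes in ascending distance order up to the parsimony limit.

    Within one distance level, every pair that joins two components distinct at
    the start of the level is added, so alternative equal-length connections
    are retained as loops for later resolution. Raises if the haplotypes
    cannot all be connected within the limit, naming the stranded components.
    """
    ids = list(haplotypes)
    if not ids:
        raise ValueError("no haplotypes supplied")
    seq_length = len(haplotypes[ids[0]].sequence)
    if limit is None:
        limit = parsimony_connection_limit(seq_length, confidence)
    dist, _ = pairwise_differences({i: haplotypes[i].sequence for i in ids})

    g = nx.Graph()
    g.add_nodes_from(ids)
    uf = nx.utils.UnionFind(ids)
    for d in range(1, limit + 1):
        snapshot = {i: uf[i] for i in ids}
        added = []
        for ii in range(len(ids)):
            for jj in range(ii + 1, len(ids)):
                if dist[ii, jj] == d and snapshot[ids[ii]] != snapshot[ids[jj]]:
                    g.add_edge(ids[ii], ids[jj], length=d)
                    added.append((ids[ii], ids[jj]))
        for a, b in added:
            uf.union(a, b)

    if not nx.is_connected(g):
        comps = sorted(sorted(c) for c in nx.connected_components(g))
        raise ValueError(
            f"haplotypes not connectable within {limit} steps; "
            f"components: {comps}"
        )
    return HaplotypeNetwork(haplotypes, g, limit)


def resolve_loops(
    net: HaplotypeNetwork,
    forced_breaks: list[tuple[str, str]] | None = None,
) -> HaplotypeNetwork:
    """Break every cycle so the network becomes a tree.

    Priority for removing an edge from a cycle (coalescent rationale: rare
    haplotypes are more likely recent tips, so connections between rare
    haplotypes are the least credible):

    1. smallest summed endpoint frequency;
    2. fewest endpoints that are interior (degree >= 3) nodes, i.e. prefer
       keeping edges anchored on interior nodes;
    3. lexicographically greatest edge id, for determinism.

    ``forced_breaks`` removes named edges first (only if the edge lies on a
    cycle, so connectivity is preserved). Removed edges are logged on the
    returned network.
    """
    g = net.graph.copy()
    removed = list(net.removed_edges)
    for a, b in forced_breaks or []:
        if g.has_edge(a, b):
            g.remove_edge(a, b)
            if nx.is_connected(g):
                removed.append((a, b))
            else:  # bridge: put it back
                g.add_edge(a, b, **net.graph.get_edge_data(a, b))

    def removal_key(edge):
        a, b = edge
        freq_sum = net.haplotypes[a].frequency + net.haplotypes[b].frequency
        interior = sum(1 for n in (a, b) if g.degree[n] >= 3)
        return (freq_sum, interior, tuple(sorted((a, b), reverse=True)))

    while True:
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            break
        victim = min((tuple(sorted(e[:2])) for e in cycle), key=removal_key)
        g.remove_edge(*victim)
        removed.append(victim)

    out = HaplotypeNetwork(net.haplotypes, g, net.connection_limit)
    out.removed_edges = removed
    return out


def label_edges(net: HaplotypeNetwork, reading_frame: bool = True) -> None:
    """Attach mutational-change labels to every edge, oriented away from root.

    With ``reading_frame`` the sequence is treated as a coding sequence in
    frame starting at position 0, and nonsynonymous changes get an amino-acid
    label in 1-based codon coordinates (e.g. E40K).
    """
    root = net.root
    order = nx.bfs_tree(net.graph, root)
    for parent, child in order.edges():
        pseq = net.haplotypes[parent].sequence.upper()
        cseq = net.haplotypes[child].sequence.upper()
        labels = []
        for site, (a, b) in enumerate(zip(pseq, cseq)):
            if a == b:
                continue
            aa_change = None
            if reading_frame and len(pseq) % 3 == 0:
                cstart = 3 * (site // 3)
                aa_from = _translate_codon(pseq[cstart : cstart + 3])
                aa_to = _translate_codon(cseq[cstart : cstart + 3])
                if aa_from and aa_to and aa_from != aa_to:
                    aa_change = f"{aa_from}{site // 3 + 1}{aa_to}"
            labels.append(MutationLabel(site, a, b, aa_change))
        net.graph.edges[parent, child]["changes"] = tuple(labels)


def _translate_codon(codon: str) -> str | None:
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        return None
    if codon in standard_dna_table.stop_codons:
        return "*"
    return str(Seq(codon).translate())


def enumerate_branches(
    net: HaplotypeNetwork, root: str | None = None
) -> list[BranchPartition]:
    """One bipartition per tree edge; side_a always holds the root haplotype."""
    if not net.is_tree:
        raise ValueError("network must be loop-resolved (a tree) first")
    root = root or net.root
    all_nodes = frozenset(net.graph.nodes)
    parts = []
    for a, b in sorted(net.graph.edges):
        g2 = net.graph.copy()
        g2.remove_edge(a, b)
        comp_a = frozenset(nx.node_connected_component(g2, a))
        comp_b = all_nodes - comp_a
        if root in comp_a:
            side_a, side_b = comp_a, comp_b
            edge = (a, b)
        else:
            side_a, side_b = comp_b, comp_a
            edge = (b, a)
        changes = net.graph.edges[a, b].get("changes", ())
        parts.append(BranchPartition(edge, side_a, side_b, tuple(changes)))
    return parts


def network_from_genealogy(
    sequences: dict[str, str],
    frequencies: dict[str, float],
    limit: int | None = None,
    confidence: float = 0.95,
    forced_breaks: list[tuple[str, str]] | None = None,
    reading_frame: bool = True,
) -> HaplotypeNetwork:
    """Convenience: build, loop-resolve and label a network from raw inputs."""
    haps = {
        hid: Haplotype(hid, seq, float(frequencies.get(hid, 0.0)))
        for hid, seq in sequences.items()
    }
    net = build_network(haps, limit=limit, confidence=confidence)
    net = resolve_loops(net, forced_breaks=forced_breaks)
    label_edges(net, reading_frame=reading_frame)
    return net
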