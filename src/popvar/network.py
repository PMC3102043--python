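"""Median-joining haplotype networks.

Nodes are observed haplotypes (sized by frequency, optionally annotated with
subgroup composition) plus inferred median vectors (Steiner-like unobserved
intermediates, frequency 0); edge weights are Hamming distances in
mutational steps.  Construction follows the classical median-joining
iteration: build the minimum-spanning network under the relaxation parameter
epsilon, add consensus (median) vectors of triplets joined by at least two
links whenever they lower the network cost, repeat until stable, then prune
cost-neutral median
vectors.  Ties always break lexicographically on haplotype strings, so the
result is independent of input order.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx


@dataclass
class HaplotypeNetwork:
    graph: nx.Graph
    epsilon: int = 0
    groups_field: str | None = None

    @property
    def observed(self) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if not d["is_median"]
        )

    @property
    def medians(self) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d["is_median"]
        )

    def total_cost(self) -> int:
        """Weight of a minimum spanning tree over the final node set."""
        return _mst_cost(list(self.graph.nodes))

    def node_table(self) -> list[dict]:
        rows = []
        for node in sorted(self.graph.nodes):
            d = self.graph.nodes[node]
            rows.append(
                {
                    "haplotype": node,
                    "frequency": d["frequency"],
                    "is_median": d["is_median"],
                    "groups": dict(d.get("groups", {})),
                }
            )
        return rows

    def edge_table(self) -> list[dict]:
        return [
            {"u": min(u, v), "v": max(u, v), "steps": self.graph.edges[u, v]["weight"]}
            for u, v in sorted(
                (tuple(sorted(e)) for e in self.graph.edges), key=tuple
            )
        ]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("haplotypes must have equal length")
    return sum(x != y for x, y in zip(a, b))


def _msn_edges(nodes: list[str], epsilon: int = 0) -> list[tuple[str, str, int]]:
    """Minimum-spanning-network edges.

    An edge (u, v) is kept iff u and v are not connected by strictly shorter
    edges, relaxed by *epsilon* extra steps; at epsilon 0 this is exactly the
    union of all minimum spanning trees.
    """
    nodes = sorted(nodes)
    pairs = sorted(
        ((hamming(u, v), u, v) for u, v in itertools.combinations(nodes, 2))
    )
    edges = []
    for d, u, v in pairs:
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(
            (a, b) for dd, a, b in pairs if dd < d - epsilon
        )
        if not nx.has_path(g, u, v):
            edges.append((u, v, d))
    return edges


def _mst_cost(nodes: list[str]) -> int:
    """Prim's algorithm on Hamming distances (deterministic tie order)."""
    nodes = sorted(nodes)
    if len(nodes) <= 1:
        return 0
    frontier = {v: hamming(nodes[0], v) for v in nodes[1:]}
    cost = 0
    while frontier:
        v = min(frontier, key=lambda x: (frontier[x], x))
        cost += frontier.pop(v)
        for u in frontier:
            d = hamming(v, u)
            if d < frontier[u]:
                frontier[u] = d
    return cost


def _median(u: str, v: str, w: str) -> str:
    """Per-site majority consensus of three haplotypes (ties -> smallest)."""
    out = []
    for a, b, c in zip(u, v, w):
        counts = Counter((a, b, c))
        top = max(counts.values())
        out.append(min(x for x, k in counts.items() if k == top))
    return "".join(out)


def _exhaustive_median_subsets(observed: list[str]) -> set[str] | None:
    """Best node set among observed plus <=3 medians of observed triples."""
    obs = sorted(set(observed))
    cands = sorted(
        {_median(*t) for t in itertools.combinations(obs, 3)} - set(obs)
    )
    best_cost = _mst_cost(obs)
    best_set: set[str] | None = set(obs)
    max_extra = min(3, max(0, len(obs) - 2))
    for r in range(1, max_extra + 1):
        for combo in itertools.combinations(cands, r):
            cost = _mst_cost(obs + list(combo))
            if cost < best_cost:
                best_cost = cost
                best_set = set(obs) | set(combo)
    return best_set


def build_mjn(haplotypes: list[str], epsilon: int = 0) -> HaplotypeNetwork:
    """Build a median-joining network from haplotype strings.

    *haplotypes* may contain duplicates; multiplicity becomes node frequency.
    Sites must already be single-character coded (indel events binary
    recoded), and each indel counts as a single mutational step regardless of
    its length.
    """
    freq = Counter(haplotypes)
    if not freq:
        raise ValueError("no haplotypes given")
    lengths = {len(h) for h in freq}
    if len(lengths) > 1:
        raise ValueError("haplotypes must have equal length")
    observed = sorted(freq)
    nodes = set(observed)

    # median-joining iteration: per round, evaluate the consensus (median)
    # vector of every node triple and adopt the one that lowers the network
    # cost the most (ties break on the lexicographically smallest vector);
    # repeat until no median reduces the cost.  Cost strictly decreases, so
    # the loop terminates.
    while True:
        base_cost = _mst_cost(sorted(nodes))
        best_gain = 0
        best_median: str | None = None
        seen: set[str] = set()
        for u, v, w in itertools.combinations(sorted(nodes), 3):
            m = _median(u, v, w)
            if m in nodes or m in seen:
                continue
            seen.add(m)
            gain = base_cost - _mst_cost(sorted(nodes | {m}))
            if gain > best_gain or (
                gain == best_gain and best_median is not None
                and gain > 0 and m < best_median
            ):
                best_gain = gain
                best_median = m
        if best_gain <= 0 or best_median is None:
            break
        nodes.add(best_median)

    # greedy median adoption can settle above the optimum when two vectors
    # only help jointly; on small instances re-search subsets of the
    # observed triples' medians exhaustively and keep the cheaper solution
    if len(observed) <= 12:
        alt = _exhaustive_median_subsets(observed)
        if alt is not None and _mst_cost(sorted(alt)) < _mst_cost(sorted(nodes)):
            nodes = alt

    # prune obsolete medians: any whose removal does not raise the network
    # cost (cost-neutral vectors included); greedy, lexicographic order
    while True:
        cost = _mst_cost(sorted(nodes))
        removed = False
        for m in sorted(nodes - set(observed)):
            if _mst_cost(sorted(nodes - {m})) <= cost:
                nodes.discard(m)
                removed = True
                break
        if not removed:
            break

    graph = nx.Graph()
    for node in sorted(nodes):
        graph.add_node(
            node,
            frequency=freq.get(node, 0),
            is_median=node not in freq,
            groups=Counter(),
        )
    for u, v, w in _msn_edges(sorted(nodes), epsilon):
        graph.add_edge(u, v, weight=w)
    return HaplotypeNetwork(graph=graph, epsilon=epsilon)


def attach_groups(
    network: HaplotypeNetwork,
    accession_haplotypes: dict[str, tuple[str, str]],
    grouping: dict[str, str] | None = None,
    field_name: str | None = None,
) -> HaplotypeNetwork:
    """Attach per-node subgroup counts (one count per haplotype copy).

    Accessions without a label are pooled into ``unassigned``.  Subgroup
    counts at each node sum to the node's frequency provided the network was
    built from the same haplotype multiset.
    """
    for node in network.graph.nodes:
        network.graph.nodes[node]["groups"] = Counter()
    for acc, haps in accession_haplotypes.items():
        label = (grouping or {}).get(acc, "unassigned")
        for hap in haps:
            if hap in network.graph.nodes:
                network.graph.nodes[hap]["groups"][label] += 1
    network.groups_field = field_name
    return network


def network_layout_export(network: HaplotypeNetwork, path) -> None:
    """DOT export: node area proportional to frequency, medians as points."""
    from .formats import write_dot

    write_dot(network, path)
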