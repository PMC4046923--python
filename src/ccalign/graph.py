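"""Homology-graph post-processing: voting, pruning, group merging.

Predictions from independent alignment methods are combined by majority
vote (a protein pair is accepted as homologous when at least two of the
three methods call it).  Individual promiscuous proteins can still
create spurious links between unrelated groups; such proteins have high
betweenness centrality, so the top-centrality node of each group is
tentatively removed — if the group falls apart into substantial
sub-groups the split is accepted, otherwise the link was backed up by
other edges and the node is restored.  Finally, orthologous groups
(OGs) connected by high-scoring merge candidates are combined into
clusters, capped at a graph diameter of four edges so clusters cannot
grow indefinitely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx


@dataclass
class HomologyGraph:
    """Proteins as nodes; accepted homology links as edges carrying the
    supporting vote count (and optionally a bit-score weight)."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def groups(self) -> list[set]:
        return [set(c) for c in nx.connected_components(self.graph)]

    def n_proteins(self) -> int:
        return self.graph.number_of_nodes()


def combine_votes(pairs_by_method: dict[str, set],
                  scores: dict | None = None) -> HomologyGraph:
    """Majority-vote combination of per-method homolog pair sets.

    An edge is kept iff the pair occurs in at least two of the supplied
    sets; the vote count is stored on the edge.
    """
    if len(pairs_by_method) < 2:
        raise ValueError("need at least two methods to vote")
    votes: dict[frozenset, int] = {}
    for method, pairs in pairs_by_method.items():
        for pair in pairs:
            key = frozenset(pair)
            if len(key) != 2:
                raise ValueError(f"self-pair {pair} in method {method}")
            votes[key] = votes.get(key, 0) + 1
    g = nx.Graph()
    for key, v in votes.items():
        if v >= 2:
            a, b = sorted(key)
            w = scores.get(key, 0.0) if scores else 0.0
            g.add_edge(a, b, votes=v, weight=w)
    return HomologyGraph(graph=g)


def _betweenness_candidate(g: nx.Graph, component: set):
    """The top-betweenness node of a component, if its centrality exceeds
    twice the component median (otherwise None)."""
    if len(component) < 4:
        return None
    sub = g.subgraph(component)
    bc = nx.betweenness_centrality(sub, normalized=True)
    ranked = sorted(bc.items(), key=lambda kv: (-kv[1], kv[0]))
    top_node, top_val = ranked[0]
    vals = sorted(bc.values())
    median = vals[len(vals) // 2] if len(vals) % 2 else \
        0.5 * (vals[len(vals) // 2 - 1] + vals[len(vals) // 2])
    if top_val > 2 * median and top_val > 0:
        return top_node
    return None


def prune_spurious(hg: HomologyGraph) -> HomologyGraph:
    """Split groups held together only by a single high-betweenness node.

    Per group the top-centrality node (centrality > 2x the group median)
    is tentatively removed; if the group disintegrates into >= 2
    sub-groups of size >= 2 each, the split is accepted and the removed
    node is re-assigned to the sub-group it shares most edges with
    (ties: larger sub-group, then lexicographically smallest member).
    Otherwise the node is restored.  Newly formed sub-groups are checked
    in turn.  Never merges groups; conserves the protein set.
    """
    g = hg.graph.copy()
    queue = [set(c) for c in nx.connected_components(g)]
    protected: set = set()  # nodes whose removal did not split their group
    while queue:
        comp = queue.pop()
        node = _betweenness_candidate(g, comp)
        if node is None or node in protected:
            continue
        rest = comp - {node}
        sub = g.subgraph(rest)
        pieces = [set(c) for c in nx.connected_components(sub)]
        if len(pieces) >= 2 and all(len(p) >= 2 for p in pieces):
            # accept: cut the spurious links, keep the node's edges into
            # the sub-group it is most connected to (ties: larger
            # sub-group, then lexicographically smallest member)
            home = sorted(pieces, key=lambda p: (
                -sum(1 for nb in g.neighbors(node) if nb in p),
                -len(p), min(p)))[0]
            for nb in list(g.neighbors(node)):
                if nb not in home:
                    g.remove_edge(node, nb)
            for p in pieces:
                queue.append(p | ({node} if p is home else set()))
        else:
            protected.add(node)  # link is backed up by other edges
    return HomologyGraph(graph=g)


def merge_groups(og_pairs: list[tuple[str, str, float]],
                 species_of_group: dict[str, set],
                 threshold: float, strict_threshold: float,
                 max_diameter: int = 4) -> list[set]:
    """Combine orthologous groups into clusters.

    Candidate pairs are filtered by score (the stricter threshold applies
    when the two groups contain overlapping species sets, to avoid
    merging paralogs), sorted by decreasing score (ties: lexicographic
    group ids), and union-merged unless the merge would give the cluster
    a group-graph diameter exceeding ``max_diameter`` edges (i.e. more
    than three groups between the farthest pair).
    """
    if strict_threshold < threshold:
        raise ValueError("strict_threshold must be >= threshold")
    accepted = nx.Graph()
    accepted.add_nodes_from(species_of_group)
    candidates = []
    for g1, g2, score in og_pairs:
        overlap = bool(species_of_group.get(g1, set())
                       & species_of_group.get(g2, set()))
        cut = strict_threshold if overlap else threshold
        if score >= cut:
            a, b = sorted((g1, g2))
            candidates.append((-score, a, b))
    candidates.sort()
    for negscore, a, b in candidates:
        accepted.add_edge(a, b)
        comp = nx.node_connected_component(accepted, a)
        diam = nx.diameter(accepted.subgraph(comp))
        if diam > max_diameter:
            accepted.remove_edge(a, b)
    return [set(c) for c in nx.connected_components(accepted)]
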