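"""Median-joining haplotype networks with geographic annotation.

The construction follows the Bandelt median-joining scheme: build the
epsilon-relaxed minimum spanning network (MSN) over the current node set,
then consider triplets of mutually-linked nodes and add the site-wise
majority consensus (median vector) of a triplet whenever doing so strictly
lowers the minimum spanning cost of the augmented node set; obsolete medians
(those no longer needed to connect observed haplotypes) are pruned and the
process iterates to a fixpoint. With epsilon = 0 and no cost-reducing median
the result is exactly the union of all minimum spanning trees, so equal-cost
alternative connections (reticulations) are retained.

Nodes carry ``sequence``, ``count`` (0 for median vectors) and ``kind``
("observed" | "median"); edges carry ``weight`` = number of differing sites.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx

from nistrace.hapstats import HaplotypeTable


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    return sum(x != y for x, y in zip(a, b))


def minimum_spanning_network(
    seqs: dict[str, str], epsilon: int = 0
) -> nx.Graph:
    """Epsilon-relaxed minimum spanning network over labelled sequences.

    Edges are examined in increasing weight classes; an edge of weight w is
    admitted when its endpoints lie in different components of the graph
    formed by all edges of weight < w - epsilon. With epsilon = 0 this yields
    the union of all minimum spanning trees.
    """
    g = nx.Graph()
    for node, seq in seqs.items():
        g.add_node(node, sequence=seq)
    names = sorted(seqs)
    edges = sorted(
        (hamming(seqs[u], seqs[v]), u, v) for u, v in combinations(names, 2)
    )
    kept: list[tuple[int, str, str]] = []
    weights = sorted({w for w, _, _ in edges})
    for w in weights:
        # components induced by strictly lighter (minus relaxation) accepted edges
        uf = nx.utils.UnionFind(names)
        for wk, u, v in kept:
            if wk < w - epsilon:
                uf.union(u, v)
        for wk, u, v in edges:
            if wk == w and uf[u] != uf[v]:
                kept.append((wk, u, v))
    for w, u, v in kept:
        g.add_edge(u, v, weight=w)
    return g


def _spanning_cost(seqs: dict[str, str]) -> int:
    g = nx.Graph()
    names = sorted(seqs)
    for u, v in combinations(names, 2):
        g.add_edge(u, v, weight=hamming(seqs[u], seqs[v]))
    return int(sum(d["weight"] for _, _, d in
                   nx.minimum_spanning_edges(g, data=True)))


def _median(a: str, b: str, c: str) -> str | None:
    """Site-wise majority consensus of three sequences; None if no site
    resolves (all-distinct sites are skipped; a median identical to an input
    is returned as-is and filtered by the caller)."""
    out = []
    for x, y, z in zip(a, b, c):
        if x == y or x == z:
            out.append(x)
        elif y == z:
            out.append(y)
        else:
            # three distinct states: no majority, keep the first (acts as
            # skip under the binary-state assumption of the classic scheme)
            out.append(x)
    return "".join(out)


def build_mj_network(table: HaplotypeTable, epsilon: int = 0) -> nx.Graph:
    """Median-joining network of a haplotype table.

    Returns a connected graph whose observed nodes are the table's hap_ids
    and whose median vectors are labelled ``mv1``, ``mv2``, ... in order of
    admission; ties everywhere are broken lexicographically so the output is
    deterministic. A single-haplotype table yields a single-node graph.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    seqs: dict[str, str] = {}
    counts: dict[str, int] = {}
    for hap_id, seq, cnt in table.haplotypes:
        seqs[hap_id] = seq
        counts[hap_id] = cnt
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) > 1:
        raise ValueError("ragged haplotype sequences")
    observed = set(seqs)
    medians: dict[str, str] = {}
    mv_counter = 0

    def all_nodes() -> dict[str, str]:
        return {**seqs, **medians}

    if len(seqs) >= 2:
        improved = True
        while improved:
            improved = False
            nodes = all_nodes()
            msn = minimum_spanning_network(nodes, epsilon)
            cost = _spanning_cost(nodes)
            # candidate triplets: mutually close in the current MSN
            existing = set(nodes.values())
            candidates = []
            for u, v, w in combinations(sorted(nodes), 3):
                links = sum(msn.has_edge(*p) for p in ((u, v), (u, w), (v, w)))
                if links >= 2:
                    m = _median(nodes[u], nodes[v], nodes[w])
                    if m is not None and m not in existing:
                        candidates.append(m)
            best = None
            for m in sorted(set(candidates)):
                trial = dict(nodes)
                trial[f"_trial"] = m
                c = _spanning_cost(trial)
                if c < cost and (best is None or c < best[0] or
                                 (c == best[0] and m < best[1])):
                    best = (c, m)
            if best is not None:
                mv_counter += 1
                medians[f"mv{mv_counter}"] = best[1]
                improved = True
        # prune obsolete medians: drop any median whose removal leaves the
        # spanning cost of the remaining node set unchanged
        changed = True
        while changed:
            changed = False
            nodes = all_nodes()
            cost = _spanning_cost(nodes)
            for name in sorted(medians):
                rest = {k: v for k, v in nodes.items() if k != name}
                if _spanning_cost(rest) <= cost:
                    del medians[name]
                    changed = True
                    break

    nodes = all_nodes()
    graph = minimum_spanning_network(nodes, epsilon) if len(nodes) > 1 else nx.Graph()
    if len(nodes) == 1:
        graph.add_node(next(iter(nodes)))
    for name in graph.nodes:
        graph.nodes[name]["sequence"] = nodes[name]
        graph.nodes[name]["count"] = counts.get(name, 0)
        graph.nodes[name]["kind"] = "observed" if name in observed else "median"
    graph.graph["species"] = table.species
    graph.graph["epsilon"] = epsilon
    return graph


def annotate_regions(graph: nx.Graph, labels: dict[str, dict[str, int]]) -> nx.Graph:
    """Attach per-region frequency vectors to observed nodes.

    ``labels`` maps hap_id -> {region: count}; every observed node must have
    a label set. Median vectors are labelled "inferred".
    """
    for name, data in graph.nodes(data=True):
        if data.get("kind") == "median":
            data["regions"] = "inferred"
        else:
            if name not in labels:
                raise KeyError(f"observed haplotype {name!r} has no region labels")
            data["regions"] = dict(labels[name])
    return graph


def write_network(graph: nx.Graph, graphml_path, edges_path) -> None:
    """Serialise a network as GraphML plus a TSV edge list."""
    g = graph.copy()
    for _, data in g.nodes(data=True):
        if isinstance(data.get("regions"), dict):
            data["regions"] = ";".join(f"{k}:{v}" for k, v in sorted(data["regions"].items()))
    nx.write_graphml(g, graphml_path)
    with open(edges_path, "w") as fh:
        fh.write("node1\tnode2\tweight\n")
        for u, v, d in sorted(g.edges(data=True)):
            fh.write(f"{u}\t{v}\t{d['weight']}\n")
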