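"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive (exhaustive enumeration, closed
forms) and shares no code path with the package's algorithms beyond the
basic monomorphism check used for support counting.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np


def label_graph(labels: dict[int, str], edges: list[tuple[int, int]]) -> nx.Graph:
    g = nx.Graph()
    for n, l in labels.items():
        g.add_node(n, aa=l)
    g.add_edges_from(edges)
    return g


def permutation_isomorphic(g1: nx.Graph, g2: nx.Graph) -> bool:
    """Exhaustive label-preserving bijection search."""
    n1, n2 = sorted(g1.nodes), sorted(g2.nodes)
    if len(n1) != len(n2) or g1.number_of_edges() != g2.number_of_edges():
        return False
    e1 = {frozenset(e) for e in g1.edges}
    for perm in itertools.permutations(n2):
        m = dict(zip(n1, perm))
        if any(g1.nodes[a]["aa"] != g2.nodes[m[a]]["aa"] for a in n1):
            continue
        if {frozenset((m[a], m[b])) for a, b in g1.edges} == {frozenset(e) for e in g2.edges}:
            return True
    return False


def exhaustive_monomorphic(pattern: nx.Graph, host: nx.Graph) -> bool:
    """Exhaustive injective label-preserving mapping search."""
    pn = sorted(pattern.nodes)
    hn = sorted(host.nodes)
    if len(pn) > len(hn):
        return False
    for combo in itertools.permutations(hn, len(pn)):
        m = dict(zip(pn, combo))
        if any(pattern.nodes[a]["aa"] != host.nodes[m[a]]["aa"] for a in pn):
            continue
        if all(host.has_edge(m[a], m[b]) for a, b in pattern.edges):
            return True
    return False


def _connected_subpatterns(g: nx.Graph):
    """All connected (node subset, edge subset) patterns of one graph."""
    nodes = sorted(g.nodes)
    for r in range(1, len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            sset = set(subset)
            induced = [e for e in g.edges if e[0] in sset and e[1] in sset]
            for er in range(0, len(induced) + 1):
                for esub in itertools.combinations(induced, er):
                    h = nx.Graph()
                    for v in subset:
                        h.add_node(v, aa=g.nodes[v]["aa"])
                    h.add_edges_from(esub)
                    if r == 1 or (h.number_of_edges() and nx.is_connected(h)):
                        # every chosen node must be touched (connected pattern)
                        if r > 1 and any(h.degree[v] == 0 for v in subset):
                            continue
                        yield h


def brute_force_closed_frequent(graphs: list[nx.Graph], t: int):
    """Closed frequent connected patterns by full enumeration.

    Returns a dict canonical-signature -> (support, pattern graph), where
    the signature is a sorted-label + sorted-canonical-edge string built
    via permutation canonicalization (independent of the package's
    canonical code).
    """
    candidates: dict[str, nx.Graph] = {}
    for g in graphs:
        for pat in _connected_subpatterns(g):
            sig = _perm_signature(pat)
            candidates.setdefault(sig, pat)
    supports: dict[str, int] = {}
    for sig, pat in candidates.items():
        supports[sig] = sum(1 for g in graphs if exhaustive_monomorphic(pat, g))
    frequent = {sig: pat for sig, pat in candidates.items() if supports[sig] >= t}
    closed = {}
    for sig, pat in frequent.items():
        is_closed = True
        for sig2, pat2 in candidates.items():
            if sig2 == sig or supports[sig2] != supports[sig]:
                continue
            bigger = (pat2.number_of_nodes() >= pat.number_of_nodes()
                      and pat2.number_of_edges() >= pat.number_of_edges()
                      and (pat2.number_of_nodes() > pat.number_of_nodes()
                           or pat2.number_of_edges() > pat.number_of_edges()))
            if bigger and exhaustive_monomorphic(pat, pat2):
                is_closed = False
                break
        if is_closed:
            closed[sig] = (supports[sig], pat)
    return closed


def _perm_signature(g: nx.Graph) -> str:
    """Minimal string over all node orderings (exact, exponential)."""
    nodes = sorted(g.nodes)
    best = None
    for perm in itertools.permutations(range(len(nodes))):
        m = dict(zip(nodes, perm))
        labels = [None] * len(nodes)
        for v, i in m.items():
            labels[i] = g.nodes[v]["aa"]
        edges = sorted((min(m[a], m[b]), max(m[a], m[b])) for a, b in g.edges)
        sig = ",".join(labels) + ";" + ",".join(f"{a}-{b}" for a, b in edges)
        if best is None or sig < best:
            best = sig
    return best or ""


def brute_force_closed_itemsets(transactions: list[frozenset], minsup: int):
    """Closed frequent itemsets by power-set enumeration (<= ~15 items)."""
    items = sorted({i for t in transactions for i in t})
    out = {}
    subsets = []
    for r in range(1, len(items) + 1):
        for combo in itertools.combinations(items, r):
            s = frozenset(combo)
            sup = sum(1 for t in transactions if s <= t)
            if sup >= minsup:
                subsets.append((s, sup))
    for s, sup in subsets:
        if not any(s < s2 and sup == sup2 for s2, sup2 in subsets):
            out[s] = sup
    return out


def delaunay_edges_bruteforce(points: np.ndarray) -> set[tuple[int, int]]:
    """3D Delaunay edges via the O(n^4) empty-circumsphere simplex test."""
    n = len(points)
    edges: set[tuple[int, int]] = set()
    for quad in itertools.combinations(range(n), 4):
        p = points[list(quad)]
        a = np.hstack([2 * (p[1:] - p[0]),])
        b = (p[1:] ** 2).sum(axis=1) - (p[0] ** 2).sum()
        try:
            center = np.linalg.solve(a, b)
        except np.linalg.LinAlgError:
            continue  # coplanar quadruple
        r2 = ((p[0] - center) ** 2).sum()
        empty = True
        for k in range(n):
            if k in quad:
                continue
            if ((points[k] - center) ** 2).sum() < r2 - 1e-9:
                empty = False
                break
        if empty:
            for a_, b_ in itertools.combinations(quad, 2):
                edges.add((min(a_, b_), max(a_, b_)))
    return edges


def random_graph_db(rng: np.random.Generator, n_graphs_max: int = 5,
                    n_nodes_max: int = 6, alphabet: str = "ABC") -> list[nx.Graph]:
    """Small random labeled graph DB for miner-vs-oracle equivalence."""
    graphs = []
    n_graphs = int(rng.integers(2, n_graphs_max + 1))
    for gi in range(n_graphs):
        n = int(rng.integers(2, n_nodes_max + 1))
        g = nx.Graph()
        for v in range(n):
            g.add_node(v, aa=str(rng.choice(list(alphabet))))
        # sparse: a random tree plus a few extras
        order = rng.permutation(n)
        for i in range(1, n):
            g.add_edge(int(order[i]), int(order[rng.integers(0, i)]))
        extra = int(rng.integers(0, 3))
        non_edges = [(u, v) for u in range(n) for v in range(u + 1, n)
                     if not g.has_edge(u, v)]
        for idx in rng.choice(len(non_edges), size=min(extra, len(non_edges)),
                              replace=False):
            g.add_edge(*non_edges[idx])
        g.graph["graph_id"] = f"g{gi}"
        graphs.append(g)
    return graphs
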