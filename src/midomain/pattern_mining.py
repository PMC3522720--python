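"""Closed frequent subgraph mining over labeled interface graphs.

The pattern language is connected node-labeled graphs with unlabeled
edges.  A pattern occurs in a database graph when a label-preserving
injective mapping sends pattern nodes to graph nodes and pattern edges
to graph edges (subgraph monomorphism).  Support is per-graph: a host
graph counts once no matter how many embeddings it holds.  A frequent
pattern is *closed* when no extension by one edge (between existing
nodes, or to one new node) keeps the same support — closed patterns are
the maximal fingerprints that still identify the same set of interfaces.

The miner grows patterns breadth-first from frequent single labels,
tracking every embedding, and deduplicates pattern shapes by an exact
canonical code (BLISS canonical labeling of the vertex-colored graph via
igraph).  Also here: labeled-graph isomorphism, isomorphic-pair counts
between fingerprint sets, and the random-graph null model for those
counts.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import igraph as ig
import networkx as nx
import numpy as np
from networkx.algorithms import isomorphism as nxiso

from .synthetic_data import random_labeled_graph

AA_MATCH = nxiso.categorical_node_match("aa", None)


@dataclass
class GraphDB:
    graphs: list[nx.Graph]
    site_id: int | None = None
    support_threshold: int = 2

    def __post_init__(self) -> None:
        if not (1 <= self.support_threshold <= max(1, len(self.graphs))):
            raise ValueError("support threshold must be in [1, |graphs|]")

    def graph_ids(self) -> list[str]:
        return [g.graph.get("graph_id", f"g{i}") for i, g in enumerate(self.graphs)]


@dataclass
class Fingerprint:
    pattern: nx.Graph
    support: int
    occurrences: frozenset[str]
    canonical_code: str
    fingerprint_id: str = ""
    site_id: int | None = None

    @property
    def n_nodes(self) -> int:
        return self.pattern.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.pattern.number_of_edges()

    @property
    def trivial(self) -> bool:
        # patterns below two edges carry no topology worth calling a fingerprint
        return self.n_edges < 2


def support_threshold(n_graphs: int, local_support: float = 0.20) -> int:
    """Global support count: ceil(n_graphs * local_support), floored at 2."""
    if n_graphs < 1:
        raise ValueError("need at least one graph")
    return max(2, math.ceil(n_graphs * local_support))


def canonical_code(g: nx.Graph) -> str:
    """Isomorphism-invariant code of a node-labeled graph.

    Built from the BLISS canonical permutation of the vertex-colored
    graph; two graphs get equal codes iff they are label-preserving
    isomorphic.
    """
    nodes = sorted(g.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    labels = [str(g.nodes[v]["aa"]) for v in nodes]
    rank = {lab: r for r, lab in enumerate(sorted(set(labels)))}
    igr = ig.Graph(n=len(nodes), edges=[(index[u], index[v]) for u, v in g.edges])
    perm = igr.canonical_permutation(color=[rank[l] for l in labels])
    # perm[i] = canonical index of node i
    canon_labels = [None] * len(nodes)
    for i, p in enumerate(perm):
        canon_labels[p] = labels[i]
    canon_edges = sorted((min(perm[index[u]], perm[index[v]]),
                          max(perm[index[u]], perm[index[v]])) for u, v in g.edges)
    return (",".join(canon_labels) + ";" +
            ",".join(f"{a}-{b}" for a, b in canon_edges))


def _canonical_perm(g: nx.Graph) -> tuple[list, list[int]]:
    nodes = sorted(g.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    labels = [str(g.nodes[v]["aa"]) for v in nodes]
    rank = {lab: r for r, lab in enumerate(sorted(set(labels)))}
    igr = ig.Graph(n=len(nodes), edges=[(index[u], index[v]) for u, v in g.edges])
    perm = igr.canonical_permutation(color=[rank[l] for l in labels])
    return nodes, list(perm)


def subgraph_occurs(pattern: nx.Graph, host: nx.Graph) -> bool:
    """True iff the pattern embeds into the host (label-preserving monomorphism)."""
    if pattern.number_of_nodes() > host.number_of_nodes():
        return False
    if pattern.number_of_edges() > host.number_of_edges():
        return False
    need = Counter(nx.get_node_attributes(pattern, "aa").values())
    have = Counter(nx.get_node_attributes(host, "aa").values())
    if any(have[l] < c for l, c in need.items()):
        return False
    gm = nxiso.GraphMatcher(host, pattern, node_match=AA_MATCH)
    return gm.subgraph_is_monomorphic()


def is_isomorphic(g1: nx.Graph, g2: nx.Graph) -> bool:
    """Label-preserving isomorphism of two node-labeled graphs."""
    if (g1.number_of_nodes() != g2.number_of_nodes()
            or g1.number_of_edges() != g2.number_of_edges()):
        return False
    if (Counter(nx.get_node_attributes(g1, "aa").values())
            != Counter(nx.get_node_attributes(g2, "aa").values())):
        return False
    if g1.number_of_nodes() <= 12:
        return canonical_code(g1) == canonical_code(g2)
    return nx.is_isomorphic(g1, g2, node_match=AA_MATCH)


# -- miner ------------------------------------------------------------------

class _Pattern:
    """Mutable mining pattern: nodes 0..k-1 with labels, plus embeddings."""

    __slots__ = ("labels", "edges", "embeddings", "support", "graph", "code")

    def __init__(self, labels: tuple[str, ...], edges: frozenset[tuple[int, int]],
                 embeddings: set[tuple[int, tuple[int, ...]]]):
        self.labels = labels
        self.edges = edges
        self.embeddings = embeddings
        self.support = len({gi for gi, _ in embeddings})
        g = nx.Graph()
        for i, lab in enumerate(labels):
            g.add_node(i, aa=lab)
        g.add_edges_from(edges)
        self.graph = g
        self.code = canonical_code(g)


def _remap_embeddings(struct_graph: nx.Graph, rep_graph: nx.Graph,
                      embeddings: Iterable[tuple[int, tuple[int, ...]]]):
    """Re-express embeddings of an isomorphic structure in the rep's node order."""
    _, perm_s = _canonical_perm(struct_graph)
    _, perm_r = _canonical_perm(rep_graph)
    inv_s = {c: i for i, c in enumerate(perm_s)}
    # rep node j -> struct node inv_s[perm_r[j]]
    order = [inv_s[perm_r[j]] for j in range(rep_graph.number_of_nodes())]
    return {(gi, tuple(mapping[i] for i in order)) for gi, mapping in embeddings}


def mine_closed_frequent(db: GraphDB, max_edges: int | None = None) -> list[Fingerprint]:
    """All closed frequent connected patterns of a graph database.

    Breadth-first pattern growth with full embedding lists; support is
    per-graph.  A frequent pattern is emitted iff no one-step extension
    (one new edge, possibly with one new node) has equal support.
    Output is deduplicated by canonical code and sorted by (size desc,
    support desc, code); identical input yields identical output.
    """
    graphs = db.graphs
    t = db.support_threshold
    gids = db.graph_ids()

    # level 1: single-node patterns
    by_code: dict[str, _Pattern] = {}
    label_embed: dict[str, set] = defaultdict(set)
    for gi, g in enumerate(graphs):
        for v in g.nodes:
            label_embed[str(g.nodes[v]["aa"])].add((gi, (v,)))
    frontier: list[_Pattern] = []
    all_patterns: dict[str, _Pattern] = {}
    child_supports: dict[str, int] = defaultdict(int)  # code -> best child support
    for lab in sorted(label_embed):
        p = _Pattern((lab,), frozenset(), label_embed[lab])
        if p.support >= t:
            frontier.append(p)
            all_patterns[p.code] = p

    while frontier:
        candidates: dict[str, _Pattern] = {}
        children_of: dict[str, set[str]] = defaultdict(set)
        for pat in frontier:
            if max_edges is not None and len(pat.edges) >= max_edges:
                continue
            k = len(pat.labels)
            ext: dict[tuple, set] = defaultdict(set)
            for gi, mapping in pat.embeddings:
                g = graphs[gi]
                mapped = set(mapping)
                for i, hv in enumerate(mapping):
                    for nb in g.adj[hv]:
                        if nb in mapped:
                            j = mapping.index(nb)
                            if i < j and (i, j) not in pat.edges:
                                ext[("back", i, j)].add((gi, mapping))
                        else:
                            ext[("fwd", i, str(g.nodes[nb]["aa"]))].add((gi, mapping + (nb,)))
            for key, embeds in ext.items():
                if key[0] == "back":
                    _, i, j = key
                    labels = pat.labels
                    edges = pat.edges | {(i, j)}
                else:
                    _, i, lab = key
                    labels = pat.labels + (lab,)
                    edges = pat.edges | {(i, k)}
                child = _Pattern(labels, edges, embeds)
                children_of[pat.code].add(child.code)
                prev = candidates.get(child.code)
                if prev is None:
                    candidates[child.code] = child
                else:
                    prev.embeddings |= _remap_embeddings(child.graph, prev.graph,
                                                         child.embeddings)
        next_frontier: list[_Pattern] = []
        for code, child in candidates.items():
            child.support = len({gi for gi, _ in child.embeddings})
            if code not in all_patterns and child.support >= t:
                all_patterns[code] = child
                next_frontier.append(child)
        # every one-step super-pattern that occurs anywhere is generated from
        # each of its frequent parents, so the recorded children suffice for
        # the closedness check
        for pat in frontier:
            best = max((candidates[c].support for c in children_of.get(pat.code, ())),
                       default=0)
            child_supports[pat.code] = max(child_supports[pat.code], best)
        frontier = next_frontier

    out: list[Fingerprint] = []
    for code, pat in all_patterns.items():
        if child_supports.get(code, 0) == pat.support:
            continue  # extensible without support loss -> not closed
        occ = frozenset(gids[gi] for gi in {g for g, _ in pat.embeddings})
        out.append(Fingerprint(pattern=pat.graph, support=pat.support,
                               occurrences=occ, canonical_code=code,
                               site_id=db.site_id))
    out.sort(key=lambda f: (-f.n_nodes, -f.n_edges, -f.support, f.canonical_code))
    for i, f in enumerate(out):
        f.fingerprint_id = f"fp{i}"
    return out


def count_isomorphic_pairs(set_a: Sequence[Fingerprint],
                           set_b: Sequence[Fingerprint]) -> int:
    """Fingerprints of the smaller set with an isomorphic partner in the other."""
    if len(set_b) < len(set_a):
        set_a, set_b = set_b, set_a
    codes_b = {f.canonical_code for f in set_b}
    return sum(1 for f in set_a if f.canonical_code in codes_b)


@dataclass
class NullTestResult:
    observed: int
    exceed_count: int
    n_reps: int

    @property
    def p_value(self) -> float:
        # p-values live in (0, 1]; a zero count is reported as the 1/n bound
        return max(self.exceed_count, 1) / self.n_reps

    @property
    def is_upper_bound(self) -> bool:
        return self.exceed_count == 0

    @property
    def formatted(self) -> str:
        if self.is_upper_bound:
            return f"< {1 / self.n_reps:.1e}"
        return f"{self.exceed_count / self.n_reps:.1e}"


def random_null_pvalue(
    set_a_sizes: Sequence[tuple[int, int]],
    set_b_sizes: Sequence[tuple[int, int]],
    label_freqs: Mapping[str, float],
    observed: int,
    n_reps: int = 2000,
    seed: int = 0,
) -> NullTestResult:
    """Null distribution of isomorphic-pair counts between random graph sets.

    Each replicate draws, for every fingerprint, a random connected
    labeled graph of the same (n_nodes, n_edges) with labels i.i.d. from
    the supplied amino-acid frequencies, then counts isomorphic pairs
    between the two random sets.  p = P(count >= observed) over
    replicates; a zero count is reported as the "< 1/n_reps" bound.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    for n, m in list(set_a_sizes) + list(set_b_sizes):
        if m < max(0, n - 1) or m > n * (n - 1) // 2:
            raise ValueError(f"impossible connected graph size (n={n}, m={m})")
    exceed = 0
    for _ in range(n_reps):
        fa = [_as_fp(random_labeled_graph(n, m, dict(label_freqs), rng))
              for n, m in set_a_sizes]
        fb = [_as_fp(random_labeled_graph(n, m, dict(label_freqs), rng))
              for n, m in set_b_sizes]
        if count_isomorphic_pairs(fa, fb) >= observed:
            exceed += 1
    return NullTestResult(observed=observed, exceed_count=exceed, n_reps=n_reps)


def _as_fp(g: nx.Graph) -> Fingerprint:
    return Fingerprint(pattern=g, support=1, occurrences=frozenset(),
                       canonical_code=canonical_code(g))


def db_label_frequencies(db: GraphDB) -> dict[str, float]:
    """Amino-acid background frequencies observed in a graph database."""
    counts: Counter = Counter()
    for g in db.graphs:
        counts.update(nx.get_node_attributes(g, "aa").values())
    total = sum(counts.values())
    return {lab: c / total for lab, c in sorted(counts.items())}


def write_fingerprint_index(fingerprints: Sequence[Fingerprint], path) -> None:
    with open(path, "w") as fh:
        fh.write("fingerprint_id\tsite_id\tn_nodes\tn_edges\tsupport\ttrivial\t"
                 "occurrences\tcanonical_code\n")
        for f in fingerprints:
            fh.write(f"{f.fingerprint_id}\t{f.site_id}\t{f.n_nodes}\t{f.n_edges}\t"
                     f"{f.support}\t{int(f.trivial)}\t{','.join(sorted(f.occurrences))}\t"
                     f"{f.canonical_code}\n")
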