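"""Relations between the multiple binding sites of a domain.

Cooperative relations are fingerprint pairs from two different sites
that co-occur in the same proteins; distinctive fingerprints belong to
exactly one site, with no isomorphic counterpart and no embedding in any
other site.  The transactional view (closed frequent itemsets over
fingerprint-by-interface occurrence) is retained for multi-way
co-occurrence.  Domain-specificity statistics compare per-fingerprint
degree- and label-assortativity distributions between two domains with
Welch t-tests, plus a size-matched subsampling disparity test on
isomorphic-pair counts.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .pattern_mining import Fingerprint, subgraph_occurs


@dataclass
class Transaction:
    fingerprint_id: str
    items: frozenset[str]  # interface identifiers where the fingerprint occurs


@dataclass
class TransactionDB:
    transactions: list[Transaction]


@dataclass
class CooperativePair:
    fp_a: str
    fp_b: str
    site_a: int
    site_b: int
    co_support: int
    n_proteins_with_both_sites: int

    @property
    def co_fraction(self) -> float:
        return self.co_support / self.n_proteins_with_both_sites


def build_transactions(
    fingerprints: Sequence[Fingerprint],
    interface_graphs: Mapping[str, nx.Graph],
) -> TransactionDB:
    """One transaction per fingerprint: the interfaces it embeds in."""
    txs = []
    for fp in fingerprints:
        items = frozenset(iid for iid, g in interface_graphs.items()
                          if subgraph_occurs(fp.pattern, g))
        if items:
            txs.append(Transaction(fp.fingerprint_id, items))
    return TransactionDB(txs)


def mine_closed_itemsets(
    transactions: Sequence[frozenset],
    minsup: int,
) -> list[tuple[frozenset, int]]:
    """All closed frequent itemsets (no proper superset has equal support).

    Closure-based depth-first enumeration over item tidsets (the LCM
    idea): every closed itemset is the intersection of the transactions
    that contain it, so candidates are generated as closures of tidsets
    and deduplicated.  Output sorted by (support desc, size desc, items).
    """
    if minsup < 1:
        raise ValueError("minsup must be >= 1")
    tx = [frozenset(t) for t in transactions]
    items = sorted({i for t in tx for i in t})
    tid_of = {it: frozenset(j for j, t in enumerate(tx) if it in t) for it in items}

    def closure(tids: frozenset) -> frozenset:
        out = None
        for j in tids:
            out = tx[j] if out is None else out & tx[j]
        return out if out is not None else frozenset()

    seen: dict[frozenset, int] = {}

    def visit(tids: frozenset) -> None:
        if len(tids) < minsup:
            return
        closed = closure(tids)
        if closed in seen:
            return
        seen[closed] = len(tids)
        for it in items:
            if it in closed:
                continue
            sub = tids & tid_of[it]
            if len(sub) >= minsup and sub != tids:
                visit(sub)

    for it in items:
        visit(tid_of[it])
    out = [(s, c) for s, c in seen.items() if s]
    out.sort(key=lambda x: (-x[1], -len(x[0]), tuple(sorted(x[0]))))
    return out


def cooperative_pairs(
    fingerprints_by_site: Mapping[int, Sequence[Fingerprint]],
    protein_site_graphs: Mapping[str, Mapping[int, nx.Graph]],
    min_co_fraction: float = 0.20,
) -> list[CooperativePair]:
    """Co-existing fingerprint pairs across two sites of one domain.

    A pair (fp from site i, fp from site j) is cooperative when both
    fingerprints embed in the respective site graphs of the same protein;
    the co-occurrence fraction is taken over proteins that possess both
    sites and must reach ``min_co_fraction``.
    """
    sites = sorted(fingerprints_by_site)
    out: list[CooperativePair] = []
    any_pair = False
    for si, sj in itertools.combinations(sites, 2):
        proteins = [p for p, graphs in protein_site_graphs.items()
                    if si in graphs and sj in graphs]
        if not proteins:
            continue
        any_pair = True
        # cache occurrence vectors
        occ: dict[tuple[int, str], set[str]] = {}
        for site, fps in ((si, fingerprints_by_site[si]), (sj, fingerprints_by_site[sj])):
            for fp in fps:
                occ[(site, fp.fingerprint_id)] = {
                    p for p in proteins
                    if subgraph_occurs(fp.pattern, protein_site_graphs[p][site])}
        for fa in fingerprints_by_site[si]:
            for fb in fingerprints_by_site[sj]:
                co = occ[(si, fa.fingerprint_id)] & occ[(sj, fb.fingerprint_id)]
                if co and len(co) / len(proteins) >= min_co_fraction:
                    out.append(CooperativePair(
                        fp_a=fa.fingerprint_id, fp_b=fb.fingerprint_id,
                        site_a=si, site_b=sj, co_support=len(co),
                        n_proteins_with_both_sites=len(proteins)))
    if not any_pair:
        warnings.warn("no protein possesses two sites; no cooperative pairs")
    return out


def distinctive_fingerprints(
    site: int,
    fingerprints_by_site: Mapping[int, Sequence[Fingerprint]],
    graphs_by_site: Mapping[int, Sequence[nx.Graph]],
) -> list[Fingerprint]:
    """Fingerprints unique to one site of a domain.

    Excluded are fingerprints with an isomorphic counterpart among any
    other site's fingerprints, or with an embedding in any other site's
    interface graphs.
    """
    other_codes = {fp.canonical_code
                   for s, fps in fingerprints_by_site.items() if s != site
                   for fp in fps}
    out = []
    for fp in fingerprints_by_site[site]:
        if fp.canonical_code in other_codes:
            continue
        occurs_elsewhere = any(
            subgraph_occurs(fp.pattern, g)
            for s, graphs in graphs_by_site.items() if s != site
            for g in graphs)
        if not occurs_elsewhere:
            out.append(fp)
    return out


def function_association(
    site_labels: Mapping[int, str | None],
    fingerprints_by_site: Mapping[int, Sequence[Fingerprint]],
    graphs_by_site: Mapping[int, Sequence[nx.Graph]],
) -> list[dict]:
    """Per function label: fingerprint counts, distinctive and shared counts.

    Sites without a label are reported under "unannotated".  A
    fingerprint is shared for a function when an isomorphic counterpart
    exists under a different function label.
    """
    label_of = {s: (site_labels.get(s) or "unannotated") for s in fingerprints_by_site}
    codes_by_label: dict[str, set[str]] = {}
    for s, fps in fingerprints_by_site.items():
        codes_by_label.setdefault(label_of[s], set()).update(f.canonical_code for f in fps)
    rows = []
    for label in sorted(codes_by_label):
        sites = [s for s in fingerprints_by_site if label_of[s] == label]
        fps = [fp for s in sites for fp in fingerprints_by_site[s]]
        other_codes = {c for l, cs in codes_by_label.items() if l != label for c in cs}
        n_shared = sum(1 for fp in fps if fp.canonical_code in other_codes)
        n_distinct = sum(len(distinctive_fingerprints(s, fingerprints_by_site,
                                                      graphs_by_site)) for s in sites)
        rows.append({"function": label, "n_sites": len(sites),
                     "n_fingerprints": len(fps), "n_distinctive": n_distinct,
                     "n_shared": n_shared})
    return rows


def degree_assortativity(g: nx.Graph) -> float | None:
    """Pearson correlation of endpoint degrees over the symmetrized edges.

    None when either marginal variance vanishes (e.g. regular graphs);
    any star is exactly -1.
    """
    if g.number_of_edges() == 0:
        raise ValueError("assortativity undefined for edgeless graph")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = nx.degree_assortativity_coefficient(g)
    return None if not np.isfinite(r) else float(r)


def label_assortativity(g: nx.Graph, attr: str = "aa") -> float | None:
    """Categorical mixing assortativity over node labels.

    r = (sum_i e_ii - sum_i a_i b_i) / (1 - sum_i a_i b_i) on the label
    mixing matrix; None for single-label graphs (denominator zero).
    """
    if g.number_of_edges() == 0:
        raise ValueError("assortativity undefined for edgeless graph")
    if len({g.nodes[v][attr] for v in g.nodes}) < 2:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = nx.attribute_assortativity_coefficient(g, attr)
    return None if not np.isfinite(r) else float(r)


@dataclass
class DomainComparison:
    p_label: float
    p_degree: float
    n_a_label: int
    n_b_label: int
    n_a_degree: int
    n_b_degree: int
    n_dropped: int


def compare_domains(fp_set_a: Sequence[Fingerprint],
                    fp_set_b: Sequence[Fingerprint]) -> DomainComparison:
    """Welch two-sample t-tests on assortativity distributions.

    Per-fingerprint degree- and label-assortativity values are compared
    between the two domains; undefined values are dropped (counted).
    """
    vals = {}
    dropped = 0
    for name, fps in (("a", fp_set_a), ("b", fp_set_b)):
        deg, lab = [], []
        for fp in fps:
            if fp.pattern.number_of_edges() == 0:
                dropped += 1
                continue
            d = degree_assortativity(fp.pattern)
            l = label_assortativity(fp.pattern)
            if d is None:
                dropped += 1
            else:
                deg.append(d)
            if l is None:
                dropped += 1
            else:
                lab.append(l)
        vals[name] = (deg, lab)
    (deg_a, lab_a), (deg_b, lab_b) = vals["a"], vals["b"]
    for arr in (deg_a, deg_b, lab_a, lab_b):
        if len(arr) < 2:
            raise ValueError("need >= 2 defined assortativity values per set")

    def welch(x, y) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = stats.ttest_ind(x, y, equal_var=False)
        return 1.0 if np.isnan(p) else float(p)

    return DomainComparison(
        p_label=welch(lab_a, lab_b), p_degree=welch(deg_a, deg_b),
        n_a_label=len(lab_a), n_b_label=len(lab_b),
        n_a_degree=len(deg_a), n_b_degree=len(deg_b), n_dropped=dropped)


@dataclass
class DisparityResult:
    p_value: float
    k: int
    n_reps: int
    mean_cross: float
    mean_within: float


def subsample_disparity(
    fp_set_a: Sequence[Fingerprint],
    fp_set_b: Sequence[Fingerprint],
    k: int = 50,
    n_reps: int = 1000,
    seed: int = 0,
) -> DisparityResult:
    """Fingerprint-volume control: disparity between size-matched subsamples.

    Repeatedly samples k fingerprints with replacement per domain; the
    disparity of a replicate is the isomorphic-pair count between the two
    samples.  The cross-domain disparity distribution is compared against
    the within-domain one (resampling pairs from the same domain, both
    domains pooled); the one-sided p-value is the probability that a
    within-domain disparity is at most a cross-domain one.  Small p means
    the two domains share far fewer patterns than a domain shares with
    itself.
    """
    if len(fp_set_a) < k or len(fp_set_b) < k:
        raise ValueError(f"both fingerprint sets must have >= k={k} members")
    rng = np.random.default_rng(seed)
    codes_a = np.array([fp.canonical_code for fp in fp_set_a])
    codes_b = np.array([fp.canonical_code for fp in fp_set_b])

    def pair_count(sa: np.ndarray, sb: np.ndarray) -> int:
        # count on the smaller-sample side (both have size k here)
        sb_set = set(sb.tolist())
        return int(sum(1 for c in sa.tolist() if c in sb_set))

    cross = np.empty(n_reps)
    within = np.empty(n_reps)
    for r in range(n_reps):
        cross[r] = pair_count(rng.choice(codes_a, k), rng.choice(codes_b, k))
        src = codes_a if r % 2 == 0 else codes_b
        within[r] = pair_count(rng.choice(src, k), rng.choice(src, k))
    # P(within <= cross) averaged over the cross distribution
    p = float(np.mean(within[None, :] <= cross[:, None]))
    p = max(p, 1.0 / n_reps)
    return DisparityResult(p_value=p, k=k, n_reps=n_reps,
                           mean_cross=float(cross.mean()),
                           mean_within=float(within.mean()))
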