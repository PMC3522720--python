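"""Interface residue detection, de-duplication and classification.

An interface is the set of residues of a host chain with at least one
heavy atom within the contact cutoff (default 5 A) of a heavy atom of a
partner chain in the *same* biological unit.  Because the same protein is
deposited many times, interfaces within one sequence cluster are mapped
onto common multiple-sequence-alignment columns, near-duplicates
(similarity >= 0.8 over the smaller interface) are collapsed to a single
representative chosen by best X-ray resolution, and representatives are
grouped into binding sites by single-linkage column similarity.

Also here: the interaction-type preference statistic, domain-range
assignment (cross-domain interface detection), and the per-cohort count
tables.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .chain_clustering import AlignConfig, ChainCluster, _make_aligner
from .structure_model import ComplexRecord, ResidueRef

INTERACTION_TYPES = ("homo-oligomer", "homo-complex", "hetero-oligomer", "hetero-complex")


@dataclass
class InterfaceInstance:
    host_chain: str          # global chain id, "<entry>:<chain>"
    partner_chain: str
    entry_id: str
    resolution: float
    bio_unit: int = 1
    positions: list[int] = field(default_factory=list)   # 0-based host sequence indices
    raw_residues: list[ResidueRef] = field(default_factory=list)
    residues: frozenset[tuple[int, str]] | None = None   # (msa column, aa), set by mapping
    site_id: int | None = None
    representative_host: str | None = None
    function_label: str | None = None

    @property
    def interface_id(self) -> str:
        return f"{self.host_chain}|{self.partner_chain}"


@dataclass
class MsaMap:
    cluster_id: int
    # per-chain mapping: 0-based sequence position -> 0-based MSA column
    columns: dict[str, dict[int, int]]
    n_columns: int = 0

    def map_interface(self, inst: InterfaceInstance) -> frozenset[tuple[int, str]]:
        col = self.columns[inst.host_chain]
        return frozenset((col[p], r.aa) for p, r in zip(inst.positions, inst.raw_residues))


@dataclass(frozen=True)
class DomainRange:
    domain_id: str
    scop_levels: tuple[str, str, str, str]  # class, fold, superfamily, family
    start: int  # author residue numbering, inclusive
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("domain range start > end")


def detect_interfaces(complex_: ComplexRecord, cutoff: float = 5.0) -> list[InterfaceInstance]:
    """Interface residues for every ordered chain pair within a bio-unit.

    Chain pairs across different biological units are never considered.
    Empty interfaces are dropped.
    """
    out: list[InterfaceInstance] = []
    for unit_no, unit_chains in sorted(complex_.bio_units().items()):
        trees = {}
        for ch in unit_chains:
            coords = ch.heavy_coords()
            trees[ch.chain_id] = cKDTree(coords) if len(coords) else None
        for host, partner in itertools.permutations(unit_chains, 2):
            tree = trees[partner.chain_id]
            if tree is None:
                continue
            positions, raws = [], []
            for pos, res in enumerate(host.residues):
                rc = res.heavy_coords()
                if not len(rc):
                    continue
                d, _ = tree.query(rc, k=1)
                if np.min(d) <= cutoff:
                    positions.append(pos)
                    raws.append(res)
            if positions:
                out.append(InterfaceInstance(
                    host_chain=f"{complex_.entry_id}:{host.chain_id}",
                    partner_chain=f"{complex_.entry_id}:{partner.chain_id}",
                    entry_id=complex_.entry_id,
                    resolution=complex_.resolution,
                    bio_unit=unit_no,
                    positions=positions,
                    raw_residues=raws,
                ))
    return out


def build_msa(sequences: Mapping[str, str], cluster_id: int = 0,
              cfg: AlignConfig | None = None) -> MsaMap:
    """Center-star multiple alignment of one cluster's chain sequences.

    The center is the chain minimizing the sum of pairwise distances
    (1 - aligned identity); ties go to the longest sequence, then the
    lexicographically smallest id.  Every other member is globally
    aligned to the center and merged into common columns; identical
    sequences receive identical column maps.
    """
    if not sequences:
        raise ValueError("empty cluster")
    cfg = cfg or AlignConfig()
    ids = sorted(sequences)
    if len(ids) == 1:
        cid = ids[0]
        n = len(sequences[cid])
        return MsaMap(cluster_id, {cid: {i: i for i in range(n)}}, n)

    aligner = _make_aligner(cfg, mode="global")

    def identity(a: str, b: str) -> float:
        aln = aligner.align(a, b)[0]
        ba, bb = aln.aligned
        ident = sum(1 for (a0, a1), (b0, b1) in zip(ba, bb)
                    for i, j in zip(range(a0, a1), range(b0, b1)) if a[i] == b[j])
        return ident / aln.length if aln.length else 0.0

    dist_sum = {i: 0.0 for i in ids}
    for a, b in itertools.combinations(ids, 2):
        d = 1.0 - identity(sequences[a], sequences[b])
        dist_sum[a] += d
        dist_sum[b] += d
    center = min(ids, key=lambda i: (dist_sum[i], -len(sequences[i]), i))
    cseq = sequences[center]
    lc = len(cseq)

    # per-member: matched member pos -> center pos, and insertion runs
    # (center pos 0..lc before which the listed member positions sit)
    matches: dict[str, dict[int, int]] = {}
    ins_runs: dict[str, dict[int, list[int]]] = {}
    for mid in ids:
        if mid == center:
            continue
        aln = aligner.align(cseq, sequences[mid])[0]
        blocks_c, blocks_m = aln.aligned
        mmatch: dict[int, int] = {}
        mins: dict[int, list[int]] = {}
        prev_m_end = 0
        for (c0, c1), (m0, m1) in zip(blocks_c, blocks_m):
            if m0 > prev_m_end:
                mins.setdefault(int(c0), []).extend(range(prev_m_end, m0))
            for i, j in zip(range(c0, c1), range(m0, m1)):
                mmatch[int(j)] = int(i)
            prev_m_end = int(m1)
        if prev_m_end < len(sequences[mid]):
            mins.setdefault(lc, []).extend(range(prev_m_end, len(sequences[mid])))
        matches[mid] = mmatch
        ins_runs[mid] = mins

    ins = [0] * (lc + 1)
    for mins in ins_runs.values():
        for cpos, run in mins.items():
            ins[cpos] = max(ins[cpos], len(run))
    offset = list(itertools.accumulate(ins))
    col_of_center = [i + offset[i] for i in range(lc)]
    n_columns = lc + offset[lc]

    columns: dict[str, dict[int, int]] = {center: {i: col_of_center[i] for i in range(lc)}}
    for mid in ids:
        if mid == center:
            continue
        cmap: dict[int, int] = {}
        for j, i in matches[mid].items():
            cmap[j] = col_of_center[i]
        # right-align each insertion run into the slots reserved before its center pos
        for cpos, run in ins_runs[mid].items():
            slot_end = col_of_center[cpos] if cpos < lc else n_columns
            start_col = slot_end - len(run)
            for k, j in enumerate(sorted(run)):
                cmap[j] = start_col + k
        columns[mid] = cmap
    return MsaMap(cluster_id, columns, n_columns)


def interface_similarity(i1: InterfaceInstance, i2: InterfaceInstance, msa: MsaMap) -> float:
    """Identical aligned residues over the smaller interface's size.

    Residues are identical when they share both the amino-acid type and
    the MSA column.
    """
    s1 = i1.residues if i1.residues is not None else msa.map_interface(i1)
    s2 = i2.residues if i2.residues is not None else msa.map_interface(i2)
    if not s1 or not s2:
        raise ValueError("empty interface")
    return len(s1 & s2) / min(len(s1), len(s2))


def jaccard_overlap(i1: InterfaceInstance, i2: InterfaceInstance, msa: MsaMap) -> float:
    """Jaccard index of the two mapped (column, aa) residue sets."""
    s1 = i1.residues if i1.residues is not None else msa.map_interface(i1)
    s2 = i2.residues if i2.residues is not None else msa.map_interface(i2)
    union = s1 | s2
    return len(s1 & s2) / len(union) if union else 0.0


def map_interfaces(instances: Sequence[InterfaceInstance], msa: MsaMap) -> None:
    for inst in instances:
        inst.residues = msa.map_interface(inst)


def dedup_interfaces(
    instances: Sequence[InterfaceInstance],
    msa: MsaMap,
    threshold: float = 0.8,
    chain_resolutions: Mapping[str, float] | None = None,
) -> list[InterfaceInstance]:
    """Collapse similar interfaces of one cluster to representatives.

    Interfaces with similarity >= threshold are connected; one
    representative per connected component is chosen by best (lowest)
    resolution, ties broken by input order.  Each representative is
    remapped onto the cluster's best-resolution chain.
    """
    if not instances:
        return []
    map_interfaces(instances, msa)
    g = nx.Graph()
    g.add_nodes_from(range(len(instances)))
    for i, j in itertools.combinations(range(len(instances)), 2):
        if interface_similarity(instances[i], instances[j], msa) >= threshold:
            g.add_edge(i, j)
    if chain_resolutions is None:
        chain_resolutions = {inst.host_chain: inst.resolution for inst in instances}
    best_chain = min(sorted(chain_resolutions), key=lambda c: chain_resolutions[c])
    rep_indices: list[int] = []
    for comp in nx.connected_components(g):
        rep_idx = min(comp, key=lambda i: (instances[i].resolution, i))
        instances[rep_idx].representative_host = best_chain
        rep_indices.append(rep_idx)
    return [instances[i] for i in sorted(rep_indices)]


def cluster_binding_sites(
    representatives: Sequence[InterfaceInstance],
    msa: MsaMap,
    site_threshold: float = 0.5,
) -> dict[int, list[InterfaceInstance]]:
    """Single-linkage grouping of representatives into binding sites.

    Representatives whose column similarity reaches ``site_threshold``
    belong to the same site; each connected component gets a site_id
    (assigned in input order of the first member).
    """
    g = nx.Graph()
    g.add_nodes_from(range(len(representatives)))
    for i, j in itertools.combinations(range(len(representatives)), 2):
        if interface_similarity(representatives[i], representatives[j], msa) >= site_threshold:
            g.add_edge(i, j)
    comps = sorted(nx.connected_components(g), key=min)
    sites: dict[int, list[InterfaceInstance]] = {}
    for sid, comp in enumerate(comps):
        members = [representatives[i] for i in sorted(comp)]
        for m in members:
            m.site_id = sid
        sites[sid] = members
    return sites


def classify_interaction(
    inst: InterfaceInstance,
    chain_to_cluster: Mapping[str, int],
    permanence: Mapping[str, str] | None = None,
) -> str:
    """Interaction type: homo/hetero x oligomer/complex.

    Homo iff host and partner chains fall in the same sequence cluster;
    oligomer (obligate) vs complex (transient) comes from a supplied
    per-interaction permanence flag, keyed by the interface id.  A missing
    flag yields "unknown" (excluded from preference counts).
    """
    same = chain_to_cluster.get(inst.host_chain) == chain_to_cluster.get(inst.partner_chain)
    flag = (permanence or {}).get(inst.interface_id)
    if flag not in ("permanent", "transient"):
        return "unknown"
    side = "oligomer" if flag == "permanent" else "complex"
    return f"{'homo' if same else 'hetero'}-{side}"


def compute_preference(counts: Mapping[str, tuple[int, int]]) -> dict[str, float]:
    """Interaction-type preference for multi-interface proteins.

    ``counts`` maps type -> (n_all, n_multi).  preference_t =
    (n_multi_t / n_all_t) / (sum n_multi / sum n_all): above 1 means the
    type is over-represented among multi-interface interactions.
    """
    tot_all = sum(a for a, _ in counts.values())
    tot_multi = sum(m for _, m in counts.values())
    if any(a <= 0 for a, _ in counts.values()) or tot_multi <= 0:
        raise ValueError("all totals must be positive and at least one multi count nonzero")
    overall = tot_multi / tot_all
    return {t: (m / a) / overall for t, (a, m) in counts.items()}


def assign_domains(inst: InterfaceInstance, domains: Sequence[DomainRange]) -> set[str]:
    """Domain ids overlapped by the interface's residues (author numbering).

    More than one id means a cross-domain interface; residues outside
    every range contribute the tag "unassigned".
    """
    out: set[str] = set()
    for res in inst.raw_residues:
        hit = False
        for dom in domains:
            if dom.start <= res.seq_num <= dom.end:
                out.add(dom.domain_id)
                hit = True
        if not hit:
            out.add("unassigned")
    return out


def interface_count_histogram(site_counts: Iterable[int]) -> dict[int, int]:
    """Multi-interface protein distribution: #binding sites -> #proteins.

    Proteins with a single site are excluded (they are not
    multi-interface).
    """
    return dict(sorted(Counter(c for c in site_counts if c >= 2).items()))


def scop_level_counts(
    protein_levels: Mapping[str, tuple[str, str, str, str]],
    multi_interface: set[str],
) -> dict[str, tuple[int, int]]:
    """Per SCOP level: (total sublevels seen, sublevels with a multi-interface protein)."""
    names = ("class", "fold", "superfamily", "family")
    out: dict[str, tuple[int, int]] = {}
    for li, name in enumerate(names):
        seen = {lv[li] for lv in protein_levels.values()}
        multi = {lv[li] for p, lv in protein_levels.items() if p in multi_interface}
        out[name] = (len(seen), len(multi))
    return out


def cross_domain_class_pairs(
    assignments: Mapping[str, set[str]],
    domain_class: Mapping[str, str],
) -> Counter:
    """Counts of SCOP class pairs spanned by cross-domain interfaces."""
    pairs: Counter = Counter()
    for _iface, doms in assignments.items():
        classes = sorted({domain_class[d] for d in doms if d in domain_class})
        if len(classes) >= 2:
            for a, b in itertools.combinations(classes, 2):
                pairs[(a, b)] += 1
    return pairs
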