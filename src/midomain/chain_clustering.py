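"""Grouping of near-identical chains by local-alignment similarity.

Redundant depositions of the same protein are collapsed by all-vs-all
Smith-Waterman local alignment (BLOSUM62, gap open 11 / extend 1) and
single-linkage clustering: chains whose aligned-region identity is at
least the threshold (default 0.975, i.e. mutation rate <= 2.5%) are
connected, and each connected component forms a cluster.  Identity is
computed over the aligned region only, not the whole sequence, so a
domain embedded in a longer multi-domain chain still joins its cluster.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices


@dataclass
class AlignConfig:
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    score_floor: float = 40.0  # raw-score floor below which a pair is skipped


@dataclass
class PairAlignment:
    chain_a: str
    chain_b: str
    n_identical: int
    align_len: int
    score: float
    # aligned residue positions a -> b (0-based, matched columns only)
    column_map: dict[int, int] = field(default_factory=dict)

    @property
    def similarity(self) -> float:
        return self.n_identical / self.align_len if self.align_len else 0.0


@dataclass
class ChainCluster:
    cluster_id: int
    members: list[str]
    edges: set[tuple[str, str]] = field(default_factory=set)


def _make_aligner(cfg: AlignConfig, mode: str = "local") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load(cfg.matrix)
    aligner.open_gap_score = -cfg.gap_open
    aligner.extend_gap_score = -cfg.gap_extend
    return aligner


def align_pair(seq_a: str, seq_b: str, cfg: AlignConfig | None = None,
               ids: tuple[str, str] = ("a", "b")) -> PairAlignment:
    """Best Smith-Waterman local alignment of two sequences.

    Similarity is identical aligned residues over alignment length
    (gapped columns of the local region included).
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    cfg = cfg or AlignConfig()
    aligner = _make_aligner(cfg)
    aln = aligner.align(seq_a, seq_b)[0]
    n_identical = 0
    column_map: dict[int, int] = {}
    blocks_a, blocks_b = aln.aligned
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            column_map[i] = j
            if seq_a[i] == seq_b[j]:
                n_identical += 1
    return PairAlignment(chain_a=ids[0], chain_b=ids[1], n_identical=n_identical,
                         align_len=int(aln.length), score=float(aln.score),
                         column_map=column_map)


def build_clusters(
    sequences: dict[str, str],
    min_similarity: float = 0.975,
    cfg: AlignConfig | None = None,
) -> tuple[list[ChainCluster], dict[tuple[str, str], float]]:
    """Single-linkage clusters of chains by pairwise aligned identity.

    Returns the clusters (deterministically ordered by smallest member id)
    and the full pairwise similarity table used to build them.
    """
    cfg = cfg or AlignConfig()
    ids = sorted(sequences)
    sims: dict[tuple[str, str], float] = {}
    g = nx.Graph()
    g.add_nodes_from(ids)
    for a, b in itertools.combinations(ids, 2):
        pa = align_pair(sequences[a], sequences[b], cfg, ids=(a, b))
        if pa.score < cfg.score_floor:
            sims[(a, b)] = 0.0
            continue
        sims[(a, b)] = pa.similarity
        if pa.similarity >= min_similarity:
            g.add_edge(a, b)
    comps = sorted((sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0])
    clusters = []
    for cid, members in enumerate(comps):
        edges = {(a, b) for a, b in itertools.combinations(members, 2)
                 if sims.get((min(a, b), max(a, b)), 0.0) >= min_similarity}
        clusters.append(ChainCluster(cluster_id=cid, members=members, edges=edges))
    return clusters, sims


def cluster_diagnostics(clusters: list[ChainCluster],
                        sims: dict[tuple[str, str], float]) -> list[tuple[int, int, float]]:
    """Per-cluster (id, size, minimum pairwise similarity); singletons report 1.0.

    Re-implements the chaining check used at full scale (most clusters
    should keep a minimum pairwise similarity around 0.9 or better).
    """
    rows = []
    for cl in clusters:
        pairs = list(itertools.combinations(cl.members, 2))
        min_sim = min((sims.get((min(a, b), max(a, b)), 0.0) for a, b in pairs), default=1.0)
        rows.append((cl.cluster_id, len(cl.members), min_sim))
    return rows


def write_clusters(clusters: list[ChainCluster], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tchain_id\n")
        for cl in clusters:
            for m in cl.members:
                fh.write(f"{cl.cluster_id}\t{m}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")
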