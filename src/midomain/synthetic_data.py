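"""Synthetic inputs for every pipeline stage.

Three generators, all pure functions of (spec, seed):

* :func:`generate_complex` — a cartoon multi-chain complex with planted
  interfaces.  Chains are laid out as residue paths (one C-alpha plus one
  pseudo side-chain atom per residue) in well-separated "home lanes";
  residue ranges listed in the interface plan detour to shared contact
  sites where host and partner residues sit within 4.5 A of each other,
  while all unplanned inter-chain residue pairs stay farther than 6 A.
  Geometry is deliberately cartoon-like: only distance relationships are
  consumed downstream, not stereochemistry.

* :func:`generate_cluster_cohort` — near-identical copies of a base
  complex (point substitutions at a controlled mutation rate, jittered
  resolutions), emulating redundant structure depositions of one protein.

* :func:`generate_graph_db` — labeled random connected graphs with motifs
  planted at controlled support, for exercising the subgraph miner.

Each generator returns a ground-truth record sufficient to score
downstream recovery tests without re-deriving geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from ._aa import STANDARD_AA
from .structure_model import AtomRecord, ChainRecord, ComplexRecord, ResidueRef

CONTACT_SEP = 3.9      # planted host-partner CA separation (A)
SITE_SPACING = 80.0    # distance between planted contact sites (A)
LANE_SPACING = 20.0    # distance between chain home lanes (A)
STEP = 3.8             # residue step along a path (A)
JITTER = 0.15          # per-coordinate uniform jitter (A)


@dataclass(frozen=True)
class InterfacePlan:
    host: str
    partner: str
    host_range: tuple[int, int]      # inclusive 0-based residue indices
    partner_range: tuple[int, int]   # same length as host_range


@dataclass
class ComplexSpec:
    chain_ids: tuple[str, ...] = ("A", "B")
    chain_length: int = 40
    interface_plan: tuple[InterfacePlan, ...] = (
        InterfacePlan("A", "B", (10, 19), (10, 19)),
    )
    resolution: float = 2.0
    entry_id: str = "SYN1"
    seed: int = 0


@dataclass
class GraphDBSpec:
    n_graphs: int = 10
    nodes_per_graph: tuple[int, int] = (8, 12)
    # each planted motif: (networkx Graph with 'aa' node labels, frequency ratio)
    planted_motifs: tuple[tuple[nx.Graph, float], ...] = ()
    label_freqs: dict[str, float] | None = None
    extra_edge_factor: float = 0.3  # extra edges beyond the spanning tree, per node
    seed: int = 0


def _validate_spec(spec: ComplexSpec) -> None:
    ids = set(spec.chain_ids)
    used: dict[str, list[tuple[int, int]]] = {c: [] for c in spec.chain_ids}
    for plan in spec.interface_plan:
        if plan.host not in ids or plan.partner not in ids or plan.host == plan.partner:
            raise ValueError(f"bad plan chains {plan.host}-{plan.partner}")
        for cid, (lo, hi) in ((plan.host, plan.host_range), (plan.partner, plan.partner_range)):
            if not (0 <= lo <= hi < spec.chain_length):
                raise ValueError(f"range {lo}-{hi} outside chain of length {spec.chain_length}")
            for plo, phi in used[cid]:
                if lo <= phi and plo <= hi:
                    raise ValueError(f"overlapping planted ranges on chain {cid}")
            used[cid].append((lo, hi))
        hl = plan.host_range[1] - plan.host_range[0]
        pl = plan.partner_range[1] - plan.partner_range[0]
        if hl != pl:
            raise ValueError("host and partner ranges must have equal length")


def _chain_paths(spec: ComplexSpec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Per-chain CA coordinates honouring the interface plan."""
    site_of: dict[tuple[str, int], tuple[int, int, bool]] = {}
    # residue -> (site index, offset within range, is_host)
    for s, plan in enumerate(spec.interface_plan):
        lo, hi = plan.host_range
        for j in range(lo, hi + 1):
            site_of[(plan.host, j)] = (s, j - lo, True)
        lo, hi = plan.partner_range
        for j in range(lo, hi + 1):
            site_of[(plan.partner, j)] = (s, j - lo, False)

    paths: dict[str, np.ndarray] = {}
    for k, cid in enumerate(spec.chain_ids):
        coords = np.empty((spec.chain_length, 3))
        lane_y = 60.0 + LANE_SPACING * k
        for j in range(spec.chain_length):
            hit = site_of.get((cid, j))
            if hit is None:
                coords[j] = (STEP * j, lane_y, 0.0)
            else:
                s, off, is_host = hit
                y = 0.0 if is_host else CONTACT_SEP
                coords[j] = (SITE_SPACING * s + STEP * off, y, 0.0)
        coords += rng.uniform(-JITTER, JITTER, coords.shape)
        paths[cid] = coords
    return paths


def _verify_geometry(spec: ComplexSpec, paths: dict[str, np.ndarray]) -> bool:
    planted: dict[tuple[str, str], set[int]] = {}
    for plan in spec.interface_plan:
        planted.setdefault((plan.host, plan.partner), set()).update(
            range(plan.host_range[0], plan.host_range[1] + 1))
        planted.setdefault((plan.partner, plan.host), set()).update(
            range(plan.partner_range[0], plan.partner_range[1] + 1))
    ids = list(spec.chain_ids)
    for a in ids:
        for b in ids:
            if a >= b:
                continue
            d = np.linalg.norm(paths[a][:, None, :] - paths[b][None, :, :], axis=2)
            want_a = planted.get((a, b), set())
            want_b = planted.get((b, a), set())
            for i in range(spec.chain_length):
                row_min = d[i].min()
                if i in want_a:
                    if row_min > 4.4:  # CA-CA; side-chain atoms are parallel offsets
                        return False
                elif row_min <= 6.0 + 3.5:  # margin covers side-chain offsets
                    return False
            for i in range(spec.chain_length):
                if i in want_b:
                    if d[:, i].min() > 4.4:
                        return False
                elif d[:, i].min() <= 6.0 + 3.5:
                    return False
    return True


def _build_residue(cid: str, j: int, aa: str, ca: np.ndarray,
                   rng: np.random.Generator, serial_start: int) -> ResidueRef:
    cb = ca + np.array([0.0, 0.0, 1.5]) + rng.uniform(-JITTER, JITTER, 3)
    atoms = [
        AtomRecord(serial=serial_start, name="CA", element="C", coords=ca),
        AtomRecord(serial=serial_start + 1, name="CB", element="C", coords=cb),
    ]
    return ResidueRef(chain_id=cid, seq_num=j + 1, icode="", aa=aa, atoms=atoms)


def generate_complex(spec: ComplexSpec) -> tuple[ComplexRecord, dict]:
    """Build a ComplexRecord with planted interfaces, plus ground truth.

    Ground truth maps each ordered planted pair ``"host-partner"`` to the
    sorted list of planted host residue indices (0-based).
    """
    _validate_spec(spec)
    rng = np.random.default_rng(spec.seed)
    sequences = {cid: "".join(rng.choice(list(STANDARD_AA), spec.chain_length))
                 for cid in spec.chain_ids}

    paths = None
    for _ in range(5):  # bounded retries with fresh jitter
        candidate = _chain_paths(spec, rng)
        if _verify_geometry(spec, candidate):
            paths = candidate
            break
    if paths is None:
        raise RuntimeError("could not realise planted interface geometry")

    chains = []
    serial = 1
    for cid in spec.chain_ids:
        residues = []
        for j in range(spec.chain_length):
            residues.append(_build_residue(cid, j, sequences[cid][j], paths[cid][j], rng, serial))
            serial += 2
        chains.append(ChainRecord(chain_id=cid, residues=residues, bio_unit=1,
                                  transform_is_identity=True))
    record = ComplexRecord(entry_id=spec.entry_id, resolution=spec.resolution,
                           method="X-RAY DIFFRACTION", chains=chains)
    truth = {
        "sequences": sequences,
        "planted": {},
    }
    for plan in spec.interface_plan:
        truth["planted"][f"{plan.host}-{plan.partner}"] = list(
            range(plan.host_range[0], plan.host_range[1] + 1))
        truth["planted"][f"{plan.partner}-{plan.host}"] = list(
            range(plan.partner_range[0], plan.partner_range[1] + 1))
    return record, truth


def generate_cluster_cohort(
    base_spec: ComplexSpec,
    n_copies: int = 5,
    mutation_rate: float = 0.02,
    seed: int = 0,
) -> tuple[list[ComplexRecord], dict]:
    """Near-identical copies of a base complex (one sequence cluster).

    The first copy is the unmutated base; every further copy carries
    exactly ``round(mutation_rate * chain_length)`` point substitutions
    per chain at random positions (the mutation rate is controlled
    exactly, not in expectation), plus a jittered resolution.  Ground
    truth records the intended cluster partition per chain letter and
    the intended best-resolution entry.
    """
    if n_copies < 2:
        raise ValueError("need at least 2 copies")
    rng = np.random.default_rng(seed)
    base, base_truth = generate_complex(base_spec)
    records: list[ComplexRecord] = []
    resolutions = np.round(base_spec.resolution + rng.permutation(n_copies) * 0.25, 2)
    n_mut = int(round(mutation_rate * base_spec.chain_length))
    for i in range(n_copies):
        entry = f"{base_spec.entry_id}{i:02d}"
        chains = []
        for ch in base.chains:
            mut_pos: set[int] = set()
            if i > 0 and n_mut:
                mut_pos = set(rng.choice(len(ch.residues), size=n_mut,
                                         replace=False).tolist())
            residues = []
            for pos, res in enumerate(ch.residues):
                aa = res.aa
                if pos in mut_pos:
                    aa = str(rng.choice([x for x in STANDARD_AA if x != aa]))
                residues.append(ResidueRef(chain_id=res.chain_id, seq_num=res.seq_num,
                                           icode=res.icode, aa=aa, atoms=res.atoms))
            chains.append(ChainRecord(chain_id=ch.chain_id, residues=residues,
                                      bio_unit=ch.bio_unit, transform_is_identity=True))
        records.append(ComplexRecord(entry_id=entry, resolution=float(resolutions[i]),
                                     method="X-RAY DIFFRACTION", chains=chains))
    best = min(records, key=lambda r: r.resolution).entry_id
    truth = {
        "base": base_truth,
        "entries": [r.entry_id for r in records],
        "clusters": {cid: [f"{r.entry_id}:{cid}" for r in records]
                     for cid in base_spec.chain_ids},
        "best_entry": best,
        "resolutions": {r.entry_id: r.resolution for r in records},
    }
    return records, truth


def write_cohort(records: list[ComplexRecord], out_dir: str | Path) -> list[Path]:
    from .structure_model import write_pdb

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in records:
        p = out / f"{rec.entry_id}.pdb"
        write_pdb(rec, p)
        paths.append(p)
    return paths


def _random_connected_graph(n: int, m: int, labels: list[str],
                            rng: np.random.Generator) -> nx.Graph:
    if m < n - 1 or m > n * (n - 1) // 2:
        raise ValueError(f"impossible (n={n}, m={m}) for a connected graph")
    g = nx.Graph()
    order = rng.permutation(n)
    g.add_node(int(order[0]))
    for i in range(1, n):
        g.add_edge(int(order[i]), int(order[rng.integers(0, i)]))
    non_edges = [(u, v) for u in range(n) for v in range(u + 1, n) if not g.has_edge(u, v)]
    extra = m - (n - 1)
    if extra:
        for idx in rng.choice(len(non_edges), size=extra, replace=False):
            g.add_edge(*non_edges[idx])
    for v in range(n):
        g.nodes[v]["aa"] = labels[v]
    return g


def random_labeled_graph(n: int, m: int, label_freqs: dict[str, float],
                         rng: np.random.Generator) -> nx.Graph:
    """Random connected graph with i.i.d. node labels (shared null model)."""
    letters = sorted(label_freqs)
    probs = np.array([label_freqs[l] for l in letters], dtype=float)
    probs = probs / probs.sum()
    labels = [str(x) for x in rng.choice(letters, size=n, p=probs)]
    return _random_connected_graph(n, m, labels, rng)


def generate_graph_db(spec: GraphDBSpec) -> tuple[list[nx.Graph], dict]:
    """Labeled graph database with planted motifs; returns (graphs, truth).

    Each motif is embedded (labels overwritten, edges added) in
    ``round(frequency * n_graphs)`` randomly chosen graphs.  Ground truth
    lists, per motif, the graph indices and node images of each embedding.
    """
    rng = np.random.default_rng(spec.seed)
    freqs = spec.label_freqs or {aa: 1.0 / 20.0 for aa in STANDARD_AA}
    lo, hi = spec.nodes_per_graph
    graphs: list[nx.Graph] = []
    for gi in range(spec.n_graphs):
        n = int(rng.integers(lo, hi + 1))
        m = min(n * (n - 1) // 2, (n - 1) + int(round(spec.extra_edge_factor * n)))
        g = random_labeled_graph(n, m, freqs, rng)
        g.graph["graph_id"] = f"g{gi}"
        graphs.append(g)
    truth: dict = {"motifs": []}
    for motif, freq in spec.planted_motifs:
        n_embed = int(round(freq * spec.n_graphs))
        targets = sorted(rng.choice(spec.n_graphs, size=n_embed, replace=False).tolist())
        embeddings = []
        for gi in targets:
            g = graphs[gi]
            nodes = sorted(rng.choice(g.number_of_nodes(), size=motif.number_of_nodes(),
                                      replace=False).tolist())
            image = dict(zip(sorted(motif.nodes()), nodes))
            for mv, gv in image.items():
                g.nodes[gv]["aa"] = motif.nodes[mv]["aa"]
            for mu, mv in motif.edges():
                g.add_edge(image[mu], image[mv])
            embeddings.append({"graph": f"g{gi}", "image": image})
        truth["motifs"].append({"n_planted": n_embed, "embeddings": embeddings})
    return graphs, truth
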