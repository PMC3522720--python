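"""Residue contact graphs from Delaunay tessellation of heavy atoms.

Edges of an interface graph must satisfy two criteria at once: the atom
pair is an edge of the 3D Delaunay tessellation of the heavy atoms fed to
the tessellation, and the pair is within the distance cutoff (default
5 A).  Atom contacts inside one residue are ignored, and multiple atom
contacts between two residues merge into a single residue edge.  Nodes
are the interface residues, labeled by amino-acid type (with the
Kyte-Doolittle hydropathy attached as an extra attribute).

Degenerate atom sets (fewer than four atoms, or coplanar/collinear
configurations where a 3D tessellation is undefined) fall back to the
complete atom graph, so that after the cutoff intersection the result is
the plain distance-cutoff graph.
"""

from __future__ import annotations

import itertools
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import Delaunay, QhullError

from ._aa import KYTE_DOOLITTLE
from .interface_extraction import InterfaceInstance
from .structure_model import ChainRecord, ComplexRecord


def delaunay_atom_edges(coords: np.ndarray, jitter: float = 1e-9) -> set[tuple[int, int]]:
    """Edges of the 3D Delaunay tessellation of the given points.

    Fewer than 2 points give the empty set; degenerate configurations
    (including 2-3 points) fall back to the complete graph.  A tiny
    deterministic jitter breaks exact cospherical ties.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 2:
        return set()
    # collinear/coplanar sets have no 3D tessellation: rank test on centered coords
    singular = np.linalg.svd(coords - coords.mean(axis=0), compute_uv=False)
    degenerate = len(singular) < 3 or singular[-1] < 1e-6
    if n >= 4 and not degenerate:
        pts = coords
        if jitter:
            rng = np.random.default_rng(0)
            pts = coords + rng.uniform(-jitter, jitter, coords.shape)
        try:
            tri = Delaunay(pts)
        except QhullError:
            tri = None
        if tri is not None and tri.simplices.size:
            edges: set[tuple[int, int]] = set()
            for simplex in tri.simplices:
                for a, b in itertools.combinations(simplex.tolist(), 2):
                    edges.add((a, b) if a < b else (b, a))
            return edges
    # degenerate fallback: complete graph (cutoff applied downstream)
    return {(a, b) for a, b in itertools.combinations(range(n), 2)}


def surface_positions(chain: ChainRecord, mode: str = "all",
                      rsa_threshold: float = 0.05) -> list[int]:
    """Sequence positions of surface residues of a chain.

    ``mode="all"`` treats every residue as surface (the default; the
    choice of surface criterion is a free parameter of the method).
    ``mode="rsa"`` keeps residues whose relative solvent accessibility,
    from a Shrake-Rupley rolling probe over the chain's heavy atoms, is
    at least ``rsa_threshold``.
    """
    if mode == "all":
        return list(range(len(chain.residues)))
    if mode != "rsa":
        raise ValueError(f"unknown surface mode {mode!r}")
    return _rsa_surface(chain, rsa_threshold)


# Tien et al. theoretical max ASA (A^2) per residue, for RSA normalisation
_MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}


def _rsa_surface(chain: ChainRecord, threshold: float, probe: float = 1.4,
                 n_points: int = 100) -> list[int]:
    """Shrake-Rupley accessible surface per residue over heavy atoms."""
    atoms = []
    owner = []
    for pos, res in enumerate(chain.residues):
        for a in res.heavy_atoms():
            atoms.append(a)
            owner.append(pos)
    if not atoms:
        return []
    coords = np.vstack([a.coords for a in atoms])
    radii = np.array([1.9 if a.element == "C" else 1.6 for a in atoms]) + probe
    # Fibonacci sphere points
    k = np.arange(n_points)
    phi = np.arccos(1 - 2 * (k + 0.5) / n_points)
    theta = np.pi * (1 + 5 ** 0.5) * k
    sphere = np.stack([np.cos(theta) * np.sin(phi),
                       np.sin(theta) * np.sin(phi), np.cos(phi)], axis=1)
    asa_per_res = np.zeros(len(chain.residues))
    from scipy.spatial import cKDTree

    tree = cKDTree(coords)
    for i in range(len(atoms)):
        pts = coords[i] + radii[i] * sphere
        neighbours = [j for j in tree.query_ball_point(coords[i], radii[i] + radii.max())
                      if j != i]
        if neighbours:
            d = np.linalg.norm(pts[:, None, :] - coords[neighbours][None, :, :], axis=2)
            accessible = np.all(d >= radii[neighbours][None, :], axis=1)
        else:
            accessible = np.ones(n_points, dtype=bool)
        asa_per_res[owner[i]] += accessible.mean() * 4 * np.pi * radii[i] ** 2
    out = []
    for pos, res in enumerate(chain.residues):
        max_asa = _MAX_ASA.get(res.aa, 200.0)
        if asa_per_res[pos] / max_asa >= threshold:
            out.append(pos)
    return out


def build_interface_graph(
    inst: InterfaceInstance,
    complex_: ComplexRecord,
    cutoff: float = 5.0,
    surface_mode: str = "all",
) -> nx.Graph:
    """Residue contact graph of one interface.

    Heavy atoms of the host chain's surface residues feed the
    tessellation; edges are Delaunay atom contacts of length <= cutoff,
    merged per residue pair, restricted to the interface residues.
    Non-standard residues (aa == 'X') are excluded from the node set.
    """
    entry, _, chain_id = inst.host_chain.partition(":")
    chain = complex_.get_chain(chain_id, inst.bio_unit)
    positions = surface_positions(chain, surface_mode)
    atoms = []
    owner = []
    for pos in positions:
        for a in chain.residues[pos].heavy_atoms():
            atoms.append(a)
            owner.append(pos)
    if not atoms:
        raise ValueError(f"no resolvable residues for interface {inst.interface_id}")
    coords = np.vstack([a.coords for a in atoms])
    edges = delaunay_atom_edges(coords)

    iface = {p for p in inst.positions if chain.residues[p].aa != "X"}
    g = nx.Graph(graph_id=inst.interface_id, site_id=inst.site_id,
                 protein_id=inst.host_chain)
    for p in sorted(iface):
        res = chain.residues[p]
        g.add_node(p, aa=res.aa,
                   msa_column=-1,
                   kd=KYTE_DOOLITTLE.get(res.aa, 0.0))
    for a, b in edges:
        ra, rb = owner[a], owner[b]
        if ra == rb:
            continue  # intra-residue atom contact
        if ra not in iface or rb not in iface:
            continue
        if np.linalg.norm(coords[a] - coords[b]) <= cutoff:
            g.add_edge(ra, rb)
    return g


def annotate_msa_columns(g: nx.Graph, inst: InterfaceInstance, msa) -> None:
    col = msa.columns[inst.host_chain]
    for p in g.nodes:
        g.nodes[p]["msa_column"] = col.get(p, -1)


def distance_cutoff_graph(inst: InterfaceInstance, complex_: ComplexRecord,
                          cutoff: float = 5.0) -> nx.Graph:
    """Pure distance-cutoff residue graph (no Delaunay filter); reference only."""
    entry, _, chain_id = inst.host_chain.partition(":")
    chain = complex_.get_chain(chain_id, inst.bio_unit)
    iface = sorted(p for p in inst.positions if chain.residues[p].aa != "X")
    g = nx.Graph()
    for p in iface:
        g.add_node(p, aa=chain.residues[p].aa)
    for a, b in itertools.combinations(iface, 2):
        da = chain.residues[a].heavy_coords()
        db = chain.residues[b].heavy_coords()
        d = np.linalg.norm(da[:, None, :] - db[None, :, :], axis=2)
        if d.min() <= cutoff:
            g.add_edge(a, b)
    return g


def write_edgelist(g: nx.Graph, path: str | Path) -> None:
    """One-graph-per-file text format consumed by the miner."""
    with open(path, "w") as fh:
        fh.write(f"#graph {g.graph.get('graph_id', '?')} "
                 f"{g.graph.get('site_id', '?')} {g.graph.get('protein_id', '?')}\n")
        for n in sorted(g.nodes):
            fh.write(f"node {n} {g.nodes[n]['aa']}\n")
        for a, b in sorted(tuple(sorted(e)) for e in g.edges):
            fh.write(f"edge {a} {b}\n")


def read_edgelist(path: str | Path) -> nx.Graph:
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "#graph":
                g.graph["graph_id"] = parts[1]
                if len(parts) > 2:
                    g.graph["site_id"] = None if parts[2] in ("?", "None") else int(parts[2])
                if len(parts) > 3:
                    g.graph["protein_id"] = parts[3]
            elif parts[0] == "node":
                g.add_node(int(parts[1]), aa=parts[2],
                           kd=KYTE_DOOLITTLE.get(parts[2], 0.0))
            elif parts[0] == "edge":
                g.add_edge(int(parts[1]), int(parts[2]))
    return g


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(g, str(path))
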