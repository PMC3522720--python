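"""End-to-end orchestration: structures in, fingerprints and stats out.

Stages: preprocess -> cluster -> interfaces -> graphs -> mine ->
relations.  Every stage writes its outputs under the run directory and
the run finishes with a JSON manifest (config, input hashes, seeds,
stage products).  The whole run is deterministic under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import yaml

from . import __version__
from .chain_clustering import (AlignConfig, build_clusters, cluster_diagnostics,
                               write_clusters, write_fasta)
from .contact_graphs import annotate_msa_columns, build_interface_graph, write_edgelist
from .interface_extraction import (InterfaceInstance, build_msa,
                                   cluster_binding_sites, dedup_interfaces,
                                   detect_interfaces, interface_count_histogram,
                                   jaccard_overlap, map_interfaces)
from .pattern_mining import (GraphDB, db_label_frequencies, mine_closed_frequent,
                             count_isomorphic_pairs, random_null_pvalue,
                             support_threshold, write_fingerprint_index)
from .relations_stats import (build_transactions, cooperative_pairs,
                              distinctive_fingerprints, mine_closed_itemsets)
from .structure_model import (FilterConfig, filter_complexes, parse_structure,
                              write_manifest)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    structures_dir: str = "structures"
    out_dir: str = "run"
    contact_cutoff: float = 5.0       # A
    dedup_threshold: float = 0.8
    cluster_similarity: float = 0.975
    site_threshold: float = 0.5
    local_support: float = 0.20
    min_chain_len: int = 30
    max_resolution: float = 3.0       # A
    min_co_fraction: float = 0.20
    null_reps: int = 500
    seed: int = 0
    max_pattern_edges: int | None = 12

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate(self) -> None:
        for name in ("dedup_threshold", "cluster_similarity", "site_threshold",
                     "local_support", "min_co_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("contact_cutoff", "max_resolution"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the run manifest (also written as JSON)."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": asdict(cfg),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }

    # -- preprocess ---------------------------------------------------------
    stage = "preprocess"
    try:
        struct_dir = Path(cfg.structures_dir)
        if not struct_dir.is_dir():
            raise FileNotFoundError(f"structures directory {struct_dir} not found")
        files = sorted(list(struct_dir.glob("*.pdb")) + list(struct_dir.glob("*.cif")))
        if not files:
            raise FileNotFoundError(f"no structure files in {struct_dir}")
        manifest["inputs"] = {f.name: _sha256(f) for f in files}
        complexes = [parse_structure(f) for f in files]
        kept, report = filter_complexes(complexes, FilterConfig(
            min_chain_len=cfg.min_chain_len, max_resolution=cfg.max_resolution,
            contact_cutoff=cfg.contact_cutoff))
        write_manifest(report, out / "chain_manifest.tsv")
        sequences = {f"{cx.entry_id}:{ch.chain_id}": ch.sequence
                     for cx in kept for ch in cx.chains}
        write_fasta(sequences, out / "chains.fasta")
        manifest["stages"][stage] = {
            "n_entries_in": len(complexes), "n_entries_kept": len(kept),
            "n_chains_kept": len(sequences),
            "dropped_entries": report.dropped_entries,
            "dropped_chains": report.dropped_chains,
        }
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- cluster ------------------------------------------------------------
    stage = "cluster"
    try:
        clusters, sims = build_clusters(sequences, cfg.cluster_similarity, AlignConfig())
        write_clusters(clusters, out / "clusters.tsv")
        diag = cluster_diagnostics(clusters, sims)
        with open(out / "cluster_diagnostics.tsv", "w") as fh:
            fh.write("cluster_id\tsize\tmin_pairwise_similarity\n")
            for cid, size, ms in diag:
                fh.write(f"{cid}\t{size}\t{ms:.4f}\n")
        chain_to_cluster = {m: cl.cluster_id for cl in clusters for m in cl.members}
        manifest["stages"][stage] = {"n_clusters": len(clusters)}
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- interfaces ---------------------------------------------------------
    stage = "interfaces"
    complex_by_entry = {cx.entry_id: cx for cx in kept}
    try:
        all_instances: list[InterfaceInstance] = []
        for cx in kept:
            all_instances.extend(detect_interfaces(cx, cfg.contact_cutoff))
        msas: dict[int, object] = {}
        reps_by_cluster: dict[int, list[InterfaceInstance]] = {}
        sites_by_cluster: dict[int, dict[int, list[InterfaceInstance]]] = {}
        chain_res = {}
        for cx in kept:
            for ch in cx.chains:
                chain_res[f"{cx.entry_id}:{ch.chain_id}"] = cx.resolution
        for cl in clusters:
            members = {m: sequences[m] for m in cl.members}
            msa = build_msa(members, cluster_id=cl.cluster_id)
            msas[cl.cluster_id] = msa
            inst = [i for i in all_instances if i.host_chain in members]
            if not inst:
                continue
            map_interfaces(inst, msa)
            reps = dedup_interfaces(inst, msa, cfg.dedup_threshold,
                                    {m: chain_res[m] for m in cl.members})
            sites = cluster_binding_sites(reps, msa, cfg.site_threshold)
            reps_by_cluster[cl.cluster_id] = reps
            sites_by_cluster[cl.cluster_id] = sites
        with open(out / "interfaces.tsv", "w") as fh:
            fh.write("cluster_id\tsite_id\thost\tpartner\tentry\tresolution\t"
                     "n_residues\tresidues\n")
            for cid, reps in sorted(reps_by_cluster.items()):
                for r in reps:
                    res_str = ",".join(
                        f"{rr.chain_id}:{rr.seq_num}:{rr.icode or '-'}:{rr.aa}"
                        for rr in r.raw_residues)
                    fh.write(f"{cid}\t{r.site_id}\t{r.host_chain}\t{r.partner_chain}\t"
                             f"{r.entry_id}\t{r.resolution}\t{len(r.positions)}\t{res_str}\n")
        site_counts = {cid: len(sites) for cid, sites in sites_by_cluster.items()}
        histogram = interface_count_histogram(site_counts.values())
        with open(out / "multi_interface_histogram.tsv", "w") as fh:
            fh.write("n_interfaces\tn_proteins\n")
            for k, v in histogram.items():
                fh.write(f"{k}\t{v}\n")
        manifest["stages"][stage] = {
            "n_interface_instances": len(all_instances),
            "n_representatives": sum(len(v) for v in reps_by_cluster.values()),
            "site_counts": site_counts,
            "multi_interface_clusters": sorted(
                cid for cid, n in site_counts.items() if n >= 2),
        }
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- graphs -------------------------------------------------------------
    stage = "graphs"
    try:
        graphs_dir = out / "graphs"
        graphs_dir.mkdir(exist_ok=True)
        # per cluster and site: one graph per member *instance* of the site
        site_instance_graphs: dict[tuple[int, int], list[nx.Graph]] = {}
        for cl in clusters:
            cid = cl.cluster_id
            if cid not in sites_by_cluster:
                continue
            msa = msas[cid]
            members = {m: sequences[m] for m in cl.members}
            inst = [i for i in all_instances if i.host_chain in members]
            map_interfaces(inst, msa)
            from .interface_extraction import interface_similarity
            for i in inst:
                # an instance belongs to the site of the representative it is
                # most similar to
                best_sid, best_sim = None, -1.0
                for s2, reps2 in sites_by_cluster[cid].items():
                    for r2 in reps2:
                        sim = interface_similarity(i, r2, msa)
                        if sim > best_sim:
                            best_sid, best_sim = s2, sim
                if best_sid is None:
                    continue
                g = build_interface_graph(i, complex_by_entry[i.entry_id],
                                          cfg.contact_cutoff)
                g.graph["site_id"] = best_sid
                g.graph["cluster_id"] = cid
                annotate_msa_columns(g, i, msa)
                site_instance_graphs.setdefault((cid, best_sid), []).append(g)
        for (cid, sid), graphs in sorted(site_instance_graphs.items()):
            for g in graphs:
                name = g.graph["graph_id"].replace(":", "_").replace("|", "__")
                write_edgelist(g, graphs_dir / f"c{cid}_s{sid}_{name}.txt")
        manifest["stages"][stage] = {
            "n_graphs": sum(len(v) for v in site_instance_graphs.values())}
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- mine ---------------------------------------------------------------
    stage = "mine"
    try:
        fp_dir = out / "fingerprints"
        fp_dir.mkdir(exist_ok=True)
        fingerprints: dict[tuple[int, int], list] = {}
        for (cid, sid), graphs in sorted(site_instance_graphs.items()):
            t = support_threshold(len(graphs), cfg.local_support)
            if t > len(graphs):
                fingerprints[(cid, sid)] = []
                continue
            db = GraphDB(graphs, site_id=sid, support_threshold=t)
            fps = mine_closed_frequent(db, max_edges=cfg.max_pattern_edges)
            for f in fps:
                f.fingerprint_id = f"c{cid}_s{sid}_{f.fingerprint_id}"
            fingerprints[(cid, sid)] = fps
            write_fingerprint_index(fps, fp_dir / f"c{cid}_s{sid}.tsv")
        manifest["stages"][stage] = {
            "n_fingerprints": {f"c{c}_s{s}": len(v)
                               for (c, s), v in fingerprints.items()}}
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- relations ----------------------------------------------------------
    stage = "relations"
    try:
        rel: dict = {"clusters": {}}
        for cid, sites in sorted(sites_by_cluster.items()):
            if len(sites) < 2:
                continue
            fps_by_site = {sid: fingerprints.get((cid, sid), [])
                           for sid in sites}
            graphs_by_site = {sid: site_instance_graphs.get((cid, sid), [])
                              for sid in sites}
            # protein (= entry) -> site -> one instance graph
            protein_site: dict[str, dict[int, nx.Graph]] = {}
            for sid, graphs in graphs_by_site.items():
                for g in graphs:
                    entry = g.graph["protein_id"].split(":")[0]
                    protein_site.setdefault(entry, {})[sid] = g
            pairs = cooperative_pairs(fps_by_site, protein_site, cfg.min_co_fraction)
            distinct = {sid: [f.fingerprint_id for f in
                              distinctive_fingerprints(sid, fps_by_site, graphs_by_site)]
                        for sid in sites}
            iface_graphs = {g.graph["graph_id"]: g
                            for graphs in graphs_by_site.values() for g in graphs}
            all_fps = [f for fps in fps_by_site.values() for f in fps]
            tdb = build_transactions(all_fps, iface_graphs)
            itemsets = mine_closed_itemsets([t.items for t in tdb.transactions],
                                            minsup=max(2, len(tdb.transactions) // 5)) \
                if tdb.transactions else []
            # pairwise isomorphism counts with null p-values
            iso = {}
            site_ids = sorted(sites)
            freqs = None
            for i, j in [(a, b) for a in site_ids for b in site_ids if a < b]:
                fa, fb = fps_by_site[i], fps_by_site[j]
                obs = count_isomorphic_pairs(fa, fb)
                entry_key = f"s{i}-s{j}"
                if fa and fb:
                    if freqs is None:
                        all_graphs = [g for graphs in graphs_by_site.values()
                                      for g in graphs]
                        freqs = db_label_frequencies(GraphDB(all_graphs,
                                                             support_threshold=1))
                    nt = random_null_pvalue(
                        [(f.n_nodes, f.n_edges) for f in fa],
                        [(f.n_nodes, f.n_edges) for f in fb],
                        freqs, obs, n_reps=cfg.null_reps, seed=cfg.seed)
                    iso[entry_key] = {"observed": obs, "p": nt.p_value,
                                      "p_formatted": nt.formatted}
                else:
                    iso[entry_key] = {"observed": obs, "p": None}
            # overlap control: mean Jaccard between sites' representatives
            msa = msas[cid]
            overlaps = []
            reps = reps_by_cluster[cid]
            for a, b in [(x, y) for x in reps for y in reps
                         if x.site_id is not None and y.site_id is not None
                         and x.site_id < y.site_id]:
                overlaps.append(jaccard_overlap(a, b, msa))
            rel["clusters"][str(cid)] = {
                "cooperative_pairs": [
                    {"fp_a": p.fp_a, "fp_b": p.fp_b, "site_a": p.site_a,
                     "site_b": p.site_b, "co_support": p.co_support,
                     "co_fraction": round(p.co_fraction, 4)} for p in pairs],
                "distinctive": distinct,
                "closed_itemsets": [[sorted(s), c] for s, c in itemsets],
                "isomorphism": iso,
                "mean_jaccard_between_sites": (
                    round(float(sum(overlaps) / len(overlaps)), 4) if overlaps else None),
            }
        (out / "relations.json").write_text(json.dumps(rel, indent=2, sort_keys=True))
        manifest["stages"][stage] = {
            "n_multi_interface_clusters": len(rel["clusters"])}
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
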