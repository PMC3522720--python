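# midomain — multi-interface protein domain analysis

A protein domain that presents two or more distinguishable binding sites
to different partners is a *multi-interface domain* — a hub of
domain–domain interaction networks. `midomain` is an analysis pipeline
that goes from multi-chain structures (PDB/mmCIF) to a characterisation
of such domains:

1. **Preprocess** — keep X-ray entries with resolution < 3.0 Å; within
   each biological unit drop transformed chains, chains shorter than 30
   residues, and chains without an interaction partner.
2. **Cluster** — group redundant depositions of the same protein by
   all-vs-all Smith–Waterman local alignment; chains with aligned-region
   identity ≥ 0.975 (mutation rate ≤ 2.5 %) are joined by single
   linkage.
3. **Interfaces** — an interface residue has a heavy atom within 5 Å of
   a partner chain's heavy atom (same biological unit only). Interfaces
   of a cluster are mapped onto common MSA columns, near-duplicates
   (similarity ≥ 0.8 over the smaller set, `sim = n_identical /
   min(|I₁|,|I₂|)`) collapse to the best-resolution representative, and
   representatives group into binding sites. Proteins with ≥ 2 sites are
   multi-interface.
4. **Contact graphs** — each interface becomes a residue graph: nodes
   are interface residues labeled by amino-acid type, edges are Delaunay
   tessellation atom contacts of length ≤ 5 Å, merged per residue pair.
5. **Fingerprints** — closed frequent subgraphs mined per binding site
   at 20 % local support: connected labeled patterns occurring in at
   least ⌈0.2·|DB|⌉ graphs such that no one-edge extension keeps the
   same support. These are the recurring residue-contact patterns that
   identify a site.
6. **Relations & statistics** — cooperative fingerprint pairs
   (co-occurring across two sites of the same protein), distinctive
   fingerprints (unique to one site), closed frequent itemsets over the
   fingerprint×interface occurrence table, isomorphic-fingerprint counts
   between sites with a random-graph null (size/edge-matched, labels
   from amino-acid frequencies), and domain-specificity tests (Welch
   t-tests on degree- and label-assortativity, subsampled disparity).

The key summary statistic is the interaction-type **preference** for
multi-interface proteins. With nᵗ interactions of type *t* (homo/hetero
× oligomer/complex) of which mᵗ involve multi-interface proteins,

```
preference_t = (m_t / n_t) / (Σ m / Σ n)
```

values above 1 mean the type is over-represented among multi-interface
interactions.

Everything runs on synthetic inputs generated by `midomain.synthetic_data`
(cartoon multi-chain complexes with planted interfaces, mutated cohort
copies, labeled graph databases with planted motifs), so no downloads
are needed to exercise or test any stage.

## Worked example

```python
from midomain.synthetic_data import (ComplexSpec, InterfacePlan,
                                     generate_cluster_cohort, write_cohort)
from midomain.pipeline import PipelineConfig, run_pipeline

spec = ComplexSpec(chain_ids=("A", "B", "C"), chain_length=40,
                   interface_plan=(InterfacePlan("A", "B", (10, 19), (10, 19)),
                                   InterfacePlan("A", "C", (25, 32), (5, 12))),
                   resolution=1.8, entry_id="SYN", seed=5)
records, truth = generate_cluster_cohort(spec, n_copies=4, mutation_rate=0.02, seed=11)
write_cohort(records, "structures/")
manifest = run_pipeline(PipelineConfig(structures_dir="structures/", out_dir="run/", seed=1))
print(manifest["stages"]["interfaces"]["site_counts"])
```

prints

```
{0: 2, 1: 1, 2: 1}
```

cluster 0 (the four A chains) carries two binding sites — one against B,
one against C — and is therefore the cohort's one multi-interface
protein; clusters 1 and 2 (the B and C chains) carry one site each.
The same run writes `run/relations.json` reporting, for cluster 0, two
cooperative fingerprint pairs across its two sites, fully distinctive
fingerprint sets (no isomorphic fingerprint shared between the sites,
null p = 1.0), and zero Jaccard overlap between the sites' residues.

The numbered drivers under `analysis/` run the same story end to end
(`01` simulate → `02` pipeline → `03` preference arithmetic → `04`
motif mining + isomorphism nulls → `05` domain-specificity tests) and
leave their tables under `results/`. For example `03` prints the
preference table computed from the published cohort's interaction
counts — 1.42 (homo-oligomer), 1.67 (homo-complex), 0.76
(hetero-oligomer), 0.96 (hetero-complex) — i.e. multi-interface
proteins favour homo-interactions.

The CLI mirrors the library: `midomain simulate cohort --out d/`,
`midomain preprocess --in d/ --out manifest.tsv`,
`midomain cluster --fasta chains.fa --out clusters.tsv`,
`midomain run --config cfg.yaml`.

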