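# Methods

This note documents the models, parameters and design choices behind
`midomain`, and what the synthetic data does and does not show.

## Structure model and preprocessing

Structures are read with gemmi. Biological units come from the file's
assembly records (REMARK 350 / `pdbx_struct_assembly`): each chain is
assigned to the first biomolecule listing it (chains listed by several
biomolecules are duplicated per unit), and a chain is flagged
identity-transformed only when every operator its unit applies to it is
the identity. Only heavy atoms are used anywhere; for alternate
locations the highest-occupancy conformer is kept; residues without any
heavy atom are dropped, so chain length equals the number of residues
usable for geometry. Non-standard residues map to `X`: they stay in
sequences but are excluded from contact-graph node labels, keeping the
mining alphabet at the 20 standard amino acids.

Filters (defaults, all configurable): X-ray only; resolution strictly
better than 3.0 Å ("better" read literally as smaller); chain length
≥ 30; transformed chains removed rather than untransformed (their
coordinates duplicate another copy's geometry under the operator);
chains with no heavy atom within 5 Å of another surviving chain of the
same unit removed *to a fixed point*, which makes filtering idempotent
(a one-pass removal would not be: removing a partnerless chain can
orphan its former neighbour); units with < 2 surviving chains dropped.

## Chain clustering

Redundant depositions are grouped by all-vs-all Smith–Waterman local
alignment (BLOSUM62, gap open 11 / extend 1 — the classic protein
defaults; a raw-score floor of 40 skips junk pairs). Identity is counted
over the aligned region only, so a single domain inside a longer
multi-domain chain still clusters with its free-standing copies. Chains
with identity ≥ 0.975 are joined and clusters are the connected
components (single linkage). The chaining risk of single linkage is
surfaced as a per-cluster minimum-pairwise-similarity diagnostic rather
than a filter. Alignment determinism relies on the aligner's first
reported optimal alignment.

## Interfaces, de-duplication, binding sites

Interface residues use the inclusive 5 Å heavy-atom criterion; chain
pairs across biological units are never considered. Within a cluster,
interfaces are mapped onto common columns of a center-star multiple
alignment (center = chain minimising the summed pairwise distance;
ties → longest sequence, then smallest id; insertion runs are
right-aligned into reserved columns). Because intra-cluster identity is
≥ 97.5 %, the center-star MSA is nearly trivial and a heavier profile
aligner would add nothing.

Interface similarity is `|identical (column, aa) pairs| / min(|I₁|,
|I₂|)`; the min-cardinality denominator makes a sub-interface of a
larger interface score 1. De-duplication connects interfaces with
similarity ≥ 0.8 and keeps one representative per component: best
(lowest) resolution, ties broken by input order; representatives are
remapped onto the cluster's best-resolution chain. Binding sites then
group representatives by single-linkage column similarity at a default
threshold of 0.5. This replaces structural superposition for site
clustering: chains in a cluster are near-identical, so MSA-column
identity is a faithful proxy for spatial identity; the threshold is a
free parameter because no reference value exists for it.

Interaction types: homo vs hetero is host/partner cluster identity;
obligate (oligomer) vs transient (complex) is consumed as an input flag
per interaction, not predicted — permanence prediction is a separate
problem with its own literature, and miscalling it here would silently
distort the preference statistic. Missing flags yield "unknown" and are
excluded from preference counts.

The preference statistic is
`(m_t/n_t) / (Σm/Σn)`; it satisfies the exact identity
`Σ_t n_t · preference_t = Σ_t n_t`, which the tests verify both in full
precision and after 2-decimal rounding (< 0.5 % residual).

## Contact graphs

Heavy atoms of the host chain's surface residues are tessellated
(scipy's Qhull Delaunay); atom edges longer than 5 Å are discarded;
intra-residue contacts are ignored and multiple inter-residue atom
contacts merge into one unweighted residue edge; nodes are restricted to
the interface residues. Degenerate inputs (< 4 atoms, or collinear/
coplanar sets detected by a rank test at 1e-6) fall back to the
complete atom graph, so the result degrades to the plain
distance-cutoff graph — the physically meaningful criterion. A 1e-9 Å
deterministic jitter breaks exact cospherical ties; rotation/translation
invariance of the edge set is property-tested. The surface-residue
criterion is a free parameter: the default uses all residues, and an
optional Shrake–Rupley relative-accessibility filter (RSA ≥ 5 %) is
provided; on the cartoon synthetic geometry an RSA filter is not
meaningful. Kyte–Doolittle hydropathy is attached to nodes for
inspection but never used as a mining label.

## Closed frequent subgraph mining

Pattern language: connected node-labeled graphs, unlabeled edges.
Occurrence is subgraph *monomorphism* (injective, label-preserving,
edges mapped to edges); support is per host graph, not per embedding.
The miner grows patterns breadth-first from frequent single labels,
keeping full embedding lists, so support counting is exact and
extension enumeration is complete; shapes are deduplicated by an exact
canonical code (BLISS canonical labeling of the vertex-colored graph,
via igraph). Anti-monotonicity justifies pruning infrequent patterns.
Closedness is checked against one-step extensions only (one new edge,
possibly with one new node), which is equivalent to full closedness for
connected pattern languages; every one-step super-pattern that occurs
anywhere is necessarily generated from each of its frequent parents, so
the recorded parent→child supports suffice. The miner is validated by
exhaustive brute-force enumeration on hundreds of random databases.

Defaults: local support 20 % (global threshold `ceil(0.2·|DB|)`,
floored at 2 so a "frequent" pattern never means a single occurrence);
"non-trivial" fingerprints are those with ≥ 2 edges — patterns below
that carry no topology (the term has no established size convention, so
the package mines everything and flags triviality rather than dropping).
A `max_pattern_edges` cap (pipeline default 12) bounds worst-case growth
on dense near-identical databases; mining at desk scale never hits it.

At full-PDB scale the graph database of a binding site spans the
representative interfaces of a domain across many proteins. At cohort
scale the pipeline builds, for each site, the database of per-entry
interface instances assigned to that site (assignment by best column
similarity to the site's representatives), and the "domain" defaults to
the sequence cluster; a supplied domain table can widen the grouping.

## Null models and statistics

Isomorphic-fingerprint counts between two sites are counted on the
smaller set's side (fingerprints with ≥ 1 isomorphic counterpart). The
null generates, per replicate, random connected labeled graphs matching
each fingerprint's node and edge counts — a uniform spanning-tree
skeleton plus uniformly chosen extra edges — with labels i.i.d. from the
database's observed amino-acid frequencies (overridable); p is the
fraction of replicates reaching the observed count, reported as
`< 1/n_reps` when zero, so p-values live in (0, 1]. The default 2000
replicates resolves p down to 5×10⁻⁴.

Assortativity uses networkx: degree assortativity is the Pearson
correlation of endpoint degrees over symmetrized edges (any star is
exactly −1; regular graphs are undefined), label assortativity is the
categorical mixing coefficient `(Σe_ii − Σa_ib_i)/(1 − Σa_ib_i)`
(undefined for single-label graphs). Undefined values are dropped from
the Welch two-sample t-tests (unequal variances assumed — the safer
default when the paper-style comparison says only "t-test") with
dropped counts reported.

The subsampling disparity test draws k = 50 fingerprints with
replacement per domain; a replicate's disparity is the isomorphic-pair
count between the two samples. The cross-domain disparity distribution
is compared against within-domain resampling (both domains pooled,
alternating); the one-sided p is P(within ≤ cross) averaged over
replicates, floored at 1/n_reps. One-sided is the natural choice here:
the question is specifically whether two domains share *fewer* patterns
than a domain shares with itself.

Cooperative pairs are defined at protein level — both fingerprints
embed in the same protein's respective site graphs — with the
co-occurrence fraction taken over proteins possessing both sites and a
default reporting floor of 0.20, matching the mining support. The
transactional closed-itemset view (closure-based DFS over tidsets; every
closed itemset is the intersection of its supporting transactions) is
emitted alongside for multi-way co-occurrence, since a pair-only view
and an itemset view answer slightly different questions.

## Synthetic data

`generate_complex` lays chains out as cartoon residue paths (one
C-alpha plus one pseudo side-chain carbon per residue, 3.8 Å steps,
±0.15 Å jitter) in home lanes 20 Å apart; planned interface ranges
detour to shared contact sites 80 Å apart where host and partner
residues sit 3.9 Å apart (≤ 4.5 Å with jitter), while all unplanned
inter-chain pairs stay > 6 Å. Geometry is verified after construction
and retried with fresh jitter (bounded), so planted interface recovery
is guaranteed by construction, not by luck. `generate_cluster_cohort`
emulates redundant depositions: copy 0 is the unmutated base and every
further copy carries exactly `round(rate·L)` substitutions per chain —
the mutation rate is controlled exactly rather than in expectation, so
a 2 % cohort sits deterministically inside the 2.5 % clustering
threshold (via the base, under single linkage) and a 10 % cohort
deterministically outside it. `generate_graph_db` plants motifs by
overwriting labels and adding edges in a controlled fraction of random
connected graphs, recording every embedding.

What passing tests on these data show: the pipeline's bookkeeping
(filters, clustering, mapping, de-duplication, site assignment, mining,
statistics) is correct under controlled conditions. What they do not
show: robustness to real structural noise — flexible loops, alternative
conformations, crystal contacts misassigned as biological, sequence
gaps — or the biological claims at full-PDB scale; the full-cohort
counts reported in the literature depend on a complete PDB snapshot and
are out of reach at desk scale.

## Problem sizes

Default analysis and test sizes are chosen to keep the whole suite in
the tens of seconds on one CPU: cohorts of 4–5 entries × 3 chains of
40–60 residues, graph databases of 10–12 graphs of 8–12 nodes,
brute-force oracle comparisons on databases of ≤ 5 graphs × ≤ 6 nodes,
2000-replicate nulls where a closed form is being checked and
100–500 elsewhere. These sizes are sufficient for every correctness
property being asserted; nothing in the algorithms is specific to them.

## Known limitations

- Obligate/transient classification is consumed, never predicted.
- The binding-site similarity threshold (0.5) has no external reference
  value; conclusions that depend on site granularity should be checked
  against it.
- The miner's embedding lists can grow combinatorially on large dense
  graphs with few distinct labels; the edge cap guards the pipeline but
  truncates patterns beyond it.
- The center-star MSA assumes near-identical sequences; it is not a
  general-purpose aligner.
- Cross-cluster (whole-domain) site matching requires a supplied domain
  table; the default treats each sequence cluster as its own domain.
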