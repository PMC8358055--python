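# Methods

This note documents the models implemented in `coevopath`, their
assumptions, the parameters that matter, the numerical choices, and what
the synthetic-data generators do and do not emulate.

## Sequence entropy and order/disorder

Entropy is *compositional*: for one sequence, `p_a` is the fraction of
residue type `a` among the non-gap positions, and
`H = -Σ_a p_a log₂ p_a` ∈ [0, log₂ 20 ≈ 4.32] bits. Gaps are excluded
from the composition because the 20-state model is exact only over the
standard residues; non-standard codes (B, J, Z, X, U, O) are folded into
the gap state with a logged warning for the same reason. Both gapped
alignment rows and ungapped member sequences can be scored — the
composition ignores gaps either way. A sequence is *ordered* when
`H < 2.9` bits, strictly: the boundary value 2.9 classifies as
disordered. The consensus sequence takes each column's modal residue
over non-gap characters (gap policy `exclude`, default) with ties broken
in fixed alphabetical residue order; all-gap columns are flagged, not
fatal.

## Mean-field DCA

The estimator is naive mean-field DCA over q = 21 states (20 residues +
gap):

1. **Reweighting.** Row weight = 1 / |{rows within fractional identity ≥
   0.8}| (self included); `M_eff` = sum of weights. The 0.8 cutoff is the
   standard mfDCA default and is exposed as a parameter.
2. **Frequencies.** Relative pseudocount λ = 0.5:
   `F_s(X) = λ/q + (1-λ)·(weighted fraction)`, pair tables with `λ/q²`,
   and the same-column block kept diagonal so pair marginals equal the
   single-site tables exactly (checked to 1e-9 in the tests).
3. **Couplings.** Connected correlations `C = F₂ - F₁F₁ᵀ` over q-1
   states per column (the gap dropped as reference state);
   `e = -C⁻¹`, mapped back with zeros in the reference rows/columns.
   A singular `C` (λ = 0 with degenerate data) raises an error that
   advises a larger pseudocount.
4. **Direct information.** Per pair, the two-site direct distribution
   `P ∝ exp(e_{s,t}) h_s h_tᵀ` is fitted so its marginals match `F_s`,
   `F_t`. The solver is a multiplicative scaling fixed point (tolerance
   1e-6 on the worst marginal error, 500 iterations). Strongly coupled
   pairs make that iteration sublinear — the coupling matrix can span
   many orders of magnitude — so on non-convergence the solver escalates
   to an over-relaxed log-domain iteration (relaxation 1.9, same fixed
   point) before raising. DI is the KL divergence of `P` against the
   product of marginals, clipped at zero against roundoff.

Two properties of this estimator are worth knowing. First, the
pseudocount induces a rank-one connected correlation
`λ(1-λ)(1/q - f_s)(1/q - f_t)` even for perfectly independent columns, so
the DI of truly independent data is small but *not* zero (≈ 0.06–0.17 in
the synthetic conditions below); planted strong couplings sit far above
that floor, which is what the tests assert. Second, DI is symmetric and
non-negative by construction.

`G_DCA` retains either the `top_k` highest-DI pairs (ties at the cut are
all kept) or all pairs with `DI ≥ min_di`; exactly one selector must be
given, since no single retention rule is canonical.

## Structure ensembles

PDB input goes through Bio.PDB: multi-MODEL records become ensemble
members, hydrogens are ignored, alternate locations resolve to the
highest-occupancy conformer, and glycine's side chain is represented by
its Cα. Models must agree on the residue set.

**RMSF** is computed on Cα coordinates with the per-residue mean as the
default reference; an optional least-squares (Kabsch) superposition maps
every model onto the reference frame first (anchored on the first model
when the reference is the mean, after which the mean is recomputed).

**Interaction-strength network.** `sc_ab` counts side-chain heavy-atom
pairs within 4.5 Å; `E_ab = 100·sc_ab/sqrt(sc_a·sc_b)` with per-residue-
type normalization values `sc_a` bundled from the protein structure-
graph literature (the largest observed side-chain contact capacity per
type); edges are kept at `E_ab ≥ E_c`, default 4%. Raising `E_c` can
only remove edges. The table, contact distance and threshold are all
replaceable through `InteractionParams`.

**GNM.** The Kirchhoff matrix of the Cα contact graph at 7.3 Å is
pseudo-inverted (SVD, zero mode dropped); correlations are normalized to
`C_ii = 1` and pairs with `|C_ij| ≥ 0.7` become `G_NMA` edges with
weight `|C_ij|`. GNM (rather than ANM) is the minimal normal-mode model
that yields a correlation matrix; a disconnected contact graph raises an
error advising a larger cutoff. **Ensemble similarity** is the Pearson
correlation between per-model GNM square-fluctuation profiles (diagonal
of the Kirchhoff pseudo-inverse); the representative model maximizes
mean similarity to the others (lowest index on ties); constant profiles
yield missing (NaN) similarities.

**Hydropathy** uses the Kyte–Doolittle scale with a centred window
(default 9, odd), truncated at the sequence edges; ranges such as 40–95
are 1-based and inclusive on both ends.

## Community structure

Girvan–Newman removes, at each step, the edge of highest weighted edge
betweenness — shortest-path betweenness divided by the edge weight, the
classic weighted generalization. Dividing by the weight (rather than
measuring path lengths as 1/weight) matters: with inverse-weight path
lengths the *strongest* intra-community edges attract all shortest paths
and are removed first, inverting the intended split on correlation
networks. Ties break on lexicographic edge order, so the procedure is
deterministic. Every partition along the removal sequence (including the
untouched network) is scored by weighted modularity and the best is
returned. This is a stopping rule, not a guarantee: the removal sequence
of a divisive algorithm need not contain the globally modularity-optimal
partition (modularity maximization is NP-hard), and small graphs exist
whose optimum is never encountered — e.g. star-like graphs whose leaf
edges carry maximal betweenness and are stripped into singletons first.

Node betweenness uses shortest paths with edge length = 1/weight,
normalized to [0, 1]. Partition comparison intersects the communities
containing a designated anchor residue (e.g. a mutation site) in two
partitions, restricted to a residue window (default 40–95), and reports
the Jaccard index of the two full communities. Stretch extraction
applies point mutations (standard `E46K` nomenclature, 1-based on the
wild type) before cutting, and refuses a mutation whose stated wild-type
residue disagrees with the sequence.

## Pathway semantics

Partner filtering keeps scores ≥ 0.5, sorted descending, truncated so
the retained set including the query has 11 members; score ties at the
cut are kept (logged) and the query is appended if absent. Pathway
filtering keeps pathways containing the query protein with ≥ 2 members.
Both filters are idempotent.

Wang similarity propagates S-values down the ancestor DAG
(`S_T(T) = 1`, `S_T(p) = max c_e·S_T(p')` over children inside the DAG,
evaluated in topological order) with contribution factors c_e = 0.8
(is-a) and 0.6 (part-of), the method's published defaults;
`SV(T) = Σ S_T(p)` and
`SS_w(T,Q) = Σ_{shared} [S_T(p)+S_Q(p)] / [SV(T)+SV(Q)]`. Terms under
disjoint roots score 0. Set-level similarity is the best-match average
over both directions. A pathway's term set is the union of its member
proteins' annotations in one ontology namespace (BP or CC — networks
are always per-namespace); unannotated members are dropped with a
warning. Zero-weight edges are omitted; edges at or above a configurable
quantile (default 0.75) of retained weights are flagged *strong*, the
analogue of bold edges in a rendered pathway graph.

PageRank iterates `PR(n) = d·Σ_m PR(m)·w_mn/W_m + (1-d)/N` from a
uniform start, with `W_m` the total incident weight; the default d = 1
is the literal rank equation. Plain power iteration oscillates with
period 2 on bipartite graphs, so on non-convergence the solver retries
with a half-averaged ("lazy") iteration — which has the same fixed
point — and only then falls back to d = 0.85 with a warning. Isolated
nodes receive teleport mass only (zero at d = 1); the result is
normalized to sum 1 and returned in descending order with deterministic
id tie-breaks. An edgeless graph short-circuits to the uniform
distribution.

## Synthetic data: what it emulates, and what it does not

All generators fan one global seed into independent per-stage streams,
so outputs are byte-identical across runs and stages do not perturb each
other. Each generator returns a truth record sufficient to predict the
downstream result without re-running it.

* **Aligned families** — background columns i.i.d. uniform over a
  reduced alphabet (default 8 letters, keeping brute-force oracles
  enumerable), conserved columns with a set conservation level, and
  planted pairs whose two binary states agree with probability
  (1+c)/2 for coupling strength c. Defaults: 500 sequences × 50
  columns, five planted pairs at c = 0.9. No phylogeny, no gaps, no
  realistic residue usage — so recovery tests demonstrate estimator
  correctness, not performance on real Pfam alignments, where
  phylogenetic correlation inflates the null.
* **Ensembles** — an ideal α-helix Cα trace (rise 1.5 Å, 100° twist,
  radius 2.3 Å) with one radial pseudo side-chain atom per residue and
  isotropic Gaussian noise (default σ = 0.5 Å, 10 models, 60 residues);
  expected RMSF about the sample mean is σ·sqrt(3(S-1)/S). An optional
  outlier model carries inflated noise. Single-atom pseudo side chains
  under-count contacts relative to real rotamers, so default-parameter
  interaction networks on synthetic helices are sparse or empty; tests
  of the interaction formula use explicit geometries and normalization
  tables instead.
* **Ontology worlds** — two rooted DAGs (BP and CC namespaces) of
  configurable depth/branching with a set part-of fraction and
  occasional second parents; the first two BP children of the root are
  pinned is-a so their similarity has the closed form 4/9. Proteins are
  annotated to leaves; every other pathway contains the query protein;
  PPI scores are uniform with a known count above 0.5.

## Pipeline

The five stages run in a fixed order and communicate only through the
documented text formats (TSV, FASTA, PDB, GraphML), so every stage can
be re-run standalone on persisted intermediates. The manifest records
the package version, full configuration, SHA-256 of every input, and
per-stage summaries. A stage failure halts the run with the stage name;
partial outputs and the partial manifest are retained. All thresholds
live in one config with the frame's canonical values as defaults (2.9
bits; λ = 0.5 and identity 0.8; E_c = 4%; GNM 7.3 Å and 0.7; PPI 0.5 /
top 11; stretch 40–95; ≥ 2 members including the query; d = 1). DCA
columns are 0-based alignment positions and are mapped to 1-based
residue numbering when compared against structure-network communities;
this identification assumes the alignment columns track the modelled
residues, which holds for the synthetic trio and must be checked by the
user for real inputs.

## Problem sizes in the test suite

Module and acceptance tests run on deliberately small instances chosen
to keep the oracles exact: toy families of 2–3 columns over 2–3 residue
states for the DI enumeration check; the 500×50 synthetic family for
planted-pair recovery; chains of ≤ 10 residues for the GNM
eigendecomposition oracle; every connected atlas graph on ≤ 6 nodes
plus seeded random connected 7- and 8-node graphs for the exhaustive
community-detection and PageRank comparisons (exhaustive partition
enumeration grows as the Bell numbers, so isomorphism-class coverage
ends at 6 nodes and larger sizes are sampled).

## Known limitations

* mfDCA here is the inverse-covariance (naive mean-field) variant;
  pseudo-likelihood DCA and APC-corrected scores are out of scope.
* The interaction-strength normalization table is type-level; residue
  conformers are not distinguished.
* GNM is Cα-only and isotropic; no ANM directionality.
* The Girvan–Newman stopping rule returns the best partition the
  removal sequence happens to contain (see above), not the global
  modularity optimum.
* Annotation namespaces other than BP/CC (e.g. molecular function) and
  information-content similarity measures are not implemented.
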