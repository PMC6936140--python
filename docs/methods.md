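# Methods

## Scope and model

`stagenet` infers stage-specific miRNA–gene interaction networks from
paired expression matrices. The statistical core is deliberately simple —
mass univariate OLS with BH-FDR selection — because the scientific object
of interest is the *network* built downstream of the screen: how the set of
significant regulatory relationships, merged with validated targets and
embedded in a protein-interaction template, changes between pathological
stages.

Assumptions worth stating explicitly:

- **Linearity on the normalized scale.** After the rank-based inverse
  normal transform both variables are marginally standard normal, so the
  per-pair model `x_g = α + β x_m + ε` is a correlation test in disguise;
  β is interpretable as normalized-scale slope, not a biochemical rate.
- **Regression direction.** Gene expression is the response and miRNA
  expression the predictor, mirroring the genotype→expression convention
  of eQTL screens with the miRNA in the regulator slot. No covariates are
  fitted.
- **Independence across pairs is not assumed for validity of BH** beyond
  the usual positive-dependence robustness; FDR is controlled within each
  stage across all `n_miRNA × n_gene` tests jointly.
- **The interaction template is undirected.** "Downstream genes" of a hub
  are its first neighbours at confidence ≥ the cutoff; a PPI database
  carries no direction.

## Preprocessing

Order of operations: feature filter → sample filter → per-stage subsetting
→ normalization. Features with a missing fraction strictly greater than
0.10 are removed (exactly 10% survives); then samples with unknown stage or
any remaining missing value are dropped. Filtering features first means a
single degraded feature cannot wipe out the cohort. Normalization maps each
feature row to `Φ⁻¹(r_i/(n+1))` with average ranks for ties (Blom's
`(r−3/8)/(n+1/4)` available via `offset="blom"`); constant rows map to all
zeros and are logged. Normalization is applied within each stage's sample
subset by default — the screen is per-stage, so ranks computed on the
analysis cohort keep the marginals exactly normal — with a flag for global
normalization before subsetting.

## Association screen

The screen is a vectorized matrix implementation: centred cross-products
give all betas at once, residual sums of squares follow from
`SS_res = SS_y − β²SS_x`, and `t = β√((n−2)SS_x/SS_res)` on n−2 df. A unit
test holds it to a naive per-pair OLS loop at 1e-10. Zero-variance miRNAs
are skipped and logged. Two-sided p-values are clamped below at 1e-300 so
the BH step-up stays defined for perfect fits. BH q-values are computed by
the step-up rule `q_(i) = min_{j≥i} p_(j)·m/j` capped at 1; statsmodels'
implementation serves as an independent oracle in the tests, not as the
implementation. Stages with fewer than 4 samples are refused (the slope
test needs n−2 ≥ 2 df).

Genomic distance uses the minimal gap between the two feature intervals
(0 when they overlap or touch), binned upper-inclusively at 1, 10, 50, 100
and 200 Mb, with cross-chromosome pairs in their own bin. Strand is
ignored. Start-to-start distance was the main alternative; the minimal-gap
convention is symmetric and insensitive to gene length, and the choice is
config-switchable.

## Gene sets and enrichment

The per-stage gene set is the union of (a) genes significantly associated
with any miRNA and (b) validated targets of those miRNAs, looked up
case-insensitively with an alias hook for miRBase/miRTarBase naming drift.
Enrichment is a two-sided Fisher exact test per GO term against a fixed
background universe, Bonferroni-corrected within each of the three GO
categories (a global-correction switch exists). Two-sided testing lets
terms be reported as enriched or depleted by their fold change
`(k/n_query)/(K/N)`. The pipeline's background universe is the
union of all annotated genes and all measured genes, standing in for a
whole-genome background. Annotations are taken as given: there is no
GO-graph ancestor propagation. Real GO use should propagate annotations to
ancestors before writing the term→gene TSV; the reader accepts any such
propagated file.

## Network construction

Template edges are used as an unweighted graph after the confidence ≥ 0.2
filter; density/diameter-style metrics downstream assume unweighted edges,
and a flag can carry weights for export. The preliminary network holds the
merged genes present in the template (ppi edges among them) plus the
stage's miRNAs and associated genes (association edges), so an associated
gene missing from the template stays connected through its miRNA.

Community detection minimizes the Reichardt–Bornholdt Hamiltonian under
the configuration null model. The null term includes the diagonal
`k_i²/2m` contribution so that at γ=1 the identity `Q = −H/m` holds exactly
(verified to 1e-12 against networkx modularity); this matches the standard
modularity convention. Optimization: single-node Potts moves proposing a
neighbour's community (90%) or a fresh singleton (10%); initial temperature
auto-set to the mean |ΔH| of sampled moves; geometric cooling at 0.96 with
20·n proposals per temperature; stop when the acceptance rate drops below
1e-3; a greedy descent sweep polishes the final state. Three restarts plus
the all-in-one and all-singleton baselines compete on energy, so the
returned partition is never worse than either baseline. On planted 3-block
graphs (20 nodes/block, p_in=0.9, p_out=0.05) the annealer recovers the
planted partition with ARI ≥ 0.9 in at least 18 of 20 seeds, and igraph's
spin-glass implementation (used as an independent oracle in one test)
finds partitions of the same modularity.

Expansion takes the top-1 gene per community by within-community degree
(ties broken lexicographically; miRNAs are never hubs), adds each hub's
template neighbours, and closes over template edges among the final node
set — growth is monotone. The hub count is configurable; one per community
is the default because the expansion is meant to probe each community's
neighbourhood, not to flood the network. A randomized expansion variant
(nodes sampled proportionally to their connectivity to the current
network) is provided but off by default.

## Comparison and alignment

Metrics use unweighted hop semantics: diameter is the maximum eccentricity
within any connected component; closeness of a node is `1/Σd` over its
component (0 for isolates); betweenness is unnormalized Brandes
betweenness with each unordered pair counted once (star centre with 4
leaves scores C(4,2)=6); density is `2m/n(n−1)`. Edge similarity defaults
to Jaccard `|E_a∩E_b|/|E_a∪E_b|` for symmetry; an asymmetric
`|E_ref∩E_s|/|E_ref|` denominator is available since "proportion of common
edges" is ambiguous. Two empty edge sets compare as 1.

Alignment propagates a node-similarity matrix `S ← normalize(A·S·B + prior)`
seeded from label identity (when anchored) and degree similarity, extracts
an injective correspondence greedily, and refines the non-anchored images
by deterministic 2-opt swaps on the objective `Σ A_ij B_{π(i)π(j)}`. With
anchoring on, shared labels always map to themselves. This is an
adjacency-based similarity-propagation scheme in the IsoRank family,
designed for the same intent as message-passing graph aligners; it does not
replicate any particular package's scores. Stage-specific subnetworks are
the edges absent from the counterpart under the correspondence, restricted
to connected components containing at least one miRNA node.

## Synthetic data: what it emulates and what it does not

The generator produces all five pipeline inputs with known ground truth.
Defaults are the study conditions used throughout the tests:

| parameter | default | meaning |
|---|---|---|
| samples/stage | 31/82/59/23 | cohort sizes of a stage-labelled tumour series |
| n_mirnas × n_genes | 50 × 300 | feature space of the screen |
| planted pairs | 40 (10/stage) | stage-specific linear effects |
| effect_size β | 2.0 | slope on a background of sd 2 |
| noise_sd σ_ε | 0.5 | residual sd of planted effects |
| bad_feature_frac | 0.05 | features with 25% missing entries (removed by the 10% rule) |
| unknown_stage_frac | 0.02 | samples dropped by the stage filter |
| chromosomes | 5 × 240 Mb | enough span to populate every distance bin |
| interaction model | planted partition, 5 blocks, p_in 0.9 / p_out 0.05 | community-structured template |
| confidence range | U(0.1, 1) | exercises the 0.2 cutoff |
| GO | 50 log-uniform terms + 1 planted (overlap 0.8) | enrichment target |

Expression is generated directly on a continuous log2-like scale
(Normal(6,2)) rather than as counts: the screen operates on rank-normalized
values, which erase count-level marginal shape anyway. Missingness is
injected completely at random within designated features. Planted effects
are active only in the designated stage's samples (`shared_effects=True`
plants them everywhere, the control used to verify that identical planted
networks produce empty stage-specific subnetworks — paired with an FDR
cutoff of 1e-6 so that false positives are excluded by construction rather
than by luck). Each artifact uses its own RNG stream spawned from the
master seed, so regenerating one file does not shift the others, and
identical configs produce byte-identical files.

What passing tests on this generator do **not** show: robustness to count
overdispersion, library-size or batch effects, correlated miRNA families,
annotation errors, GO-term dependency structure, or weighted/directed
interaction evidence. The generator is a correctness harness, not a
realism benchmark.

## Problem sizes and numerical choices

The test and acceptance workloads run at deliberately modest sizes — null
screens of 100×200 features over 50–60 samples, planted-partition graphs
of 60 nodes, alignment instances of 30 nodes, the default cohort above for
end-to-end runs — chosen so each check isolates one property with ample
Monte-Carlo margin. Tolerances: 1e-10 for the OLS-vs-loop equivalence,
1e-12 for the Q = −H/m identity, exact agreement for combinatorial oracles
(Fisher enumeration, Floyd–Warshall, path-counting betweenness), and
2–3 Monte-Carlo standard errors for stochastic rates. Ties are broken
deterministically everywhere (lexicographic hubs, stable sorts in greedy
matching), and all stochastic components take explicit seeds.

## Known limitations

- The diameter/centrality/betweenness suite is unweighted; confidence
  scores act only as a filter. Weighted-path semantics would change the
  reported diameters materially on large dense networks.
- The 2-opt alignment refinement is O(n²) per sweep and is intended for
  networks up to a few hundred nodes; larger alignments should rely on the
  propagation + greedy stage alone.
- Bonferroni (not FDR) controls the enrichment family-wise error, which is
  conservative for large, correlated term collections.
- The annealer's schedule constants are tuned for networks up to a few
  thousand nodes; much larger graphs need a faster cooling or a seeded
  initialization from a cheaper method (e.g. greedy modularity).
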