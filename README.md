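# stagenet

Stage-specific miRNA–gene interaction networks from paired expression
profiles.

## The problem

miRNAs repress target genes post-transcriptionally, and their regulatory
influence can differ between pathological stages of a tumour (I–IV in colon
cancer staging). Given per-patient miRNA and gene expression matrices with
clinical stage labels, `stagenet` asks: *which miRNA–gene relationships are
active in each stage, and how do the resulting regulatory networks differ
as disease progresses?* It is written for computational biologists working
with TCGA-style multi-omic cohorts plus the usual reference resources
(miRTarBase-style validated targets, an InWeb-style confidence-scored
protein-interaction template, GO annotations, GFF3 coordinates).

## The method

Five steps per stage, after preprocessing (drop features with >10% missing
values, drop stage-unknown or incomplete samples, rank-based inverse normal
transform per feature, `Φ⁻¹(r/(n+1))`):

1. **Association screen** — for every (miRNA *m*, gene *g*) pair fit OLS
   `x_g = α + β x_m + ε` over the stage's samples; Wald *t* on *n*−2 df,
   two-sided *p*, Benjamini–Hochberg over all `n_miRNA × n_gene` tests,
   keep pairs with *q* ≤ 0.05. Each hit is binned by genomic distance
   ((0,1MB], (1,10MB], (10,50MB], (50,100MB], (100,200MB], >200MB,
   CrossChr).
2. **Target retrieval** — validated targets of the significant miRNAs.
3. **Gene-set merge + GO enrichment** — the union of associated and
   targeted genes, tested per GO term with a two-sided Fisher exact test,
   Bonferroni within category (MF/BP/CC).
4. **Network construction** — overlay the merged set on the interaction
   template (confidence ≥ 0.2), add miRNA→gene association edges, detect
   communities by minimizing the Reichardt–Bornholdt spin-glass Hamiltonian
   `H(σ) = −½ Σ_{ij} (A_ij − γ k_i k_j / 2m) δ(σ_i, σ_j)` by simulated
   annealing (at γ=1, modularity Q = −H/m), then expand each community's
   most-connected gene by its template neighbours.
5. **Comparison** — per-stage topology metrics (components, hop diameter,
   mean closeness `1/Σd`, unnormalized mean betweenness, edge density
   `2m/n(n−1)`), edge similarity vs a reference stage, degree
   distributions, and adjacency-based network alignment (similarity
   propagation + greedy injective matching) that isolates the
   miRNA-anchored subnetworks specific to each stage.

A synthetic-data module generates all five inputs with planted ground truth
(stage-specific linear effects, a planted community partition, a planted
enriched term) so every step's answer is recoverable and testable.

## Worked example

```sh
python examples/06_full_pipeline.py
```

simulates the default four-stage cohort (sample sizes 31/82/59/23, 50
miRNAs × 300 genes, 40 planted pairs with slope 2 and residual sd 0.5) and
runs the whole pipeline:

```
stages analysed: I, II, III, IV

stage I: 11 associations (10/10 planted recovered), merged gene set 33, network 221 nodes / 4669 edges, 1 enriched terms
stage II: 10 associations (10/10 planted recovered), merged gene set 30, network 266 nodes / 6350 edges, 1 enriched terms
stage III: 10 associations (10/10 planted recovered), merged gene set 26, network 267 nodes / 6421 edges, 0 enriched terms
stage IV: 12 associations (10/10 planted recovered), merged gene set 34, network 268 nodes / 6439 edges, 1 enriched terms

topology metrics (edge similarity is Jaccard vs stage I):
       nodes  edges  components  edge_similarity  diameter  centrality  betweenness  edge_density
stage
I        221   4669           1              NaN         4    0.002405    99.814480      0.192061
II       266   6350           1         0.496130         4    0.002003   118.857143      0.180167
III      267   6421           1         0.443822         5    0.001997   119.112360      0.180817
IV       268   6439           1         0.469507         5    0.001988   119.861940      0.179971
```

Each stage recovers all 10 of its planted pairs at *q* ≤ 0.05 with one or
two additional (false) discoveries — consistent with 5% FDR — and the
stage networks share only ~45–50% of their edges because the planted
associations, hence the seed gene sets, are stage-specific. The remaining
examples (`examples/01`–`05`) exercise each capability in isolation:
simulation, the association screen, enrichment, community detection, and
network comparison/alignment.

The same pipeline runs from the shell:

```sh
stagenet simulate --seed 42 --out cohort/
stagenet run --config pipeline.yaml   # paths + thresholds, see PipelineConfig
```

Real data drop in through the same readers: expression/stage TSVs, GFF3,
target TSV (`mirna<TAB>gene`), interaction TSV
(`gene_a<TAB>gene_b<TAB>confidence`), GO TSV (`term<TAB>category<TAB>gene`).

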