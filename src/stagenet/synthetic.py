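"""Synthetic data with planted ground truth for the full pipeline.

Emulates the five inputs the pipeline consumes — stage-labelled miRNA and
gene expression, feature coordinates, a validated-target map, a
confidence-scored interaction template, and a GO annotation — each with a
recoverable planted answer: linear miRNA->gene effects active in one stage,
a planted community partition, and one planted enriched term.

Expression is generated directly on a log2-like continuous scale
(Normal(6, 2) background) because the association model operates on
rank-normalized values, making count-level realism unnecessary.  Each
artifact draws from its own RNG stream spawned from the master seed, so
regenerating one file never shifts the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotations import FeatureAnnotation, FeatureAnnotationSet, write_gff3
from .enrichment import GOAnnotation, write_go_tsv, CATEGORIES
from .expression import ExpressionMatrix, STAGES
from .gene_sets import TargetDB, write_target_tsv
from .network import InteractionDB, write_interaction_tsv

__all__ = ["SyntheticConfig", "GroundTruth", "generate_expression", "generate_annotations",
           "generate_interactions", "generate_target_db", "generate_go", "write_all"]

# gap (bp) used to populate each same-chromosome distance bin, cycled over
# planted pairs, with every 7th pair placed cross-chromosome
_BIN_GAPS = (500_000, 5_000_000, 30_000_000, 70_000_000, 150_000_000, 210_000_000)

_STREAMS = {"expression": 0, "annotations": 1, "interactions": 2, "targets": 3, "go": 4}


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror a TCGA-like colon-cancer cohort: per-stage sample counts
    31/82/59/23 (stages I--IV), strong planted regressions (slope 2.0 on a
    background of sd 2, residual sd 0.5), a planted-partition interaction
    template, and a GO annotation with one planted term.
    """

    n_samples_per_stage: int | dict[str, int] = field(
        default_factory=lambda: {"I": 31, "II": 82, "III": 59, "IV": 23})
    n_mirnas: int = 50
    n_genes: int = 300
    n_planted_pairs: int = 40
    effect_size: float = 2.0       # regression slope beta
    noise_sd: float = 0.5          # residual sd sigma_eps
    shared_effects: bool = False   # plant every effect in all stages (control runs)
    bad_feature_frac: float = 0.05  # features carrying heavy entry-level missingness
    bad_entry_frac: float = 0.25    # missing rate inside a bad feature
    unknown_stage_frac: float = 0.02
    n_chromosomes: int = 5
    chrom_length: int = 240_000_000
    interaction_model: str = "planted-partition"  # or "scale-free"
    n_communities: int = 5
    p_in: float = 0.9
    p_out: float = 0.05
    confidence_range: tuple[float, float] = (0.1, 1.0)
    target_coverage: float = 0.5        # share of planted genes put in the target DB
    random_targets_per_mirna: int = 2
    n_go_terms: int = 50
    planted_term_overlap: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        counts = self.stage_counts()
        if min(counts.values()) <= 0 or self.n_mirnas <= 0 or self.n_genes <= 0:
            raise ValueError("sample and feature counts must be positive")
        if self.n_planted_pairs < 0 or self.n_planted_pairs > self.n_mirnas * self.n_genes:
            raise ValueError("n_planted_pairs must lie in [0, n_mirnas * n_genes]")
        if not (0 <= self.p_out < self.p_in <= 1):
            raise ValueError("need 0 <= p_out < p_in <= 1")
        lo, hi = self.confidence_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("confidence_range must be ordered within [0, 1]")
        if self.interaction_model not in {"planted-partition", "scale-free"}:
            raise ValueError(f"unknown interaction model {self.interaction_model!r}")
        if not (0 <= self.planted_term_overlap <= 1):
            raise ValueError("planted_term_overlap must lie in [0, 1]")

    def stage_counts(self) -> dict[str, int]:
        if isinstance(self.n_samples_per_stage, int):
            return {s: self.n_samples_per_stage for s in STAGES}
        return dict(self.n_samples_per_stage)

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],)))

    def mirna_ids(self) -> list[str]:
        return [f"mir-{i:04d}" for i in range(self.n_mirnas)]

    def gene_ids(self) -> list[str]:
        return [f"GENE{i:04d}" for i in range(self.n_genes)]


@dataclass
class GroundTruth:
    """What was planted, for downstream recovery checks."""

    planted_pairs: set[tuple[str, str]] = field(default_factory=set)
    stage_of_effect: dict[tuple[str, str], str] = field(default_factory=dict)
    planted_partition: dict[str, int] = field(default_factory=dict)
    planted_term: str | None = None

    def planted_genes(self) -> set[str]:
        return {g for _, g in self.planted_pairs}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_pairs": sorted([m, g] for m, g in self.planted_pairs),
            "stage_of_effect": {f"{m}|{g}": s for (m, g), s in sorted(self.stage_of_effect.items())},
            "planted_partition": self.planted_partition,
            "planted_term": self.planted_term,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def _planted_pairs(config: SyntheticConfig) -> list[tuple[str, str]]:
    """Deterministic pair choice: distinct genes, miRNAs cycled."""
    mirnas = config.mirna_ids()
    genes = config.gene_ids()
    return [(mirnas[i % len(mirnas)], genes[i]) for i in range(config.n_planted_pairs)]


def generate_expression(config: SyntheticConfig) -> tuple[ExpressionMatrix, ExpressionMatrix, GroundTruth]:
    """Stage-labelled miRNA and gene matrices with planted linear effects.

    Planted effects follow  x_g = alpha + beta * x_m + eps  within the
    designated stage's samples only (all stages when ``shared_effects``);
    elsewhere the gene row is background Normal(6, 2).  A configurable share
    of non-planted features carries heavy missingness to exercise the
    feature filter, and a share of samples gets an unknown stage label.
    """
    rng = config.rng("expression")
    counts = config.stage_counts()
    sample_ids: list[str] = []
    stage_map: dict[str, str] = {}
    for s in STAGES:
        for i in range(counts.get(s, 0)):
            sid = f"S{s}-{i:03d}"
            sample_ids.append(sid)
            stage_map[sid] = s
    n = len(sample_ids)
    n_unknown = int(round(config.unknown_stage_frac * n))
    if n_unknown:
        for sid in rng.choice(sample_ids, size=n_unknown, replace=False):
            stage_map[str(sid)] = "unknown"

    mirna_ids = config.mirna_ids()
    gene_ids = config.gene_ids()
    X = rng.normal(6.0, 2.0, size=(config.n_mirnas, n))
    Y = rng.normal(6.0, 2.0, size=(config.n_genes, n))

    pairs = _planted_pairs(config)
    truth = GroundTruth(planted_pairs=set(pairs))
    mirna_index = {m: i for i, m in enumerate(mirna_ids)}
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    stage_cycle = list(STAGES)
    sample_stage = np.array([stage_map[s] for s in sample_ids])
    for idx, (m, g) in enumerate(pairs):
        stage = stage_cycle[idx % len(stage_cycle)]
        truth.stage_of_effect[(m, g)] = "all" if config.shared_effects else stage
        mask = np.ones(n, bool) if config.shared_effects else (sample_stage == stage)
        xm = X[mirna_index[m], mask]
        eps = rng.normal(0.0, config.noise_sd, size=mask.sum())
        Y[gene_index[g], mask] = 6.0 + config.effect_size * (xm - 6.0) + eps

    # heavy missingness on a share of non-planted features (both matrices)
    planted_gene_rows = {gene_index[g] for _, g in pairs}
    planted_mirna_rows = {mirna_index[m] for m, _ in pairs}
    for mat, excluded in ((X, planted_mirna_rows), (Y, planted_gene_rows)):
        candidates = [i for i in range(mat.shape[0]) if i not in excluded]
        n_bad = int(round(config.bad_feature_frac * mat.shape[0]))
        if n_bad and candidates:
            bad = rng.choice(candidates, size=min(n_bad, len(candidates)), replace=False)
            for i in bad:
                holes = rng.random(n) < config.bad_entry_frac
                mat[i, holes] = np.nan

    mirna = ExpressionMatrix(pd.DataFrame(X, index=mirna_ids, columns=sample_ids), stage_map)
    gene = ExpressionMatrix(pd.DataFrame(Y, index=gene_ids, columns=sample_ids), dict(stage_map))
    return mirna, gene, truth


def generate_annotations(config: SyntheticConfig) -> FeatureAnnotationSet:
    """Coordinates on ``n_chromosomes`` chromosomes, 1-based closed intervals.

    Planted pairs are cycled through the same-chromosome distance bins (gaps
    0.5, 5, 30, 70, 150, 210 Mb) with every 7th pair placed
    cross-chromosome, so each distance bin of the association summary is
    populated; remaining features land uniformly.
    """
    rng = config.rng("annotations")
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    out = FeatureAnnotationSet()
    placed: set[str] = set()

    def add(fid: str, chrom: str, start: int, length: int, fclass: str) -> None:
        start = int(max(1, min(start, config.chrom_length - length)))
        out.add(FeatureAnnotation(id=fid, chrom=chrom, start=start, end=start + length - 1,
                                  strand="+" if rng.random() < 0.5 else "-",
                                  feature_class=fclass))
        placed.add(fid)

    for idx, (m, g) in enumerate(_planted_pairs(config)):
        if m in placed or g in placed:
            continue
        slot = idx % (len(_BIN_GAPS) + 1)
        chrom = chroms[idx % len(chroms)]
        mirna_len = 80
        gene_len = int(rng.integers(1_000, 100_000))
        if slot == len(_BIN_GAPS):  # cross-chromosome
            add(m, chrom, int(rng.integers(1, config.chrom_length // 2)), mirna_len, "miRNA")
            other = chroms[(idx + 1) % len(chroms)]
            add(g, other, int(rng.integers(1, config.chrom_length // 2)), gene_len, "gene")
        else:
            gap = _BIN_GAPS[slot]
            start = int(rng.integers(1, max(2, config.chrom_length - gap - gene_len - mirna_len - 2)))
            add(m, chrom, start, mirna_len, "miRNA")
            mirna_end = start + mirna_len - 1
            add(g, chrom, mirna_end + gap + 1, gene_len, "gene")

    for m in config.mirna_ids():
        if m not in placed:
            add(m, chroms[int(rng.integers(len(chroms)))],
                int(rng.integers(1, config.chrom_length - 200)), 80, "miRNA")
    for g in config.gene_ids():
        if g not in placed:
            add(g, chroms[int(rng.integers(len(chroms)))],
                int(rng.integers(1, config.chrom_length - 200_000)),
                int(rng.integers(1_000, 100_000)), "gene")
    return out


def generate_interactions(config: SyntheticConfig) -> tuple[InteractionDB, GroundTruth]:
    """Confidence-scored gene-gene template with planted communities.

    Planted-partition mode assigns genes round-robin to ``n_communities``
    blocks and draws within/between edges at ``p_in``/``p_out``; scale-free
    mode grows a preferential-attachment graph instead (no planted
    partition).  Confidences are Uniform over ``confidence_range``.
    """
    rng = config.rng("interactions")
    genes = config.gene_ids()
    db = InteractionDB()
    truth = GroundTruth()
    lo, hi = config.confidence_range

    if config.interaction_model == "planted-partition":
        part = {g: i % config.n_communities for i, g in enumerate(genes)}
        truth.planted_partition = part
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                p = config.p_in if part[genes[i]] == part[genes[j]] else config.p_out
                if rng.random() < p:
                    db.add(genes[i], genes[j], float(rng.uniform(lo, hi)))
    else:  # scale-free preferential attachment, 3 links per new node
        import networkx as nx
        g = nx.barabasi_albert_graph(len(genes), min(3, len(genes) - 1),
                                     seed=int(rng.integers(2**31)))
        for a, b in g.edges():
            db.add(genes[a], genes[b], float(rng.uniform(lo, hi)))
    return db, truth


def generate_target_db(config: SyntheticConfig) -> TargetDB:
    """Sparse miRNA->gene validated-target map.

    Includes ``target_coverage`` of each planted pair (so Step 2 retrieval
    finds planted genes) plus ``random_targets_per_mirna`` random genes per
    miRNA.
    """
    rng = config.rng("targets")
    db = TargetDB()
    genes = config.gene_ids()
    for m, g in _planted_pairs(config):
        if rng.random() < config.target_coverage:
            db.add(m, {g})
    for m in config.mirna_ids():
        k = config.random_targets_per_mirna
        if k:
            db.add(m, {str(x) for x in rng.choice(genes, size=min(k, len(genes)), replace=False)})
    return db


def generate_go(config: SyntheticConfig) -> tuple[GOAnnotation, GroundTruth]:
    """Term->gene annotation over the synthetic gene universe.

    Term sizes are log-uniform; one planted term draws a
    ``planted_term_overlap`` share of its members from the planted genes
    (the rest at random), so enrichment of the recovered gene set is itself
    recoverable.
    """
    rng = config.rng("go")
    genes = config.gene_ids()
    universe = set(genes)
    terms: dict[str, set[str]] = {}
    categories: dict[str, str] = {}
    truth = GroundTruth()

    planted_genes = sorted({g for _, g in _planted_pairs(config)})
    lo, hi = np.log(5), np.log(max(6, config.n_genes // 3))
    for t in range(config.n_go_terms):
        term = f"GO:{t + 1:07d}"
        size = int(round(np.exp(rng.uniform(lo, hi))))
        size = max(2, min(size, len(genes)))
        terms[term] = {str(x) for x in rng.choice(genes, size=size, replace=False)}
        categories[term] = CATEGORIES[t % len(CATEGORIES)]

    if planted_genes:
        term = f"GO:{config.n_go_terms + 1:07d}"
        n_overlap = int(round(config.planted_term_overlap * len(planted_genes)))
        members = set(rng.choice(planted_genes, size=n_overlap, replace=False).tolist()) if n_overlap else set()
        others = sorted(universe - set(planted_genes))
        n_fill = len(planted_genes) - n_overlap
        if n_fill and others:
            members |= {str(x) for x in rng.choice(others, size=min(n_fill, len(others)), replace=False)}
        if len(members) >= 2:
            terms[term] = members
            categories[term] = "biological process"
            truth.planted_term = term
    return GOAnnotation(terms=terms, categories=categories, universe=universe), truth


def write_all(config: SyntheticConfig, outdir: str | Path) -> GroundTruth:
    """Generate all five artifacts and write them under ``outdir``.

    Identical config + seed yields byte-identical files.  Returns the
    combined ground truth (also written as ``ground_truth.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mirna, gene, truth_expr = generate_expression(config)
    annotations = generate_annotations(config)
    interactions, truth_net = generate_interactions(config)
    targets = generate_target_db(config)
    go, truth_go = generate_go(config)

    mirna.to_tsv(outdir / "mirna.tsv")
    gene.to_tsv(outdir / "gene.tsv")
    mirna.stage_to_tsv(outdir / "stages.tsv")
    write_gff3(sorted(annotations, key=lambda f: (f.chrom, f.start, f.id)),
               outdir / "features.gff3")
    write_interaction_tsv(interactions, outdir / "interactions.tsv")
    write_target_tsv(targets, outdir / "targets.tsv")
    write_go_tsv(go, outdir / "go.tsv")

    truth = GroundTruth(
        planted_pairs=truth_expr.planted_pairs,
        stage_of_effect=truth_expr.stage_of_effect,
        planted_partition=truth_net.planted_partition,
        planted_term=truth_go.planted_term,
    )
    truth.to_json(outdir / "ground_truth.json")
    return truth
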