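"""End-to-end orchestration of the five-step pipeline.

Per stage: preprocess -> mass association -> target/associated gene merge ->
GO enrichment -> network construction (confidence filter, spin-glass
communities, hub expansion).  Cross-stage: distance-bin summary, Venn
overlap counts, the topology metric table, and pairwise alignment against a
reference stage with stage-specific subnetwork extraction.  A manifest
(config hash, seeds, version) and a Markdown report are written alongside
the TSV outputs; identical config and seeds reproduce identical bytes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import pandas as pd

from . import __version__
from .annotations import read_gff3
from .association import records_to_frame, run_stage, summarize_bins
from .compare import align, degree_histogram, metrics_table, stage_specific_subnetworks
from .communities import AnnealSchedule, spin_glass_communities
from .enrichment import enrich_stage, read_go_tsv
from .expression import STAGES, read_expression_tsv, read_stage_tsv
from .gene_sets import build_stage_set, compare_stage_overlap, read_target_tsv
from .network import build_preliminary, expand, most_connected, read_interaction_tsv, write_network_tsv
from .preprocess import EmptyCohortError, preprocess_stage

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_all"]


@dataclass
class PipelineConfig:
    """Inputs, thresholds and seeds for one pipeline run."""

    mirna_tsv: str
    gene_tsv: str
    stages_tsv: str
    gff3: str
    targets_tsv: str
    interactions_tsv: str
    go_tsv: str
    out_dir: str
    fdr: float = 0.05
    min_conf: float = 0.2
    gamma: float = 1.0
    top_k_hubs: int = 1
    enrichment_alpha: float = 0.05
    max_missing_frac: float = 0.10
    reference_stage: str = "I"
    edge_similarity_denominator: str = "jaccard"
    community_seed: int = 0
    alignment_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fdr", "min_conf", "enrichment_alpha"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")
        for name in ("mirna_tsv", "gene_tsv", "stages_tsv", "gff3", "targets_tsv",
                     "interactions_tsv", "go_tsv"):
            p = Path(getattr(self, name))
            if not p.is_file():
                raise FileNotFoundError(f"{name}: {p} does not exist")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


@dataclass
class PipelineResult:
    stages: list[str]
    records: dict[str, list] = field(default_factory=dict)
    gene_sets: dict[str, object] = field(default_factory=dict)
    enrichment: dict[str, list] = field(default_factory=dict)
    networks: dict[str, nx.Graph] = field(default_factory=dict)
    partitions: dict[str, object] = field(default_factory=dict)
    venn: dict[str, dict[str, int]] = field(default_factory=dict)
    metrics: pd.DataFrame | None = None
    subnetworks: dict[str, nx.Graph] = field(default_factory=dict)
    alignments: dict[str, object] = field(default_factory=dict)


def run_all(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline; see module docstring for the stages."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage_map = read_stage_tsv(config.stages_tsv)
    mirna_all = read_expression_tsv(config.mirna_tsv, stage_map)
    gene_all = read_expression_tsv(config.gene_tsv, stage_map)
    annotations = read_gff3(config.gff3)
    targets = read_target_tsv(config.targets_tsv)
    interactions = read_interaction_tsv(config.interactions_tsv)
    go = read_go_tsv(config.go_tsv)
    # background universe = annotated genes plus every measured gene
    go.universe |= set(gene_all.feature_ids)

    stages = [s for s in STAGES if any(v == s for v in stage_map.values())]
    result = PipelineResult(stages=[])
    all_records = []

    for stage in stages:
        try:
            mirna = preprocess_stage(mirna_all, stage, config.max_missing_frac)
            gene = preprocess_stage(gene_all, stage, config.max_missing_frac)
        except EmptyCohortError as exc:
            logger.warning("stage %s skipped during preprocessing: %s", stage, exc)
            continue
        shared = [s for s in mirna.sample_ids if s in set(gene.sample_ids)]
        mirna = mirna.subset_samples(shared)
        gene = gene.subset_samples(shared)
        try:
            records = run_stage(mirna, gene, stage, fdr=config.fdr, annotations=annotations)
        except ValueError as exc:
            logger.warning("stage %s skipped: %s", stage, exc)
            continue
        result.stages.append(stage)
        result.records[stage] = records
        all_records.extend(records)
        records_to_frame(records).to_csv(out / f"associations_{stage}.tsv", sep="\t", index=False)

        gs = build_stage_set(records, targets)
        result.gene_sets[stage] = gs

        try:
            enr = enrich_stage(gs, go, alpha=config.enrichment_alpha)
        except ValueError as exc:
            logger.warning("stage %s: enrichment skipped (%s)", stage, exc)
            enr = []
        result.enrichment[stage] = enr
        pd.DataFrame(
            [{"term": e.term, "category": e.category, "k": e.k, "n_query": e.n_query,
              "K": e.K, "N": e.N, "fold": e.fold, "p": e.p_value,
              "p_bonferroni": e.p_bonferroni, "direction": e.direction} for e in enr]
        ).to_csv(out / f"enrichment_{stage}.tsv", sep="\t", index=False)

        net = build_preliminary(gs, interactions, config.min_conf)
        if net.number_of_nodes() > 0:
            part = spin_glass_communities(net, gamma=config.gamma,
                                          schedule=AnnealSchedule(),
                                          seed=config.community_seed)
            result.partitions[stage] = part
            hubs = most_connected(part.membership, net, config.top_k_hubs)
            net = expand(net, hubs, interactions, config.min_conf)
        result.networks[stage] = net
        write_network_tsv(net, out / f"network_{stage}.tsv")
        nx.write_graphml(net, out / f"network_{stage}.graphml")

    if not result.stages:
        raise EmptyCohortError("no stage produced a usable cohort")

    # cross-stage summaries
    bins = summarize_bins(all_records)
    bins.to_csv(out / "distance_bins.tsv", sep="\t")

    if len(result.stages) >= 2:
        assoc_sets = {s: {(r.mirna_id, r.gene_id) for r in result.records[s]} for s in result.stages}
        mirna_sets = {s: {r.mirna_id for r in result.records[s]} for s in result.stages}
        gene_sets_ = {s: result.gene_sets[s].merged for s in result.stages}
        result.venn = {
            "associations": compare_stage_overlap(assoc_sets),
            "mirnas": compare_stage_overlap(mirna_sets),
            "genes": compare_stage_overlap(gene_sets_),
        }
        (out / "venn.json").write_text(json.dumps(result.venn, indent=1, sort_keys=True) + "\n")

    nonempty = {s: n for s, n in result.networks.items() if n.number_of_nodes() > 0}
    if nonempty:
        ref = config.reference_stage if config.reference_stage in nonempty else sorted(nonempty)[0]
        result.metrics = metrics_table(nonempty, reference=ref,
                                       denominator=config.edge_similarity_denominator)
        result.metrics.to_csv(out / "network_metrics.tsv", sep="\t", float_format="%.6g")
        hist_rows = []
        for s, n in nonempty.items():
            for deg, count in sorted(degree_histogram(n).items()):
                hist_rows.append({"stage": s, "degree": deg, "count": count})
        pd.DataFrame(hist_rows).to_csv(out / "degree_histograms.tsv", sep="\t", index=False)

        for s in sorted(nonempty):
            if s == ref:
                continue
            res = align(nonempty[ref], nonempty[s], anchor_labels=True, seed=config.alignment_seed)
            result.alignments[s] = res
            pd.DataFrame(sorted(res.correspondence.items()), columns=["node_ref", "node_other"]).to_csv(
                out / f"alignment_{ref}_vs_{s}.tsv", sep="\t", index=False)
            sub_ref, sub_s = stage_specific_subnetworks(nonempty[ref], nonempty[s], res)
            result.subnetworks.setdefault(ref, nx.Graph())
            result.subnetworks[s] = sub_s
            write_network_tsv(sub_s, out / f"subnetwork_specific_{s}.tsv")
        # reference-specific edges vs the union of the others
        if len(nonempty) >= 2:
            others = [s for s in sorted(nonempty) if s != ref]
            ref_specific = result.networks[ref].copy()
            for s in others:
                res = result.alignments[s]
                sub_ref, _ = stage_specific_subnetworks(ref_specific, nonempty[s], res)
                ref_specific = sub_ref
            result.subnetworks[ref] = ref_specific
            write_network_tsv(ref_specific, out / f"subnetwork_specific_{ref}.tsv")

    _write_manifest(config, result, out)
    _write_report(config, result, bins, out)
    return result


def _write_manifest(config: PipelineConfig, result: PipelineResult, out: Path) -> None:
    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stagenet_version": __version__,
        "stages_run": result.stages,
        "seeds": {"community": config.community_seed, "alignment": config.alignment_seed},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")


def _write_report(config: PipelineConfig, result: PipelineResult,
                  bins: pd.DataFrame, out: Path) -> None:
    lines = ["# Stage-specific miRNA-gene network report", ""]
    lines.append(f"Stages analysed: {', '.join(result.stages)}")
    lines.append("")
    lines.append("## Significant associations per distance bin")
    lines.append("")
    lines.append(bins.to_markdown())
    lines.append("")
    lines.append("## Gene sets and enrichment")
    lines.append("")
    lines.append("| stage | miRNAs | associated | targeted | merged | enriched terms |")
    lines.append("|---|---|---|---|---|---|")
    for s in result.stages:
        gs = result.gene_sets[s]
        lines.append(f"| {s} | {len(gs.source_mirnas)} | {len(gs.associated_genes)} | "
                     f"{len(gs.targeted_genes)} | {len(gs.merged)} | {len(result.enrichment[s])} |")
    lines.append("")
    if result.metrics is not None:
        lines.append("## Network topology metrics")
        lines.append("")
        lines.append(result.metrics.to_markdown())
        lines.append("")
    (out / "report.md").write_text("\n".join(lines) + "\n")
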