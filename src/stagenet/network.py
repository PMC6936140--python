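"""Integrated miRNA-gene network construction.

The merged gene set of a stage is overlaid on a confidence-scored
protein-interaction template (edges below the confidence cutoff, 0.2 by
default, are ignored), miRNA->gene association edges are added, communities
are detected with the spin-glass annealer, and the network is expanded by
pulling in the template neighbors of each community's most-connected gene
("hub"), closing over template edges among the final node set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .gene_sets import StageGeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionDB",
    "build_preliminary",
    "most_connected",
    "expand",
    "randomized_expand",
    "read_interaction_tsv",
    "write_interaction_tsv",
    "write_network_tsv",
    "read_network_tsv",
]

# Node attribute "kind" in {"gene", "mirna"}; edge attribute "kind" in
# {"ppi", "mirna_assoc"}.  Stage label stored in graph attribute "stage".


class InteractionDB:
    """Undirected gene-gene interactions with confidence scores in [0, 1].

    Edges are stored canonically (smaller id first); duplicates keep the
    higher confidence.  Self-loops are rejected.
    """

    def __init__(self) -> None:
        self._edges: dict[tuple[str, str], float] = {}
        self._adj: dict[str, dict[str, float]] = {}

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a < b else (b, a)

    def add(self, a: str, b: str, confidence: float) -> None:
        if a == b:
            raise ValueError(f"self-loop on {a!r}")
        if not (0.0 <= confidence <= 1.0):
            raise ValueError("confidence must lie in [0, 1]")
        key = self._key(a, b)
        prev = self._edges.get(key)
        if prev is None or confidence > prev:
            self._edges[key] = confidence
            self._adj.setdefault(a, {})[b] = confidence
            self._adj.setdefault(b, {})[a] = confidence

    def confidence(self, a: str, b: str) -> float | None:
        return self._edges.get(self._key(a, b))

    def neighbors(self, node: str, min_conf: float = 0.0) -> set[str]:
        return {v for v, c in self._adj.get(node, {}).items() if c >= min_conf}

    def edges(self):
        return self._edges.items()

    def genes(self) -> set[str]:
        return set(self._adj)

    def __len__(self) -> int:
        return len(self._edges)

    def __contains__(self, gene: str) -> bool:
        return gene in self._adj


def build_preliminary(genes: StageGeneSet, db: InteractionDB, min_conf: float = 0.2) -> nx.Graph:
    """Overlay the merged gene set on the interaction template.

    Nodes: merged genes present in the template, plus the stage's source
    miRNAs and any associated genes (kept even if absent from the template,
    so miRNA->gene association edges survive).  Edges: template edges with
    both endpoints in the merged set and confidence >= ``min_conf``
    (type "ppi"), plus the stage's significant associations
    (type "mirna_assoc").
    """
    net = nx.Graph(stage=genes.stage)
    merged = genes.merged
    in_template = sorted(g for g in merged if g in db)
    for g in in_template:
        net.add_node(g, kind="gene")
    for (a, b), conf in db.edges():
        if conf >= min_conf and a in merged and b in merged:
            if a in net and b in net:
                net.add_edge(a, b, kind="ppi", confidence=conf)
    for rec in genes.associations:
        net.add_node(rec.mirna_id, kind="mirna")
        net.add_node(rec.gene_id, kind="gene")
        net.add_edge(rec.mirna_id, rec.gene_id, kind="mirna_assoc")
    if net.number_of_nodes() == 0:
        logger.warning("build_preliminary[%s]: empty network", genes.stage)
    return net


def most_connected(partition: dict[str, int], net: nx.Graph, top_k: int = 1) -> set[str]:
    """The ``top_k`` gene nodes of each community by within-community degree.

    miRNA nodes are never hubs; a community with no gene nodes contributes
    none.  Degree ties break lexicographically by node id.
    """
    missing = set(net.nodes) - set(partition)
    if missing:
        raise ValueError(f"partition does not cover the network: {sorted(missing)[:5]} ...")
    by_comm: dict[int, list[str]] = {}
    for node, comm in partition.items():
        by_comm.setdefault(comm, []).append(node)
    hubs: set[str] = set()
    for comm, members in by_comm.items():
        member_set = set(members)
        genes = [n for n in members if net.nodes[n].get("kind") == "gene"]
        if not genes:
            logger.info("most_connected: community %s has no gene nodes", comm)
            continue
        within_deg = {
            g: sum(1 for nb in net.neighbors(g) if nb in member_set) for g in genes
        }
        ranked = sorted(genes, key=lambda g: (-within_deg[g], g))
        hubs.update(ranked[:top_k])
    return hubs


def expand(net: nx.Graph, hubs: set[str], db: InteractionDB, min_conf: float = 0.2) -> nx.Graph:
    """Grow the network by each hub's template neighbors, then close over
    template edges among the final node set.

    Node and edge sets only grow ("downstream genes" are first neighbors in
    the undirected template).
    """
    unknown = hubs - set(net.nodes)
    if unknown:
        raise ValueError(f"hubs not in network: {sorted(unknown)[:5]}")
    out = net.copy()
    for hub in sorted(hubs):
        for nb in sorted(db.neighbors(hub, min_conf)):
            if nb not in out:
                out.add_node(nb, kind="gene")
    nodes = set(out.nodes)
    for (a, b), conf in db.edges():
        if conf >= min_conf and a in nodes and b in nodes and not out.has_edge(a, b):
            out.add_edge(a, b, kind="ppi", confidence=conf)
    return out


def randomized_expand(net: nx.Graph, db: InteractionDB, n_add: int, seed: int,
                      min_conf: float = 0.2) -> nx.Graph:
    """Randomized network expansion (off by default in the pipeline).

    Adds ``n_add`` new gene nodes sampled with probability proportional to
    their template connectivity to the current network, mimicking
    connectivity-guided randomized growth.  Candidates with zero
    connectivity are never chosen.
    """
    if n_add < 0:
        raise ValueError("n_add must be >= 0")
    rng = np.random.default_rng(seed)
    out = net.copy()
    for _ in range(n_add):
        nodes = set(out.nodes)
        candidates: list[str] = []
        weights: list[int] = []
        for g in sorted(db.genes() - nodes):
            conn = len(db.neighbors(g, min_conf) & nodes)
            if conn > 0:
                candidates.append(g)
                weights.append(conn)
        if not candidates:
            break
        probs = np.asarray(weights, float)
        choice = candidates[int(rng.choice(len(candidates), p=probs / probs.sum()))]
        out.add_node(choice, kind="gene")
        for nb in sorted(db.neighbors(choice, min_conf) & nodes):
            out.add_edge(choice, nb, kind="ppi", confidence=db.confidence(choice, nb))
    return out


def read_interaction_tsv(path: str | Path) -> InteractionDB:
    db = InteractionDB()
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("gene_a"):
            raise ValueError("interaction TSV must start with 'gene_a<TAB>gene_b<TAB>confidence'")
        for line in fh:
            a, b, conf = line.rstrip("\n").split("\t")
            db.add(a, b, float(conf))
    return db


def write_interaction_tsv(db: InteractionDB, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tconfidence\n")
        for (a, b), conf in sorted(db.edges()):
            fh.write(f"{a}\t{b}\t{conf:.6g}\n")


def write_network_tsv(net: nx.Graph, path: str | Path) -> None:
    """Edge list with node- and edge-type columns (isolated nodes appended
    with an empty partner)."""
    with open(path, "w") as fh:
        fh.write("node_a\tkind_a\tnode_b\tkind_b\tedge_kind\n")
        for a, b, data in sorted(net.edges(data=True)):
            fh.write(
                f"{a}\t{net.nodes[a].get('kind', 'gene')}\t"
                f"{b}\t{net.nodes[b].get('kind', 'gene')}\t{data.get('kind', 'ppi')}\n"
            )
        for n in sorted(net.nodes):
            if net.degree(n) == 0:
                fh.write(f"{n}\t{net.nodes[n].get('kind', 'gene')}\t\t\t\n")


def read_network_tsv(path: str | Path) -> nx.Graph:
    net = nx.Graph()
    with open(path) as fh:
        fh.readline()
        for line in fh:
            a, ka, b, kb, ek = line.rstrip("\n").split("\t")
            net.add_node(a, kind=ka)
            if b:
                net.add_node(b, kind=kb)
                net.add_edge(a, b, kind=ek)
    return net
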