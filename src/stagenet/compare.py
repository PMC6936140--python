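"""Cross-stage network comparison: topology metrics, degree distributions,
and adjacency-based network alignment.

Metrics follow unweighted hop semantics: diameter is the longest shortest
path within any connected component; closeness of a node is the reciprocal
of its summed distances to the nodes of its component (0 for isolated
nodes); betweenness is unnormalized Brandes betweenness with each unordered
pair counted once.  Alignment is a similarity-propagation scheme over the
two adjacency matrices with greedy injective extraction and a deterministic
2-opt refinement of the objective  sum_ij A_ij B_{pi(i) pi(j)}.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "NetworkMetrics",
    "AlignmentResult",
    "edge_similarity",
    "metrics",
    "degree_histogram",
    "align",
    "stage_specific_subnetworks",
    "metrics_table",
]


@dataclass
class NetworkMetrics:
    stage: str
    n_nodes: int
    n_edges: int
    n_components: int
    diameter: int
    mean_closeness: float
    mean_betweenness: float
    edge_density: float
    degree_histogram: dict[int, int]
    edge_similarity_vs_ref: float | None = None  # NA for the reference stage


@dataclass
class AlignmentResult:
    correspondence: dict[str, str]  # injective partial map net_a -> net_b
    objective: float                # sum_ij A_ij B_{pi(i) pi(j)} (ordered pairs)
    common_nodes: set[str]          # shared labels


def _canon_edges(net: nx.Graph) -> set[tuple[str, str]]:
    return {(u, v) if u < v else (v, u) for u, v in net.edges()}


def edge_similarity(a: nx.Graph, b: nx.Graph, denominator: str = "jaccard") -> float:
    """Proportion of common edges between two networks.

    ``denominator="jaccard"`` gives |Ea ∩ Eb| / |Ea ∪ Eb|;
    ``denominator="first"`` gives the asymmetric |Ea ∩ Eb| / |Ea| (share of
    the first network's edges found in the second).  Two empty edge sets
    compare as 1.
    """
    ea, eb = _canon_edges(a), _canon_edges(b)
    inter = len(ea & eb)
    if denominator == "first":
        return inter / len(ea) if ea else 1.0
    union = len(ea | eb)
    return inter / union if union else 1.0


def degree_histogram(net: nx.Graph) -> dict[int, int]:
    hist: dict[int, int] = {}
    for _, d in net.degree():
        hist[d] = hist.get(d, 0) + 1
    return hist


def metrics(net: nx.Graph, stage: str | None = None) -> NetworkMetrics:
    """Topology metric suite of one network (unweighted hops)."""
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("cannot compute metrics of an empty network")
    m = net.number_of_edges()
    comps = list(nx.connected_components(net))
    diameter = 0
    closeness_sum = 0.0
    for comp in comps:
        sub = net.subgraph(comp)
        for v in comp:
            dists = nx.single_source_shortest_path_length(sub, v)
            total = sum(dists.values())
            ecc = max(dists.values())
            diameter = max(diameter, ecc)
            closeness_sum += (1.0 / total) if total > 0 else 0.0
    bet = nx.betweenness_centrality(net, normalized=False)
    return NetworkMetrics(
        stage=stage or str(net.graph.get("stage", "")),
        n_nodes=n,
        n_edges=m,
        n_components=len(comps),
        diameter=int(diameter),
        mean_closeness=closeness_sum / n,
        mean_betweenness=float(np.mean(list(bet.values()))),
        edge_density=(2.0 * m / (n * (n - 1))) if n > 1 else 0.0,
        degree_histogram=degree_histogram(net),
    )


def metrics_table(nets: dict[str, nx.Graph], reference: str | None = None,
                  denominator: str = "jaccard") -> pd.DataFrame:
    """Per-stage metric table with edge similarity against a reference stage
    (the first stage by sort order when unspecified)."""
    stages = sorted(nets)
    reference = reference or stages[0]
    rows = []
    for s in stages:
        nm = metrics(nets[s], stage=s)
        if s != reference:
            nm.edge_similarity_vs_ref = edge_similarity(nets[reference], nets[s], denominator)
        rows.append({
            "stage": s,
            "nodes": nm.n_nodes,
            "edges": nm.n_edges,
            "components": nm.n_components,
            "edge_similarity": nm.edge_similarity_vs_ref if nm.edge_similarity_vs_ref is not None else float("nan"),
            "diameter": nm.diameter,
            "centrality": nm.mean_closeness,
            "betweenness": nm.mean_betweenness,
            "edge_density": nm.edge_density,
        })
    return pd.DataFrame(rows).set_index("stage")


def _objective(A: np.ndarray, B: np.ndarray, perm: np.ndarray) -> float:
    """sum over ordered pairs of matched nodes of A_ij * B_{pi(i) pi(j)};
    perm[i] = -1 marks an unmatched node."""
    idx = np.where(perm >= 0)[0]
    if idx.size == 0:
        return 0.0
    return float(A[np.ix_(idx, idx)].ravel() @ B[np.ix_(perm[idx], perm[idx])].ravel())


def align(a: nx.Graph, b: nx.Graph, iters: int = 30, anchor_labels: bool = True,
          seed: int = 0) -> AlignmentResult:
    """Align two networks from their adjacency matrices.

    A node-similarity matrix seeded from label identity (when
    ``anchor_labels``) and degree similarity is propagated through
    ``S <- normalize(A S B + prior)``; an injective correspondence is
    extracted greedily by descending similarity and refined by deterministic
    2-opt swaps of the non-anchored images.  With anchoring on, shared
    labels always map to themselves.
    """
    na, nb = sorted(a.nodes), sorted(b.nodes)
    if not na or not nb:
        return AlignmentResult({}, 0.0, set(a.nodes) & set(b.nodes))
    ia = {v: i for i, v in enumerate(na)}
    ib = {v: i for i, v in enumerate(nb)}
    A = nx.to_numpy_array(a, nodelist=na, dtype=np.float64, weight=None)
    B = nx.to_numpy_array(b, nodelist=nb, dtype=np.float64, weight=None)
    deg_a = A.sum(axis=1)
    deg_b = B.sum(axis=1)

    prior = 1.0 / (1.0 + np.abs(deg_a[:, None] - deg_b[None, :]))
    common = set(na) & set(nb)
    if anchor_labels:
        for v in common:
            prior[ia[v], ib[v]] += 2.0
    S = prior.copy()
    for _ in range(iters):
        S = A @ S @ B + 0.5 * prior
        norm = np.max(S)
        if norm > 0:
            S /= norm

    rng = np.random.default_rng(seed)
    perm = np.full(len(na), -1, dtype=np.int64)
    used_b = np.zeros(len(nb), dtype=bool)
    if anchor_labels:
        for v in common:
            perm[ia[v]] = ib[v]
            used_b[ib[v]] = True
    # greedy extraction, deterministic tie order
    order = np.argsort(-S, axis=None, kind="stable")
    free_a = int((perm < 0).sum())
    budget = min(free_a, int((~used_b).sum()))
    for flat in order:
        if budget == 0:
            break
        i, j = divmod(int(flat), len(nb))
        if perm[i] < 0 and not used_b[j]:
            perm[i] = j
            used_b[j] = True
            budget -= 1

    # 2-opt refinement over non-anchored images
    anchored = np.zeros(len(na), dtype=bool)
    if anchor_labels:
        for v in common:
            anchored[ia[v]] = True
    movable = [i for i in range(len(na)) if perm[i] >= 0 and not anchored[i]]
    rng.shuffle(movable)
    best_obj = _objective(A, B, perm)
    for _ in range(20):
        improved = False
        for x in range(len(movable)):
            for y in range(x + 1, len(movable)):
                i, k = movable[x], movable[y]
                perm[i], perm[k] = perm[k], perm[i]
                obj = _objective(A, B, perm)
                if obj > best_obj + 1e-9:
                    best_obj = obj
                    improved = True
                else:
                    perm[i], perm[k] = perm[k], perm[i]
        if not improved:
            break

    correspondence = {na[i]: nb[perm[i]] for i in range(len(na)) if perm[i] >= 0}
    return AlignmentResult(correspondence, best_obj, common)


def stage_specific_subnetworks(a: nx.Graph, b: nx.Graph,
                               result: AlignmentResult) -> tuple[nx.Graph, nx.Graph]:
    """Induced subgraphs of the edges absent from the counterpart network.

    An edge (u, v) of ``a`` is shared when its images under the
    correspondence form an edge of ``b`` (and symmetrically via the inverse
    map).  Each output is restricted to connected components containing at
    least one miRNA node, mirroring miRNA-anchored stage-specific
    subnetworks.
    """
    fwd = result.correspondence
    inv = {v: k for k, v in fwd.items()}

    def specific(src: nx.Graph, dst: nx.Graph, mapping: dict[str, str]) -> nx.Graph:
        edges = []
        for u, v in src.edges():
            mu, mv = mapping.get(u), mapping.get(v)
            if mu is None or mv is None or not dst.has_edge(mu, mv):
                edges.append((u, v))
        sub = nx.Graph()
        for u, v in edges:
            sub.add_node(u, **src.nodes[u])
            sub.add_node(v, **src.nodes[v])
            sub.add_edge(u, v, **src.edges[u, v])
        keep: set[str] = set()
        for comp in nx.connected_components(sub):
            if any(sub.nodes[n].get("kind") == "mirna" for n in comp):
                keep |= comp
        return sub.subgraph(keep).copy()

    return specific(a, b, fwd), specific(b, a, inv)
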