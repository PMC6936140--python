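"""GO over-representation analysis of per-stage merged gene sets.

One two-sided Fisher exact test per term against a fixed background
universe, Bonferroni-corrected within each GO category (molecular function /
biological process / cellular component), with terms labelled enriched or
depleted by their fold change.  Annotations are taken as given: no GO-graph
ancestor propagation is performed (a reader for propagated annotation files
can be slotted in where the TSV reader sits).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from scipy import stats

from .gene_sets import StageGeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "GOAnnotation",
    "EnrichmentResult",
    "fisher_term",
    "enrich_stage",
    "read_go_tsv",
    "write_go_tsv",
]

CATEGORIES = ("molecular function", "biological process", "cellular component")


@dataclass
class GOAnnotation:
    """Term -> gene annotation over a background universe."""

    terms: dict[str, set[str]] = field(default_factory=dict)          # term id -> members
    categories: dict[str, str] = field(default_factory=dict)          # term id -> category
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for term, members in self.terms.items():
            if not members <= self.universe:
                raise ValueError(f"term {term}: members outside the universe")


@dataclass
class EnrichmentResult:
    term: str
    category: str
    k: int          # |query ∩ term|
    n_query: int
    K: int          # term size
    N: int          # universe size
    fold: float
    p_value: float
    p_bonferroni: float
    direction: str  # enriched | depleted


def fisher_term(k: int, n_query: int, K: int, N: int) -> tuple[float, str, float]:
    """Two-sided Fisher exact p for a query/term 2x2 table.

    Table: [[k, n_query-k], [K-k, N-K-n_query+k]].  Fold change is
    (k/n_query)/(K/N); direction 'enriched' when fold >= 1.
    """
    if not (0 <= k <= min(n_query, K) <= N):
        raise ValueError("inconsistent margins: need 0 <= k <= min(n_query, K) <= N")
    if N - K - n_query + k < 0:
        raise ValueError("inconsistent margins: table cell below zero")
    table = [[k, n_query - k], [K - k, N - K - n_query + k]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    expected = K * n_query / N if N else 0.0
    fold = (k / expected) if expected > 0 else float("inf") if k else 1.0
    direction = "enriched" if fold >= 1.0 else "depleted"
    return float(p), direction, float(fold)


def enrich_stage(genes: StageGeneSet, go: GOAnnotation, alpha: float = 0.05,
                 per_category_bonferroni: bool = True) -> list[EnrichmentResult]:
    """Test every term against the stage's merged gene set.

    Returns results significant after Bonferroni (per category by default)
    at ``alpha``, sorted by corrected p.  Query genes outside the universe
    are dropped with a warning.
    """
    query = genes.merged & go.universe
    outside = genes.merged - go.universe
    if outside:
        logger.warning("enrich_stage[%s]: %d query genes outside the universe dropped",
                       genes.stage, len(outside))
    if not query:
        raise ValueError(f"stage {genes.stage}: query does not intersect the universe")
    N = len(go.universe)
    n_query = len(query)
    n_tests_by_cat: dict[str, int] = {}
    for term in go.terms:
        cat = go.categories.get(term, "biological process")
        n_tests_by_cat[cat] = n_tests_by_cat.get(cat, 0) + 1
    n_tests_total = len(go.terms)

    results: list[EnrichmentResult] = []
    for term, members in go.terms.items():
        cat = go.categories.get(term, "biological process")
        K = len(members)
        k = len(query & members)
        p, direction, fold = fisher_term(k, n_query, K, N)
        m = n_tests_by_cat[cat] if per_category_bonferroni else n_tests_total
        p_bonf = min(1.0, p * m)
        if p_bonf <= alpha:
            results.append(EnrichmentResult(term, cat, k, n_query, K, N, fold, p, p_bonf, direction))
    results.sort(key=lambda r: (r.p_bonferroni, r.p_value, r.term))
    return results


def read_go_tsv(path: str | Path, universe: set[str] | None = None) -> GOAnnotation:
    """Read a term<TAB>category<TAB>gene annotation file.

    If no universe is given, the union of all annotated genes is used.
    """
    terms: dict[str, set[str]] = {}
    categories: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("term"):
            raise ValueError("GO TSV must start with a 'term<TAB>category<TAB>gene' header")
        for line in fh:
            term, cat, gene = line.rstrip("\n").split("\t")
            terms.setdefault(term, set()).add(gene)
            categories[term] = cat
    if universe is None:
        universe = set().union(*terms.values()) if terms else set()
    return GOAnnotation(terms=terms, categories=categories, universe=set(universe))


def write_go_tsv(go: GOAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("term\tcategory\tgene\n")
        for term in sorted(go.terms):
            cat = go.categories.get(term, "biological process")
            for gene in sorted(go.terms[term]):
                fh.write(f"{term}\t{cat}\t{gene}\n")
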