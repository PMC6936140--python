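"""Merging associated and targeted genes into per-stage gene sets.

For each stage the miRNAs carrying at least one significant association are
looked up in a validated-target database (miRTarBase-style); the union of
their targets with the associated genes is the stage's "target and
associated gene set", the seed set for network construction.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .association import AssociationRecord

logger = logging.getLogger(__name__)

__all__ = [
    "TargetDB",
    "StageGeneSet",
    "lookup_targets",
    "build_stage_set",
    "compare_stage_overlap",
    "read_target_tsv",
    "write_target_tsv",
]


class TargetDB:
    """miRNA id -> set of validated target gene ids.

    Lookups are case-insensitive to absorb miRBase/miRTarBase naming
    inconsistencies (hsa-mir vs hsa-miR); an optional translation table maps
    aliases onto canonical ids before matching.
    """

    def __init__(self, mapping: dict[str, set[str]] | None = None,
                 aliases: dict[str, str] | None = None) -> None:
        self._map: dict[str, set[str]] = {}
        self._aliases = {k.lower(): v for k, v in (aliases or {}).items()}
        for mirna, genes in (mapping or {}).items():
            self.add(mirna, genes)

    def _canon(self, mirna_id: str) -> str:
        key = mirna_id.lower()
        return self._aliases.get(key, key)

    def add(self, mirna_id: str, genes) -> None:
        self._map.setdefault(self._canon(mirna_id), set()).update(genes)

    def get(self, mirna_id: str) -> set[str]:
        return set(self._map.get(self._canon(mirna_id), set()))

    def __contains__(self, mirna_id: str) -> bool:
        return self._canon(mirna_id) in self._map

    def __len__(self) -> int:
        return len(self._map)

    def mirnas(self) -> list[str]:
        return list(self._map)


@dataclass
class StageGeneSet:
    """The per-stage merged gene set and its provenance."""

    stage: str
    associated_genes: set[str] = field(default_factory=set)
    targeted_genes: set[str] = field(default_factory=set)
    source_mirnas: set[str] = field(default_factory=set)
    associations: list[AssociationRecord] = field(default_factory=list)

    @property
    def merged(self) -> set[str]:
        return self.associated_genes | self.targeted_genes


def lookup_targets(mirnas: set[str], db: TargetDB) -> set[str]:
    """Union of target sets of the given miRNAs; absent miRNAs contribute
    nothing and are logged."""
    out: set[str] = set()
    for m in sorted(mirnas):
        if m in db:
            out |= db.get(m)
        else:
            logger.info("lookup_targets: miRNA %s not in target database", m)
    return out


def build_stage_set(records: list[AssociationRecord], db: TargetDB) -> StageGeneSet:
    """Steps 2-3: merge associated genes with validated targets of the
    stage's significant miRNAs."""
    stages = {r.stage for r in records}
    if len(stages) > 1:
        raise ValueError(f"records span multiple stages: {sorted(stages)}")
    stage = stages.pop() if stages else "?"
    if not records:
        logger.warning("build_stage_set: no significant associations for stage %s", stage)
        return StageGeneSet(stage=stage)
    mirnas = {r.mirna_id for r in records}
    associated = {r.gene_id for r in records}
    targeted = lookup_targets(mirnas, db)
    return StageGeneSet(
        stage=stage,
        associated_genes=associated,
        targeted_genes=targeted,
        source_mirnas=mirnas,
        associations=list(records),
    )


def compare_stage_overlap(sets: dict[str, set]) -> dict[str, int]:
    """Venn region counts over >= 2 labelled collections.

    Keys are '&'-joined sorted label subsets (e.g. ``"I&II"``); each element
    of the union is counted in exactly one region, so region counts sum to
    the union cardinality.
    """
    if len(sets) < 2:
        raise ValueError("need at least two collections to compare")
    labels = sorted(sets)
    regions: dict[str, int] = {}
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            regions["&".join(combo)] = 0
    for element in set().union(*sets.values()):
        membership = tuple(l for l in labels if element in sets[l])
        regions["&".join(membership)] += 1
    return regions


def read_target_tsv(path: str | Path) -> TargetDB:
    db = TargetDB()
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("mirna"):
            raise ValueError("target TSV must start with a 'mirna<TAB>gene' header")
        for line in fh:
            mirna, gene = line.rstrip("\n").split("\t")
            db.add(mirna, {gene})
    return db


def write_target_tsv(db: TargetDB, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna\tgene\n")
        for mirna in sorted(db.mirnas()):
            for gene in sorted(db.get(mirna)):
                fh.write(f"{mirna}\t{gene}\n")
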