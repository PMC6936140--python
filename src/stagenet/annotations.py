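"""Feature coordinates: a minimal GFF3 dialect for miRNAs and genes.

Coordinates are 1-based closed intervals, as in GFF3.  Only the fields the
distance analysis needs are modelled (seqid, type, start, end, strand, ID).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

__all__ = ["FeatureAnnotation", "FeatureAnnotationSet", "write_gff3", "read_gff3"]

_CLASSES = ("miRNA", "gene")


@dataclass(frozen=True)
class FeatureAnnotation:
    """One annotated feature on the genome."""

    id: str
    chrom: str
    start: int  # 1-based, inclusive
    end: int    # inclusive
    strand: str = "+"
    feature_class: str = "gene"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.id}: start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError(f"{self.id}: coordinates are 1-based")
        if self.feature_class not in _CLASSES:
            raise ValueError(f"{self.id}: unknown feature class {self.feature_class!r}")


class FeatureAnnotationSet:
    """Lookup table id -> :class:`FeatureAnnotation`."""

    def __init__(self, features: Iterable[FeatureAnnotation] = ()) -> None:
        self._by_id: dict[str, FeatureAnnotation] = {}
        for f in features:
            self.add(f)

    def add(self, f: FeatureAnnotation) -> None:
        if f.id in self._by_id:
            raise ValueError(f"duplicate feature id {f.id!r}")
        self._by_id[f.id] = f

    def get(self, feature_id: str) -> FeatureAnnotation | None:
        return self._by_id.get(feature_id)

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._by_id

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self):
        return iter(self._by_id.values())

    def ids(self) -> list[str]:
        return list(self._by_id)


def write_gff3(features: Iterable[FeatureAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            source = "stagenet"
            ftype = "miRNA" if f.feature_class == "miRNA" else "gene"
            fh.write(
                f"{f.chrom}\t{source}\t{ftype}\t{f.start}\t{f.end}\t.\t{f.strand}\t.\tID={f.id}\n"
            )


def read_gff3(path: str | Path) -> FeatureAnnotationSet:
    out = FeatureAnnotationSet()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            chrom, _source, ftype, start, end, _score, strand, _phase, attrs = cols
            fid = None
            for item in attrs.split(";"):
                if item.startswith("ID="):
                    fid = item[3:]
                    break
            if fid is None:
                raise ValueError(f"GFF3 line without ID attribute: {line!r}")
            fclass = "miRNA" if ftype == "miRNA" else "gene"
            out.add(
                FeatureAnnotation(
                    id=fid, chrom=chrom, start=int(start), end=int(end),
                    strand=strand, feature_class=fclass,
                )
            )
    return out
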