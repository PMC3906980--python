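"""Strand-aware genomic annotation container with GFF3 I/O.

Coordinates are 1-based inclusive throughout (TAIR/GFF3 convention).
Feature classes used by the classifier:

    gene (container span), protein_coding_exon, protein_coding_intron,
    five_prime_UTR, three_prime_UTR, miRNA_stem_loop, mature_miRNA,
    tasiRNA_locus, rRNA, tRNA, pseudogene, transposable_element

Introns are not written to GFF3 (TAIR does not); they are derived on load
as the gaps between a transcript's exons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import pandas as pd
from intervaltree import IntervalTree

GFF3_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]

# GFF3 feature type -> internal class
_TYPE_MAP = {
    "gene": "gene",
    "exon": "protein_coding_exon",
    "five_prime_UTR": "five_prime_UTR",
    "three_prime_UTR": "three_prime_UTR",
    "miRNA_primary_transcript": "miRNA_stem_loop",
    "miRNA": "mature_miRNA",
    "tasiRNA_locus": "tasiRNA_locus",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "pseudogene": "pseudogene",
    "transposable_element": "transposable_element",
}
_CLASS_TO_TYPE = {v: k for k, v in _TYPE_MAP.items()}
_CLASS_TO_TYPE["protein_coding_intron"] = "intron"

FEATURE_CLASSES = tuple(_TYPE_MAP.values()) + ("protein_coding_intron",)


@dataclass(frozen=True)
class Feature:
    """One strand-aware genomic feature, 1-based inclusive span."""

    feature_id: str
    feature_class: str
    chrom: str
    start: int
    end: int
    strand: str
    gene_id: Optional[str] = None  # parent gene linkage

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.feature_id}: start {self.start} > end {self.end}")
        if self.strand not in "+-":
            raise ValueError(f"{self.feature_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlap_length(self, start: int, end: int) -> int:
        return max(0, min(self.end, end) - max(self.start, start) + 1)


class AnnotationSet:
    """Indexed collection of features supporting strand-aware overlap queries."""

    def __init__(self, features: Iterable[Feature]):
        self.features: list[Feature] = list(features)
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        self._any_strand: dict[str, IntervalTree] = {}
        for f in self.features:
            key = (f.chrom, f.strand)
            self._trees.setdefault(key, IntervalTree())
            # IntervalTree is half-open; store [start, end+1)
            self._trees[key].addi(f.start, f.end + 1, f)
            self._any_strand.setdefault(f.chrom, IntervalTree())
            self._any_strand[f.chrom].addi(f.start, f.end + 1, f)

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[Feature]:
        return iter(self.features)

    def overlapping(self, chrom: str, start: int, end: int,
                    strand: Optional[str] = None) -> list[Feature]:
        """Features overlapping [start, end] by >= 1 base; strand=None ignores strand."""
        tree = (self._any_strand.get(chrom) if strand is None
                else self._trees.get((chrom, strand)))
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.overlap(start, end + 1)),
                      key=lambda f: (f.start, f.end, f.feature_id))

    def of_class(self, *classes: str) -> list[Feature]:
        want = set(classes)
        return [f for f in self.features if f.feature_class in want]

    @property
    def genes(self) -> list[Feature]:
        return self.of_class("gene")


def derive_introns(exons: list[Feature], gene_id: str) -> list[Feature]:
    """Introns are the gaps between consecutive exons of one gene."""
    out = []
    exons = sorted(exons, key=lambda f: f.start)
    for i, (a, b) in enumerate(zip(exons, exons[1:]), start=1):
        if b.start > a.end + 1:
            out.append(Feature(
                feature_id=f"{gene_id}.intron{i}",
                feature_class="protein_coding_intron",
                chrom=a.chrom, start=a.end + 1, end=b.start - 1,
                strand=a.strand, gene_id=gene_id,
            ))
    return out


def _fmt_attrs(f: Feature) -> str:
    attrs = [f"ID={f.feature_id}"]
    if f.gene_id and f.gene_id != f.feature_id:
        attrs.append(f"Parent={f.gene_id}")
    return ";".join(attrs)


def _parse_attrs(s: str) -> dict[str, str]:
    out = {}
    for part in s.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def write_gff3(ann: AnnotationSet, path) -> None:
    rows = []
    for f in sorted(ann.features, key=lambda f: (f.chrom, f.start, f.end, f.feature_id)):
        if f.feature_class == "protein_coding_intron":
            continue  # derived on load
        rows.append((f.chrom, "nitroseq", _CLASS_TO_TYPE[f.feature_class],
                     f.start, f.end, ".", f.strand, ".", _fmt_attrs(f)))
    df = pd.DataFrame(rows, columns=GFF3_COLUMNS)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_gff3(path) -> AnnotationSet:
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=GFF3_COLUMNS,
                     dtype={"seqid": str})
    feats: list[Feature] = []
    exons_by_gene: dict[str, list[Feature]] = {}
    for row in df.itertuples(index=False):
        ftype = row.type
        if ftype == "mRNA":
            continue  # transcript container; gene span carries the same info here
        cls = _TYPE_MAP.get(ftype)
        if cls is None:
            continue
        attrs = _parse_attrs(row.attributes)
        fid = attrs.get("ID", f"{ftype}:{row.seqid}:{row.start}")
        parent = attrs.get("Parent")
        gene_id = parent.split(".")[0] if parent else (
            fid if cls == "gene" else None)
        f = Feature(fid, cls, str(row.seqid), int(row.start), int(row.end),
                    str(row.strand), gene_id)
        feats.append(f)
        if cls == "protein_coding_exon" and gene_id:
            exons_by_gene.setdefault(gene_id, []).append(f)
    for gid, exons in exons_by_gene.items():
        feats.extend(derive_introns(exons, gid))
    return AnnotationSet(feats)
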