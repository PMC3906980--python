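"""miRNA-locus genomic-context annotation and novelty flagging.

Loci arrive from an external hairpin predictor (tabular) or from packaged
reference tables; this module assigns each locus a genomic context —
known stem-loop, 5'UTR, intron, pseudogene or intergenic — flags novelty
against a known mature-sequence catalog (U/T- and case-insensitive), and
summarizes the context breakdown. A locus lying inside a known miRNA
precursor span is assigned to the stem-loop regardless of strand or of any
host gene (precursor-internal sequences belong to the precursor); loci
overlapping a protein-coding exon in sense are reported as unclassifiable
rather than silently binned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

import pandas as pd

from .annotation import AnnotationSet
from .classify import SmallRnaCatalog, normalize_rna

CONTEXT_CLASSES = ("known_stem_loop", "five_prime_UTR", "intron",
                   "pseudogene", "intergenic")


@dataclass
class MirnaLocus:
    name: str
    chrom: str
    strand: str
    start: int                      # 1-based inclusive
    end: int
    mature_sequence: str            # RNA string
    star_detected: bool = False
    prior_report: str = "Novel"
    context: Optional[str] = None   # one of CONTEXT_CLASSES or "unclassifiable"
    context_detail: str = ""        # host transcript / precursor / flanking genes

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def classify_mirna_locus(locus: MirnaLocus, ann: AnnotationSet) -> MirnaLocus:
    """Assign context with priority known_stem_loop > 5'UTR > intron >
    pseudogene > intergenic; stem-loop overlap counts on either strand,
    gene-hosted contexts require same-strand overlap."""
    stem = [f for f in ann.overlapping(locus.chrom, locus.start, locus.end)
            if f.feature_class == "miRNA_stem_loop"]
    if stem:
        locus.context = "known_stem_loop"
        locus.context_detail = stem[0].feature_id
        return locus
    sense = ann.overlapping(locus.chrom, locus.start, locus.end, strand=locus.strand)
    by_class = {}
    for f in sense:
        by_class.setdefault(f.feature_class, f)
    for cls, ctx in (("five_prime_UTR", "five_prime_UTR"),
                     ("protein_coding_intron", "intron"),
                     ("pseudogene", "pseudogene")):
        if cls in by_class:
            f = by_class[cls]
            locus.context = ctx
            locus.context_detail = f.gene_id or f.feature_id
            return locus
    if "protein_coding_exon" in by_class or "three_prime_UTR" in by_class:
        locus.context = "unclassifiable"
        locus.context_detail = by_class.get(
            "protein_coding_exon", by_class.get("three_prime_UTR")).gene_id or ""
        warnings.warn(f"{locus.name}: sense-exonic locus is unclassifiable")
        return locus
    locus.context = "intergenic"
    left, right = None, None
    for g in ann.genes:
        if g.chrom != locus.chrom:
            continue
        if g.end < locus.start and (left is None or g.end > left.end):
            left = g
        if g.start > locus.end and (right is None or g.start < right.start):
            right = g
    locus.context_detail = "-".join(
        x.feature_id if x else "" for x in (left, right))
    return locus


def flag_novel(locus: MirnaLocus, catalog: SmallRnaCatalog) -> str:
    """'Novel' iff the mature sequence is absent from the catalog, else the
    catalog name (comparison is U/T- and case-insensitive)."""
    target = normalize_rna(locus.mature_sequence)
    for name, seq in catalog.sequences.items():
        if seq == target:
            return name
    return "Novel"


@dataclass
class ContextSummary:
    context_counts: dict[str, int] = field(default_factory=dict)
    total: int = 0
    novel: int = 0
    cross_validated: int = 0   # prior_report other than "Novel"

    def __post_init__(self):
        if sum(self.context_counts.values()) != self.total:
            raise ValueError("context counts do not sum to total")


def summarize_contexts(loci: Iterable[MirnaLocus]) -> ContextSummary:
    counts: dict[str, int] = {}
    total = novel = crossval = 0
    for locus in loci:
        if locus.context is None:
            raise ValueError(f"{locus.name}: unlabeled locus")
        counts[locus.context] = counts.get(locus.context, 0) + 1
        total += 1
        if locus.prior_report == "Novel":
            novel += 1
        else:
            crossval += 1
    return ContextSummary(counts, total, novel, crossval)


def context_from_label(located_in: str) -> str:
    """Map a free-text 'located in' label to a context class."""
    s = located_in.strip()
    if "stem loop" in s:
        return "known_stem_loop"
    if "intron" in s:
        return "intron"
    if "5'UTR" in s:
        return "five_prime_UTR"
    if "pseudogene" in s:
        return "pseudogene"
    if s.startswith("Intergenic region"):
        return "intergenic"
    raise ValueError(f"unrecognized context label: {located_in!r}")


def loci_from_frame(df: pd.DataFrame) -> list[MirnaLocus]:
    loci = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            locus = MirnaLocus(
                name=str(row.mirna), chrom=str(row.chrom), strand=str(row.strand),
                start=int(row.start), end=int(row.end),
                mature_sequence=str(row.mature_sequence),
                star_detected=str(row.star_detected).upper() == "YES",
                prior_report=str(row.prior_report),
                context=context_from_label(str(row.located_in)),
                context_detail=str(row.located_in))
        except (ValueError, AttributeError) as e:
            raise ValueError(f"malformed miRNA table row {i + 1}: {e}") from e
        if locus.length != len(locus.mature_sequence):
            warnings.warn(f"{locus.name}: span length {locus.length} != mature "
                          f"length {len(locus.mature_sequence)}")
        loci.append(locus)
    return loci


def loci_to_frame(loci: Iterable[MirnaLocus]) -> pd.DataFrame:
    rows = [{"mirna": l.name, "chrom": l.chrom, "strand": l.strand,
             "start": l.start, "end": l.end,
             "mature_sequence": l.mature_sequence,
             "star_detected": "YES" if l.star_detected else "NO",
             "prior_report": l.prior_report, "located_in": l.context_detail}
            for l in loci]
    return pd.DataFrame(rows)


def load_fixture_tables() -> tuple[pd.DataFrame, list[MirnaLocus]]:
    """Packaged reference tables: the 40 newly nitrate-responsive genes absent
    from the ATH1 array (AGI id, description, log2 KNO3/KCl ratio) and the 51
    novel miRNA loci with coordinates, mature sequences and contexts."""
    data = resources.files("nitroseq") / "data"
    genes = pd.read_csv(data / "table1_new_nitrate_genes.tsv", sep="\t")
    if genes.isna().any().any():
        raise ValueError("malformed gene-table fixture row")
    mirnas = pd.read_csv(data / "table2_novel_mirnas.tsv", sep="\t")
    return genes, loci_from_frame(mirnas)


def loci_to_gff3(loci: Iterable[MirnaLocus], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for l in sorted(loci, key=lambda l: (l.chrom, l.start)):
            fh.write(f"{l.chrom}\tnitroseq\tmiRNA\t{l.start}\t{l.end}\t.\t{l.strand}"
                     f"\t.\tID={l.name};context={l.context}\n")
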