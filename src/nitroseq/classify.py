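"""Genomic-origin classification of alignments with 1/n_loci weighting.

Each placement is assigned the single highest-priority category whose
same-strand feature overlaps it by at least one base; placements with no
same-strand overlap are intergenic (antisense placements over genes land
here, which is what the novel-region stage feeds on). A read mapping to n
loci contributes multiplicity/n to the category of each placement, so the
weighted category totals conserve the number of mapped reads exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .annotation import AnnotationSet
from .mapping import AlignmentRecord
from .reads import ReadSet

# Overlap precedence, highest first; protein_coding collapses exon/UTR/intron.
DEFAULT_PRIORITY = (
    "mature_miRNA",
    "miRNA_stem_loop",
    "tasiRNA_locus",
    "rRNA",
    "tRNA",
    "protein_coding",
    "pseudogene",
    "transposable_element",
)

_PROTEIN_CODING_CLASSES = {
    "protein_coding_exon", "protein_coding_intron",
    "five_prime_UTR", "three_prime_UTR", "gene",
}

CATEGORIES = DEFAULT_PRIORITY + ("intergenic",)


def _to_category(feature_class: str) -> str:
    if feature_class in _PROTEIN_CODING_CLASSES:
        return "protein_coding"
    return feature_class


def classify_alignment(rec: AlignmentRecord, ann: AnnotationSet,
                       priority: tuple[str, ...] = DEFAULT_PRIORITY,
                       chrom_lengths: Optional[dict[str, int]] = None) -> str:
    if chrom_lengths is not None:
        L = chrom_lengths.get(rec.chrom)
        if L is None or rec.start < 1 or rec.end > L:
            raise ValueError(f"record {rec.read_id} outside chromosome bounds")
    hits = ann.overlapping(rec.chrom, rec.start, rec.end, strand=rec.strand)
    if not hits:
        return "intergenic"
    cats = {_to_category(f.feature_class) for f in hits}
    for cat in priority:
        if cat in cats:
            return cat
    return "intergenic"


@dataclass
class CategoryBreakdown:
    counts: pd.Series            # category -> weighted read count
    scope: str                   # "all" | "unique"
    label: str = ""

    @property
    def percentages(self) -> pd.Series:
        total = self.counts.sum()
        return self.counts / total * 100 if total else self.counts * 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"weighted_count": self.counts,
                             "percent": self.percentages})


def weighted_category_counts(records: Iterable[AlignmentRecord], ann: AnnotationSet,
                             scope: str = "all",
                             priority: tuple[str, ...] = DEFAULT_PRIORITY,
                             label: str = "") -> CategoryBreakdown:
    """Per-category weighted counts: each placement adds multiplicity/n_loci.

    scope="unique" restricts to reads with a single genome-wide placement.
    """
    if scope not in ("all", "unique"):
        raise ValueError("scope must be 'all' or 'unique'")
    totals = {cat: 0.0 for cat in priority + ("intergenic",)}
    for rec in records:
        if scope == "unique" and rec.n_loci != 1:
            continue
        cat = classify_alignment(rec, ann, priority)
        totals[cat] += rec.multiplicity / rec.n_loci
    return CategoryBreakdown(pd.Series(totals), scope=scope, label=label)


def size_distribution(srna: ReadSet, size_min: int = 18, size_max: int = 28) -> pd.Series:
    """Post-trim insert-length histogram over the retained sRNA reads."""
    hist = pd.Series(0, index=range(size_min, size_max + 1), name=srna.label)
    for seq, mult in srna.counts.items():
        n = len(seq)
        if size_min <= n <= size_max:
            hist[n] += mult
    return hist


@dataclass
class SmallRnaCatalog:
    """Known mature small-RNA catalog keyed by name; sequences stored as DNA."""

    sequences: dict[str, str] = field(default_factory=dict)
    families: dict[str, str] = field(default_factory=dict)  # name -> family

    def __post_init__(self):
        norm = {}
        for name, seq in self.sequences.items():
            if name in norm:
                raise ValueError(f"duplicate catalog name {name}")
            norm[name] = normalize_rna(seq)
        self.sequences = norm
        if not self.families:
            self.families = {n: family_of(n) for n in self.sequences}

    @classmethod
    def from_tsv(cls, path) -> "SmallRnaCatalog":
        df = pd.read_csv(path, sep="\t", header=None, names=["name", "sequence"])
        if df["name"].duplicated().any():
            dup = df.loc[df["name"].duplicated(), "name"].iloc[0]
            raise ValueError(f"duplicate catalog name {dup}")
        return cls(dict(zip(df["name"], df["sequence"])))


def normalize_rna(seq: str) -> str:
    """U/T- and case-insensitive comparison form (DNA upper-case)."""
    return seq.upper().replace("U", "T")


def family_of(name: str) -> str:
    """miRNA family from a mature name: strip species prefix, arm and variant
    letters, e.g. ath-miR166a-5p -> miR166."""
    base = name.split("-miR")[-1] if "-miR" in name else name.replace("miR", "", 1)
    base = base.split("-")[0]
    return "miR" + base.rstrip("abcdefghij")


def known_srna_expression(reads: ReadSet, catalog: SmallRnaCatalog) -> pd.DataFrame:
    """Per-catalog-entry read counts; an entry is detected iff >= 1 retained
    read equals its sequence exactly (U<->T normalized)."""
    if not catalog.sequences:
        raise ValueError("catalog is empty")
    by_seq = {normalize_rna(s): m for s, m in reads.counts.items()}
    rows = []
    for name, seq in catalog.sequences.items():
        count = by_seq.get(seq, 0)
        rows.append({"name": name, "family": catalog.families[name],
                     "sequence": seq, "count": count, "detected": count >= 1})
    return pd.DataFrame(rows)


def detection_summary(expr: pd.DataFrame) -> dict:
    det = expr[expr["detected"]]
    return {"detected_sequences": int(len(det)),
            "detected_families": int(det["family"].nunique())}
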