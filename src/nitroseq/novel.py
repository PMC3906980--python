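"""Novel transcribed-region discovery, including natural antisense transcripts.

Uniquely mapping poly-A+ alignments with no same-strand overlap with any
annotated feature are pooled across all samples; per strand, maximal
zero-gap runs of overlapping or abutting alignments spanning >= 300 bp are
emitted as candidate transcribed regions. A candidate lying opposite an
annotated gene is a NAT candidate (antisense_to that gene); otherwise it is
intergenic with its flanking genes recorded. Candidates are quantified per
sample so the differential-expression stage can test them like genes.

Antisense placements are deliberately *not* excluded during pooling — a read
inside a gene's span on the opposite strand is exactly the NAT signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .annotation import AnnotationSet, Feature
from .mapping import AlignmentRecord

MIN_CLUSTER_LENGTH = 300


@dataclass
class TranscribedCluster:
    cluster_id: str
    chrom: str
    start: int          # 1-based inclusive
    end: int
    strand: str
    relation: str                      # "intergenic" | "antisense_to"
    antisense_gene: Optional[str] = None
    flank_upstream: Optional[str] = None
    flank_downstream: Optional[str] = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def pool_unannotated(records_by_sample: dict[str, Iterable[AlignmentRecord]],
                     ann: AnnotationSet) -> list[AlignmentRecord]:
    """Pool unique-match alignments with zero same-strand annotated overlap.

    Opposite-strand overlap does not exclude (NAT prerequisite).
    """
    pooled = []
    for sample in sorted(records_by_sample):
        for rec in records_by_sample[sample]:
            if rec.n_loci != 1:
                continue
            if not ann.overlapping(rec.chrom, rec.start, rec.end, strand=rec.strand):
                pooled.append(rec)
    return pooled


def call_clusters(pooled: Iterable[AlignmentRecord],
                  min_length: int = MIN_CLUSTER_LENGTH,
                  max_gap: int = 0) -> list[TranscribedCluster]:
    """Per strand and chromosome, maximal runs of alignments where consecutive
    reads overlap or abut (gap <= max_gap); emit runs spanning >= min_length.
    Span endpoints are the outermost read edges."""
    by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for rec in pooled:
        by_key.setdefault((rec.chrom, rec.strand), []).append((rec.start, rec.end))
    clusters = []
    serial = 0
    for (chrom, strand) in sorted(by_key):
        spans = sorted(by_key[(chrom, strand)])
        cur_start, cur_end = spans[0]
        runs = []
        for s, e in spans[1:]:
            if s <= cur_end + 1 + max_gap:
                cur_end = max(cur_end, e)
            else:
                runs.append((cur_start, cur_end))
                cur_start, cur_end = s, e
        runs.append((cur_start, cur_end))
        for s, e in runs:
            if e - s + 1 >= min_length:
                serial += 1
                clusters.append(TranscribedCluster(
                    f"NTR{serial:03d}", chrom, s, e, strand, "intergenic"))
    return clusters


def classify_cluster(c: TranscribedCluster, ann: AnnotationSet) -> TranscribedCluster:
    """Label antisense_to the longest-overlap opposite-strand gene, else
    intergenic with nearest up/downstream gene ids."""
    other = "-" if c.strand == "+" else "+"
    genes = [f for f in ann.overlapping(c.chrom, c.start, c.end, strand=other)
             if f.feature_class == "gene"]
    if genes:
        best = max(genes, key=lambda g: (g.overlap_length(c.start, c.end), g.feature_id))
        c.relation = "antisense_to"
        c.antisense_gene = best.feature_id
        return c
    c.relation = "intergenic"
    left, right = None, None
    for g in ann.genes:
        if g.chrom != c.chrom:
            continue
        if g.end < c.start and (left is None or g.end > left.end):
            left = g
        if g.start > c.end and (right is None or g.start < right.start):
            right = g
    c.flank_upstream = left.feature_id if left else None
    c.flank_downstream = right.feature_id if right else None
    return c


def cluster_counts(clusters: list[TranscribedCluster],
                   records_by_sample: dict[str, Iterable[AlignmentRecord]]) -> pd.DataFrame:
    """Per-sample counts of unique-match same-strand reads overlapping each
    cluster; rows are appendable to the DE count matrix."""
    samples = sorted(records_by_sample)
    data = {s: dict.fromkeys((c.cluster_id for c in clusters), 0) for s in samples}
    for sample in samples:
        for rec in records_by_sample[sample]:
            if rec.n_loci != 1:
                continue
            for c in clusters:
                if (c.chrom == rec.chrom and c.strand == rec.strand
                        and rec.start <= c.end and rec.end >= c.start):
                    data[sample][c.cluster_id] += rec.multiplicity
    return pd.DataFrame(data, columns=samples).astype(int)


def clusters_to_gff3(clusters: list[TranscribedCluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in sorted(clusters, key=lambda c: (c.chrom, c.start)):
            attrs = [f"ID={c.cluster_id}", f"relation={c.relation}"]
            if c.antisense_gene:
                attrs.append(f"antisense_gene={c.antisense_gene}")
            if c.flank_upstream or c.flank_downstream:
                attrs.append(f"flanks={c.flank_upstream},{c.flank_downstream}")
            fh.write(f"{c.chrom}\tnitroseq\ttranscribed_region\t{c.start}\t{c.end}"
                     f"\t.\t{c.strand}\t.\t{';'.join(attrs)}\n")


def clusters_to_bed6(clusters: list[TranscribedCluster], path) -> None:
    with open(path, "w") as fh:
        for c in sorted(clusters, key=lambda c: (c.chrom, c.start)):
            fh.write(f"{c.chrom}\t{c.start - 1}\t{c.end}\t{c.cluster_id}\t0\t{c.strand}\n")
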