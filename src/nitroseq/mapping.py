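"""Perfect-match read placement on both genome strands.

Only exact full-length matches are reported (the pipeline discards anything
else upstream), so the index is a simple seeded k-mer lookup over the forward
genome sequence; minus-strand placements are found by searching the reverse
complement of the read. Every placement of a multi-mapping read is reported
and records carry ``n_loci``, the genome-wide placement count of their read.

Coordinates are 1-based inclusive; BED export converts to 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pysam
from Bio import SeqIO

from .reads import ReadSet

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignmentRecord:
    """One perfect-match placement of one distinct read sequence."""

    read_id: str
    sequence: str
    multiplicity: int
    chrom: str
    start: int      # 1-based inclusive
    end: int
    strand: str
    n_loci: int

    def __post_init__(self):
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("span length != read length")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")


class GenomeIndex:
    """Exact-substring lookup over both strands via a k-mer seed table."""

    def __init__(self, chroms: dict[str, str], seed_size: int = 12):
        if len(set(chroms)) != len(chroms):
            raise ValueError("duplicate chromosome names")
        self.chroms = {name: seq.upper() for name, seq in chroms.items()}
        for name, seq in self.chroms.items():
            if not seq:
                raise ValueError(f"empty chromosome {name}")
            if set(seq) - set("ACGTN"):
                raise ValueError(f"chromosome {name}: non-ACGTN base")
        self.seed_size = seed_size
        self._seeds: dict[str, list[tuple[str, int]]] = {}
        k = seed_size
        for name, seq in self.chroms.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i:i + k]
                if "N" in kmer:
                    continue
                self._seeds.setdefault(kmer, []).append((name, i))

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chroms.items()}

    def find_forward(self, query: str) -> list[tuple[str, int]]:
        """All (chrom, 1-based start) forward-strand exact occurrences of query.

        Queries containing N never match (N in the genome matches nothing).
        """
        q = query.upper()
        L = len(q)
        if L == 0 or "N" in q:
            return []
        hits: list[tuple[str, int]] = []
        if L >= self.seed_size:
            for chrom, i in self._seeds.get(q[:self.seed_size], ()):
                if self.chroms[chrom][i:i + L] == q:
                    hits.append((chrom, i + 1))
        else:
            for chrom, seq in self.chroms.items():
                i = seq.find(q)
                while i >= 0:
                    if "N" not in seq[i:i + L]:
                        hits.append((chrom, i + 1))
                    i = seq.find(q, i + 1)
        return sorted(hits)


def build_index(genome: "dict[str, str] | str", seed_size: int = 12) -> GenomeIndex:
    """Build from a {chrom: sequence} dict or a FASTA path."""
    if isinstance(genome, dict):
        return GenomeIndex(genome, seed_size=seed_size)
    chroms: dict[str, str] = {}
    for rec in SeqIO.parse(str(genome), "fasta"):
        if rec.id in chroms:
            raise ValueError(f"duplicate chromosome name {rec.id}")
        chroms[rec.id] = str(rec.seq).upper()
    return GenomeIndex(chroms, seed_size=seed_size)


def map_reads(reads: ReadSet, index: GenomeIndex,
              max_loci: Optional[int] = None) -> tuple[list[AlignmentRecord], dict]:
    """Place every distinct sequence on both strands; returns (records, accounting).

    accounting: {"mapped_distinct", "unmapped_distinct", "mapped_reads",
    "unmapped_reads", "capped_distinct"}. Reads exceeding ``max_loci``
    placements are excluded and logged under "capped_distinct".
    """
    records: list[AlignmentRecord] = []
    acct = {"mapped_distinct": 0, "unmapped_distinct": 0,
            "mapped_reads": 0, "unmapped_reads": 0, "capped_distinct": 0}
    for ridx, (seq, mult) in enumerate(sorted(reads.counts.items())):
        fwd = index.find_forward(seq)
        rev = index.find_forward(revcomp(seq))
        n_loci = len(fwd) + len(rev)
        if n_loci == 0:
            acct["unmapped_distinct"] += 1
            acct["unmapped_reads"] += mult
            continue
        if max_loci is not None and n_loci > max_loci:
            acct["capped_distinct"] += 1
            continue
        rid = f"r{ridx}"
        L = len(seq)
        for chrom, start in fwd:
            records.append(AlignmentRecord(rid, seq, mult, chrom,
                                           start, start + L - 1, "+", n_loci))
        for chrom, start in rev:
            records.append(AlignmentRecord(rid, seq, mult, chrom,
                                           start, start + L - 1, "-", n_loci))
        acct["mapped_distinct"] += 1
        acct["mapped_reads"] += mult
    return records, acct


def unique_alignments(records: Iterable[AlignmentRecord]) -> list[AlignmentRecord]:
    """Records of reads placing exactly once genome-wide."""
    return [r for r in records if r.n_loci == 1]


def write_sam(records: Iterable[AlignmentRecord], index: GenomeIndex, path) -> None:
    """Minimal SAM with the NH tag carrying n_loci."""
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": ln} for name, ln in index.lengths.items()],
    })
    refs = list(index.lengths)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in records:
            a = pysam.AlignedSegment(header)
            a.query_name = r.read_id
            seq = r.sequence if r.strand == "+" else revcomp(r.sequence)
            a.query_sequence = seq
            a.flag = 0 if r.strand == "+" else 16
            a.reference_id = refs.index(r.chrom)
            a.reference_start = r.start - 1
            a.mapping_quality = 255
            a.cigarstring = f"{len(r.sequence)}M"
            a.set_tag("NH", r.n_loci)
            a.set_tag("NM", 0)
            out.write(a)


def read_sam(path, index: GenomeIndex, multiplicities: Optional[dict] = None
             ) -> list[AlignmentRecord]:
    """Import externally produced alignments; records with mismatches (NM>0)
    or without a full-length match CIGAR are rejected."""
    records = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            if a.has_tag("NM") and a.get_tag("NM") > 0:
                raise ValueError(f"{a.query_name}: mismatched alignment (NM>0) rejected")
            if len(a.cigartuples) != 1 or a.cigartuples[0][0] != 0:
                raise ValueError(f"{a.query_name}: non-full-length CIGAR rejected")
            strand = "-" if a.is_reverse else "+"
            seq = a.query_sequence.upper()
            read_seq = seq if strand == "+" else revcomp(seq)
            n_loci = a.get_tag("NH") if a.has_tag("NH") else 1
            mult = (multiplicities or {}).get(read_seq, 1)
            records.append(AlignmentRecord(
                a.query_name, read_seq, mult, a.reference_name,
                a.reference_start + 1, a.reference_start + len(seq), strand, n_loci))
    return records


def write_bed6(records: Iterable[AlignmentRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.read_id}\t{r.n_loci}\t{r.strand}\n")
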