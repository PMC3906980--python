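"""Raw-read quality filtering, 3' adaptor trimming, and size/composition filters.

The filter chain mirrors a standard small-RNA preprocessing stack: reads must
have at least ``min_frac_at_phred`` of their bases at or above Q20, the 3'
cloning-linker adaptor is trimmed by exact match (full occurrence anywhere, or
a >= ``min_adaptor_overlap``-base adaptor prefix flush with the read's 3' end),
then a size window (18-28 nt for sRNA libraries, >= 18 nt for poly-A+) and a
polynucleotide filter (single-base fraction > 0.8 discards) are applied.
Survivors are collapsed to distinct sequences with multiplicities, and every
read is accounted for: raw == retained + sum(per-filter losses).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from Bio import SeqIO

# 3' cloning-linker prefix used by the sRNA library protocol
DEFAULT_ADAPTOR = "CTGTAGGCACCATCAAT"


@dataclass
class SequencingRead:
    identifier: str
    sequence: str
    qualities: list[int]

    def __post_init__(self):
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.identifier}: sequence and quality lengths differ")
        if set(self.sequence) - set("ACGTN"):
            raise ValueError(f"read {self.identifier}: non-ACGTN base")


@dataclass
class FilterConfig:
    phred_min: int = 20
    min_frac_at_phred: float = 0.9
    adaptor: str = DEFAULT_ADAPTOR
    min_adaptor_overlap: int = 5
    size_min: int = 18
    size_max: Optional[int] = 28      # None = unbounded (poly-A+ libraries)
    homopolymer_max_frac: float = 0.8

    def __post_init__(self):
        if not (0 < self.min_frac_at_phred <= 1):
            raise ValueError("min_frac_at_phred must be in (0, 1]")
        if self.size_max is not None and self.size_min > self.size_max:
            raise ValueError("size_min > size_max")

    @classmethod
    def srna(cls, **kw) -> "FilterConfig":
        return cls(size_min=18, size_max=28, **kw)

    @classmethod
    def polya(cls, **kw) -> "FilterConfig":
        return cls(size_min=18, size_max=None, **kw)


@dataclass
class FilterStats:
    raw: int = 0
    quality_fail: int = 0
    size_fail: int = 0
    polynucleotide_fail: int = 0
    retained: int = 0

    def check_conservation(self) -> None:
        total = self.retained + self.quality_fail + self.size_fail + self.polynucleotide_fail
        if total != self.raw:
            raise AssertionError(
                f"filter accounting broken: raw={self.raw} but parts sum to {total}")


@dataclass
class ReadSet:
    """Distinct retained sequences with multiplicities, plus filter accounting."""

    counts: Counter = field(default_factory=Counter)
    label: str = "sRNA"           # "sRNA" | "polyA"
    stats: FilterStats = field(default_factory=FilterStats)

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def n_distinct(self) -> int:
        return len(self.counts)


def read_fastq(path) -> Iterator[SequencingRead]:
    """Stream Sanger Phred+33 FASTQ records."""
    for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
        try:
            yield SequencingRead(rec.id, str(rec.seq).upper(),
                                 list(rec.letter_annotations["phred_quality"]))
        except ValueError as e:
            raise ValueError(f"malformed FASTQ record {i}: {e}") from e


def write_fastq(reads: Iterable[SequencingRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.identifier}\n{r.sequence}\n+\n{qual}\n")


def passes_quality(read: SequencingRead, cfg: FilterConfig) -> bool:
    """True iff >= min_frac_at_phred of bases have Phred >= phred_min and no N.

    N-containing reads cannot perfectly match the genome downstream, so they
    are rejected here and booked as quality failures.
    """
    if "N" in read.sequence:
        return False
    n_ok = sum(q >= cfg.phred_min for q in read.qualities)
    return n_ok >= cfg.min_frac_at_phred * len(read.qualities)


def filter_quality(reads: Iterable[SequencingRead], cfg: FilterConfig,
                   stats: Optional[FilterStats] = None) -> Iterator[SequencingRead]:
    for read in reads:
        if stats is not None:
            stats.raw += 1
        if passes_quality(read, cfg):
            yield read
        elif stats is not None:
            stats.quality_fail += 1


def trim_adaptor(read: SequencingRead, cfg: FilterConfig) -> SequencingRead:
    """Truncate at the leftmost full adaptor occurrence, or at a 3'-terminal
    adaptor prefix of length >= min_adaptor_overlap; unchanged otherwise."""
    adaptor, seq = cfg.adaptor, read.sequence
    if not adaptor:
        raise ValueError("adaptor must be non-empty")
    cut = seq.find(adaptor)
    if cut < 0:
        for k in range(min(len(adaptor) - 1, len(seq)), cfg.min_adaptor_overlap - 1, -1):
            if seq.endswith(adaptor[:k]):
                cut = len(seq) - k
                break
    if cut < 0:
        return read
    return SequencingRead(read.identifier, seq[:cut], read.qualities[:cut])


def _homopolymer_frac(seq: str) -> float:
    if not seq:
        return 1.0
    return max(Counter(seq).values()) / len(seq)


def filter_size_and_composition(reads: Iterable[SequencingRead], cfg: FilterConfig,
                                label: str = "sRNA",
                                stats: Optional[FilterStats] = None) -> ReadSet:
    """Size window + polynucleotide filter, collapsing survivors to a ReadSet."""
    rs = ReadSet(label=label, stats=stats if stats is not None else FilterStats())
    for read in reads:
        n = len(read.sequence)
        if n < cfg.size_min or (cfg.size_max is not None and n > cfg.size_max):
            rs.stats.size_fail += 1
            continue
        if _homopolymer_frac(read.sequence) > cfg.homopolymer_max_frac:
            rs.stats.polynucleotide_fail += 1
            continue
        rs.counts[read.sequence] += 1
        rs.stats.retained += 1
    return rs


def process_library(reads: Iterable[SequencingRead], cfg: FilterConfig,
                    label: str = "sRNA") -> ReadSet:
    """Full chain: quality filter -> adaptor trim -> size/composition -> ReadSet."""
    stats = FilterStats()
    passed = filter_quality(reads, cfg, stats)
    trimmed = (trim_adaptor(r, cfg) for r in passed)
    rs = filter_size_and_composition(trimmed, cfg, label=label, stats=stats)
    rs.stats.check_conservation()
    return rs


def stats_table(stats_by_sample: dict[str, FilterStats]):
    """Filter-statistics report: raw, passing and per-filter losses per library."""
    import pandas as pd

    rows = []
    for name, s in stats_by_sample.items():
        rows.append({"sample": name, "raw": s.raw, "retained": s.retained,
                     "quality_fail": s.quality_fail, "size_fail": s.size_fail,
                     "polynucleotide_fail": s.polynucleotide_fail})
    return pd.DataFrame(rows)
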