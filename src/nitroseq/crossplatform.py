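"""RNA-seq vs microarray concordance stratified by average gene coverage (AGC).

AGC = reads matching a gene x read length / gene length — a dimensionless
depth proxy. Concordance between sequencing and array log ratios improves
with coverage, so the correlation is reported along an AGC-threshold grid;
detection overlap compares array present calls with the >= 1 read rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

DEFAULT_AGC_GRID = (0.0, 0.1, 0.2, 0.4, 0.8, 1.6, 3.2)


def compute_agc(read_counts: pd.Series, gene_lengths: pd.Series,
                read_length: int = 50) -> pd.DataFrame:
    """AGC per gene from its sense unique-read count.

    ``read_counts`` and ``gene_lengths`` are gene-indexed; genes missing from
    ``read_counts`` get 0 reads.
    """
    if (gene_lengths <= 0).any():
        bad = gene_lengths.index[gene_lengths <= 0][0]
        raise ValueError(f"gene {bad} has non-positive length")
    counts = read_counts.reindex(gene_lengths.index).fillna(0)
    agc = counts * read_length / gene_lengths
    return pd.DataFrame({"read_count": counts, "read_length": read_length,
                         "gene_length": gene_lengths, "agc": agc})


def ratio_correlation_by_agc(seq_ratios: pd.Series, array_ratios: pd.Series,
                             agc: pd.DataFrame,
                             thresholds: Sequence[float] = DEFAULT_AGC_GRID,
                             method: str = "pearson") -> pd.DataFrame:
    """Per AGC threshold: r^2 between platform log2 ratios over genes with
    AGC >= threshold present on both platforms. Thresholds with < 3 genes
    are omitted with a warning; a zero-variance ratio vector raises."""
    shared = seq_ratios.index.intersection(array_ratios.index).intersection(agc.index)
    seq = seq_ratios[shared].astype(float)
    arr = array_ratios[shared].astype(float)
    cov = agc.loc[shared, "agc"]
    rows = []
    for t in sorted(thresholds):
        mask = (cov >= t) & seq.notna() & arr.notna()
        n = int(mask.sum())
        if n < 3:
            warnings.warn(f"AGC threshold {t}: only {n} genes; point omitted")
            continue
        x, y = seq[mask], arr[mask]
        if x.std() == 0 or y.std() == 0:
            raise ValueError(f"AGC threshold {t}: zero-variance ratio vector")
        r = x.corr(y, method=method)
        rows.append({"agc_threshold": t, "r2": r * r, "n_genes": n})
    return pd.DataFrame(rows)


@dataclass
class DetectionComparison:
    present_and_detected: int      # array present, >= 1 read
    present_not_detected: int      # array present, 0 reads
    absent_but_detected: int       # array absent, >= 1 read
    absent_not_detected: int
    no_probe_detected: int         # detected by sequencing, no array probe
    no_probe_not_detected: int

    def total(self) -> int:
        return (self.present_and_detected + self.present_not_detected
                + self.absent_but_detected + self.absent_not_detected
                + self.no_probe_detected + self.no_probe_not_detected)


def detection_comparison(array_table: pd.DataFrame, read_counts: pd.Series,
                         gene_universe: Optional[Sequence[str]] = None
                         ) -> DetectionComparison:
    """Partition the gene universe by array present call vs sequencing detection.

    ``array_table`` needs columns 'gene' and 'present' (bool); sequencing
    detection is read count >= 1.
    """
    probed = array_table.set_index("gene")["present"]
    if gene_universe is None:
        universe = probed.index.union(read_counts.index)
    else:
        universe = pd.Index(gene_universe)
        unknown = probed.index.difference(universe)
        if len(unknown):
            raise ValueError(f"probe maps to unknown gene {unknown[0]}")
    detected = read_counts.reindex(universe).fillna(0) >= 1
    has_probe = universe.isin(probed.index)
    present = probed.reindex(universe).astype("boolean").fillna(False).astype(bool)
    return DetectionComparison(
        present_and_detected=int((has_probe & present & detected).sum()),
        present_not_detected=int((has_probe & present & ~detected).sum()),
        absent_but_detected=int((has_probe & ~present & detected).sum()),
        absent_not_detected=int((has_probe & ~present & ~detected).sum()),
        no_probe_detected=int((~has_probe & detected).sum()),
        no_probe_not_detected=int((~has_probe & ~detected).sum()),
    )
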