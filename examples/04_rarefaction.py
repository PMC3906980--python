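"""Rarefaction: how many distinct sequences appear as sampling depth grows.
A flat tail means the population is sequenced to saturation; a near-linear
curve means most molecules were seen once and quantitative comparisons are
underpowered at this depth."""

import tempfile
from pathlib import Path

import pandas as pd

from nitroseq import FilterConfig, GenomeSpec, simulate_command
from nitroseq.rarefaction import rarefaction_curve, saturation_assessment
from nitroseq.reads import ReadSet, process_library, read_fastq

with tempfile.TemporaryDirectory() as tmp:
    cfg = simulate_command(GenomeSpec(seed=7), Path(tmp) / "demo")
    rs = process_library(read_fastq(cfg.fastq["KNO3_1"]["sRNA"]),
                         FilterConfig.srna(), "sRNA")

    catalog = pd.read_csv(cfg.srna_catalog, sep="\t", header=None,
                          names=["name", "seq"])
    mirna = ReadSet(label="sRNA")   # the known-miRNA fraction of the library
    for seq in catalog["seq"]:
        if seq in rs.counts:
            mirna.counts[seq] = rs.counts[seq]

    for label, lib in (("full sRNA library", rs),
                       ("known-miRNA fraction", mirna)):
        curve = rarefaction_curve(lib, n_resamples=10, seed=0)
        ratio = saturation_assessment(curve)
        print(f"{label}: {lib.total_reads} reads, {lib.n_distinct} distinct")
        print(curve.to_frame().round(1).to_string(index=False))
        print(f"saturation ratio (final/initial slope): {ratio:.3f}\n")

    print("The known-miRNA fraction is a handful of distinct molecules sampled")
    print("deeply, so its curve flattens to a plateau (ratio near 0). The full")
    print("library is dominated by a diverse siRNA background in which almost")
    print("every new read is a new sequence (ratio near 1): at this depth the")
    print("sRNA fraction is far from saturation, which is why per-sequence")
    print("counts are too sparse for reliable differential tests.")
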