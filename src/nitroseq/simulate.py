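"""Synthetic genome, annotation, truth table and stranded FASTQ libraries.

The generator emulates the study design every downstream stage assumes:
two conditions (KNO3 vs KCl) x two biological replicates; 50 bp stranded
poly-A+ reads and 35-cycle sRNA reads whose 3' end runs into the cloning
linker; negative-binomially distributed gene counts with planted log2 fold
changes; a 21/24-nt bimodal sRNA insert-length structure; planted
unannotated sense/antisense transcribed regions >= 300 bp (one NAT induced
4x by nitrate); and planted intronic/intergenic novel miRNA loci next to a
set of known stem-loop loci. Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .annotation import AnnotationSet, Feature, derive_introns
from .mapping import revcomp
from .reads import DEFAULT_ADAPTOR

SAMPLES = ("KNO3_1", "KNO3_2", "KCl_1", "KCl_2")
CONDITION_OF = {"KNO3_1": "KNO3", "KNO3_2": "KNO3", "KCl_1": "KCl", "KCl_2": "KCl"}

# sRNA insert-length mixture: 21-nt dominant, 24-nt secondary mode
SRNA_LENGTH_WEIGHTS = {
    18: 0.01, 19: 0.03, 20: 0.05, 21: 0.40, 22: 0.10, 23: 0.07,
    24: 0.25, 25: 0.05, 26: 0.03, 27: 0.005, 28: 0.005,
}


@dataclass
class GenomeSpec:
    genome_length: int = 200_000
    n_genes: int = 40
    n_mirna_loci: int = 6            # known stem-loop loci (annotated)
    n_rrna_loci: int = 2
    n_trna_loci: int = 2
    n_tasirna_loci: int = 1
    n_pseudogenes: int = 2
    n_transposons: int = 3
    frac_de_genes: float = 0.2
    lfc_magnitude: float = 2.0
    nb_dispersion: float = 0.01
    n_planted_nats: int = 4
    n_planted_intergenic_clusters: int = 13
    n_novel_mirna_intronic: int = 2
    n_novel_mirna_intergenic: int = 2
    read_length_mrna: int = 50
    srna_cycle_length: int = 35
    adaptor: str = DEFAULT_ADAPTOR
    mean_gene_expression: float = 200.0
    cluster_mean_count: float = 60.0
    mirna_mean_count: float = 80.0
    n_background_srna: int = 3000    # per sample
    n_background_polya: int = 0      # keeps the novel-region stage noise-free
    low_quality_read_frac: float = 0.05
    q_high: int = 35
    q_low: int = 10
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.frac_de_genes <= 1):
            raise ValueError("frac_de_genes must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")


@dataclass
class TruthTable:
    """Planted ground truth: per-gene condition means and fold changes,
    planted cluster coordinates, and planted miRNA loci."""

    genes: pd.DataFrame      # id-indexed: chrom,start,end,strand,mean_KCl,mean_KNO3,lfc,is_de
    clusters: pd.DataFrame   # id-indexed: chrom,start,end,strand,relation,host_gene,mean_KCl,mean_KNO3,induced
    mirnas: pd.DataFrame     # name-indexed: chrom,start,end,strand,mature,context,host_gene,known,mean_count

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        self.genes.to_csv(outdir / "truth_genes.tsv", sep="\t")
        self.clusters.to_csv(outdir / "truth_clusters.tsv", sep="\t")
        self.mirnas.to_csv(outdir / "truth_mirnas.tsv", sep="\t")


def _nb_draw(rng: np.random.Generator, mean, dispersion: float, size=None):
    """NB with Var = mean + dispersion * mean^2 (Poisson when dispersion ~ 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion < 1e-12:
        return rng.poisson(mean, size=size)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


def _gene_structure(rng, gene_id, chrom, start, strand, n_exons):
    """Lay out 5'UTR | exon (intron exon)* | 3'UTR left-to-right."""
    feats = []
    pos = start
    feats.append(("five_prime_UTR", pos, pos + 99))
    pos += 100
    exons = []
    for i in range(n_exons):
        ex_len = int(rng.integers(150, 401))
        exons.append((pos, pos + ex_len - 1))
        pos += ex_len
        if i < n_exons - 1:
            pos += int(rng.integers(80, 251))  # intron gap
    feats.append(("three_prime_UTR", pos, pos + 149))
    pos += 150
    end = pos - 1
    out = [Feature(gene_id, "gene", chrom, start, end, strand, gene_id)]
    for cls, s, e in feats:
        out.append(Feature(f"{gene_id}.{cls}", cls, chrom, s, e, strand, gene_id))
    exon_feats = [Feature(f"{gene_id}.exon{i+1}", "protein_coding_exon",
                          chrom, s, e, strand, gene_id)
                  for i, (s, e) in enumerate(exons)]
    out.extend(exon_feats)
    out.extend(derive_introns(exon_feats, gene_id))
    return out, end


def make_genome(spec: GenomeSpec) -> tuple[dict[str, str], AnnotationSet, TruthTable]:
    """Build a single-chromosome toy genome with all annotated feature classes,
    plus planted unannotated elements recorded only in the truth table."""
    rng = np.random.default_rng((spec.seed, 1))
    chrom = "Chr1"

    # plan blocks left-to-right; lengths drawn first so sizing can be checked
    blocks: list[tuple[str, int]] = []
    for i in range(spec.n_genes):
        blocks.append((f"gene:{i}", 0))  # length decided during layout
    for i in range(spec.n_mirna_loci):
        blocks.append((f"mirna:{i}", 120))
    for i in range(spec.n_rrna_loci):
        blocks.append((f"rrna:{i}", 500))
    for i in range(spec.n_trna_loci):
        blocks.append((f"trna:{i}", 80))
    for i in range(spec.n_tasirna_loci):
        blocks.append((f"tasirna:{i}", 300))
    for i in range(spec.n_pseudogenes):
        blocks.append((f"pseudo:{i}", 400))
    for i in range(spec.n_transposons):
        blocks.append((f"te:{i}", 600))
    for i in range(spec.n_planted_intergenic_clusters):
        blocks.append((f"igcluster:{i}", int(rng.integers(350, 601))))
    for i in range(spec.n_novel_mirna_intergenic):
        blocks.append((f"igmirna:{i}", 21))
    rng.shuffle(blocks)

    max_gene_footprint = 100 + 4 * 400 + 3 * 250 + 150
    footprint = sum(L if L else max_gene_footprint for _, L in blocks)
    min_gap = 50
    slack = spec.genome_length - footprint - min_gap * (len(blocks) + 1)
    if slack < 0:
        raise ValueError(
            f"feature footprints (~{footprint} b + gaps) exceed genome_length "
            f"{spec.genome_length}")
    extra = rng.multinomial(slack, np.full(len(blocks) + 1, 1 / (len(blocks) + 1)))
    gaps = extra + min_gap

    feats: list[Feature] = []
    gene_rows, cluster_rows, mirna_rows = [], [], []
    known_mirna_spans = []
    pos = 1
    gene_serial = 0
    for bi, (tag, length) in enumerate(blocks):
        pos += int(gaps[bi])
        kind, idx = tag.split(":")
        strand = "+" if rng.random() < 0.5 else "-"
        if kind == "gene":
            gene_serial += 1
            gid = f"G{gene_serial:04d}"
            n_exons = int(rng.integers(2, 5))
            gfeats, end = _gene_structure(rng, gid, chrom, pos, strand, n_exons)
            feats.extend(gfeats)
            gene_rows.append({"id": gid, "chrom": chrom, "start": pos, "end": end,
                              "strand": strand})
            pos = end + 1
        elif kind == "mirna":
            mid = f"MIR{int(idx)+1:03d}"
            end = pos + length - 1
            feats.append(Feature(mid, "miRNA_stem_loop", chrom, pos, end, strand, mid))
            mat_s = pos + 20
            feats.append(Feature(f"{mid}.mature", "mature_miRNA", chrom,
                                 mat_s, mat_s + 20, strand, mid))
            known_mirna_spans.append((mid, mat_s, mat_s + 20, strand))
            pos = end + 1
        elif kind in ("rrna", "trna", "tasirna", "pseudo", "te"):
            cls = {"rrna": "rRNA", "trna": "tRNA", "tasirna": "tasiRNA_locus",
                   "pseudo": "pseudogene", "te": "transposable_element"}[kind]
            fid = f"{cls}_{int(idx)+1}"
            end = pos + length - 1
            feats.append(Feature(fid, cls, chrom, pos, end, strand, fid))
            pos = end + 1
        elif kind == "igcluster":
            end = pos + length - 1
            cluster_rows.append({"id": f"IGC{int(idx)+1:02d}", "chrom": chrom,
                                 "start": pos, "end": end, "strand": strand,
                                 "relation": "intergenic", "host_gene": ""})
            pos = end + 1
        elif kind == "igmirna":
            end = pos + 20
            mirna_rows.append({"name": f"novel-mir-ig{int(idx)+1}", "chrom": chrom,
                               "start": pos, "end": end, "strand": strand,
                               "context": "intergenic", "host_gene": "", "known": False})
            pos = end + 1

    genome_seq = "".join(np.array(list("ACGT"))[
        rng.integers(0, 4, size=spec.genome_length)])
    genome = {chrom: genome_seq}

    genes = pd.DataFrame(gene_rows).set_index("id") if gene_rows else pd.DataFrame(
        columns=["chrom", "start", "end", "strand"])

    # planted NATs: inside a gene's span, opposite strand
    host_ids = list(genes.index[: spec.n_planted_nats])
    if len(host_ids) < spec.n_planted_nats:
        raise ValueError("not enough genes to host the planted NATs")
    for i, gid in enumerate(host_ids):
        g = genes.loc[gid]
        length = min(500, int(g.end - g.start + 1) - 40)
        if length < 300:
            raise ValueError(f"gene {gid} too short to host a >=300 bp NAT")
        s = int(g.start) + 20
        cluster_rows.append({"id": f"NAT{i+1:02d}", "chrom": chrom, "start": s,
                             "end": s + length - 1,
                             "strand": "-" if g.strand == "+" else "+",
                             "relation": "antisense_to", "host_gene": gid})

    # planted intronic novel miRNAs: inside an intron, same strand as host
    ann_tmp = AnnotationSet(feats)
    introns = ann_tmp.of_class("protein_coding_intron")
    if len(introns) < spec.n_novel_mirna_intronic:
        raise ValueError("not enough introns to host planted intronic miRNAs")
    for i in range(spec.n_novel_mirna_intronic):
        intron = introns[i * max(1, len(introns) // max(spec.n_novel_mirna_intronic, 1))]
        s = intron.start + (intron.length - 21) // 2
        mirna_rows.append({"name": f"novel-mir-in{i+1}", "chrom": chrom,
                           "start": s, "end": s + 20, "strand": intron.strand,
                           "context": "intron", "host_gene": intron.gene_id,
                           "known": False})
    for mid, s, e, strand in known_mirna_spans:
        mirna_rows.append({"name": f"{mid}.mature", "chrom": chrom, "start": s,
                           "end": e, "strand": strand, "context": "known_stem_loop",
                           "host_gene": mid, "known": True})

    # condition means and fold changes
    if len(genes):
        base = np.exp(rng.normal(np.log(spec.mean_gene_expression), 0.6,
                                 size=len(genes))).clip(min=10)
        n_de = int(round(spec.frac_de_genes * len(genes)))
        lfc = np.zeros(len(genes))
        de_idx = rng.choice(len(genes), size=n_de, replace=False)
        signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
        lfc[de_idx] = signs * spec.lfc_magnitude
        genes["mean_KCl"] = base
        genes["mean_KNO3"] = base * 2.0 ** lfc
        genes["lfc"] = lfc
        genes["is_de"] = lfc != 0

    cluster_cols = ["id", "chrom", "start", "end", "strand", "relation", "host_gene"]
    clusters = pd.DataFrame(cluster_rows, columns=cluster_cols).set_index("id")
    clusters["mean_KCl"] = spec.cluster_mean_count
    clusters["mean_KNO3"] = spec.cluster_mean_count
    clusters["induced"] = False
    if spec.n_planted_nats > 0:
        clusters.loc["NAT01", "mean_KNO3"] = 4.0 * spec.cluster_mean_count
        clusters.loc["NAT01", "induced"] = True

    mirna_cols = ["name", "chrom", "start", "end", "strand", "context",
                  "host_gene", "known"]
    mirnas = pd.DataFrame(mirna_rows, columns=mirna_cols).set_index("name")
    mat = []
    for name, row in mirnas.iterrows():
        sub = genome_seq[int(row.start) - 1:int(row.end)]
        mat.append(sub if row.strand == "+" else revcomp(sub))
    mirnas["mature"] = mat
    mirnas["mean_count"] = np.where(mirnas["known"], spec.mirna_mean_count, 30.0)

    truth = TruthTable(genes, clusters, mirnas)
    return genome, AnnotationSet(feats), truth


def simulate_counts(truth: TruthTable, n_replicates: int,
                    spec: GenomeSpec) -> dict[str, pd.DataFrame]:
    """NB counts per feature and sample for genes, clusters and miRNAs."""
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    rng = np.random.default_rng((spec.seed, 2))
    samples = [f"{c}_{r+1}" for c in ("KNO3", "KCl") for r in range(n_replicates)]

    def draw(df, mean_cols) -> pd.DataFrame:
        out = {}
        for s in samples:
            cond = s.split("_")[0]
            means = df[mean_cols[cond]].to_numpy(dtype=float) if len(df) else []
            out[s] = _nb_draw(rng, means, spec.nb_dispersion)
        return pd.DataFrame(out, index=df.index, dtype=int)

    cols = {"KNO3": "mean_KNO3", "KCl": "mean_KCl"}
    return {
        "genes": draw(truth.genes, cols),
        "clusters": draw(truth.clusters, cols),
        "mirnas": draw(truth.mirnas, {"KNO3": "mean_count", "KCl": "mean_count"}),
    }


def _qualities(rng, n_bases: int, spec: GenomeSpec, bad: bool) -> list[int]:
    if bad:
        return [spec.q_low] * n_bases
    q = np.full(n_bases, spec.q_high)
    low = rng.random(n_bases) < 0.01
    q[low] = spec.q_low
    return q.tolist()


def _spaced_starts(start: int, end: int, read_len: int, n: int) -> np.ndarray:
    """n read starts evenly covering [start, end] (outermost edges exact)."""
    hi = end - read_len + 1
    if n == 1:
        return np.array([start])
    return np.unique(np.round(np.linspace(start, hi, n)).astype(int))


def simulate_reads(genome: dict[str, str], ann: AnnotationSet, truth: TruthTable,
                   counts: dict[str, pd.DataFrame], spec: GenomeSpec,
                   outdir) -> dict[str, dict[str, Path]]:
    """Write {sample}_polyA.fastq and {sample}_sRNA.fastq per sample.

    Poly-A+ reads are read_length_mrna-base sense fragments of gene spans
    (planted clusters emit reads on the cluster strand, half of them evenly
    spaced so the planted region is fully tiled); sRNA reads carry the 3'
    adaptor whenever the insert is shorter than the cycle length.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chrom = next(iter(genome))
    seq = genome[chrom]
    L = spec.read_length_mrna
    cyc = spec.srna_cycle_length
    paths: dict[str, dict[str, Path]] = {}
    samples = list(counts["genes"].columns)
    for si, sample in enumerate(samples):
        rng = np.random.default_rng((spec.seed, 3, si))
        polya_lines: list[str] = []
        serial = 0

        def emit_polya(start0: int, strand: str, rlen: int = L):
            nonlocal serial
            frag = seq[start0:start0 + rlen]
            if strand == "-":
                frag = revcomp(frag)
            bad = rng.random() < spec.low_quality_read_frac
            q = "".join(chr(33 + x) for x in _qualities(rng, rlen, spec, bad))
            serial += 1
            polya_lines.append(f"@pA_{sample}_{serial}\n{frag}\n+\n{q}\n")

        for gid, c in counts["genes"][sample].items():
            g = truth.genes.loc[gid]
            hi = int(g.end) - L + 1
            if hi < int(g.start):
                raise ValueError(f"gene {gid} shorter than the read length")
            for s0 in rng.integers(int(g.start), hi + 1, size=int(c)):
                emit_polya(int(s0) - 1, g.strand)
        for cid, c in counts["clusters"][sample].items():
            cl = truth.clusters.loc[cid]
            c = int(c)
            if c == 0:
                continue
            n_even = max(2, c // 2)
            starts = list(_spaced_starts(int(cl.start), int(cl.end), L, n_even))
            n_rand = max(0, c - len(starts))
            hi = int(cl.end) - L + 1
            starts += list(rng.integers(int(cl.start), hi + 1, size=n_rand))
            for s0 in starts:
                emit_polya(int(s0) - 1, cl.strand)
        for _ in range(spec.n_background_polya):
            s0 = int(rng.integers(0, len(seq) - L))
            emit_polya(s0, "+" if rng.random() < 0.5 else "-")

        srna_lines: list[str] = []
        serial = 0

        def emit_srna(insert: str):
            nonlocal serial
            read = (insert + spec.adaptor + "A" * cyc)[:cyc]
            bad = rng.random() < spec.low_quality_read_frac
            q = "".join(chr(33 + x) for x in _qualities(rng, len(read), spec, bad))
            serial += 1
            srna_lines.append(f"@sR_{sample}_{serial}\n{read}\n+\n{q}\n")

        for name, c in counts["mirnas"][sample].items():
            mature = truth.mirnas.loc[name, "mature"]
            for _ in range(int(c)):
                emit_srna(mature)
        lengths = np.array(list(SRNA_LENGTH_WEIGHTS))
        weights = np.array(list(SRNA_LENGTH_WEIGHTS.values()))
        weights = weights / weights.sum()
        for _ in range(spec.n_background_srna):
            u = rng.random()
            if u < 0.02:       # too-short junk, removed by the size filter
                ln = int(rng.integers(10, 18))
            elif u < 0.04:     # long degradation fragment, removed by size filter
                ln = int(rng.integers(29, 41))
            else:
                ln = int(rng.choice(lengths, p=weights))
            s0 = int(rng.integers(0, len(seq) - ln))
            insert = seq[s0:s0 + ln]
            if rng.random() < 0.5:
                insert = revcomp(insert)
            emit_srna(insert)

        p_polya = outdir / f"{sample}_polyA.fastq"
        p_srna = outdir / f"{sample}_sRNA.fastq"
        p_polya.write_text("".join(polya_lines))
        p_srna.write_text("".join(srna_lines))
        paths[sample] = {"polyA": p_polya, "sRNA": p_srna}
    return paths


def simulate_array_table(truth: TruthTable, spec: GenomeSpec,
                         frac_no_probe: float = 0.1,
                         present_threshold: float = 30.0) -> pd.DataFrame:
    """Synthetic normalized microarray table with present/absent calls.

    A fraction of genes get no probe (emulating array under-representation);
    signals are noisy log2 condition means; the present call is a detection
    verdict driven by expression level.
    """
    rng = np.random.default_rng((spec.seed, 4))
    genes = truth.genes
    n_probe = int(round(len(genes) * (1 - frac_no_probe)))
    probed = list(genes.index[:n_probe])
    rows = []
    for i, gid in enumerate(probed):
        g = genes.loc[gid]
        noise = rng.normal(0, 0.1, size=2)
        rows.append({
            "probe": f"P{i+1:05d}_at", "gene": gid,
            "signal_KNO3": float(np.log2(g.mean_KNO3 + 1) + noise[0]),
            "signal_KCl": float(np.log2(g.mean_KCl + 1) + noise[1]),
            "present": bool(max(g.mean_KNO3, g.mean_KCl) >= present_threshold),
        })
    return pd.DataFrame(rows)


def write_fasta(genome: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
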