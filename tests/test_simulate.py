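import numpy as np
import pandas as pd
import pytest

from nitroseq.mapping import revcomp
from nitroseq.reads import DEFAULT_ADAPTOR, FilterConfig, process_library, read_fastq
from nitroseq.simulate import (SRNA_LENGTH_WEIGHTS, GenomeSpec, make_genome,
                               simulate_counts, simulate_reads)

from conftest import gene_truth, make_truth


class TestMakeGenome:
    def test_no_genes_no_gene_features(self):
        spec = GenomeSpec(n_genes=0, n_planted_nats=0, n_novel_mirna_intronic=0,
                          genome_length=60_000, seed=1)
        _, ann, truth = make_genome(spec)
        assert ann.genes == [] and len(truth.genes) == 0

    def test_same_seed_byte_identical(self, tmp_path):
        from nitroseq.annotation import write_gff3
        from nitroseq.simulate import write_fasta
        spec = GenomeSpec(seed=5)
        for run in ("a", "b"):
            genome, ann, truth = make_genome(spec)
            write_fasta(genome, tmp_path / f"{run}.fa")
            write_gff3(ann, tmp_path / f"{run}.gff3")
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()
        assert (tmp_path / "a.gff3").read_bytes() == (tmp_path / "b.gff3").read_bytes()

    def test_planted_nats_inside_host_genes_opposite_strand(self):
        _, ann, truth = make_genome(GenomeSpec(n_planted_nats=4, seed=2))
        nats = truth.clusters[truth.clusters.relation == "antisense_to"]
        assert len(nats) == 4
        for _, nat in nats.iterrows():
            host = truth.genes.loc[nat.host_gene]
            assert host.start <= nat.start <= nat.end <= host.end
            assert nat.strand != host.strand
            # and no same-strand annotated feature under the cluster
            assert not ann.overlapping(nat.chrom, nat.start, nat.end,
                                       strand=nat.strand)

    def test_planted_elements_within_bounds_and_unique(self):
        spec = GenomeSpec(seed=3)
        genome, ann, truth = make_genome(spec)
        L = len(genome["Chr1"])
        for df in (truth.genes, truth.clusters, truth.mirnas):
            assert df.index.is_unique
            assert (df.start >= 1).all() and (df.end <= L).all()

    def test_oversized_footprint_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            make_genome(GenomeSpec(genome_length=5_000, seed=0))


class TestSimulateCounts:
    def test_null_construction_mean_ratio_near_zero(self):
        truth = gene_truth(400, frac_de=0.0, lfc=0.0, seed=4)
        counts = simulate_counts(truth, 2, GenomeSpec(seed=4))["genes"]
        ratio = np.log2((counts[["KNO3_1", "KNO3_2"]].mean(1) + 0.5)
                        / (counts[["KCl_1", "KCl_2"]].mean(1) + 0.5))
        assert abs(ratio.mean()) < 0.02

    def test_poisson_limit_variance_equals_mean(self):
        truth = gene_truth(10_000, frac_de=0.0, lfc=0.0, seed=5,
                           mean_log=np.log(100), sd_log=1e-9)
        spec = GenomeSpec(seed=5, nb_dispersion=1e-13)
        draws = simulate_counts(truth, 2, spec)["genes"].to_numpy().ravel()
        assert draws.var() == pytest.approx(draws.mean(), rel=0.05)

    def test_nb_variance_recovered(self):
        truth = gene_truth(10_000, frac_de=0.0, lfc=0.0, seed=6,
                           mean_log=np.log(100), sd_log=1e-9)
        spec = GenomeSpec(seed=6, nb_dispersion=0.05)
        draws = simulate_counts(truth, 2, spec)["genes"].to_numpy().ravel()
        expected = 100 + 0.05 * 100 ** 2
        assert draws.var() == pytest.approx(expected, rel=0.10)

    def test_planted_fourfold_gene_realized_ratio(self):
        genes = pd.DataFrame(
            {"chrom": "Chr1", "start": 1, "end": 100, "strand": "+",
             "mean_KCl": [100.0] * 200, "mean_KNO3": [400.0] * 200,
             "lfc": 2.0, "is_de": True},
            index=pd.Index([f"G{i}" for i in range(200)], name="id"))
        counts = simulate_counts(make_truth(genes=genes), 2, GenomeSpec(seed=7))["genes"]
        ratio = np.log2(counts[["KNO3_1", "KNO3_2"]].mean(1).mean()
                        / counts[["KCl_1", "KCl_2"]].mean(1).mean())
        assert ratio == pytest.approx(2.0, abs=0.1)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            simulate_counts(make_truth(), 1, GenomeSpec(seed=0))


@pytest.fixture(scope="module")
def dataset(tmp_path_factory):
    spec = GenomeSpec(seed=11, n_background_srna=6000)
    genome, ann, truth = make_genome(spec)
    counts = simulate_counts(truth, 2, spec)
    outdir = tmp_path_factory.mktemp("reads")
    paths = simulate_reads(genome, ann, truth, counts, spec, outdir)
    return spec, genome, truth, counts, paths


class TestSimulateReads:
    def test_mirna_counts_become_exact_reads(self, dataset):
        spec, genome, truth, counts, paths = dataset
        name = truth.mirnas.index[0]
        mature = truth.mirnas.loc[name, "mature"]
        rs = process_library(read_fastq(paths["KNO3_1"]["sRNA"]),
                             FilterConfig.srna(adaptor=spec.adaptor))
        # every copy of the mature miRNA trims back to exactly its sequence;
        # low-quality reads are lost to the Q20 filter, so count is a lower bound
        assert rs.counts[mature] >= 1
        raw = [r for r in read_fastq(paths["KNO3_1"]["sRNA"])
               if r.sequence.startswith(mature)]
        assert len(raw) == counts["mirnas"].loc[name, "KNO3_1"]

    def test_adaptor_follows_insert(self, dataset):
        spec, genome, truth, counts, paths = dataset
        mature = truth.mirnas["mature"].iloc[0]
        for r in read_fastq(paths["KCl_1"]["sRNA"]):
            if r.sequence.startswith(mature) and len(mature) < spec.srna_cycle_length:
                tail = r.sequence[len(mature):]
                assert spec.adaptor.startswith(tail) or tail.startswith(spec.adaptor[
                    :spec.srna_cycle_length - len(mature)])
                break
        else:
            pytest.fail("no mature-miRNA read found")

    def test_insert_length_histogram_bimodal_21_then_24(self, dataset):
        spec, genome, truth, counts, paths = dataset
        from nitroseq.classify import size_distribution
        rs = process_library(read_fastq(paths["KNO3_1"]["sRNA"]),
                             FilterConfig.srna(adaptor=spec.adaptor))
        assert rs.total_reads >= 5000
        hist = size_distribution(rs)
        ranked = hist.drop(21).idxmax()
        assert hist.idxmax() == 21 and ranked == 24

    def test_polya_reads_are_sense_fragments(self, dataset):
        spec, genome, truth, counts, paths = dataset
        gene = truth.genes.iloc[0]
        span = genome["Chr1"][int(gene.start) - 1:int(gene.end)]
        if gene.strand == "-":
            span = revcomp(span)
        hits = 0
        for r in read_fastq(paths["KCl_2"]["polyA"]):
            if r.sequence in span:
                hits += 1
                if hits >= 5:
                    break
        assert hits >= 5

    def test_same_seed_identical_fastq_bytes(self, dataset, tmp_path):
        spec, genome, truth, counts, paths = dataset
        _, ann2, _ = make_genome(spec)
        paths2 = simulate_reads(genome, ann2, truth, counts, spec, tmp_path)
        a = paths["KNO3_1"]["sRNA"].read_bytes()
        b = paths2["KNO3_1"]["sRNA"].read_bytes()
        assert a == b
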