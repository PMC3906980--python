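import numpy as np
import pytest

from nitroseq.annotation import AnnotationSet, Feature
from nitroseq.classify import (SmallRnaCatalog, classify_alignment,
                               detection_summary, known_srna_expression,
                               size_distribution, weighted_category_counts)
from nitroseq.mapping import AlignmentRecord
from nitroseq.reads import ReadSet


def rec(start, end, strand="+", n_loci=1, mult=1, seq=None):
    seq = seq or "A" * (end - start + 1)
    return AlignmentRecord("r", seq, mult, "c", start, end, strand, n_loci)


@pytest.fixture
def ann():
    return AnnotationSet([
        Feature("rrna1", "rRNA", "c", 100, 600, "+"),
        Feature("g1", "gene", "c", 1000, 2000, "+", "g1"),
        Feature("g1.e1", "protein_coding_exon", "c", 1000, 1400, "+", "g1"),
        Feature("g1.i1", "protein_coding_intron", "c", 1401, 1600, "+", "g1"),
        Feature("g1.e2", "protein_coding_exon", "c", 1601, 2000, "+", "g1"),
        Feature("mir1", "miRNA_stem_loop", "c", 3000, 3120, "+", "mir1"),
        Feature("mir1.m", "mature_miRNA", "c", 3020, 3040, "+", "mir1"),
    ])


class TestClassifyAlignment:
    def test_same_strand_rrna(self, ann):
        assert classify_alignment(rec(150, 170), ann) == "rRNA"

    def test_no_same_strand_overlap_is_intergenic(self, ann):
        assert classify_alignment(rec(150, 170, strand="-"), ann) == "intergenic"
        assert classify_alignment(rec(5000, 5020), ann) == "intergenic"

    def test_mature_mirna_outranks_stem_loop(self, ann):
        assert classify_alignment(rec(3025, 3045), ann) == "mature_miRNA"
        assert classify_alignment(rec(3050, 3070), ann) == "miRNA_stem_loop"

    def test_exon_intron_utr_collapse_to_protein_coding(self, ann):
        assert classify_alignment(rec(1390, 1410), ann) == "protein_coding"

    def test_out_of_bounds_record_raises(self, ann):
        with pytest.raises(ValueError, match="bounds"):
            classify_alignment(rec(9990, 10010), ann, chrom_lengths={"c": 10000})


class TestWeightedCounts:
    def test_multi_locus_read_split_across_categories(self, ann):
        records = [
            AlignmentRecord("r", "A" * 21, 1, "c", 3020, 3040, "+", 2),
            AlignmentRecord("r", "A" * 21, 1, "c", 5000, 5020, "+", 2),
        ]
        b = weighted_category_counts(records, ann)
        assert b.counts["mature_miRNA"] == pytest.approx(0.5)
        assert b.counts["intergenic"] == pytest.approx(0.5)

    def test_unique_exonic_reads_count_whole(self, ann):
        records = [rec(1000 + 30 * i, 1020 + 30 * i) for i in range(3)]
        b = weighted_category_counts(records, ann)
        assert b.counts["protein_coding"] == pytest.approx(3.0)

    def test_unique_scope_excludes_multimappers(self, ann):
        records = [rec(1000, 1020),
                   AlignmentRecord("m", "A" * 21, 5, "c", 150, 170, "+", 2),
                   AlignmentRecord("m", "A" * 21, 5, "c", 5000, 5020, "+", 2)]
        all_scope = weighted_category_counts(records, ann, scope="all")
        uniq = weighted_category_counts(records, ann, scope="unique")
        assert uniq.counts.sum() == pytest.approx(1.0)
        assert (uniq.counts <= all_scope.counts + 1e-12).all()

    def test_conservation_total_weight_equals_read_multiplicities(self, ann):
        rng = np.random.default_rng(2)
        records, total = [], 0.0
        for i in range(300):
            n_loci = int(rng.integers(1, 4))
            mult = int(rng.integers(1, 6))
            total += mult
            for j in range(n_loci):
                s = int(rng.integers(1, 6000))
                records.append(AlignmentRecord(f"r{i}", "A" * 21, mult, "c",
                                               s, s + 20, "+", n_loci))
        b = weighted_category_counts(records, ann)
        assert b.counts.sum() == pytest.approx(total, abs=1e-9)
        assert b.percentages.sum() == pytest.approx(100.0)


class TestSizeDistribution:
    def test_single_length_single_bin(self):
        rs = ReadSet(label="sRNA")
        rs.counts["A" * 10 + "C" * 11] = 7
        hist = size_distribution(rs)
        assert hist[21] == 7 and hist.sum() == 7

    def test_empty_set_all_zero(self):
        assert size_distribution(ReadSet(label="sRNA")).sum() == 0

    def test_bimodal_library_peaks_at_21_then_24(self):
        rng = np.random.default_rng(0)
        rs = ReadSet(label="sRNA")
        for i in range(2000):
            L = 21 if rng.random() < 0.55 else 24
            rs.counts["".join(rng.choice(list("ACGT"), L))] += 1
        hist = size_distribution(rs)
        ranked = hist.sort_values(ascending=False)
        assert list(ranked.index[:2]) == [21, 24]


class TestKnownSrnaExpression:
    def test_detection_counts(self):
        cat = SmallRnaCatalog({"a": "ACGUACGUACGUACGUACGU",
                               "b": "UGCAUGCAUGCAUGCAUGCA",
                               "c": "GGGGCCCCGGGGCCCCGGGG"})
        rs = ReadSet(label="sRNA")
        rs.counts["ACGTACGTACGTACGTACGT"] = 5
        rs.counts["TGCATGCATGCATGCATGCA"] = 2
        expr = known_srna_expression(rs, cat)
        assert detection_summary(expr)["detected_sequences"] == 2
        assert expr.set_index("name").loc["a", "count"] == 5

    def test_u_t_normalization_mir5640(self):
        # mature sequence of the intronic miRNA targeting AtPPC3
        cat = SmallRnaCatalog({"miR5640": "AUGAGAGAAGGAAUUAGAUUC"})
        rs = ReadSet(label="sRNA")
        rs.counts["ATGAGAGAAGGAATTAGATTC"] = 1
        expr = known_srna_expression(rs, cat)
        assert bool(expr["detected"].iloc[0])

    def test_empty_reads_zero_detections(self):
        cat = SmallRnaCatalog({"a": "ACGUACGUACGUACGUACGU"})
        expr = known_srna_expression(ReadSet(label="sRNA"), cat)
        assert detection_summary(expr)["detected_sequences"] == 0

    def test_duplicate_catalog_names_rejected(self, tmp_path):
        p = tmp_path / "cat.tsv"
        p.write_text("a\tACGUACGUACGUACGUACGU\na\tUGCAUGCAUGCAUGCAUGCA\n")
        with pytest.raises(ValueError, match="duplicate"):
            SmallRnaCatalog.from_tsv(p)
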