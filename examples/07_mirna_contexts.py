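"""Genomic-context annotation of the packaged novel-miRNA table: each locus
is assigned to a known stem-loop, 5'UTR, intron, pseudogene or intergenic
context, and flagged novel against a known mature-sequence catalog."""

from nitroseq import load_fixture_tables, summarize_contexts
from nitroseq.classify import SmallRnaCatalog
from nitroseq.mirna import flag_novel

genes, loci = load_fixture_tables()
s = summarize_contexts(loci)
print(f"{s.total} novel miRNA loci by genomic context:")
for ctx, n in sorted(s.context_counts.items(), key=lambda kv: -kv[1]):
    print(f"  {ctx:16s} {n}")
print(f"cross-validated by other studies: {s.cross_validated}")

catalog = SmallRnaCatalog({"miR5640-mature": "AUGAGAGAAGGAAUUAGAUUC"})
m = next(l for l in loci if l.name == "miR5640")
print(f"\nmiR5640 ({m.chrom}:{m.start}-{m.end} {m.strand}, context {m.context},"
      f" host {m.context_detail}) vs a one-entry catalog: "
      f"{flag_novel(m, catalog)}")
print("\nIntronic miRNAs like miR5640 (inside an intron of CALS1) can be")
print("transcribed with their host or from their own promoter; the context")
print("label is the starting point for that analysis.")

print(f"\nCompanion gene table: {len(genes)} nitrate-responsive genes absent")
print("from the ATH1 array, led by "
      + genes.iloc[0]["agi"] + f" (log2 KNO3/KCl = {genes.iloc[0]['log2_ratio']}).")
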