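"""End-to-end orchestration: filter -> map -> classify -> rarefaction ->
counts -> differential expression -> cross-platform -> novel regions ->
miRNA annotation, with a reproducibility manifest of output checksums."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import annotation, classify, crossplatform, diffexpr, mapping, mirna, novel
from . import rarefaction as rare
from . import reads as rd
from . import simulate as sim

log = logging.getLogger("nitroseq")


@dataclass
class PipelineConfig:
    genome: str
    annotation: str
    fastq: dict[str, dict[str, str]]          # sample -> {"polyA": path, "sRNA": path}
    conditions: dict[str, str]                # sample -> KNO3 | KCl
    outdir: str = "nitroseq_out"
    srna_catalog: Optional[str] = None        # TSV name<TAB>sequence
    array_table: Optional[str] = None         # TSV probe/gene/signals/present
    mirna_loci: Optional[str] = None          # TSV in the novel-miRNA table layout
    min_cluster_len: int = 300
    alpha: float = 0.05
    agc_thresholds: tuple = crossplatform.DEFAULT_AGC_GRID
    read_length_mrna: int = 50
    adaptor: str = rd.DEFAULT_ADAPTOR
    rarefaction_resamples: int = 5
    seed: int = 0

    def validate(self) -> None:
        missing = [p for p in self._paths() if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input path(s): {missing}")
        if self.min_cluster_len <= 0 or self.alpha <= 0:
            raise ValueError("thresholds must be positive")

    def _paths(self) -> list[str]:
        out = [self.genome, self.annotation]
        for files in self.fastq.values():
            out.extend(files.values())
        out += [p for p in (self.srna_catalog, self.array_table, self.mirna_loci) if p]
        return out

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "agc_thresholds" in raw:
            raw["agc_thresholds"] = tuple(raw["agc_thresholds"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = self.__dict__.copy()
        d["agc_thresholds"] = list(d["agc_thresholds"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages, writing TSV/GFF3/BED outputs and a run manifest.

    Returns the manifest dict (config snapshot + per-output sha256 checksums).
    """
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "filter"
    try:
        ann = annotation.read_gff3(cfg.annotation)
        index = mapping.build_index(cfg.genome)

        polya_sets, srna_sets, stats = {}, {}, {}
        for sample, files in sorted(cfg.fastq.items()):
            pa = rd.process_library(rd.read_fastq(files["polyA"]),
                                    rd.FilterConfig.polya(adaptor=cfg.adaptor),
                                    label="polyA")
            sr = rd.process_library(rd.read_fastq(files["sRNA"]),
                                    rd.FilterConfig.srna(adaptor=cfg.adaptor),
                                    label="sRNA")
            polya_sets[sample], srna_sets[sample] = pa, sr
            stats[f"{sample}_polyA"], stats[f"{sample}_sRNA"] = pa.stats, sr.stats
            log.info("filter %s: polyA %d/%d retained, sRNA %d/%d retained",
                     sample, pa.stats.retained, pa.stats.raw,
                     sr.stats.retained, sr.stats.raw)
        rd.stats_table(stats).to_csv(out / "filter_stats.tsv", sep="\t", index=False)

        stage = "map"
        polya_recs, srna_recs = {}, {}
        for sample in sorted(cfg.fastq):
            polya_recs[sample], acct_p = mapping.map_reads(polya_sets[sample], index)
            srna_recs[sample], acct_s = mapping.map_reads(srna_sets[sample], index)
            log.info("map %s: polyA %s sRNA %s", sample, acct_p, acct_s)

        stage = "classify"
        breakdowns = []
        for sample in sorted(cfg.fastq):
            for label, recs in (("polyA", polya_recs[sample]), ("sRNA", srna_recs[sample])):
                for scope in ("all", "unique"):
                    b = classify.weighted_category_counts(recs, ann, scope=scope,
                                                          label=f"{sample}_{label}")
                    df = b.to_frame()
                    df.insert(0, "library", f"{sample}_{label}")
                    df.insert(1, "scope", scope)
                    breakdowns.append(df)
        pd.concat(breakdowns).to_csv(out / "category_breakdown.tsv", sep="\t")
        hists = pd.DataFrame({s: classify.size_distribution(srna_sets[s])
                              for s in sorted(cfg.fastq)})
        hists.to_csv(out / "srna_size_distribution.tsv", sep="\t")
        if cfg.srna_catalog:
            catalog = classify.SmallRnaCatalog.from_tsv(cfg.srna_catalog)
            pooled = rd.ReadSet(label="sRNA")
            for s in srna_sets.values():
                pooled.counts.update(s.counts)
            expr = classify.known_srna_expression(pooled, catalog)
            expr.to_csv(out / "known_srna_expression.tsv", sep="\t", index=False)

        stage = "rarefaction"
        curves = []
        for sample in sorted(cfg.fastq):
            for label, rs in (("polyA", polya_sets[sample]), ("sRNA", srna_sets[sample])):
                curve = rare.rarefaction_curve(
                    rs, n_resamples=cfg.rarefaction_resamples, seed=cfg.seed)
                df = curve.to_frame()
                df.insert(0, "library", f"{sample}_{label}")
                df["saturation_ratio"] = rare.saturation_assessment(curve)
                curves.append(df)
        pd.concat(curves).to_csv(out / "rarefaction.tsv", sep="\t", index=False)

        stage = "counts"
        cm = diffexpr.gene_counts(polya_recs, ann, cfg.conditions)

        stage = "novel_regions"
        pooled = novel.pool_unannotated(polya_recs, ann)
        clusters = [novel.classify_cluster(c, ann)
                    for c in novel.call_clusters(pooled, min_length=cfg.min_cluster_len)]
        novel.clusters_to_gff3(clusters, out / "novel_clusters.gff3")
        novel.clusters_to_bed6(clusters, out / "novel_clusters.bed")
        cl_counts = novel.cluster_counts(clusters, polya_recs)
        cm_all = cm.append(cl_counts) if len(clusters) else cm

        stage = "diff_expr"
        factors = diffexpr.size_factors(cm_all)
        qc = diffexpr.replicate_correlation(cm_all, factors)
        log.info("replicate correlation: %s", qc)
        results = diffexpr.adjust_and_call(diffexpr.nb_test(cm_all, factors),
                                           alpha=cfg.alpha)
        results.to_csv(out / "differential_expression.tsv", sep="\t", index=False)
        with open(out / "qc.json", "w") as fh:
            json.dump({"replicate_correlation": qc}, fh, indent=2)

        stage = "cross_platform"
        if cfg.array_table:
            arr = pd.read_csv(cfg.array_table, sep="\t")
            gene_lengths = pd.Series({g.feature_id: g.length for g in ann.genes})
            sense_counts = cm.counts.sum(axis=1)
            agc = crossplatform.compute_agc(sense_counts, gene_lengths,
                                            cfg.read_length_mrna)
            agc.to_csv(out / "agc.tsv", sep="\t")
            seq_ratio = results.loc[results["id"].isin(gene_lengths.index),
                                    "log2_ratio"]
            arr_ratio = pd.Series((arr["signal_KNO3"] - arr["signal_KCl"]).values,
                                  index=arr["gene"])
            curve = crossplatform.ratio_correlation_by_agc(
                seq_ratio, arr_ratio, agc, cfg.agc_thresholds)
            curve.to_csv(out / "agc_correlation.tsv", sep="\t", index=False)
            det = crossplatform.detection_comparison(
                arr.rename(columns={"present": "present"}), sense_counts)
            with open(out / "detection_comparison.json", "w") as fh:
                json.dump(det.__dict__, fh, indent=2)

        stage = "mirna_annotation"
        if cfg.mirna_loci:
            loci = mirna.loci_from_frame(pd.read_csv(cfg.mirna_loci, sep="\t"))
            for locus in loci:
                mirna.classify_mirna_locus(locus, ann)
                if cfg.srna_catalog:
                    locus.prior_report = mirna.flag_novel(locus, catalog)
            mirna.loci_to_frame(loci).to_csv(out / "mirna_annotation.tsv",
                                             sep="\t", index=False)
            summary = mirna.summarize_contexts(loci)
            with open(out / "mirna_context_summary.json", "w") as fh:
                json.dump({"context_counts": summary.context_counts,
                           "total": summary.total, "novel": summary.novel,
                           "cross_validated": summary.cross_validated}, fh, indent=2)
    except Exception as e:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {e}") from e

    manifest = {
        "config": {k: (v if not isinstance(v, tuple) else list(v))
                   for k, v in cfg.__dict__.items()},
        "checksums": {p.name: _sha256(p) for p in sorted(out.iterdir())
                      if p.is_file() and p.name != "manifest.json"},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def simulate_command(spec: sim.GenomeSpec, outdir, force: bool = False,
                     with_array_table: bool = True) -> PipelineConfig:
    """Write a full synthetic dataset (genome, GFF3, truth, 4 sample FASTQ
    pairs, catalog, array table) and return a ready-to-run PipelineConfig."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"output directory {outdir} is not empty")
    outdir.mkdir(parents=True, exist_ok=True)

    genome, ann, truth = sim.make_genome(spec)
    counts = sim.simulate_counts(truth, n_replicates=2, spec=spec)
    sim.write_fasta(genome, outdir / "genome.fa")
    annotation.write_gff3(ann, outdir / "annotation.gff3")
    truth.write(outdir)
    paths = sim.simulate_reads(genome, ann, truth, counts, spec, outdir / "fastq")

    catalog_path = outdir / "known_srna_catalog.tsv"
    known = truth.mirnas[truth.mirnas["known"]]
    with open(catalog_path, "w") as fh:
        for name, row in known.iterrows():
            fh.write(f"{name}\t{row.mature}\n")

    array_path = None
    if with_array_table:
        array_path = outdir / "array_table.tsv"
        sim.simulate_array_table(truth, spec).to_csv(array_path, sep="\t", index=False)

    cfg = PipelineConfig(
        genome=str(outdir / "genome.fa"),
        annotation=str(outdir / "annotation.gff3"),
        fastq={s: {k: str(v) for k, v in files.items()}
               for s, files in paths.items()},
        conditions={s: sim.CONDITION_OF[s] for s in paths},
        outdir=str(outdir / "results"),
        srna_catalog=str(catalog_path),
        array_table=str(array_path) if array_path else None,
        read_length_mrna=spec.read_length_mrna,
        adaptor=spec.adaptor,
        seed=spec.seed,
    )
    cfg.to_yaml(outdir / "config.yaml")
    return cfg
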