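import numpy as np
import pandas as pd
import pytest

from nitroseq.pipeline import run_pipeline, simulate_command
from nitroseq.simulate import GenomeSpec, TruthTable, make_genome


def make_truth(genes: pd.DataFrame | None = None,
               clusters: pd.DataFrame | None = None,
               mirnas: pd.DataFrame | None = None) -> TruthTable:
    """TruthTable with empty defaults, for count-level tests that need no genome."""
    if genes is None:
        genes = pd.DataFrame(
            columns=["chrom", "start", "end", "strand", "mean_KCl", "mean_KNO3",
                     "lfc", "is_de"], index=pd.Index([], name="id"))
    if clusters is None:
        clusters = pd.DataFrame(
            columns=["chrom", "start", "end", "strand", "relation", "host_gene",
                     "mean_KCl", "mean_KNO3", "induced"], index=pd.Index([], name="id"))
    if mirnas is None:
        mirnas = pd.DataFrame(
            columns=["chrom", "start", "end", "strand", "context", "host_gene",
                     "known", "mature", "mean_count"], index=pd.Index([], name="name"))
    return TruthTable(genes, clusters, mirnas)


def gene_truth(n: int, frac_de: float, lfc: float, seed: int,
               mean_log: float = np.log(200), sd_log: float = 0.6) -> TruthTable:
    """Gene-only truth with lognormal base means and planted fold changes."""
    rng = np.random.default_rng(seed)
    base = np.exp(rng.normal(mean_log, sd_log, n)).clip(10)
    lfcs = np.zeros(n)
    n_de = int(round(frac_de * n))
    de = rng.choice(n, n_de, replace=False)
    lfcs[de] = np.where(np.arange(n_de) % 2 == 0, lfc, -lfc)
    genes = pd.DataFrame(
        {"chrom": "Chr1", "start": 1, "end": 1000, "strand": "+",
         "mean_KCl": base, "mean_KNO3": base * 2.0 ** lfcs,
         "lfc": lfcs, "is_de": lfcs != 0},
        index=pd.Index([f"G{i:05d}" for i in range(n)], name="id"))
    return make_truth(genes=genes)


@pytest.fixture(scope="session")
def demo_spec() -> GenomeSpec:
    return GenomeSpec(seed=7)


@pytest.fixture(scope="session")
def demo_genome(demo_spec):
    return make_genome(demo_spec)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory, demo_spec):
    """One full synthetic dataset + two pipeline runs (for determinism checks)."""
    root = tmp_path_factory.mktemp("demo")
    cfg = simulate_command(demo_spec, root / "data")
    manifest1 = run_pipeline(cfg)
    cfg.outdir = str(root / "results2")
    manifest2 = run_pipeline(cfg)
    return {"root": root, "cfg": cfg, "manifest1": manifest1, "manifest2": manifest2}
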