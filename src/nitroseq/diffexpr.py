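"""Two-condition negative-binomial differential expression.

A documented re-implementation of the classic NB exact test for digital gene
expression at small replicate number: per-sample depth is normalized by
median-of-ratios size factors, per-feature mean and dispersion are estimated
by pooled method-of-moments, and the p-value is the exact conditional
probability, under the null NB model, of condition-sum splits (a, b) with
a + b fixed that are no more probable than the observed split. Calls are made
at Benjamini-Hochberg adjusted p < alpha and split into induced / repressed
by the sign of log2(KNO3/KCl).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import AnnotationSet
from .mapping import AlignmentRecord

CONDITIONS = ("KNO3", "KCl")
MIN_DISPERSION = 1e-8
PSEUDOCOUNT = 0.5


@dataclass
class CountMatrix:
    """Integer feature x sample counts with a sample -> condition labelling."""

    counts: pd.DataFrame                 # features x samples
    conditions: dict[str, str]           # sample -> "KNO3" | "KCl"

    def __post_init__(self):
        unknown = set(self.conditions.values()) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown condition label(s): {unknown}")
        missing = set(self.counts.columns) - set(self.conditions)
        if missing:
            raise ValueError(f"samples without condition label: {missing}")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.conditions[s] == condition]

    def require_replicates(self, n: int = 2) -> None:
        for c in CONDITIONS:
            if len(self.samples_of(c)) < n:
                raise ValueError(f"condition {c} has fewer than {n} replicates")

    def append(self, extra: pd.DataFrame) -> "CountMatrix":
        return CountMatrix(pd.concat([self.counts, extra[self.counts.columns]]),
                           dict(self.conditions))


def gene_counts(records_by_sample: dict[str, Iterable[AlignmentRecord]],
                ann: AnnotationSet, conditions: dict[str, str]) -> CountMatrix:
    """Per-gene counts of uniquely mapping sense reads.

    Only reads with a single genome-wide placement that overlap the gene span
    on the gene's own strand contribute (multiplicity-weighted).
    """
    genes = ann.genes
    gene_ids = [g.feature_id for g in genes]
    data = {}
    for sample, records in records_by_sample.items():
        if sample not in conditions:
            raise ValueError(f"unknown sample label {sample}")
        counts = dict.fromkeys(gene_ids, 0)
        for rec in records:
            if rec.n_loci != 1:
                continue
            for f in ann.overlapping(rec.chrom, rec.start, rec.end, strand=rec.strand):
                if f.feature_class == "gene":
                    counts[f.feature_id] += rec.multiplicity
        data[sample] = counts
    df = pd.DataFrame(data, index=gene_ids).astype(int)
    return CountMatrix(df, dict(conditions))


def size_factors(m: CountMatrix) -> pd.Series:
    """Median-of-ratios normalization against the geometric-mean reference."""
    counts = m.counts.to_numpy(dtype=float)
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError("no feature with positive counts in every sample")
    logc = np.log(counts[all_positive])
    log_ref = logc.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logc - log_ref, axis=0))
    return pd.Series(factors, index=m.counts.columns, name="size_factor")


def _nb_params(mu: float, var: float) -> tuple[float, float]:
    """scipy nbinom (n, p) for a given mean/variance (var > mu required)."""
    n = mu * mu / (var - mu)
    p = mu / var
    return n, p


def _exact_conditional_p(ka: int, kb: int, mu_a: float, var_a: float,
                         mu_b: float, var_b: float) -> float:
    """P of splits no more probable than observed, given the total a + b."""
    s = ka + kb
    if s == 0:
        return 1.0
    a = np.arange(s + 1)
    pa = stats.nbinom.logpmf(a, *_nb_params(mu_a, var_a))
    pb = stats.nbinom.logpmf(s - a, *_nb_params(mu_b, var_b))
    joint = pa + pb
    # stabilized exp to tolerate very small probabilities
    joint = np.exp(joint - joint.max())
    obs = joint[ka]
    return float(joint[joint <= obs * (1 + 1e-8)].sum() / joint.sum())


def fit_dispersion_trend(q: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Parametric mean-dispersion trend alpha(q) = a0 + a1/q, least squares
    over features with positive mean; returns fitted values clipped >= 0."""
    ok = q > 0
    X = np.column_stack([np.ones(ok.sum()), 1.0 / q[ok]])
    coef, *_ = np.linalg.lstsq(X, disp[ok], rcond=None)
    fitted = np.zeros_like(q)
    fitted[ok] = np.clip(X @ coef, 0.0, None)
    return fitted


def nb_test(m: CountMatrix, factors: Optional[pd.Series] = None,
            dispersion_sharing: str = "maximum") -> pd.DataFrame:
    """Per-feature NB exact test; returns a DifferentialResult frame.

    Columns: id, mean_KCl, mean_KNO3, log2_ratio, pval (log2 ratio is
    KNO3/KCl on normalized condition means with a +0.5 pseudocount; features
    with zero total count get p = 1 and an undefined ratio).

    With only two replicates per condition the per-feature method-of-moments
    dispersion has two degrees of freedom and badly underestimates for many
    features, making the exact test anti-conservative; by default each
    feature's dispersion is therefore the maximum of its own estimate and a
    parametric mean-dispersion trend fitted across features
    (``dispersion_sharing="per-feature"`` disables the sharing).
    """
    m.require_replicates(2)
    if factors is None:
        factors = size_factors(m)
    factors = factors.reindex(m.counts.columns)
    counts = m.counts
    norm = counts / factors

    sA = m.samples_of("KNO3")
    sB = m.samples_of("KCl")
    q = norm.mean(axis=1).to_numpy()
    # pooled MoM dispersion: within-condition variance of normalized counts
    v = 0.5 * (norm[sA].var(axis=1, ddof=1) + norm[sB].var(axis=1, ddof=1)).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(q > 0, (v - q) / np.maximum(q, 1e-300) ** 2, 0.0)
    if dispersion_sharing == "maximum" and (q > 0).sum() >= 10:
        alpha = np.maximum(alpha, fit_dispersion_trend(q, alpha))
    elif dispersion_sharing not in ("maximum", "per-feature"):
        raise ValueError("dispersion_sharing must be 'maximum' or 'per-feature'")
    alpha = np.maximum(alpha, MIN_DISPERSION)

    SA = float(factors[sA].sum()); SSA = float((factors[sA] ** 2).sum())
    SB = float(factors[sB].sum()); SSB = float((factors[sB] ** 2).sum())
    kA = counts[sA].sum(axis=1).to_numpy()
    kB = counts[sB].sum(axis=1).to_numpy()
    meanA = norm[sA].mean(axis=1).to_numpy()
    meanB = norm[sB].mean(axis=1).to_numpy()

    pvals = np.ones(len(counts))
    ratios = np.full(len(counts), np.nan)
    for i in range(len(counts)):
        s = int(kA[i] + kB[i])
        if s == 0:
            continue
        ratios[i] = np.log2((meanA[i] + PSEUDOCOUNT) / (meanB[i] + PSEUDOCOUNT))
        mu_a = q[i] * SA
        mu_b = q[i] * SB
        var_a = mu_a + alpha[i] * q[i] ** 2 * SSA
        var_b = mu_b + alpha[i] * q[i] ** 2 * SSB
        pvals[i] = _exact_conditional_p(int(kA[i]), int(kB[i]),
                                        mu_a, var_a, mu_b, var_b)
    return pd.DataFrame({
        "id": counts.index, "mean_KCl": meanB, "mean_KNO3": meanA,
        "log2_ratio": ratios, "pval": pvals,
    }).set_index("id", drop=False)


def adjust_and_call(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """BH adjustment and induced/repressed/unchanged calls at adjusted p < alpha."""
    p = results["pval"].to_numpy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    out = results.copy()
    out["padj"] = stats.false_discovery_control(p, method="bh")
    sig = out["padj"] < alpha
    out["call"] = "unchanged"
    out.loc[sig & (out["log2_ratio"] > 0), "call"] = "induced"
    out.loc[sig & (out["log2_ratio"] < 0), "call"] = "repressed"
    return out


def called(results: pd.DataFrame) -> pd.DataFrame:
    return results[results["call"] != "unchanged"]


def replicate_correlation(m: CountMatrix,
                          factors: Optional[pd.Series] = None) -> dict[str, float]:
    """Pearson r between replicate pairs on log2(normalized count + 1)."""
    if factors is None:
        factors = size_factors(m)
    norm = np.log2(m.counts / factors + 1)
    out = {}
    for c in CONDITIONS:
        samples = m.samples_of(c)
        if len(samples) != 2:
            raise ValueError(f"condition {c} needs exactly 2 replicates")
        x, y = norm[samples[0]], norm[samples[1]]
        if x.std() == 0 or y.std() == 0:
            out[c] = float("nan")  # not assessable
        else:
            out[c] = float(np.corrcoef(x, y)[0, 1])
    return out
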