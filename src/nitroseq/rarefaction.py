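"""Rarefaction (saturation) analysis of sequence diversity.

Classical rarefaction: at each depth d, draw d reads without replacement from
the multiplicity-expanded library and count distinct sequences, averaging over
resamples. A curve that keeps climbing at the full library depth means the
library is far from saturation — every additional read still tends to reveal
a sequence not seen before.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .reads import ReadSet


@dataclass
class RarefactionCurve:
    depths: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    n_resamples: int
    seed: Optional[int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"depth": self.depths, "mean_distinct": self.means,
                             "sd_distinct": self.sds})


def default_depths(total: int, n_points: int = 10) -> list[int]:
    """Ten log-spaced depths from 1 to the library total."""
    if total < 1:
        raise ValueError("empty library")
    pts = np.unique(np.round(np.geomspace(1, total, n_points)).astype(int))
    return list(pts)


def rarefaction_curve(reads: ReadSet, depths: Optional[Sequence[int]] = None,
                      n_resamples: int = 10, seed: Optional[int] = None) -> RarefactionCurve:
    total = reads.total_reads
    if depths is None:
        depths = default_depths(total)
    depths = np.asarray(sorted(depths), dtype=int)
    if len(depths) == 0 or depths[0] < 1:
        raise ValueError("depths must be positive")
    if depths[-1] > total:
        raise ValueError(f"depth {depths[-1]} exceeds library size {total}")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")

    mults = np.fromiter(reads.counts.values(), dtype=int)
    expanded = np.repeat(np.arange(len(mults)), mults)
    rng = np.random.default_rng(seed)
    values = np.empty((n_resamples, len(depths)))
    for r in range(n_resamples):
        perm = rng.permutation(expanded)
        # index of first occurrence of each distinct id in the permutation
        _, first_idx = np.unique(perm, return_index=True)
        values[r] = np.searchsorted(np.sort(first_idx), depths, side="left")
    return RarefactionCurve(depths, values.mean(axis=0),
                            values.std(axis=0, ddof=0), n_resamples, seed)


def saturation_assessment(curve: RarefactionCurve) -> Optional[float]:
    """Final-segment slope over initial slope, in [0, 1].

    The initial slope is taken from the origin (0 reads, 0 distinct) to the
    first depth point; near 0 means saturated, near 1 means every new read is
    still new. Returns None (not assessable) when the initial slope is zero.
    """
    if len(curve.depths) < 3:
        raise ValueError("need >= 3 depths to assess saturation")
    s0 = curve.means[0] / curve.depths[0]
    if s0 <= 0:
        return None
    s1 = (curve.means[-1] - curve.means[-2]) / (curve.depths[-1] - curve.depths[-2])
    return float(min(max(s1 / s0, 0.0), 1.0))
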