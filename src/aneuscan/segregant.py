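"""Pooled-segregant mapping of a causative aneuploid chromosome.

Spores from 2:2 tetrads are pooled by phenotype (resistant vs sensitive)
and the pools sequenced. The chromosome whose extra copy causes the
phenotype sits at ratio ~2 in the resistant pool and ~1 in the sensitive
pool (haploid baseline), while independently assorting disomies land near
1.5 in both; the per-chromosome divergence D = ratio_R - ratio_S separates
the causative chromosome (D -> 1) from passengers (D -> 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .depth_io import COLUMNS, DepthProfile
from .ploidy import normalize

DEFAULT_D_THRESHOLD = 0.5  # half the causative-vs-passenger gap


def pool_profiles(spore_profiles: Sequence[DepthProfile]) -> DepthProfile:
    """Equimolar pool: per-bin mean depth across spore profiles.

    All profiles must share the genome and the exact binning; pooling is
    permutation-invariant.
    """
    if len(spore_profiles) == 0:
        raise ValueError("need at least one profile to pool")
    first = spore_profiles[0]
    coords = first.data[["chrom", "start", "end"]]
    for p in spore_profiles[1:]:
        if p.genome != first.genome or not p.data[["chrom", "start", "end"]].equals(coords):
            raise ValueError("profiles have mismatched genomes or binning")
    depth = np.mean([p.depths for p in spore_profiles], axis=0)
    df = coords.copy()
    df["depth"] = depth
    return DepthProfile(df[COLUMNS], first.genome)


@dataclass
class PoolComparison:
    """Per-chromosome resistant/sensitive pool ratios ranked by divergence."""

    table: pd.DataFrame  # chrom index; ratio_R, ratio_S, D, candidate; sorted by D desc
    d_threshold: float

    @property
    def candidates(self) -> list[str]:
        return self.table.index[self.table["candidate"]].tolist()

    @property
    def top(self) -> str:
        return str(self.table.index[0])


def compare_pools(
    pool_r: DepthProfile,
    pool_s: DepthProfile,
    baseline_ploidy: int = 1,
    d_threshold: float = DEFAULT_D_THRESHOLD,
) -> PoolComparison:
    """Normalized per-chromosome ratios of both pools and their divergence.

    Chromosomes with D = ratio_R - ratio_S >= d_threshold are flagged as
    candidate causative chromosomes, ranked by D descending.
    """
    norm_r = normalize(pool_r)
    norm_s = normalize(pool_s)
    table = pd.DataFrame({"ratio_R": norm_r.ratios, "ratio_S": norm_s.ratios})
    table["D"] = table["ratio_R"] - table["ratio_S"]
    table["candidate"] = table["D"] >= d_threshold
    table = table.sort_values("D", ascending=False, kind="stable")
    _ = baseline_ploidy  # ratios already live on the baseline scale
    return PoolComparison(table=table, d_threshold=d_threshold)
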