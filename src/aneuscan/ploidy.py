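"""Per-chromosome copy-number inference from normalized median read depth.

A chromosome's ratio is its median bin depth divided by a genome-wide
normalization constant (by default the median over all bins). In a diploid,
ratios near 0.5 are monosomies, 1.5 trisomies and 2.0 tetrasomies; ratios
between class centers are reported as intermediate with a two-population
mixture fraction rather than silently rounded.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Literal, Mapping, Union

import numpy as np
import pandas as pd

from .depth_io import DepthProfile

MIN_BINS_PER_CHROM = 20
DEFAULT_TOLERANCE = 0.1

NormalizationMethod = Literal["genome_median", "median_of_medians"]


class MixtureError(ValueError):
    """Raised when a ratio sits exactly at a class center: pure class, no mixture."""


@dataclass(frozen=True)
class NormalizedDepth:
    """Per-chromosome median depths and ratios plus the normalization constant."""

    medians: pd.Series
    ratios: pd.Series
    constant: float

    def __getitem__(self, chrom: str) -> float:
        return float(self.ratios[chrom])


@dataclass(frozen=True)
class MixtureEstimate:
    """Two-population interpretation of an intermediate ratio: a fraction f
    of cells carries ``upper`` copies, the rest ``lower`` = upper - 1."""

    lower: int
    upper: int
    fraction: float


@dataclass(frozen=True)
class ChromosomeCall:
    chrom: str
    median_depth: float
    ratio: float
    copy_class: Union[int, str]  # integer copies or "intermediate"
    mixture_fraction: float | None
    mixture_bounds: tuple[int, int] | None

    @property
    def is_intermediate(self) -> bool:
        return self.copy_class == "intermediate"


@dataclass
class KaryotypeCall:
    """The full per-chromosome classification of one isolate."""

    baseline_ploidy: int
    calls: dict[str, ChromosomeCall] = field(default_factory=dict)

    def __getitem__(self, chrom: str) -> ChromosomeCall:
        return self.calls[chrom]

    @property
    def aneuploid_chromosomes(self) -> list[str]:
        return [
            c.chrom
            for c in self.calls.values()
            if c.copy_class != self.baseline_ploidy
        ]

    @property
    def is_aneuploid(self) -> bool:
        return bool(self.aneuploid_chromosomes)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chrom": c.chrom,
                "median_depth": c.median_depth,
                "ratio": c.ratio,
                "copy_class": c.copy_class,
                "mixture_fraction": c.mixture_fraction,
            }
            for c in self.calls.values()
        ]
        return pd.DataFrame(rows).set_index("chrom")


def normalize(
    profile: DepthProfile, method: NormalizationMethod = "genome_median"
) -> NormalizedDepth:
    """Per-chromosome median bin depth over a genome-wide constant.

    The default constant is the median over all bins genome-wide, which is
    robust as long as a minority of bins is aneuploid; "median_of_medians"
    (median of the 16 chromosome medians) is available as an alternative.
    Requires >= 20 bins per chromosome; rejects an all-zero profile.
    """
    for chrom in profile.chromosomes:
        n = len(profile.chrom_table(chrom))
        if n < MIN_BINS_PER_CHROM:
            raise ValueError(
                f"chromosome {chrom} has only {n} bins "
                f"(minimum {MIN_BINS_PER_CHROM} for a stable median)"
            )
    medians = pd.Series(
        {chrom: float(np.median(profile.chrom_depths(chrom))) for chrom in profile.chromosomes}
    )
    if method == "genome_median":
        constant = float(np.median(profile.depths))
    elif method == "median_of_medians":
        constant = float(np.median(medians.to_numpy()))
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    if constant <= 0:
        raise ValueError("normalization constant is zero (all-zero depth profile?)")
    return NormalizedDepth(medians=medians, ratios=medians / constant, constant=constant)


def estimate_mixture(r: float, baseline_ploidy: int) -> MixtureEstimate:
    """Fraction of cells at the upper of two adjacent copy numbers.

    For a ratio strictly between c/P and (c+1)/P the linear two-population
    model r = ((1-f)*c + f*(c+1))/P gives f = P*r - c.
    """
    if r < 0:
        raise ValueError("ratio must be non-negative")
    scaled = r * baseline_ploidy
    lower = math.floor(scaled)
    frac = scaled - lower
    if frac == 0.0:
        raise MixtureError(
            f"ratio {r} is exactly at copy number {lower}: pure class, no mixture"
        )
    return MixtureEstimate(lower=lower, upper=lower + 1, fraction=frac)


def _round_to_baseline(scaled: float, baseline: int) -> int:
    """Nearest integer; an exact .5 midpoint breaks toward the baseline copy."""
    lower, upper = math.floor(scaled), math.ceil(scaled)
    if lower == upper:
        return lower
    if scaled - lower < upper - scaled:
        return lower
    if upper - scaled < scaled - lower:
        return upper
    return lower if abs(lower - baseline) <= abs(upper - baseline) else upper


def classify(
    ratios: Union[NormalizedDepth, Mapping[str, float], pd.Series],
    baseline_ploidy: int = 2,
    tolerance: float = DEFAULT_TOLERANCE,
) -> KaryotypeCall:
    """Assign integer copy numbers where the ratio is within tolerance of a
    class center c/P; otherwise report "intermediate" with a mixture fraction.
    """
    if not 0 < tolerance < 1 / (2 * baseline_ploidy):
        raise ValueError(
            f"tolerance must lie in (0, {1 / (2 * baseline_ploidy)}), got {tolerance}"
        )
    if isinstance(ratios, NormalizedDepth):
        medians = ratios.medians
        ratio_map = ratios.ratios
    else:
        ratio_map = pd.Series(ratios, dtype=float)
        medians = pd.Series(np.nan, index=ratio_map.index)

    call = KaryotypeCall(baseline_ploidy=baseline_ploidy)
    for chrom, r in ratio_map.items():
        r = float(r)
        c = _round_to_baseline(r * baseline_ploidy, baseline_ploidy)
        if abs(r - c / baseline_ploidy) <= tolerance:
            cc = ChromosomeCall(str(chrom), float(medians[chrom]), r, c, None, None)
        else:
            mix = estimate_mixture(r, baseline_ploidy)
            cc = ChromosomeCall(
                str(chrom),
                float(medians[chrom]),
                r,
                "intermediate",
                mix.fraction,
                (mix.lower, mix.upper),
            )
        call.calls[str(chrom)] = cc
    return call


def call_karyotype(
    profile: DepthProfile,
    baseline_ploidy: int = 2,
    tolerance: float = DEFAULT_TOLERANCE,
    method: NormalizationMethod = "genome_median",
) -> KaryotypeCall:
    """normalize + classify in one step."""
    return classify(normalize(profile, method=method), baseline_ploidy, tolerance)


@dataclass
class IsolateSummary:
    """Cohort-level counts over a set of classified isolates."""

    n_isolates: int
    n_aneuploid: int
    per_chromosome: dict[str, int]  # isolates with any aneuploidy of that chromosome
    per_copy_class: dict[str, Counter]  # chrom -> Counter{copy_class: n isolates}

    def n_with_copy(self, chrom: str, copy_class: int) -> int:
        return self.per_copy_class.get(chrom, Counter()).get(copy_class, 0)

    def n_with_gain(self, chrom: str, baseline: int = 2) -> int:
        ctr = self.per_copy_class.get(chrom, Counter())
        return sum(n for c, n in ctr.items() if isinstance(c, int) and c > baseline)

    def n_with_loss(self, chrom: str, baseline: int = 2) -> int:
        ctr = self.per_copy_class.get(chrom, Counter())
        return sum(n for c, n in ctr.items() if isinstance(c, int) and c < baseline)


def summarize_isolates(calls: Mapping[str, KaryotypeCall]) -> IsolateSummary:
    """Count aneuploid isolates and isolates per aneuploid chromosome/class."""
    if not calls:
        raise ValueError("no isolates to summarize")
    per_chrom: Counter = Counter()
    per_class: dict[str, Counter] = {}
    n_aneuploid = 0
    for call in calls.values():
        aneu = call.aneuploid_chromosomes
        if aneu:
            n_aneuploid += 1
        for chrom in aneu:
            per_chrom[chrom] += 1
            per_class.setdefault(chrom, Counter())[call[chrom].copy_class] += 1
    return IsolateSummary(
        n_isolates=len(calls),
        n_aneuploid=n_aneuploid,
        per_chromosome=dict(per_chrom),
        per_copy_class=per_class,
    )
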