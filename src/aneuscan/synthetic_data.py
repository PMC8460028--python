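"""Synthetic inputs for the pipeline: depth profiles, tetrads, mixtures, expression.

The generator emulates the sequencing design of a diploid yeast aneuploidy
study: ~100x whole-genome coverage over a 16-chromosome genome in 1 kb bins,
per-chromosome copy-number deviations (monosomy through tetrasomy), segmental
duplications/deletions on one homolog, 2:2 tetrad segregation of disomies,
mixed cell populations, and gene expression proportional to copy number.

Per-bin depth is negative binomial with mean ``lambda * c / P`` (``c`` the
local copy number, ``P`` the baseline ploidy); the Poisson case is the
infinite-dispersion limit. Mappability, GC bias and repeat masking are not
modeled. All draws are seeded and reproducible: identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .genome import GenomeModel
from .depth_io import COLUMNS, DepthProfile
from .expression import ExpressionTable

DEFAULT_COVERAGE = 100.0  # reads per full bin per baseline copy set (~100-fold WGS)
DEFAULT_DISPERSION = 50.0  # per-bin CV ~17% at 100x, typical of WGS in 1 kb bins


@dataclass(frozen=True)
class Segment:
    """A sub-chromosomal interval with its own copy number."""

    chrom: str
    start: int
    end: int
    copy_number: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"segment {self.chrom}:{self.start}-{self.end} is empty")
        if self.copy_number < 0:
            raise ValueError("segment copy number must be >= 0")


@dataclass
class Karyotype:
    """Baseline ploidy plus per-chromosome and per-segment copy numbers.

    Chromosomes absent from ``copy_number`` default to the baseline.
    """

    baseline_ploidy: int = 2
    copy_number: dict[str, int] = field(default_factory=dict)
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.baseline_ploidy < 1:
            raise ValueError("baseline ploidy must be >= 1")
        for chrom, c in self.copy_number.items():
            if c < 0:
                raise ValueError(f"copy number for {chrom} must be >= 0, got {c}")
        self.segments = [s if isinstance(s, Segment) else Segment(*s) for s in self.segments]

    def copy_of(self, chrom: str) -> int:
        return self.copy_number.get(chrom, self.baseline_ploidy)

    def copy_at(self, chrom: str, pos: int) -> int:
        """Local copy number at a position, segment overrides included."""
        for seg in self.segments:
            if seg.chrom == chrom and seg.start <= pos < seg.end:
                return seg.copy_number
        return self.copy_of(chrom)

    def validate_against(self, genome: GenomeModel) -> None:
        for chrom in self.copy_number:
            if chrom not in genome.lengths:
                raise ValueError(f"karyotype names unknown chromosome {chrom!r}")
        for seg in self.segments:
            if seg.chrom not in genome.lengths:
                raise ValueError(f"segment on unknown chromosome {seg.chrom!r}")
            length = genome.length(seg.chrom)
            if seg.start < 0 or seg.end > length:
                raise ValueError(
                    f"segment {seg.chrom}:{seg.start}-{seg.end} lies outside "
                    f"chromosome {seg.chrom} (length {length})"
                )

    def bin_copy_numbers(self, genome: GenomeModel, chrom: str) -> np.ndarray:
        """Per-bin expected copy number; partially overlapped bins are
        overlap-weighted so expectations stay exact at segment edges."""
        starts, ends = genome.bin_edges(chrom)
        starts_a, ends_a = np.asarray(starts), np.asarray(ends)
        base = float(self.copy_of(chrom))
        copies = np.full(len(starts), base)
        for seg in self.segments:
            if seg.chrom != chrom:
                continue
            overlap = np.clip(
                np.minimum(ends_a, seg.end) - np.maximum(starts_a, seg.start), 0, None
            )
            frac = overlap / (ends_a - starts_a)
            copies += frac * (seg.copy_number - base)
        return copies

    def to_yaml(self, path) -> None:
        doc = {
            "baseline_ploidy": self.baseline_ploidy,
            "copy_number": dict(self.copy_number),
            "segments": [
                {"chrom": s.chrom, "start": s.start, "end": s.end, "copy_number": s.copy_number}
                for s in self.segments
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Karyotype":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        segs = [
            Segment(s["chrom"], int(s["start"]), int(s["end"]), int(s["copy_number"]))
            for s in doc.get("segments", []) or []
        ]
        return cls(
            baseline_ploidy=int(doc.get("baseline_ploidy", 2)),
            copy_number={k: int(v) for k, v in (doc.get("copy_number") or {}).items()},
            segments=segs,
        )


@dataclass(frozen=True)
class NoiseModel:
    """Coverage noise: NB per bin with mean lambda*c/P and overdispersion.

    ``mean_coverage`` is reads per full-size bin per baseline copy set;
    variance is mu + mu^2 / dispersion (Poisson as dispersion -> inf).
    The default dispersion of 50 gives a per-bin CV of ~17% at 100x
    coverage, in the range observed for real short-read WGS in 1 kb bins;
    smaller values model noisier libraries.
    """

    mean_coverage: float = DEFAULT_COVERAGE
    dispersion: float = DEFAULT_DISPERSION
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be > 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")


@dataclass(frozen=True)
class TetradCross:
    """One parent x wild-type cross: which chromosomes are disomic in the
    aneuploid parent, which disomy causes resistance, and how many 2:2
    tetrads to emit."""

    parental_disomies: frozenset[str]
    causative: str
    n_tetrads: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "parental_disomies", frozenset(self.parental_disomies))
        if self.causative not in self.parental_disomies:
            raise ValueError(
                f"causative chromosome {self.causative!r} not among parental disomies"
            )
        if self.n_tetrads < 1:
            raise ValueError("n_tetrads must be >= 1")


@dataclass(frozen=True)
class TetradSet:
    crosses: tuple[TetradCross, ...]

    def __post_init__(self) -> None:
        if not self.crosses:
            raise ValueError("tetrad set must contain at least one cross")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    out = np.zeros_like(mu)
    pos = mu > 0
    p = dispersion / (dispersion + mu[pos])
    out[pos] = rng.negative_binomial(dispersion, p)
    return out


def _expected_bin_depth(
    genome: GenomeModel, karyotype: Karyotype, chrom: str, noise: NoiseModel
) -> np.ndarray:
    starts, ends = genome.bin_edges(chrom)
    frac = (np.asarray(ends) - np.asarray(starts)) / genome.bin_size
    copies = karyotype.bin_copy_numbers(genome, chrom)
    return noise.mean_coverage * frac * copies / karyotype.baseline_ploidy


def simulate_depth(
    genome: GenomeModel, karyotype: Karyotype, noise: NoiseModel
) -> DepthProfile:
    """Draw a binned depth profile for one clonal karyotype.

    Expected depth per bin is lambda * c_local / P, scaled by partial-bin
    length; c_local includes segment overrides.
    """
    karyotype.validate_against(genome)
    rng = np.random.default_rng(noise.seed)
    rows = []
    for chrom in genome.names:
        starts, ends = genome.bin_edges(chrom)
        mu = _expected_bin_depth(genome, karyotype, chrom, noise)
        depth = _nb_draw(rng, mu, noise.dispersion)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "depth": depth}))
    return DepthProfile(pd.concat(rows, ignore_index=True), genome)


def simulate_mixture_profile(
    genome: GenomeModel,
    karyotype_a: Karyotype,
    karyotype_b: Karyotype,
    fraction_b: float,
    noise: NoiseModel,
) -> DepthProfile:
    """Depth profile of a mixed cell population.

    Expected bin depth is the mixture (1-f)*E[a] + f*E[b]; models, e.g., a
    population in which only a fraction of cells carries a trisomy.
    """
    if not 0.0 <= fraction_b <= 1.0:
        raise ValueError(f"fraction_b must lie in [0, 1], got {fraction_b}")
    karyotype_a.validate_against(genome)
    karyotype_b.validate_against(genome)
    rng = np.random.default_rng(noise.seed)
    rows = []
    for chrom in genome.names:
        starts, ends = genome.bin_edges(chrom)
        mu_a = _expected_bin_depth(genome, karyotype_a, chrom, noise)
        mu_b = _expected_bin_depth(genome, karyotype_b, chrom, noise)
        mu = (1.0 - fraction_b) * mu_a + fraction_b * mu_b
        depth = _nb_draw(rng, mu, noise.dispersion)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "depth": depth}))
    return DepthProfile(pd.concat(rows, ignore_index=True), genome)


def simulate_tetrads(
    tetrads: TetradSet, noise: NoiseModel
) -> tuple[list[Karyotype], list[Karyotype]]:
    """Segregate parental disomies through meiosis, keeping 2:2 tetrads.

    Every tetrad yields four haploid spores; the causative chromosome's
    extra copy goes to exactly two spores (the resistant ones), and each
    non-causative disomy assorts independently and uniformly into two of the
    four spores. Spore-viability filtering is not modeled.
    """
    rng = np.random.default_rng(noise.seed)
    resistant: list[Karyotype] = []
    sensitive: list[Karyotype] = []
    for cross in tetrads.crosses:
        others = sorted(cross.parental_disomies - {cross.causative})
        for _ in range(cross.n_tetrads):
            spores: list[dict[str, int]] = [{} for _ in range(4)]
            carriers = rng.permutation(4)[:2]
            for i in carriers:
                spores[i][cross.causative] = 2
            for chrom in others:
                for i in rng.permutation(4)[:2]:
                    spores[i][chrom] = 2
            for i, cn in enumerate(spores):
                kt = Karyotype(baseline_ploidy=1, copy_number=cn)
                (resistant if i in carriers else sensitive).append(kt)
    return resistant, sensitive


# -- expression ---------------------------------------------------------------


def make_gene_map(
    genome: GenomeModel,
    spacing: int = 20_000,
    rp_names: list[str] | None = None,
    prefix: str = "G",
) -> pd.DataFrame:
    """Evenly spaced synthetic genes: columns gene_id, chrom, pos.

    One gene every ``spacing`` bp per chromosome. If ``rp_names`` is given,
    that many genes, spread evenly across the map, are renamed to those
    identifiers (used to wire the packaged synthetic RP set to the map).
    """
    rows = []
    for chrom in genome.names:
        length = genome.length(chrom)
        for pos in range(spacing // 2, length, spacing):
            rows.append((chrom, pos))
    gene_ids = [f"{prefix}{i:04d}" for i in range(1, len(rows) + 1)]
    df = pd.DataFrame(rows, columns=["chrom", "pos"])
    df.insert(0, "gene_id", gene_ids)
    if rp_names:
        if len(rp_names) > len(df):
            raise ValueError("more RP names than genes in the map")
        idx = np.linspace(0, len(df) - 1, len(rp_names)).round().astype(int)
        df.loc[df.index[idx], "gene_id"] = list(rp_names)
    return df


def simulate_expression(
    genome: GenomeModel,
    karyotype: Karyotype,
    gene_map: pd.DataFrame,
    base_tpm,
    cv: float = 0.2,
    seed: int = 0,
    n_replicates: int = 1,
    sample_prefix: str = "S",
) -> ExpressionTable:
    """Gene-level tpm proportional to local copy number, with log-normal noise.

    Expected pre-normalization tpm is base_tpm * c / P; multiplicative
    log-normal noise has mean 1 and coefficient of variation ``cv``; each
    sample column is renormalized to a total of 1e6.
    """
    karyotype.validate_against(genome)
    unmapped = sorted(set(gene_map["chrom"]) - set(genome.names))
    if unmapped:
        raise ValueError(f"gene map references unknown chromosome(s): {unmapped}")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    base = (
        pd.Series(float(base_tpm), index=gene_map["gene_id"])
        if np.isscalar(base_tpm)
        else pd.Series(base_tpm).reindex(gene_map["gene_id"])
    )
    if base.isna().any():
        missing = base[base.isna()].index.tolist()[:5]
        raise ValueError(f"base_tpm missing for genes {missing}")

    dosage = np.array(
        [
            karyotype.copy_at(chrom, pos) / karyotype.baseline_ploidy
            for chrom, pos in zip(gene_map["chrom"], gene_map["pos"])
        ]
    )
    expected = base.to_numpy() * dosage

    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv**2))
    cols = {}
    for r in range(1, n_replicates + 1):
        noise = np.exp(rng.normal(-sigma**2 / 2, sigma, size=len(expected))) if cv > 0 else 1.0
        tpm = expected * noise
        total = tpm.sum()
        if total <= 0:
            raise ValueError("simulated sample has zero total expression")
        cols[f"{sample_prefix}{r}"] = tpm * (1e6 / total)

    df = pd.DataFrame(cols, index=gene_map["gene_id"])
    df.insert(0, "chrom", gene_map.set_index("gene_id")["chrom"])
    return ExpressionTable(df)
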