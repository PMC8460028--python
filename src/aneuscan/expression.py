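"""Copy-number -> expression dosage analysis on gene-level tpm tables.

Covers per-gene log2 aneuploid/wild-type ratios clustered by chromosome,
single-gene and gene-set (e.g. ribosomal-protein) summaries, equal-variance
t-tests with Benjamini-Hochberg FDR control, and the star-label convention
for replicate assay statistics.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_EPSILON = 0.5  # pseudocount in tpm for log ratios
DEFAULT_FDR = 1e-4  # 0.01%


class ExpressionTable:
    """Gene-level tpm: index gene_id, one ``chrom`` column plus sample columns.

    Each sample column sums to ~1e6 (1% tolerance); tpm values are
    non-negative.
    """

    def __init__(self, data: pd.DataFrame, genome=None):
        if "chrom" not in data.columns:
            raise ValueError("expression table needs a 'chrom' column")
        df = data.copy()
        samples = [c for c in df.columns if c != "chrom"]
        if not samples:
            raise ValueError("expression table has no sample columns")
        values = df[samples].to_numpy(dtype=float)
        if (values < 0).any() or not np.isfinite(values).all():
            raise ValueError("tpm values must be finite and non-negative")
        totals = values.sum(axis=0)
        if (np.abs(totals - 1e6) > 1e4).any():
            bad = [s for s, t in zip(samples, totals) if abs(t - 1e6) > 1e4]
            raise ValueError(f"sample column(s) {bad} do not sum to ~1e6 tpm")
        if genome is not None:
            bad_chroms = sorted(set(df["chrom"]) - set(genome.names))
            if bad_chroms:
                raise ValueError(f"genes mapped to unknown chromosome(s) {bad_chroms}")
        self.data = df
        self.samples = samples

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    def tpm(self, columns: Sequence[str] | None = None) -> pd.DataFrame:
        return self.data[list(columns) if columns else self.samples]

    def write_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path, genome=None) -> "ExpressionTable":
        df = pd.read_csv(path, sep="\t", index_col="gene_id", comment="#")
        return cls(df, genome=genome)


@dataclass
class DosageSummary:
    """Per-gene log2 aneuploid/WT ratios and per-chromosome medians."""

    per_gene: pd.DataFrame  # gene_id index; chrom, log2_ratio
    per_chromosome: pd.DataFrame  # chrom index; median_log2_ratio, n_genes[, expected]


def dosage_log2(
    aneuploid: ExpressionTable,
    wt: ExpressionTable,
    epsilon: float = DEFAULT_EPSILON,
    karyotype=None,
) -> DosageSummary:
    """log2((aneuploid + eps) / (wt + eps)) per gene, medians per chromosome.

    Replicate columns are averaged per condition before the ratio. With a
    karyotype supplied, each chromosome's expected log2(c/P) is included.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    shared = aneuploid.genes.intersection(wt.genes)
    if len(shared) == 0:
        raise ValueError("expression tables share no genes")
    a = aneuploid.tpm().loc[shared].mean(axis=1)
    w = wt.tpm().loc[shared].mean(axis=1)
    log2_ratio = np.log2((a + epsilon) / (w + epsilon))
    per_gene = pd.DataFrame(
        {"chrom": aneuploid.data.loc[shared, "chrom"], "log2_ratio": log2_ratio}
    )
    grouped = per_gene.groupby("chrom", sort=False)["log2_ratio"]
    per_chrom = pd.DataFrame(
        {"median_log2_ratio": grouped.median(), "n_genes": grouped.size()}
    )
    if karyotype is not None:
        per_chrom["expected_log2"] = [
            np.log2(karyotype.copy_of(c) / karyotype.baseline_ploidy)
            if karyotype.copy_of(c) > 0
            else -np.inf
            for c in per_chrom.index
        ]
    return DosageSummary(per_gene=per_gene, per_chromosome=per_chrom)


def heatmap_matrix(
    tables: Mapping[str, ExpressionTable],
    wt: ExpressionTable,
    epsilon: float = DEFAULT_EPSILON,
) -> pd.DataFrame:
    """Per-replicate log2 ratio matrix (genes x samples), chromosome-grouped.

    Each sample column of each aneuploid table is ratioed against the
    averaged wild-type columns; row order follows the wild-type table's
    chromosome grouping (plain matrix export, ready for any heat-map tool).
    """
    w = wt.tpm().mean(axis=1)
    cols = {}
    for name, table in tables.items():
        shared = table.genes.intersection(wt.genes)
        for s in table.samples:
            ratio = np.log2((table.data.loc[shared, s] + epsilon) / (w.loc[shared] + epsilon))
            cols[f"{name}:{s}"] = ratio
    mat = pd.DataFrame(cols)
    mat.insert(0, "chrom", wt.data.loc[mat.index, "chrom"])
    return mat.sort_values("chrom", kind="stable", key=lambda s: s.map(
        {c: i for i, c in enumerate(dict.fromkeys(wt.data["chrom"]))}
    ))


@dataclass
class GeneResponse:
    gene_id: str
    means: dict[str, float]
    sds: dict[str, float]
    fold_changes: dict[tuple[str, str], float]


def gene_response(
    table: ExpressionTable,
    gene_id: str,
    conditions: Mapping[str, Sequence[str]],
    pairs: Sequence[tuple[str, str]] = (),
) -> GeneResponse:
    """Mean +/- SD tpm of one gene per condition, with fold-changes per pair.

    ``conditions`` maps a condition name to its replicate columns (>= 2
    each); each (numerator, denominator) pair yields mean_num / mean_den.
    """
    if gene_id not in table.genes:
        raise KeyError(f"gene {gene_id!r} not in expression table")
    means, sds = {}, {}
    for name, cols in conditions.items():
        if len(cols) < 2:
            raise ValueError(f"condition {name!r} needs >= 2 replicate columns")
        vals = table.data.loc[gene_id, list(cols)].to_numpy(dtype=float)
        means[name] = float(vals.mean())
        sds[name] = float(vals.std(ddof=1))
    fc = {(a, b): means[a] / means[b] for a, b in pairs}
    return GeneResponse(gene_id=gene_id, means=means, sds=sds, fold_changes=fc)


@dataclass
class GenesetResponse:
    median_a: float
    median_b: float
    median_log2_change: float
    per_gene: pd.DataFrame  # gene_id index; mean_a, mean_b, log2_change


def geneset_response(
    table: ExpressionTable,
    gene_set: Iterable[str],
    condition_a: Sequence[str],
    condition_b: Sequence[str],
    epsilon: float = DEFAULT_EPSILON,
) -> GenesetResponse:
    """Distribution summary for a gene set between two conditions (violin-ready).

    Returns the median tpm of the set under each condition and the median
    per-gene log2 change b-vs-a.
    """
    genes = list(gene_set)
    if not genes:
        raise ValueError("gene set is empty")
    missing = sorted(set(genes) - set(table.genes))
    if missing:
        raise KeyError(f"gene(s) not in table: {missing[:5]}")
    a = table.data.loc[genes, list(condition_a)].mean(axis=1)
    b = table.data.loc[genes, list(condition_b)].mean(axis=1)
    log2_change = np.log2((b + epsilon) / (a + epsilon))
    per_gene = pd.DataFrame({"mean_a": a, "mean_b": b, "log2_change": log2_change})
    return GenesetResponse(
        median_a=float(a.median()),
        median_b=float(b.median()),
        median_log2_change=float(log2_change.median()),
        per_gene=per_gene,
    )


def differential_test(
    table: ExpressionTable,
    condition_a: Sequence[str],
    condition_b: Sequence[str],
    fdr: float = DEFAULT_FDR,
) -> pd.DataFrame:
    """Per-gene unpaired equal-variance t-test with BH q-values.

    Significant iff q <= fdr (default 1e-4, i.e. a 0.01% false discovery
    rate threshold). Genes with zero variance in both groups get p = 1 when
    the group means are equal, p = 0 when they differ.
    """
    if len(condition_a) < 2 or len(condition_b) < 2:
        raise ValueError("each condition needs >= 2 replicates")
    a = table.data[list(condition_a)].to_numpy(dtype=float)
    b = table.data[list(condition_b)].to_numpy(dtype=float)
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    diff = a.mean(axis=1) - b.mean(axis=1)
    degenerate = ~np.isfinite(p)
    t = np.where(degenerate, np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t)
    p = np.where(degenerate, np.where(diff == 0, 1.0, 0.0), p)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {
            "chrom": table.data["chrom"],
            "t": t,
            "p": p,
            "q": q,
            "significant": q <= fdr,
        },
        index=table.genes,
    )


# -- replicate assay statistics ----------------------------------------------


def star_label(p: float) -> str:
    """Significance stars: * p<0.05, ** p<0.01, *** p<0.001 (strict; an
    exact threshold boundary maps to the weaker label)."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class AssayStats:
    means: dict[str, float]
    sds: dict[str, float]
    comparisons: pd.DataFrame  # group_a, group_b, t, p, stars


def assay_stats(groups: Mapping[str, Sequence[float]]) -> AssayStats:
    """Means, SDs and all pairwise equal-variance t-tests with star labels.

    Groups are independent replicate measurements (>= 3 each by the assay
    convention; < 2 is rejected outright).
    """
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} needs >= 2 replicates")
    names = list(groups)
    means = {n: float(np.mean(groups[n])) for n in names}
    sds = {n: float(np.std(groups[n], ddof=1)) for n in names}
    rows = []
    for i, na in enumerate(names):
        for nb in names[i + 1 :]:
            t, p = stats.ttest_ind(groups[na], groups[nb], equal_var=True)
            if not np.isfinite(p):
                t, p = (0.0, 1.0) if means[na] == means[nb] else (np.inf, 0.0)
            rows.append((na, nb, float(t), float(p), star_label(float(p))))
    comparisons = pd.DataFrame(rows, columns=["group_a", "group_b", "t", "p", "stars"])
    return AssayStats(means=means, sds=sds, comparisons=comparisons)


def load_rp_set() -> list[str]:
    """The packaged synthetic ribosomal-protein gene set (132 identifiers)."""
    ref = importlib.resources.files("aneuscan.data") / "rp_genes_synthetic.txt"
    text = ref.read_text()
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
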