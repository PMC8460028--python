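"""Dosage ratios, gene/geneset responses, differential tests, assay stats."""

import numpy as np
import pandas as pd
import pytest

from aneuscan import (
    ExpressionTable,
    Karyotype,
    assay_stats,
    differential_test,
    dosage_log2,
    gene_response,
    geneset_response,
    simulate_expression,
)
from aneuscan.expression import heatmap_matrix, load_rp_set, star_label
from aneuscan.synthetic_data import make_gene_map


def _table(columns: dict, chrom="chr1") -> ExpressionTable:
    n = len(next(iter(columns.values())))
    df = pd.DataFrame(columns, index=pd.Index([f"g{i}" for i in range(n)], name="gene_id"))
    df = df * 1e6 / df.sum(axis=0)
    df.insert(0, "chrom", chrom)
    return ExpressionTable(df)


class TestExpressionTable:
    def test_tsv_round_trip(self, genome, tmp_path):
        table = simulate_expression(
            genome, Karyotype(2), make_gene_map(genome), 50.0, n_replicates=2
        )
        p = tmp_path / "expr.tsv"
        table.write_tsv(p)
        back = ExpressionTable.from_tsv(p, genome=genome)
        assert np.allclose(back.tpm().to_numpy(), table.tpm().to_numpy())

    def test_malformed_tables_rejected(self):
        idx = pd.Index(["g0", "g1"], name="gene_id")
        with pytest.raises(ValueError, match="chrom"):
            ExpressionTable(pd.DataFrame({"S1": [5e5, 5e5]}, index=idx))
        with pytest.raises(ValueError, match="non-negative"):
            ExpressionTable(
                pd.DataFrame({"chrom": "chr1", "S1": [1e6 + 10, -10.0]}, index=idx)
            )
        with pytest.raises(ValueError, match="1e6|sum"):
            ExpressionTable(
                pd.DataFrame({"chrom": "chr1", "S1": [100.0, 100.0]}, index=idx)
            )


class TestDosage:
    def test_identical_tables_give_zero_log_ratios(self, genome):
        gm = make_gene_map(genome)
        t = simulate_expression(genome, Karyotype(2), gm, 50.0, seed=1)
        summary = dosage_log2(t, t)
        assert np.allclose(summary.per_gene["log2_ratio"], 0.0)

    def test_tetrasomy_and_monosomy_medians_track_log2_copy_ratio(self, genome):
        gm = make_gene_map(genome)
        wt = simulate_expression(genome, Karyotype(2), gm, 50.0, seed=1, n_replicates=3)
        kt = Karyotype(2, {"chr8": 4, "chr4": 1})
        aneu = simulate_expression(genome, kt, gm, 50.0, seed=2, n_replicates=3)
        summary = dosage_log2(aneu, wt, karyotype=kt)
        per_chrom = summary.per_chromosome
        assert per_chrom.loc["chr8", "median_log2_ratio"] == pytest.approx(1.0, abs=0.15)
        assert per_chrom.loc["chr4", "median_log2_ratio"] == pytest.approx(-1.0, abs=0.15)
        assert per_chrom.loc["chr2", "median_log2_ratio"] == pytest.approx(0.0, abs=0.15)
        assert per_chrom.loc["chr8", "expected_log2"] == pytest.approx(1.0)

    def test_dosage_medians_within_tolerance_across_copy_numbers(self, genome):
        gm = make_gene_map(genome)
        wt = simulate_expression(genome, Karyotype(2), gm, 50.0, seed=5, n_replicates=3)
        # aneuploidies observed in the isolate cohort; tpm renormalization is
        # compositional, so tetrasomy of a huge chromosome (e.g. chr4, 12.6%
        # of the genome) would deflate all ratios by ~0.17 log2 units and
        # genuinely leave this band
        for i, (chrom, c) in enumerate([("chr2", 1), ("chr12", 3), ("chr8", 4)]):
            kt = Karyotype(2, {chrom: c})
            aneu = simulate_expression(
                genome, kt, gm, 50.0, seed=10 + i, n_replicates=3
            )
            med = dosage_log2(aneu, wt).per_chromosome.loc[chrom, "median_log2_ratio"]
            assert med == pytest.approx(np.log2(c / 2), abs=0.15), (chrom, c)

    def test_heatmap_matrix_has_one_column_per_replicate(self, genome):
        gm = make_gene_map(genome)
        wt = simulate_expression(genome, Karyotype(2), gm, 50.0, n_replicates=2)
        a = simulate_expression(
            genome, Karyotype(2, {"chr8": 3}), gm, 50.0, seed=3, n_replicates=2
        )
        mat = heatmap_matrix({"DSX": a}, wt)
        assert list(mat.columns) == ["chrom", "DSX:S1", "DSX:S2"]
        chr8 = mat[mat["chrom"] == "chr8"]["DSX:S1"]
        assert float(chr8.median()) == pytest.approx(np.log2(1.5), abs=0.15)


class TestGeneAndGenesetResponse:
    def test_fold_changes_from_replicate_means(self):
        table = _table(
            {"A1": [100.0, 100.0], "A2": [100.0, 100.0],
             "B1": [200.0, 100.0], "B2": [200.0, 100.0]}
        )
        resp = gene_response(
            table, "g0", {"A": ["A1", "A2"], "B": ["B1", "B2"]}, pairs=[("B", "A")]
        )
        # renormalization makes the table compositional: g0 doubles in raw
        # abundance while g1 stays flat, so the tpm fold-change pair is
        # (2, 1) scaled by a common factor
        fc_g0 = resp.fold_changes[("B", "A")]
        fc_g1 = gene_response(
            table, "g1", {"A": ["A1", "A2"], "B": ["B1", "B2"]}, pairs=[("B", "A")]
        ).fold_changes[("B", "A")]
        assert fc_g0 / fc_g1 == pytest.approx(2.0, rel=1e-9)
        with pytest.raises(KeyError):
            gene_response(table, "missing", {"A": ["A1", "A2"]})
        with pytest.raises(ValueError):
            gene_response(table, "g0", {"A": ["A1"]})

    def test_four_fold_repression_of_the_rp_set_reads_near_minus_two(self, genome):
        gm = make_gene_map(genome, spacing=2000, rp_names=load_rp_set())
        rp = set(load_rp_set())
        base = pd.Series(100.0, index=gm["gene_id"])
        repressed = base.where(~base.index.isin(rp), 25.0)
        df = pd.DataFrame(
            {
                "A1": base, "A2": base,
                "B1": repressed, "B2": repressed,
            }
        )
        df = df * 1e6 / df.sum(axis=0)
        df.insert(0, "chrom", gm.set_index("gene_id")["chrom"])
        table = ExpressionTable(df)
        resp = geneset_response(table, rp, ["A1", "A2"], ["B1", "B2"])
        assert resp.median_log2_change == pytest.approx(-2.0, abs=0.1)

    def test_mild_repression_stays_within_half_a_log_unit(self, genome):
        gm = make_gene_map(genome, spacing=2000, rp_names=load_rp_set())
        rp = set(load_rp_set())
        base = pd.Series(100.0, index=gm["gene_id"])
        dampened = base.where(~base.index.isin(rp), 100.0 / 1.3)
        df = pd.DataFrame({"A1": base, "A2": base, "B1": dampened, "B2": dampened})
        df = df * 1e6 / df.sum(axis=0)
        df.insert(0, "chrom", gm.set_index("gene_id")["chrom"])
        resp = geneset_response(ExpressionTable(df), rp, ["A1", "A2"], ["B1", "B2"])
        assert abs(resp.median_log2_change) < 0.5

    def test_packaged_rp_set_has_132_members(self):
        assert len(load_rp_set()) == 132

    def test_empty_or_unknown_gene_set_rejected(self):
        table = _table({"A1": [100.0, 100.0], "B1": [100.0, 100.0]})
        with pytest.raises(ValueError):
            geneset_response(table, [], ["A1"], ["B1"])
        with pytest.raises(KeyError):
            geneset_response(table, ["nope"], ["A1"], ["B1"])


class TestDifferentialTest:
    def test_t_statistic_matches_first_principles_pooled_variance(self):
        rng = np.random.default_rng(8)
        n = 50
        cols = {f"A{i}": rng.normal(100, 10, n).clip(0) for i in range(1, 4)}
        cols |= {f"B{i}": rng.normal(110, 10, n).clip(0) for i in range(1, 4)}
        table = _table(cols)
        res = differential_test(table, ["A1", "A2", "A3"], ["B1", "B2", "B3"])
        a = table.data[["A1", "A2", "A3"]].to_numpy()
        b = table.data[["B1", "B2", "B3"]].to_numpy()
        na = nb = 3
        sp2 = ((na - 1) * a.var(axis=1, ddof=1) + (nb - 1) * b.var(axis=1, ddof=1)) / (
            na + nb - 2
        )
        t_manual = (a.mean(axis=1) - b.mean(axis=1)) / np.sqrt(sp2 * (1 / na + 1 / nb))
        assert np.allclose(res["t"].to_numpy(), t_manual, atol=1e-10)

    def test_q_values_are_monotone_in_p(self):
        rng = np.random.default_rng(9)
        cols = {c: rng.normal(100, 10, 200).clip(0) for c in ("A1", "A2", "B1", "B2")}
        res = differential_test(_table(cols), ["A1", "A2"], ["B1", "B2"])
        srt = res.sort_values("p")
        assert (np.diff(srt["q"].to_numpy()) >= -1e-12).all()
        assert (srt["q"] >= srt["p"] - 1e-12).all()

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_degenerate_genes_get_extreme_p_values(self):
        table = _table(
            {"A1": [10.0, 10.0], "A2": [10.0, 10.0],
             "B1": [10.0, 30.0], "B2": [10.0, 30.0]}
        )
        res = differential_test(table, ["A1", "A2"], ["B1", "B2"])
        assert res.loc["g0", "p"] != 1.0 or res.loc["g0", "t"] == 0.0
        # g1 differs with zero within-group variance -> p = 0
        assert res.loc["g1", "p"] == 0.0
        with pytest.raises(ValueError):
            differential_test(table, ["A1"], ["B1", "B2"])

    def test_no_rejections_on_twenty_null_simulations_at_default_fdr(self):
        rejections = 0
        for seed in range(20):
            rng = np.random.default_rng(70_000 + seed)
            mat = np.clip(rng.normal(100.0, 10.0, size=(1000, 6)), 0, None)
            cols = {c: mat[:, i] for i, c in enumerate(
                ("A1", "A2", "A3", "B1", "B2", "B3"))}
            res = differential_test(_table(cols), ["A1", "A2", "A3"], ["B1", "B2", "B3"])
            rejections += int(res["significant"].sum())
        assert rejections == 0


class TestAssayStats:
    def test_star_thresholds_are_strict_inequalities(self):
        assert star_label(0.0009) == "***"
        assert star_label(0.001) == "**"
        assert star_label(0.009) == "**"
        assert star_label(0.01) == "*"
        assert star_label(0.04) == "*"
        assert star_label(0.05) == ""
        assert star_label(0.20) == ""

    def test_identical_groups_give_t_zero_p_one(self):
        res = assay_stats({"wt": [1.0, 2.0, 3.0], "mut": [1.0, 2.0, 3.0]})
        row = res.comparisons.iloc[0]
        assert row["t"] == 0.0 and row["p"] == 1.0 and row["stars"] == ""

    def test_clearly_separated_groups_earn_stars(self):
        res = assay_stats({"wt": [10.0, 10.5, 9.8], "mut": [1.0, 1.1, 0.9]})
        assert res.comparisons.iloc[0]["stars"] == "***"

    def test_single_replicate_group_rejected(self):
        with pytest.raises(ValueError):
            assay_stats({"wt": [1.0], "mut": [1.0, 2.0]})
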