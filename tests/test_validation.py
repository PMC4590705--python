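from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mutexsl import (
    ContingencyCounts,
    GarpTable,
    SLCandidate,
    differential_essentiality,
    essentiality_ranks,
    ge_rank,
    me_ge_trend,
    paired_differential,
    rank_by_me,
    read_cellline_annotations,
    read_garp_table,
    top_quartile_enrichment,
)
from mutexsl.errors import ConfigError, DataValidationError, GeneLookupError
from mutexsl.validation import pearson_chi2, per_line_enrichment, write_garp_table

from _oracles import pearson_chi2_by_hand

DATA = Path(__file__).parent / "data"


class TestAnnotations:
    def test_fixture_shape(self):
        anns = read_cellline_annotations(DATA / "cell_line_annotations.tsv")
        assert len(anns) == 10
        by_line = {a.cell_line: a for a in anns}
        assert len(by_line["HCC1395"].deficiencies) == 4
        assert by_line["MCF7"].is_control
        assert "TP53" in by_line["HCC1143"].deficiencies

    def test_unknown_defect_code(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text("cell_line\tgene_a\tdefect\tis_control\n"
                     "L1\tTP53\tFUSION\t0\n")
        with pytest.raises(DataValidationError, match="FUSION"):
            read_cellline_annotations(p)

    def test_non_control_without_gene(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text("cell_line\tgene_a\tdefect\tis_control\nL1\t\t\t0\n")
        with pytest.raises(DataValidationError, match="L1"):
            read_cellline_annotations(p)


class TestGarpIO:
    def test_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        scores = pd.DataFrame(
            rng.normal(size=(5, 3)),
            index=[f"G{i}" for i in range(5)], columns=["L1", "L2", "L3"])
        scores.iloc[1, 2] = np.nan
        garp = GarpTable(scores)
        path = tmp_path / "garp.tsv"
        write_garp_table(garp, path)
        back = read_garp_table(path)
        pd.testing.assert_frame_equal(back.scores, garp.scores)

    def test_duplicate_gene_rejected(self):
        df = pd.DataFrame(0.0, index=["G1", "G1"], columns=["L1"])
        with pytest.raises(DataValidationError):
            GarpTable(df)


class TestEssentialityRanks:
    def _garp(self):
        return GarpTable(pd.DataFrame(
            {"L1": [-5.0, 0.0, -5.0]}, index=["g1", "g2", "g3"]))

    def test_tie_broken_by_symbol(self):
        ranks = essentiality_ranks(self._garp(), "L1")
        assert ranks.to_dict() == {"g1": 1, "g3": 2, "g2": 3}

    def test_single_gene(self):
        garp = GarpTable(pd.DataFrame({"L1": [1.0]}, index=["g1"]))
        assert essentiality_ranks(garp, "L1").to_dict() == {"g1": 1}

    def test_order_invariance(self):
        garp = self._garp()
        shuffled = GarpTable(garp.scores.loc[["g2", "g3", "g1"]])
        assert (essentiality_ranks(garp, "L1").sort_index().to_dict()
                == essentiality_ranks(shuffled, "L1").sort_index().to_dict())

    def test_unknown_cell_line(self):
        with pytest.raises(GeneLookupError):
            essentiality_ranks(self._garp(), "NOPE")

    def test_masked_genes_omitted(self):
        garp = GarpTable(pd.DataFrame(
            {"L1": [-1.0, np.nan, 0.0]}, index=["g1", "g2", "g3"]))
        ranks = essentiality_ranks(garp, "L1")
        assert "g2" not in ranks.index
        assert ranks.to_dict() == {"g1": 1, "g3": 2}


class TestGeRank:
    def test_values(self):
        assert ge_rank(1, 5000) == 4999
        assert ge_rank(5000, 5000) == 0
        assert ge_rank(5001, 5000) is None

    def test_strictly_decreasing(self):
        values = [ge_rank(r, 100) for r in range(1, 101)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_invalid_rank(self):
        with pytest.raises(ConfigError):
            ge_rank(0)


def _quartile_garp(n_genes=100, seed=0, lines=("L1",)):
    rng = np.random.default_rng(seed)
    scores = pd.DataFrame(
        rng.normal(size=(n_genes, len(lines))),
        index=[f"G{i:05d}" for i in range(n_genes)], columns=list(lines))
    return GarpTable(scores)


class TestEnrichment:
    def test_null_proportioned_table(self):
        garp = _quartile_garp(8)
        ranks = essentiality_ranks(garp, "L1")
        top = set(ranks.index[ranks.to_numpy() <= 2])
        rest = [g for g in garp.genes if g not in top]
        candidates = {next(iter(top))} | set(rest[:3])  # 1 of 2 top, 3 of 6 rest
        res = top_quartile_enrichment(candidates, garp, ["L1"], 0.25)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_chi2_matches_hand_oracle(self):
        table = np.array([[80, 20], [3920, 11980]])
        stat, p = pearson_chi2(table)
        assert stat == pytest.approx(pearson_chi2_by_hand(table), rel=1e-12)
        assert p == pytest.approx(float(stats.chi2.sf(stat, 1)))

    def test_row_swap_invariance(self):
        table = np.array([[80, 20], [3920, 11980]])
        assert pearson_chi2(table)[0] == pytest.approx(
            pearson_chi2(table[::-1])[0], rel=1e-12)

    def test_all_candidates_in_top_quartile(self):
        garp = _quartile_garp(16000, seed=1)
        ranks = essentiality_ranks(garp, "L1")
        candidates = set(ranks.index[ranks.to_numpy() <= 100])
        res = top_quartile_enrichment(candidates, garp, ["L1"], 0.25)
        assert res.p_value < 1e-5
        assert res.table[0, 1] == 0

    def test_dropped_candidates_counted(self):
        garp = _quartile_garp(20)
        res = top_quartile_enrichment(
            set(garp.genes[:4]) | {"ABSENT"}, garp, ["L1"])
        assert res.n_candidates_dropped == 1

    def test_no_overlap_errors(self):
        garp = _quartile_garp(20)
        with pytest.raises(DataValidationError):
            top_quartile_enrichment({"NOPE"}, garp, ["L1"])

    def test_per_line_mode(self):
        garp = _quartile_garp(40, lines=("L1", "L2"))
        per = per_line_enrichment(set(garp.genes[:10]), garp, ["L1", "L2"])
        assert set(per) == {"L1", "L2"}
        pooled = top_quartile_enrichment(set(garp.genes[:10]), garp,
                                         ["L1", "L2"])
        assert pooled.table.sum() == sum(r.table.sum() for r in per.values())


def _ranked_candidates(gene_bs, gene_a="QA"):
    cands = [
        SLCandidate(
            gene_a=gene_a, class_a="loss", gene_b=gb, class_b="gain",
            counts=ContingencyCounts(100, 10, 10, 0),
            p_value=0.001 * (i + 1), cohort_scope="pooled",
        )
        for i, gb in enumerate(gene_bs)
    ]
    return rank_by_me(cands)


class TestTrend:
    def test_perfect_antimonotone(self):
        # gene with ME rank i is also the i-th most essential
        genes = [f"G{i}" for i in range(20)]
        garp = GarpTable(pd.DataFrame(
            {"L1": np.arange(20, dtype=float)}, index=genes))
        cands = _ranked_candidates(genes)
        res = me_ge_trend(cands, garp, "L1", K=100)
        assert res.defined
        assert res.coefficient == pytest.approx(-1.0)

    def test_me_equal_essentiality_rank_is_minus_one(self):
        # ge_rank = K - rank makes equal rankings perfectly anti-correlated
        genes = [f"G{i}" for i in range(10)]
        rng = np.random.default_rng(2)
        scores = np.sort(rng.normal(size=10))
        garp = GarpTable(pd.DataFrame({"L1": scores}, index=genes))
        cands = _ranked_candidates(genes)
        res = me_ge_trend(cands, garp, "L1", K=50)
        me = [p[0] for p in res.pairs]
        raw_rank = [50 - p[1] for p in res.pairs]
        rho_raw = stats.spearmanr(me, raw_rank).statistic
        assert res.coefficient == pytest.approx(-rho_raw)

    def test_beyond_k_excluded(self):
        genes = [f"G{i}" for i in range(10)]
        garp = GarpTable(pd.DataFrame(
            {"L1": np.arange(10, dtype=float)}, index=genes))
        res = me_ge_trend(_ranked_candidates(genes), garp, "L1", K=5)
        assert res.n_pairs == 5

    def test_fewer_than_three_pairs_flagged(self):
        garp = GarpTable(pd.DataFrame(
            {"L1": [0.0, 1.0]}, index=["G0", "G1"]))
        res = me_ge_trend(_ranked_candidates(["G0", "G1"]), garp, "L1", K=10)
        assert not res.defined
        assert np.isnan(res.coefficient)

    def test_random_rankings_centre_on_zero(self):
        # permutation oracle: independent rankings give mean rho ~ 0
        rng = np.random.default_rng(7)
        n_pairs = 30
        coeffs = []
        for _ in range(1000):
            ge = rng.permutation(n_pairs)
            coeffs.append(stats.spearmanr(np.arange(n_pairs), ge).statistic)
        genes = [f"G{i}" for i in range(n_pairs)]
        assert abs(np.mean(coeffs)) < 3 / np.sqrt(n_pairs)

    def test_requires_single_gene_a(self):
        garp = GarpTable(pd.DataFrame({"L1": [0.0]}, index=["G0"]))
        cands = (_ranked_candidates(["G0"], "A1")
                 + _ranked_candidates(["G0"], "A2"))
        with pytest.raises(ConfigError):
            me_ge_trend(cands, garp, "L1")

    def test_annotation_pairing_rule(self):
        anns = read_cellline_annotations(DATA / "cell_line_annotations.tsv")
        genes = [f"G{i}" for i in range(5)]
        garp = GarpTable(pd.DataFrame(
            {"HCC1143": np.arange(5, dtype=float)}, index=genes))
        cands = _ranked_candidates(genes, gene_a="TP53")
        res = me_ge_trend(cands, garp, "HCC1143", K=10, annotations=anns)
        assert res.defined
        with pytest.raises(DataValidationError):
            me_ge_trend(_ranked_candidates(genes, gene_a="CDH1"),
                        garp, "HCC1143", K=10, annotations=anns)


class TestDifferential:
    def _garp_with_shift(self, shift, seed=0, n_genes=50, noise=0.3):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=n_genes)
        df = pd.DataFrame(
            {
                "CTRL": base,
                "D1": base + shift + rng.normal(0, noise, n_genes),
                "D2": base + shift + rng.normal(0, noise, n_genes),
            },
            index=[f"G{i}" for i in range(n_genes)],
        )
        return GarpTable(df)

    def test_shifted_groups_significant(self):
        garp = self._garp_with_shift(-2.0)
        res = differential_essentiality(garp, set(garp.genes),
                                        ["D1", "D2"], "CTRL")
        assert res.p_value < 1e-3
        assert res.group_means["D1"] < res.group_means["CTRL"]

    def test_two_group_f_equals_t_squared(self):
        garp = self._garp_with_shift(-1.0)
        res = differential_essentiality(garp, set(garp.genes), ["D1"], "CTRL")
        x = garp.scores["D1"].to_numpy()
        y = garp.scores["CTRL"].to_numpy()
        t, p_t = stats.ttest_ind(x, y)
        assert res.statistic == pytest.approx(t**2, rel=1e-10)
        assert res.p_value == pytest.approx(p_t, rel=1e-10)

    def test_null_calibration(self):
        rng = np.random.default_rng(11)
        rejections = 0
        n_sims = 500
        for _ in range(n_sims):
            groups = [rng.normal(size=20) for _ in range(3)]
            if stats.f_oneway(*groups).pvalue < 0.05:
                rejections += 1
        rate = rejections / n_sims
        se = np.sqrt(0.05 * 0.95 / n_sims)
        assert abs(rate - 0.05) <= 3 * se

    def test_control_must_differ(self):
        garp = self._garp_with_shift(0.0)
        with pytest.raises(ConfigError):
            differential_essentiality(garp, set(garp.genes),
                                      ["CTRL"], "CTRL")

    def test_line_without_scores_errors(self):
        df = pd.DataFrame({"CTRL": [1.0], "D1": [np.nan]}, index=["G0"])
        with pytest.raises(DataValidationError):
            differential_essentiality(GarpTable(df), {"G0"}, ["D1"], "CTRL")


class TestPairedDifferential:
    def test_identical_vectors(self):
        df = pd.DataFrame({"L1": [1.0, 2.0, 3.0], "L2": [1.0, 2.0, 3.0]},
                          index=["G0", "G1", "G2"])
        res = paired_differential(GarpTable(df), {"G0", "G1", "G2"},
                                  "L1", "L2")
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_constant_nonzero_difference_degenerate(self):
        df = pd.DataFrame({"L1": [1.0, 2.0, 3.0], "L2": [2.0, 3.0, 4.0]},
                          index=["G0", "G1", "G2"])
        res = paired_differential(GarpTable(df), {"G0", "G1", "G2"},
                                  "L1", "L2")
        assert res.degenerate

    def test_shifted_differences_significant(self):
        # p < 0.001 in >= 95% of 200 seeded replicates for Normal(-1, 1) diffs
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            base = rng.normal(size=100)
            df = pd.DataFrame(
                {"KO": base + rng.normal(-1, 1, 100), "WT": base},
                index=[f"G{i}" for i in range(100)])
            res = paired_differential(GarpTable(df),
                                      {f"G{i}" for i in range(100)},
                                      "KO", "WT")
            if res.p_value < 1e-3:
                hits += 1
        assert hits >= 0.95 * 200

    def test_too_few_pairs(self):
        df = pd.DataFrame({"L1": [1.0, np.nan], "L2": [1.0, 2.0]},
                          index=["G0", "G1"])
        with pytest.raises(DataValidationError):
            paired_differential(GarpTable(df), {"G0", "G1"}, "L1", "L2")
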