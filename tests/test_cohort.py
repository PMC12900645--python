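"""Cohort stratification rules and the expression/immune statistics."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import ctnnbscan as cs
from ctnnbscan.simulate import simulate_classified_cohort, simulate_expression


def _mut(gene="CTNNB1", pc="p.S45F", mclass="missense", gain=False, sample="S0"):
    return {
        "sample": sample, "tissue": "liver", "gene": gene,
        "protein_change": pc, "mutation_class": mclass, "cnv_gain": gain,
    }


def _classify(records, mes_lookup, **kw):
    df = pd.DataFrame(records) if records else pd.DataFrame(
        columns=["sample", "gene", "protein_change", "mutation_class", "cnv_gain"]
    )
    return cs.classify_sample(df, mes_lookup, **kw)


class TestParseProteinChange:
    @pytest.mark.parametrize("text", ["p.S45F", "S45F"])
    def test_dialects(self, text):
        assert cs.parse_protein_change(text) == ("S", 45, "F")

    @pytest.mark.parametrize(
        "text", ["p.S45del", "p.I35_H36delinsSN", "p.S45*", "p.S45Ffs*3", "", None, "S45S"]
    )
    def test_complex_events_do_not_parse(self, text):
        assert cs.parse_protein_change(text) is None


class TestClassifySample:
    MES = {"S45F": 9000.0, "T41A": 25000.0, "S33P": 12000.0}

    def test_high_mes_hotspot_is_strong(self):
        assert _classify([_mut(pc="p.T41A")], self.MES).group == "strong"

    def test_low_mes_with_gain_reassigns_to_strong(self):
        assert _classify([_mut(pc="p.S45F", gain=True)], self.MES).group == "strong"

    def test_low_mes_without_gain_is_weak(self):
        assert _classify([_mut(pc="p.S45F")], self.MES).group == "weak"

    def test_boundary_mes_is_weak(self):
        mes = {"S45F": 18000.0}
        assert _classify([_mut(pc="p.S45F")], mes).group == "weak"

    def test_non_hotspot_missense_is_other(self):
        assert _classify([_mut(pc="p.K335I")], self.MES).group == "other"

    def test_axin1_coding_mutation(self):
        assert _classify([_mut(gene="AXIN1", pc="p.R395C")], self.MES).group == "AXIN1"

    def test_no_records_is_no_mutation(self):
        assert _classify([], self.MES).group == "no_mutation"

    def test_multiple_group_membership_excludes(self):
        records = [_mut(pc="p.T41A"), _mut(gene="AXIN1", pc="p.R395C")]
        assert _classify(records, self.MES).group == "exclude"

    def test_hotspot_plus_other_missense_excludes(self):
        records = [_mut(pc="p.T41A"), _mut(pc="p.K335I")]
        assert _classify(records, self.MES).group == "exclude"

    def test_deletion_or_complex_event_excludes(self):
        assert _classify([_mut(pc="p.S45del", mclass="inframe_del")], self.MES).group == "exclude"
        assert _classify([_mut(pc="p.S45F", mclass="missense"), _mut(pc="p.T41del", mclass="deletion")], self.MES).group == "exclude"

    def test_unparseable_protein_change_excludes_with_reason(self):
        result = _classify([_mut(pc="p.I35_H36delinsSN")], self.MES)
        assert result.group == "exclude"
        assert "unparseable" in result.reason

    def test_missing_data_excludes(self):
        assert _classify([_mut(pc="p.T41A")], self.MES, has_required_data=False).group == "exclude"

    def test_multiple_hotspot_mutations_exclude(self):
        records = [_mut(pc="p.T41A"), _mut(pc="p.S33P")]
        assert _classify(records, self.MES).group == "exclude"

    def test_cnv_gain_only_moves_weak_to_strong(self):
        """Adding a gain never demotes; it only reassigns weak to strong."""
        for pc, mes in [("p.T41A", self.MES), ("p.S45F", self.MES)]:
            without = _classify([_mut(pc=pc, gain=False)], mes).group
            with_gain = _classify([_mut(pc=pc, gain=True)], mes).group
            assert (without, with_gain) in {
                ("strong", "strong"), ("weak", "strong")
            }


class TestClassifyCohort:
    def test_partition_and_exact_truth_recovery(self, mes_lookup):
        mes = pd.Series(mes_lookup)
        catalog, truth = simulate_classified_cohort(mes, n_per_group=8, seed=5)
        result = cs.classify_cohort(catalog, mes_lookup, all_samples=list(truth.index))
        assert len(result) == len(truth)
        assert (result["group"] == truth.loc[result.index]).all()
        assert result["group"].value_counts().sum() == len(truth)


class TestTissueSummary:
    def test_orders_by_weak_strong_ratio(self, mes_lookup):
        rows = []
        for i in range(120):
            rows.append({"sample": f"a{i}", "tissue": "weakville", "gene": "CTNNB1",
                         "protein_change": "p.L31A", "mutation_class": "missense"})
            rows.append({"sample": f"b{i}", "tissue": "strongtown", "gene": "CTNNB1",
                         "protein_change": "p.S47Y", "mutation_class": "missense"})
        catalog = pd.DataFrame(rows)
        out = cs.tissue_summary(catalog, mes_lookup, min_mutations=100)
        assert list(out.index) == ["weakville", "strongtown"]
        assert np.isinf(out.loc["weakville", "weak_strong_ratio"])
        assert out.loc["strongtown", "weak_strong_ratio"] == 0.0

    def test_min_count_filter(self, mes_lookup):
        catalog = pd.DataFrame([
            {"sample": "a", "tissue": "rare", "gene": "CTNNB1",
             "protein_change": "p.S45F", "mutation_class": "missense"}
        ])
        assert cs.tissue_summary(catalog, mes_lookup, min_mutations=100).empty

    def test_identical_catalogs_identical_summaries(self, mes_lookup):
        rows = [
            {"sample": f"s{i}", "tissue": t, "gene": "CTNNB1",
             "protein_change": "p.T41A", "mutation_class": "missense"}
            for t in ("left", "right") for i in range(150)
        ]
        out = cs.tissue_summary(pd.DataFrame(rows), mes_lookup, min_mutations=100)
        assert (out.loc["left"] == out.loc["right"]).all()


class TestMannWhitney:
    def test_identical_samples_give_large_p(self):
        x = np.arange(10.0)
        assert cs.mes_distribution_compare(x, x) > 0.9

    def test_matches_exhaustive_permutation_oracle(self):
        """Exact p by enumerating all assignments of pooled values (n=6 vs 6)."""
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 6)
        y = rng.normal(1.5, 1, 6)
        observed = cs.mes_distribution_compare(x, y)

        pooled = np.concatenate([x, y])
        ranks = pd.Series(pooled).rank().to_numpy()
        def u_stat(idx):
            r = ranks[list(idx)].sum()
            return abs(r - 6 * 13 / 2)
        obs = u_stat(range(6))
        count = sum(u_stat(c) >= obs - 1e-12 for c in combinations(range(12), 6))
        oracle = count / 924
        assert observed == pytest.approx(oracle, abs=1e-9)

    def test_power_under_shift_alternative(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 1, 50)
            y = rng.normal(1, 1, 50)
            hits += cs.mes_distribution_compare(x, y) < 0.05
        assert hits / 40 >= 0.9

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            cs.mes_distribution_compare([], [1.0])


class TestMLSAdjustedCompare:
    def _catalog(self, labels):
        return pd.DataFrame(
            {"sample": [f"s{i}" for i in range(len(labels))],
             "protein_change": [f"p.{l}" for l in labels]}
        )

    def test_identical_catalogs_give_p_near_one(self, mes_lookup):
        labels = list(mes_lookup)[:40]
        mls = {l: 1.0 for l in mes_lookup}
        out = cs.mls_adjusted_compare(
            self._catalog(labels), self._catalog(labels), mls, mes_lookup,
            n_resamples=500, seed=1,
        )
        assert out["p_value"] > 0.9
        assert out["observed_diff"] == 0.0

    def test_seeded_reproducibility(self, mes_lookup):
        labels_a = list(mes_lookup)[:30]
        labels_b = list(mes_lookup)[-30:]
        mls = {l: 1.0 for l in mes_lookup}
        kw = dict(n_resamples=300, seed=7)
        o1 = cs.mls_adjusted_compare(self._catalog(labels_a), self._catalog(labels_b),
                                     mls, mes_lookup, **kw)
        o2 = cs.mls_adjusted_compare(self._catalog(labels_a), self._catalog(labels_b),
                                     mls, mes_lookup, **kw)
        assert o1["p_value"] == o2["p_value"]
        assert np.array_equal(o1["null"], o2["null"])

    def test_detects_selection_on_extremes(self, mes_lookup):
        labels = sorted(mes_lookup, key=mes_lookup.get)
        mls = {l: 1.0 for l in mes_lookup}
        out = cs.mls_adjusted_compare(
            self._catalog(labels[-80:]), self._catalog(labels[:100]),
            mls, mes_lookup, n_resamples=999, seed=3,
        )
        assert out["p_value"] < 0.01


class TestExpressionSummaries:
    def test_identical_groups_give_100_percent(self):
        groups = pd.Series(["strong"] * 10 + ["weak"] * 10,
                           index=[f"s{i}" for i in range(20)])
        rng = np.random.default_rng(1)
        base = rng.integers(100, 1000, size=5).astype(float)
        expr = pd.DataFrame(
            np.tile(base[:, None], 20), columns=groups.index,
            index=[f"G{i}" for i in range(5)],
        )
        out = cs.target_gene_percent(expr, groups, list(expr.index))
        assert out["median_percent"]["weak"] == pytest.approx(100.0)

    def test_exact_halving_gives_50_percent(self):
        groups = pd.Series(["strong"] * 4 + ["weak"] * 4,
                           index=[f"s{i}" for i in range(8)])
        expr = pd.DataFrame(
            [[100] * 4 + [50] * 4, [80] * 4 + [40] * 4],
            columns=groups.index, index=["G0", "G1"], dtype=float,
        )
        out = cs.target_gene_percent(expr, groups, ["G0", "G1"])
        assert out["median_percent"]["weak"] == pytest.approx(50.0)

    def test_per_gene_scale_invariance(self):
        groups = pd.Series(["strong"] * 6 + ["weak"] * 6,
                           index=[f"s{i}" for i in range(12)])
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.uniform(10, 100, (4, 12)), columns=groups.index,
                            index=[f"G{i}" for i in range(4)])
        scaled = expr.mul(pd.Series([1.0, 7.0, 0.3, 100.0], index=expr.index), axis=0)
        o1 = cs.target_gene_percent(expr, groups, list(expr.index))
        o2 = cs.target_gene_percent(scaled, groups, list(expr.index))
        pd.testing.assert_series_equal(o1["median_percent"], o2["median_percent"])

    def test_nb_simulation_recovers_fold_change(self):
        groups = pd.Series(["strong"] * 50 + ["weak"] * 25,
                           index=[f"s{i}" for i in range(75)])
        expr, target_genes = simulate_expression(groups, {"weak": 0.5}, seed=6)
        out = cs.target_gene_percent(expr, groups, target_genes)
        assert 40 <= out["median_percent"]["weak"] <= 60

    def test_geneset_score_zero_at_cohort_mean(self):
        expr = pd.DataFrame(
            [[5.0, 5.0, 5.0], [2.0, 2.0, 2.0]], index=["A", "B"],
            columns=["s0", "s1", "s2"],
        )
        # constant genes have zero variance; add one varying gene
        expr.loc["C"] = [1.0, 2.0, 3.0]
        score = cs.geneset_score(expr, ["C"])
        assert score["s1"] == pytest.approx(0.0)

    def test_geneset_score_shifted_sample(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.normal(0, 1, (5, 30)),
                            index=[f"G{i}" for i in range(5)],
                            columns=[f"s{i}" for i in range(30)])
        sd = expr.std(axis=1, ddof=0)
        expr["s0"] = expr["s0"] + 3 * sd
        score = cs.geneset_score(expr, list(expr.index))
        assert score["s0"] == score.max()

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cs.geneset_score(pd.DataFrame([[1.0]]), [])


class TestImmuneScore:
    def _cls(self, groups):
        return pd.Series(groups, name="group")

    def test_all_zero_scores_give_p_one(self):
        scores = pd.Series(0, index=[f"s{i}" for i in range(20)])
        groups = self._cls({f"s{i}": "weak" if i < 10 else "strong" for i in range(20)})
        out = cs.immune_score_test(scores, groups)
        assert out["p_value"] == pytest.approx(1.0)

    def test_matches_hypergeometric_oracle(self):
        from test_degron import oracle_fisher_two_sided

        idx = [f"s{i}" for i in range(80)]
        groups = self._cls({s: ("weak" if i < 27 else "strong") for i, s in enumerate(idx)})
        scores = pd.Series(0, index=idx)
        scores.iloc[:13] = 1          # 13 of 27 weak with score >= 1
        scores.iloc[27:27 + 41] = 2   # 41 of 53 strong with score >= 1
        out = cs.immune_score_test(scores, groups)
        assert out["table"].tolist() == [[13, 14], [41, 12]]
        assert out["p_value"] == pytest.approx(oracle_fisher_two_sided(13, 27, 41, 53))

    def test_group_effect_detected(self):
        hits = 0
        for seed in range(25):
            rng = np.random.default_rng(seed)
            idx = [f"s{i}" for i in range(80)]
            groups = self._cls({s: ("weak" if i < 30 else "strong") for i, s in enumerate(idx)})
            # odds ratio ~4 for nonzero score in the weak group
            p_weak, p_strong = 0.67, 0.33
            scores = pd.Series(
                [rng.random() < (p_weak if groups[s] == "weak" else p_strong) for s in idx],
                index=idx, dtype=int,
            )
            out = cs.immune_score_test(scores, groups)
            hits += out["p_value"] < 0.05
        assert hits / 25 >= 0.6

    def test_missing_scores_dropped_and_reported(self):
        idx = [f"s{i}" for i in range(10)]
        groups = self._cls({s: ("weak" if i < 5 else "strong") for i, s in enumerate(idx)})
        scores = pd.Series([0, 1, np.nan, 2, 0, 1, np.nan, 0, 3, 0], index=idx)
        out = cs.immune_score_test(scores, groups)
        assert out["n_missing"] == 2

    def test_invalid_scores_rejected(self):
        idx = ["a", "b"]
        groups = self._cls({"a": "weak", "b": "strong"})
        with pytest.raises(ValueError, match="outside"):
            cs.immune_score_test(pd.Series([0, 7], index=idx), groups)
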