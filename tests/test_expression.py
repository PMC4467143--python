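"""Expression integration: correlation calls, BH, GSEA, relevance logic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mirmycn as mm
from mirmycn.expression import GseaResult


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert mm.bh_adjust([0.3]) == pytest.approx([0.3])

    def test_hand_stepup_example(self):
        assert mm.bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones(self):
        assert mm.bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mm.bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=50, derandomize=True)
    def test_never_below_raw_and_order_preserved(self, ps):
        q = mm.bh_adjust(ps)
        assert np.all(q >= np.asarray(ps) - 1e-12)
        # monotone in the order statistics
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestPiValue:
    def test_worked_example(self):
        assert mm.pi_value(0.01, -0.5) == pytest.approx(-1.0)

    def test_sign_matches_effect(self):
        assert mm.pi_value(0.001, 0.8) > 0
        assert mm.pi_value(0.001, -0.8) < 0
        assert mm.pi_value(1.0, -0.8) == 0.0


class TestCorrelateToMycn:
    def test_perfect_anticorrelation(self):
        samples = [f"s{i}" for i in range(8)]
        mycn = pd.Series(np.arange(8.0), index=samples)
        mat = pd.DataFrame({"m1": -np.arange(8.0)}, index=samples).T
        out = mm.correlate_to_mycn(mat, mycn)
        assert out.at["m1", "coefficient"] == pytest.approx(-1.0)
        assert out.at["m1", "call"] == "inverse"

    def test_constant_row_not_testable(self):
        samples = [f"s{i}" for i in range(8)]
        mycn = pd.Series(np.arange(8.0), index=samples)
        mat = pd.DataFrame(
            {"flat": np.ones(8), "anti": -np.arange(8.0)}, index=samples
        ).T
        out = mm.correlate_to_mycn(mat, mycn)
        assert out.at["flat", "call"] == "not-testable"
        assert out.at["anti", "call"] == "inverse"

    def test_null_cohort_inverse_calls_near_bh_expectation(self):
        # no planted coupling: BH at q<=0.05 keeps false calls rare
        mirna_m, mrna_m, _ = mm.generate_cohort(
            mm.CohortSimConfig(n_samples=60, n_mirnas=200, n_genes=10, seed=4)
        )
        out = mm.correlate_to_mycn(mirna_m, mrna_m.loc["MYCN"])
        n_called = int((out["call"] != "n.s.").sum())
        assert n_called <= 10  # 5% of 200 plus slack

    def test_pearson_switch_recorded(self):
        samples = [f"s{i}" for i in range(8)]
        mycn = pd.Series(np.arange(8.0), index=samples)
        mat = pd.DataFrame({"m1": -np.arange(8.0)}, index=samples).T
        out = mm.correlate_to_mycn(mat, mycn, method="pearson")
        assert out.at["m1", "method"] == "pearson"
        assert out.at["m1", "coefficient"] == pytest.approx(-1.0)

    def test_planted_cohort_recovery_and_pi_shift(self, noisy_cohort):
        mirna_m, mrna_m, truth, planted = noisy_cohort
        out = mm.correlate_to_mycn(mirna_m, mrna_m.loc["MYCN"])
        calls = out.loc[list(planted), "call"]
        assert (calls == "inverse").mean() >= 0.9
        others = out.index.difference(planted)
        ks = mm.ks_two_sample(
            out.loc[list(planted), "pi_value"], out.loc[others, "pi_value"]
        )
        assert ks.p_value < 0.01


class TestRankGenes:
    def _toy(self):
        samples = [f"s{i}" for i in range(10)]
        x = pd.Series(np.arange(10.0), index=samples)
        mat = pd.DataFrame(
            {
                "g1": np.arange(10.0),
                "g2": np.ones(10),
                "g3": -np.arange(10.0),
            },
            index=samples,
        ).T
        return x, mat

    def test_ordering(self):
        x, mat = self._toy()
        ranked = mm.rank_genes_for_mirna(x, mat)
        assert list(ranked.index) == ["g1", "g2", "g3"]

    def test_tie_broken_lexicographically(self):
        samples = [f"s{i}" for i in range(6)]
        x = pd.Series(np.arange(6.0), index=samples)
        mat = pd.DataFrame(
            {"zz": np.ones(6), "aa": np.ones(6)}, index=samples
        ).T
        ranked = mm.rank_genes_for_mirna(x, mat)
        assert list(ranked.index) == ["aa", "zz"]

    @given(st.sampled_from(["exp", "cube", "logistic"]))
    @settings(max_examples=10, derandomize=True)
    def test_invariant_to_monotone_transform(self, transform):
        rng = np.random.default_rng(9)
        samples = [f"s{i}" for i in range(12)]
        x = pd.Series(rng.normal(size=12), index=samples)
        mat = pd.DataFrame(
            rng.normal(size=(5, 12)), index=list("abcde"), columns=samples
        )
        f = {
            "exp": np.exp,
            "cube": lambda v: v**3,
            "logistic": lambda v: 1 / (1 + np.exp(-v)),
        }[transform]
        base = mm.rank_genes_for_mirna(x, mat)
        trans = mm.rank_genes_for_mirna(pd.Series(f(x.to_numpy()), index=samples), mat)
        assert list(base.index) == list(trans.index)
        assert base.to_numpy() == pytest.approx(trans.to_numpy())


def brute_force_gsea(genes, statvals, gene_set, n_permutations, seed):
    """Independent plain-Python preranked GSEA used as the oracle."""
    members = set(gene_set)
    in_list = [g in members for g in genes]
    nh = sum(in_list)
    n = len(genes)

    def es_of(flags):
        wsum = sum(abs(s) for s, f in zip(statvals, flags) if f)
        run, values = 0.0, []
        for s, f in zip(statvals, flags):
            if f:
                run += abs(s) / wsum if wsum > 0 else 1.0 / sum(flags)
            else:
                run -= 1.0 / (n - sum(flags))
            values.append(run)
        # same tie policy as the implementation: select the extremum on
        # the running sum rounded to 12 decimals
        best_i, best_abs = 0, -1.0
        for i, v in enumerate(values):
            a = abs(float(np.round(v, 12)))
            if a > best_abs:
                best_i, best_abs = i, a
        return values[best_i]

    es = es_of(in_list)
    rng = np.random.default_rng(seed)
    null = []
    for _ in range(n_permutations):
        idx = set(rng.choice(n, size=nh, replace=False).tolist())
        null.append(es_of([i in idx for i in range(n)]))
    null = np.asarray(null)
    same = null >= 0 if es >= 0 else null < 0
    if same.sum() == 0:
        mean_abs = float(np.mean(np.abs(null)))
        return es, es / mean_abs
    mean_abs = float(np.mean(np.abs(null[same])))
    return es, es / mean_abs


class TestGseaPreranked:
    def test_single_top_gene_full_es(self):
        ranked = pd.Series([3.0, 2.0, 1.0, -1.0], index=list("abcd"))
        r = mm.gsea_preranked(ranked, {"a"}, n_permutations=100, seed=0)
        assert r.es == pytest.approx(1.0)

    def test_bottom_set_negative_es(self):
        ranked = pd.Series([3.0, 2.0, -1.0, -2.0], index=list("abcd"))
        r = mm.gsea_preranked(ranked, {"c", "d"}, n_permutations=100, seed=0)
        assert r.es < 0

    def test_empty_intersection_rejected(self):
        ranked = pd.Series([1.0, 0.5], index=["a", "b"])
        with pytest.raises(ValueError):
            mm.gsea_preranked(ranked, {"zz"}, n_permutations=100, seed=0)

    def test_full_coverage_rejected(self):
        ranked = pd.Series([1.0, 0.5], index=["a", "b"])
        with pytest.raises(ValueError):
            mm.gsea_preranked(ranked, {"a", "b"}, n_permutations=100, seed=0)

    def test_oracle_equivalence_tiny_instances(self):
        rng = np.random.default_rng(123)
        for trial in range(50):
            n = int(rng.integers(6, 13))
            genes = [f"g{i}" for i in range(n)]
            statvals = np.sort(rng.normal(size=n))[::-1]
            size = int(rng.integers(1, 5))
            members = set(rng.choice(genes, size=size, replace=False).tolist())
            seed = int(rng.integers(0, 2**31 - 1))
            ranked = pd.Series(statvals, index=genes)
            r = mm.gsea_preranked(ranked, members, n_permutations=100, seed=seed)
            es_o, nes_o = brute_force_gsea(genes, statvals, members, 100, seed)
            assert r.es == pytest.approx(es_o, abs=1e-9)
            assert r.nes == pytest.approx(nes_o, abs=1e-9)

    def test_random_set_es_centered_near_zero(self):
        # with a sign-symmetric ranking profile the random-set null is
        # symmetric, so the empirical ES mean sits near zero
        from mirmycn.expression import _running_es

        rng = np.random.default_rng(7)
        statvals = np.linspace(2, -2, 40)
        means = []
        for _ in range(1000):
            idx = rng.choice(40, size=6, replace=False)
            in_set = np.zeros(40, dtype=bool)
            in_set[idx] = True
            means.append(_running_es(statvals, in_set))
        assert abs(np.mean(means)) < 0.05


class TestClassifyActivityRelation:
    def _res(self, nes, fdr):
        return GseaResult("set", np.sign(nes) * 0.5, nes, 0.01, fdr, 100, 0, 10)

    def test_negative_rule(self):
        out = mm.classify_activity_relation([self._res(-2.5, 0.1)])
        assert out == {"call": "negative", "ambiguous": False}

    def test_inside_band_none(self):
        out = mm.classify_activity_relation(
            [self._res(-1.5, 0.01), self._res(1.9, 0.01)]
        )
        assert out["call"] == "none"

    def test_mirrored_positive_rule(self):
        out = mm.classify_activity_relation([self._res(2.5, 0.1)])
        assert out["call"] == "positive"

    def test_fdr_gate(self):
        out = mm.classify_activity_relation([self._res(-2.5, 0.3)])
        assert out["call"] == "none"

    def test_both_directions_ambiguous(self):
        out = mm.classify_activity_relation(
            [self._res(-2.5, 0.1), self._res(2.5, 0.1)]
        )
        assert out == {"call": "negative", "ambiguous": True}


class TestChiSquare:
    def test_worked_example(self):
        stat, p = mm.chi_square_2x2([[10, 5], [5, 10]])
        assert stat == pytest.approx(10 / 3)

    def test_independence(self):
        stat, p = mm.chi_square_2x2([[5, 5], [5, 5]])
        assert stat == 0.0 and p == 1.0

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            mm.chi_square_2x2([[5, -1], [5, 5]])

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            mm.chi_square_2x2([[0, 0], [5, 5]])


class TestClassifyRelevance:
    def test_inverse_expression_alone_is_relevant(self):
        calls = mm.classify_relevance(["m"], {"m": "inverse"}, {"m": "none"})
        assert calls[0].final == "relevant"

    def test_conflicting_axes_excluded(self):
        calls = mm.classify_relevance(["m"], {"m": "inverse"}, {"m": "positive"})
        assert calls[0].final == "conflicting-excluded"

    def test_positive_only_is_mycn_induced(self):
        calls = mm.classify_relevance(["m"], {"m": "positive"}, {"m": "none"})
        assert calls[0].final == "mycn-induced"

    def test_absent_from_platform_is_no_data(self):
        calls = mm.classify_relevance(["m"], {}, {})
        assert calls[0].final == "no-data"

    def test_non_hit_emits_nothing(self):
        assert mm.classify_relevance([], {"m": "inverse"}, {}) == []

    def test_pure_function_deterministic(self):
        args = (["a", "b"], {"a": "inverse"}, {"b": "negative"})
        assert mm.classify_relevance(*args) == mm.classify_relevance(*args)
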