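import itertools

import numpy as np
import pytest

from essprofile.stats_compare import (
    ComparisonSpec,
    bonferroni_threshold,
    compare_categorical,
    compare_numeric,
    normality_gate,
    term_enrichment,
)
from oracles import hypergeom_tail_ge, mwu_permutation_p


def spec(feature="f", kind="numeric", m=1):
    return ComparisonSpec(feature=feature, kind=kind, m=m)


class TestNormalityGate:
    def test_normal_samples_mostly_pass(self):
        passed = 0
        for seed in range(40):
            x = np.random.default_rng(seed).normal(10, 3, size=1000)
            passed += normality_gate(x)
        assert passed >= 36  # >= 90% of seeds

    def test_exponential_samples_fail(self):
        for seed in range(20):
            x = np.random.default_rng(seed).exponential(size=1000)
            assert not normality_gate(x)

    def test_constant_sample_fails_gracefully(self):
        assert normality_gate([5.0] * 50) is False

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="n >= 8"):
            normality_gate([1, 2, 3])


class TestCompareNumeric:
    def test_identical_samples_p_one(self):
        res = compare_numeric([1, 2, 3], [1, 2, 3], spec())
        assert res.test == "mann_whitney_u"
        assert res.p == pytest.approx(1.0)
        assert not res.significant

    def test_fully_separated_small_samples_exact(self):
        res = compare_numeric([1, 2, 3], [4, 5, 6], spec())
        assert res.statistic == 0.0
        assert res.p == pytest.approx(0.1)

    def test_normal_samples_use_welch(self):
        rng = np.random.default_rng(0)
        res = compare_numeric(rng.normal(0, 1, 500), rng.normal(0.5, 2, 500),
                              spec())
        assert res.test == "welch_t"
        assert res.significant

    def test_lognormal_samples_use_mwu(self):
        rng = np.random.default_rng(1)
        res = compare_numeric(rng.lognormal(1, 1, 300),
                              rng.lognormal(1, 1, 300), spec())
        assert res.test == "mann_whitney_u"

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compare_numeric([], [1.0], spec())

    def test_medians_reported(self):
        res = compare_numeric([1, 2, 9], [4, 5, 6], spec())
        assert res.summary_a == 2.0
        assert res.summary_b == 5.0

    @pytest.mark.parametrize("na,nb", [(1, 3), (2, 2), (3, 3), (4, 3), (5, 5)])
    def test_mwu_matches_permutation_oracle(self, na, nb):
        rng = np.random.default_rng(na * 10 + nb)
        for _ in range(10):
            pooled = rng.permutation(np.arange(1, na + nb + 1, dtype=float))
            a, b = list(pooled[:na]), list(pooled[na:])
            res = compare_numeric(a, b, spec())
            assert res.p == pytest.approx(mwu_permutation_p(a, b), abs=1e-12)

    def test_paper_scale_median_shift_detected(self):
        # log-normal samples with the study's gene-length medians
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            a = rng.lognormal(np.log(28913), 0.8, 500)
            b = rng.lognormal(np.log(21629), 0.8, 500)
            res = compare_numeric(a, b, spec(m=6))
            hits += res.significant and res.summary_a > res.summary_b
        assert hits == 5


class TestCompareCategorical:
    def test_known_counts_chi_squared(self):
        res = compare_categorical(213, 1301, 1004, 3451,
                                  spec(kind="categorical"))
        assert res.test == "chi_squared"
        assert res.statistic == pytest.approx(80.25, abs=0.05)
        assert round(res.summary_a, 1) == 16.4
        assert round(res.summary_b, 1) == 29.1

    def test_equal_proportions_p_one(self):
        res = compare_categorical(50, 100, 50, 100, spec(kind="categorical"))
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_sparse_table_falls_back_to_fisher(self):
        res = compare_categorical(0, 10, 10, 10, spec(kind="categorical"))
        assert res.test == "fisher_exact"
        # two-sided Fisher on a fully separated 2x2: both tails collapse
        assert res.p == pytest.approx(2 * hypergeom_tail_ge(10, 20, 10, 10),
                                      rel=1e-6)

    def test_chi_squared_equals_hand_formula(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n_a, n_b = int(rng.integers(40, 200)), int(rng.integers(40, 200))
            k_a = int(rng.integers(10, n_a - 10))
            k_b = int(rng.integers(10, n_b - 10))
            res = compare_categorical(k_a, n_a, k_b, n_b,
                                      spec(kind="categorical"))
            if res.test != "chi_squared":
                continue
            obs = np.array([[k_a, n_a - k_a], [k_b, n_b - k_b]], float)
            exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
            assert res.statistic == pytest.approx(
                ((obs - exp) ** 2 / exp).sum())

    def test_successes_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            compare_categorical(11, 10, 1, 10, spec(kind="categorical"))


class TestBonferroni:
    @pytest.mark.parametrize("m,expected", [
        (6, 0.05 / 6), (13, 0.05 / 13), (20, 0.0025),
        (16, 0.003125), (4, 0.0125), (1, 0.05),
    ])
    def test_thresholds(self, m, expected):
        assert bonferroni_threshold(m) == pytest.approx(expected, rel=1e-12)

    def test_strictly_decreasing_in_m(self):
        values = [bonferroni_threshold(m) for m in range(1, 30)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_invalid_family_size(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0)


class TestTermEnrichment:
    def _toy(self):
        background = {f"g{i}" for i in range(100)}
        query = {f"g{i}" for i in range(10)}
        return query, background

    def test_perfectly_enriched_term_ranks_first(self):
        query, background = self._toy()
        terms = {
            "hit": set(query),
            "flat": {f"g{i}" for i in range(0, 100, 10)},
            "other": {f"g{i}" for i in range(50, 90)},
        }
        results = term_enrichment(query, background, terms)
        assert results[0].term == "hit"
        assert results[0].corrected_p < results[-1].corrected_p

    def test_proportional_term_not_enriched(self):
        query, background = self._toy()
        # 10% of query and ~10% of background annotated
        terms = {"flat": {"g0", "g15", "g25", "g35", "g45",
                          "g55", "g65", "g75", "g85", "g95"}}
        res = term_enrichment(query, background, terms)[0]
        assert res.p > 0.5

    def test_fisher_matches_hypergeometric_oracle(self):
        query, background = self._toy()
        term_genes = set(list(query)[:8]) | {f"g{i}" for i in range(60, 70)}
        res = term_enrichment(query, background, {"t": term_genes})[0]
        expected = hypergeom_tail_ge(8, 100, len(term_genes), 10)
        assert res.p == pytest.approx(expected, rel=1e-9)
        assert res.corrected_p == pytest.approx(min(1.0, res.p))

    def test_query_outside_background_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            term_enrichment({"x"}, {"a", "b"}, {"t": {"a"}})

    def test_term_annotating_nothing_rejected(self):
        with pytest.raises(ValueError, match="no background gene"):
            term_enrichment({"a"}, {"a", "b"}, {"t": {"zzz"}})
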