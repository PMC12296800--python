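"""The smoothed log-odds statistic, its variance, thresholding and ranking."""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lexkey import (
    FrequencyTable,
    KeynessDomainError,
    bonferroni_threshold,
    compute_keyness,
    keyness_scores,
    loridp_delta,
    loridp_variance,
    merge_tables,
    select_keys,
    top_k_table,
)
from lexkey.keyness import KeynessResult


def oracle_delta(y_i, n_i, y_j, n_j, a_w, a_0):
    """Exact-rational odds ratio, log taken last (independent oracle)."""
    odds_i = Fraction(y_i + a_w, n_i + a_0 - (y_i + a_w))
    odds_j = Fraction(y_j + a_w, n_j + a_0 - (y_j + a_w))
    return math.log(odds_i / odds_j)


def oracle_variance(y_i, y_j, a_w):
    return float(Fraction(1, y_i + a_w) + Fraction(1, y_j + a_w))


class TestDelta:
    def test_exact_rational_substitution(self):
        # (5+6)/(10+20-11) = 11/19 against (1+6)/(10+20-7) = 7/23
        assert loridp_delta(5, 10, 1, 10, 6, 20) == pytest.approx(
            math.log(Fraction(11, 19) / Fraction(7, 23)), abs=1e-15
        )
        assert math.isclose(
            loridp_delta(5, 10, 1, 10, 6, 20), math.log(253 / 133)
        )

    def test_identical_corpora_give_zero(self):
        assert loridp_delta(4, 9, 4, 9, 8, 18) == 0.0

    def test_swapping_roles_negates(self):
        forward = loridp_delta(5, 10, 1, 12, 6, 22)
        assert loridp_delta(1, 12, 5, 10, 6, 22) == pytest.approx(-forward)

    def test_degenerate_denominator_raises(self):
        # one-lemma corpus: n + alpha_0 - (y + alpha_w) = 0
        with pytest.raises(KeynessDomainError):
            loridp_delta(3, 3, 3, 3, 6, 6)

    def test_monotone_in_target_count(self):
        # alpha_w recomputed from the pooled counts, as the pipeline does
        y_j, n_i, n_j = 7, 200, 150
        deltas = [
            loridp_delta(y_i, n_i, y_j, n_j, y_i + y_j, n_i + n_j)
            for y_i in range(0, 60)
        ]
        assert all(b >= a for a, b in zip(deltas, deltas[1:]))


class TestVariance:
    def test_exact_rational_substitution(self):
        # 1/(5+6) + 1/(1+6) = 1/11 + 1/7 = 18/77
        assert loridp_variance(5, 1, 6) == pytest.approx(
            float(Fraction(18, 77)), abs=1e-15
        )

    def test_symmetric_in_corpus_roles(self):
        assert loridp_variance(5, 1, 6) == loridp_variance(1, 5, 6)

    def test_doubling_counts_decreases_variance(self):
        assert loridp_variance(10, 2, 12) < loridp_variance(5, 1, 6)

    def test_zero_smoothed_count_raises(self):
        with pytest.raises(KeynessDomainError):
            loridp_variance(0, 3, 0)


class TestComputeKeyness:
    def test_toy_z_composition(self):
        combined = merge_tables(
            FrequencyTable("t", {"w": 5, "x": 5}, 10),
            FrequencyTable("r", {"w": 1, "x": 9}, 10),
        )
        results = {r.lemma: r for r in compute_keyness(combined)}
        expected_delta = oracle_delta(5, 10, 1, 10, 6, 20)
        expected_var = oracle_variance(5, 1, 6)
        assert results["w"].delta == pytest.approx(expected_delta, abs=1e-12)
        assert results["w"].variance == pytest.approx(expected_var, abs=1e-12)
        assert results["w"].z == pytest.approx(
            expected_delta / math.sqrt(expected_var), abs=1e-12
        )

    def test_identical_corpora_all_zero(self):
        table = FrequencyTable("x", {"a": 6, "b": 3, "c": 1}, 10)
        combined = merge_tables(table, table)
        _, _, z = keyness_scores(combined)
        assert np.all(z == 0.0)

    def test_swapping_roles_negates_all_z(self):
        combined = merge_tables(
            FrequencyTable("t", {"a": 8, "b": 2, "c": 5}, 15),
            FrequencyTable("r", {"a": 1, "b": 9, "d": 4}, 14),
        )
        _, _, z = keyness_scores(combined)
        _, _, z_swapped = keyness_scores(combined.swapped())
        assert np.allclose(z_swapped, -z, atol=1e-14)

    @given(st.data())
    @settings(derandomize=True, max_examples=120)
    def test_matches_exact_rational_oracle(self, data):
        n_lemmas = data.draw(st.integers(1, 6))
        lemmas = [f"w{i}" for i in range(n_lemmas)]
        counts_t = data.draw(
            st.lists(st.integers(0, 20), min_size=n_lemmas, max_size=n_lemmas)
        )
        counts_r = data.draw(
            st.lists(st.integers(0, 20), min_size=n_lemmas, max_size=n_lemmas)
        )
        pooled_ok = [t + r >= 1 for t, r in zip(counts_t, counts_r)]
        counts_t = [t if ok else t + 1
                    for t, ok in zip(counts_t, pooled_ok)]
        target = {w: c for w, c in zip(lemmas, counts_t) if c > 0}
        reference = {w: c for w, c in zip(lemmas, counts_r) if c > 0}
        if not target or not reference:
            return
        combined = merge_tables(
            FrequencyTable("t", target, sum(target.values())),
            FrequencyTable("r", reference, sum(reference.values())),
        )
        if combined.n_rows < 2:
            return  # statistic undefined on a one-lemma universe
        delta, variance, z = keyness_scores(combined)
        a_0 = combined.alpha_0
        for i, lemma in enumerate(combined.lemmas):
            y_t = target.get(lemma, 0)
            y_r = reference.get(lemma, 0)
            a_w = y_t + y_r
            expected_delta = oracle_delta(
                y_t, combined.n_target, y_r, combined.n_reference, a_w, a_0
            )
            expected_var = oracle_variance(y_t, y_r, a_w)
            assert delta[i] == pytest.approx(expected_delta, abs=1e-12)
            assert variance[i] == pytest.approx(expected_var, abs=1e-12)
            assert z[i] == pytest.approx(
                expected_delta / math.sqrt(expected_var), abs=1e-12
            )


class TestBonferroniThreshold:
    def test_published_threshold_to_two_decimals(self):
        assert round(bonferroni_threshold(0.01, 59190), 2) == 5.10

    def test_single_test_median(self):
        assert bonferroni_threshold(0.5, 1) == pytest.approx(0.0, abs=1e-12)

    def test_single_test_five_percent(self):
        assert bonferroni_threshold(0.05, 1) == pytest.approx(1.6449, abs=5e-5)

    def test_two_sided_is_stricter(self):
        one = bonferroni_threshold(0.01, 59190)
        two = bonferroni_threshold(0.01, 59190, "two-sided")
        assert two > one

    @pytest.mark.parametrize(
        "alpha,m,tails",
        [(0.0, 10, "one-sided"), (1.0, 10, "one-sided"),
         (0.01, 0, "one-sided"), (0.01, 10, "sideways")],
    )
    def test_invalid_arguments(self, alpha, m, tails):
        with pytest.raises(ValueError):
            bonferroni_threshold(alpha, m, tails)


def _result(lemma, z):
    return KeynessResult(lemma=lemma, y_target=1, y_reference=1,
                         delta=z, variance=1.0, z=z)


class TestSelectKeys:
    def test_manual_split(self):
        results = [_result("a", 6.0), _result("b", -5.5), _result("c", 1.0)]
        target, reference = select_keys(results, 5.10)
        assert [r.lemma for r in target] == ["a"]
        assert [r.lemma for r in reference] == ["b"]
        assert target[0].rank == 1 and reference[0].rank == 1
        assert [r.significant for r in results] == [True, True, False]

    def test_no_keys_below_threshold(self):
        target, reference = select_keys(
            [_result("a", 2.0), _result("b", -3.0)], 5.10
        )
        assert target == [] and reference == []

    def test_ordering_and_deterministic_ties(self):
        results = [_result("b", 7.0), _result("a", 7.0), _result("c", 9.0),
                   _result("z", -6.0), _result("y", -8.0)]
        target, reference = select_keys(results, 5.0)
        assert [r.lemma for r in target] == ["c", "a", "b"]
        assert [r.rank for r in target] == [1, 2, 3]
        assert [r.lemma for r in reference] == ["y", "z"]

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError):
            select_keys([], 0.0)


class TestTopK:
    def test_empty_keys(self):
        assert top_k_table([], 50).empty

    def test_fewer_keys_than_k(self):
        target, _ = select_keys(
            [_result("a", 8.0), _result("b", 6.0), _result("c", 7.0)], 5.0
        )
        table = top_k_table(target, 50)
        assert list(table["rank"]) == [1, 2, 3]
        assert list(table["lemma"]) == ["a", "c", "b"]

    def test_truncation_keeps_highest_scores(self):
        results = [_result(f"w{i:03d}", 5.5 + i * 0.1) for i in range(60)]
        target, _ = select_keys(results, 5.0)
        table = top_k_table(target, 50)
        assert len(table) == 50
        assert table["abs_z"].is_monotonic_decreasing
        assert table["abs_z"].iloc[0] == pytest.approx(5.5 + 59 * 0.1)

    def test_gloss_mapping(self):
        target, _ = select_keys([_result("війна", 9.0)], 5.0)
        table = top_k_table(target, 5, {"війна": "war"})
        assert list(table["gloss"]) == ["war"]
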