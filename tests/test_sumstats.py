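import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from freqbias import sumstats
from freqbias.sumstats import (
    SummaryVector,
    fit_turnover_exponent,
    ks_against_neutral,
    mean_turnover,
    simpson_diversity,
    summary_names,
    summary_vector,
    top_list,
    turnover_matrix,
    turnover_series,
    turnover_profile,
)

from conftest import make_freq


class TestTopList:
    def test_hand_ranking(self):
        assert top_list({"A": 5, "B": 3, "C": 1}, 2) == ["A", "B"]

    def test_truncates_to_present(self):
        assert top_list({"A": 2, "B": 1, "C": 0}, 10) == ["A", "B"]

    def test_tie_break_is_stable(self):
        first = top_list({"A": 2, "B": 2}, 1)
        assert all(top_list({"B": 2, "A": 2}, 1) == first for _ in range(5))
        assert first == ["A"]  # id order breaks the tie

    def test_invalid_size(self):
        with pytest.raises(ValueError):
            top_list({"A": 1}, 0)


class TestTurnover:
    def test_one_replacement(self):
        # top-2 {A,B} -> {A,C}: one new entrant
        ft = make_freq([[5, 3, 1], [5, 1, 3]])
        assert turnover_series(ft, 2).tolist() == [1]

    def test_identical_rankings_zero(self):
        ft = make_freq([[5, 3, 1]] * 4)
        assert np.all(turnover_matrix(ft, 3) == 0)

    def test_disjoint_lists_attain_bound(self):
        ft = make_freq([[3, 2, 0, 0], [0, 0, 3, 2]])
        assert turnover_series(ft, 2).tolist() == [2]

    def test_single_timepoint_errors(self):
        with pytest.raises(ValueError, match="2 timepoints"):
            turnover_matrix(make_freq([[1, 2]]), 2)

    def test_tie_break_uses_first_appearance(self):
        # B and C tie at t2; B appeared earlier so it outranks C
        ft = make_freq([[3, 2, 0], [3, 1, 1], [1, 2, 2]])
        orders = sumstats.rank_orders(ft)
        assert orders[2].tolist() == [1, 2, 0]  # B, C (tie -> earlier first seen), A

    @given(
        st.integers(2, 6).flatmap(
            lambda T: st.lists(
                st.lists(st.integers(0, 5), min_size=4, max_size=4),
                min_size=T,
                max_size=T,
            )
        ).filter(lambda rows: all(sum(r) > 0 for r in rows))
    )
    @settings(max_examples=60, deadline=None)
    def test_turnover_bounded_by_list_size(self, rows):
        ft = make_freq(rows)
        z = turnover_matrix(ft, 5)
        ys = np.arange(1, 6)
        assert np.all(z >= 0)
        assert np.all(z <= ys[None, :])
        # column y of the matrix equals the dedicated series
        for y in (1, 3, 5):
            assert np.array_equal(turnover_series(ft, y), z[:, y - 1])


class TestPowerLawFit:
    def test_exact_recovery(self):
        y = np.arange(1, 101)
        A, x = fit_turnover_exponent(2.0 * y**0.86)
        assert A == pytest.approx(2.0, abs=1e-12)
        assert x == pytest.approx(0.86, abs=1e-12)

    def test_identity_profile(self):
        A, x = fit_turnover_exponent(np.arange(1.0, 21.0))
        assert (A, x) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_zero_entries_excluded(self):
        z = np.array([0.0, 2 * 2**0.5, 0.0, 2 * 4**0.5])
        A, x = fit_turnover_exponent(z)
        assert A == pytest.approx(2.0) and x == pytest.approx(0.5)

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError, match=">= 2"):
            fit_turnover_exponent([0.0, 1.0])

    def test_profile_caps_at_minimum_present(self):
        # 3 variants present at t0 but y_max=5: fit ignores saturated sizes
        ft = make_freq([[5, 3, 1, 0, 0], [3, 5, 0, 1, 0], [1, 2, 5, 1, 0]])
        prof = turnover_profile(ft, 5)
        assert len(prof.mean_turnover) == 5
        uncapped = turnover_profile(ft, 5, cap_at_present=False)
        assert prof.exponent != uncapped.exponent


class TestSimpson:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ({"A": 1, "B": 1}, 0.5),
            ({"A": 7}, 1.0),
            ({"A": 2, "B": 1, "C": 1}, 0.375),
        ],
    )
    def test_with_replacement_form(self, counts, expected):
        assert simpson_diversity(counts) == pytest.approx(expected)

    def test_unbiased_form(self):
        assert simpson_diversity({"A": 2, "B": 1, "C": 1}, unbiased=True) == pytest.approx(
            2 / 12
        )

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            simpson_diversity({})

    @given(st.lists(st.integers(0, 9), min_size=1, max_size=8).filter(lambda c: sum(c) > 0))
    @settings(max_examples=60, deadline=None)
    def test_bounds_and_monomorphic(self, counts):
        d = simpson_diversity(counts)
        assert 0 < d <= 1
        assert (d == 1.0) == (sum(1 for c in counts if c > 0) == 1)


class TestSummaryVector:
    def test_study_geometry_length(self):
        # 1 (x) + 142 (zbar) + 32 (D_t) + 1 (Dbar) = 176; 178 with LDA axes
        assert len(summary_names(142, 32)) == 176
        assert len(summary_names(142, 32, lda=True)) == 178

    def test_tiny_geometry_length(self):
        ft = make_freq([[2, 1], [1, 2]])
        vec = summary_vector(ft, 1)
        assert len(vec) == 5  # 1 + 1 + 2 + 1
        assert vec.names() == ["x", "zbar_1", "D_1", "D_2", "Dbar"]

    def test_degenerate_turnover_gives_nan_exponent(self):
        ft = make_freq([[5, 3, 1]] * 3)
        vec = summary_vector(ft, 3)
        assert np.isnan(vec.exponent)
        assert np.all(vec.mean_turnover == 0)

    def test_slot_order_round_trip(self):
        ft = make_freq([[5, 3, 1, 1], [4, 4, 1, 1], [1, 6, 2, 1]])
        vec = summary_vector(ft, 3)
        s = vec.to_series()
        arr = vec.to_array()
        assert s.index.tolist() == vec.names()
        assert np.array_equal(s.to_numpy(), arr)
        assert arr[0] == vec.exponent or (np.isnan(arr[0]) and np.isnan(vec.exponent))
        assert arr[-1] == vec.mean_diversity
        with_lda = vec.with_lda(np.array([0.1, -0.2]))
        assert len(with_lda) == len(vec) + 2
        assert with_lda.names()[-2:] == ["LD1", "LD2"]

    def test_require_full_lists(self):
        ft = make_freq([[5, 3, 0], [4, 4, 1]])
        with pytest.raises(ValueError, match="minimum per-timepoint"):
            summary_vector(ft, 3, require_full_lists=True)
        summary_vector(ft, 2, require_full_lists=True)  # 2 always present


class TestKS:
    def test_sample_vs_itself(self):
        z = np.array([1.0, 2.0, 3.0, 4.0])
        stat, p = ks_against_neutral(z, z)
        assert stat == 0.0 and p == 1.0

    def test_disjoint_supports(self):
        stat, _ = ks_against_neutral(np.zeros(10), np.ones(10))
        assert stat == 1.0

    def test_per_size_mean_method(self):
        obs = np.array([[1, 2], [3, 4]])
        neu = np.array([[1, 2], [3, 4]])
        stat, p = ks_against_neutral(obs, neu, method="per_size_mean")
        assert stat == 0.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            ks_against_neutral(np.array([]), np.ones(3))
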