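import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import zeta

from gozipf.corpus_builder import Corpus, frequency_table
from gozipf.powerlaw import (
    DegenerateTailError,
    EmptyTailError,
    NoCandidateError,
    ccdf,
    convert_exponents,
    fit_power_law,
    gof_pvalue,
    ks_distance,
    mle_beta,
    rank_frequency,
    select_xmin,
)
from gozipf.synthetic_data import sample_discrete_power_law

# ---------------------------------------------------------------- oracles


def grid_mle(values, xmin, lo=1.001, hi=8.0):
    """Brute-force MLE: coarse global grid, then a fine local grid."""
    values = np.asarray(values)
    tail = values[values >= xmin]
    log_sum = np.log(tail).sum()

    def best(grid):
        ll = -tail.size * np.log(zeta(grid, xmin)) - grid * log_sum
        return grid[np.argmax(ll)]

    b0 = best(np.arange(lo, hi, 1e-3))
    return best(np.arange(b0 - 2e-3, b0 + 2e-3, 1e-7))


def brute_ks(values, beta, xmin):
    """KS distance by direct enumeration over every distinct tail value."""
    tail = [v for v in values if v >= xmin]
    out = 0.0
    for x in sorted(set(tail)):
        emp = sum(1 for v in tail if v >= x) / len(tail)
        model = zeta(beta, x) / zeta(beta, xmin)
        out = max(out, abs(emp - model))
    return out


# ----------------------------------------------------------------- ccdf


class TestCCDF:
    def test_hand_counts(self):
        c = ccdf([1, 1, 2, 3])
        assert c.x.tolist() == [1, 2, 3]
        assert c.p.tolist() == [1.0, 0.5, 0.25]

    def test_single_value(self):
        c = ccdf([5])
        assert c.x.tolist() == [5] and c.p.tolist() == [1.0]

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            ccdf([])

    @given(st.lists(st.integers(1, 50), min_size=1, max_size=200))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_non_increasing_and_one_at_min(self, values):
        c = ccdf(values)
        assert np.all(np.diff(c.p) <= 0)
        assert c.p[0] == 1.0


# ------------------------------------------------------------------ MLE


class TestMleBeta:
    def test_matches_brute_force_grid_search(self):
        values = sample_discrete_power_law(2.3, 1, 200, seed=11)
        assert mle_beta(values, 1) == pytest.approx(grid_mle(values, 1), abs=2e-6)

    def test_matches_brute_force_above_threshold(self):
        values = sample_discrete_power_law(1.8, 3, 200, seed=12)
        assert mle_beta(values, 3) == pytest.approx(grid_mle(values, 3), abs=2e-6)

    def test_recovers_known_exponent_within_three_se(self):
        values = sample_discrete_power_law(2.5, 1, 50_000, seed=13)
        beta_hat = mle_beta(values, 1)
        se = (beta_hat - 1) / np.sqrt(values.size)  # conservative bound
        assert abs(beta_hat - 2.5) <= 3 * se

    def test_continuous_limit_at_large_xmin(self):
        """For xmin >> 1 the discrete MLE approaches the continuous one."""
        xmin = 50
        values = sample_discrete_power_law(2.5, xmin, 5000, seed=42)
        continuous = 1 + values.size / np.log(values / (xmin - 0.5)).sum()
        assert mle_beta(values, xmin) == pytest.approx(continuous, abs=5e-3)

    def test_all_equal_tail_diverges(self):
        with pytest.raises(DegenerateTailError):
            mle_beta([7] * 30, 7)

    def test_empty_tail_is_an_error(self):
        with pytest.raises(EmptyTailError):
            mle_beta([1, 2, 3], 10)


# ------------------------------------------------------------------- KS


class TestKsDistance:
    def test_matches_brute_force_enumeration(self):
        values = sample_discrete_power_law(2.0, 1, 20, seed=3)
        d = ks_distance(values, 2.1, 1)
        assert d == pytest.approx(brute_ks(values, 2.1, 1), abs=1e-12)

    def test_small_for_data_from_the_model(self):
        values = sample_discrete_power_law(2.2, 1, 10_000, seed=4)
        assert ks_distance(values, 2.2, 1) < 0.05

    def test_single_distinct_tail_value_bounded(self):
        d = ks_distance([4, 4, 4], 2.0, 4)
        assert 0.0 <= d <= 1.0

    def test_beta_at_most_one_is_a_domain_error(self):
        with pytest.raises(ValueError):
            ks_distance([1, 2, 3], 1.0, 1)


# ----------------------------------------------------------- select_xmin


class TestSelectXmin:
    def test_matches_exhaustive_candidate_scan(self):
        values = sample_discrete_power_law(2.0, 1, 100, seed=21)
        xmin, beta, d = select_xmin(values, min_tail=10)
        best = None
        for x in np.unique(values):
            tail = values[values >= x]
            if tail.size < 10 or np.unique(tail).size < 2:
                continue
            b = mle_beta(tail, int(x))
            dd = ks_distance(tail, b, int(x))
            if best is None or dd < best[2]:
                best = (int(x), b, dd)
        assert xmin == best[0]
        assert beta == pytest.approx(best[1], abs=1e-9)
        assert d == pytest.approx(best[2], abs=1e-9)

    def test_finds_the_spliced_threshold(self):
        """Uniform noise on {1..3} under a power-law tail from xmin=4."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noise = rng.integers(1, 4, size=1000)
            tail = sample_discrete_power_law(2.5, 4, 1000, rng)
            xmin, _, _ = select_xmin(np.concatenate([noise, tail]))
            hits += xmin in (3, 4, 5)
        assert hits >= 18

    def test_pure_power_law_keeps_a_small_xmin(self):
        hits = 0
        for seed in range(20):
            values = sample_discrete_power_law(2.2, 1, 1000,
                                               np.random.default_rng(100 + seed))
            xmin, _, _ = select_xmin(values)
            hits += xmin <= 3
        assert hits >= 14

    def test_no_candidate_with_enough_tail(self):
        with pytest.raises(NoCandidateError):
            select_xmin([1, 2, 3], min_tail=10)


# -------------------------------------------------------- bootstrap GOF


class TestGofPvalue:
    def test_deterministic_under_fixed_seed(self):
        values = sample_discrete_power_law(2.0, 1, 300, seed=5)
        fit = fit_power_law(values)
        p1 = gof_pvalue(values, fit, n_bootstrap=40, seed=9)
        p2 = gof_pvalue(values, fit, n_bootstrap=40, seed=9)
        assert p1 == p2

    def test_plausibility_flag_follows_the_0_1_rule(self):
        values = sample_discrete_power_law(2.0, 1, 300, seed=6)
        fit = fit_power_law(values, n_bootstrap=40, seed=10)
        assert fit.plausible == (fit.p_value > 0.1)

    def test_bad_replicate_count_rejected(self):
        values = sample_discrete_power_law(2.0, 1, 300, seed=7)
        fit = fit_power_law(values)
        with pytest.raises(ValueError):
            gof_pvalue(values, fit, n_bootstrap=0, seed=1)


# ----------------------------------------------------- exponent algebra


class TestConvertExponents:
    def test_anchor_point(self):
        e = convert_exponents(k=1.0)
        assert e.alpha == 1.0 and e.beta == 2.0

    def test_beta_to_alpha(self):
        e = convert_exponents(beta=2.04)
        assert e.alpha == pytest.approx(1 / 1.04, abs=1e-12)
        assert e.k == pytest.approx(1.04, abs=1e-12)

    def test_round_trip_is_identity(self):
        e = convert_exponents(beta=2.04)
        assert convert_exponents(alpha=e.alpha).beta == pytest.approx(
            2.04, abs=1e-12)

    @given(st.floats(1.01, 9.0))
    @settings(max_examples=100, derandomize=True)
    def test_triple_identities_hold_simultaneously(self, beta):
        e = convert_exponents(beta=beta)
        assert abs(e.beta - (1 + 1 / e.alpha)) < 1e-9
        assert abs(e.alpha - 1 / e.k) < 1e-9
        assert abs(e.beta - (1 + e.k)) < 1e-9

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            convert_exponents(beta=1.0)
        with pytest.raises(ValueError):
            convert_exponents(alpha=-1.0)
        with pytest.raises(ValueError):
            convert_exponents()
        with pytest.raises(ValueError):
            convert_exponents(alpha=1.0, beta=2.0)


# --------------------------------------------------------- rank points


class TestRankFrequency:
    def test_points_from_table(self):
        table = frequency_table(Corpus(["A", "A", "A", "B", "B", "C"], "BP"))
        points = rank_frequency(table)
        assert points.tolist() == [[1, 3], [2, 2], [3, 1]]
        assert np.all(np.diff(points[:, 1]) <= 0)

    def test_round_trip_with_generated_corpus(self):
        rng = np.random.default_rng(8)
        tokens = [f"GO:{i:07d}" for i in rng.integers(0, 30, size=500)]
        table = frequency_table(Corpus(tokens, "MF"))
        points = rank_frequency(table)
        assert points[:, 1].sum() == 500
        assert points[:, 0].tolist() == list(range(1, len(table) + 1))

    def test_empty_table_is_an_error(self):
        import pandas as pd

        with pytest.raises(ValueError):
            rank_frequency(pd.DataFrame(columns=["term", "frequency", "rank"]))
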