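import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from tibetscan.data_model import SiteFrequencyTable, site_frequency_table
from tibetscan.introgression import (
    _intersect_curves,
    abba_baba_terms,
    block_bootstrap_ci,
    d_statistic,
    dstar_scores,
    overlap_permutation_test,
    sstar_haplotype_score,
    u_statistic,
    window_d_u,
)


def _freq_table(p1, p2, p3, p4=None, positions=None):
    """Frequency table from per-site frequency vectors (denominator 100)."""
    p1, p2, p3 = map(np.asarray, (p1, p2, p3))
    n = len(p1)
    positions = positions if positions is not None else np.arange(1, n + 1) * 1000
    out = np.zeros(n, dtype=np.int8) if p4 is None else np.asarray(p4, dtype=np.int8)
    return SiteFrequencyTable(
        chromosome="1",
        positions=np.asarray(positions),
        derived={"TIB": (p1 * 100).astype(int), "HAN": (p2 * 100).astype(int)},
        total={"TIB": np.full(n, 100), "HAN": np.full(n, 100)},
        archaic={"DEN": ((p3 * 2).astype(int), np.full(n, 2))},
        outgroup_allele=out,
    )


class TestDStatistic:
    def test_symmetric_frequencies_give_zero(self):
        sft = _freq_table([0.2, 0.5], [0.2, 0.5], [1, 1])
        tc, tt = abba_baba_terms(sft, "TIB", "HAN")
        assert d_statistic(tc, tt) == pytest.approx(0.0)

    def test_exclusive_case_sharing_is_plus_one(self):
        # case fixed derived, control ancestral, archaic derived, outgroup
        # ancestral: the narrative orientation makes this +1
        sft = _freq_table([1.0], [0.0], [1.0])
        tc, tt = abba_baba_terms(sft, "TIB", "HAN")
        assert d_statistic(tc, tt) == pytest.approx(1.0)

    def test_three_site_toy_by_hand(self):
        sft = _freq_table([0.5, 0.0, 0.5], [0.0, 0.5, 0.5], [1.0, 1.0, 1.0])
        tc, tt = abba_baba_terms(sft, "TIB", "HAN")
        # terms: (0.5, 0) / (0, 0.5) / (0.25, 0.25): numerator 0
        assert d_statistic(tc, tt) == pytest.approx(0.0)

    def test_outgroup_derived_sites_excluded(self):
        sft = _freq_table([1.0], [0.0], [1.0], p4=[1])
        tc, tt = abba_baba_terms(sft, "TIB", "HAN")
        assert tc[0] == 0 and tt[0] == 0
        with pytest.raises(ValueError):
            d_statistic(tc, tt)

    def test_sign_flips_under_case_control_swap(self):
        rng = np.random.default_rng(0)
        sft = _freq_table(rng.uniform(size=50), rng.uniform(size=50),
                          rng.integers(0, 2, 50).astype(float))
        a_c, a_t = abba_baba_terms(sft, "TIB", "HAN")
        b_c, b_t = abba_baba_terms(sft, "HAN", "TIB")
        assert d_statistic(a_c, a_t) == pytest.approx(-d_statistic(b_c, b_t))

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_bounded_in_minus_one_one(self, data):
        n = data.draw(st.integers(2, 30))
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        sft = _freq_table(rng.uniform(size=n), rng.uniform(size=n),
                          rng.integers(0, 3, n) / 2.0)
        tc, tt = abba_baba_terms(sft, "TIB", "HAN")
        if (tc + tt).sum() > 0:
            assert -1.0 <= d_statistic(tc, tt) <= 1.0


class TestUStatistic:
    def test_no_informative_sites_gives_zero(self):
        sft = _freq_table([0.5], [0.5], [0.0])
        tc, tt = abba_baba_terms(sft, "TIB", "HAN")
        assert u_statistic(tc, tt) == 0.0

    def test_single_site_terms(self):
        sft = _freq_table([1.0], [0.0], [1.0])
        tc, tt = abba_baba_terms(sft, "TIB", "HAN")
        assert u_statistic(tc, tt) == pytest.approx(1.0)

    def test_u_equals_d_denominator_per_window(self):
        rng = np.random.default_rng(1)
        n = 200
        sft = _freq_table(rng.uniform(size=n), rng.uniform(size=n),
                          rng.integers(0, 3, n) / 2.0,
                          positions=rng.choice(np.arange(1, 10**6), n, replace=False))
        wdu = window_d_u(sft, "TIB", "HAN", width=200_000)
        tc, tt = abba_baba_terms(sft, "TIB", "HAN")
        from tibetscan.data_model import assign_windows
        win = assign_windows(sft.positions, 200_000)
        for _, row in wdu.iterrows():
            w = (row["start"] - 1) // 200_000
            assert row["U"] == pytest.approx((tc + tt)[win == w].sum())


class TestBlockBootstrap:
    def test_identical_blocks_zero_width(self):
        # same terms in every block -> every resample gives the same D
        pos = np.concatenate([np.arange(5) * 1000 + b * 10**6 + 1 for b in range(4)])
        tc = np.tile([0.5, 0.2, 0.1, 0.3, 0.4], 4)
        tt = np.tile([0.1, 0.1, 0.1, 0.1, 0.1], 4)
        ci = block_bootstrap_ci(pos, tc, tt, replicates=50, seed=0)
        assert ci.upper - ci.lower < 1e-12

    def test_single_block_rejected(self):
        with pytest.raises(ValueError):
            block_bootstrap_ci(np.array([1, 2]), np.array([1.0, 0]), np.array([0, 1.0]))

    def test_ci_contains_point(self, archaic_sim):
        _, sft, _, _ = archaic_sim
        tc, tt = abba_baba_terms(sft, "TIB", "HAN")
        ci = block_bootstrap_ci(sft.positions, tc, tt, replicates=200, seed=1,
                                block_size=200_000)
        assert ci.lower <= ci.point <= ci.upper

    def test_equal_admixture_ci_covers_zero(self, archaic_sim):
        # both populations got the same pulses: D should be consistent with 0
        _, sft, _, _ = archaic_sim
        tc, tt = abba_baba_terms(sft, "TIB", "HAN")
        ci = block_bootstrap_ci(sft.positions, tc, tt, replicates=200, seed=2,
                                block_size=200_000)
        assert ci.lower <= 0.0 <= ci.upper


class TestDStar:
    def _windows(self, d, u):
        n = len(d)
        return pd.DataFrame(
            {"chrom": "1", "start": np.arange(n) * 200_000 + 1,
             "end": (np.arange(n) + 1) * 200_000, "D": d, "U": u,
             "n_sites": 10}
        )

    def test_constant_d_raises_zero_sd(self):
        w = self._windows(np.full(40, 0.3), np.arange(40.0))
        with pytest.raises(ValueError):
            dstar_scores(w, n_groups=4)

    def test_normalization_arithmetic(self):
        # one group of 4 windows with D = [0.5, 0, 0.25, 0.25]: SD ~ 0.2041
        d = np.array([0.5, 0.0, 0.25, 0.25])
        w = self._windows(d, np.ones(4))
        out = dstar_scores(w, n_groups=1)
        sd = np.std(d, ddof=1)
        assert out["D_star"].iloc[0] == pytest.approx(0.5 / sd)

    def test_group_sizes_near_equal_with_remainder_low(self):
        rng = np.random.default_rng(0)
        w = self._windows(rng.normal(size=43), rng.uniform(size=43))
        out = dstar_scores(w, n_groups=4)
        sizes = out.groupby("u_group").size().sort_index()
        assert sizes.tolist() == [11, 11, 11, 10]
        # the bigger groups sit at the lowest U values
        assert out.sort_values("U").u_group.iloc[0] == 1

    def test_within_group_sd_of_dstar_is_unit(self):
        rng = np.random.default_rng(5)
        w = self._windows(rng.normal(0, 0.4, 100), rng.uniform(size=100))
        out = dstar_scores(w, n_groups=5)
        for _, g in out.groupby("u_group"):
            assert g["D_star"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_null_ensemble_gives_p_and_q(self):
        rng = np.random.default_rng(2)
        w = self._windows(rng.normal(0, 0.4, 60), rng.uniform(size=60))
        out = dstar_scores(w, n_groups=3, null_dstar=rng.normal(size=500))
        assert out["p"].between(0, 1).all()
        assert (out["q"] >= out["p"] - 1e-12).all()


def _sstar_bruteforce(positions, bonus=5000, mismatch=-10_000, min_spacing=10):
    best = float("-inf")
    m = len(positions)
    for k in range(2, m + 1):
        for subset in itertools.combinations(range(m), k):
            total = 0
            for i, j in zip(subset, subset[1:]):
                d = positions[j] - positions[i]
                total += bonus + d if d >= min_spacing else mismatch
            best = max(best, total)
    return best


class TestSStar:
    def test_two_congruent_sites(self):
        score, chain = sstar_haplotype_score(np.array([1000, 3000]))
        assert score == 7000  # 5000 + 2000
        assert chain == [0, 1]

    def test_three_equally_spaced_sites(self):
        score, chain = sstar_haplotype_score(np.array([1000, 3000, 5000]))
        assert score == 14_000
        assert chain == [0, 1, 2]

    def test_close_pair_penalized(self):
        score, _ = sstar_haplotype_score(np.array([1000, 1005]))
        assert score == -10_000

    def test_dp_equals_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            m = rng.integers(2, 12)
            pos = np.sort(rng.choice(np.arange(1, 50_000), size=m, replace=False))
            got, _ = sstar_haplotype_score(pos)
            assert got == _sstar_bruteforce(pos)

    def test_single_site_has_no_score(self):
        score, chain = sstar_haplotype_score(np.array([500]))
        assert score == float("-inf") and chain == []


class TestQAdmixture:
    def test_degenerate_constant_curves_intersect_exactly(self):
        coef = {"DEN": (0.1, 1.0, 0.0), "NEA": (0.2, 0.0, 1.0)}
        q_obs = {"DEN": 0.1 + 0.004, "NEA": 0.2 + 0.02}
        m_d, m_n = _intersect_curves(coef, q_obs)
        assert m_d == pytest.approx(0.004, abs=1e-6)
        assert m_n == pytest.approx(0.02, abs=1e-6)

    def test_coupled_curves_solve_linear_system(self):
        coef = {"DEN": (0.1, 1.0, 0.3), "NEA": (0.2, 0.4, 1.0)}
        md_true, mn_true = 0.01, 0.03
        q_obs = {
            "DEN": 0.1 + 1.0 * md_true + 0.3 * mn_true,
            "NEA": 0.2 + 0.4 * md_true + 1.0 * mn_true,
        }
        m_d, m_n = _intersect_curves(coef, q_obs)
        assert m_d == pytest.approx(md_true, abs=1e-6)
        assert m_n == pytest.approx(mn_true, abs=1e-6)

    def test_non_intersecting_curves_diagnosed(self):
        coef = {"DEN": (0.1, 1.0, 0.0), "NEA": (0.2, 0.0, 1.0)}
        q_obs = {"DEN": 0.1 + 0.004, "NEA": 0.2 + 3.0}  # m_N would be 3
        with pytest.raises(ValueError):
            _intersect_curves(coef, q_obs)


class TestOverlapPermutation:
    def test_no_introgressed_windows(self):
        obs, p = overlap_permutation_test(np.zeros(50, bool), np.random.default_rng(0).normal(size=50))
        assert obs == 0 and p == 1.0

    def test_matches_hypergeometric_tail_on_toy(self):
        # 5 introgressed among 100 windows; scores put 3 of them in the top 10
        rng = np.random.default_rng(3)
        scores = rng.normal(size=100)
        intro = np.zeros(100, bool)
        top10 = np.argsort(scores)[::-1][:10]
        intro[top10[:3]] = True
        intro[np.argsort(scores)[:2]] = True  # 2 more outside the top
        obs, p = overlap_permutation_test(intro, scores, top_fraction=0.1,
                                          replicates=20_000, seed=4)
        assert obs == 3
        expected = stats.hypergeom.sf(2, 100, 10, 5)  # P(X >= 3)
        assert p == pytest.approx(expected, abs=0.01)

    def test_mismatched_partitions_rejected(self):
        with pytest.raises(ValueError):
            overlap_permutation_test(np.zeros(5, bool), np.zeros(6))
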