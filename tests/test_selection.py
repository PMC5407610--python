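import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tibetscan.data_model import HaplotypePanel
from tibetscan.selection import (
    delta_daf,
    ehh_profile,
    fst_terms,
    genomewide_fst,
    haplotype_scores,
    normalize_scores,
    pbs,
    site_fst,
    xpehh_raw,
)


def _panel(alleles, positions=None, pop="P"):
    alleles = np.asarray(alleles, dtype=np.int8)
    n = alleles.shape[0]
    if positions is None:
        positions = np.arange(1, alleles.shape[1] + 1) * 1000
    inds = np.array([f"i{k}" for k in range(n)])
    return HaplotypePanel(
        "1", np.asarray(positions), alleles, inds, {f"i{k}": pop for k in range(n)}
    )


def _hudson_oracle(c1, n1, c2, n2):
    """Symbol-by-symbol transcription of the Hudson estimator."""
    p1, p2 = c1 / n1, c2 / n2
    num = (p1 - p2) ** 2 - (p1 * (1 - p1)) / (n1 - 1) - (p2 * (1 - p2)) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


class TestFst:
    def test_no_differentiation_is_zero_at_large_n(self):
        assert site_fst(5000, 10000, 5000, 10000) == pytest.approx(0.0, abs=1e-3)

    def test_hand_evaluated_hudson(self):
        assert site_fst(8, 10, 2, 10) == pytest.approx(0.4771, abs=1e-4)

    def test_published_site_example(self):
        # derived counts 38/54 vs 0/124 -> ~0.70
        assert site_fst(38, 54, 0, 124) == pytest.approx(0.70, abs=0.01)

    def test_both_monomorphic_same_allele_flagged(self):
        assert np.isnan(site_fst(0, 10, 0, 10))
        assert np.isnan(site_fst(10, 10, 12, 12))

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            site_fst(1, 1, 3, 10)

    @given(
        c1=st.integers(0, 54), c2=st.integers(0, 124),
    )
    @settings(max_examples=200, deadline=None)
    def test_hudson_matches_bruteforce_oracle(self, c1, c2):
        num, den = fst_terms(c1, 54, c2, 124, "hudson")
        onum, oden = _hudson_oracle(c1, 54.0, c2, 124.0)
        assert num == pytest.approx(onum, abs=1e-12)
        assert den == pytest.approx(oden, abs=1e-12)

    def test_population_swap_invariance(self):
        rng = np.random.default_rng(3)
        c1 = rng.integers(0, 55, 100)
        c2 = rng.integers(0, 125, 100)
        for est in ("hudson", "wc"):
            f12 = genomewide_fst(c1, 54, c2, 124, est)
            f21 = genomewide_fst(c2, 124, c1, 54, est)
            assert f12 == pytest.approx(f21, abs=1e-12)

    def test_genomewide_is_ratio_of_sums(self):
        # two hand-computed sites: ratio-of-sums differs from mean-of-ratios
        n1, d1 = _hudson_oracle(8, 10.0, 2, 10.0)
        n2, d2 = _hudson_oracle(5, 10.0, 5, 10.0)
        expected = (n1 + n2) / (d1 + d2)
        got = genomewide_fst(np.array([8, 5]), 10, np.array([2, 5]), 10)
        assert got == pytest.approx(expected, abs=1e-12)
        mean_of_ratios = np.mean([n1 / d1, n2 / d2])
        assert abs(got - mean_of_ratios) > 1e-3

    def test_identical_frequencies_zero(self):
        got = genomewide_fst(np.array([500, 100]), 1000, np.array([500, 100]), 1000)
        assert got == pytest.approx(0.0, abs=2e-3)


class TestDeltaDaf:
    def test_printed_frequency_difference(self):
        assert delta_daf(0.852, 0.427) == pytest.approx(0.425)

    def test_equal_frequencies_zero(self):
        assert delta_daf(0.3, 0.3) == 0.0

    def test_fixed_contrast(self):
        assert delta_daf(0.70, 0.0) == pytest.approx(0.70)

    def test_sign_flips_under_swap(self):
        f1, f2 = np.array([0.9, 0.1]), np.array([0.2, 0.4])
        assert np.allclose(delta_daf(f1, f2), -delta_daf(f2, f1))


class TestEhh:
    def test_identical_carriers_keep_ehh_one(self):
        panel = _panel([[1, 1, 1], [1, 1, 1], [0, 0, 1]])
        left, right = ehh_profile(panel, 0, 1)
        assert np.allclose(right, 1.0)

    def test_two_identical_pairs_give_third(self):
        # 4 carriers split into two identical pairs -> EHH = 2/C(4,2) = 1/3
        panel = _panel([[1, 0], [1, 0], [1, 1], [1, 1]])
        _, right = ehh_profile(panel, 0, 1)
        assert right[0] == pytest.approx(1 / 3)

    def test_all_distinct_carriers_give_zero(self):
        panel = _panel([[1, 0, 0], [1, 1, 0], [1, 0, 1], [1, 1, 1]])
        _, right = ehh_profile(panel, 0, 1)
        assert right[-1] == 0.0

    def test_fewer_than_two_carriers_invalid(self):
        panel = _panel([[1, 0], [0, 0], [0, 1]])
        with pytest.raises(ValueError):
            ehh_profile(panel, 0, 1)

    def test_non_increasing_outward(self, neutral_panel):
        rows = neutral_panel.population_haplotypes("TIB")
        sub = neutral_panel.subset(haplotypes=rows)
        core = sub.n_sites // 2
        for allele in (0, 1):
            carriers = (sub.alleles[:, core] == allele).sum()
            if carriers < 2:
                continue
            left, right = ehh_profile(sub, core, allele)
            assert np.all(np.diff(left) <= 1e-12)
            assert np.all(np.diff(right) <= 1e-12)


class TestHaplotypeScores:
    def test_step_function_ihh(self):
        # EHH = 1 over 0.1 cM on both sides of the core, then a site that
        # splits both allele classes completely: iHH per allele is the
        # trapezoid 0.1 + 0.0005 per side = 0.1005, so ~0.201 in total.
        split = np.array([0, 1, 0, 1], dtype=np.int8)
        inner = np.zeros(4, dtype=np.int8)
        core = np.array([1, 1, 0, 0], dtype=np.int8)
        alleles = np.column_stack([split, inner, core, inner, split])
        positions = np.array([99_000, 100_000, 200_000, 300_000, 301_000])
        panel = _panel(alleles, positions)
        hs = haplotype_scores(panel, 2, daf_range=(0.0, 1.0), min_carriers=2)
        assert hs.valid
        expected = 2 * (0.1 + 0.5 * 0.001)
        assert hs.ihh_derived == pytest.approx(expected, abs=1e-9)
        assert hs.ihh_ancestral == pytest.approx(expected, abs=1e-9)
        assert hs.ihs_raw == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_profiles_give_zero_scores(self):
        alleles = np.array(
            [[0, 1, 0], [0, 1, 1], [1, 0, 0], [1, 0, 1]], dtype=np.int8
        )
        panel = _panel(alleles)
        hs = haplotype_scores(panel, 1, daf_range=(0.0, 1.0), min_carriers=2)
        assert hs.valid
        assert hs.ihs_raw == pytest.approx(0.0, abs=1e-12)
        assert hs.delta_ihh_raw == pytest.approx(0.0, abs=1e-12)

    def test_daf_guard_flags_rare_cores(self):
        alleles = np.zeros((40, 3), dtype=np.int8)
        alleles[0, 1] = 1
        panel = _panel(alleles)
        hs = haplotype_scores(panel, 1)
        assert not hs.valid

    def test_ihh_invariant_under_permutation(self, neutral_panel):
        rows = neutral_panel.population_haplotypes("TIB")
        sub = neutral_panel.subset(haplotypes=rows)
        core = sub.n_sites // 2
        hs0 = haplotype_scores(sub, core, daf_range=(0.0, 1.0))
        perm = np.random.default_rng(1).permutation(sub.n_haplotypes)
        hs1 = haplotype_scores(sub.subset(haplotypes=perm), core, daf_range=(0.0, 1.0))
        if hs0.valid:
            assert hs0.ihh_ancestral == pytest.approx(hs1.ihh_ancestral)
            assert hs0.ihh_derived == pytest.approx(hs1.ihh_derived)


class TestXpehh:
    def test_identical_panels_zero(self):
        alleles = np.array([[0, 1, 0], [1, 1, 0], [0, 1, 1], [1, 0, 1]], dtype=np.int8)
        a = _panel(alleles)
        b = _panel(alleles)
        assert xpehh_raw(a, b, 1) == pytest.approx(0.0, abs=1e-12)

    def test_homozygous_population_positive_with_hand_integral(self):
        # population A identical over the region, B fully diverse
        positions = np.array([100_000, 200_000, 300_000])
        a = _panel(np.tile([0, 1, 0], (6, 1)), positions)
        b_all = np.array(
            [[0, 1, 0], [1, 1, 0], [0, 1, 1], [1, 1, 1], [0, 0, 1], [1, 0, 1]],
            dtype=np.int8,
        )
        b = _panel(b_all, positions)
        got = xpehh_raw(a, b, 1)
        assert got > 0
        # hand integral: A EHH = 1 both sides -> iHH_A = 0.2 cM. B left:
        # site 0 splits {3,3} -> EHH 6/15; trapezoid [1, 0.4] over 0.1 cM =
        # 0.07. B right: site 2 splits {2,4} -> EHH 7/15; trapezoid 0.07333.
        ihh_b = (1 + 6 / 15) / 2 * 0.1 + (1 + 7 / 15) / 2 * 0.1
        assert got == pytest.approx(np.log(0.2 / ihh_b), abs=1e-9)

    def test_sign_flips_under_swap(self, neutral_panel):
        rows_t = neutral_panel.population_haplotypes("TIB")
        rows_h = neutral_panel.population_haplotypes("HAN")
        a = neutral_panel.subset(haplotypes=rows_t)
        b = neutral_panel.subset(haplotypes=rows_h)
        core = a.n_sites // 2
        ab = xpehh_raw(a, b, core)
        ba = xpehh_raw(b, a, core)
        assert ab == pytest.approx(-ba, abs=1e-9)


class TestNormalizeAndPbs:
    def test_constant_scores_error(self):
        with pytest.raises(ValueError):
            normalize_scores(np.array([1.0, 1.0, 1.0]))

    def test_closed_form_two_values(self):
        out = normalize_scores(np.array([-1.0, 1.0]))
        assert np.allclose(out, [-1.0, 1.0])

    def test_external_moments_used_when_given(self):
        out = normalize_scores(np.array([2.0, 4.0]), mean=2.0, sd=2.0)
        assert np.allclose(out, [0.0, 1.0])

    def test_pbs_zero_and_hand_value(self):
        assert pbs(0.0, 0.0, 0.0) == 0.0
        assert pbs(0.1, 0.1, 0.1) == pytest.approx(0.05268, abs=1e-4)

    def test_pbs_negative_inputs_clamped(self):
        assert pbs(-0.05, 0.0, 0.0) == 0.0

    def test_pbs_fixed_branch_invalid(self):
        assert np.isnan(pbs(1.0, 0.1, 0.1))

    def test_pbs_epas1_indel_scale(self):
        # 62.9% vs 0.8% vs 0%: the target branch dominates
        f_th = site_fst(round(0.629 * 54), 54, 1, 124)
        f_te = site_fst(round(0.629 * 54), 54, 0, 200)
        f_he = site_fst(1, 124, 0, 200)
        val = pbs(f_th, f_te, f_he)
        assert 0.3 < val < 1.2  # calibration-scale check, not a unit value
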