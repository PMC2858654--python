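import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from raoeb.sumstats import (MISSING_CODE, HaplotypeDataset, LocusData,
                            dataset_summary, empirical_pvalues, ewens_log_pmf,
                            fst, harmonic_number, locus_stats, null_test,
                            spectra, watterson_expected_s)
from raoeb.synthetic_data import make_fixture


TOY = np.array([[0, 0, 0], [0, 0, 1], [0, 1, 1], [1, 1, 1]], dtype=np.int8)


class TestLocusStats:
    def test_toy_alignment_values(self):
        st_ = locus_stats(TOY, ancestral=np.zeros(3, dtype=np.int8), length=16)
        assert st_.S == 3 and st_.K == 4
        assert st_.pi_locus == pytest.approx(5 / 3)
        assert st_.D == pytest.approx(0.1677, abs=5e-4)
        assert st_.Fs == pytest.approx(-2.181, abs=5e-3)
        assert st_.H == pytest.approx(-2 / 3)

    def test_fs_closed_form(self):
        # P(K=4 | theta, n=4) = theta^3 / ((theta+1)(theta+2)(theta+3))
        theta = 5 / 3
        p = theta ** 3 / ((theta + 1) * (theta + 2) * (theta + 3))
        assert p == pytest.approx(0.1015, abs=2e-4)
        st_ = locus_stats(TOY, length=16)
        assert st_.Fs == pytest.approx(np.log(p / (1 - p)), rel=1e-9)

    def test_monomorphic_flags_undefined(self):
        H = np.zeros((6, 0), dtype=np.int8)
        st_ = locus_stats(H, length=100)
        assert st_.K == 1 and st_.S == 0 and st_.pi == 0
        assert np.isnan(st_.D) and np.isnan(st_.Fs) and np.isnan(st_.H)

    def test_missing_ancestral_flags_h_only(self):
        st_ = locus_stats(TOY, ancestral=None, length=16)
        assert np.isnan(st_.H)
        assert not np.isnan(st_.D)

    def test_missing_data_merges_compatible_haplotypes(self):
        H = np.array([[0, 0], [0, 0], [1, 1], [1, MISSING_CODE]], dtype=np.int8)
        st_ = locus_stats(H, length=10)
        # the N-carrying row is compatible with (1,1): K = 2
        assert st_.K == 2
        # the missing entry drops from the column's pairwise comparisons
        assert st_.S == 2

    def test_subset_selection(self, toy4):
        full = locus_stats(toy4.loci[0])
        sub = locus_stats(toy4.loci[0], subset=np.array([0, 1, 2, 3]))
        assert full.as_dict() == sub.as_dict()


class TestEwens:
    @staticmethod
    def crp_k_distribution(n, theta):
        """Distribution of the number of types under the sequential
        (Chinese-restaurant) construction — an oracle independent of the
        Stirling-number formula."""
        probs = {1: 1.0}
        for i in range(1, n):
            new = {}
            p_new = theta / (theta + i)
            for k, p in probs.items():
                new[k + 1] = new.get(k + 1, 0.0) + p * p_new
                new[k] = new.get(k, 0.0) + p * (1 - p_new)
            probs = new
        return probs

    @pytest.mark.parametrize("n,theta", [(2, 0.5), (4, 5 / 3), (5, 1.0), (6, 3.7)])
    def test_matches_sequential_oracle(self, n, theta):
        oracle = self.crp_k_distribution(n, theta)
        pmf = np.exp(ewens_log_pmf(n, theta))
        for k in range(1, n + 1):
            assert pmf[k] == pytest.approx(oracle.get(k, 0.0), abs=1e-12)

    @pytest.mark.parametrize("n", [10, 100, 430])
    def test_sums_to_one_in_log_space(self, n):
        for theta in (0.1, 2.5, 40.0):
            total = np.exp(ewens_log_pmf(n, theta)).sum()
            assert total == pytest.approx(1.0, abs=1e-10)


class TestIndependentOracle:
    """Straight-from-the-literature re-implementations, coded separately."""

    @staticmethod
    def tajima_d(H):
        n, S = H.shape[0], 0
        pi = 0.0
        for j in range(H.shape[1]):
            col = H[:, j]
            vals, cnt = np.unique(col, return_counts=True)
            if len(vals) > 1:
                S += 1
                pi += 1 - sum(c * (c - 1) for c in cnt) / (n * (n - 1))
        if S == 0:
            return np.nan
        a1 = sum(1 / i for i in range(1, n))
        a2 = sum(1 / i ** 2 for i in range(1, n))
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n ** 2 + n + 3) / (9 * n * (n - 1))
        c1, c2 = b1 - 1 / a1, b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
        e1, e2 = c1 / a1, c2 / (a1 ** 2 + a2)
        return (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))

    @staticmethod
    def fay_wu_h(H, anc):
        n = H.shape[0]
        pi = theta_h = 0.0
        for j in range(H.shape[1]):
            col = H[:, j]
            vals, cnt = np.unique(col, return_counts=True)
            if len(vals) > 1:
                pi += 1 - sum(c * (c - 1) for c in cnt) / (n * (n - 1))
            for v, c in zip(vals, cnt):
                if v != anc[j] and 1 <= c <= n - 1:
                    theta_h += 2 * c ** 2 / (n * (n - 1))
        return pi - theta_h

    def test_d_and_h_agree_on_random_alignments(self):
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(50):
            n = int(rng.integers(4, 12))
            s = int(rng.integers(1, 8))
            H = rng.integers(0, 2, size=(n, s)).astype(np.int8)
            anc = np.zeros(s, dtype=np.int8)
            ours = locus_stats(H, ancestral=anc, length=100)
            d_ref = self.tajima_d(H)
            if np.isnan(d_ref):
                assert np.isnan(ours.D)
                continue
            assert ours.D == pytest.approx(d_ref, rel=1e-10)
            assert ours.H == pytest.approx(self.fay_wu_h(H, anc), rel=1e-10)
            checked += 1
        assert checked >= 40


class TestFst:
    def test_identical_frequencies_near_zero(self):
        rng = np.random.default_rng(1)
        patt = rng.integers(0, 2, size=(2, 4)).astype(np.int8)
        H = np.vstack([patt[[0, 1]]] * 50 + [patt[[0, 1]]] * 50)
        ds = HaplotypeDataset(
            loci=[LocusData(100, np.arange(4), H, [("A", "T")] * 4)],
            samples=[f"s{i}" for i in range(100)],
            populations=np.array(["P1"] * 100 + ["P2"] * 100))
        g, _ = fst(ds)
        assert abs(g) < 0.02

    def test_fixed_haplotypes_give_one(self, two_pop):
        g, pair = fst(two_pop)
        assert g == pytest.approx(1.0)
        assert pair.loc["P1", "P2"] == pytest.approx(1.0)

    def test_three_population_golden_value(self):
        # pop1: A x6, B x2; pop2: A x2, B x6; pop3: A x4, B x4
        def pop_block(na, nb):
            return [[0]] * na + [[1]] * nb

        H = np.array(pop_block(6, 2) + pop_block(2, 6) + pop_block(4, 4),
                     dtype=np.int8)
        ds = HaplotypeDataset(
            loci=[LocusData(10, np.array([0]), H, [("A", "T")])],
            samples=[f"s{i}" for i in range(12)],
            populations=np.array(["P1"] * 8 + ["P2"] * 8 + ["P3"] * 8))
        # independent explicit variance-components computation
        sizes = np.array([8.0, 8.0, 8.0])
        N, r = 24.0, 3
        n_c = (N - (sizes ** 2).sum() / N) / (r - 1)
        expected_num = expected_den = 0.0
        for freqs in [np.array([6, 2, 4]) / 8, np.array([2, 6, 4]) / 8]:
            pbar = (sizes * freqs).sum() / N
            msp = (sizes * (freqs - pbar) ** 2).sum() / (r - 1)
            msg = (sizes * freqs * (1 - freqs)).sum() / (N - r)
            a = (msp - msg) / n_c
            expected_num += a
            expected_den += a + msg
        g, _ = fst(ds)
        assert g == pytest.approx(expected_num / expected_den, rel=1e-12)

    def test_invariant_under_relabeling(self, two_pop):
        g1, _ = fst(two_pop)
        perm = np.array([1, 0, 3, 2, 5, 4, 7, 6])
        loci = [LocusData(l.length, l.positions, l.alleles[perm],
                          l.site_alleles, l.ancestral) for l in two_pop.loci]
        shuffled = HaplotypeDataset(loci=loci, samples=two_pop.samples,
                                    populations=two_pop.populations[perm])
        g2, _ = fst(shuffled)
        assert g1 == pytest.approx(g2, rel=1e-12)

    def test_single_population_raises(self, toy4):
        with pytest.raises(ValueError, match="two populations"):
            fst(toy4)


class TestSpectra:
    def test_folded_expected_counts_small_n(self):
        # n=4, one locus with S=2 so theta_W = 2/a1; rescale to theta_W=1
        H = np.array([[0, 0], [0, 0], [0, 1], [1, 1]], dtype=np.int8)
        ds = HaplotypeDataset(
            loci=[LocusData(50, np.arange(2), H, [("A", "T")] * 2,
                            np.zeros(2, dtype=np.int8))],
            samples=["a", "b"], populations=np.array(["P"] * 4))
        maf, daf = spectra(ds, "P")
        a1 = harmonic_number(3)
        theta_w = 2 / a1
        # phi(1) = 1 + 1/3, phi(2) = (1/2 + 1/2)/2
        assert maf.expected[0] == pytest.approx(theta_w * 4 / 3)
        assert maf.expected[1] == pytest.approx(theta_w * 0.5)
        # folded expectation sums to E[S] = theta_W * a1 = S
        assert maf.expected.sum() == pytest.approx(2.0)
        assert maf.observed.sum() == 2
        assert daf is None  # no expected DAF supplied

    def test_two_class_chi2_example(self):
        # 100 variants: 50 observed singletons where 30 are expected
        # chi2 = 400/30 + 400/70
        obs = np.array([50.0, 50.0])
        exp = np.array([30.0, 70.0])
        chi2 = ((obs - exp) ** 2 / exp).sum()
        assert chi2 == pytest.approx(19.0476, abs=1e-3)
        assert sps.chi2.sf(chi2, 1) == pytest.approx(1.28e-5, rel=0.02)

    def test_identical_obs_exp_gives_p_one(self):
        # one site at derived count 2 and one fixed-derived site
        H = np.array([[0, 1], [0, 1], [1, 1], [1, 1]], dtype=np.int8)
        ds = HaplotypeDataset(
            loci=[LocusData(50, np.arange(2), H, [("A", "T")] * 2,
                            np.zeros(2, dtype=np.int8))],
            samples=["a", "b"], populations=np.array(["P"] * 4))
        maf, daf = spectra(ds, "P", expected_daf=np.array([0.0, 1.0, 0.0, 1.0]))
        assert daf.observed[1] == 1 and daf.observed[3] == 1
        assert daf.chi2 == pytest.approx(0.0, abs=1e-12)
        assert daf.p == pytest.approx(1.0)

    def test_zero_expected_class_is_an_error(self):
        H = np.array([[0, 0], [0, 0], [0, 1], [1, 1]], dtype=np.int8)
        ds = HaplotypeDataset(
            loci=[LocusData(50, np.arange(2), H, [("A", "T")] * 2,
                            np.zeros(2, dtype=np.int8))],
            samples=["a", "b"], populations=np.array(["P"] * 4))
        with pytest.raises(ValueError, match="zero expected"):
            spectra(ds, "P", expected_daf=np.array([1.0, 1.0, 0.0, 0.0]))


class TestDatasetSummary:
    def test_identical_loci_zero_sd(self, toy4):
        ds = HaplotypeDataset(loci=toy4.loci * 20, samples=toy4.samples,
                              populations=toy4.populations)
        sv = dataset_summary(ds, with_fst=False)
        assert sv["P_D_sd"] == pytest.approx(0.0, abs=1e-12)
        assert sv["P_D_mean"] == pytest.approx(0.1677, abs=5e-4)

    def test_single_locus_sd_undefined(self, toy4):
        sv = dataset_summary(toy4, with_fst=False)
        assert np.isnan(sv["P_K_sd"])
        assert sv["P_K_mean"] == 4.0

    def test_pooled_scope_merges_populations(self, two_pop):
        sv = dataset_summary(two_pop)
        assert sv["pooled_S_mean"] == 2.0
        assert sv["fst_global"] == pytest.approx(1.0)


class TestEmpiricalPvalues:
    def test_observed_at_median_gives_p_near_one(self):
        null = pd.DataFrame({"x": np.arange(999, dtype=float)})
        obs = pd.Series({"x": 499.0})
        p = empirical_pvalues(obs, null).loc["x", "p"]
        assert p > 0.99

    def test_observed_beyond_all_gives_add_one_floor(self):
        null = pd.DataFrame({"x": np.arange(999, dtype=float)})
        obs = pd.Series({"x": 1e9})
        p = empirical_pvalues(obs, null).loc["x", "p"]
        assert p == pytest.approx(2 / 1000)

    def test_null_test_refuses_coarse_resolution(self, toy4):
        sv = dataset_summary(toy4, with_fst=False)
        with pytest.raises(ValueError, match="n_sims"):
            null_test(sv, n_sims=50)


def test_watterson_expected_s_study_configuration():
    theta_locus = 4 * 1e4 * 2.5e-8 * 1330
    assert watterson_expected_s(213, theta_locus) == pytest.approx(7.9, abs=0.05)
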