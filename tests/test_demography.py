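import math

import msprime
import numpy as np
import pytest
from scipy import integrate, stats as sps

from raoeb.coalsim import SampleConfig, run_batch
from raoeb.demography import (ModelVariant, build_demography,
                              constant_size_model)
from raoeb.priors import derive_composites
from raoeb.synthetic_data import table3_draw
from tests.conftest import fixed_priors


class TestBuildVariantA:
    def test_point_estimate_event_times(self):
        model = build_demography(table3_draw(), "A")
        times = {type(ev).__name__: [] for ev in model.demography.events}
        for ev in model.demography.events:
            times[type(ev).__name__].append(ev.time)
        # Eurasian split at 22500 y / 25 = 900 generations,
        # exodus at 60000 y / 25 = 2400, archaic split at 1.9e6 / 25
        assert 900.0 in times["PopulationSplit"]
        assert 2400.0 in times["Admixture"]
        assert 76000.0 in times["PopulationSplit"]

    def test_full_replacement_reduces_to_clean_tree(self):
        model = build_demography(table3_draw().replace(delta=1.0), "A")
        names = [type(ev).__name__ for ev in model.demography.events]
        assert "Admixture" not in names

    def test_no_bottleneck_when_beta_is_one(self):
        d = derive_composites(table3_draw().replace(beta_OoA=1.0))
        assert d.N_OoA == d.N_prime
        model = build_demography(d, "A")
        changes = [ev for ev in model.demography.events
                   if type(ev).__name__ == "PopulationParametersChange"
                   and ev.population == "EUR"]
        assert changes[0].initial_size == pytest.approx(d.N_prime)

    def test_event_ordering_violation_raises(self):
        bad = table3_draw().replace(T_EEA=70000.0)  # later than the exodus
        with pytest.raises(ValueError, match="ordering"):
            build_demography(bad, "A")

    def test_sampled_demes_present_at_time_zero(self):
        d = table3_draw()
        model = build_demography(d, "A")
        sizes = {p.name: p.initial_size for p in model.demography.populations}
        assert sizes["AFR"] == pytest.approx(d.N_A)
        assert sizes["EUR"] == pytest.approx(d.N_E)
        assert sizes["EAS"] == pytest.approx(d.N_EA)

    def test_describe_roundtrips_event_times(self):
        model = build_demography(table3_draw(), "A")
        table = model.describe()
        assert set(table["time_gen"]) == {ev.time for ev in model.demography.events}


class TestVariantsBCD:
    def test_variant_cd_requires_second_exodus(self):
        with pytest.raises(ValueError, match="T_OoA_2"):
            build_demography(table3_draw(), "C")

    def test_second_exodus_must_be_more_recent(self):
        d = table3_draw().replace(T_OoA_2=90000.0)
        with pytest.raises(ValueError, match="ordering"):
            build_demography(d, "C")

    @pytest.mark.parametrize("tag", ["B", "C", "D"])
    def test_two_dispersal_variants_build_and_simulate(self, tag):
        d = table3_draw()
        if tag in ("C", "D"):
            d = d.replace(T_OoA_2=50000.0, T_OoA=70000.0)
        model = build_demography(d, tag)
        ts = msprime.sim_ancestry(samples={"AFR": 5, "EUR": 4, "EAS": 4},
                                  demography=model.demography,
                                  sequence_length=500, ploidy=2, random_seed=1)
        assert ts.num_samples == 26

    def test_variant_b_daughters_are_exchangeable(self, small_samples):
        """With symmetric priors the two independently-founded Eurasian
        populations must give exchangeable summary statistics."""
        draw = table3_draw().replace(t_E=8750.0, alpha_E=0.0025,
                                     t_EA=8750.0, alpha_EA=0.0025)
        draw = derive_composites(draw)
        pri = fixed_priors(draw)
        tab = run_batch(pri, "B", 150, samples=small_samples, rng_seed=21,
                        n_loci=5, scopes=("EUR", "EAS"), with_fst=False)
        ks = sps.ks_2samp(tab.df["EUR_S_mean"], tab.df["EAS_S_mean"])
        assert ks.pvalue > 0.01


class TestConstantSizeModel:
    def test_no_events_no_migration(self):
        model = constant_size_model(1e4)
        assert len(model.demography.events) == 0
        assert np.all(np.asarray(model.demography.migration_matrix) == 0)

    def test_nonpositive_size_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            constant_size_model({"P": 0.0})

    def test_pairwise_expected_s_two_haplotypes(self):
        # E[S] for n=2 is 4*Ne*mu*L (a_1 = 1)
        model = constant_size_model({"P": 1e4})
        mu, L = 2.5e-8, 1330
        reps = msprime.sim_ancestry(samples={"P": 1}, ploidy=2,
                                    demography=model.demography,
                                    sequence_length=L, random_seed=4,
                                    num_replicates=4000)
        rng = np.random.default_rng(8)
        tot = sum(msprime.sim_mutations(
            ts, rate=mu, random_seed=int(rng.integers(1, 2 ** 31))).num_sites
            for ts in reps)
        assert tot / 4000 == pytest.approx(4 * 1e4 * mu * L, rel=0.07)


class TestCoalescenceClosedForm:
    def test_african_pairwise_tmrca_matches_quadrature(self):
        """delta=1, no migration: E[TMRCA] of two African lineages equals
        the closed form for exponential growth into a constant epoch."""
        d = derive_composites(table3_draw().replace(delta=1.0, m=0.0,
                                                    m0=0.0 + 1e-300))
        model = build_demography(d, "A")
        g = d.generation_time
        t_a = d.t_A / g

        def n_of(t):
            return d.N_A * math.exp(-d.alpha_A * t) if t < t_a else d.N_prime

        def survival(t):
            # coalescence hazard for 2 lineages: 1 / (2N(t))
            cum, _ = integrate.quad(lambda u: 1.0 / (2.0 * n_of(u)), 0, t,
                                    points=[t_a], limit=200)
            return math.exp(-cum)

        expected, _ = integrate.quad(survival, 0, 2e6, limit=400)
        reps = msprime.sim_ancestry(samples={"AFR": 1}, ploidy=2,
                                    demography=model.demography,
                                    sequence_length=1, random_seed=17,
                                    num_replicates=3000)
        tmrcas = np.array([ts.first().time(ts.first().root) for ts in reps])
        se = tmrcas.std(ddof=1) / np.sqrt(len(tmrcas))
        assert abs(tmrcas.mean() - expected) < 4 * se


def test_model_variant_validation():
    with pytest.raises(ValueError, match="variant"):
        ModelVariant("E")
    with pytest.raises(ValueError, match="archaic"):
        ModelVariant("A", "triple")
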