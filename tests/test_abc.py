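import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from raoeb.abc import (accuracy_eval, evaluate_estimates, model_posterior,
                       regress_adjust, reject, stat_set_presets, summarize,
                       weighted_quantile, prior_sensitivity)
from raoeb.bestfit import DistanceConfig
from raoeb.coalsim import SimulationTable
from raoeb.priors import PriorSet, PriorSpec, default_table2_priors


def toy_table(n=2000, seed=0, slope=1.0, noise=0.3, param="T_OoA",
              bounds=(0.0, 10.0)):
    """theta ~ U(bounds); statistic s = slope*theta + noise."""
    rng = np.random.default_rng(seed)
    theta = rng.uniform(*bounds, n)
    s = slope * theta + rng.normal(0, noise, n)
    return SimulationTable(df=pd.DataFrame({param: theta, "s0": s}), meta={})


class TestReject:
    def test_whole_table_accepted(self):
        t = toy_table(100, seed=1)
        cfg = DistanceConfig(statistics=["s0"])
        acc = reject(t, pd.Series({"s0": 5.0}), 100, cfg)
        assert len(acc) == 100

    def test_smallest_distances_kept(self):
        df = pd.DataFrame({"p": np.arange(5.0), "s0": [5.0, 1.0, 3.0, 2.0, 4.0]})
        cfg = DistanceConfig(statistics=["s0"], scales=np.array([1.0]))
        acc = reject(SimulationTable(df=df), pd.Series({"s0": 0.0}), 3, cfg)
        assert sorted(acc.table["s0"]) == [1.0, 2.0, 3.0]
        assert acc.d_max == 3.0

    def test_scale_invariance_of_accepted_set(self):
        t = toy_table(500, seed=2)
        obs = pd.Series({"s0": 5.0})
        acc1 = reject(t, obs, 50, DistanceConfig(statistics=["s0"],
                                                 scales=np.array([1.0])))
        acc2 = reject(t, obs, 50, DistanceConfig(statistics=["s0"],
                                                 scales=np.array([2.0])))
        pd.testing.assert_frame_equal(acc1.table, acc2.table)

    def test_n_accept_too_large(self):
        t = toy_table(10)
        with pytest.raises(ValueError, match="n_accept"):
            reject(t, pd.Series({"s0": 0.0}), 11,
                   DistanceConfig(statistics=["s0"]))


class TestRegression:
    def test_linear_toy_recovers_truth(self):
        t = toy_table(4000, seed=3, noise=0.3)
        cfg = DistanceConfig(statistics=["s0"])
        acc = reject(t, pd.Series({"s0": 5.0}), 400, cfg)
        post = regress_adjust(acc, priors=None, params=["T_OoA"],
                              transform=False)
        x, w = post.samples["T_OoA"].to_numpy(), post.weights
        mean = np.average(x, weights=w)
        var = np.average((x - mean) ** 2, weights=w)
        assert mean == pytest.approx(5.0, abs=0.05)
        # residual spread ~ noise sd of the generating relation
        assert np.sqrt(var) == pytest.approx(0.3, rel=0.35)

    def test_no_signal_leaves_draws_unchanged_on_average(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"T_OoA": rng.uniform(0, 10, 2000),
                           "s0": rng.normal(0, 1, 2000)})
        cfg = DistanceConfig(statistics=["s0"])
        acc = reject(SimulationTable(df=df), pd.Series({"s0": 0.0}), 300, cfg)
        post = regress_adjust(acc, params=["T_OoA"], transform=False)
        diff = post.samples["T_OoA"] - post.raw["T_OoA"]
        assert abs(diff.mean()) < 0.2

    def test_exact_match_means_zero_adjustment(self):
        df = pd.DataFrame({"T_OoA": np.linspace(1, 2, 50),
                           "s0": np.full(50, 7.0)})
        cfg = DistanceConfig(statistics=["s0"], scales=np.array([1.0]))
        acc = reject(SimulationTable(df=df), pd.Series({"s0": 7.0}), 50, cfg)
        post = regress_adjust(acc, params=["T_OoA"], transform=False)
        np.testing.assert_allclose(post.samples["T_OoA"], post.raw["T_OoA"])

    def test_independent_table_returns_the_prior(self):
        """With statistics carrying no information the posterior must be
        indistinguishable from the prior."""
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"T_OoA": rng.uniform(45020, 87500, 3000),
                           "s0": rng.normal(0, 1, 3000),
                           "s1": rng.normal(0, 1, 3000)})
        cfg = DistanceConfig(statistics=["s0", "s1"])
        acc = reject(SimulationTable(df=df), pd.Series({"s0": 0.0, "s1": 0.0}),
                     600, cfg)
        post = regress_adjust(acc, priors=default_table2_priors(),
                              params=["T_OoA"])
        ks = sps.kstest(post.samples["T_OoA"], "uniform",
                        args=(45020, 87500 - 45020))
        assert ks.pvalue > 0.01

    def test_logit_transform_respects_prior_box(self):
        pri = default_table2_priors()
        rng = np.random.default_rng(6)
        theta = rng.uniform(0.99, 1.0, 2000)
        s = 50 * (theta - 0.995) + rng.normal(0, 0.5, 2000)
        df = pd.DataFrame({"delta": theta, "s0": s})
        cfg = DistanceConfig(statistics=["s0"])
        acc = reject(SimulationTable(df=df), pd.Series({"s0": 0.3}), 300, cfg)
        post = regress_adjust(acc, priors=pri, params=["delta"])
        assert post.samples["delta"].between(0.99, 1.0).all()

    def test_too_few_accepted_raises(self):
        t = toy_table(10)
        cfg = DistanceConfig(statistics=["s0"])
        acc = reject(t, pd.Series({"s0": 0.0}), 2, cfg)
        with pytest.raises(ValueError, match="more accepted"):
            regress_adjust(acc, params=["T_OoA"])


class TestSummarize:
    def make_posterior(self, x, w=None):
        from raoeb.abc import Posterior

        x = np.asarray(x, dtype=float)
        w = np.ones(len(x)) if w is None else np.asarray(w, dtype=float)
        return Posterior(samples=pd.DataFrame({"p": x}), weights=w,
                         raw=pd.DataFrame({"p": x}), d_max=1.0)

    def test_symmetric_sample_mean_equals_median(self):
        rng = np.random.default_rng(7)
        post = self.make_posterior(rng.normal(3.0, 1.0, 5000))
        m, _ = summarize(post, "p", "mean")
        med, _ = summarize(post, "p", "median")
        assert m == pytest.approx(med, abs=0.05)

    def test_point_mass_degenerate(self):
        post = self.make_posterior(np.full(100, 4.2))
        for est in ("mean", "median", "mode"):
            point, (lo, hi) = summarize(post, "p", est)
            assert point == pytest.approx(4.2)
            assert lo == pytest.approx(4.2) and hi == pytest.approx(4.2)

    def test_mixture_mode_vs_mean(self):
        rng = np.random.default_rng(8)
        x = np.concatenate([rng.normal(0, 1, 9000), rng.normal(10, 1, 1000)])
        post = self.make_posterior(x)
        mean, _ = summarize(post, "p", "mean")
        mode, _ = summarize(post, "p", "mode")
        assert mean == pytest.approx(1.0, abs=0.15)
        assert abs(mode) < 0.5

    def test_weighted_quantile_monotone(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=500)
        w = rng.random(500)
        q = weighted_quantile(x, w, [0.1, 0.5, 0.9])
        assert q[0] < q[1] < q[2]

    def test_unknown_estimator(self):
        post = self.make_posterior([1.0, 2.0])
        with pytest.raises(ValueError, match="estimator"):
            summarize(post, "p", "midrange")


class TestModelPosterior:
    def test_label_frequencies_among_accepted(self):
        df = pd.DataFrame({"s0": [0.1, 0.2, 5.0, 0.15, 0.25, 6.0],
                           "model": ["A", "A", "A", "B", "B", "B"]})
        cfg = DistanceConfig(statistics=["s0"], scales=np.array([1.0]))
        probs = model_posterior(df, pd.Series({"s0": 0.0}), cfg, n_accept=4)
        assert probs["A"] == pytest.approx(0.5)
        assert probs["B"] == pytest.approx(0.5)
        assert probs.sum() == pytest.approx(1.0)

    def test_single_model_rejected(self):
        df = pd.DataFrame({"s0": [0.1, 0.2], "model": ["A", "A"]})
        cfg = DistanceConfig(statistics=["s0"], scales=np.array([1.0]))
        with pytest.raises(ValueError, match="two models"):
            model_posterior(df, pd.Series({"s0": 0.0}), cfg, n_accept=2)

    def test_unanimous_acceptance(self):
        df = pd.DataFrame({"s0": [0.1, 0.2, 9.0, 9.5],
                           "model": ["A", "A", "B", "B"]})
        cfg = DistanceConfig(statistics=["s0"], scales=np.array([1.0]))
        probs = model_posterior(df, pd.Series({"s0": 0.0}), cfg, n_accept=2)
        assert probs["A"] == 1.0 and probs["B"] == 0.0


class TestAccuracy:
    def test_oracle_estimates_are_perfect(self):
        records = [{"parameter": "x", "stat_set": "s", "estimator": "mean",
                    "truth": t, "estimate": t, "ci_lo": t - 1, "ci_hi": t + 1}
                   for t in np.linspace(1, 5, 20)]
        out = evaluate_estimates(records)
        row = out.iloc[0]
        assert row["B"] == 0 and row["SE"] == 0 and row["RMSE"] == 0
        assert row["CI_hits"] == 1.0

    def test_constant_multiplicative_bias(self):
        records = [{"parameter": "x", "stat_set": "s", "estimator": "mean",
                    "truth": t, "estimate": 1.1 * t, "ci_lo": 0.0,
                    "ci_hi": 2 * t} for t in np.linspace(1, 5, 20)]
        row = evaluate_estimates(records).iloc[0]
        assert row["B"] == pytest.approx(0.10)
        assert row["RMSE"] == pytest.approx(0.10)

    def test_rmse_decomposition_identity(self):
        rng = np.random.default_rng(10)
        records = [{"parameter": "x", "stat_set": "s", "estimator": "mean",
                    "truth": t, "estimate": t * (1 + rng.normal(0.05, 0.2)),
                    "ci_lo": 0.0, "ci_hi": 10.0}
                   for t in rng.uniform(1, 5, 200)]
        row = evaluate_estimates(records).iloc[0]
        n = row["n"]
        assert row["RMSE"] ** 2 == pytest.approx(
            row["B"] ** 2 + row["SE"] ** 2 * (n - 1) / n, abs=1e-12)

    def test_accuracy_eval_excludes_constant_parameter(self):
        t = toy_table(800, seed=11)
        t.df["frozen"] = 3.0
        pseudo = [({"T_OoA": 5.0, "frozen": 3.0}, pd.Series({"s0": 5.0}))]
        with pytest.warns(UserWarning, match="constant"):
            rep = accuracy_eval(t, pseudo, {"only": ["s0"]},
                                estimators=("mean",),
                                params=["T_OoA", "frozen"], n_accept=100)
        assert set(rep.table["parameter"]) == {"T_OoA"}


class TestPriorSensitivity:
    def test_identity_modification_fully_overlaps(self):
        t = toy_table(3000, seed=12)
        cfg = DistanceConfig(statistics=["s0"])
        obs = pd.Series({"s0": 5.0})
        acc = reject(t, obs, 300, cfg)
        base = regress_adjust(acc, params=["T_OoA"], transform=False)
        report = prior_sensitivity(obs, base, {"T_OoA": (None, t)}, cfg,
                                   n_accept=300)
        row = report.iloc[0]
        assert row["ci_overlap"] > 0.95
        assert not row["flagged"]


def test_stat_set_presets_structure():
    presets = stat_set_presets()
    assert set(presets) == {"pop_means", "pop_means_sds",
                            "pop_means_sds_fst", "pooled_fst"}
    assert "AFR_D_mean" in presets["pop_means"]
    assert "fst_global" in presets["pop_means_sds_fst"]
    assert len(presets["pop_means_sds"]) == 42
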