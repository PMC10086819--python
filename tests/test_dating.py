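"""Node-dating MCMC: HPD/ESS utilities, prior sampling, recovery, pruning."""

import numpy as np
import pytest
from scipy import stats as st

from stratadate.dating import (
    CalibrationPrior,
    DatingConfig,
    default_calibrations,
    ess,
    hpd_interval,
    reduce_outgroups,
    run_dating_mcmc,
    summarize_trace,
)
from stratadate.seqmodels import SubstitutionModel
from stratadate.simulate import gametolog_time_tree, gametolog_tree, \
    simulate_alignment
from stratadate.trees import SpeciesTree, TreeError, write_newick


def brute_force_hpd(samples, mass=0.95):
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    m = int(np.ceil(mass * n))
    best = (np.inf, None)
    for i in range(n - m + 1):
        w = x[i + m - 1] - x[i]
        if w < best[0]:
            best = (w, (x[i], x[i + m - 1]))
    return best[1]


class TestHpd:
    def test_constant_samples_zero_width(self):
        assert hpd_interval([3.0] * 10) == (3.0, 3.0)

    def test_integer_grid_matches_brute_force(self):
        samples = np.arange(1, 101, dtype=float)
        lo, hi = hpd_interval(samples, 0.95)
        assert hi - lo == 94.0
        assert (lo, hi) == brute_force_hpd(samples, 0.95)

    def test_random_samples_match_brute_force(self, rng):
        for _ in range(10):
            x = rng.normal(size=57)
            assert hpd_interval(x, 0.9) == brute_force_hpd(x, 0.9)

    def test_uniform_limit_width(self, rng):
        x = rng.uniform(0, 1, size=10_000)
        lo, hi = hpd_interval(x, 0.95)
        assert hi - lo == pytest.approx(0.95, abs=0.02)

    def test_never_wider_than_equal_tailed(self, rng):
        for _ in range(10):
            x = rng.gamma(2.0, size=400)
            lo, hi = hpd_interval(x, 0.95)
            qlo, qhi = np.quantile(x, [0.025, 0.975])
            assert hi - lo <= qhi - qlo + 1e-12

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            hpd_interval([])


class TestEss:
    def test_iid_close_to_n(self, rng):
        x = rng.normal(size=10_000)
        assert abs(ess(x) - 10_000) / 10_000 < 0.1

    def test_ar1_closed_form(self, rng):
        phi = 0.6
        n = 20_000
        e = rng.normal(size=n)
        x = np.empty(n)
        x[0] = e[0]
        for i in range(1, n):
            x[i] = phi * x[i - 1] + e[i]
        expected = n * (1 - phi) / (1 + phi)
        assert abs(ess(x) - expected) / expected < 0.2

    def test_constant_series_warns(self):
        with pytest.warns(UserWarning, match="constant"):
            assert ess([2.0] * 10) == 10.0

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            ess([1.0] * 5)


class TestCalibrations:
    def test_distributions_logpdf(self):
        c = CalibrationPrior(frozenset("AB"), "normal", (10.0, 2.0))
        assert c.logpdf(10.0) == pytest.approx(st.norm.logpdf(10, 10, 2))
        u = CalibrationPrior(frozenset("AB"), "uniform", (1.0, 3.0))
        assert u.logpdf(2.0) == pytest.approx(-np.log(2.0))
        assert u.logpdf(5.0) == -np.inf
        ln = CalibrationPrior(frozenset("AB"), "lognormal", (1.0, 0.5))
        assert ln.logpdf(np.exp(1.0)) == pytest.approx(
            st.lognorm.logpdf(np.e, 0.5, scale=np.e))

    def test_unknown_distribution(self):
        with pytest.raises(ValueError):
            CalibrationPrior(frozenset("AB"), "beta", (1, 1))

    def test_calibration_on_focal_node_rejected(self, small_tree):
        topo = write_newick(gametolog_time_tree(small_tree, 0.35))
        bad = default_calibrations(small_tree) + [
            CalibrationPrior(frozenset({"F", "F_W"}), "normal", (0.3, 0.05))
        ]
        cfg = DatingConfig(chain_length=100, sample_interval=10, pre_burnin=0,
                           seed=1)
        with pytest.raises(TreeError, match="focal"):
            run_dating_mcmc(None, topo, bad, cfg, likelihood_on=False)


class TestSampler:
    def test_trace_length_bookkeeping(self, small_tree):
        topo = write_newick(gametolog_time_tree(small_tree, 0.35))
        cals = default_calibrations(small_tree)
        cfg = DatingConfig(chain_length=5300, sample_interval=100,
                           pre_burnin=250, seed=3)
        trace = run_dating_mcmc(None, topo, cals, cfg, likelihood_on=False)
        assert len(trace) == (5300 - 250) // 100

    def test_prior_only_marginal_matches_calibration(self, small_tree):
        # sampling from the prior: a well-separated normal calibration is
        # recovered by the marginal of its node (KS < 0.05 at 10k samples)
        topo = write_newick(gametolog_time_tree(small_tree, 0.35))
        cals = default_calibrations(small_tree, sd_frac=0.03)
        cfg = DatingConfig(chain_length=110_000, sample_interval=10,
                           pre_burnin=10_000, seed=11)
        trace = run_dating_mcmc(None, topo, cals, cfg, likelihood_on=False)
        roots = trace.root_ages
        ksstat = st.kstest(roots, st.norm(1.0, 0.03).cdf).statistic
        assert ksstat < 0.05

    def test_strict_clock_recovery_smoke(self, small_tree):
        # short-chain check that the posterior concentrates near the truth;
        # full 20-replicate coverage lives in the acceptance suite
        t_true = 0.35
        model = SubstitutionModel(family="JC69")
        gt, _ = gametolog_tree(small_tree, t_true, w_rate=1.0, clock_rate=0.1)
        aln = simulate_alignment(gt, model, 500, seed=11)
        topo = write_newick(gametolog_time_tree(small_tree, t_true))
        cals = default_calibrations(small_tree, sd_frac=0.08)
        cfg = DatingConfig(chain_length=50_000, sample_interval=100,
                           pre_burnin=5_000, clock="strict", seed=42)
        trace = run_dating_mcmc(aln, topo, cals, cfg, model=model)
        res = summarize_trace(trace, normalized=False)
        assert res.hpd_lo <= t_true <= res.hpd_hi
        assert res.hpd_lo <= res.median <= res.hpd_hi

    def test_normalized_summary_in_unit_interval(self, small_tree):
        t_true = 0.35
        model = SubstitutionModel(family="JC69")
        gt, _ = gametolog_tree(small_tree, t_true, w_rate=1.0, clock_rate=0.1)
        aln = simulate_alignment(gt, model, 300, seed=2)
        topo = write_newick(gametolog_time_tree(small_tree, t_true))
        cfg = DatingConfig(chain_length=20_000, sample_interval=100,
                           pre_burnin=2_000, clock="strict", seed=5)
        trace = run_dating_mcmc(aln, topo, default_calibrations(small_tree), cfg,
                                model=model)
        res = summarize_trace(trace, normalized=True)
        assert 0 < res.hpd_lo <= res.median <= res.hpd_hi <= 1.0

    def test_relaxed_clock_runs(self, small_tree):
        t_true = 0.35
        model = SubstitutionModel(family="JC69")
        gt, _ = gametolog_tree(small_tree, t_true, w_rate=1.5, clock_rate=0.1)
        aln = simulate_alignment(gt, model, 300, seed=3)
        topo = write_newick(gametolog_time_tree(small_tree, t_true))
        cfg = DatingConfig(chain_length=10_000, sample_interval=100,
                           pre_burnin=1_000, clock="ucln", seed=6)
        trace = run_dating_mcmc(aln, topo, default_calibrations(small_tree), cfg,
                                model=model)
        assert "sigma" in trace.data.columns
        assert np.all(trace.focal_ages > 0)

    def test_deterministic_given_seed(self, small_tree):
        topo = write_newick(gametolog_time_tree(small_tree, 0.35))
        cals = default_calibrations(small_tree)
        cfg = DatingConfig(chain_length=3000, sample_interval=50,
                           pre_burnin=100, seed=9)
        t1 = run_dating_mcmc(None, topo, cals, cfg, likelihood_on=False)
        t2 = run_dating_mcmc(None, topo, cals, cfg, likelihood_on=False)
        assert t1.data.equals(t2.data)


class TestReduceOutgroups:
    def test_keep_all_is_identity(self, ref_tree):
        pruned, _, _ = reduce_outgroups(ref_tree, None, 12)
        assert set(pruned.tips) == set(ref_tree.tips)
        assert pruned.root_age == pytest.approx(ref_tree.root_age)

    def test_keep_one_gives_two_tip_problem(self, ref_tree):
        pruned, _, _ = reduce_outgroups(ref_tree, None, 1)
        assert set(pruned.tips) == {"A_arundinaceus", "A_stentoreus"}

    def test_closest_first_order(self, ref_tree):
        pruned, _, _ = reduce_outgroups(ref_tree, None, 3)
        assert set(pruned.tips) == {"A_arundinaceus", "A_stentoreus",
                                    "A_palustris", "I_opaca"}
        assert pruned.root_age == pytest.approx(7.0)

    def test_excess_keep_raises(self, ref_tree):
        with pytest.raises(TreeError, match="exceeds"):
            reduce_outgroups(ref_tree, None, 13)

    def test_calibrations_pruned_consistently(self, ref_tree):
        cals = default_calibrations(ref_tree)
        pruned, _, pcals = reduce_outgroups(ref_tree, None, 3, calibrations=cals)
        assert len(pcals) == 3  # one per surviving internal node
        ages = sorted(c.params[0] for c in pcals)
        assert ages == [4.0, 6.0, 7.0]

    def test_alignment_pruned_consistently(self, ref_tree):
        from stratadate.simulate import default_model
        gt, _ = gametolog_tree(ref_tree, 10.0)
        aln = simulate_alignment(gt, default_model(), 60, seed=1)
        _, paln, _ = reduce_outgroups(ref_tree, aln, 3)
        assert set(paln.labels) == {"A_arundinaceus", "A_arundinaceus_W",
                                    "A_stentoreus", "A_palustris", "I_opaca"}


class TestConfigIO:
    def test_calibration_roundtrip(self, small_tree, tmp_path):
        from stratadate.dating import load_calibrations, save_calibrations

        cals = default_calibrations(small_tree)
        p = tmp_path / "cals.json"
        save_calibrations(cals, p)
        back = load_calibrations(p)
        assert back == cals

    def test_model_config_roundtrip(self):
        m = SubstitutionModel(family="TN93", kappa1=5.0, kappa2=2.0,
                              pi=[0.3, 0.2, 0.25, 0.25], alpha=0.4, pinv=0.1)
        back = SubstitutionModel.from_config(m.to_config())
        assert back.family == m.family
        assert np.allclose(back.pi, m.pi)
        assert back.kappa1 == m.kappa1 and back.pinv == m.pinv
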