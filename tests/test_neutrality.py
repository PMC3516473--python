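"""Component p-values, HEW calibration and decision, BH correction, HKA,
and clade-wise diversity tests."""

import numpy as np
import pytest

from sweepscan import coalsim, neutrality
from sweepscan.coalsim import (
    clade_conditioned_sample,
    mutate_fixed_theta,
    null_distribution,
    sample_statistics,
    simulate_genealogy,
)
from sweepscan.neutrality import (
    bh_adjust,
    calibrate_hew_threshold,
    clade_diversity_test,
    component_pvalues,
    hew_test,
    hka_test,
    pick_hka_neighbors,
)


class Obs:
    def __init__(self, D=np.nan, H_norm=np.nan, F=np.nan):
        self.D, self.H_norm, self.F = D, H_norm, F


@pytest.fixture(scope="module")
def null_10_5():
    return null_distribution(10, 5.0, reps=999, seed=21, calibration_reps=1500)


class TestComponentPvalues:
    def test_extreme_h_hits_addone_floor(self, null_10_5):
        obs = Obs(D=0.0, H_norm=null_10_5.H[0] - 10, F=0.5)
        p_H, _, _ = component_pvalues(obs, null_10_5)
        assert p_H == pytest.approx(1 / (null_10_5.m + 1))

    def test_median_f_gives_half(self, null_10_5):
        obs = Obs(D=0.0, H_norm=0.0, F=float(np.median(null_10_5.F)))
        _, p_EW, _ = component_pvalues(obs, null_10_5)
        assert abs(p_EW - 0.5) < 0.05

    def test_undefined_stat_gives_nan(self, null_10_5):
        p_H, p_EW, p_D = component_pvalues(Obs(), null_10_5)
        assert np.isnan(p_H) and np.isnan(p_EW) and np.isnan(p_D)

    def test_neutral_pvalues_uniform(self):
        """Component p-values on neutral data are uniform (KS vs U(0,1))."""
        from scipy.stats import kstest
        rng = np.random.default_rng(31)
        # the null must be much larger than the test sample, otherwise its
        # own Monte-Carlo error is shared across every p-value and KS sees it
        null = null_distribution(20, 8.0, reps=20_000, seed=32, calibration_reps=0)
        ps = {"H": [], "EW": []}
        for _ in range(2000):
            s = mutate_fixed_theta(simulate_genealogy(20, rng), 8.0, rng)
            if s.S == 0:
                continue
            D, H, F = sample_statistics(s)
            p_H, p_EW, _ = component_pvalues(Obs(D, H, F), null)
            ps["H"].append(p_H)
            # F is a discrete statistic with large atoms at small n, so the
            # plain right-tail p is conservative by construction; uniformity
            # of the tie-randomized p is the correct calibration check
            lo = np.searchsorted(null.F, F, side="left")
            hi = np.searchsorted(null.F, F, side="right")
            below = null.m - hi          # strictly greater than obs
            ties = hi - lo
            p_rand = (below + rng.uniform() * (ties + 1) + 1) / (null.m + 1)
            ps["EW"].append(p_rand)
        assert kstest(ps["H"], "uniform").pvalue > 0.01
        assert kstest(ps["EW"], "uniform").pvalue > 0.01


class TestCalibration:
    def test_independent_uniform_pairs(self):
        rng = np.random.default_rng(1)
        pairs = rng.uniform(size=(100_000, 2))
        t = calibrate_hew_threshold(pairs, 0.05)
        assert t == pytest.approx(np.sqrt(0.05), abs=0.01)

    def test_perfectly_correlated_pairs(self):
        rng = np.random.default_rng(2)
        u = rng.uniform(size=50_000)
        t = calibrate_hew_threshold(np.column_stack([u, u]), 0.05)
        assert t == pytest.approx(0.05, abs=0.005)

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(3)
        pairs = rng.uniform(size=(20_000, 2))
        ts = [calibrate_hew_threshold(pairs, a) for a in (0.01, 0.05, 0.1, 0.2)]
        assert ts == sorted(ts)

    def test_requires_enough_pairs(self):
        with pytest.raises(ValueError):
            calibrate_hew_threshold(np.random.uniform(size=(500, 2)), 0.05)

    def test_joint_rate_does_not_exceed_alpha(self):
        rng = np.random.default_rng(4)
        pairs = rng.uniform(size=(50_000, 2)) ** 0.7
        for alpha in (0.01, 0.05):
            t = calibrate_hew_threshold(pairs, alpha)
            joint = np.mean((pairs[:, 0] <= t) & (pairs[:, 1] <= t))
            assert joint <= alpha


class TestHewDecision:
    def test_reject_both_extreme(self):
        rng = np.random.default_rng(5)
        pairs = rng.uniform(size=(5000, 2))
        res = hew_test(0.001, 0.001, 0.22, pairs)
        assert res.reject and res.compound_p < 0.01

    def test_single_extreme_component_not_rejected(self):
        rng = np.random.default_rng(6)
        pairs = rng.uniform(size=(5000, 2))
        res = hew_test(0.5, 0.001, 0.22, pairs)
        assert not res.reject

    def test_undefined_components_flagged(self):
        res = hew_test(np.nan, 0.01, 0.2, np.random.uniform(size=(2000, 2)))
        assert not res.reject and np.isnan(res.compound_p)

    def test_power_on_swept_data_exceeds_neutral_rate(self):
        """Calibrated HEW rejects complete-sweep samples far more often than
        neutral ones (> 5x the nominal rate)."""
        from sweepscan.experiments import hew_power
        from sweepscan.synthetic_data import ScenarioConfig

        cfg = ScenarioConfig(scenario="complete_sweep", n=50, theta=10.0, tau=0.01)
        power, tested = hew_power(17, cfg, n_loci=150, null_reps=1500,
                                  calibration_reps=1000)
        assert tested > 100
        assert power > 5 * 0.05


class TestBH:
    def test_closed_form_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_nan_entries_excluded_from_family(self):
        out = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        assert out[0] == pytest.approx(0.02)  # m=2 family

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_matches_textbook_stepup(self):
        """Independent step-up transcription on random vectors."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(2, 30))
            m = p.size
            order = np.argsort(p)
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                idx = order[rank - 1]
                running = min(running, p[idx] * m / rank)
                adj[idx] = running
            assert bh_adjust(p) == pytest.approx(adj, abs=1e-12)


class TestHka:
    def test_proportional_data_fit_perfectly(self):
        res = hka_test([("a", 20, 30, 10, 500), ("b", 40, 60, 10, 500)],
                       reps=300, seed=8)
        assert res.chi2 == pytest.approx(0.0, abs=1e-8)
        assert res.p_value > 0.5

    def test_fit_matches_independent_optimizer(self):
        """Moment fit equals an independent least-squares solve of the same
        equations (scipy)."""
        from scipy.optimize import fsolve
        from sweepscan.sumstats import harmonic_number

        loci = [("a", 25, 40, 12, 480), ("b", 60, 85, 20, 510), ("c", 9, 30, 12, 450)]
        res = hka_test(loci, reps=200, seed=9)
        S = np.array([25, 60, 9], float)
        D = np.array([40, 85, 30], float)
        a = np.array([harmonic_number(n) for n in (12, 20, 12)])

        def eqs(x):
            th, T = x[:3], x[3]
            # the classical estimating equations: per-locus totals plus the
            # global divergence constraint
            return np.r_[th * (a + T + 1) - (S + D),
                         th.sum() * (T + 1) - D.sum()]

        fit = fsolve(eqs, x0=np.r_[S / a, 1.0], full_output=False)
        assert res.T == pytest.approx(fit[3], rel=1e-6)
        assert res.theta == pytest.approx(fit[:3], rel=1e-6)

    def test_planted_deficit_dominates_chi2(self):
        # locus c has a 5x deficit of polymorphism
        loci = [("a", 50, 60, 10, 500), ("b", 55, 66, 10, 500), ("c", 11, 66, 10, 500)]
        res = hka_test(loci, reps=200, seed=10)
        assert np.argmax(res.chi2_per_locus) == 2

    def test_needs_two_loci(self):
        with pytest.raises(ValueError):
            hka_test([("a", 5, 5, 10, 100)], reps=200)

    def test_p_uniform_under_own_model(self):
        """Re-simulated datasets under the fitted neutral model give roughly
        uniform simulation p-values."""
        from scipy.stats import kstest
        from sweepscan.sumstats import harmonic_number

        rng = np.random.default_rng(11)
        n = (10, 10, 10)
        thetaL = np.array([5.0, 8.0, 12.0])
        T = 2.0
        pvals = []
        for _ in range(150):
            S = []
            D = []
            for i in range(3):
                g = simulate_genealogy(n[i], rng)
                S.append(rng.poisson(thetaL[i] / 2 * g.total_length))
                D.append(rng.poisson(thetaL[i] * (T + rng.exponential())))
            res = hka_test(list(zip("abc", S, D, n, [500] * 3)),
                           reps=150, seed=rng)
            pvals.append(res.p_value)
        assert kstest(pvals, "uniform").pvalue > 0.01


@pytest.fixture(scope="module")
def conditioned():
    return clade_conditioned_sample(20, 6, 12, reps=1500, seed=12)


class TestCladeDiversity:

    def test_median_observation_is_typical(self, conditioned):
        med = float(np.median(conditioned.clade_stats["B"]["pi"]))
        p = clade_diversity_test({"B": {"pi": med}}, conditioned)
        assert 0.3 < p["B"]["pi"] < 0.7

    def test_extreme_deficit_hits_addone_floor(self, conditioned):
        p = clade_diversity_test({"B": {"S": -1}}, conditioned)
        assert p["B"]["S"] == pytest.approx(1 / (conditioned.accepted + 1))

    def test_unknown_clade_errors(self, conditioned):
        with pytest.raises(ValueError):
            clade_diversity_test({"Z": {"S": 1}}, conditioned)

    def test_planted_low_diversity_clade_detected(self):
        """A large clade with far less variation than its size predicts is
        flagged at p < 0.05.  (Deficits are detectable in the larger clade;
        the smaller conditioned clade is often variation-free under the
        neutral null itself.)"""
        cond = clade_conditioned_sample(20, 8, 15, reps=1500, seed=13)
        p = clade_diversity_test({"A": {"pi": 0.05, "S": 0}}, cond)
        assert p["A"]["pi"] < 0.05 and p["A"]["S"] < 0.05


def test_pick_hka_neighbors_skips_significant():
    order = ["g1", "g2", "g3", "g4", "g5"]
    up, down = pick_hka_neighbors("g3", order, significant={"g2", "g4"})
    assert (up, down) == ("g1", "g5")
    up, down = pick_hka_neighbors("g1", order, significant=set())
    assert up is None and down == "g2"
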