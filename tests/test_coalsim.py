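"""Coalescent machinery: closed-form moments, independent-simulator
agreement, and the clade-conditioned rejection sampler."""

import numpy as np
import pytest

from sweepscan import coalsim
from sweepscan.coalsim import (
    clade_conditioned_sample,
    mutate_fixed_s,
    mutate_fixed_theta,
    null_distribution,
    sample_statistics,
    simulate_genealogy,
)
from sweepscan.sumstats import harmonic_number


# --- independent oracle: a deliberately naive coalescent ------------------

def naive_coalescent_masks(n, rng):
    """Branch (tipset, length) pairs from an independently coded coalescent."""
    lineages = {i: frozenset([i]) for i in range(n)}
    birth = {i: 0.0 for i in range(n)}
    t = 0.0
    branches = []
    nxt = n
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(2.0 / (k * (k - 1)))
        a, b = rng.choice(list(lineages), size=2, replace=False)
        branches.append((lineages[a], t - birth[a]))
        branches.append((lineages[b], t - birth[b]))
        lineages[nxt] = lineages.pop(a) | lineages.pop(b)
        birth[nxt] = t
        nxt += 1
    return branches, t


class TestGenealogy:
    def test_pairwise_tmrca_is_one(self, rng):
        times = [simulate_genealogy(2, rng).t_mrca for _ in range(10_000)]
        mean, se = np.mean(times), np.std(times) / np.sqrt(len(times))
        assert abs(mean - 1.0) < 3 * se

    def test_total_length_matches_harmonic_sum(self, rng):
        lens = [simulate_genealogy(10, rng).total_length for _ in range(10_000)]
        expect = 2 * harmonic_number(10)
        assert expect == pytest.approx(5.657936, abs=1e-5)
        se = np.std(lens) / np.sqrt(len(lens))
        assert abs(np.mean(lens) - expect) < 3 * se

    def test_seed_determinism(self):
        g1 = simulate_genealogy(12, seed=7)
        g2 = simulate_genealogy(12, seed=7)
        assert np.array_equal(g1.time, g2.time)
        assert g1.clade_mask == g2.clade_mask

    def test_rejects_single_tip(self):
        with pytest.raises(ValueError):
            simulate_genealogy(1)

    def test_structure_invariants(self, rng):
        g = simulate_genealogy(9, rng)
        assert (g.branch_lengths() > 0).all()
        assert g.clade_mask[g.root] == (1 << 9) - 1


class TestMutations:
    def test_mean_mutation_count(self, rng):
        theta, n = 5.0, 10
        S = [mutate_fixed_theta(simulate_genealogy(n, rng), theta, rng).S
             for _ in range(10_000)]
        expect = theta * harmonic_number(n)
        se = np.std(S) / np.sqrt(len(S))
        assert abs(np.mean(S) - expect) < 3 * se

    def test_singleton_fraction(self, rng):
        """E[S_1]/E[S] = 1/a_n under the neutral SFS."""
        n = 10
        singles = total = 0
        for _ in range(5000):
            s = mutate_fixed_theta(simulate_genealogy(n, rng), 5.0, rng)
            singles += int((s.derived_counts == 1).sum())
            total += s.S
        frac = singles / total
        expect = 1 / harmonic_number(n)
        assert abs(frac - expect) < 0.02

    def test_theta_must_be_positive(self, rng):
        g = simulate_genealogy(4, rng)
        with pytest.raises(ValueError):
            mutate_fixed_theta(g, 0.0, rng)

    def test_fixed_s_exact(self, rng):
        for S in (0, 1, 7):
            s = mutate_fixed_s(simulate_genealogy(6, rng), S, rng)
            assert s.S == S

    def test_fixed_s_singleton_probability_matches_naive_sim(self, rng):
        """n=4, S=1: P(singleton) equals the branch-length expectation from an
        independently coded simulator."""
        n, reps = 4, 20_000
        mine = 0
        for _ in range(reps):
            s = mutate_fixed_s(simulate_genealogy(n, rng), 1, rng)
            mine += int(s.derived_counts[0] == 1)
        naive = 0
        rng2 = np.random.default_rng(999)
        for _ in range(reps):
            branches, _ = naive_coalescent_masks(n, rng2)
            lens = np.array([l for _, l in branches])
            pick = rng2.choice(len(branches), p=lens / lens.sum())
            naive += int(len(branches[pick][0]) == 1)
        p1, p2 = mine / reps, naive / reps
        se = np.sqrt(p1 * (1 - p1) / reps + p2 * (1 - p2) / reps)
        assert abs(p1 - p2) < 3 * se


class TestNullDistribution:
    def test_bounds_and_determinism(self):
        nd1 = null_distribution(10, 5.0, reps=300, seed=3, calibration_reps=0)
        nd2 = null_distribution(10, 5.0, reps=300, seed=3, calibration_reps=0)
        assert (nd1.F > 0).all() and (nd1.F <= 1).all()
        assert np.array_equal(nd1.H, nd2.H)
        assert np.array_equal(np.quantile(nd1.D, [0.05, 0.5, 0.95]),
                              np.quantile(nd2.D, [0.05, 0.5, 0.95]))

    def test_mean_d_and_h_near_zero(self):
        """Neutral expectation at n=25, theta=5.

        Tajima's D has a small negative finite-sample expectation (~ -0.08
        at these conditions, confirmed against msprime), so enough
        replicates are used that Monte-Carlo error cannot straddle the band.
        """
        rng = np.random.default_rng(2024)
        out = []
        for _ in range(30_000):
            s = mutate_fixed_theta(simulate_genealogy(25, rng), 5.0, rng)
            if s.S:
                out.append(sample_statistics(s))
        out = np.asarray(out)
        assert abs(out[:, 0].mean()) < 0.1  # D
        assert abs(out[:, 1].mean()) < 0.1  # H_norm

    def test_moments_at_reference_parameters(self, rng):
        """E[S] = theta a_n and E[Pi] = theta at (n, theta) = (50, 10)."""
        S, Pi = [], []
        from sweepscan.sumstats import theta_estimators_from_sfs
        for _ in range(10_000):
            s = mutate_fixed_theta(simulate_genealogy(50, rng), 10.0, rng)
            S.append(s.S)
            if s.S:
                tp, _, _ = theta_estimators_from_sfs(s.sfs_counts(), 50)
                Pi.append(tp)
        expect_S = 10.0 * harmonic_number(50)
        assert abs(np.mean(S) - expect_S) < 3 * np.std(S) / np.sqrt(len(S))
        assert abs(np.mean(Pi) - 10.0) < 3 * np.std(Pi) / np.sqrt(len(Pi))

    def test_rejects_too_few_reps(self):
        with pytest.raises(ValueError):
            null_distribution(10, 5.0, reps=50)

    def test_d_distribution_matches_msprime(self):
        """Two-sample KS agreement with an established coalescent simulator
        (n=25, theta=5, no recombination)."""
        msprime = pytest.importorskip("msprime")
        from scipy.stats import ks_2samp
        from sweepscan.sumstats import (
            tajimas_d_from_counts, theta_estimators_from_sfs)

        rng = np.random.default_rng(4)
        mine = []
        for _ in range(10_000):
            s = mutate_fixed_theta(simulate_genealogy(25, rng), 5.0, rng)
            if s.S:
                mine.append(sample_statistics(s)[0])
        other = []
        reps = msprime.sim_ancestry(samples=25, ploidy=1, sequence_length=1,
                                    num_replicates=10_000, random_seed=11)
        for ts in reps:
            mts = msprime.sim_mutations(ts, rate=2.5, discrete_genome=False)
            counts = mts.allele_frequency_spectrum(
                polarised=True, span_normalise=False)[1:25]
            S = counts.sum()
            if S:
                tp, _, _ = theta_estimators_from_sfs(counts, 25)
                other.append(tajimas_d_from_counts(25, S, tp))
        assert ks_2samp(mine, other).pvalue > 0.01


class TestCladeConditioned:
    def test_four_tips_always_contain_a_cherry(self):
        out = clade_conditioned_sample(4, 2, 3, reps=300, seed=5)
        assert out.acceptance_rate == 1.0

    def test_caterpillar_probability(self):
        """P(some edge subtends 3 of 4 tips) = 2/3 over labeled histories."""
        out = clade_conditioned_sample(4, 3, 3, reps=4000, seed=5)
        p = out.acceptance_rate
        se = np.sqrt(p * (1 - p) / out.attempts)
        assert abs(p - 2 / 3) < 3 * se

    def test_exact_segregating_sites(self):
        out = clade_conditioned_sample(8, 3, 11, reps=50, seed=2, keep_samples=True)
        assert all(s.S == 11 for s, _ in out.samples)

    def test_clade_size_partition(self):
        out = clade_conditioned_sample(10, 3, 9, reps=50, seed=2, keep_samples=True)
        for _, mask in out.samples:
            assert mask.bit_count() == 3

    def test_fixed_theta_sfs_matches_closed_form(self, rng):
        """E[S_i] = theta/i under fixed-theta mutation, so the expected
        spectrum shares are exactly (1/i)/a_n."""
        n, theta, reps = 10, 5.0, 6000
        counts = np.zeros(n - 1)
        for _ in range(reps):
            s = mutate_fixed_theta(simulate_genealogy(n, rng), theta, rng)
            for d in s.derived_counts:
                counts[d - 1] += 1
        mean_counts = counts / reps
        expect = theta / np.arange(1, n)
        # Var(S_i) inflated by tree-length variance; generous 5 SE of Poisson
        se = np.sqrt(expect / reps)
        assert (np.abs(mean_counts - expect) < 6 * se).all()

    def test_fixed_s_sfs_matches_naive_simulator(self, rng):
        """The fixed-S spectrum (E[l_i/L], not E[l_i]/E[L]) agrees with an
        independently coded coalescent oracle."""
        n, S, reps = 10, 5, 4000
        counts = np.zeros(n - 1)
        for _ in range(reps):
            s = mutate_fixed_s(simulate_genealogy(n, rng), S, rng)
            for d in s.derived_counts:
                counts[d - 1] += 1
        frac = counts / counts.sum()
        rng2 = np.random.default_rng(777)
        counts2 = np.zeros(n - 1)
        for _ in range(reps):
            branches, _ = naive_coalescent_masks(n, rng2)
            lens = np.array([l for _, l in branches])
            picks = rng2.choice(len(branches), size=S, p=lens / lens.sum())
            for p in picks:
                counts2[len(branches[p][0]) - 1] += 1
        frac2 = counts2 / counts2.sum()
        se = np.sqrt(frac * (1 - frac) / (reps * S)
                     + frac2 * (1 - frac2) / (reps * S))
        assert (np.abs(frac - frac2) < 4 * np.maximum(se, 1e-3)).all()

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            clade_conditioned_sample(4, 1, 3, reps=10)
        with pytest.raises(ValueError):
            clade_conditioned_sample(4, 2, 0, reps=10)
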