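"""Desk-scale calibration experiments.

These drive whole-method calibration runs (many simulated loci through the
full testing machinery) and are used both by the test suite and by
``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from . import coalsim, neutrality
from .pipeline import NullCache
from .sumstats import harmonic_number

__all__ = ["hew_neutral_rejection_rate", "hew_power", "fst_type_i_error"]


def hew_neutral_rejection_rate(
    seed: int,
    n_loci: int = 500,
    n: int = 50,
    theta: float = 10.0,
    null_reps: int = 2000,
    calibration_reps: int = 1000,
    alpha: float = 0.05,
    cache: NullCache | None = None,
) -> tuple[float, int]:
    """Empirical rejection rate of the calibrated compound HEW test on
    neutral coalescent data.

    Simulates ``n_loci`` neutral loci, computes each locus's normalized H and
    Ewens-Watterson F, converts them to Monte-Carlo p-values against nulls at
    the locus's own Watterson estimate (cached by rounded theta), applies the
    jointly calibrated threshold at ``alpha``, and returns (rate, #tested).
    Monomorphic loci carry no test and are excluded.
    """
    rng = np.random.default_rng([seed, 1])
    if cache is None:
        cache = NullCache(null_reps, calibration_reps, seed=seed % (2 ** 31 - 1))
    a_n = harmonic_number(n)
    rejected = tested = 0
    for _ in range(n_loci):
        g = coalsim.simulate_genealogy(n, rng)
        s = coalsim.mutate_fixed_theta(g, theta, rng)
        if s.S == 0:
            continue
        _, H_obs, F_obs = coalsim.sample_statistics(s)
        null = cache.get(n, s.S / a_n)
        p_H = coalsim.p_left(null.H, H_obs)
        p_EW = coalsim.p_right(null.F, F_obs)
        t = neutrality.calibrate_hew_threshold(null.calibration_pairs, alpha)
        if neutrality.hew_test(p_H, p_EW, t, null.calibration_pairs).reject:
            rejected += 1
        tested += 1
    return rejected / tested, tested


def hew_power(
    seed: int,
    scenario_cfg,
    n_loci: int = 200,
    null_reps: int = 2000,
    calibration_reps: int = 1000,
    alpha: float = 0.05,
    cache: NullCache | None = None,
) -> tuple[float, int]:
    """Rejection rate of the calibrated HEW test on samples drawn from a
    non-neutral scenario genealogy (power at ``alpha``)."""
    from .synthetic_data import scenario_genealogy

    rng = np.random.default_rng([seed, 2])
    if cache is None:
        cache = NullCache(null_reps, calibration_reps, seed=seed % (2 ** 31 - 1))
    a_n = harmonic_number(scenario_cfg.n)
    rejected = tested = 0
    for _ in range(n_loci):
        g = scenario_genealogy(scenario_cfg, rng)
        s = coalsim.mutate_fixed_theta(g, scenario_cfg.theta, rng)
        if s.S == 0:
            continue
        _, H_obs, F_obs = coalsim.sample_statistics(s)
        null = cache.get(scenario_cfg.n, s.S / a_n)
        p_H = coalsim.p_left(null.H, H_obs)
        p_EW = coalsim.p_right(null.F, F_obs)
        t = neutrality.calibrate_hew_threshold(null.calibration_pairs, alpha)
        if neutrality.hew_test(p_H, p_EW, t, null.calibration_pairs).reject:
            rejected += 1
        tested += 1
    return (rejected / tested if tested else float("nan")), tested


def fst_type_i_error(
    seed: int,
    n_experiments: int = 500,
    n: int = 50,
    theta: float = 10.0,
    n_perm: int = 199,
    alpha: float = 0.05,
) -> tuple[float, np.ndarray]:
    """Type-I error of the F_ST permutation test under panmixia.

    Simulates one panmictic sample per experiment, splits it by a random
    bipartition, and runs the permutation test; returns (fraction significant
    at ``alpha``, array of p-values).
    """
    from .popdiff import fst_permutation_test

    rng = np.random.default_rng([seed, 3])
    pvals = []
    for _ in range(n_experiments):
        g = coalsim.simulate_genealogy(n, rng)
        s = coalsim.mutate_fixed_theta(g, theta, rng)
        if s.S < 2:
            continue
        mat = np.where(s.matrix().astype(bool), b"G", b"A").astype("S1")
        idx = rng.permutation(n)
        half = n // 2
        res = fst_permutation_test(mat[idx[:half]], mat[idx[half:]],
                                   n_perm=n_perm, seed=rng, alpha=alpha)
        if np.isfinite(res.p_value):
            pvals.append(res.p_value)
    pvals = np.asarray(pvals)
    return float(np.mean(pvals < alpha)), pvals
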