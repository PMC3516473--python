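"""Neutrality tests: component p-values, the compound HEW decision with
jointly calibrated thresholds, multiple-testing correction, the multilocus
HKA test, and clade-wise diversity tests.

The compound HEW test combines the normalized Fay & Wu H (left tail: excess
of high-frequency derived alleles) with Ewens-Watterson homozygosity F
(right tail: excess haplotype homozygosity).  Each component is converted to
an add-one Monte-Carlo p-value against a coalescent null at (n, theta_hat),
and the pair is rejected only when both components fall below a threshold t
calibrated so that the joint null probability Pr(p_H <= t and p_EW <= t)
equals the nominal level.  Because both components come from the same data,
the joint event is exactly {max(p_H, p_EW) <= t}, so t is an empirical
quantile of the max-component over calibration pairs, and the compound
p-value is the max-component rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coalsim import NullDistribution, p_left, p_right, simulate_genealogy
from .sumstats import harmonic_number, harmonic_number_2

__all__ = [
    "HewResult", "HkaResult", "component_pvalues", "calibrate_hew_threshold",
    "hew_test", "bh_adjust", "hka_test", "clade_diversity_test",
    "pick_hka_neighbors",
]


@dataclass
class HewResult:
    locus: str
    stratum: str
    p_H: float
    p_EW: float
    threshold: float
    compound_p: float
    reject: bool
    corrected_p: float = float("nan")


@dataclass
class HkaResult:
    loci: list
    S_obs: np.ndarray
    D_obs: np.ndarray
    n: np.ndarray
    L: np.ndarray
    theta: np.ndarray      # fitted per-locus theta (per locus, not per site)
    T: float               # fitted divergence time, 2N units
    chi2: float
    chi2_per_locus: np.ndarray
    p_value: float
    reps: int


def component_pvalues(obs, null: NullDistribution):
    """(p_H, p_EW, p_D) for observed statistics against a simulated null.

    ``obs`` needs attributes ``H_norm``, ``F`` and ``D`` (a
    :class:`~sweepscan.sumstats.SummaryStats` works).  p_H is left-tailed,
    p_EW right-tailed, p_D two-tailed (min tail x2, capped at 1); all use the
    add-one (r+1)/(m+1) correction.  Undefined observed statistics yield NaN.
    """
    p_H = p_left(null.H, obs.H_norm) if np.isfinite(obs.H_norm) else float("nan")
    p_EW = p_right(null.F, obs.F) if np.isfinite(obs.F) else float("nan")
    if np.isfinite(obs.D):
        p_D = min(1.0, 2.0 * min(p_left(null.D, obs.D), p_right(null.D, obs.D)))
    else:
        p_D = float("nan")
    return p_H, p_EW, p_D


def calibrate_hew_threshold(calibration_pairs: np.ndarray, alpha: float = 0.05) -> float:
    """Largest threshold t with empirical Pr(p_H <= t AND p_EW <= t) <= alpha.

    Both components below t is equivalent to max(p_H, p_EW) <= t, so t is the
    largest observed max-component value whose empirical CDF does not exceed
    alpha.  If even the smallest calibration max exceeds the budget, returns
    half that value (the test then never rejects).
    """
    pairs = np.asarray(calibration_pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[0] < 1000:
        raise ValueError("need >= 1000 calibration pairs")
    M = np.sort(np.max(pairs, axis=1))
    N = M.size
    uniq = np.unique(M)
    cdf = np.searchsorted(M, uniq, side="right") / N
    ok = uniq[cdf <= alpha]
    if ok.size == 0:
        # no attainable threshold: return a value below every calibration max
        return float(uniq[0] / 2.0)
    return float(ok[-1])


def hew_test(
    p_H: float,
    p_EW: float,
    threshold: float,
    calibration_pairs: np.ndarray,
    locus: str = "",
    stratum: str = "",
) -> HewResult:
    """Compound HEW decision: reject iff both component p-values <= t.

    The compound p is the add-one empirical probability, over calibration
    pairs, that max(p_H*, p_EW*) <= max(p_H, p_EW) — monotone in the decision
    rule, so reject at level alpha iff compound p is in the lowest alpha mass.
    """
    if not (np.isfinite(p_H) and np.isfinite(p_EW)):
        return HewResult(locus, stratum, p_H, p_EW, threshold,
                         float("nan"), False)
    M = np.max(np.asarray(calibration_pairs, dtype=float), axis=1)
    m_obs = max(p_H, p_EW)
    compound = (int(np.count_nonzero(M <= m_obs)) + 1) / (M.size + 1)
    reject = bool(p_H <= threshold and p_EW <= threshold)
    return HewResult(locus, stratum, p_H, p_EW, threshold, compound, reject)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR correction, input order preserved.

    NaN entries are excluded from the family (and returned as NaN).  Values
    outside [0, 1] raise.
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# multilocus HKA
# ---------------------------------------------------------------------------

def _hka_fit(S, D, n, L, max_iter=500, tol=1e-12):
    """Iteratively solve the moment equations
    E[S_i] = theta_i L_i a_{n_i};  E[D_i] = theta_i L_i (T + 1)."""
    S = np.asarray(S, float); D = np.asarray(D, float)
    n = np.asarray(n, int); L = np.asarray(L, float)
    a = np.array([harmonic_number(k) for k in n])
    T = max(np.sum(D) / max(np.sum(S / a), 1e-12) - 1.0, 1e-9)
    thetaL = (S + D) / (a + T + 1.0)
    for _ in range(max_iter):
        T_new = max(np.sum(D) / max(np.sum(thetaL), 1e-12) - 1.0, 1e-9)
        thetaL_new = (S + D) / (a + T_new + 1.0)
        delta = abs(T_new - T) + np.abs(thetaL_new - thetaL).sum()
        T, thetaL = T_new, thetaL_new
        if delta < tol:
            return thetaL, T, True
    return thetaL, T, False


def _hka_chi2(S, D, n, L, thetaL, T):
    a = np.array([harmonic_number(k) for k in n])
    b = np.array([harmonic_number_2(k) for k in n])
    ES = thetaL * a
    ED = thetaL * (T + 1.0)
    varS = ES + thetaL ** 2 * b
    varD = ED + thetaL ** 2
    # a locus with no variation and no divergence fits theta = 0 exactly;
    # its deviation terms are zero rather than 0/0
    with np.errstate(invalid="ignore", divide="ignore"):
        tS = np.where(varS > 0, (S - ES) ** 2 / varS, 0.0)
        tD = np.where(varD > 0, (D - ED) ** 2 / varD, 0.0)
    terms = tS + tD
    return float(terms.sum()), terms


def hka_test(loci, reps: int = 2000, seed=None) -> HkaResult:
    """Multilocus HKA: polymorphism vs divergence proportionality across loci.

    ``loci`` is a sequence of (locus_id, S_i, D_i, n_i, L_i) with S_i silent
    segregating sites, D_i silent fixed differences from the outgroup, n_i
    chromosomes and L_i analyzed silent length.  Fits per-locus theta_i and a
    common divergence time T (2N units) by the moment equations, forms the
    X^2 sum of squared deviations scaled by the neutral variances
    Var(S) = E[S] + (theta_i L_i)^2 b_n, Var(D) = E[D] + (theta_i L_i)^2,
    and measures significance as the fraction of coalescent simulations under
    the fitted parameters with simulated X^2 >= observed (add-one corrected).
    """
    if len(loci) < 2:
        raise ValueError("HKA needs >= 2 loci")
    ids = [x[0] for x in loci]
    S = np.array([x[1] for x in loci], float)
    D = np.array([x[2] for x in loci], float)
    n = np.array([x[3] for x in loci], int)
    L = np.array([x[4] for x in loci], float)
    if (S < 0).any() or (D < 0).any():
        raise ValueError("counts must be >= 0")
    thetaL, T, converged = _hka_fit(S, D, n, L)
    if not converged:
        raise RuntimeError(f"HKA moment fit did not converge (residual thetaL={thetaL}, T={T})")
    chi2, terms = _hka_chi2(S, D, n, L, thetaL, T)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    count = 0
    n_loci = len(ids)
    for _ in range(reps):
        S_sim = np.empty(n_loci)
        D_sim = np.empty(n_loci)
        for i in range(n_loci):
            g = simulate_genealogy(int(n[i]), rng)
            S_sim[i] = rng.poisson(thetaL[i] / 2.0 * g.total_length)
            # divergence: Poisson(theta L (T + t_anc)), t_anc ~ Exp(1) for the
            # ancestral coalescent time => Var(D) = E[D] + (theta L)^2
            D_sim[i] = rng.poisson(thetaL[i] * (T + rng.exponential(1.0)))
        thetaL_s, T_s, ok = _hka_fit(S_sim, D_sim, n, L)
        if not ok:
            continue
        chi2_s, _ = _hka_chi2(S_sim, D_sim, n, L, thetaL_s, T_s)
        if chi2_s >= chi2:
            count += 1
    p = (count + 1) / (reps + 1)
    return HkaResult(
        loci=ids, S_obs=S, D_obs=D, n=n, L=L,
        theta=thetaL, T=T, chi2=chi2, chi2_per_locus=terms,
        p_value=p, reps=reps,
    )


def pick_hka_neighbors(focal: str, loci_by_coordinate: list[str], significant: set[str]):
    """Nearest upstream and downstream neighbors of ``focal`` (in genomic
    coordinate order) that did not themselves reject neutrality.

    Returns (upstream, downstream); either may be None at the ends of the map.
    """
    idx = loci_by_coordinate.index(focal)
    up = next((l for l in reversed(loci_by_coordinate[:idx]) if l not in significant), None)
    down = next((l for l in loci_by_coordinate[idx + 1:] if l not in significant), None)
    return up, down


def clade_diversity_test(observed: dict, conditioned) -> dict:
    """Left-tail p-values for per-clade diversity deficits.

    ``observed`` maps clade label ('A'/'B') to a dict with keys among
    {'h', 'S', 'pi'}; pi must be the unscaled mean pairwise difference count
    so it is commensurable with the abstract-site simulations.
    ``conditioned`` is a :class:`~sweepscan.coalsim.CladeConditionedSample`
    generated at matching (n, clade_size, S).  For each clade and statistic,
    p = add-one fraction of accepted simulations with value <= observed.
    """
    sizes = {"A": max(conditioned.n - conditioned.clade_size, conditioned.clade_size),
             "B": min(conditioned.n - conditioned.clade_size, conditioned.clade_size)}
    out = {}
    for lab, stats in observed.items():
        if lab not in conditioned.clade_stats:
            raise ValueError(f"clade {lab!r} not in conditioned sample")
        out[lab] = {}
        for name, obs_val in stats.items():
            sim = conditioned.clade_stats[lab][name]
            sim = sim[np.isfinite(sim)]
            p = (int(np.count_nonzero(sim <= obs_val)) + 1) / (sim.size + 1)
            out[lab][name] = p
    return out
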