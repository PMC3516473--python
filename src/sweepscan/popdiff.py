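"""Genetic differentiation between population strata.

Weir-Cockerham variance-components F_ST for haploid samples (phased
chromosomes are the sampling unit, so the diploid heterozygosity component is
absent), significance by label permutation, and shared-polymorphism
proportions with rarefaction-based sample-size correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqdata import LocusAlignment

__all__ = ["FstResult", "wc_fst", "fst_permutation_test", "shared_polymorphism"]

_BASES = (b"A", b"C", b"G", b"T")


@dataclass
class FstResult:
    locus: str
    pair: tuple
    fst: float
    n_perm: int
    p_value: float
    significant: bool


def _allele_counts(mat: np.ndarray) -> np.ndarray:
    """(4, L) counts of A,C,G,T per column (missing excluded)."""
    return np.stack([np.count_nonzero(mat == b, axis=0) for b in _BASES]).astype(float)


def _fst_from_counts(cA: np.ndarray, cB: np.ndarray) -> float:
    """Multi-site ratio-of-sums Weir-Cockerham F_ST from per-population
    per-allele count tables (4, L).

    Per site and allele u: with r = 2 samples of sizes n_i and allele
    frequencies p_iu,
        MSA_u = sum_i n_i (p_iu - pbar_u)^2 / (r - 1)
        MSW_u = sum_i n_i p_iu (1 - p_iu) / sum_i (n_i - 1)
        n_c   = (sum n_i - sum n_i^2 / sum n_i) / (r - 1)
        a_u   = (MSA_u - MSW_u) / n_c          (among-population component)
        b_u   = MSW_u                          (within-population component)
    and F_ST = sum a / sum (a + b) over alleles and sites.  Sites monomorphic
    overall or with fewer than two usable chromosomes in either sample
    contribute nothing.  Returns NaN when no site is polymorphic.
    """
    nA = cA.sum(axis=0)
    nB = cB.sum(axis=0)
    tot = cA + cB
    poly = ((tot > 0).sum(axis=0) >= 2) & (nA >= 2) & (nB >= 2)
    if not poly.any():
        return float("nan")
    cA = cA[:, poly]; cB = cB[:, poly]
    nA = nA[poly]; nB = nB[poly]
    pA = cA / nA
    pB = cB / nB
    n_tot = nA + nB
    pbar = (cA + cB) / n_tot
    msa = nA * (pA - pbar) ** 2 + nB * (pB - pbar) ** 2  # /(r-1)=1
    msw = (nA * pA * (1 - pA) + nB * pB * (1 - pB)) / (n_tot - 2)
    n_c = n_tot - (nA ** 2 + nB ** 2) / n_tot
    a = (msa - msw) / n_c
    b = msw
    denom = (a + b).sum()
    if denom == 0:
        return float("nan")
    return float(a.sum() / denom)


def wc_fst(alnA, alnB) -> float:
    """Weir-Cockerham F_ST between two haplotype samples at shared columns.

    Arguments may be :class:`LocusAlignment` or raw (n, L) S1 matrices.
    May be slightly negative; NaN when no site is polymorphic overall.
    """
    mA = alnA.matrix if isinstance(alnA, LocusAlignment) else np.asarray(alnA, dtype="S1")
    mB = alnB.matrix if isinstance(alnB, LocusAlignment) else np.asarray(alnB, dtype="S1")
    if mA.shape[0] < 2 or mB.shape[0] < 2:
        raise ValueError("each sample needs >= 2 haplotypes")
    if mA.shape[1] != mB.shape[1]:
        raise ValueError("samples must share columns")
    return _fst_from_counts(_allele_counts(mA), _allele_counts(mB))


def fst_permutation_test(
    alnA, alnB, n_perm: int = 1000, seed=None, locus: str = "", alpha: float = 0.05,
) -> FstResult:
    """Permutation significance for F_ST > 0.

    Population labels are shuffled across the pooled haplotypes preserving
    group sizes; p = (1 + #{F_perm >= F_obs}) / (n_perm + 1); significant iff
    p < alpha.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    mA = alnA.matrix if isinstance(alnA, LocusAlignment) else np.asarray(alnA, dtype="S1")
    mB = alnB.matrix if isinstance(alnB, LocusAlignment) else np.asarray(alnB, dtype="S1")
    f_obs = wc_fst(mA, mB)
    pair = (getattr(alnA, "locus_id", "A"), getattr(alnB, "locus_id", "B"))
    if not np.isfinite(f_obs):
        return FstResult(locus, pair, f_obs, n_perm, float("nan"), False)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pooled = np.vstack([mA, mB])
    nA = mA.shape[0]
    n = pooled.shape[0]
    # one-hot cube (4, n, L) lets each permutation be two sums
    cube = np.stack([(pooled == b) for b in _BASES]).astype(float)
    count = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)
        selA = idx[:nA]
        cA = cube[:, selA, :].sum(axis=1)
        cB = cube.sum(axis=1) - cA
        if _fst_from_counts(cA, cB) >= f_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return FstResult(locus, pair, f_obs, n_perm, p, bool(p < alpha))


def _segregating_mask(mat: np.ndarray) -> np.ndarray:
    counts = _allele_counts(mat)
    return (counts > 0).sum(axis=0) >= 2


def shared_polymorphism(alnA, alnB, n_sub: int, reps: int = 100, seed=None) -> float:
    """Mean proportion of A's segregating sites also segregating in B, after
    rarefaction: both samples are repeatedly down-sampled to ``n_sub``
    haplotypes without replacement and the proportion is averaged over reps.
    """
    mA = alnA.matrix if isinstance(alnA, LocusAlignment) else np.asarray(alnA, dtype="S1")
    mB = alnB.matrix if isinstance(alnB, LocusAlignment) else np.asarray(alnB, dtype="S1")
    if n_sub < 2:
        raise ValueError("n_sub must be >= 2")
    if n_sub > min(mA.shape[0], mB.shape[0]):
        raise ValueError("n_sub exceeds a sample size")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    props = []
    for _ in range(reps):
        subA = mA[rng.choice(mA.shape[0], n_sub, replace=False)]
        subB = mB[rng.choice(mB.shape[0], n_sub, replace=False)]
        segA = _segregating_mask(subA)
        if not segA.any():
            continue
        segB = _segregating_mask(subB)
        props.append((segA & segB).sum() / segA.sum())
    return float(np.mean(props)) if props else float("nan")
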