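"""Neutral coalescent machinery for null distributions.

Genealogies are simulated under the standard n-coalescent without
recombination: with k lineages the waiting time to the next coalescence is
exponential with rate k(k-1)/2 (time in units of 2N generations) and a
uniformly random pair merges.  Mutations follow the infinite-sites model at
rate theta/2 per lineage per unit time, so E[S] = theta * a_n with
theta = 4 N mu.  Simulated sites are abstract (no sequence length); statistics
that need per-site scaling are compared unscaled or at matched length.

Tip sets are stored as integer bitmasks, which keeps per-replicate costs low
enough for the 10^4-10^5-replicate null distributions used by the scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sumstats import (
    ew_f_from_frequencies,
    fay_wu_h_from_sfs,
    tajimas_d_from_counts,
    theta_estimators_from_sfs,
)

__all__ = [
    "Genealogy", "SimulatedSample", "NullDistribution", "CladeConditionedSample",
    "simulate_genealogy", "mutate_fixed_theta", "mutate_fixed_s",
    "null_distribution", "clade_conditioned_sample", "sample_statistics",
]


@dataclass
class Genealogy:
    """A realized coalescent tree: 2n-1 nodes, tips 0..n-1 at time 0."""

    n: int
    parent: np.ndarray   # (2n-1,) int; root has parent -1
    time: np.ndarray     # (2n-1,) float, increasing with node index for internals
    clade_mask: list     # per-node bitmask of descendant tips

    @property
    def root(self) -> int:
        return 2 * self.n - 2

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node (2n-2 entries)."""
        idx = np.arange(2 * self.n - 2)
        return self.time[self.parent[idx]] - self.time[idx]

    @property
    def total_length(self) -> float:
        return float(self.branch_lengths().sum())

    @property
    def t_mrca(self) -> float:
        return float(self.time[self.root])

    def internal_clade_sizes(self) -> list[int]:
        """Descendant-tip counts of internal non-root nodes (edges of the tree
        that could define a clade)."""
        return [int(m.bit_count()) for m in
                (self.clade_mask[i] for i in range(self.n, 2 * self.n - 2))]


@dataclass
class SimulatedSample:
    """Infinite-sites sample: one bitmask of derived carriers per mutation."""

    n: int
    masks: list            # per-mutation tip bitmask
    derived_counts: np.ndarray  # per-mutation popcount

    @property
    def S(self) -> int:
        return len(self.masks)

    def sfs_counts(self) -> np.ndarray:
        counts = np.zeros(self.n - 1)
        for d in self.derived_counts:
            counts[d - 1] += 1
        return counts

    def haplotype_frequencies(self) -> np.ndarray:
        """Relative frequencies of distinct haplotypes (mutation-set classes)."""
        keys = [0] * self.n
        for j, m in enumerate(self.masks):
            bit = 1 << j
            mm = m
            while mm:
                t = (mm & -mm).bit_length() - 1
                keys[t] |= bit
                mm &= mm - 1
        _, counts = np.unique(np.asarray(keys, dtype=object), return_counts=True)
        return counts / self.n

    def matrix(self) -> np.ndarray:
        """(n, S) 0/1 matrix of derived states."""
        out = np.zeros((self.n, self.S), dtype=np.int8)
        for j, m in enumerate(self.masks):
            mm = m
            while mm:
                t = (mm & -mm).bit_length() - 1
                out[t, j] = 1
                mm &= mm - 1
        return out


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_genealogy(n: int, seed=None) -> Genealogy:
    """Standard neutral coalescent genealogy for n tips (time in 2N units)."""
    if n < 2:
        raise ValueError("need n >= 2 tips")
    rng = _rng(seed)
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes)
    masks = [1 << i for i in range(n)] + [0] * (n - 1)
    active = list(range(n))
    t = 0.0
    nxt = n
    k = n
    # pre-draw randomness in bulk
    waits = rng.exponential(1.0, size=n - 1)
    while k > 1:
        t += waits[n - k] * 2.0 / (k * (k - 1))
        i = rng.integers(k)
        j = rng.integers(k - 1)
        if j >= i:
            j += 1
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        time[nxt] = t
        masks[nxt] = masks[a] | masks[b]
        # replace a with the new node, remove b
        active[min(i, j)] = nxt
        active.pop(max(i, j))
        nxt += 1
        k -= 1
    return Genealogy(n=n, parent=parent, time=time, clade_mask=masks)


def _place_mutations(g: Genealogy, branch_idx: np.ndarray) -> SimulatedSample:
    masks = [g.clade_mask[b] for b in branch_idx]
    counts = np.array([m.bit_count() for m in masks], dtype=np.int64)
    return SimulatedSample(n=g.n, masks=masks, derived_counts=counts)


def mutate_fixed_theta(g: Genealogy, theta: float, seed=None) -> SimulatedSample:
    """Poisson(theta/2 x total length) mutations placed uniformly on branches."""
    if theta <= 0:
        raise ValueError("theta must be > 0")
    rng = _rng(seed)
    lengths = g.branch_lengths()
    total = lengths.sum()
    n_mut = rng.poisson(theta / 2.0 * total)
    if n_mut == 0:
        return SimulatedSample(n=g.n, masks=[], derived_counts=np.zeros(0, dtype=np.int64))
    branches = rng.choice(lengths.size, size=n_mut, p=lengths / total)
    return _place_mutations(g, branches)


def mutate_fixed_s(g: Genealogy, S: int, seed=None) -> SimulatedSample:
    """Exactly S mutations, branches chosen with probability prop. to length."""
    if S < 0:
        raise ValueError("S must be >= 0")
    rng = _rng(seed)
    if S == 0:
        return SimulatedSample(n=g.n, masks=[], derived_counts=np.zeros(0, dtype=np.int64))
    lengths = g.branch_lengths()
    branches = rng.choice(lengths.size, size=S, p=lengths / lengths.sum())
    return _place_mutations(g, branches)


def sample_statistics(s: SimulatedSample) -> tuple[float, float, float]:
    """(D, H_norm, F) of a simulated sample; D and H are NaN when S = 0."""
    if s.S == 0:
        return float("nan"), float("nan"), 1.0
    counts = s.sfs_counts()
    theta_pi, _, _ = theta_estimators_from_sfs(counts, s.n)
    D = tajimas_d_from_counts(s.n, s.S, theta_pi)
    H = fay_wu_h_from_sfs(counts, s.n)
    F = ew_f_from_frequencies(s.haplotype_frequencies())
    return D, H, F


@dataclass
class NullDistribution:
    """Simulated null vectors of (D, H_norm, F) for a given (n, theta),
    plus the paired (p_H, p_EW) sample used to calibrate the joint HEW
    threshold.  Replicates with S = 0 are excluded from p-value denominators
    (``n_zero`` records how many there were)."""

    n: int
    theta: float
    reps: int
    seed: object
    D: np.ndarray          # sorted, S>0 replicates only
    H: np.ndarray          # sorted
    F: np.ndarray          # sorted
    n_zero: int
    calibration_pairs: np.ndarray = field(default=None)  # (m, 2): p_H, p_EW

    @property
    def m(self) -> int:
        return self.H.size


def _simulate_stats(n: int, theta: float, reps: int, rng) -> tuple[np.ndarray, int]:
    out = np.empty((reps, 3))
    n_zero = 0
    for r in range(reps):
        g = simulate_genealogy(n, rng)
        s = mutate_fixed_theta(g, theta, rng)
        if s.S == 0:
            n_zero += 1
            out[r] = np.nan
            continue
        out[r] = sample_statistics(s)
    return out[~np.isnan(out[:, 0])], n_zero


def p_left(sorted_null: np.ndarray, obs: float) -> float:
    """Add-one left-tail Monte-Carlo p: Pr(sim <= obs)."""
    m = sorted_null.size
    r = int(np.searchsorted(sorted_null, obs, side="right"))
    return (r + 1) / (m + 1)


def p_right(sorted_null: np.ndarray, obs: float) -> float:
    """Add-one right-tail Monte-Carlo p: Pr(sim >= obs)."""
    m = sorted_null.size
    r = m - int(np.searchsorted(sorted_null, obs, side="left"))
    return (r + 1) / (m + 1)


def null_distribution(
    n: int,
    theta: float,
    reps: int,
    seed=None,
    calibration_reps: int = 1000,
) -> NullDistribution:
    """Simulate the null vectors of D, H_norm and F at (n, theta), then an
    independent calibration set whose (p_H, p_EW) pairs (computed against the
    null vectors) parameterize the joint HEW threshold."""
    if reps < 100:
        raise ValueError("reps must be >= 100")
    rng = _rng(seed)
    stats, n_zero = _simulate_stats(n, theta, reps, rng)
    D = np.sort(stats[:, 0])
    H = np.sort(stats[:, 1])
    F = np.sort(stats[:, 2])
    # calibration needs calibration_reps *valid* (S>0) pairs; at small theta
    # a fair share of replicates are monomorphic, so oversample as needed
    chunks = []
    have = 0
    for _ in range(50):
        if have >= calibration_reps:
            break
        cs, _ = _simulate_stats(n, theta, calibration_reps - have, rng)
        if cs.size:
            chunks.append(cs)
            have += cs.shape[0]
    cal_stats = np.vstack(chunks) if chunks else np.empty((0, 3))
    pairs = np.column_stack([
        [p_left(H, h) for h in cal_stats[:, 1]],
        [p_right(F, f) for f in cal_stats[:, 2]],
    ]) if cal_stats.size else np.empty((0, 2))
    return NullDistribution(
        n=n, theta=theta, reps=reps, seed=seed,
        D=D, H=H, F=F, n_zero=n_zero, calibration_pairs=pairs,
    )


@dataclass
class CladeConditionedSample:
    """Accepted fixed-S samples from genealogies containing an internal edge
    subtending exactly ``clade_size`` tips, with per-clade statistics.

    ``clade_stats[label]`` maps 'h'/'S'/'pi' to (reps,) arrays; pi is the mean
    pairwise difference count within the clade (unscaled).  The conditioned
    clade and its complement are labeled by size: the larger is 'A' (ties go
    to 'B' = the conditioned clade)."""

    n: int
    clade_size: int
    S: int
    accepted: int
    attempts: int
    clade_stats: dict
    samples: list = field(default_factory=list)

    @property
    def acceptance_rate(self) -> float:
        return self.accepted / self.attempts if self.attempts else float("nan")


def _clade_substats(s: SimulatedSample, tip_mask: int, n_clade: int):
    """(h, S, Pi) of the sample restricted to tips in ``tip_mask``."""
    sub_counts = []
    sub_masks = []
    for m in s.masks:
        mm = m & tip_mask
        d = mm.bit_count()
        if 0 < d < n_clade:
            sub_counts.append(d)
            sub_masks.append(mm)
    S_c = len(sub_masks)
    # haplotype classes within the clade
    keys = {}
    mm_all = tip_mask
    tips = []
    while mm_all:
        tips.append((mm_all & -mm_all).bit_length() - 1)
        mm_all &= mm_all - 1
    for t in tips:
        key = 0
        for j, m in enumerate(sub_masks):
            if (m >> t) & 1:
                key |= 1 << j
        keys[key] = keys.get(key, 0) + 1
    h_c = len(keys)
    if n_clade >= 2:
        d = np.asarray(sub_counts, dtype=float)
        pi_c = float(np.sum(2.0 * d * (n_clade - d)) / (n_clade * (n_clade - 1)))
    else:
        pi_c = float("nan")
    return h_c, S_c, pi_c


def clade_conditioned_sample(
    n: int,
    clade_size: int,
    S: int,
    reps: int,
    seed=None,
    attempt_cap: int | None = None,
    size_tolerance: int = 0,
    keep_samples: bool = False,
) -> CladeConditionedSample:
    """Rejection sampling of genealogies whose topology contains an internal
    edge subtending exactly ``clade_size`` tips (+/- ``size_tolerance``),
    then exactly S mutations dropped on each accepted genealogy.

    When several edges qualify, one is chosen uniformly at random.  Raises
    RuntimeError (reporting the acceptance rate) if the attempt cap is hit.
    """
    if not (2 <= clade_size <= n - 1):
        raise ValueError("clade_size must be in [2, n-1]")
    if S < 1:
        raise ValueError("S must be >= 1")
    rng = _rng(seed)
    cap = attempt_cap if attempt_cap is not None else 100 * reps
    accepted = 0
    attempts = 0
    labels = ("A", "B")
    stats = {lab: {"h": np.empty(reps), "S": np.empty(reps), "pi": np.empty(reps)}
             for lab in labels}
    samples = []
    full_mask = (1 << n) - 1
    while accepted < reps:
        if attempts >= cap:
            raise RuntimeError(
                f"clade-conditioned sampler: attempt cap {cap} exceeded "
                f"(acceptance rate {accepted / attempts:.4g})"
            )
        attempts += 1
        g = simulate_genealogy(n, rng)
        qualifying = [i for i in range(n, 2 * n - 2)
                      if abs(g.clade_mask[i].bit_count() - clade_size) <= size_tolerance]
        if not qualifying:
            continue
        node = qualifying[rng.integers(len(qualifying))]
        clade_mask = g.clade_mask[node]
        k = clade_mask.bit_count()
        s = mutate_fixed_s(g, S, rng)
        comp_mask = full_mask & ~clade_mask
        # larger side is A; tie -> conditioned clade is B
        if n - k > k or n - k == k:
            sides = {"A": (comp_mask, n - k), "B": (clade_mask, k)}
        else:
            sides = {"A": (clade_mask, k), "B": (comp_mask, n - k)}
        for lab, (mask, sz) in sides.items():
            h_c, S_c, pi_c = _clade_substats(s, mask, sz)
            stats[lab]["h"][accepted] = h_c
            stats[lab]["S"][accepted] = S_c
            stats[lab]["pi"][accepted] = pi_c
        if keep_samples:
            samples.append((s, clade_mask))
        accepted += 1
    return CladeConditionedSample(
        n=n, clade_size=clade_size, S=S, accepted=accepted, attempts=attempts,
        clade_stats=stats, samples=samples,
    )
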