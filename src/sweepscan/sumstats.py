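"""Per-locus, per-population summary statistics.

Implements the classical frequency-spectrum and haplotype summaries used to
scan short gene fragments for sweeps: Watterson's theta, nucleotide diversity
pi, Tajima's D, the normalized Fay & Wu H (Zeng-style normalization of
theta_pi - theta_L), and Ewens-Watterson haplotype homozygosity F.  The
frequency-spectrum kernels operate on plain counts so the coalescent null
machinery can reuse them on simulated 0/1 samples.

Conventions: n = number of chromosomes; the unfolded SFS S_i counts polarized
segregating sites with derived-allele count i (i = 1..n-1); "per site" values
divide by the number of analyzed (non-excluded) columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import seqdata
from .seqdata import LocusAlignment, SiteTracks

__all__ = [
    "SFS", "SummaryStats", "harmonic_number", "harmonic_number_2",
    "unfolded_sfs", "nucleotide_diversity", "watterson_theta", "tajimas_d",
    "fay_wu_h_normalized", "ew_homozygosity", "summarize_locus",
    "tajimas_d_from_counts", "fay_wu_h_from_sfs", "theta_estimators_from_sfs",
    "ew_f_from_frequencies", "segregating_sites", "mean_pairwise_differences",
]


def harmonic_number(n: int) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i."""
    return float(np.sum(1.0 / np.arange(1, n)))


def harmonic_number_2(n: int) -> float:
    """b_n = sum_{i=1}^{n-1} 1/i^2."""
    return float(np.sum(1.0 / np.arange(1, n) ** 2))


@dataclass
class SFS:
    """Unfolded site-frequency spectrum over polarized biallelic sites."""

    n: int
    counts: np.ndarray  # length n-1, counts[i-1] = S_i
    unpolarized: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape[0] != self.n - 1:
            raise ValueError(f"SFS for n={self.n} needs {self.n - 1} bins")
        if (self.counts < 0).any():
            raise ValueError("negative SFS count")

    @property
    def S(self) -> float:
        return float(self.counts.sum())


@dataclass
class SummaryStats:
    """One record per locus x stratum (Table-style output row)."""

    locus_id: str
    stratum: str
    n: int
    L_analyzed: int
    S: int
    h: int
    F: float
    pi_per_site: float
    theta_w_per_site: float
    D: float = float("nan")
    H_norm: float = float("nan")
    theta_pi: float = float("nan")  # per locus, unscaled
    theta_L: float = float("nan")
    theta_H: float = float("nan")
    S_polarized: int = 0
    notes: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# count-level kernels (shared with the coalescent null machinery)
# ---------------------------------------------------------------------------

def theta_estimators_from_sfs(counts: np.ndarray, n: int) -> tuple[float, float, float]:
    """(theta_pi, theta_L, theta_H), unscaled, from unfolded SFS counts.

    theta_pi = sum 2 i (n-i) S_i / (n (n-1));  theta_L = sum i S_i / (n-1);
    theta_H = sum 2 i^2 S_i / (n (n-1)).  Identity: theta_pi + theta_H
    = 2 theta_L.
    """
    counts = np.asarray(counts, dtype=float)
    i = np.arange(1, n)
    theta_pi = float(np.sum(2.0 * i * (n - i) * counts) / (n * (n - 1)))
    theta_L = float(np.sum(i * counts) / (n - 1))
    theta_H = float(np.sum(2.0 * i * i * counts) / (n * (n - 1)))
    return theta_pi, theta_L, theta_H


def tajimas_d_from_counts(n: int, S: float, pi_total: float) -> float:
    """Tajima's D from n, the number of segregating sites, and the mean
    pairwise difference count Pi (unscaled).  Returns NaN when S == 0."""
    if S <= 0:
        return float("nan")
    a1 = harmonic_number(n)
    a2 = harmonic_number_2(n)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return float("nan")
    return float((pi_total - S / a1) / np.sqrt(var))


def fay_wu_h_from_sfs(counts: np.ndarray, n: int) -> float:
    """Normalized Fay & Wu's H from unfolded SFS counts.

    H_norm = (theta_pi - theta_L) / sqrt(Var), with

      Var = theta (n-2) / (6 (n-1))
          + theta2 * [18 n^2 (3n+2) b_{n+1} - (88 n^3 + 9 n^2 - 13 n + 6)]
                    / (9 n (n-1)^2)

    where theta = S/a_n, theta2 = S(S-1)/(a_n^2 + b_n), a_n = sum 1/i,
    b_n = sum 1/i^2 (i to n-1) and b_{n+1} = b_n + 1/n^2.  NaN when S == 0.
    """
    counts = np.asarray(counts, dtype=float)
    S = counts.sum()
    if S <= 0:
        return float("nan")
    theta_pi, theta_L, _ = theta_estimators_from_sfs(counts, n)
    an = harmonic_number(n)
    bn = harmonic_number_2(n)
    bn1 = bn + 1.0 / (n * n)
    theta = S / an
    theta2 = S * (S - 1.0) / (an * an + bn)
    var = (theta * (n - 2) / (6.0 * (n - 1))
           + theta2 * (18.0 * n * n * (3.0 * n + 2) * bn1
                       - (88.0 * n ** 3 + 9.0 * n * n - 13.0 * n + 6))
           / (9.0 * n * (n - 1.0) ** 2))
    if var <= 0:
        raise FloatingPointError(f"non-positive variance {var} in normalized H (n={n}, S={S})")
    return float((theta_pi - theta_L) / np.sqrt(var))


def ew_f_from_frequencies(freqs) -> float:
    """Ewens-Watterson homozygosity F = sum p_k^2 over haplotype frequencies."""
    p = np.asarray(freqs, dtype=float)
    return float(np.sum(p * p))


# ---------------------------------------------------------------------------
# alignment-level operations
# ---------------------------------------------------------------------------

def _allele_count_table(aln: LocusAlignment) -> tuple[np.ndarray, np.ndarray]:
    """Per-column counts of each of A,C,G,T (4, L) and non-missing totals (L,)."""
    counts = np.stack([
        np.count_nonzero(aln.matrix == b, axis=0) for b in (b"A", b"C", b"G", b"T")
    ]).astype(float)
    return counts, counts.sum(axis=0)


def segregating_sites(aln: LocusAlignment) -> np.ndarray:
    """Column indices with >= 2 distinct non-missing alleles."""
    counts, _ = _allele_count_table(aln)
    return np.flatnonzero((counts > 0).sum(axis=0) >= 2)


def unfolded_sfs(aln: LocusAlignment, tracks: SiteTracks,
                 columns: np.ndarray | None = None) -> SFS:
    """Unfolded SFS over polarized biallelic segregating columns.

    The derived count at a column is computed over non-missing entries only;
    a column whose non-missing count is below n keeps its observed derived
    count (missing entries are simply excluded from the basis).  Columns with
    status unpolarizable increment ``unpolarized``.
    """
    n = aln.n
    counts = np.zeros(n - 1)
    unpolarized = 0
    seg = set(segregating_sites(aln).tolist())
    cols = seg if columns is None else (seg & set(np.asarray(columns).tolist()))
    for c in sorted(cols):
        st = tracks.status[c]
        if st == seqdata.POL_POLARIZED:
            nd, _ = seqdata.derived_count(aln, tracks, c)
            if 1 <= nd <= n - 1:
                counts[nd - 1] += 1
        elif st == seqdata.POL_UNPOLARIZABLE:
            unpolarized += 1
    return SFS(n=n, counts=counts, unpolarized=unpolarized)


def _pairwise_column_stats(aln: LocusAlignment) -> tuple[np.ndarray, np.ndarray]:
    """Per column: (#differing pairs, #comparable pairs) over non-missing."""
    counts, tot = _allele_count_table(aln)
    pairs_same = (counts * (counts - 1) / 2.0).sum(axis=0)
    pairs_all = tot * (tot - 1) / 2.0
    return pairs_all - pairs_same, pairs_all


def mean_pairwise_differences(aln: LocusAlignment) -> float:
    """Pi: average number of nucleotide differences between haplotype pairs
    (unscaled).  Missing data handled pairwise-complete per column."""
    if aln.n < 2:
        raise ValueError("need >= 2 haplotypes")
    diff, comp = _pairwise_column_stats(aln)
    ok = comp > 0
    return float(np.sum(diff[ok] / comp[ok]))


def nucleotide_diversity(aln: LocusAlignment, L_analyzed: int | None = None) -> float:
    """pi per site: mean pairwise difference proportion / analyzed length."""
    L = aln.L if L_analyzed is None else L_analyzed
    if L == 0:
        return float("nan")
    return mean_pairwise_differences(aln) / L


def watterson_theta(aln: LocusAlignment, L_analyzed: int | None = None) -> float:
    """theta_W per site = S / (a_n * L)."""
    if aln.n < 2:
        raise ValueError("need >= 2 haplotypes")
    L = aln.L if L_analyzed is None else L_analyzed
    if L == 0:
        return float("nan")
    S = segregating_sites(aln).size
    return S / (harmonic_number(aln.n) * L)


def tajimas_d(aln: LocusAlignment) -> float:
    """Tajima's D on the alignment's segregating sites (NaN when S = 0)."""
    S = segregating_sites(aln).size
    return tajimas_d_from_counts(aln.n, S, mean_pairwise_differences(aln))


def fay_wu_h_normalized(sfs: SFS) -> float:
    """Normalized Fay & Wu H from an unfolded SFS (NaN when no polarized S)."""
    return fay_wu_h_from_sfs(sfs.counts, sfs.n)


def ew_homozygosity(aln: LocusAlignment, return_dropped: bool = False):
    """(h, F): number of distinct haplotypes and homozygosity F = sum p_k^2.

    Haplotype strings are compared over segregating columns; haplotypes with
    any missing call at a segregating column are dropped from h/F (logged in
    the caller's notes) — deterministic and conservative for phased inputs.
    """
    seg = segregating_sites(aln)
    if aln.n == 0:
        raise ValueError("empty alignment")
    sub = aln.matrix[:, seg] if seg.size else aln.matrix[:, :0]
    missing = np.isin(sub, [b"N", b"-"]).any(axis=1)
    kept = sub[~missing]
    n_dropped = int(missing.sum())
    if kept.shape[0] == 0:
        out = (0, float("nan"))
        return (*out, n_dropped) if return_dropped else out
    if kept.shape[1] == 0:
        counts = np.array([kept.shape[0]])
    else:
        _, counts = np.unique(kept, axis=0, return_counts=True)
    h = int(counts.size)
    F = ew_f_from_frequencies(counts / counts.sum())
    return (h, F, n_dropped) if return_dropped else (h, F)


def _safe_h(sfs: SFS) -> float:
    """Normalized H for reporting: NaN (rather than an error) when undefined,
    e.g. S = 0 or n = 2 where the normalizing variance vanishes."""
    if sfs.S <= 0:
        return float("nan")
    try:
        return fay_wu_h_normalized(sfs)
    except FloatingPointError:
        return float("nan")


def summarize_locus(
    aln: LocusAlignment,
    partition,
    tracks: SiteTracks,
    silent_only: bool = True,
) -> list[SummaryStats]:
    """One :class:`SummaryStats` per stratum on the (silent) sub-alignment.

    Strata with n < 2 are skipped with a log entry; strata with S = 0 are
    recorded with undefined (NaN) test statistics.
    """
    import logging
    logger = logging.getLogger(__name__)

    records = []
    if silent_only:
        keep = tracks.silent_columns()
    else:
        keep = np.flatnonzero(tracks.site_class != seqdata.SITE_EXCLUDED)
    for stratum in partition.strata:
        haps = [h for h in aln.haplotype_ids if partition.assignment.get(h) == stratum]
        if len(haps) < 2:
            logger.info("skipping stratum %s at %s: n=%d < 2", stratum, aln.locus_id, len(haps))
            continue
        sub = aln.subset_rows(haps).subset_columns(keep)
        Lan = sub.L
        seg = segregating_sites(sub)
        S = int(seg.size)
        h, F, n_dropped = ew_homozygosity(sub, return_dropped=True)
        # SFS needs the original column indices of the silent subset
        sub_tracks = SiteTracks(
            site_class=tracks.site_class[keep],
            status=tracks.status[keep],
            ancestral=tracks.ancestral[keep],
            derived=tracks.derived[keep],
        )
        sfs = unfolded_sfs(sub, sub_tracks)
        theta_pi, theta_L, theta_H = theta_estimators_from_sfs(sfs.counts, sub.n)
        rec = SummaryStats(
            locus_id=aln.locus_id,
            stratum=stratum,
            n=sub.n,
            L_analyzed=Lan,
            S=S,
            h=h,
            F=F,
            pi_per_site=nucleotide_diversity(sub, Lan),
            theta_w_per_site=watterson_theta(sub, Lan),
            D=tajimas_d(sub),
            H_norm=_safe_h(sfs),
            theta_pi=theta_pi,
            theta_L=theta_L,
            theta_H=theta_H,
            S_polarized=int(sfs.S),
        )
        if n_dropped:
            rec.notes.append(f"{n_dropped} haplotype(s) dropped from h/F for missing data")
        if S == 0:
            rec.notes.append("S=0: D and H undefined")
        records.append(rec)
    return records
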