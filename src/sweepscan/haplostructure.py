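"""LD matrices, perfect-LD block discovery, haplogroup delineation, NJ gene
trees, sliding-window Jukes-Cantor divergence, and phase-confidence QC.

A "haplogroup" is a clade of haplotypes delimited by a set of co-segregating
(perfect-LD) variants; the larger clade is labeled A, the smaller B, and
haplotypes conflicting with the majority pattern at the defining sites are
flagged as recombinants (A*).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqdata import LocusAlignment, MISSING

__all__ = [
    "LDMatrix", "Haplogroups", "KjcProfile", "ld_r2_matrix",
    "find_perfect_ld_sites", "delineate_haplogroups", "nj_tree",
    "sliding_kjc", "phase_confidence_qc", "jukes_cantor", "clade_consensus",
]

_MISS = [b"N", b"-"]


@dataclass
class LDMatrix:
    sites: np.ndarray      # original column coordinates of usable sites
    r2: np.ndarray         # symmetric (k, k)
    freq: np.ndarray       # minor/derived allele frequency per site
    empty: bool = False


@dataclass
class Haplogroups:
    defining_sites: np.ndarray
    labels: list                 # per haplotype: 'A', 'B' or 'A*-recombinant'
    clade_sizes: dict
    fixed_differences: int
    error: str | None = None

    def members(self, label: str) -> np.ndarray:
        return np.flatnonzero([l == label for l in self.labels])


@dataclass
class KjcProfile:
    window: int
    step: int
    starts: np.ndarray
    p_distance: np.ndarray   # NaN where no comparable sites
    kjc: np.ndarray          # NaN where p >= 3/4 (undefined)

    @property
    def max_kjc(self) -> float:
        vals = self.kjc[np.isfinite(self.kjc)]
        return float(vals.max()) if vals.size else float("nan")


def _biallelic_indicator(aln: LocusAlignment):
    """For each biallelic segregating column: (col, 0/1/-1 vector, minor freq).

    Codes are 0 for the alphabetically first allele, 1 for the second, -1 for
    missing entries.
    """
    out = []
    for c in range(aln.L):
        col = aln.matrix[:, c]
        ok = ~np.isin(col, _MISS)
        alleles = sorted(set(col[ok].tolist()))
        if len(alleles) != 2:
            continue
        x = np.full(aln.n, -1, dtype=np.int8)
        x[ok] = (col[ok] == alleles[1]).astype(np.int8)
        f = x[ok].mean()
        out.append((c, x, min(f, 1 - f)))
    return out


def ld_r2_matrix(aln: LocusAlignment) -> LDMatrix:
    """Squared genetic correlation r^2 between all biallelic variant sites.

    r^2 = (p_AB - p_A p_B)^2 / (p_A (1-p_A) p_B (1-p_B)), computed on phased
    haplotypes, pairwise-complete over missing entries.
    """
    sites = _biallelic_indicator(aln)
    if len(sites) < 2:
        return LDMatrix(
            sites=np.array([s[0] for s in sites], dtype=int),
            r2=np.zeros((len(sites), len(sites))),
            freq=np.array([s[2] for s in sites]),
            empty=True,
        )
    k = len(sites)
    r2 = np.eye(k)
    for i in range(k):
        _, xi, _ = sites[i]
        for j in range(i + 1, k):
            _, xj, _ = sites[j]
            ok = (xi >= 0) & (xj >= 0)
            a, b = xi[ok].astype(float), xj[ok].astype(float)
            pa, pb = a.mean(), b.mean()
            va, vb = pa * (1 - pa), pb * (1 - pb)
            if va == 0 or vb == 0:
                val = 0.0
            else:
                pab = (a * b).mean()
                val = (pab - pa * pb) ** 2 / (va * vb)
            r2[i, j] = r2[j, i] = val
    return LDMatrix(
        sites=np.array([s[0] for s in sites], dtype=int),
        r2=r2,
        freq=np.array([s[2] for s in sites]),
    )


def find_perfect_ld_sites(
    ld: LDMatrix,
    aln: LocusAlignment,
    min_sites: int = 3,
    max_recombinants: int = 0,
) -> list[dict]:
    """Candidate defining-site sets: groups of sites whose haplotype
    bipartitions agree (up to allele relabeling) on at least
    n - max_recombinants haplotypes.

    Greedy clustering seeded on each unused site; returns sets with
    >= min_sites, ordered by set size (desc) then physical span (desc).  Each
    entry records the site coordinates, the seed partition, and the
    haplotypes that disagree with it anywhere in the set (candidate
    recombinants).
    """
    indicators = {c: x for c, x, _ in _biallelic_indicator(aln)}
    cols = [int(c) for c in ld.sites if c in indicators]
    used = set()
    results = []
    n = aln.n
    for seed_col in cols:
        if seed_col in used:
            continue
        seed = indicators[seed_col]
        group = [seed_col]
        mism: set[int] = set()
        for c in cols:
            if c == seed_col or c in used:
                continue
            x = indicators[c]
            ok = (seed >= 0) & (x >= 0)
            diff = np.flatnonzero(ok & (x != seed))
            diff_c = np.flatnonzero(ok & (x != (1 - seed)))
            best = diff if diff.size <= diff_c.size else diff_c
            if best.size <= max_recombinants:
                group.append(c)
                mism.update(best.tolist())
        if len(group) >= min_sites and len(mism) <= max_recombinants:
            for c in group:
                used.add(c)
            results.append({
                "sites": np.array(sorted(group)),
                "partition": seed.copy(),
                "recombinants": sorted(mism),
                "span": max(group) - min(group),
            })
    results.sort(key=lambda r: (-len(r["sites"]), -r["span"]))
    return results


def delineate_haplogroups(aln: LocusAlignment, defining_sites) -> Haplogroups:
    """Partition haplotypes into clades A/B by their alleles at the defining
    sites (majority-consistent assignment); conflicting haplotypes are
    labeled recombinant; A is the larger clade.  Counts the number of sites
    fixed between the non-recombinant members of A and B."""
    defining_sites = np.asarray(defining_sites, dtype=int)
    indicators = {c: x for c, x, _ in _biallelic_indicator(aln)}
    for c in defining_sites:
        if int(c) not in indicators:
            raise ValueError(f"defining site {c} is not biallelic")
    codes = np.stack([indicators[int(c)] for c in defining_sites])  # (k, n)
    # orient all sites to the first one (allele labels are arbitrary)
    ref = codes[0]
    for i in range(1, codes.shape[0]):
        ok = (codes[i] >= 0) & (ref >= 0)
        agree = (codes[i][ok] == ref[ok]).mean() if ok.any() else 1.0
        if agree < 0.5:
            codes[i][codes[i] >= 0] = 1 - codes[i][codes[i] >= 0]
    n = aln.n
    labels = []
    side = np.full(n, -1)
    for h in range(n):
        vals = codes[:, h]
        vals = vals[vals >= 0]
        if vals.size == 0:
            labels.append("A*-recombinant")
            continue
        ones = int(vals.sum())
        if ones == vals.size:
            side[h] = 1
            labels.append("?1")
        elif ones == 0:
            side[h] = 0
            labels.append("?0")
        else:
            labels.append("A*-recombinant")
    n0 = int(np.count_nonzero(side == 0))
    n1 = int(np.count_nonzero(side == 1))
    if n0 == 0 or n1 == 0:
        return Haplogroups(
            defining_sites=defining_sites, labels=["A"] * n,
            clade_sizes={"A": n}, fixed_differences=0,
            error="no bipartition: all haplotypes carry one allele",
        )
    big = 1 if n1 >= n0 else 0
    labels = ["A" if l == f"?{big}" else ("B" if l.startswith("?") else l) for l in labels]
    hg = Haplogroups(
        defining_sites=defining_sites,
        labels=labels,
        clade_sizes={"A": max(n0, n1), "B": min(n0, n1),
                     "A*-recombinant": labels.count("A*-recombinant")},
        fixed_differences=0,
    )
    # fixed differences between non-recombinant clade members
    rows_a = hg.members("A")
    rows_b = hg.members("B")
    fixed = 0
    for c in range(aln.L):
        col = aln.matrix[:, c]
        va = set(col[rows_a].tolist()) - {b"N", b"-"}
        vb = set(col[rows_b].tolist()) - {b"N", b"-"}
        if len(va) == 1 and len(vb) == 1 and va != vb:
            fixed += 1
    hg.fixed_differences = fixed
    return hg


# ---------------------------------------------------------------------------
# distances and neighbor joining
# ---------------------------------------------------------------------------

def _p_distance(a: np.ndarray, b: np.ndarray) -> float:
    ok = ~(np.isin(a, _MISS) | np.isin(b, _MISS))
    if not ok.any():
        return float("nan")
    return float(np.count_nonzero(a[ok] != b[ok]) / np.count_nonzero(ok))


def jukes_cantor(p: float) -> float:
    """K_JC = -(3/4) ln(1 - 4p/3); undefined (NaN) for p >= 3/4."""
    if p >= 0.75:
        return float("nan")
    return float(-0.75 * np.log1p(-4.0 * p / 3.0))


def nj_tree(aln: LocusAlignment, outgroup_seqs: dict | None = None) -> str:
    """Saitou-Nei neighbor joining on pairwise Jukes-Cantor distances.

    ``outgroup_seqs`` maps label -> (L,) S1 sequence; outgroups are appended
    as extra taxa.  Negative branch lengths are clamped to 0 with the amount
    redistributed to the sister edge.  Returns a Newick string.  Raises if
    any pairwise p-distance >= 3/4 (JC undefined), naming the pair.
    """
    seqs = list(aln.matrix)
    names = list(aln.haplotype_ids)
    for label, seq in (outgroup_seqs or {}).items():
        seqs.append(np.asarray(seq, dtype="S1"))
        names.append(label)
    k = len(seqs)
    if k < 3:
        raise ValueError("NJ needs >= 3 sequences")
    D = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            p = _p_distance(seqs[i], seqs[j])
            d = jukes_cantor(p)
            if not np.isfinite(d):
                raise ValueError(
                    f"pairwise distance undefined (p={p:.3f} >= 3/4) between "
                    f"{names[i]!r} and {names[j]!r}"
                )
            D[i, j] = D[j, i] = d
    nodes = [f"{_escape(nm)}" for nm in names]
    active = list(range(k))
    dist = D.copy()
    while len(active) > 2:
        m = len(active)
        sub = dist[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i_loc, j_loc = np.unravel_index(np.argmin(Q), Q.shape)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = dist[i, j]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2.0 * (m - 2))
        lj = dij - li
        # clamp negatives, moving the deficit to the sister edge
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        new_label = f"({nodes[i]}:{li:.6g},{nodes[j]}:{lj:.6g})"
        new_idx = dist.shape[0]
        newrow = 0.5 * (dist[i] + dist[j] - dij)
        dist = np.pad(dist, ((0, 1), (0, 1)))
        dist[new_idx, :new_idx] = newrow
        dist[:new_idx, new_idx] = newrow
        nodes.append(new_label)
        active = [a for a in active if a not in (i, j)] + [new_idx]
    a, b = active
    dab = max(dist[a, b], 0.0)
    return f"({nodes[a]}:{dab / 2:.6g},{nodes[b]}:{dab / 2:.6g});"


def _escape(name: str) -> str:
    if any(ch in name for ch in " ():,;'"):
        return "'" + name.replace("'", "''") + "'"
    return name


def clade_consensus(aln: LocusAlignment, rows: np.ndarray) -> np.ndarray:
    """Per-column majority allele within a clade (ties -> first
    alphabetically); columns with no non-missing member become N."""
    out = np.full(aln.L, b"N", dtype="S1")
    for c in range(aln.L):
        col = aln.matrix[rows, c]
        ok = ~np.isin(col, _MISS)
        if not ok.any():
            continue
        vals, counts = np.unique(col[ok], return_counts=True)
        best = vals[np.lexsort((vals, -counts))][0]
        out[c] = best
    return out


def sliding_kjc(
    clade_consensus_seq: np.ndarray,
    outgroup_seq: np.ndarray,
    window: int = 50,
    step: int = 10,
) -> KjcProfile:
    """Sliding-window Jukes-Cantor corrected divergence along the fragment.

    Windows are physical (monomorphic columns included) at offsets 0, step,
    2*step, ... while start + window <= L; per window p = differing / compared
    sites (missing excluded) and K_JC = -(3/4) ln(1 - 4p/3), NaN (flagged)
    where p >= 3/4.
    """
    a = np.asarray(clade_consensus_seq, dtype="S1")
    b = np.asarray(outgroup_seq, dtype="S1")
    if a.shape != b.shape:
        raise ValueError("sequences must have equal length")
    L = a.shape[0]
    if window > L:
        raise ValueError("window exceeds sequence length")
    starts = np.arange(0, L - window + 1, step)
    ps = np.empty(starts.size)
    ks = np.empty(starts.size)
    for w, s in enumerate(starts):
        p = _p_distance(a[s:s + window], b[s:s + window])
        ps[w] = p
        ks[w] = jukes_cantor(p) if np.isfinite(p) else float("nan")
    return KjcProfile(window=window, step=step, starts=starts, p_distance=ps, kjc=ks)


def phase_confidence_qc(confidence_tables: dict, flag_quantile: float = 0.05) -> pd.DataFrame:
    """Rank loci by phase-reconstruction uncertainty.

    ``confidence_tables`` maps locus id -> array of per-variant-site PHASE
    confidence probabilities in [0.5, 1.0].  Reports, per locus, the
    proportion of sites with confidence < 1 and the mean confidence among
    those sites; loci in the top ``flag_quantile`` by proportion are flagged.
    """
    rows = []
    for locus, conf in confidence_tables.items():
        conf = np.asarray(conf, dtype=float)
        if conf.size and ((conf < 0.5) | (conf > 1.0)).any():
            raise ValueError(f"confidence outside [0.5, 1] at locus {locus!r}")
        sub = conf[conf < 1.0]
        rows.append({
            "locus": locus,
            "n_sites": conf.size,
            "prop_sub_one": sub.size / conf.size if conf.size else 0.0,
            "mean_conf_sub_one": float(sub.mean()) if sub.size else float("nan"),
        })
    df = pd.DataFrame(rows).sort_values("prop_sub_one", ascending=False).reset_index(drop=True)
    n_flag = max(1, int(np.ceil(flag_quantile * len(df)))) if len(df) else 0
    flagged = np.zeros(len(df), dtype=bool)
    if len(df):
        # flag the top quantile, but never loci with zero uncertain sites
        for i in range(n_flag):
            if df.loc[i, "prop_sub_one"] > 0:
                flagged[i] = True
    df["flagged"] = flagged
    return df
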