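"""Synthetic study generator.

Produces complete synthetic studies — population strata x gene fragments with
gene models, phased haplotype alignments, outgroup sequences, metadata and
phase-confidence tables — under stated demographic/selection scenarios, so
the whole scan can be exercised without any field data.

Scenarios modify the genealogy, not the mutation process:

* ``neutral_constant`` — standard coalescent.
* ``growth`` / ``bottleneck`` — piecewise-constant population-size history;
  coalescence rates are scaled by the inverse relative size in each epoch.
* ``complete_sweep`` — lineages surviving to the sweep end time tau are
  forced into a near-simultaneous (star-like) merger, the genealogical
  footprint of a recent fixation.  Each lineage independently escapes the
  merger with probability ``escape_prob`` (default 0.05), representing
  chromosomes that recombined off the selected background while the allele
  swept; escaped lineages coalesce neutrally with the swept ancestor.  The
  escapes are what give a completed sweep its detectable signature: the
  mutations on the swept ancestor's deep branch sit at high derived
  frequency (strongly negative normalized H) while haplotype homozygosity
  stays high.  With ``escape_prob=0`` the genealogy is a pure star and all
  variation is post-sweep singletons.
* ``partial_sweep`` — the star merger applies only to a random fraction f of
  the surviving lineages; the rest coalesce neutrally.
* ``standing_sweep`` — the merger is seeded onto k pre-existing ancestral
  lineages (selection on standing variation), yielding k sharply defined
  haplotype clades separated by older mutations.

Mutations are then dropped on the genealogy at rate theta/2 (theta = 4 N mu
per locus) under infinite sites and mapped onto a random reference sequence;
the functional class of each variant follows from the codon position of the
column it lands on.  An outgroup lineage diverged T_div (2N units) supplies
ancestral states and fixed differences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import coalsim
from .coalsim import Genealogy, SimulatedSample
from .seqdata import Exon, LocusAlignment

__all__ = [
    "ScenarioConfig", "PhaseProfile", "make_reference_gene",
    "simulate_population_sample", "simulate_multipop_study",
    "emit_phase_confidences", "scenario_genealogy",
]

SCENARIOS = ("neutral_constant", "growth", "bottleneck", "complete_sweep",
             "partial_sweep", "standing_sweep")

#: default fragment layout: ~500 bp spanning an intron (two coding exons)
DEFAULT_LENGTH = 500
DEFAULT_EXONS = ((0, 200, 0), (300, 500, 2))


@dataclass
class ScenarioConfig:
    """Demographic/selection scenario for one stratum x locus."""

    scenario: str = "neutral_constant"
    n: int = 50                      # chromosomes sampled
    theta: float = 10.0              # 4 N mu per locus
    length: int = DEFAULT_LENGTH
    exon_layout: tuple = DEFAULT_EXONS
    T_div: float = 2.0               # outgroup divergence, 2N units
    tau: float = 0.01                # sweep end time, 2N units
    escape_prob: float = 0.05        # per-lineage sweep escape (recombination)
    sweep_fraction: float = 0.5      # f, partial sweep
    standing_k: int = 2              # initial haplotype count, standing sweep
    # piecewise-constant history: (epoch start time, relative size); the
    # defaults model a 10x expansion 0.1 x 2N ago (growth) and a 20x crash
    # between 0.02 and 0.07 (bottleneck)
    growth_epochs: tuple = ((0.0, 1.0), (0.1, 0.1))
    bottleneck_epochs: tuple = ((0.0, 1.0), (0.02, 0.05), (0.07, 1.0))
    seed: int | None = None

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if not (0 < self.sweep_fraction <= 1):
            raise ValueError("sweep_fraction must be in (0, 1]")
        if self.tau < 0 or self.T_div < 0:
            raise ValueError("times must be >= 0")


@dataclass
class PhaseProfile:
    """Distribution of per-site PHASE-style confidence probabilities.

    Most sites are phased unambiguously (confidence exactly 1); a fraction
    carries sub-one confidence drawn from a Beta stretched onto [0.5, 1),
    shaped so its mean is ~0.78.
    """

    fraction_sub_one: float = 0.45
    beta_a: float = 2.8
    beta_b: float = 2.2

    def __post_init__(self):
        if not (0 <= self.fraction_sub_one <= 1):
            raise ValueError("fraction_sub_one must be in [0, 1]")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def make_reference_gene(
    length: int = DEFAULT_LENGTH,
    exon_layout=DEFAULT_EXONS,
    gc: float = 0.5,
    seed=None,
) -> tuple[np.ndarray, list[Exon]]:
    """Random reference sequence plus its gene model.

    ``exon_layout`` is a sequence of (start, end[, frame]) tuples; frames
    default to the cumulative spliced reading frame starting at 0.
    """
    rng = _rng(seed)
    exons = []
    pos = 0
    for entry in exon_layout:
        if len(entry) == 3:
            s, e, f = entry
        else:
            s, e = entry
            f = pos % 3
        if e > length:
            raise ValueError(f"exon [{s},{e}) outside fragment of length {length}")
        exons.append(Exon(int(s), int(e), int(f)))
        pos += e - s
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = rng.choice(np.array([b"A", b"C", b"G", b"T"]), size=length, p=p)
    return seq.astype("S1"), exons


# ---------------------------------------------------------------------------
# scenario genealogies
# ---------------------------------------------------------------------------

def _coalesce_epochs(n, rng, epochs):
    """Coalescent with piecewise-constant relative population size.

    ``epochs`` = ((t0, size0), (t1, size1), ...) with t0 = 0; within an epoch
    of relative size s the pair-coalescence rate is 1/s.
    """
    starts = [t for t, _ in epochs]
    sizes = [s for _, s in epochs]
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes)
    masks = [1 << i for i in range(n)] + [0] * (n - 1)
    active = list(range(n))
    t = 0.0
    nxt = n
    k = n
    epoch = 0
    while k > 1:
        rate = k * (k - 1) / 2.0
        while True:
            size = sizes[epoch]
            wait = rng.exponential(size / rate)
            nxt_boundary = starts[epoch + 1] if epoch + 1 < len(starts) else np.inf
            if t + wait <= nxt_boundary:
                t += wait
                break
            t = nxt_boundary
            epoch += 1
        i = rng.integers(k)
        j = rng.integers(k - 1)
        if j >= i:
            j += 1
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        time[nxt] = t
        masks[nxt] = masks[a] | masks[b]
        active[min(i, j)] = nxt
        active.pop(max(i, j))
        nxt += 1
        k -= 1
    return Genealogy(n=n, parent=parent, time=time, clade_mask=masks)


def _partial_tree(n, rng, stop_time):
    """Neutral coalescence until ``stop_time``; returns the partial forest."""
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes)
    masks = [1 << i for i in range(n)] + [0] * (n - 1)
    active = list(range(n))
    t = 0.0
    nxt = n
    k = n
    while k > 1:
        wait = rng.exponential(2.0 / (k * (k - 1)))
        if t + wait >= stop_time:
            t = stop_time
            break
        t += wait
        i = rng.integers(k)
        j = rng.integers(k - 1)
        if j >= i:
            j += 1
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        time[nxt] = t
        masks[nxt] = masks[a] | masks[b]
        active[min(i, j)] = nxt
        active.pop(max(i, j))
        nxt += 1
        k -= 1
    return parent, time, masks, active, nxt, t


def _star_merge(parent, time, masks, lineages, t0, nxt, eps=1e-7):
    """Merge ``lineages`` into one ancestor by near-simultaneous pair mergers
    starting at t0 (tiny eps offsets keep branch lengths positive)."""
    t = t0
    current = list(lineages)
    while len(current) > 1:
        t += eps
        a = current.pop()
        b = current.pop()
        parent[a] = parent[b] = nxt
        time[nxt] = t
        masks[nxt] = masks[a] | masks[b]
        current.append(nxt)
        nxt += 1
    return current[0], nxt, t


def _finish_neutral(parent, time, masks, active, t, nxt, rng):
    k = len(active)
    while k > 1:
        t += rng.exponential(2.0 / (k * (k - 1)))
        i = rng.integers(k)
        j = rng.integers(k - 1)
        if j >= i:
            j += 1
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        time[nxt] = t
        masks[nxt] = masks[a] | masks[b]
        active[min(i, j)] = nxt
        active.pop(max(i, j))
        nxt += 1
        k -= 1
    return Genealogy(n=(len(masks) + 1) // 2, parent=parent, time=time, clade_mask=masks)


def scenario_genealogy(cfg: ScenarioConfig, rng) -> Genealogy:
    """A genealogy realized under the configured scenario."""
    n = cfg.n
    if cfg.scenario == "neutral_constant":
        return coalsim.simulate_genealogy(n, rng)
    if cfg.scenario == "growth":
        return _coalesce_epochs(n, rng, cfg.growth_epochs)
    if cfg.scenario == "bottleneck":
        return _coalesce_epochs(n, rng, cfg.bottleneck_epochs)

    parent, time, masks, active, nxt, t = _partial_tree(n, rng, cfg.tau)
    if cfg.scenario == "complete_sweep":
        escaped = [a for a in active if rng.random() < cfg.escape_prob]
        core = [a for a in active if a not in escaped]
        if len(core) < 2:  # nearly everything escaped: no merger to force
            core, escaped = active, []
        if len(core) > 1:
            anc, nxt, t = _star_merge(parent, time, masks, core, cfg.tau, nxt)
        else:
            anc = core[0]
        return _finish_neutral(parent, time, masks, escaped + [anc], t, nxt, rng)
    if cfg.scenario == "partial_sweep":
        k = len(active)
        m = max(2, int(np.ceil(cfg.sweep_fraction * k)))
        if m >= k:
            m = k
        chosen = list(rng.choice(k, size=m, replace=False))
        swept = [active[i] for i in chosen]
        rest = [active[i] for i in range(k) if i not in chosen]
        if len(swept) > 1:
            anc, nxt, t = _star_merge(parent, time, masks, swept, cfg.tau, nxt)
        else:
            anc = swept[0]
        return _finish_neutral(parent, time, masks, rest + [anc], t, nxt, rng)
    if cfg.scenario == "standing_sweep":
        k = len(active)
        kk = min(cfg.standing_k, k)
        groups = [[] for _ in range(kk)]
        order = rng.permutation(k)
        for rank, idx in enumerate(order):
            groups[rank % kk].append(active[idx])
        ancestors = []
        for grp in groups:
            if len(grp) > 1:
                anc, nxt, t = _star_merge(parent, time, masks, grp, cfg.tau, nxt)
            else:
                anc = grp[0]
            ancestors.append(anc)
        return _finish_neutral(parent, time, masks, ancestors, max(t, cfg.tau), nxt, rng)
    raise ValueError(cfg.scenario)


# ---------------------------------------------------------------------------
# sequence-level simulation
# ---------------------------------------------------------------------------

_OTHER = {b"A": [b"C", b"G", b"T"], b"C": [b"A", b"G", b"T"],
          b"G": [b"A", b"C", b"T"], b"T": [b"A", b"C", b"G"]}


def _apply_mutations(reference, columns, rng):
    """Pick a derived base per column; returns dict col -> derived byte."""
    out = {}
    for c in columns:
        ref = reference[c]
        out[int(c)] = _OTHER[bytes(ref)][rng.integers(3)]
    return out


def simulate_population_sample(
    cfg: ScenarioConfig,
    reference: np.ndarray | None = None,
    gene_model: list[Exon] | None = None,
    seed=None,
    locus_id: str = "locus",
    stratum: str = "M",
    column_pool: list | None = None,
):
    """One stratum's haplotype alignment plus outgroup and truth record.

    Returns (LocusAlignment, outgroup sequence, truth dict).  ``column_pool``
    (a mutable list of available column indices) lets a multi-locus driver
    share one infinite-sites column space between strata at the same locus.
    """
    rng = _rng(seed if seed is not None else cfg.seed)
    if reference is None:
        reference, gene_model = make_reference_gene(cfg.length, cfg.exon_layout, seed=rng)
    g = scenario_genealogy(cfg, rng)
    sample = coalsim.mutate_fixed_theta(g, cfg.theta, rng)
    # outgroup lineage: split T_div ago (stretched to the root if older)
    t_split = max(cfg.T_div, g.t_mrca)
    out_path = 2.0 * t_split - g.t_mrca
    n_out = rng.poisson(cfg.theta / 2.0 * out_path)

    if column_pool is None:
        column_pool = list(rng.permutation(cfg.length))
    need = sample.S + n_out
    if need > len(column_pool):
        raise ValueError(
            f"not enough columns ({len(column_pool)}) for {need} mutations; "
            "increase fragment length or lower theta/T_div"
        )
    cols = [column_pool.pop() for _ in range(need)]
    ingroup_cols = cols[:sample.S]
    outgroup_cols = cols[sample.S:]
    derived = _apply_mutations(reference, ingroup_cols, rng)
    out_derived = _apply_mutations(reference, outgroup_cols, rng)

    mat = np.tile(reference, (cfg.n, 1))
    for j, c in enumerate(ingroup_cols):
        mask = sample.masks[j]
        rows = []
        while mask:
            rows.append((mask & -mask).bit_length() - 1)
            mask &= mask - 1
        mat[rows, c] = derived[c]
    outgroup = reference.copy()
    for c, b in out_derived.items():
        outgroup[c] = b

    n_samples = (cfg.n + 1) // 2
    ids = []
    for i in range(n_samples):
        ids.append(f"{stratum}{i:03d}/1")
        if len(ids) < cfg.n:
            ids.append(f"{stratum}{i:03d}/2")
    aln = LocusAlignment(
        locus_id=locus_id, haplotype_ids=ids[:cfg.n], matrix=mat,
        gene_model=list(gene_model or []),
    )
    truth = {
        "locus": locus_id, "stratum": stratum, "scenario": cfg.scenario,
        "theta": cfg.theta, "n": cfg.n, "S": sample.S,
        "fixed_differences": len(outgroup_cols), "t_mrca": g.t_mrca,
        "tau": cfg.tau, "T_div": cfg.T_div,
    }
    return aln, outgroup, truth


def emit_phase_confidences(
    aln: LocusAlignment,
    profile: PhaseProfile | None = None,
    seed=None,
) -> pd.DataFrame:
    """Per-variant-site confidence table emulating PHASE output.

    The majority of sites get confidence exactly 1.0; a ``fraction_sub_one``
    share draws from 0.5 + 0.5 * Beta(a, b), always within [0.5, 1.0].
    """
    from .sumstats import segregating_sites

    profile = profile or PhaseProfile()
    rng = _rng(seed)
    seg = segregating_sites(aln)
    conf = np.ones(seg.size)
    sub = rng.random(seg.size) < profile.fraction_sub_one
    conf[sub] = 0.5 + 0.5 * rng.beta(profile.beta_a, profile.beta_b, size=int(sub.sum()))
    conf = np.minimum(conf, 1.0 - 1e-12 * sub)  # sub-one stays strictly < 1
    return pd.DataFrame({"locus": aln.locus_id, "column": seg + 1, "confidence": conf})


def _derive_seed(base_seed: int, *parts) -> int:
    """Deterministic per-locus/stratum seed below 2^31 from a study seed."""
    import zlib
    key = "|".join(str(p) for p in parts)
    return (int(base_seed) * 1_000_003 + zlib.crc32(key.encode())) % (2 ** 31 - 1)


def simulate_multipop_study(
    study: dict,
    out_dir: str | Path,
    seed: int = 0,
) -> dict:
    """Write a full study bundle consumable by the pipeline end to end.

    ``study`` maps locus id -> {stratum: ScenarioConfig}.  All strata at a
    locus share one reference and one outgroup; mutation columns are drawn
    from a shared pool so the joint alignment respects infinite sites.
    Emits, under ``out_dir``::

        <locus>.fasta            aligned haplotypes, all strata
        <locus>.outgroup.fasta   outgroup sequence
        gene_models.tsv          locus_id, exon_start, exon_end, frame
        metadata.tsv             sample_id, stratum, karyotype, year
        phase_confidence.tsv     locus, column, confidence
        manifest.json            seeds, scenario truth per locus x stratum

    Returns the manifest dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "loci": {}}
    meta_rows = []
    model_rows = []
    conf_frames = []
    karyotype = {"M": "2La/2La", "S": "2La/2La", "GOUNDRY_aa": "2La/2La",
                 "GOUNDRY_pp": "2L+/2L+"}
    for locus, strata in study.items():
        any_cfg = next(iter(strata.values()))
        ref_rng = _rng(_derive_seed(seed, locus, "reference"))
        reference, gene_model = make_reference_gene(
            any_cfg.length, any_cfg.exon_layout, seed=ref_rng)
        pool = list(ref_rng.permutation(any_cfg.length))
        records = []
        outgroup = None
        manifest["loci"][locus] = {}
        for stratum, cfg in strata.items():
            s = _derive_seed(seed, locus, stratum)
            aln, og, truth = simulate_population_sample(
                cfg, reference, gene_model, seed=s, locus_id=locus,
                stratum=stratum, column_pool=pool,
            )
            truth["seed"] = s
            manifest["loci"][locus][stratum] = truth
            if outgroup is None:
                outgroup = og  # shared outgroup: first stratum's divergence draw
            records.extend(zip(aln.haplotype_ids, aln.matrix))
            for hap in aln.haplotype_ids[::2]:
                sample = hap.rsplit("/", 1)[0]
                meta_rows.append({"sample_id": sample, "stratum": stratum,
                                  "karyotype": karyotype.get(stratum, "NA"),
                                  "year": 2007})
            conf_frames.append(emit_phase_confidences(
                aln, seed=_derive_seed(seed, locus, stratum, "phase")))
        with open(out_dir / f"{locus}.fasta", "w") as fh:
            for hap_id, row in records:
                fh.write(f">{hap_id}\n{b''.join(row).decode()}\n")
        with open(out_dir / f"{locus}.outgroup.fasta", "w") as fh:
            fh.write(f">outgroup\n{b''.join(outgroup).decode()}\n")
        for ex in gene_model:
            model_rows.append({"locus_id": locus, "exon_start": ex.start,
                               "exon_end": ex.end, "frame": ex.frame})
    pd.DataFrame(meta_rows).drop_duplicates("sample_id").to_csv(
        out_dir / "metadata.tsv", sep="\t", index=False)
    pd.DataFrame(model_rows).to_csv(out_dir / "gene_models.tsv", sep="\t", index=False)
    pd.concat(conf_frames).to_csv(out_dir / "phase_confidence.tsv", sep="\t", index=False)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=float)
    return manifest
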