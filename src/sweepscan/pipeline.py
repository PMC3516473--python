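"""Orchestration: the full selection scan and the haplogroup deep-dive.

``run_scan`` drives, per locus x stratum: optional seeded down-sampling to
n_max chromosomes, silent-site extraction, summary statistics, coalescent
null distributions at (n, theta_hat_W), component p-values, the calibrated
compound HEW decision, Benjamini-Hochberg correction, and pairwise F_ST with
permutation significance.  ``run_haplogroup_analysis`` dissects one locus x
stratum: LD matrix, perfect-LD defining sets, haplogroup delineation,
clade-conditioned significance, NJ tree, and sliding Jukes-Cantor divergence.

Null distributions are cached keyed by (n, theta rounded to 3 significant
digits, reps) with seeds derived deterministically from the run seed, so a
scan over many loci at similar diversity reuses most simulations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coalsim, haplostructure, neutrality, popdiff, seqdata, sumstats

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "NullCache", "run_scan", "run_haplogroup_analysis", "load_bundle"]


@dataclass
class RunConfig:
    """Scan configuration (YAML-serializable)."""

    input_dir: str = "."
    loci: list = field(default_factory=list)          # empty = autodiscover
    strata: list = field(default_factory=list)        # empty = all in metadata
    alpha: float = 0.05
    null_reps: int = 100_000
    calibration_reps: int = 2000
    permutations: int = 100_000
    n_max: int = 100
    bh_scope: str = "per-stratum"                     # or "global"
    silent_only: bool = True
    region_by_locus: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.null_reps < 100 or self.permutations < 100:
            raise ValueError("reps and permutations must be >= 100")
        if not (0 < self.alpha < 0.5):
            raise ValueError("alpha must be in (0, 0.5)")
        if self.bh_scope not in ("per-stratum", "global"):
            raise ValueError("bh_scope must be 'per-stratum' or 'global'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _derive_seed(base: int, *parts) -> int:
    import zlib
    key = "|".join(str(p) for p in parts)
    return (int(base) * 1_000_003 + zlib.crc32(key.encode())) % (2 ** 31 - 1)


class NullCache:
    """Cache of coalescent null distributions keyed by
    (n, theta rounded to 3 significant digits, reps)."""

    def __init__(self, reps: int, calibration_reps: int, seed: int):
        self.reps = reps
        self.calibration_reps = calibration_reps
        self.seed = seed
        self._store: dict = {}

    @staticmethod
    def round_theta(theta: float) -> float:
        if theta <= 0:
            return 0.0
        from math import floor, log10
        digits = 2 - int(floor(log10(abs(theta))))
        return round(theta, digits)

    def get(self, n: int, theta: float) -> coalsim.NullDistribution:
        key = (n, self.round_theta(theta), self.reps)
        if key not in self._store:
            s = _derive_seed(self.seed, "null", *key)
            self._store[key] = coalsim.null_distribution(
                n, key[1], self.reps, seed=s,
                calibration_reps=self.calibration_reps,
            )
        return self._store[key]


def load_bundle(input_dir, loci=None):
    """Load a study bundle directory (the format simulate_multipop_study
    writes): alignments, outgroups, gene models, metadata."""
    input_dir = Path(input_dir)
    models = pd.read_csv(input_dir / "gene_models.tsv", sep="\t")
    metadata = pd.read_csv(input_dir / "metadata.tsv", sep="\t")
    if not loci:
        loci = sorted(models["locus_id"].unique())
    bundle = {}
    for locus in loci:
        rows = models[models["locus_id"] == locus]
        gene_model = [seqdata.Exon(int(r.exon_start), int(r.exon_end), int(r.frame))
                      for r in rows.itertuples()]
        aln = seqdata.read_fasta_alignment(
            input_dir / f"{locus}.fasta", gene_model, locus_id=locus)
        outgroup = seqdata.read_outgroup_sequence(input_dir / f"{locus}.outgroup.fasta")
        bundle[locus] = (aln, outgroup)
    return bundle, metadata


def _downsample(aln, hap_ids, n_max, rng):
    if len(hap_ids) <= n_max:
        return hap_ids
    keep = rng.choice(len(hap_ids), size=n_max, replace=False)
    return [hap_ids[i] for i in sorted(keep)]


def run_scan(config: RunConfig, out_dir=None, cache: NullCache | None = None):
    """Run the full scan; returns dict of DataFrames (and writes TSVs + a
    JSON manifest when ``out_dir`` is given).

    Per-locus errors are recorded and the scan continues; raises only if all
    loci fail.  An external :class:`NullCache` may be passed to share null
    distributions across several scans at the same sample sizes.
    """
    rng = np.random.default_rng(_derive_seed(config.seed, "scan"))
    bundle, metadata = load_bundle(config.input_dir, config.loci)
    if cache is None:
        cache = NullCache(config.null_reps, config.calibration_reps, config.seed)

    stat_rows, hew_rows, fst_rows, errors = [], [], [], []
    for locus, (aln, outgroup) in bundle.items():
        try:
            partition = seqdata.attach_metadata(aln, metadata)
            tracks = seqdata.build_site_tracks(aln, outgroup)
            strata = config.strata or partition.strata
            sub_ids = {}
            for stratum in strata:
                haps = [h for h in aln.haplotype_ids
                        if partition.assignment.get(h) == stratum]
                if len(haps) < 2:
                    continue
                ds_rng = np.random.default_rng(
                    _derive_seed(config.seed, "downsample", locus, stratum))
                sub_ids[stratum] = _downsample(aln, haps, config.n_max, ds_rng)
            sub_partition = seqdata.PopulationPartition(
                assignment={h: s for s, ids in sub_ids.items() for h in ids},
                counts={s: len(ids) for s, ids in sub_ids.items()},
            )
            keep_rows = [h for ids in sub_ids.values() for h in ids]
            sub_aln = aln.subset_rows(keep_rows)
            records = sumstats.summarize_locus(
                sub_aln, sub_partition, tracks, silent_only=config.silent_only)
            for rec in records:
                stat_rows.append(asdict_shallow(rec))
                if rec.S == 0 or rec.theta_w_per_site == 0:
                    hew_rows.append({
                        "locus": locus, "stratum": rec.stratum, "p_H": np.nan,
                        "p_EW": np.nan, "p_D": np.nan, "threshold": np.nan,
                        "compound_p": np.nan, "reject": False,
                    })
                    continue
                theta_hat = rec.theta_w_per_site * rec.L_analyzed
                null = cache.get(rec.n, theta_hat)
                p_H, p_EW, p_D = neutrality.component_pvalues(rec, null)
                t = neutrality.calibrate_hew_threshold(
                    null.calibration_pairs, config.alpha)
                res = neutrality.hew_test(p_H, p_EW, t, null.calibration_pairs,
                                          locus=locus, stratum=rec.stratum)
                hew_rows.append({
                    "locus": locus, "stratum": rec.stratum, "p_H": p_H,
                    "p_EW": p_EW, "p_D": p_D, "threshold": t,
                    "compound_p": res.compound_p, "reject": res.reject,
                })
            # pairwise F_ST on the silent sub-alignment
            silent = seqdata.silent_subalignment(sub_aln, tracks.site_class)
            strata_here = sorted(sub_ids)
            for i in range(len(strata_here)):
                for j in range(i + 1, len(strata_here)):
                    a, b = strata_here[i], strata_here[j]
                    alnA = silent.subset_rows(sub_ids[a])
                    alnB = silent.subset_rows(sub_ids[b])
                    fr = popdiff.fst_permutation_test(
                        alnA, alnB, n_perm=config.permutations,
                        seed=_derive_seed(config.seed, "fst", locus, a, b),
                        locus=locus, alpha=config.alpha)
                    fst_rows.append({
                        "locus": locus, "pair": f"{a}-{b}", "fst": fr.fst,
                        "p": fr.p_value, "significant": fr.significant,
                        "region": config.region_by_locus.get(locus, aln.chrom_region),
                    })
        except Exception as exc:  # keep scanning other loci
            logger.exception("locus %s failed", locus)
            errors.append({"locus": locus, "error": str(exc)})
    if errors and not stat_rows:
        raise RuntimeError(f"all loci failed; first error: {errors[0]}")

    hew = pd.DataFrame(hew_rows)
    if len(hew):
        if config.bh_scope == "per-stratum":
            hew["corrected_p"] = np.nan
            for s, idx in hew.groupby("stratum").groups.items():
                hew.loc[idx, "corrected_p"] = neutrality.bh_adjust(
                    hew.loc[idx, "compound_p"].to_numpy())
        else:
            hew["corrected_p"] = neutrality.bh_adjust(hew["compound_p"].to_numpy())
        hew["reject_corrected"] = (hew["corrected_p"] < config.alpha).fillna(False)
    results = {
        "summary": pd.DataFrame(stat_rows),
        "hew": hew,
        "fst": pd.DataFrame(fst_rows),
        "errors": pd.DataFrame(errors),
    }
    if len(results["fst"]):
        results["fst_by_region"] = (
            results["fst"].groupby(["region", "pair"])["fst"].mean().reset_index())
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, df in results.items():
            df.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
        manifest = {
            "config": {k: v for k, v in asdict(config).items()},
            "n_loci": len(bundle),
            "null_cache_keys": [list(map(float, k[:2])) + [k[2]]
                                for k in cache._store],
        }
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
    return results


def asdict_shallow(rec) -> dict:
    d = dict(rec.__dict__)
    d["notes"] = "; ".join(d.get("notes") or [])
    return d


def run_haplogroup_analysis(
    config: RunConfig,
    locus: str,
    stratum: str,
    out_dir=None,
    min_sites: int = 3,
    max_recombinants: int = 2,
    conditioned_reps: int = 2000,
    window: int = 50,
    step: int = 10,
):
    """Haplogroup deep-dive for one locus x stratum.

    Returns a report dict: LD matrix, defining-site sets, haplogroup
    partition, per-clade statistics with clade-conditioned p-values, a NJ
    Newick string including the outgroup, and sliding K_JC profiles per
    clade.  If no qualifying defining set exists the report says so and the
    remaining analyses are skipped.
    """
    bundle, metadata = load_bundle(config.input_dir, [locus])
    aln, outgroup = bundle[locus]
    partition = seqdata.attach_metadata(aln, metadata)
    haps = [h for h in aln.haplotype_ids if partition.assignment.get(h) == stratum]
    if len(haps) < 4:
        raise ValueError(f"stratum {stratum!r} has too few haplotypes at {locus!r}")
    sub = aln.subset_rows(haps)
    tracks = seqdata.build_site_tracks(sub, outgroup)

    report: dict = {"locus": locus, "stratum": stratum, "n": sub.n}
    ld = haplostructure.ld_r2_matrix(sub)
    report["ld"] = ld
    sets = haplostructure.find_perfect_ld_sites(
        ld, sub, min_sites=min_sites, max_recombinants=max_recombinants)
    report["defining_sets"] = sets
    if not sets:
        report["haplogroups"] = None
        report["message"] = "no qualifying perfect-LD defining set found"
        return report
    hg = haplostructure.delineate_haplogroups(sub, sets[0]["sites"])
    report["haplogroups"] = hg
    if hg.error:
        report["message"] = hg.error
        return report

    seg = sumstats.segregating_sites(sub)
    S_total = int(seg.size)
    clade_obs = {}
    for lab in ("A", "B"):
        rows = hg.members(lab)
        clade = sub.subset_rows([sub.haplotype_ids[i] for i in rows])
        S_c = int(sumstats.segregating_sites(clade).size)
        h_c, F_c = sumstats.ew_homozygosity(clade)
        pi_c = sumstats.mean_pairwise_differences(clade)
        clade_obs[lab] = {"h": h_c, "S": S_c, "pi": pi_c}
    report["clade_stats"] = clade_obs

    clade_size = hg.clade_sizes["B"]
    n_eff = hg.clade_sizes["A"] + hg.clade_sizes["B"]
    try:
        cond = coalsim.clade_conditioned_sample(
            n_eff, clade_size, max(S_total, 1), conditioned_reps,
            seed=_derive_seed(config.seed, "cond", locus, stratum))
        report["clade_pvalues"] = neutrality.clade_diversity_test(clade_obs, cond)
        report["acceptance_rate"] = cond.acceptance_rate
    except (RuntimeError, ValueError) as exc:
        report["clade_pvalues"] = None
        report["message"] = f"clade-conditioned sampling unavailable: {exc}"

    report["newick"] = haplostructure.nj_tree(sub, {"outgroup": outgroup})
    profiles = {}
    for lab in ("A", "B"):
        cons = haplostructure.clade_consensus(sub, hg.members(lab))
        profiles[lab] = haplostructure.sliding_kjc(cons, outgroup, window, step)
    report["kjc"] = profiles

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / f"{locus}.{stratum}.nwk", "w") as fh:
            fh.write(report["newick"] + "\n")
        rows = []
        for lab, prof in profiles.items():
            for s, p, k in zip(prof.starts, prof.p_distance, prof.kjc):
                rows.append({"clade": lab, "start": int(s),
                             "end": int(s) + window, "p": p, "kjc": k})
        pd.DataFrame(rows).to_csv(out_dir / f"{locus}.{stratum}.kjc.tsv",
                                  sep="\t", index=False)
        summary = {
            "clade_sizes": hg.clade_sizes,
            "fixed_differences": hg.fixed_differences,
            "defining_sites": sets[0]["sites"].tolist(),
            "clade_stats": clade_obs,
            "clade_pvalues": report.get("clade_pvalues"),
        }
        with open(out_dir / f"{locus}.{stratum}.haplogroups.json", "w") as fh:
            json.dump(summary, fh, indent=1, default=float)
    return report
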