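"""Aligned haplotype data: reading, validation, site classification, polarization.

The sampling unit throughout is the phased chromosome (haplotype), not the
diploid individual.  Alignments are per-locus multiple sequence alignments of
~500 bp PCR fragments; each fragment carries a gene model (exon intervals with
reading-frame offsets) so that coding columns can be split into synonymous and
nonsynonymous classes.  "Silent" sites — synonymous plus noncoding — are the
default basis for the neutrality statistics downstream.

Coordinates are 0-based half-open internally; log messages use 1-based column
numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset(b"ACGTN-")
#: Codes treated as missing data in a haplotype entry.
MISSING = frozenset(b"N-")

CHROM_REGIONS = ("inside_2La", "near_2La", "collinear_2L", "other_arm")
STRATA = ("M", "S", "GOUNDRY_aa", "GOUNDRY_pp")

SITE_SYNONYMOUS = "synonymous"
SITE_NONSYNONYMOUS = "nonsynonymous"
SITE_NONCODING = "noncoding"
SITE_EXCLUDED = "excluded"

POL_POLARIZED = "polarized"
POL_UNPOLARIZABLE = "unpolarizable"
POL_MONOMORPHIC = "monomorphic"
POL_FIXED_DIFF = "fixed_difference"

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


class AlignmentError(ValueError):
    """Raised for malformed or mutually inconsistent alignment inputs."""


class GeneModelError(ValueError):
    """Raised when exon intervals or frames are invalid."""


@dataclass(frozen=True)
class Exon:
    """Exon interval in alignment coordinates, 0-based half-open.

    ``frame`` is the offset of the exon's first column within its codon
    (0 = first codon position).
    """

    start: int
    end: int
    frame: int = 0

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise GeneModelError(f"invalid exon interval [{self.start}, {self.end})")
        if self.frame not in (0, 1, 2):
            raise GeneModelError(f"frame must be 0, 1 or 2, got {self.frame}")


@dataclass
class LocusAlignment:
    """Columns x phased haplotypes for one gene fragment."""

    locus_id: str
    haplotype_ids: list[str]
    matrix: np.ndarray  # (n_haplotypes, L), dtype 'S1', uppercase
    gene_model: list[Exon] = field(default_factory=list)
    chrom_region: str = "other_arm"
    #: maps each column back to the coordinate system of the source alignment
    column_map: np.ndarray | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype="S1")
        if self.matrix.ndim != 2:
            raise AlignmentError("haplotype matrix must be 2-D")
        if len(self.haplotype_ids) != self.matrix.shape[0]:
            raise AlignmentError("haplotype_ids length does not match matrix rows")
        if len(set(self.haplotype_ids)) != len(self.haplotype_ids):
            raise AlignmentError("haplotype_ids are not unique")
        if self.chrom_region not in CHROM_REGIONS:
            raise AlignmentError(f"unknown chrom_region {self.chrom_region!r}")
        bad = ~np.isin(self.matrix, [bytes([c]) for c in b"ACGTN-"])
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise AlignmentError(
                f"illegal character {self.matrix[i, j]!r} in record "
                f"{self.haplotype_ids[i]!r} at column {j + 1}"
            )
        prev_end = -1
        for ex in sorted(self.gene_model, key=lambda e: e.start):
            if ex.start < prev_end:
                raise GeneModelError("exon intervals overlap")
            if ex.end > self.L:
                raise GeneModelError(f"exon [{ex.start},{ex.end}) exceeds alignment length {self.L}")
            prev_end = ex.end
        self.gene_model = sorted(self.gene_model, key=lambda e: e.start)
        if self.column_map is None:
            self.column_map = np.arange(self.L)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def L(self) -> int:
        return self.matrix.shape[1]

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, L): True where the entry is N or a gap."""
        return np.isin(self.matrix, [b"N", b"-"])

    def subset_rows(self, ids: list[str]) -> "LocusAlignment":
        index = {h: i for i, h in enumerate(self.haplotype_ids)}
        missing = [h for h in ids if h not in index]
        if missing:
            raise AlignmentError(f"haplotype id(s) not in alignment: {missing[:3]}")
        rows = [index[h] for h in ids]
        return replace(self, haplotype_ids=list(ids), matrix=self.matrix[rows],
                       column_map=self.column_map.copy())

    def subset_columns(self, cols: np.ndarray) -> "LocusAlignment":
        cols = np.asarray(cols, dtype=int)
        keep_exons = []  # gene model does not survive column subsetting
        return LocusAlignment(
            locus_id=self.locus_id,
            haplotype_ids=list(self.haplotype_ids),
            matrix=self.matrix[:, cols],
            gene_model=keep_exons,
            chrom_region=self.chrom_region,
            column_map=self.column_map[cols],
        )


@dataclass
class PopulationPartition:
    """Assignment of haplotypes to population strata with per-stratum counts."""

    assignment: dict[str, str]  # haplotype_id -> stratum
    counts: dict[str, int]
    dropped: list[str] = field(default_factory=list)

    def haplotypes_in(self, stratum: str) -> list[str]:
        return [h for h, s in self.assignment.items() if s == stratum]

    @property
    def strata(self) -> list[str]:
        return sorted(self.counts)


@dataclass
class SiteTracks:
    """Per-column functional class and ancestral/derived polarity."""

    site_class: np.ndarray  # (L,) object array of class labels
    status: np.ndarray  # (L,) polarity status labels
    ancestral: np.ndarray  # (L,) dtype S1; b'?' where unknown
    derived: np.ndarray  # (L,) dtype S1; b'?' where unknown/absent

    def silent_columns(self) -> np.ndarray:
        return np.flatnonzero(
            (self.site_class == SITE_SYNONYMOUS) | (self.site_class == SITE_NONCODING)
        )


def read_fasta_alignment(
    path,
    gene_model: list[Exon] | None = None,
    locus_id: str | None = None,
    chrom_region: str = "other_arm",
) -> LocusAlignment:
    """Read an aligned FASTA into a validated :class:`LocusAlignment`.

    All records must have equal length; lowercase is normalized to uppercase;
    allele codes outside ``{A,C,G,T,N,-}`` raise with the record id and 1-based
    column.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no records in {path}")
    ids = [r.id for r in records]
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        bad = [r.id for r in records if len(r.seq) != len(records[0].seq)]
        raise AlignmentError(
            f"records have unequal lengths in {path}; e.g. {bad[0]!r} "
            f"(lengths seen: {sorted(lengths)})"
        )
    mat = np.array([list(str(r.seq).upper().encode()) for r in records], dtype=np.uint8)
    mat = mat.view("S1").reshape(len(records), -1)
    return LocusAlignment(
        locus_id=locus_id or str(path),
        haplotype_ids=ids,
        matrix=mat,
        gene_model=list(gene_model or []),
        chrom_region=chrom_region,
    )


def read_outgroup_sequence(path) -> np.ndarray:
    """Read a single outgroup sequence as a (L,) S1 array (first FASTA record)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no records in {path}")
    seq = str(records[0].seq).upper().encode()
    return np.frombuffer(seq, dtype="S1").copy()


def sample_id_of(haplotype_id: str) -> str:
    """``sample/1`` and ``sample/2`` both map to ``sample``."""
    return haplotype_id.rsplit("/", 1)[0]


def attach_metadata(aln: LocusAlignment, table) -> PopulationPartition:
    """Build a :class:`PopulationPartition` from a sample metadata table.

    ``table`` is a pandas DataFrame with columns ``sample_id`` and ``stratum``
    (extra columns such as karyotype and year are ignored here).  Haplotypes
    of samples whose stratum is empty/"unassigned" are dropped and logged;
    a haplotype whose sample has no row at all is an error.
    """
    import pandas as pd  # local import keeps module import light

    df = pd.DataFrame(table)
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise AlignmentError(f"duplicate metadata row for sample {dup!r}")
    stratum_of = dict(zip(df["sample_id"], df["stratum"]))

    assignment: dict[str, str] = {}
    dropped: list[str] = []
    for hap in aln.haplotype_ids:
        sample = sample_id_of(hap)
        if sample not in stratum_of:
            raise AlignmentError(f"no metadata row for haplotype {hap!r} (sample {sample!r})")
        stratum = stratum_of[sample]
        if stratum is None or (isinstance(stratum, float) and np.isnan(stratum)) \
                or str(stratum).lower() in ("", "unassigned", "na", "nan"):
            dropped.append(hap)
            logger.info("dropping haplotype %s: sample unassigned to a stratum", hap)
            continue
        stratum = str(stratum)
        if stratum not in STRATA:
            raise AlignmentError(f"unknown stratum label {stratum!r} for sample {sample!r}")
        assignment[hap] = stratum
    counts: dict[str, int] = {}
    for s in assignment.values():
        counts[s] = counts.get(s, 0) + 1
    return PopulationPartition(assignment=assignment, counts=counts, dropped=dropped)


def _column_alleles(col: np.ndarray) -> list[bytes]:
    """Distinct non-missing alleles in a column, sorted for determinism."""
    seen = set(col.tolist()) - {b"N", b"-"}
    return sorted(seen)


def _spliced_coding_columns(gene_model: list[Exon], L: int) -> np.ndarray:
    cols = []
    for ex in gene_model:
        cols.extend(range(ex.start, min(ex.end, L)))
    return np.asarray(cols, dtype=int)


def classify_sites(aln: LocusAlignment, reference_row: str | int = 0) -> np.ndarray:
    """Classify every column as synonymous / nonsynonymous / noncoding / excluded.

    Exon columns are judged per codon of the spliced coding sequence against
    the designated reference haplotype: an observed biallelic substitution
    whose two codons encode the same amino acid is synonymous, a different one
    nonsynonymous.  Monomorphic coding columns (nothing observed to judge) are
    called synonymous only when every possible substitution at the position is
    synonymous (fourfold-degenerate reference codon).  Columns in codons whose
    reference bases include N or gaps, or columns with more than two alleles,
    are excluded.  Columns outside exons are noncoding.
    """
    if isinstance(reference_row, str):
        try:
            ref_idx = aln.haplotype_ids.index(reference_row)
        except ValueError:
            raise AlignmentError(f"reference haplotype {reference_row!r} not found") from None
    else:
        ref_idx = int(reference_row)
    ref = aln.matrix[ref_idx]

    classes = np.full(aln.L, SITE_NONCODING, dtype=object)
    coding_cols = _spliced_coding_columns(aln.gene_model, aln.L)
    if coding_cols.size == 0:
        return classes

    # validate declared frames against the cumulative spliced position
    pos = aln.gene_model[0].frame
    for k, ex in enumerate(aln.gene_model):
        if k > 0 and ex.frame != pos % 3:
            raise GeneModelError(
                f"exon starting at {ex.start} declares frame {ex.frame}, "
                f"but cumulative coding position implies {pos % 3}"
            )
        pos += ex.end - ex.start
    if any(ref[c] in (b"-",) for c in coding_cols):
        raise AlignmentError("reference haplotype has gaps inside exons")

    offset = aln.gene_model[0].frame
    # pad the front so codons align; padded positions never classified
    spliced = [-1] * offset + coding_cols.tolist()
    for c0 in range(0, len(spliced) - 2, 3):
        codon_cols = spliced[c0:c0 + 3]
        if len(codon_cols) < 3:
            break
        real = [c for c in codon_cols if c >= 0]
        ref_codon = [ref[c].decode() if c >= 0 else "N" for c in codon_cols]
        if any(b in "N-" for b in ref_codon):
            for c in real:
                classes[c] = SITE_EXCLUDED
            continue
        ref_aa = _CODON_TABLE["".join(ref_codon)]
        for k, c in enumerate(codon_cols):
            if c < 0:
                continue
            alleles = _column_alleles(aln.matrix[:, c])
            if len(alleles) > 2:
                classes[c] = SITE_EXCLUDED
            elif len(alleles) == 2:
                aas = set()
                for a in alleles:
                    codon = list(ref_codon)
                    codon[k] = a.decode()
                    aas.add(_CODON_TABLE["".join(codon)])
                classes[c] = SITE_SYNONYMOUS if len(aas) == 1 else SITE_NONSYNONYMOUS
            else:
                # monomorphic (or all-missing): class by full degeneracy
                aas = set()
                for b in "ACGT":
                    codon = list(ref_codon)
                    codon[k] = b
                    aas.add(_CODON_TABLE["".join(codon)])
                classes[c] = SITE_SYNONYMOUS if len(aas) == 1 else SITE_NONSYNONYMOUS
    # trailing partial codon: leave as-is? columns covered above only when a
    # full codon exists; any coding column not touched becomes excluded.
    touched = set(np.flatnonzero(classes != SITE_NONCODING).tolist())
    for c in coding_cols:
        if c not in touched:
            classes[c] = SITE_EXCLUDED
    return classes


def polarize_sites(aln: LocusAlignment, outgroup_seq: np.ndarray) -> SiteTracks:
    """Polarize alleles against the outgroup; returns a full :class:`SiteTracks`
    with ``site_class`` unset (fill via :func:`classify_sites` or pass tracks
    through :func:`build_site_tracks`).

    At each biallelic column, if the outgroup allele equals one segregating
    allele, that allele is ancestral and the other derived; otherwise the
    column is unpolarizable.  Columns monomorphic in-sample but differing from
    a valid outgroup base are recorded as fixed differences (divergence for
    HKA).  Columns with >2 in-sample alleles are unpolarizable.
    """
    outgroup_seq = np.asarray(outgroup_seq, dtype="S1")
    if outgroup_seq.shape[0] != aln.L:
        raise AlignmentError(
            f"outgroup length {outgroup_seq.shape[0]} != alignment length {aln.L}"
        )
    L = aln.L
    status = np.full(L, POL_MONOMORPHIC, dtype=object)
    ancestral = np.full(L, b"?", dtype="S1")
    derived = np.full(L, b"?", dtype="S1")
    for c in range(L):
        alleles = _column_alleles(aln.matrix[:, c])
        out = outgroup_seq[c]
        out_ok = out not in (b"N", b"-")
        if len(alleles) == 0:
            status[c] = POL_MONOMORPHIC
        elif len(alleles) == 1:
            if out_ok and out != alleles[0]:
                status[c] = POL_FIXED_DIFF
                ancestral[c] = out
                derived[c] = alleles[0]
            else:
                status[c] = POL_MONOMORPHIC
                ancestral[c] = alleles[0] if not out_ok else out
        elif len(alleles) == 2:
            if out_ok and out in alleles:
                status[c] = POL_POLARIZED
                ancestral[c] = out
                derived[c] = alleles[0] if alleles[1] == out else alleles[1]
            else:
                status[c] = POL_UNPOLARIZABLE
        else:
            status[c] = POL_UNPOLARIZABLE
    return SiteTracks(
        site_class=np.full(L, SITE_NONCODING, dtype=object),
        status=status,
        ancestral=ancestral,
        derived=derived,
    )


def build_site_tracks(
    aln: LocusAlignment,
    outgroup_seq: np.ndarray,
    reference_row: str | int = 0,
) -> SiteTracks:
    """Convenience: classification + polarization in one :class:`SiteTracks`."""
    tracks = polarize_sites(aln, outgroup_seq)
    tracks.site_class = classify_sites(aln, reference_row)
    return tracks


def silent_subalignment(aln: LocusAlignment, site_class: np.ndarray) -> LocusAlignment:
    """Columns with class synonymous or noncoding, with a coordinate map back
    to the source alignment (strictly increasing)."""
    cols = np.flatnonzero(
        (site_class == SITE_SYNONYMOUS) | (site_class == SITE_NONCODING)
    )
    return aln.subset_columns(cols)


def derived_count(aln: LocusAlignment, tracks: SiteTracks, col: int,
                  rows: np.ndarray | None = None) -> tuple[int, int]:
    """(derived count, non-missing count) at a polarized column, over ``rows``."""
    column = aln.matrix[:, col] if rows is None else aln.matrix[rows, col]
    ok = ~np.isin(column, [b"N", b"-"])
    nd = int(np.count_nonzero(column[ok] == tracks.derived[col]))
    return nd, int(np.count_nonzero(ok))
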