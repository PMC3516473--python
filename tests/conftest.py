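import numpy as np
import pytest

from sweepscan.seqdata import Exon, LocusAlignment


def make_alignment(seqs, ids=None, gene_model=None, locus_id="locus"):
    """Build a LocusAlignment from python strings."""
    ids = ids or [f"h{i}" for i in range(len(seqs))]
    mat = np.array([list(s) for s in seqs], dtype="S1")
    return LocusAlignment(locus_id=locus_id, haplotype_ids=ids, matrix=mat,
                          gene_model=list(gene_model or []))


@pytest.fixture
def mkaln():
    return make_alignment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def coding_alignment():
    """Ten-column fragment: exon [0, 6) in frame 0, intron [6, 10).

    Reference codons GCT-ACT (Ala, Thr); haplotypes carry a synonymous
    variant at column 2 (GCT<->GCC), a nonsynonymous one at column 3
    (ACT<->CCT), and an intronic variant at column 7.
    """
    seqs = [
        "GCTACTAAAA",
        "GCCACTAGAA",
        "GCTCCTAAAA",
        "GCCACTAGAA",
    ]
    return make_alignment(seqs, gene_model=[Exon(0, 6, 0)])
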