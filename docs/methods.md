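# Methods

This note records the models, estimators and numerical conventions behind
`sweepscan`, the choices made where the design was genuinely open, and what
the synthetic data do and do not establish about real samples.

## Data model

The unit of observation is the phased chromosome. A locus is a multiple
sequence alignment of ~500 bp haplotypes with a gene model (exon intervals
carrying reading-frame offsets, 0-based half-open in alignment
coordinates), one outgroup sequence, and a sample-metadata table assigning
each individual to one population stratum (M, S, GOUNDRY 2La a/a, GOUNDRY
2La +/+). Entries `N`/`-` are treated as missing per haplotype; a column is
segregating only on its non-missing entries.

### Site classification

Coding columns are judged per codon of the spliced CDS against a designated
reference haplotype: an observed biallelic substitution is synonymous iff
both codons translate identically. Columns outside exons are noncoding;
columns in codons whose reference bases include N or gaps, or with more
than two alleles, are excluded. Monomorphic coding columns carry no
substitution to judge; they are classed synonymous only when the position
is fourfold degenerate in the reference codon, else nonsynonymous. This is
a deliberate convention (it makes the silent length L a property of the
reference sequence, not of the variation) and differs from fractional
site-counting schemes; since the same convention scales both numerator and
denominator of per-site statistics within a study, comparisons across
strata are unaffected. "Silent" = synonymous + noncoding; all neutrality
statistics default to the silent sub-alignment.

### Polarization

At a biallelic column, the allele matching the outgroup is ancestral, the
other derived. Columns where the outgroup matches neither allele, has
N/gap, or where the sample carries >2 alleles are unpolarizable: excluded
from the unfolded SFS (hence from H and θ_L) but retained for π, θ_W, D and
haplotype statistics, which need no polarity. Columns monomorphic in-sample
but differing from the outgroup are fixed differences, the divergence
counts D_i used by HKA.

## Summary statistics

Per stratum on the silent sub-alignment: n, S, θ_W/site = S/(a_n·L), π/site
(pairwise-complete over missing data), Tajima's D with the 1989 constants,
the normalized Fay & Wu H (variance from θ̂ = S/a_n and
θ̂² = S(S−1)/(a_n²+b_n); the exact identity θ_π + θ_H = 2θ_L is asserted in
tests), and Ewens–Watterson homozygosity F = Σp_k² with the haplotype count
h. Haplotypes with missing calls at any segregating column are dropped from
h/F (deterministic and conservative; phased inputs are normally complete).
n = 2 leaves the H normalizing variance zero; the statistic is reported
undefined. Strata with S = 0 are recorded with undefined D and H.

## Coalescent nulls

The null simulator is the standard n-coalescent without recombination
(short fragments; assuming no recombination makes haplotype-based tests
conservative): waiting times Exp(k(k−1)/2) in units of 2N generations,
uniformly random pair merges, infinite-sites mutations at rate θ/2 per
lineage per unit so E[S] = θ·a_n with θ = 4Nμ per locus. Closed-form moment
checks (E[T_MRCA(2)] = 1, E[L] = 2a_n, E[S], E[π], E[S_i] = θ/i) and a
two-sample KS comparison of Tajima's D against msprime are part of the test
suite. Fixed-S mutation (branches weighted by length) serves the
clade-conditioned analyses; note that under fixed-S the expected spectrum
is E[l_i/L], which differs measurably from the fixed-θ ratio (1/i)/a_n —
both behaviors are pinned by tests against an independently coded
simulator.

Null distributions of (D, H, F) are simulated at (n, θ̂_W) per locus,
excluding S = 0 replicates from p-value denominators, and cached keyed by
(n, θ̂ rounded to 3 significant digits, reps) with seeds derived
deterministically from the run seed — a scan over many loci of similar
diversity reuses most simulations. All Monte-Carlo p-values carry the
add-one (r+1)/(m+1) correction.

## The compound HEW decision

p_H is left-tailed (sweeps push H negative), p_EW right-tailed (sweeps push
homozygosity up), p_D two-tailed. Since "reject iff both p ≤ t" is the
event {max(p_H, p_EW) ≤ t}, the calibrated threshold is the largest
empirical quantile of the max-component over ≥1000 calibration pairs
(simulated independently of the test nulls) whose CDF does not exceed α;
the compound p-value is the add-one rank of the observed max-component in
that calibration sample. This max-rank definition is our own (the source
procedure defers to its citation without printing a formula); it is
monotone in the decision rule, so thresholding the compound p at α
reproduces the joint decision. Empirical size on neutral data is checked at
500 loci (t-style calibration experiment); the empirically calibrated size
is also what `scripts/acceptance.py` reports. The EW component's p-value is
conservative at small n because F is discrete with large atoms; the test
suite therefore checks uniformity of the tie-randomized p.

Multiple testing uses Benjamini–Hochberg (statsmodels' step-up), by default
within stratum (switchable to a global family): the four strata are
separate populations asking separate questions.

## HKA

One population plus one outgroup, divergence only (no outgroup
polymorphism): solve θ_i(a_{n_i} + T + 1) = S_i + D_i per locus together
with (T+1)Σθ_i = ΣD_i by fixed-point iteration, then
X² = Σ[(S_i−E[S_i])²/Var(S_i) + (D_i−E[D_i])²/Var(D_i)] with
Var(S_i) = E[S_i] + (θ_iL_i)²b_{n_i} and Var(D_i) = E[D_i] + (θ_iL_i)²
(the (θL)² terms are the ancestral-coalescent contributions; the "+1" in
E[D] is the expected 2N of ancestral lineage coalescence). Significance is
the add-one fraction of simulations under the fitted model — genealogy-based
S_i and D_i ~ Poisson(θ_iL_i(T + Exp(1))) — with X² at least the observed.
The moment system matches an independent `fsolve` of the same equations to
1e-6; the simulation p is approximately uniform under re-simulation from
the fitted model. No claim of bit-identity with other HKA programs is made;
relative population size of the outgroup is not modeled. A helper picks the
nearest non-significant upstream/downstream neighbors of a focal locus by
map order for the local three-locus comparisons.

## Differentiation

Weir–Cockerham variance components for haploid samples (phased chromosomes
are the sampling unit; the diploid heterozygosity component is absent):
per site and allele, a = (MSA − MSW)/n_c among populations and b = MSW
within, summed over alleles, with the multi-site estimate Σa/Σ(a+b) (ratio
of sums — stable for short fragments). Sites monomorphic overall, or with
fewer than two usable chromosomes in either sample, contribute nothing.
Significance: population labels permuted across the pooled haplotypes
preserving group sizes, p = (1+#{F* ≥ F_obs})/(n_perm+1). Shared
polymorphism between strata is rarefaction-corrected: both samples are
repeatedly down-sampled to a common size and the proportion of A's
segregating sites also segregating in B is averaged (the "sample-size
correction" is unspecified in the source; rarefaction is our reading).

## Haplogroups, trees, divergence profiles

r² between biallelic sites is computed from phased haplotype frequencies,
pairwise-complete over missing. Perfect-LD defining sets are found by
greedy clustering of sites whose bipartitions agree (up to allele
relabeling) on at least n − max_recombinants haplotypes; haplotypes
conflicting with the majority pattern at the defining sites are A*
recombinants, excluded from clade statistics. A is the larger clade.
Clade-conditioned significance re-simulates genealogies, accepting those
containing an internal edge subtending exactly the observed clade size
(tolerance configurable; "similar clade structure" is otherwise undefined),
drops exactly S mutations, and compares clade-wise h, S and Π left-tailed.
Deficits are statistically detectable mainly in the larger clade — the
smaller conditioned clade is often variation-free under the neutral null
itself, which mirrors how such tables look in practice. Observed Π must be
passed unscaled (mean pairwise difference count) to be commensurable with
the abstract-site simulations.

NJ trees use Saitou–Nei on Jukes–Cantor distances (pairwise-complete
p-distances; p ≥ 3/4 is an error naming the pair). Negative branch lengths
are clamped to zero with the deficit moved to the sister edge. JC replaces
composite-likelihood distances used by desktop phylogenetics suites — at
within-complex divergences the topologies agree, and topology is what the
haplogroup argument consumes. Sliding K_JC uses physical windows (window
50 bp, step 10 bp, start+window ≤ L ⇒ (L−window)/step + 1 windows) on the
clade consensus (per-column majority, ties to the alphabetically first
base) versus the outgroup; windows with p ≥ 3/4 are flagged undefined.

Phase-confidence QC ranks loci by the proportion of variant sites whose
phasing confidence is below one and flags the top 5% (configurable); a
locus with no uncertain sites is never flagged.

## Synthetic studies

The generator emulates the study shape: four strata × many ~500 bp
fragments, two coding exons flanking an intron (layout (0,200) + (300,500)
by default), an outgroup at divergence T_div = 2.0 × 2N (giving
divergence-to-diversity ratios of the magnitude seen between *A. gambiae*
and *A. merus* at silent sites), and per-locus θ defaulting to 10 (0.02/site
at 500 bp, inside the 0.011–0.037 silent-θ range of the field samples;
sample sizes 56–170 chromosomes per stratum in full-study configurations,
n = 50 in the calibration experiments). Scenarios act on the genealogy
only:

- growth/bottleneck: piecewise-constant size histories (10× expansion at
  0.1×2N; 20× crash between 0.02 and 0.07).
- complete sweep: lineages surviving to τ (default 0.01×2N) star-merge;
  each lineage escapes with probability 0.05, standing for chromosomes
  recombined off the selected background during the sweep. The escapes are
  what make a completed sweep detectable by H (mutations on the swept
  ancestor's branch ride at high derived frequency); with no escapes the
  genealogy is a star and all variation is post-sweep singletons.
- partial sweep: the merger takes a fraction f (default 0.5) of lineages.
- standing sweep: the merger is seeded onto k (default 2) pre-existing
  lineages that then coalesce neutrally — two old clades separated by the
  mutations on their deep stems.

Mutations land on distinct uniformly drawn columns (strict infinite sites
within a locus, shared across strata so joint alignments stay consistent);
the functional class of a variant follows from the codon position it hits.
Strata are simulated as independent populations on a shared reference:
differentiation between strata arises from private variants only, so
realistic *shared* polymorphism between strata is not modeled (fixtures for
shared-polymorphism behavior are constructed directly in tests). The
outgroup path length is 2·T_div − t_MRCA (stretched when the genealogy is
older), with ingroup-stem mutations folded into the outgroup's private
columns — polarity of fixed differences is arbitrary for every consumer in
the package. PHASE-style confidence tables give most sites confidence
exactly 1 and a Beta-distributed remainder on [0.5, 1) with mean ≈ 0.78.

What passing tests show: the statistics, calibration and dissection
machinery behave correctly on data whose generating process is known. What
they do not show: robustness to intra-fragment recombination mosaics,
gene conversion, sequencing/phasing error beyond the missing-data paths, or
real shared demography between strata.

## Problem sizes and numerics

Calibration experiments use 500 loci with 2,000-replicate nulls and
≥1,000-pair threshold calibration (null cache keyed on 3-significant-digit
θ̂ keeps this desk-scale); permutation experiments use 199–999 permutations;
moment checks use 10⁴ replicates (3×10⁴ where a band sits near a true
finite-sample offset — Tajima's D has expectation ≈ −0.08 at n = 25,
θ = 5, not 0, which the band test must not confuse with miscalibration).
Fixed-point HKA iteration converges to 1e-12 or errors with residuals.
Tie-breaks (consensus bases, equal clade sizes: the conditioned clade is B)
are deterministic. All randomness flows from a single run seed through
documented derivations (crc32 of the component name), keeping every output
byte-reproducible.

## Known limitations

- No recombination anywhere: within-fragment r² structure under neutrality
  is therefore stronger than in real data of matched θ; the HEW null is
  conservative in the published sense but the haplogroup false-discovery
  behavior on recombining fragments is untested.
- The sweep scenarios are genealogical approximations, not forward
  simulations with selection coefficients; they make no quantitative claim
  about s or sweep duration.
- HKA's variances are moment approximations; small-count loci (S_i + D_i
  near zero) fit θ ≈ 0 and contribute no deviation.
- The silent-site classification convention for monomorphic coding columns
  (fourfold-degenerate rule) shrinks L relative to fractional site
  counting; per-site θ and π are therefore not directly comparable to
  outputs of programs using other conventions.
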