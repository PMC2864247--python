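# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `nemamap`. Coordinates are 0-based half-open everywhere in
memory; AGP, TSV and VCF outputs use their formats' 1-based inclusive
conventions; BED is 0-based half-open.

## Synthetic study conditions (`nemamap.simulate`)

The generator emulates a two-strain nematode resequencing experiment: a
reference genome assembled from fingerprint-map contigs (AGP with random
component orientations and fixed 100 bp scaffold gaps), a divergent strain,
and capillary-trace-like shotgun reads.

Defaults and their rationale:

| parameter | default | rationale |
|---|---|---|
| `snp_rate` | 1/163 per bp | observed density between highly divergent wild isolates |
| `transition_bias` | 0.571 | fraction of substitutions in the A:T→G:C class |
| `small_indel_rate` | 1/500 per bp, sizes 1–49 bp uniform | small-indel candidates are roughly a quarter as dense as SNPs; the true size distribution is not published, so it is exposed as configuration rather than guessed |
| `medium_indel_rate` | 5.5×10⁻⁵ per bp, sizes 50–2,000 bp uniform | ~212 medium indels per ~3.9 Mb of uniquely aligned sequence |
| `read_length` / `coverage` / `error_rate` | 500 bp / 8× / 10⁻³ | trace-like reads; coverage high enough that ≥ 2 reads span most loci |

Substitutions are planted by first drawing a strand-collapsed class from the
six-class spectrum (default: 57.1% A:T→G:C, remainder uniform) and then a
position whose reference base matches the class, which realizes the
configured spectrum in expectation regardless of genome composition —
sampling positions uniformly cannot reach a 57.1% A:T→G:C fraction when
only half the bases are A/T.

Indels are non-overlapping and left-normalized; each reserves a 25 bp
exclusion margin (the stated minimum spacing is 1 bp; the wider margin is a
deliberate choice so that co-optimal alignment paths around adjacent
opposite-sign indels cannot scramble truth matching). Insertions use
uniform random sequence. Read errors are substitutions only; chimeric
reads, base-quality modeling, repeat families, and >2 kb variants are out
of scope. Consequences: passing recall/precision tests show the callers
handle divergence, indels and sequencing error at realistic densities in
*unique* sequence; they say nothing about repeat-induced mismapping, error
clustering at trace ends, or reference misassembly.

All operations are pure functions of (inputs, seed): the reference, strain
and reads use decoupled seeds derived from `SimConfig.seed`.

## Read alignment (`nemamap.align`)

A seed-and-extend aligner over exact k-mer seeds (k = 13, sampled every
11 bp, seeds with > 50 genome hits ignored). Seed hits vote for windows
(diagonal clustering with a 2,100 bp tolerance so that a read spanning a
2 kb deletion still yields a single cluster); both read orientations are
tried. The best window is aligned base-level with banded edit distance
(edlib); a read whose runner-up window ties the best edit distance is
flagged non-unique and excluded from variant calling.

Three post-processing passes repair known pathologies of unit-cost edit
paths:

1. **Gap consolidation** — edit distance is blind to gap contiguity, so a
   backtrace may fragment an 18 bp deletion into scattered 1–7 bp pieces
   separated by coincidental matches. Any region of indel runs separated by
   (mis)match runs ≤ 10 columns is rewritten as one left-placed indel of
   the region's net length.
2. **End cleaning** — reads that begin or end inside novel (inserted)
   sequence have their overhang force-aligned as garbage. A
   maximal-scoring-segment trim (match +1, mismatch −3, gap run −4 flat)
   removes garbage ends, and any terminal gap run whose distal side has
   < 25 aligned columns or < 90% identity is peeled off.
3. **Affine refinement** — nearby opposite-sign indels (e.g. a 44 bp
   deletion 140 bp from a 46 bp insertion) admit co-optimal unit-cost paths
   that scramble both. Paths with ≥ 3 indel runs or ≥ 20 mismatch columns
   are re-aligned with affine gap costs (match 1, mismatch −2, open −6,
   extend −0.2; Biopython PairwiseAligner), which uniquely prefers
   contiguous gaps. Only ~a few percent of reads trigger this.

Because a unit-cost path never opens a gap longer than the read sequence
beyond it, a read spanning a medium indel initially keeps only its longer
flank. Unaligned head/tail remainders ≥ 30 bp are seed-anchored in a
window extending 2,100 bp past the outermost block (two diagonal-consistent
seeds required, killing coincidental anchors) and re-aligned, producing the
distal block of a split alignment. Remainders that are novel inserted
sequence find no consistent anchor and are dropped.

Gaps ≥ 50 bp split the alignment into blocks; gaps ≤ 49 bp stay inside a
block. This places the small-indel/medium-indel partition exactly at the
49/50 bp class boundary.

## Discovery (`nemamap.discovery`)

SNP calls collapse mismatch columns from unique alignments per locus;
the majority alternate base wins. Quality is defined as
`support × mean(alignment identity of supporting reads)` — the published
pipeline thresholds an unspecified quality score, so the package defines
one and exposes the threshold (default 1.5, i.e. effectively ≥ 2
supporting reads, which suppresses singleton sequencing errors at 8×
coverage while keeping recall ≥ 0.95). Small-indel calls (1–49 bp) are
left-normalized and merged by (contig, position, type, size) with a
majority allele. A locus is one variant: co-located SNP calls are dropped
in favor of indel calls.

`unique_aligned_bp` counts reference positions covered ≥ 1× by uniquely
placed alignments — the de-duplication rule for overlapping traces is not
published, so this documented definition is used. Summary identities:
`density_per_kb = 1000 × loci / unique_aligned_bp` (2 decimals),
`bp_per_snp = unique_aligned_bp / loci` (nearest integer).

AGP liftover maps contig coordinates through component rows (forward:
`chrom_start + (pos − comp_start)`; reverse: `chrom_end − 1 − (pos −
comp_start)` in 0-based form); contigs absent from the AGP are reported
unplaced, and flank-based placement (the internal aligner on ≥ 50 bp of
flanking sequence, unique best hit above 90% identity) covers them.
Repeat masking is replaced by the aligner's uniqueness flag — there is no
repeat library at this scale.

## Breakpoint detection (`nemamap.breakpoint`)

Adjacent block pairs with `max(read_gap, ref_gap) ≥ 10 bp` become
breakpoint records. Micro-homology at a breakpoint lets both blocks claim
the same bases, making one gap negative; the overlap (tolerated to 30 bp)
is shifted onto the opposite gap, which preserves the size difference
exactly — clamping would bias sizes by the homology length. Classification
is pure gap arithmetic (deletion `ref_gap − read_gap`, insertion
`read_gap − ref_gap`, opposite strands ⇒ inversion with approximate size,
inter-contig ⇒ "other", never sized). Clustering merges same-contig,
same-type records with breakpoints within 50 bp and sizes within 20%
(median position/size; singleton support kept — the published 689 reads →
635 variants ratio implies singletons were kept; the exact collapsing rule
is not published, so this windowed rule is a documented choice). The
medium set keeps sizes in [50, 2,000]; inversions/others go to a side
report. The call position is the left block's reference end (the base
before the event).

## Assay design (`nemamap.assays`)

The shipped 30-enzyme panel (TSV: name, IUPAC site, top-strand cut offset)
contains the named assay enzymes (DraI TTT^AAA, HindIII A^AGCTT, SalI
G^TCGAC, SacI GAGCT^C, EcoRI G^AATTC) plus 25 common inexpensive 6-cutters;
the original panel's full list is not published, so the panel is
user-replaceable. Entries are single-cut; non-palindromic sites are matched
on both strands with bottom-strand cuts mapped to top-strand coordinates
(`site_start + len − offset`). Digestion of a linear amplicon returns
fragment lengths between consecutive cuts; cuts at position 0 or the
amplicon end are dropped (no zero-length fragments).

The snip-SNP screen examines the ±(max site length − 1) bp window around
each SNP and compares, per enzyme, the cut positions of site occurrences
overlapping the SNP between the two alleles. Comparing cut positions
(rather than only occurrence counts) makes the classifier provably
equivalent to digesting full amplicons of both alleles, which the tests
assert against that brute-force oracle.

Primer picking scans 18–27-mers outward from the target on both sides,
accepting nearest-neighbor Tm (Biopython `Tm_NN`, default salt/primer
concentrations) within range; the two sides are advanced alternately so
the first conforming pair (smallest conforming product) is found without
scanning the whole geometric range. Each primer must occur exactly once in
the genome (exact match, both strands). Dimer/hairpin screening and
multiplexing are out of scope.

RFLP status: `too_many_bands` if either strain digests into > 4 fragments;
`not_resolvable` if no fragment of one strain differs from every fragment
of the other by ≥ max(10 bp, 5% of the fragment length) — the published
filter ("not easily distinguishable on a gel") is qualitative, so this
quantitative rule is exposed. PLP assays enforce the class geometry (small:
7–49 bp indels, 200–400 bp reference amplicon; medium: 300–800 bp) and the
identity `|amplicon_ref − amplicon_alt| = indel size`; indels < 7 bp are
excluded as unresolvable on gels.

The validation summary follows the standard arithmetic: `successful =
attempted − pcr_failures`, `confirmed = similar + different`, rates as
integer percentages of successful PCRs.

## Mapping (`nemamap.mapping`)

F2 selfing crosses are simulated per chromosome: each F2 receives two
independent F1 gametes; along a chromosome the gamete's strain of origin
flips between adjacent loci with probability r from the Haldane map
function r = ½(1 − e^(−2d/100)) (Kosambi available; no crossover
interference). Phenotype is recessive: mutant ⇔ homozygous reference at the
mutation locus. The simulation is vectorized (numpy), so thousand-replicate
power checks run in seconds. The X chromosome is treated as an autosome
(all scored F2 are hermaphrodites); male X0 inheritance is not modeled.

Pool band intensities are proportional to pooled allele dosage with
multiplicative lognormal noise; background subtraction of gel images is the
caller's responsibility — intensities are consumed as numbers. ULV =
intensity_A / intensity_H in the mutant lane; when the divergent band falls
below 1% of the reference band the ratio is capped at 50 and flagged
(tightly linked markers would otherwise divide by ~0). In a recessive
mutant pool the reference allele segregates at frequency 1 − r per
chromosome, so E[ULV] ≈ (1 − r)/r: 1 when unlinked, 9 at r = 0.1.

Linkage calling declares chromosomes with ULV ≥ threshold linked and
assigns the mutation only when exactly one chromosome qualifies. The
default threshold is 1.5 — appropriate for confirming a single candidate
chromosome. For a genome-wide six-chromosome scan with 20-animal pools,
binomial sampling noise pushes an unlinked chromosome past 1.5 in roughly
40% of scans (P(Binom(40, ½) ≥ 24) ≈ 0.10 per chromosome), so the scan
tests use a threshold of 2.5, at which a marker 5 cM from the mutation
(E[ULV] ≈ 9.5) is assigned correctly in ≥ 95% of replicates while unlinked
false positives are ~2% family-wise. Sub-chromosomal localization assigns
the mutation to the marker with maximal ULV (ties span the tied markers;
< 3 markers yields a warning but still returns the argmax).

SRA: r̂ = k/n with n = animals × 2 chromosomes; a heterozygous marker
genotype in a homozygous-mutant animal contributes 1 recombinant
chromosome, homozygous divergent contributes 2. The 95% CI is Wilson's
(statsmodels). The estimator is exact integer arithmetic; simulations
confirm it is unbiased within Monte-Carlo error at r ∈ {0.02, 0.1, 0.3}.

## Problem sizes used by the test suite

The discovery benchmark runs on a 1 Mb genome (4 contigs on 2 chromosomes)
at 8× coverage — large enough for ≥ 5,000 SNPs (binomial convergence of
the spectrum, ±3σ rate checks) while the full suite stays in the
single-digit minutes. The breakpoint fixture is 200 kb with ~30 planted
medium indels of 50–350 bp (error-free reads), sized so 500 bp reads can
span insertions with ≥ 30 bp anchors. ULV calibration uses 500-animal
pools; the unlinked baseline is 1,000 replicates.

## Numerical and degenerate-input choices

- Ties in seed voting are resolved by aligning both candidate windows and
  comparing edit distances; an exact tie marks the read non-unique.
- Clustering is idempotent: re-clustering emitted calls (weighted by their
  support) reproduces them.
- Zero SNP loci: density 0, bp-per-SNP reported absent; an empty
  substitution spectrum is an error rather than a division by zero.
- Validation summaries with zero records report all-zero counts and omit
  rates.
- `expected_ulv` is undefined at r ≤ 0 and raises.

## Known limitations

- Insertions longer than (read length − ~60 bp) cannot be spanned by a
  single read and are invisible to the breakpoint caller; deletions are
  detectable to the full 2 kb class bound.
- Variant calling is restricted to uniquely aligned reads; variants inside
  genomic repeats are a non-goal.
- The aligner is designed for 300–800 bp trace-like reads; it has no
  paired-end model and is untested on short-read or long-read error
  profiles.
- Primer uniqueness is exact-match only; near-matches that would
  cross-amplify are not screened.
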