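"""SNP and small-indel discovery from read alignments.

Implements the trace-based discovery contract: collapse per-read mismatch
and short-gap evidence from unique alignments into variant calls, compute
the Table-1-style summary statistics (density per kb, bp per SNP) and the
strand-collapsed substitution spectrum, and place contig coordinates onto
chromosomes either through the assembly AGP or by aligning flanking
sequence.

Only *unique* alignments contribute evidence: a locus is one variant, and
calls carry a support count and a composite quality (supporting reads x
mean alignment identity) thresholded by ``min_quality``.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .align import (AlignParams, KmerIndex, ReadAlignment, align_read,
                    parse_cigar)
from .simulate import (AgpRow, ReferenceGenome, left_normalize,
                       substitution_class, SPECTRUM_CLASSES)

SMALL_INDEL_MAX = 49


@dataclass(frozen=True)
class SnpCall:
    contig: str
    position: int  # 0-based on the contig
    ref: str
    alt: str
    support: int
    quality: float

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.support < 1 or self.quality < 0:
            raise ValueError("support >= 1 and quality >= 0 required")


@dataclass(frozen=True)
class SmallIndelCall:
    contig: str
    position: int  # 0-based, left-normalized
    indel_type: str  # "ins" | "del"
    size: int
    allele: str  # inserted or deleted sequence
    support: int

    def __post_init__(self):
        if not 1 <= self.size <= SMALL_INDEL_MAX:
            raise ValueError(f"small indel size must be 1..{SMALL_INDEL_MAX}")


@dataclass
class DiscoverySummary:
    """Table-1-style per-strain discovery statistics."""

    traces_examined: int
    traces_aligned: int
    aligned_bp: int
    unique_aligned_bp: int
    unique_snp_loci: int
    density_per_kb: Optional[float] = None
    bp_per_snp: Optional[int] = None
    spectrum: Optional[dict[str, float]] = None

    def __post_init__(self):
        if self.unique_snp_loci > 0:
            if self.unique_aligned_bp <= 0:
                raise ValueError("nonzero loci require aligned bases")
            self.density_per_kb = round(
                1000.0 * self.unique_snp_loci / self.unique_aligned_bp, 2)
            self.bp_per_snp = round(self.unique_aligned_bp / self.unique_snp_loci)
        else:
            self.density_per_kb = 0.0
            self.bp_per_snp = None

    @classmethod
    def from_counts(cls, loci: int, unique_aligned_bp: int,
                    traces_examined: int = 0, traces_aligned: int = 0,
                    aligned_bp: int = 0) -> "DiscoverySummary":
        return cls(traces_examined, traces_aligned, aligned_bp,
                   unique_aligned_bp, loci)


def _iter_block_events(aln: ReadAlignment):
    """Yield (kind, contig, ref_pos, read_pos, length) for X/I/D runs."""
    for block in aln.blocks:
        q, t = block.read_start, block.ref_start
        for n, op in parse_cigar(block.cigar):
            if op in "=M":
                q += n; t += n
            elif op == "X":
                for j in range(n):
                    yield "X", block.ref_contig, t + j, q + j, 1
                q += n; t += n
            elif op == "I":
                yield "I", block.ref_contig, t, q, n
                q += n
            elif op == "D":
                yield "D", block.ref_contig, t, q, n
                t += n


def call_snps(alignments: list[ReadAlignment], genome: ReferenceGenome,
              min_quality: float = 1.5, min_support: int = 1
              ) -> list[SnpCall]:
    """Collapse mismatch evidence from unique alignments into SNP calls.

    Per locus, the majority alternate base wins; quality is the number of
    supporting reads times their mean alignment identity, so singleton
    mismatches from sequencing error fall below the default threshold while
    true variants at >= 2x depth pass.
    """
    evidence: dict[tuple[str, int], list[tuple[str, float]]] = defaultdict(list)
    for aln in alignments:
        for b in aln.blocks:
            if b.ref_contig not in genome.contigs:
                raise ValueError(
                    f"alignment references unknown contig {b.ref_contig}")
        if not aln.unique:
            continue
        for kind, contig, t, q, n in _iter_block_events(aln):
            if kind != "X":
                continue
            evidence[(contig, t)].append((aln.query[q], aln.identity))
    calls: list[SnpCall] = []
    for (contig, pos), obs in evidence.items():
        counts = Counter(b for b, _ in obs)
        alt, support = counts.most_common(1)[0]
        ref = genome.contigs[contig][pos]
        if alt == ref:
            continue
        idents = [i for b, i in obs if b == alt]
        quality = support * float(np.mean(idents))
        if support >= min_support and quality >= min_quality:
            calls.append(SnpCall(contig, pos, ref, alt, support, quality))
    calls.sort(key=lambda c: (c.contig, c.position))
    return calls


def call_small_indels(alignments: list[ReadAlignment], genome: ReferenceGenome,
                      min_support: int = 1) -> list[SmallIndelCall]:
    """Collapse in-block gap evidence (1-49 bp) into left-normalized calls."""
    evidence: dict[tuple, Counter] = defaultdict(Counter)
    for aln in alignments:
        if not aln.unique:
            continue
        for kind, contig, t, q, n in _iter_block_events(aln):
            if kind not in "ID" or n > SMALL_INDEL_MAX:
                continue
            ref = genome.contigs[contig]
            if kind == "D":
                pos, allele = left_normalize(ref, t, "del", ref[t:t + n])
                evidence[(contig, pos, "del", n)][allele] += 1
            else:
                pos, allele = left_normalize(ref, t, "ins", aln.query[q:q + n])
                evidence[(contig, pos, "ins", n)][allele] += 1
    calls = []
    for (c, p, ty, n), alleles in evidence.items():
        support = sum(alleles.values())
        if support >= min_support:
            calls.append(SmallIndelCall(c, p, ty, n,
                                        alleles.most_common(1)[0][0], support))
    calls.sort(key=lambda c: (c.contig, c.position))
    return calls


def dedupe_loci(snps: list[SnpCall], indels: list[SmallIndelCall]
                ) -> tuple[list[SnpCall], list[SmallIndelCall]]:
    """Enforce one variant per locus: indel calls win over co-located SNPs."""
    indel_pos = {(c.contig, c.position) for c in indels}
    return [s for s in snps if (s.contig, s.position) not in indel_pos], indels


def alignment_stats(alignments: list[ReadAlignment], genome: ReferenceGenome,
                    traces_examined: int = 0) -> dict[str, int]:
    """Aligned-base bookkeeping: total and unique-coverage base counts.

    ``unique_aligned_bp`` counts reference positions covered at least once
    by a uniquely placed alignment (the de-duplication rule for overlapping
    traces).
    """
    aligned_bp = 0
    cov = {c: np.zeros(len(s), dtype=bool) for c, s in genome.contigs.items()}
    for aln in alignments:
        for b in aln.blocks:
            aligned_bp += b.ref_end - b.ref_start
            if aln.unique:
                cov[b.ref_contig][b.ref_start:b.ref_end] = True
    return {
        "traces_examined": traces_examined or len(alignments),
        "traces_aligned": len(alignments),
        "aligned_bp": aligned_bp,
        "unique_aligned_bp": int(sum(a.sum() for a in cov.values())),
    }


def summarize_discovery(snp_calls: list[SnpCall], stats: dict[str, int]
                        ) -> DiscoverySummary:
    """Build the per-strain summary (density per kb, bp per SNP, spectrum)."""
    summary = DiscoverySummary(
        traces_examined=stats.get("traces_examined", 0),
        traces_aligned=stats.get("traces_aligned", 0),
        aligned_bp=stats.get("aligned_bp", 0),
        unique_aligned_bp=stats["unique_aligned_bp"],
        unique_snp_loci=len(snp_calls),
    )
    if snp_calls:
        summary.spectrum = substitution_spectrum(snp_calls)
    return summary


def substitution_spectrum(snp_calls: list[SnpCall]) -> dict[str, float]:
    """Fractions of the six strand-collapsed substitution classes."""
    if not snp_calls:
        raise ValueError("spectrum requires at least one SNP call")
    counts = Counter(substitution_class(c.ref, c.alt) for c in snp_calls)
    total = sum(counts.values())
    return {name: counts.get(name, 0) / total for name in SPECTRUM_CLASSES}


# ---------------------------------------------------------------------------
# Coordinate placement


@dataclass(frozen=True)
class Placement:
    status: str  # "placed" | "unplaced" | "ambiguous"
    chromosome: Optional[str] = None
    position: Optional[int] = None  # 0-based chromosome coordinate
    contig: Optional[str] = None
    contig_position: Optional[int] = None


def liftover_agp(contig: str, position: int, agp: list[AgpRow]) -> Placement:
    """Place a 0-based contig coordinate onto its chromosome via the AGP.

    Forward components map position p to ``chrom_start + (p - comp_start)``;
    reverse components to ``chrom_end - 1 - (p - comp_start)``.  Contigs
    absent from the AGP are reported unplaced.
    """
    seen = False
    for row in agp:
        if row.kind != "component" or row.component_id != contig:
            continue
        seen = True
        if row.component_start <= position < row.component_end:
            off = position - row.component_start
            if row.orientation == "+":
                chrom_pos = row.chrom_start + off
            else:
                chrom_pos = row.chrom_end - 1 - off
            return Placement("placed", row.chromosome, chrom_pos,
                             contig, position)
    if seen:
        raise ValueError(f"position {position} outside component span of {contig}")
    return Placement("unplaced", contig=contig, contig_position=position)


def liftover_agp_inverse(chromosome: str, position: int, agp: list[AgpRow]
                         ) -> Placement:
    """Map a 0-based chromosome coordinate back to (contig, position)."""
    for row in agp:
        if row.chromosome != chromosome or row.kind != "component":
            continue
        if row.chrom_start <= position < row.chrom_end:
            off = position - row.chrom_start
            if row.orientation == "+":
                cpos = row.component_start + off
            else:
                cpos = row.component_end - 1 - off
            return Placement("placed", chromosome, position,
                             row.component_id, cpos)
    return Placement("unplaced", chromosome=chromosome, position=position)


def place_by_flank(flank: str, genome: ReferenceGenome,
                   min_length: int = 50, min_identity: float = 0.9,
                   params: AlignParams = AlignParams(),
                   index: Optional[KmerIndex] = None,
                   agp: Optional[list[AgpRow]] = None) -> Placement:
    """Place a variant by aligning its flanking sequence to the genome.

    A unique best hit above the identity threshold places the flank start;
    equally scoring distinct hits are ambiguous; anything else is unplaced.
    With an AGP, the contig hit is additionally lifted to chromosome
    coordinates.
    """
    if len(flank) < min_length:
        raise ValueError(f"flank shorter than minimum ({min_length} bp)")
    if index is None:
        index = KmerIndex(genome, params.k)
    aln = align_read(flank, genome, index, params)
    if aln is None or aln.identity < min_identity:
        return Placement("unplaced")
    if not aln.unique:
        return Placement("ambiguous")
    contig = aln.contig
    pos = aln.blocks[0].ref_start
    if agp:
        lifted = liftover_agp(contig, pos, agp)
        if lifted.status == "placed":
            return lifted
    return Placement("placed", contig=contig, contig_position=pos)
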