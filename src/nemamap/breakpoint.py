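"""Split-alignment detection of medium (50-2,000 bp) indels.

A read spanning a structural variant aligns in two (or more) blocks
separated by a gap on the read, on the reference, or both.  This module
screens multi-block alignments for gaps of at least ``min_gap`` (10 bp by
default), classifies each block pair from the gap arithmetic and strand
configuration (deletion, insertion, inversion, other), clusters supporting
reads into variant calls, and filters calls to the 50-2,000 bp medium
class.  The small-indel caller handles everything below 50 bp, so the two
callers partition indel sizes exactly at the 49/50 boundary.

Gap conventions: ``read_gap = right.read_start - left.read_end`` and
``ref_gap = right.ref_start - left.ref_end``; micro-overlaps of up to 30 bp
(micro-homology at the breakpoint claimed by both blocks) are shifted onto
the opposite gap, which keeps the insertion/deletion size arithmetic
exact.  The call position is the left block's reference end, i.e. the base
before the event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from statistics import median
from typing import Optional

from .align import ReadAlignment

logger = logging.getLogger(__name__)

MAX_OVERLAP = 30


@dataclass
class Hypothesis:
    kind: str  # "ins" | "del" | "inversion" | "other"
    size: Optional[int]
    contig: Optional[str]
    position: Optional[int]
    approximate: bool = False


@dataclass
class BreakpointRead:
    """One adjacent block pair of a split alignment with gap >= min_gap."""

    read_id: str
    left: "object"
    right: "object"
    read_gap: int
    ref_gap: int
    same_strand: bool
    same_contig: bool
    hypothesis: Optional[Hypothesis] = None


@dataclass
class MediumIndelCall:
    contig: str
    position: int  # left breakpoint, 0-based (base before the event)
    indel_type: str  # "ins" | "del"
    size: int
    support: int


def find_breakpoint_reads(alignments: list[ReadAlignment], min_gap: int = 10
                          ) -> list[BreakpointRead]:
    """Screen alignments for adjacent block pairs with gaps >= min_gap.

    Multi-block alignments yield one record per adjacent pair.  Pairs whose
    blocks overlap on the read by more than the clamp are rejected with a
    logged reason.
    """
    records: list[BreakpointRead] = []
    for aln in alignments:
        blocks = sorted(aln.blocks, key=lambda b: b.read_start)
        for left, right in zip(blocks, blocks[1:]):
            read_gap = right.read_start - left.read_end
            same_contig = left.ref_contig == right.ref_contig
            same_strand = left.strand == right.strand
            ref_gap = right.ref_start - left.ref_end if same_contig else 0
            # Micro-homology at a breakpoint lets both blocks claim the same
            # bases, making one gap negative.  Shifting the overlap onto the
            # other gap preserves the size difference exactly; overlaps
            # beyond the tolerance indicate a misalignment and are rejected.
            if read_gap < 0:
                if read_gap < -MAX_OVERLAP:
                    logger.warning("rejected %s: blocks overlap on the read "
                                   "by %d bp", aln.read_id, -read_gap)
                    continue
                ref_gap -= read_gap
                read_gap = 0
            if same_contig and ref_gap < 0:
                if ref_gap < -MAX_OVERLAP:
                    logger.warning("rejected %s: blocks overlap on the "
                                   "reference by %d bp", aln.read_id, -ref_gap)
                    continue
                read_gap -= ref_gap
                ref_gap = 0
            if same_contig and max(read_gap, ref_gap) < min_gap:
                continue
            records.append(BreakpointRead(aln.read_id, left, right,
                                          read_gap, ref_gap,
                                          same_strand, same_contig))
    return records


def classify_breakpoint(bp: BreakpointRead) -> Hypothesis:
    """Infer variant type and size from the gap arithmetic.

    Same strand with a larger reference gap implies a deletion of
    ``ref_gap - read_gap`` bases; larger read gap implies an insertion of
    ``read_gap - ref_gap``; opposite strands flag an inversion (size
    approximated by the reference gap); inter-contig pairs and balanced
    gaps are "other".
    """
    contig = bp.left.ref_contig if bp.same_contig else None
    position = bp.left.ref_end if bp.same_contig else None
    if not bp.same_contig:
        hyp = Hypothesis("other", None, None, None)
    elif not bp.same_strand:
        hyp = Hypothesis("inversion", bp.ref_gap, contig, position,
                         approximate=True)
    elif bp.ref_gap > bp.read_gap:
        hyp = Hypothesis("del", bp.ref_gap - bp.read_gap, contig, position)
    elif bp.read_gap > bp.ref_gap:
        hyp = Hypothesis("ins", bp.read_gap - bp.ref_gap, contig, position)
    else:
        hyp = Hypothesis("other", None, contig, position)
    bp.hypothesis = hyp
    return hyp


def cluster_variants(breakpoint_reads: list[BreakpointRead],
                     window: int = 50, size_tolerance: float = 0.2
                     ) -> list[MediumIndelCall]:
    """Merge breakpoint reads supporting the same event into one call.

    Reads on the same contig, of the same type, with breakpoints within
    ``window`` bp and sizes within ``size_tolerance`` (relative) merge;
    the call takes the median position and size of its supporters.
    Singleton support is kept.
    """
    classified = []  # (contig, kind, position, size, weight)
    for item in breakpoint_reads:
        if isinstance(item, MediumIndelCall):
            classified.append((item.contig, item.indel_type, item.position,
                               item.size, item.support))
            continue
        hyp = item.hypothesis or classify_breakpoint(item)
        if hyp.kind in ("ins", "del") and hyp.contig is not None:
            classified.append((hyp.contig, hyp.kind, hyp.position, hyp.size, 1))
    classified.sort(key=lambda h: (h[0], h[1], h[2]))
    calls: list[MediumIndelCall] = []
    group: list[tuple] = []

    def flush():
        if not group:
            return
        calls.append(MediumIndelCall(
            group[0][0],
            int(median(h[2] for h in group)),
            group[0][1],
            int(median(h[3] for h in group)),
            sum(h[4] for h in group)))
        group.clear()

    for hyp in classified:
        if group and (hyp[0] != group[0][0]
                      or hyp[1] != group[0][1]
                      or hyp[2] - group[-1][2] > window
                      or abs(hyp[3] - group[0][3]) >
                      size_tolerance * max(hyp[3], group[0][3])):
            flush()
        group.append(hyp)
    flush()
    calls.sort(key=lambda c: (c.contig, c.position))
    return calls


def filter_medium(calls: list[MediumIndelCall], lo: int = 50, hi: int = 2000
                  ) -> list[MediumIndelCall]:
    """Retain insertion/deletion calls with lo <= size <= hi."""
    if lo >= hi:
        raise ValueError(f"invalid size bounds ({lo}, {hi})")
    return [c for c in calls if lo <= c.size <= hi]


def side_report(breakpoint_reads: list[BreakpointRead]) -> list[Hypothesis]:
    """Inversion/other records excluded from the medium-indel set."""
    out = []
    for bp in breakpoint_reads:
        hyp = bp.hypothesis or classify_breakpoint(bp)
        if hyp.kind not in ("ins", "del"):
            out.append(hyp)
    return out
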