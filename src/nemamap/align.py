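"""Seeded gapped read-to-reference alignment.

A light seed-and-extend aligner in the spirit of hashed-seed trace aligners:
exact k-mer seeds (k = 13 by default) locate one or a few candidate windows
on the reference, and a banded edit-distance alignment (edlib) produces a
base-level path through each window.  The path is then cut into alignment
blocks wherever the read and reference diverge by a gap of at least
``split_gap`` bases (50 by default): gaps below the limit stay inside a
block and feed the small-indel caller, while block-to-block gaps are the
substrate of the breakpoint module, partitioning indel sizes exactly at the
49/50 bp boundary.

Reads whose best seed cluster is not clearly better than the runner-up are
aligned against both windows and flagged non-unique on a score tie.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

import edlib
import numpy as np
from Bio import Align as _bioalign

from .simulate import ReadSet, ReferenceGenome, revcomp

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class AlignmentBlock:
    """One gap-free-ish block of a read alignment (0-based half-open).

    ``read_start/read_end`` are on the read in its aligned orientation;
    ``cigar`` is the extended-CIGAR edit string for the block (ops =, X and
    indel runs shorter than the aligner's split limit).
    """

    read_start: int
    read_end: int
    ref_contig: str
    ref_start: int
    ref_end: int
    strand: str
    cigar: str = ""

    def __post_init__(self):
        if self.read_end <= self.read_start or self.ref_end <= self.ref_start:
            raise ValueError("block ends must exceed starts")


@dataclass
class ReadAlignment:
    """A read's gapped alignment: ordered blocks plus summary scores."""

    read_id: str
    blocks: list[AlignmentBlock]
    score: float
    identity: float
    unique: bool = True
    query: str = ""  # read sequence in aligned orientation

    @property
    def strand(self) -> str:
        return self.blocks[0].strand

    @property
    def contig(self) -> str:
        return self.blocks[0].ref_contig


@dataclass(frozen=True)
class AlignParams:
    """Tunable aligner parameters (defaults chosen for 500 bp trace-like reads)."""

    k: int = 13
    seed_step: int = 11
    split_gap: int = 50         # gaps >= this split blocks (49/50 partition)
    merge_run: int = 10         # match runs <= this may sit inside a gap region
    min_block: int = 20         # blocks shorter than this are dropped
    max_seed_hits: int = 50     # ignore repetitive seeds
    max_gap: int = 2100         # window padding; covers medium indels to 2 kb
    min_identity: float = 0.7


class KmerIndex:
    """Sorted-array exact k-mer index over all contigs of a genome."""

    def __init__(self, genome: ReferenceGenome, k: int = 13):
        self.k = k
        self.contig_names = list(genome.contigs)
        offsets = {}
        pos_chunks = []
        kmer_chunks = []
        off = 0
        self._offsets = []
        for cid in self.contig_names:
            seq = genome.contigs[cid]
            offsets[cid] = off
            self._offsets.append(off)
            enc = _encode(seq)
            if len(enc) >= k:
                km = _rolling_kmers(enc, k)
                kmer_chunks.append(km)
                pos_chunks.append(np.arange(len(km), dtype=np.int64) + off)
            off += len(seq)
        self._offsets = np.array(self._offsets, dtype=np.int64)
        kmers = np.concatenate(kmer_chunks)
        positions = np.concatenate(pos_chunks)
        order = np.argsort(kmers, kind="stable")
        self._sorted_kmers = kmers[order]
        self._sorted_pos = positions[order]
        self._genome = genome

    def lookup(self, kmer_val: int) -> np.ndarray:
        lo = np.searchsorted(self._sorted_kmers, kmer_val, side="left")
        hi = np.searchsorted(self._sorted_kmers, kmer_val, side="right")
        return self._sorted_pos[lo:hi]

    def to_contig(self, global_pos: int) -> tuple[str, int]:
        i = int(np.searchsorted(self._offsets, global_pos, side="right") - 1)
        return self.contig_names[i], int(global_pos - self._offsets[i])


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.zeros(arr.shape, dtype=np.int64)
    out[arr == ord("C")] = 1
    out[arr == ord("G")] = 2
    out[arr == ord("T")] = 3
    return out


def _rolling_kmers(enc: np.ndarray, k: int) -> np.ndarray:
    """Base-4 value of every k-mer: sum(enc[i+j] * 4^(k-1-j))."""
    n = len(enc) - k + 1
    out = np.zeros(n, dtype=np.int64)
    for j in range(k):
        out <<= 2
        out += enc[j:j + n]
    return out


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def _affine_aligner() -> "_bioalign.PairwiseAligner":
    aligner = _bioalign.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -6
    aligner.extend_gap_score = -0.2
    return aligner


_AFFINE = _affine_aligner()


def _is_messy(ops: list[tuple[int, str]]) -> bool:
    """Heuristic for a scrambled co-optimal edit path.

    Unit-cost edit distance cannot distinguish a contiguous deletion plus a
    contiguous insertion from the same edits scattered through the
    intervening matches; such paths show many short indel runs and excess
    mismatch columns and are re-aligned with affine gap costs.
    """
    indel_runs = sum(1 for n, op in ops if op in "ID")
    x_cols = sum(n for n, op in ops if op == "X")
    return indel_runs >= 3 or x_cols >= 20


def _affine_path(query: str, target: str) -> Optional[tuple[list[tuple[int, str]], int, int]]:
    """Affine-gap local alignment as (ops, target_start, query_start)."""
    try:
        aln = _AFFINE.align(target, query)[0]
    except (IndexError, OverflowError, MemoryError):
        return None
    t_blocks, q_blocks = aln.aligned
    if len(t_blocks) == 0:
        return None
    ops: list[tuple[int, str]] = []
    prev_t, prev_q = None, None
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if prev_t is not None:
            if ts > prev_t:
                ops.append((ts - prev_t, "D"))
            if qs > prev_q:
                ops.append((qs - prev_q, "I"))
        i = 0
        while i < te - ts:
            same = target[ts + i] == query[qs + i]
            j = i
            while j < te - ts and (target[ts + j] == query[qs + j]) == same:
                j += 1
            ops.append((j - i, "=" if same else "X"))
            i = j
        prev_t, prev_q = te, qe
    return ops, int(t_blocks[0][0]), int(q_blocks[0][0])


def _canonicalize(ops: list[tuple[int, str]], merge_run: int
                  ) -> list[tuple[int, str]]:
    """Consolidate fragmented gaps in an optimal edit path.

    Edit distance is blind to gap contiguity: a 18 bp deletion interleaved
    with coincidental single-base matches costs the same as one contiguous
    run, and the backtrace returns an arbitrary optimum.  Any region of
    indel runs separated by (mis)match runs of <= ``merge_run`` columns is
    rewritten as one left-placed indel of the region's net length followed
    by an aligned run, which restores contiguous gaps for the callers."""
    out: list[tuple[int, str]] = []
    i = 0
    while i < len(ops):
        n, op = ops[i]
        if op not in "ID":
            out.append((n, op))
            i += 1
            continue
        ql = n if op == "I" else 0
        tl = n if op == "D" else 0
        last = i
        j = i + 1
        while j < len(ops):
            nj, oj = ops[j]
            if oj in "ID":
                ql += nj if oj == "I" else 0
                tl += nj if oj == "D" else 0
                last = j
                j += 1
            elif nj <= merge_run and j + 1 < len(ops) and ops[j + 1][1] in "ID":
                ql += nj
                tl += nj
                j += 1
            else:
                break
        if last == i:
            out.append((n, op))
        else:
            net = tl - ql
            if net > 0:
                out.append((net, "D"))
                if tl - net:
                    out.append((tl - net, "="))
            elif net < 0:
                out.append((-net, "I"))
                if ql + net:
                    out.append((ql + net, "="))
            else:
                out.append((ql, "="))
        i = last + 1
    # merge adjacent same-op runs introduced by the rewrite
    merged: list[tuple[int, str]] = []
    for n, op in out:
        if merged and merged[-1][1] == op:
            merged[-1] = (merged[-1][0] + n, op)
        else:
            merged.append((n, op))
    return merged


_TRIM_MATCH, _TRIM_MISMATCH, _TRIM_GAP = 1, -3, -4


def _trim_ends(ops: list[tuple[int, str]]) -> tuple[list[tuple[int, str]], int, int]:
    """Keep the maximal-scoring contiguous run of the alignment path.

    Reads that start or end inside novel (inserted) sequence have their
    overhang force-aligned by the edit-distance extension; scoring each op
    run (match +1 per column, mismatch -3 per column, any gap run -4 flat)
    and keeping the best-scoring segment discards those garbage ends while
    leaving genuine long indels, which cost a flat gap penalty, intact.
    Returns (trimmed ops, query offset, target offset) of the kept segment.
    """
    scores = []
    for n, op in ops:
        if op in "=M":
            scores.append(n * _TRIM_MATCH)
        elif op == "X":
            scores.append(n * _TRIM_MISMATCH)
        else:
            scores.append(_TRIM_GAP)
    best = cur = 0
    best_range = (0, 0)
    cur_start = 0
    for i, s in enumerate(scores):
        cur += s
        if cur > best:
            best = cur
            best_range = (cur_start, i + 1)
        if cur < 0:
            cur = 0
            cur_start = i + 1
    lo, hi = best_range
    q0 = sum(n for n, op in ops[:lo] if op in "=XMI")
    t0 = sum(n for n, op in ops[:lo] if op in "=XMD")
    return ops[lo:hi], q0, t0


_END_ANCHOR = 25
_END_IDENTITY = 0.9


def _peel_unanchored(ops: list[tuple[int, str]]
                     ) -> tuple[list[tuple[int, str]], int, int]:
    """Drop terminal gap runs that lack a clean flanking anchor.

    Reads ending just inside an insertion leave a gap run followed by a
    short, marginally matching stub (the novel sequence aligned by
    coincidence); such stubs survive segment trimming when attached to a
    long clean alignment.  Any outermost gap run whose distal side has
    fewer than 25 aligned columns or < 90% identity is cut together with
    its tail, from both ends, to convergence.
    """
    def tail_ok(tail: list[tuple[int, str]]) -> bool:
        cols = sum(n for n, op in tail if op in "=XM")
        match = sum(n for n, op in tail if op in "=M")
        return cols >= _END_ANCHOR and (cols == 0 or match / cols >= _END_IDENTITY)

    dq = dt = 0
    changed = True
    while changed and ops:
        changed = False
        gap_idx = [i for i, (n, op) in enumerate(ops) if op in "ID"]
        if gap_idx:
            last = gap_idx[-1]
            if not tail_ok(ops[last + 1:]):
                ops = ops[:last]
                changed = True
                continue
            first = gap_idx[0]
            if not tail_ok(ops[:first]):
                for n, op in ops[:first + 1]:
                    if op in "=XMI":
                        dq += n
                    if op in "=XMD":
                        dt += n
                ops = ops[first + 1:]
                changed = True
    return ops, dq, dt


def _seed_votes(index: KmerIndex, read_enc: np.ndarray, params: AlignParams
                ) -> list[tuple[int, int]]:
    """Cluster seed hits by projected window start; return (votes, start)."""
    k, step = params.k, params.seed_step
    if len(read_enc) < k:
        return []
    km = _rolling_kmers(read_enc, k)
    projected = []
    for off in range(0, len(km), step):
        hits = index.lookup(int(km[off]))
        if 0 < len(hits) <= params.max_seed_hits:
            projected.extend(int(h) - off for h in hits)
    if not projected:
        return []
    projected.sort()
    clusters: list[tuple[int, int]] = []
    start = projected[0]
    count = 1
    for p in projected[1:]:
        if p - start <= params.max_gap:
            count += 1
        else:
            clusters.append((count, start))
            start = p
            count = 1
    clusters.append((count, start))
    clusters.sort(reverse=True)
    return clusters


def _blocks_from_path(query: str, contig: str, ref_start: int, cigar,
                      strand: str, params: AlignParams, read_offset: int = 0
                      ) -> tuple[list[AlignmentBlock], int, int]:
    """Cut an alignment path into blocks at large-gap regions.

    Returns (blocks, n_match, n_cols).  A "gap region" is a maximal run of
    indel ops, allowing interspersed (mis)match runs of <= ``merge_run``
    columns, whose net read/reference length difference reaches
    ``split_gap``; coincidental matches inside a long gap therefore do not
    fragment it.
    """
    raw = parse_cigar(cigar) if isinstance(cigar, str) else cigar
    ops = _canonicalize(raw, params.merge_run)
    ops, q0, t0 = _trim_ends(ops)
    ops, dq, dt = _peel_unanchored(ops)
    q0 += dq
    t0 += dt
    if not ops:
        return [], 0, 0

    blocks: list[AlignmentBlock] = []
    q, t = q0, t0
    n_match = n_cols = 0
    bq, bt = q0, t0  # current block start (q, t)
    bops: list[str] = []

    def flush():
        nonlocal bops
        if q > bq and t > bt:
            blocks.append(AlignmentBlock(read_offset + bq, read_offset + q,
                                         contig, ref_start + bt,
                                         ref_start + t, strand, "".join(bops)))
        bops = []

    for n, op in ops:
        if op in "ID" and n >= params.split_gap:
            # block-splitting gap: not part of any block's aligned columns
            flush()
            if op == "I":
                q += n
            else:
                t += n
            bq, bt = q, t
            continue
        bops.append(f"{n}{op}")
        if op in "=XM":
            q += n; t += n; n_cols += n
            if op in "=M":
                n_match += n
        elif op == "I":
            q += n; n_cols += n
        else:
            t += n; n_cols += n
    flush()
    blocks = [b for b in blocks
              if min(b.read_end - b.read_start, b.ref_end - b.ref_start) >= params.min_block]
    return blocks, n_match, n_cols


def _align_window(read: str, genome: ReferenceGenome, index: KmerIndex,
                  window_start: int, params: AlignParams
                  ) -> Optional[tuple[str, int, str, int]]:
    """Edit-distance alignment of a read in a padded reference window.

    Returns (contig, ref_start_of_path, cigar, edit_distance) or None.
    """
    contig, local = index.to_contig(max(window_start, 0))
    seq = genome.contigs[contig]
    lo = max(local - params.max_gap, 0)
    hi = min(local + len(read) + params.max_gap, len(seq))
    target = seq[lo:hi]
    if not target:
        return None
    limit = max(int(len(read) * (1 - params.min_identity)), 8)
    res = edlib.align(read, target, mode="HW", task="path", k=limit)
    if res["editDistance"] < 0:
        res = edlib.align(read, target, mode="HW", task="path", k=-1)
        if res["editDistance"] < 0:
            return None
    start = res["locations"][0][0]
    return contig, lo + start, res["cigar"], res["editDistance"]


def align_read(read: str, genome: ReferenceGenome, index: KmerIndex,
               params: AlignParams = AlignParams(),
               read_id: str = "read") -> Optional[ReadAlignment]:
    """Align one read (trying both orientations); None if no credible hit."""
    enc_f = _encode(read)
    rc = revcomp(read)
    enc_r = _encode(rc)
    cand = []
    for strand, enc, seq in (("+", enc_f, read), ("-", enc_r, rc)):
        for votes, start in _seed_votes(index, enc, params)[:2]:
            cand.append((votes, strand, seq, start))
    if not cand:
        return None
    cand.sort(reverse=True, key=lambda c: c[0])
    best_votes = cand[0][0]
    results = []
    for votes, strand, seq, start in cand[:3]:
        if votes < 0.5 * best_votes and results:
            break
        hit = _align_window(seq, genome, index, start, params)
        if hit is not None:
            results.append((hit[3], strand, seq, hit))
    if not results:
        return None
    results.sort(key=lambda r: r[0])
    dist, strand, seq, (contig, ref_start, cigar, _) = results[0]
    # de-duplicate same-window results before judging uniqueness
    distinct = {(r[3][0], round(r[3][1] / 100)) for r in results}
    unique = len(results) == 1 or len(distinct) == 1 or results[1][0] > dist
    path = _canonicalize(parse_cigar(cigar), params.merge_run)
    read_off = 0
    if _is_messy(path):
        ref = genome.contigs[contig]
        t_len = sum(n for n, op in path if op in "=XMD")
        w_lo = max(ref_start - 30, 0)
        w_hi = min(ref_start + t_len + 30, len(ref))
        refined = _affine_path(seq, ref[w_lo:w_hi])
        if refined is not None:
            path, t_start, read_off = refined
            ref_start = w_lo + t_start
    blocks, n_match, n_cols = _blocks_from_path(seq, contig, ref_start, path,
                                                strand, params,
                                                read_offset=read_off)
    if not blocks:
        return None
    for extra in _extend_remainders(seq, genome, index, contig, blocks, strand,
                                    params):
        blocks.append(extra[0])
        n_match += extra[1]
        n_cols += extra[2]
    blocks.sort(key=lambda b: b.read_start)
    identity = n_match / n_cols if n_cols else 0.0
    if identity < params.min_identity:
        return None
    return ReadAlignment(read_id, blocks, score=float(n_match),
                         identity=identity, unique=unique, query=seq)


def _anchor_seeds(index: KmerIndex, sub: str, contig: str, lo: int, hi: int,
                  params: AlignParams) -> list[tuple[int, int]]:
    """Seed hits of a remainder restricted to a reference window.

    Returns (read offset, contig-local ref position) pairs for sampled
    k-mers of ``sub`` whose unique-ish index hits fall inside [lo, hi).
    """
    enc = _encode(sub)
    k = params.k
    if len(enc) < k:
        return []
    km = _rolling_kmers(enc, k)
    ci = index.contig_names.index(contig)
    goff = int(index._offsets[ci])
    glo, ghi = goff + lo, goff + hi
    anchors = []
    for off in range(0, len(km), 4):
        hits = index.lookup(int(km[off]))
        if len(hits) > params.max_seed_hits:
            continue
        for h in hits:
            if glo <= h < ghi:
                anchors.append((off, int(h) - goff))
    return anchors


def _extend_remainders(seq: str, genome: ReferenceGenome, index: KmerIndex,
                       contig: str, blocks: list[AlignmentBlock], strand: str,
                       params: AlignParams
                       ) -> list[tuple[AlignmentBlock, int, int]]:
    """Align unaligned read head/tail remainders in adjacent windows.

    A unit-cost edit path never opens a gap longer than the read sequence
    beyond it, so a read spanning a medium indel keeps only its longer
    flank in the primary path.  Any remainder of >= min_block + 10 bases is
    seed-anchored in a window extending ``max_gap`` past the outermost
    block and re-aligned, yielding the distal block of a split (breakpoint)
    alignment.  A remainder that is novel inserted sequence has no
    consistent seed anchor and is dropped; for remainders that mix novel
    sequence with a real flank, seeding finds where the flank begins so
    only the genuine part is aligned.
    """
    ref = genome.contigs[contig]
    out: list[tuple[AlignmentBlock, int, int]] = []
    min_len = params.min_block + 10
    jobs = []
    head_end = min(b.read_start for b in blocks)
    tail_start = max(b.read_end for b in blocks)
    first_ref = min(b.ref_start for b in blocks)
    last_ref = max(b.ref_end for b in blocks)
    if head_end >= min_len:
        lo = max(first_ref - params.max_gap - head_end, 0)
        jobs.append(("head", 0, head_end, lo, min(first_ref, len(ref))))
    if len(seq) - tail_start >= min_len:
        hi = min(last_ref + params.max_gap + (len(seq) - tail_start), len(ref))
        jobs.append(("tail", tail_start, len(seq), max(last_ref, 0), hi))
    for side, q_lo, q_hi, lo, hi in jobs:
        sub = seq[q_lo:q_hi]
        anchors = _anchor_seeds(index, sub, contig, lo, hi, params)
        # require two diagonal-consistent anchors (kills coincidental hits)
        consistent = [
            (off, pos) for off, pos in anchors
            if sum(1 for o2, p2 in anchors
                   if abs((p2 - pos) - (o2 - off)) <= 30) >= 2]
        if not consistent:
            continue
        if side == "tail":
            off, pos = min(consistent)
            slack = min(off, 10)
            sub2 = sub[off - slack:]
            t_lo = max(pos - slack - 5, lo)
            target = ref[t_lo:hi]
            read_offset = q_lo + off - slack
        else:
            off, pos = max(consistent)
            end = min(off + params.k + 10, len(sub))
            sub2 = sub[:end]
            t_hi = min(pos + params.k + 15, hi)
            target = ref[lo:t_hi]
            t_lo = lo
            read_offset = q_lo
        if not target or not sub2:
            continue
        res = edlib.align(sub2, target, mode="HW", task="path",
                          k=max(int(len(sub2) * 0.3), 8))
        if res["editDistance"] < 0:
            continue
        start = res["locations"][0][0]
        sub_blocks, m, c = _blocks_from_path(sub2, contig, t_lo + start,
                                             res["cigar"], strand, params,
                                             read_offset=read_offset)
        aligned = sum(b.read_end - b.read_start for b in sub_blocks)
        if not sub_blocks or c == 0 or m / c < 0.9 or aligned < params.min_block:
            continue
        # keep only the single largest clean block from the remainder
        best = max(sub_blocks, key=lambda b: b.read_end - b.read_start)
        out.append((best, m, c))
    return out


def align_reads(reads: ReadSet, genome: ReferenceGenome,
                params: AlignParams = AlignParams(),
                index: Optional[KmerIndex] = None) -> list[ReadAlignment]:
    """Align a read set against a reference genome.

    Returns one best alignment per alignable read; reads with two equally
    scoring locations keep ``unique=False`` and are excluded from variant
    calling downstream.
    """
    if index is None:
        index = KmerIndex(genome, params.k)
    out: list[ReadAlignment] = []
    for read_id, seq, *_ in reads.reads:
        aln = align_read(seq, genome, index, params, read_id=read_id)
        if aln is not None:
            out.append(aln)
    return out
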