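"""File formats: FASTA, AGP v2.0, tabular alignments, TSV tables, VCF, BED.

All TSV artifacts are tab-separated UTF-8 with ``#``-prefixed header lines
carrying provenance (tool version, subcommand, parameters, seed).  TSV and
AGP coordinates are 1-based inclusive on disk; BED is 0-based half-open;
everything in memory is 0-based half-open.  Files written by this package
round-trip byte-identically through their readers.
"""

from __future__ import annotations

from typing import Iterable, Optional

from . import __version__
from .align import AlignmentBlock, ReadAlignment
from .simulate import AgpRow, ReadSet, ReferenceGenome, TruthVariant

FASTA_WIDTH = 60


class FormatError(ValueError):
    """Malformed record; the message names the offending line."""


def provenance_header(subcommand: str, seed: Optional[int] = None,
                      **params) -> str:
    parts = [f"# nemamap v{__version__} {subcommand}"]
    if seed is not None:
        parts.append(f"# seed: {seed}")
    for k, v in params.items():
        parts.append(f"# {k}: {v}")
    return "\n".join(parts) + "\n"


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def write_fasta(path, sequences: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), FASTA_WIDTH):
                fh.write(seq[i:i + FASTA_WIDTH] + "\n")


def read_fasta(path) -> dict[str, str]:
    sequences: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    sequences[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif name is None and line:
                raise FormatError(f"{path}:{lineno}: sequence before header")
            else:
                chunks.append(line)
    if name is not None:
        sequences[name] = "".join(chunks)
    return sequences


def write_reads_fasta(path, reads: ReadSet) -> None:
    write_fasta(path, {r[0]: r[1] for r in reads.reads})


def write_reads_fastq(path, reads: ReadSet, quality: str = "I") -> None:
    with open(path, "w") as fh:
        for read_id, seq, *_ in reads.reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{quality * len(seq)}\n")


def read_reads_fasta(path) -> ReadSet:
    seqs = read_fasta(path)
    return ReadSet([(name, seq, "", -1, "?") for name, seq in seqs.items()])


# ---------------------------------------------------------------------------
# AGP v2.0


def write_agp(path, agp: list[AgpRow], evidence: str = "map") -> None:
    """Write AGP v2.0 (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.0\n")
        part = {}
        for row in agp:
            part[row.chromosome] = part.get(row.chromosome, 0) + 1
            cols = [row.chromosome, str(row.chrom_start + 1),
                    str(row.chrom_end), str(part[row.chromosome])]
            if row.kind == "component":
                cols += ["W", row.component_id, str(row.component_start + 1),
                         str(row.component_end), row.orientation]
            else:
                cols += ["N", str(row.gap_length), "scaffold", "yes", evidence]
            fh.write("\t".join(cols) + "\n")


def read_agp(path) -> list[AgpRow]:
    rows: list[AgpRow] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 8:
                raise FormatError(f"{path}:{lineno}: expected >= 8 AGP columns")
            try:
                chrom, start, end = f[0], int(f[1]) - 1, int(f[2])
                if f[4] in ("N", "U"):
                    rows.append(AgpRow(chrom, start, end, "gap",
                                       gap_length=int(f[5])))
                else:
                    rows.append(AgpRow(chrom, start, end, "component",
                                       component_id=f[5],
                                       component_start=int(f[6]) - 1,
                                       component_end=int(f[7]),
                                       orientation=f[8] if len(f) > 8 else "+"))
            except (ValueError, IndexError) as e:
                raise FormatError(f"{path}:{lineno}: {e}") from e
    return rows


# ---------------------------------------------------------------------------
# Truth set and variant-call TSV


def write_truth_tsv(path, truth: list[TruthVariant], header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        fh.write("# class\tcontig\tpos\tref\talt\ttype\tsize\n")
        for v in truth:
            fh.write(f"{v.var_class}\t{v.contig}\t{v.ref_position + 1}\t"
                     f"{v.ref_allele or '.'}\t{v.alt_allele or '.'}\t"
                     f"{v.indel_type or '.'}\t{v.size}\n")


def read_truth_tsv(path) -> list[TruthVariant]:
    out: list[TruthVariant] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 7:
                raise FormatError(f"{path}:{lineno}: expected 7 columns")
            out.append(TruthVariant(
                f[0], f[1], int(f[2]) - 1,
                "" if f[3] == "." else f[3],
                "" if f[4] == "." else f[4],
                None if f[5] == "." else f[5], int(f[6])))
    return out


def write_calls_tsv(path, snps, indels=(), medium=(), header: str = "",
                    agp: Optional[list[AgpRow]] = None) -> None:
    """Variant calls as TSV: id, contig, pos (1-based), ref, alt, type,
    size, support, quality, chromosome, chrom_pos."""
    from .discovery import liftover_agp

    def place(contig, pos):
        if not agp:
            return ".", "."
        p = liftover_agp(contig, pos, agp)
        if p.status == "placed":
            return p.chromosome, str(p.position + 1)
        return "unplaced", "."

    with open(path, "w") as fh:
        if header:
            fh.write(header)
        fh.write("# id\tcontig\tpos\tref\talt\ttype\tsize\tsupport\t"
                 "quality\tchromosome\tchrom_pos\n")
        i = 0
        for c in snps:
            chrom, cpos = place(c.contig, c.position)
            fh.write(f"snp{i:06d}\t{c.contig}\t{c.position + 1}\t{c.ref}\t"
                     f"{c.alt}\tsnp\t1\t{c.support}\t{c.quality:.3f}\t"
                     f"{chrom}\t{cpos}\n")
            i += 1
        for c in indels:
            chrom, cpos = place(c.contig, c.position)
            fh.write(f"sid{i:06d}\t{c.contig}\t{c.position + 1}\t.\t"
                     f"{c.allele or '.'}\t{c.indel_type}\t{c.size}\t"
                     f"{c.support}\t.\t{chrom}\t{cpos}\n")
            i += 1
        for c in medium:
            chrom, cpos = place(c.contig, c.position)
            fh.write(f"mid{i:06d}\t{c.contig}\t{c.position + 1}\t.\t.\t"
                     f"{c.indel_type}\t{c.size}\t{c.support}\t.\t"
                     f"{chrom}\t{cpos}\n")
            i += 1


# ---------------------------------------------------------------------------
# 12-column tabular pairwise alignments (BLAST outfmt-6-like)


def write_alignments_tabular(path, alignments: list[ReadAlignment],
                             header: str = "") -> None:
    """One row per alignment block: query, target, identity (%), length,
    mismatches, gap opens, qstart, qend, tstart, tend, score, bitscore.
    Query/target coordinates are 1-based inclusive; minus-strand blocks
    have tstart > tend."""
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        for aln in alignments:
            for b in aln.blocks:
                length = max(b.read_end - b.read_start, b.ref_end - b.ref_start)
                if b.strand == "+":
                    t1, t2 = b.ref_start + 1, b.ref_end
                else:
                    t1, t2 = b.ref_end, b.ref_start + 1
                fh.write("\t".join(map(str, [
                    aln.read_id, b.ref_contig,
                    f"{100.0 * aln.identity:.2f}", length, 0, 0,
                    b.read_start + 1, b.read_end, t1, t2,
                    f"{aln.score:.1f}", f"{aln.score:.1f}"])) + "\n")


def read_alignments_tabular(path) -> list[ReadAlignment]:
    """Parse 12-column alignments back into block-structured alignments."""
    by_query: dict[str, list[AlignmentBlock]] = {}
    ident: dict[str, float] = {}
    score: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 12:
                raise FormatError(f"{path}:{lineno}: expected 12 columns")
            try:
                q, t = f[0], f[1]
                qs, qe, ts, te = int(f[6]) - 1, int(f[7]), int(f[8]), int(f[9])
                if ts <= te:
                    block = AlignmentBlock(qs, qe, t, ts - 1, te, "+")
                else:
                    block = AlignmentBlock(qs, qe, t, te - 1, ts, "-")
                by_query.setdefault(q, []).append(block)
                ident[q] = float(f[2]) / 100.0
                score[q] = float(f[11])
            except (ValueError, IndexError) as e:
                raise FormatError(f"{path}:{lineno}: {e}") from e
    return [ReadAlignment(q, sorted(bs, key=lambda b: b.read_start),
                          score[q], ident[q])
            for q, bs in by_query.items()]


# ---------------------------------------------------------------------------
# VCF / BED


def write_vcf(path, snps, indels, genome: ReferenceGenome,
              header: str = "") -> None:
    """Minimal VCF 4.2 export of SNP and small-indel calls."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if header:
            for line in header.rstrip("\n").split("\n"):
                fh.write("##" + line.lstrip("# ") + "\n")
        for cid, seq in genome.contigs.items():
            fh.write(f"##contig=<ID={cid},length={len(seq)}>\n")
        fh.write('##INFO=<ID=SUPPORT,Number=1,Type=Integer,'
                 'Description="Supporting reads">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        records = []
        for c in snps:
            records.append((c.contig, c.position, c.ref, c.alt,
                            f"{c.quality:.1f}", c.support))
        for c in indels:
            seq = genome.contigs[c.contig]
            anchor_pos = c.position - 1 if c.position > 0 else c.position
            anchor = seq[anchor_pos]
            if c.indel_type == "del":
                ref, alt = anchor + c.allele, anchor
            else:
                ref, alt = anchor, anchor + c.allele
            records.append((c.contig, anchor_pos, ref, alt, ".", c.support))
        records.sort(key=lambda r: (r[0], r[1]))
        for contig, pos, ref, alt, qual, support in records:
            fh.write(f"{contig}\t{pos + 1}\t.\t{ref}\t{alt}\t{qual}\tPASS\t"
                     f"SUPPORT={support}\n")


def write_bed(path, intervals: Iterable[tuple[str, int, int, str]],
              header: str = "") -> None:
    """BED (0-based half-open) of e.g. assay amplicons."""
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        for contig, start, end, name in intervals:
            fh.write(f"{contig}\t{start}\t{end}\t{name}\n")


# ---------------------------------------------------------------------------
# Mapping tables


def read_genetic_map_tsv(path):
    """Genetic map TSV: chromosome, marker, cM, arm label."""
    from .mapping import Marker
    markers = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 columns")
            markers.append(Marker(f[1], f[0], float(f[2]),
                                  f[3] if len(f) > 3 else ""))
    return markers


def read_pool_intensity_tsv(path):
    """Pool-intensity TSV: marker, lane, intensity_A, intensity_H."""
    from .mapping import PoolIntensity
    pools = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            pools.append(PoolIntensity(f[0], f[1], float(f[2]), float(f[3])))
    return pools


def write_assays_tsv(path, rflps=(), plps=(), header: str = "") -> None:
    """Assay tables mirroring the marker-table layout: id, contig, location,
    enzyme or indel size, primers, per-strain patterns, status."""
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        fh.write("# id\tenzyme_or_size\tleft_primer\tright_primer\t"
                 "pattern_ref\tpattern_alt\tstatus\n")
        for a in rflps:
            lp = a.primers.left if a.primers else "."
            rp = a.primers.right if a.primers else "."
            fr = "+".join(map(str, a.fragments_ref)) or "."
            fa = "+".join(map(str, a.fragments_alt)) or "."
            fh.write(f"{a.snp_id}\t{a.enzyme}\t{lp}\t{rp}\t{fr}\t{fa}\t"
                     f"{a.status}\n")
        for a in plps:
            lp = a.primers.left if a.primers else "."
            rp = a.primers.right if a.primers else "."
            fh.write(f"{a.indel_id}\t{a.assay_class}\t{lp}\t{rp}\t"
                     f"{a.amplicon_ref or '.'}\t{a.amplicon_alt or '.'}\t"
                     f"{a.status}\n")
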