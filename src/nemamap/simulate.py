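"""Synthetic two-strain genomes, variant truth sets, and shotgun reads.

This module builds miniature analogues of a two-strain nematode mapping
experiment: a multi-contig reference genome assembled onto chromosomes via
an AGP, a divergent strain derived from it by planting SNPs and indels at
configurable densities (with the strong A:T->G:C substitution bias seen
between wild isolates), and error-bearing shotgun reads drawn from the
divergent strain.  Every operation is a pure function of its inputs and a
seed, and the planted variants are returned as a ground-truth list so that
discovery recall/precision can be measured exactly.

Coordinates are 0-based half-open everywhere in memory; the AGP writer in
:mod:`nemamap.io` converts to the 1-based inclusive convention of AGP v2.0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Strand-collapsed substitution classes.  The first entry is the A:T->G:C
#: transition class that dominates the HK104/AF16 spectrum.
SPECTRUM_CLASSES = (
    "A:T>G:C",
    "A:T>C:G",
    "A:T>T:A",
    "G:C>A:T",
    "G:C>T:A",
    "G:C>C:G",
)

# (ref, alt) pairs realizing each class, keyed by class name.
_CLASS_SUBS = {
    "A:T>G:C": (("A", "G"), ("T", "C")),
    "A:T>C:G": (("A", "C"), ("T", "G")),
    "A:T>T:A": (("A", "T"), ("T", "A")),
    "G:C>A:T": (("G", "A"), ("C", "T")),
    "G:C>T:A": (("G", "T"), ("C", "A")),
    "G:C>C:G": (("G", "C"), ("C", "G")),
}


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def substitution_class(ref: str, alt: str) -> str:
    """Strand-collapsed class name for a single-base substitution."""
    for name, pairs in _CLASS_SUBS.items():
        if (ref, alt) in pairs:
            return name
    raise ValueError(f"not a substitution: {ref}>{alt}")


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is invalid."""


class GenerationError(RuntimeError):
    """Raised when variants cannot be placed under the configured rates."""


@dataclass(frozen=True)
class AgpRow:
    """One row of an AGP assembly description (0-based half-open in memory)."""

    chromosome: str
    chrom_start: int
    chrom_end: int
    kind: str  # "component" | "gap"
    component_id: Optional[str] = None
    component_start: Optional[int] = None
    component_end: Optional[int] = None
    orientation: str = "+"
    gap_length: Optional[int] = None

    def __post_init__(self):
        span = self.chrom_end - self.chrom_start
        if self.kind == "component":
            if span != self.component_end - self.component_start:
                raise ValueError("AGP component span mismatch")
        elif self.kind == "gap":
            if span != self.gap_length:
                raise ValueError("AGP gap span mismatch")
        else:
            raise ValueError(f"unknown AGP row kind {self.kind!r}")


@dataclass
class ReferenceGenome:
    """Reference contigs plus their AGP placement onto chromosomes."""

    contigs: dict[str, str]
    agp: list[AgpRow]

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not self.contigs:
            raise ValueError("genome has no contigs")
        for cid, seq in self.contigs.items():
            if not seq or set(seq) - set(BASES):
                raise ValueError(f"contig {cid} empty or non-ACGT")
        last_end: dict[str, int] = {}
        for row in self.agp:
            if row.kind == "component" and row.component_id not in self.contigs:
                raise ValueError(f"AGP component {row.component_id} not in contigs")
            if row.chrom_start < last_end.get(row.chromosome, 0):
                raise ValueError("AGP spans overlap or are unordered")
            last_end[row.chromosome] = row.chrom_end

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def chromosome_names(self) -> list[str]:
        seen: list[str] = []
        for row in self.agp:
            if row.chromosome not in seen:
                seen.append(row.chromosome)
        return seen


@dataclass(frozen=True)
class TruthVariant:
    """A planted variant: the simulator's ground truth for one locus.

    ``ref_position`` is 0-based on the contig.  For insertions the inserted
    sequence appears *before* ``ref_position`` in the strain; ``ref_allele``
    is the deleted sequence for deletions and "" for insertions.
    """

    var_class: str  # "snp" | "small_indel" | "medium_indel"
    contig: str
    ref_position: int
    ref_allele: str
    alt_allele: str
    indel_type: Optional[str] = None  # "ins" | "del"
    size: int = 0

    @property
    def is_indel(self) -> bool:
        return self.var_class != "snp"


@dataclass
class ReadSet:
    """Simulated shotgun reads; origin is kept for diagnostics only."""

    reads: list[tuple[str, str, str, int, str]]  # (id, seq, contig, strain_start, strand)

    def __len__(self) -> int:
        return len(self.reads)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic two-strain experiment.

    Defaults mirror the HK104-vs-AF16 comparison: one SNP per 163 bp with
    57.1% of substitutions in the A:T->G:C class, small indels of 1-49 bp,
    and sparser medium indels of 50-2,000 bp.
    """

    n_chromosomes: int = 1
    contigs_per_chromosome: int = 1
    contig_length: tuple[int, int] = (100_000, 100_000)
    gap_length: int = 100
    snp_rate: float = 1.0 / 163.0
    transition_bias: float = 0.571
    spectrum: Optional[tuple[float, ...]] = None  # 6 fractions; overrides bias
    small_indel_rate: float = 1.0 / 500.0
    small_indel_size: tuple[int, int] = (1, 49)
    medium_indel_rate: float = 5.5e-5
    medium_indel_size: tuple[int, int] = (50, 2000)
    read_length: int = 500
    coverage: float = 8.0
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self):
        for name in ("snp_rate", "transition_bias", "small_indel_rate",
                     "medium_indel_rate", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0,1]")
        for name in ("contig_length", "small_indel_size", "medium_indel_size"):
            lo, hi = getattr(self, name)
            if lo <= 0 or lo > hi:
                raise ConfigurationError(f"{name}={(lo, hi)} not an ordered positive range")
        if self.n_chromosomes <= 0 or self.contigs_per_chromosome <= 0:
            raise ConfigurationError("chromosome/contig counts must be positive")
        if self.read_length <= 0 or self.coverage < 0:
            raise ConfigurationError("read length must be positive, coverage >= 0")

    def spectrum_weights(self) -> np.ndarray:
        if self.spectrum is not None:
            w = np.asarray(self.spectrum, dtype=float)
            if w.shape != (6,) or w.min() < 0:
                raise ConfigurationError("spectrum must be 6 non-negative fractions")
        else:
            b = self.transition_bias
            w = np.array([b] + [(1.0 - b) / 5.0] * 5)
        return w / w.sum()


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def generate_reference(config: SimConfig) -> ReferenceGenome:
    """Generate a multi-contig reference genome with a consistent AGP.

    Contigs are uniform-random sequences; each chromosome is assembled from
    ``contigs_per_chromosome`` contigs separated by fixed-length gaps, with
    random component orientations (as in real fingerprint-contig AGPs).
    """
    rng = np.random.default_rng(config.seed)
    contigs: dict[str, str] = {}
    agp: list[AgpRow] = []
    cidx = 0
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        pos = 0
        for k in range(config.contigs_per_chromosome):
            if k > 0:
                agp.append(AgpRow(chrom, pos, pos + config.gap_length, "gap",
                                  gap_length=config.gap_length))
                pos += config.gap_length
            cidx += 1
            cid = f"ctg{cidx:04d}"
            lo, hi = config.contig_length
            length = int(rng.integers(lo, hi + 1))
            contigs[cid] = _random_sequence(rng, length)
            orientation = "+" if rng.random() < 0.5 else "-"
            agp.append(AgpRow(chrom, pos, pos + length, "component",
                              component_id=cid, component_start=0,
                              component_end=length, orientation=orientation))
            pos += length
    return ReferenceGenome(contigs, agp)


def left_normalize(ref: str, pos: int, indel_type: str, seq: str) -> tuple[int, str]:
    """Shift an indel to its leftmost equivalent placement.

    For a deletion ``seq`` is the deleted reference substring starting at
    ``pos``; for an insertion ``seq`` is inserted before ``pos``.
    """
    if indel_type == "del":
        size = len(seq)
        while pos > 0 and ref[pos - 1] == ref[pos + size - 1]:
            pos -= 1
        return pos, ref[pos:pos + size]
    if indel_type == "ins":
        while pos > 0 and seq and seq[-1] == ref[pos - 1]:
            seq = ref[pos - 1] + seq[:-1]
            pos -= 1
        return pos, seq
    raise ValueError(f"unknown indel type {indel_type!r}")


def _place_variants(rng: np.random.Generator, contig: str, seq: str,
                    config: SimConfig) -> list[TruthVariant]:
    """Plant non-overlapping, left-normalized variants on one contig."""
    L = len(seq)
    occupied = np.zeros(L + 1, dtype=bool)
    variants: list[TruthVariant] = []

    def reserve(lo: int, hi: int) -> bool:
        lo, hi = max(lo, 0), min(hi, L + 1)
        if occupied[lo:hi].any():
            return False
        occupied[lo:hi] = True
        return True

    # Indels first (they occupy intervals), medium before small.
    for var_class, rate, (smin, smax) in (
            ("medium_indel", config.medium_indel_rate, config.medium_indel_size),
            ("small_indel", config.small_indel_rate, config.small_indel_size)):
        n = rng.binomial(L, rate)
        placed = tries = 0
        while placed < n and tries < 50 * n + 100:
            tries += 1
            size = int(rng.integers(smin, smax + 1))
            is_del = rng.random() < 0.5
            span = size if is_del else 0
            pos = int(rng.integers(1, max(L - span - 1, 2)))
            # Indels get a 25 bp exclusion margin so that nearby variants
            # cannot produce ambiguous alignment paths around the event.
            margin = 25
            if is_del:
                pos, dseq = left_normalize(seq, pos, "del", seq[pos:pos + size])
                if not reserve(pos - margin, pos + size + margin):
                    continue
                variants.append(TruthVariant(var_class, contig, pos, dseq, "",
                                             "del", size))
            else:
                ins = _random_sequence(rng, size)
                pos, ins = left_normalize(seq, pos, "ins", ins)
                if not reserve(pos - margin, pos + margin):
                    continue
                variants.append(TruthVariant(var_class, contig, pos, "", ins,
                                             "ins", size))
            placed += 1
        if placed < n:
            raise GenerationError(
                f"could not place {n} {var_class}s on {contig} (rates too high)")

    # SNPs: class chosen from the spectrum, then a position whose reference
    # base matches the class (this realizes the configured A:T->G:C fraction
    # exactly in expectation regardless of genome composition).
    n_snps = rng.binomial(L, config.snp_rate)
    weights = config.spectrum_weights()
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    at_pos = np.flatnonzero((arr == ord("A")) | (arr == ord("T")))
    gc_pos = np.flatnonzero((arr == ord("G")) | (arr == ord("C")))
    classes = rng.choice(6, size=n_snps, p=weights)
    for cls_idx in classes:
        name = SPECTRUM_CLASSES[cls_idx]
        pool = at_pos if name.startswith("A:T") else gc_pos
        if len(pool) == 0:
            raise GenerationError(f"no eligible bases for class {name} on {contig}")
        for _ in range(200):
            pos = int(pool[rng.integers(0, len(pool))])
            if not occupied[pos]:
                break
        else:
            raise GenerationError(f"could not place SNPs on {contig} (rates too high)")
        occupied[pos] = True
        ref = seq[pos]
        alt = dict(_CLASS_SUBS[name])[ref]
        variants.append(TruthVariant("snp", contig, pos, ref, alt))

    variants.sort(key=lambda v: v.ref_position)
    return variants


def apply_variants(seq: str, variants: list[TruthVariant]) -> str:
    """Apply sorted, non-overlapping variants to a reference sequence."""
    pieces: list[str] = []
    cursor = 0
    for v in variants:
        pieces.append(seq[cursor:v.ref_position])
        if v.var_class == "snp":
            pieces.append(v.alt_allele)
            cursor = v.ref_position + 1
        elif v.indel_type == "del":
            cursor = v.ref_position + v.size
        else:  # insertion
            pieces.append(v.alt_allele)
            cursor = v.ref_position
    pieces.append(seq[cursor:])
    return "".join(pieces)


def revert_variants(strain_seq: str, ref_seq: str,
                    variants: list[TruthVariant]) -> str:
    """Invert :func:`apply_variants`; used to check the round-trip property."""
    pieces: list[str] = []
    ref_cursor = 0
    strain_cursor = 0
    for v in variants:
        keep = v.ref_position - ref_cursor
        pieces.append(strain_seq[strain_cursor:strain_cursor + keep])
        strain_cursor += keep
        ref_cursor = v.ref_position
        if v.var_class == "snp":
            pieces.append(v.ref_allele)
            strain_cursor += 1
            ref_cursor += 1
        elif v.indel_type == "del":
            pieces.append(v.ref_allele)
            ref_cursor += v.size
        else:
            strain_cursor += v.size
    pieces.append(strain_seq[strain_cursor:])
    return "".join(pieces)


def derive_strain(genome: ReferenceGenome, config: SimConfig,
                  seed: Optional[int] = None
                  ) -> tuple[dict[str, str], list[TruthVariant]]:
    """Derive a divergent strain from the reference with a known truth set.

    Returns the strain's contig sequences and the sorted list of planted
    variants (ground truth).  Deterministic under ``seed`` (defaults to
    ``config.seed + 1`` so reference and strain randomness are decoupled).
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    strain: dict[str, str] = {}
    truth: list[TruthVariant] = []
    for cid in genome.contigs:
        seq = genome.contigs[cid]
        variants = _place_variants(rng, cid, seq, config)
        strain[cid] = apply_variants(seq, variants)
        truth.extend(variants)
    return strain, truth


def strain_to_ref(variants: list[TruthVariant], contig: str, pos: int) -> int:
    """Map a strain coordinate back to the reference (diagnostics only)."""
    offset = 0
    for v in variants:
        if v.contig != contig:
            continue
        if v.ref_position + offset > pos:
            break
        if v.indel_type == "del":
            offset -= v.size
        elif v.indel_type == "ins":
            offset += v.size
    return pos - offset


def simulate_reads(strain: dict[str, str], config: SimConfig,
                   seed: Optional[int] = None) -> ReadSet:
    """Draw shotgun reads from the strain with per-base substitution errors.

    Read count is ``coverage * genome_size / read_length`` (rounded); start
    positions are uniform, strands equiprobable.  Reads are truncated only
    when a contig is shorter than the configured read length.
    """
    if config.coverage <= 0:
        raise ConfigurationError("coverage must be > 0 to simulate reads")
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    names = list(strain)
    lengths = np.array([len(strain[c]) for c in names])
    if config.read_length > lengths.max():
        raise ConfigurationError("read length exceeds the longest contig")
    total = int(lengths.sum())
    n_reads = int(round(config.coverage * total / config.read_length))
    probs = lengths / total
    choices = rng.choice(len(names), size=n_reads, p=probs)
    reads: list[tuple[str, str, str, int, str]] = []
    base_arr = np.array(list(BASES))
    for i, ci in enumerate(choices):
        cid = names[ci]
        seq = strain[cid]
        rl = min(config.read_length, len(seq))
        start = int(rng.integers(0, len(seq) - rl + 1))
        read = seq[start:start + rl]
        if config.error_rate > 0:
            n_err = rng.binomial(rl, config.error_rate)
            if n_err:
                pos = rng.choice(rl, size=n_err, replace=False)
                chars = list(read)
                for p in pos:
                    alts = [b for b in BASES if b != chars[p]]
                    chars[p] = alts[rng.integers(0, 3)]
                read = "".join(chars)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            read = revcomp(read)
        reads.append((f"read{i:06d}", read, cid, start, strand))
    return ReadSet(reads)
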