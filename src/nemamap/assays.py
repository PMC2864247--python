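"""Genotyping assay design: snip-SNP RFLPs and indel PLPs.

A snip-SNP is a SNP whose alternate allele creates or destroys a
restriction-enzyme recognition site, so that after PCR and digestion the
two strains show different band patterns on a gel (an RFLP).  Indels are
typed more simply as PCR length polymorphisms (PLPs): the two strains'
amplicons differ in length by the indel size.

The module screens SNPs against a 30-enzyme panel, picks PCR primers under
amplicon-size and melting-temperature constraints (nearest-neighbor Tm via
Biopython), digests amplicons in silico for both alleles, applies the gel
practicality filters (at most 4 bands per strain, patterns resolvable on a
gel), and aggregates wet-lab validation outcomes into the standard summary
arithmetic (success rate = confirmed / successful PCRs).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Optional

from Bio.SeqUtils import MeltingTemp

from .simulate import ReferenceGenome, revcomp

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}
_IUPAC_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _iupac_revcomp(site: str) -> str:
    return site.translate(_IUPAC_COMP)[::-1]


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A single-cut restriction enzyme: IUPAC site and top-strand cut offset."""

    name: str
    site: str
    cut_offset: int

    def __post_init__(self):
        if len(self.site) < 4:
            raise ValueError("recognition site must be >= 4 bp")
        if not 0 <= self.cut_offset <= len(self.site):
            raise ValueError("cut offset outside the site")
        if set(self.site) - set(IUPAC):
            raise ValueError(f"non-IUPAC characters in site {self.site!r}")

    @property
    def is_palindromic(self) -> bool:
        return _iupac_revcomp(self.site) == self.site

    def cut_positions(self, seq: str) -> list[int]:
        """Sorted internal cut positions on a linear molecule (both strands)."""
        cuts = set()
        pat = re.compile("(?=" + "".join(IUPAC[b] for b in self.site) + ")")
        for m in pat.finditer(seq):
            cuts.add(m.start() + self.cut_offset)
        if not self.is_palindromic:
            rc = _iupac_revcomp(self.site)
            pat = re.compile("(?=" + "".join(IUPAC[b] for b in rc) + ")")
            for m in pat.finditer(seq):
                cuts.add(m.start() + len(self.site) - self.cut_offset)
        return sorted(c for c in cuts if 0 < c < len(seq))


@dataclass
class EnzymePanel:
    enzymes: list[RestrictionEnzyme]

    def __post_init__(self):
        names = [e.name for e in self.enzymes]
        if len(names) != len(set(names)):
            raise ValueError("duplicate enzyme names in panel")

    def __iter__(self):
        return iter(self.enzymes)

    def __len__(self):
        return len(self.enzymes)

    def get(self, name: str) -> RestrictionEnzyme:
        for e in self.enzymes:
            if e.name == name:
                return e
        raise KeyError(name)

    @property
    def max_site_length(self) -> int:
        return max(len(e.site) for e in self.enzymes)

    @classmethod
    def from_tsv(cls, path) -> "EnzymePanel":
        enzymes = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                name, site, off = line.split("\t")
                enzymes.append(RestrictionEnzyme(name, site.upper(), int(off)))
        return cls(enzymes)


def default_panel() -> EnzymePanel:
    """The shipped 30-enzyme panel of common, cheap single-cut enzymes."""
    path = resources.files("nemamap.data").joinpath("enzymes.tsv")
    with resources.as_file(path) as p:
        return EnzymePanel.from_tsv(p)


def digest_amplicon(amplicon: str, enzyme: RestrictionEnzyme) -> list[int]:
    """In-silico digest of a linear amplicon: sorted fragment lengths.

    Cut positions are site start + cut offset for every occurrence on
    either strand (degenerate IUPAC bases matched, overlapping occurrences
    included); with no site the single fragment is the whole amplicon.
    """
    if not amplicon:
        raise ValueError("empty amplicon")
    cuts = enzyme.cut_positions(amplicon)
    bounds = [0] + cuts + [len(amplicon)]
    return sorted(b - a for a, b in zip(bounds, bounds[1:]))


# ---------------------------------------------------------------------------
# Snip-SNP screening


def snp_cut_sets(ref_window: str, alt_window: str, enzyme: RestrictionEnzyme,
                 center: int) -> tuple[set[int], set[int]]:
    """Cut positions (within the window) from sites overlapping the SNP."""
    L = len(enzyme.site)

    def overlapping_cuts(window: str) -> set[int]:
        cuts = set()
        pats = [(enzyme.site, enzyme.cut_offset)]
        if not enzyme.is_palindromic:
            pats.append((_iupac_revcomp(enzyme.site), L - enzyme.cut_offset))
        for site, off in pats:
            pat = re.compile("(?=" + "".join(IUPAC[b] for b in site) + ")")
            for m in pat.finditer(window):
                if m.start() <= center < m.start() + L:
                    cuts.add(m.start() + off)
        return cuts

    return overlapping_cuts(ref_window), overlapping_cuts(alt_window)


def find_snip_snps(snps, genome: ReferenceGenome, panel: EnzymePanel
                   ) -> list[tuple[object, dict[str, str]]]:
    """Screen SNPs for alleles that alter restriction sites.

    For each enzyme, recognition-site occurrences overlapping the SNP are
    collected in the reference-allele and alternate-allele windows (both
    strands); enzymes whose resulting cut positions differ between alleles
    are reported as ``gained`` (more sites in the alternate allele),
    ``lost`` (fewer) or ``shifted``.  SNPs with at least one such enzyme
    are snip-SNPs; SNPs too close to a contig end are skipped.
    """
    w = panel.max_site_length - 1
    results = []
    for snp in snps:
        seq = genome.contigs[snp.contig]
        if snp.position < w or snp.position + w + 1 > len(seq):
            continue  # window would run off the contig
        ref_window = seq[snp.position - w:snp.position + w + 1]
        alt_window = ref_window[:w] + snp.alt + ref_window[w + 1:]
        hits: dict[str, str] = {}
        for enzyme in panel:
            ref_cuts, alt_cuts = snp_cut_sets(ref_window, alt_window, enzyme, w)
            if ref_cuts != alt_cuts:
                if len(alt_cuts) > len(ref_cuts):
                    hits[enzyme.name] = "gained"
                elif len(alt_cuts) < len(ref_cuts):
                    hits[enzyme.name] = "lost"
                else:
                    hits[enzyme.name] = "shifted"
        if hits:
            results.append((snp, hits))
    return results


def snip_snp_fraction(n_snip: int, n_total: int) -> float:
    """Percentage of SNPs that are snip-SNPs, rounded to 2 decimals."""
    return round(100.0 * n_snip / n_total, 2)


# ---------------------------------------------------------------------------
# Primer design


@dataclass(frozen=True)
class PrimerPair:
    left: str
    right: str  # 5'->3' on the bottom strand
    left_start: int  # 0-based contig coordinate of the left primer's 5' end
    right_end: int  # 0-based half-open end of the amplicon
    tm_left: float
    tm_right: float

    @property
    def product_size(self) -> int:
        return self.right_end - self.left_start


class PrimerFailure(Exception):
    """No acceptable primer pair exists for the requested geometry."""


def _tm(seq: str) -> float:
    # Nearest-neighbor Tm at the library's default salt/primer concentrations.
    return MeltingTemp.Tm_NN(seq)


def _occurrences(genome: ReferenceGenome, primer: str) -> int:
    n = 0
    rc = revcomp(primer)
    for seq in genome.contigs.values():
        n += seq.count(primer) + seq.count(rc)
    return n


def design_primers(genome: ReferenceGenome, contig: str, target_start: int,
                   target_end: int, product_range: tuple[int, int] = (500, 1000),
                   tm_range: tuple[float, float] = (54.0, 56.0),
                   primer_length: tuple[int, int] = (18, 27)) -> PrimerPair:
    """Scan outward from the target for a unique primer pair.

    Primers of 18-27 bp are accepted when their nearest-neighbor Tm falls
    in ``tm_range``, the product lies in ``product_range`` and contains the
    target, and each primer occurs exactly once in the genome (both strands
    counted).  Raises :class:`PrimerFailure` when the geometry admits no
    pair.
    """
    seq = genome.contigs[contig]
    lo_prod, hi_prod = product_range
    if target_end - target_start > hi_prod:
        raise ValueError("target interval longer than the maximum product")
    lmin, lmax = primer_length
    tlo, thi = tm_range

    def left_candidates():
        # 5' ends walk outward (leftward) from the target
        for start in range(target_start - lmin,
                           max(target_end - hi_prod, 0) - 1, -1):
            if start < 0:
                return
            for L in range(lmin, lmax + 1):
                if start + L > target_start + 1:
                    break
                tm = _tm(seq[start:start + L])
                if tlo <= tm <= thi:
                    yield (start, L, tm)
                    break

    def right_candidates():
        # amplicon 3' ends walk outward (rightward) from the target
        for end in range(target_end + lmin,
                         min(target_start + hi_prod, len(seq)) + 1):
            for L in range(lmin, lmax + 1):
                if end - L < target_end - 1:
                    break
                tm = _tm(revcomp(seq[end - L:end]))
                if tlo <= tm <= thi:
                    yield (end, L, tm)
                    break

    # Alternate pulling candidates from each side so the first acceptable
    # pair (smallest conforming product) is found without scanning the
    # whole geometric range.
    lefts: list[tuple[int, int, float]] = []
    rights: list[tuple[int, int, float]] = []
    gen_l, gen_r = left_candidates(), right_candidates()
    exhausted_l = exhausted_r = False

    def try_pair(start, Ll, tml, end, Lr, tmr):
        size = end - start
        if size < lo_prod or size > hi_prod:
            return None
        left = seq[start:start + Ll]
        right = revcomp(seq[end - Lr:end])
        if _occurrences(genome, left) != 1 or _occurrences(genome, right) != 1:
            return None
        return PrimerPair(left, right, start, end, tml, tmr)

    while not (exhausted_l and exhausted_r):
        if not exhausted_l:
            cand = next(gen_l, None)
            if cand is None:
                exhausted_l = True
            else:
                lefts.append(cand)
                for end, Lr, tmr in rights:
                    pair = try_pair(cand[0], cand[1], cand[2], end, Lr, tmr)
                    if pair:
                        return pair
        if not exhausted_r:
            cand = next(gen_r, None)
            if cand is None:
                exhausted_r = True
            else:
                rights.append(cand)
                for start, Ll, tml in lefts:
                    pair = try_pair(start, Ll, tml, cand[0], cand[1], cand[2])
                    if pair:
                        return pair
    raise PrimerFailure(
        f"no primer pair for {contig}:{target_start}-{target_end} "
        f"(product {product_range}, Tm {tm_range})")


# ---------------------------------------------------------------------------
# RFLP and PLP assays


@dataclass
class RflpAssay:
    snp_id: str
    enzyme: str
    primers: Optional[PrimerPair]
    fragments_ref: list[int]
    fragments_alt: list[int]
    status: str  # pass | too_many_bands | not_resolvable | primer_failure


def patterns_resolvable(a: list[int], b: list[int], min_diff: int = 10,
                        rel_diff: float = 0.05) -> bool:
    """Gel resolvability: some fragment of one pattern differs from every
    fragment of the other by at least max(min_diff, rel_diff * length)."""
    for one, other in ((a, b), (b, a)):
        for f in one:
            margin = max(min_diff, rel_diff * f)
            if all(abs(f - g) >= margin for g in other):
                return True
    return False


def predict_rflp(snp, snp_id: str, enzyme: RestrictionEnzyme,
                 genome: ReferenceGenome,
                 product_range: tuple[int, int] = (500, 1000),
                 tm_range: tuple[float, float] = (54.0, 56.0),
                 max_bands: int = 4) -> RflpAssay:
    """Design and evaluate one RFLP assay for a snip-SNP/enzyme pair."""
    try:
        primers = design_primers(genome, snp.contig, snp.position,
                                 snp.position + 1, product_range, tm_range)
    except (PrimerFailure, ValueError):
        return RflpAssay(snp_id, enzyme.name, None, [], [], "primer_failure")
    seq = genome.contigs[snp.contig]
    amp_ref = seq[primers.left_start:primers.right_end]
    off = snp.position - primers.left_start
    amp_alt = amp_ref[:off] + snp.alt + amp_ref[off + 1:]
    frags_ref = digest_amplicon(amp_ref, enzyme)
    frags_alt = digest_amplicon(amp_alt, enzyme)
    if len(frags_ref) > max_bands or len(frags_alt) > max_bands:
        status = "too_many_bands"
    elif frags_ref == frags_alt or not patterns_resolvable(frags_ref, frags_alt):
        status = "not_resolvable"
    else:
        status = "pass"
    return RflpAssay(snp_id, enzyme.name, primers, frags_ref, frags_alt, status)


@dataclass
class PlpAssay:
    indel_id: str
    assay_class: str  # "small" | "medium"
    primers: Optional[PrimerPair]
    amplicon_ref: int
    amplicon_alt: int
    status: str  # pass | excluded_too_small | infeasible | primer_failure


#: Reference-strain amplicon size ranges by assay class.
PLP_PRODUCT_RANGES = {"small": (200, 400), "medium": (300, 800)}
SMALL_PLP_MIN_SIZE = 7


def plp_band_sizes(amplicon_ref: int, indel_type: str, size: int) -> int:
    """Alternate-strain amplicon length implied by an indel.

    The alternate strain carries the indel, so its amplicon is shorter by
    ``size`` for a deletion and longer for an insertion.
    """
    return amplicon_ref - size if indel_type == "del" else amplicon_ref + size


def design_plp(indel, indel_id: str, genome: ReferenceGenome,
               assay_class: str,
               tm_range: tuple[float, float] = (54.0, 56.0)) -> PlpAssay:
    """Design a PCR length-polymorphism assay for an indel call.

    Small-class assays (7-49 bp indels) target reference amplicons of
    200-400 bp; medium-class assays (50-2,000 bp) target 300-800 bp.
    Indels under 7 bp cannot be resolved on a gel and are excluded.
    """
    if assay_class not in PLP_PRODUCT_RANGES:
        raise ValueError(f"unknown assay class {assay_class!r}")
    product_range = PLP_PRODUCT_RANGES[assay_class]
    if assay_class == "small" and indel.size < SMALL_PLP_MIN_SIZE:
        return PlpAssay(indel_id, assay_class, None, 0, 0, "excluded_too_small")
    span = indel.size if indel.indel_type == "del" else 0
    if span + 2 * 18 > product_range[1]:
        return PlpAssay(indel_id, assay_class, None, 0, 0, "infeasible")
    try:
        primers = design_primers(genome, indel.contig, indel.position,
                                 indel.position + span, product_range, tm_range)
    except (PrimerFailure, ValueError):
        return PlpAssay(indel_id, assay_class, None, 0, 0, "primer_failure")
    ref_len = primers.product_size
    alt_len = plp_band_sizes(ref_len, indel.indel_type, indel.size)
    return PlpAssay(indel_id, assay_class, primers, ref_len, alt_len, "pass")


# ---------------------------------------------------------------------------
# Validation summary


VALID_LABELS = {"pcr_failure", "similar", "different", "false"}


@dataclass
class ValidationSummary:
    """Per-category wet-lab validation bookkeeping.

    ``confirmed = similar + different`` (a polymorphism was present, whether
    or not the bands matched prediction); rates are percentages of
    successful PCRs, rounded to the nearest integer.
    """

    categories: dict[str, dict[str, int]]
    totals: dict[str, int]
    success_rate: Optional[int] = None
    similar_rate: Optional[int] = None

    def __post_init__(self):
        t = self.totals
        if t.get("successful", 0) > 0:
            confirmed = t["similar"] + t["different"]
            self.success_rate = round(100.0 * confirmed / t["successful"])
            self.similar_rate = round(100.0 * t["similar"] / t["successful"])


def summarize_validation(records: list[tuple[str, str]]) -> ValidationSummary:
    """Aggregate (category, label) validation records.

    Labels: ``pcr_failure``, ``similar`` (bands as predicted), ``different``
    (polymorphism present but bands differ), ``false`` (no polymorphism).
    """
    categories: dict[str, dict[str, int]] = {}
    for category, label in records:
        if label not in VALID_LABELS:
            raise ValueError(f"unlabeled/unknown record label {label!r}")
        c = categories.setdefault(category, {k: 0 for k in VALID_LABELS})
        c[label] += 1
    for c in categories.values():
        c["attempted"] = sum(c[k] for k in VALID_LABELS)
        c["successful"] = c["attempted"] - c["pcr_failure"]
        c["confirmed"] = c["similar"] + c["different"]
    keys = ("attempted", "pcr_failure", "successful", "similar", "different",
            "false", "confirmed")
    totals = {k: sum(c[k] for c in categories.values()) for k in keys}
    return ValidationSummary(categories, totals)


def summarize_validation_counts(counts: dict[str, dict[str, int]]
                                ) -> ValidationSummary:
    """Build the summary from per-category label counts."""
    records = [(cat, label) for cat, labels in counts.items()
               for label, n in labels.items() for _ in range(n)]
    return summarize_validation(records)
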