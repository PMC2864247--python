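"""Mutation mapping by bulk-segregant ULV statistics and single-recombinant
analysis.

The experimental design: a mutant in the reference background (carrying a
recessive mutation) is crossed to the divergent strain; F1 hermaphrodites
self, and F2 progeny segregate 1:2:1 at every locus.  Pooled DNA from
phenotypically mutant F2 animals is genotyped at strain-diagnostic markers.
At a marker with recombination fraction r to the mutation, mutant animals
carry the reference allele at frequency 1-r per chromosome, so the ratio of
reference-strain to divergent-strain band intensity in the mutant lane (the
unitless linkage value, ULV) has expectation (1-r)/r: about 1 for unlinked
markers and larger for linked ones.

Single recombinant analysis (SRA) genotypes individual mutant F2 animals:
the recombination fraction estimate is simply recombinant chromosomes over
chromosomes scored (each animal contributes two), with a Wilson 95% CI.

Cross simulation uses the Haldane map function r = (1 - e^(-2d/100)) / 2
(no interference) and is fully vectorized, so thousand-replicate power
checks of the ULV and SRA statistics run in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from statsmodels.stats.proportion import proportion_confint


def haldane_r(d_cm: float) -> float:
    """Recombination fraction for a map distance in centimorgans."""
    return 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))


def kosambi_r(d_cm: float) -> float:
    return 0.5 * np.tanh(2.0 * d_cm / 100.0)


MAP_FUNCTIONS = {"haldane": haldane_r, "kosambi": kosambi_r}


@dataclass(frozen=True)
class Marker:
    name: str
    chromosome: str
    cm: float
    arm: str = ""  # optional arm/center annotation for region labels


@dataclass
class GeneticMap:
    """Ordered markers per chromosome plus the mutation locus."""

    markers: list[Marker]
    mutation_chromosome: str
    mutation_cm: float
    map_function: str = "haldane"

    def __post_init__(self):
        if not self.markers:
            raise ValueError("empty genetic map")
        if self.map_function not in MAP_FUNCTIONS:
            raise ValueError(f"unknown map function {self.map_function!r}")
        for m in self.markers:
            if m.cm < 0:
                raise ValueError("negative map position")
        by_chrom: dict[str, list[Marker]] = {}
        for m in self.markers:
            by_chrom.setdefault(m.chromosome, []).append(m)
        for ms in by_chrom.values():
            ms.sort(key=lambda m: m.cm)
        self.by_chromosome = by_chrom

    def chromosome_loci(self, chromosome: str) -> tuple[list[str], np.ndarray]:
        """Locus names and cM positions on one chromosome, mutation included."""
        names = [m.name for m in self.by_chromosome.get(chromosome, [])]
        pos = [m.cm for m in self.by_chromosome.get(chromosome, [])]
        if chromosome == self.mutation_chromosome:
            names.append("__mutation__")
            pos.append(self.mutation_cm)
            order = np.argsort(pos, kind="stable")
            names = [names[i] for i in order]
            pos = [pos[i] for i in order]
        return names, np.asarray(pos, dtype=float)


@dataclass
class F2Cohort:
    """Genotypes of an F2 selfing cohort (0/1/2 = divergent-allele dosage)."""

    genotypes: dict[str, np.ndarray]  # chromosome -> (n, n_loci)
    locus_names: dict[str, list[str]]
    phenotype_mutant: np.ndarray  # (n,) bool

    def __len__(self) -> int:
        return len(self.phenotype_mutant)

    def marker_genotypes(self, marker: str, mutant_only: bool = False
                         ) -> np.ndarray:
        for chrom, names in self.locus_names.items():
            if marker in names:
                g = self.genotypes[chrom][:, names.index(marker)]
                return g[self.phenotype_mutant] if mutant_only else g
        raise KeyError(marker)

    def to_individuals(self) -> list[dict]:
        """Per-animal records with AA/AH/HH genotype strings."""
        code = {0: "AA", 1: "AH", 2: "HH"}
        out = []
        for i in range(len(self)):
            geno = {}
            for chrom, names in self.locus_names.items():
                for j, name in enumerate(names):
                    if name != "__mutation__":
                        geno[name] = code[int(self.genotypes[chrom][i, j])]
            out.append({"phenotype": "mutant" if self.phenotype_mutant[i]
                        else "wild", "genotypes": geno})
        return out


def simulate_cross(gmap: GeneticMap, n_f2: int, seed: int) -> F2Cohort:
    """Simulate n_f2 progeny of a selfing F1 heterozygote.

    Each F2 receives two independent F1 gametes; along a chromosome, the
    gamete's strain-of-origin switches between adjacent loci with the
    recombination fraction given by the map function (no interference).
    Phenotype is recessive: mutant iff homozygous for the reference-strain
    allele at the mutation locus.
    """
    if n_f2 <= 0:
        raise ValueError("n_f2 must be positive")
    rng = np.random.default_rng(seed)
    rfun = MAP_FUNCTIONS[gmap.map_function]
    genotypes: dict[str, np.ndarray] = {}
    locus_names: dict[str, list[str]] = {}
    phenotype: Optional[np.ndarray] = None
    chroms = sorted(set(m.chromosome for m in gmap.markers)
                    | {gmap.mutation_chromosome})
    for chrom in chroms:
        names, pos = gmap.chromosome_loci(chrom)
        L = len(names)
        rs = np.array([rfun(d) for d in np.diff(pos)])
        # gametes: (n, 2, L) indicator of divergent-strain origin
        start = rng.random((n_f2, 2, 1)) < 0.5
        if L > 1:
            rec = rng.random((n_f2, 2, L - 1)) < rs
            path = np.concatenate([start, rec], axis=2)
            # cumulative XOR along loci: strain of origin flips at recombinations
            alleles = (np.cumsum(path, axis=2) % 2).astype(np.int8)
        else:
            alleles = start.astype(np.int8)
        g = alleles.sum(axis=1)  # (n, L) dosage of divergent allele
        genotypes[chrom] = g
        locus_names[chrom] = names
        if "__mutation__" in names:
            phenotype = g[:, names.index("__mutation__")] == 0
    if phenotype is None:
        raise ValueError("mutation locus not on the map")
    return F2Cohort(genotypes, locus_names, phenotype)


@dataclass
class PoolIntensity:
    """Band intensities of one pool lane at one marker."""

    marker: str
    lane: str  # "mutant" | "non-mutant"
    intensity_a: float  # reference-strain band
    intensity_h: float  # divergent-strain band

    def __post_init__(self):
        if self.intensity_a < 0 or self.intensity_h < 0:
            raise ValueError("negative band intensity")
        if self.intensity_a == 0 and self.intensity_h == 0:
            raise ValueError("both bands zero")


def pool_intensities(genotypes: np.ndarray, marker: str, lane: str,
                     noise_sd: float, seed: int) -> PoolIntensity:
    """Band intensities for a pooled lane: intensity is proportional to
    pooled allele dosage, perturbed by multiplicative lognormal noise."""
    g = np.asarray(genotypes)
    if g.size == 0:
        raise ValueError("empty pool")
    dose_h = float(g.sum())
    dose_a = float((2 - g).sum())
    if dose_a == 0 and dose_h == 0:
        raise ValueError("no allele dosage in pool")
    rng = np.random.default_rng(seed)
    noise = np.exp(rng.normal(0.0, noise_sd, size=2)) if noise_sd > 0 else (1.0, 1.0)
    return PoolIntensity(marker, lane, dose_a * noise[0], dose_h * noise[1])


@dataclass
class UlvResult:
    marker: str
    ulv: float
    linked: bool
    capped: bool = False
    lane: str = "mutant"


ULV_CAP = 50.0
ULV_NOISE_FLOOR = 0.01  # H band below 1% of A band -> capped


def compute_ulv(pool: PoolIntensity, threshold: float = 1.5,
                cap: float = ULV_CAP, noise_floor: float = ULV_NOISE_FLOOR
                ) -> UlvResult:
    """ULV = reference-band intensity / divergent-band intensity.

    When the divergent band vanishes into the noise floor the ratio is
    capped (tightly linked markers would otherwise divide by ~0).
    """
    a, h = pool.intensity_a, pool.intensity_h
    if h <= noise_floor * a:
        return UlvResult(pool.marker, cap, cap >= threshold, capped=True,
                         lane=pool.lane)
    ulv = a / h
    return UlvResult(pool.marker, ulv, ulv >= threshold, lane=pool.lane)


@dataclass
class LinkageCall:
    status: str  # "assigned" | "ambiguous" | "unlinked"
    chromosome: Optional[str]
    ulvs: dict[str, float]


def call_linkage(ulvs_by_chromosome: dict[str, UlvResult],
                 threshold: float = 1.5) -> LinkageCall:
    """Assign the mutation to a chromosome from one marker per chromosome."""
    linked = [c for c, u in ulvs_by_chromosome.items() if u.ulv >= threshold]
    values = {c: u.ulv for c, u in ulvs_by_chromosome.items()}
    if len(linked) == 1:
        return LinkageCall("assigned", linked[0], values)
    if not linked:
        return LinkageCall("unlinked", None, values)
    return LinkageCall("ambiguous", None, values)


@dataclass
class Localization:
    region: str  # arm label of the winning marker, or tied interval
    markers: list[str]
    warning: Optional[str] = None


def localize(marker_ulvs: list[tuple[Marker, float]]) -> Localization:
    """Assign the mutation to the marker (region) with the largest ULV.

    With fewer than 3 markers the argmax is still returned but flagged as
    insufficient resolution; exact ties span the tied markers.
    """
    if not marker_ulvs:
        raise ValueError("no markers")
    warning = ("insufficient resolution: fewer than 3 markers"
               if len(marker_ulvs) < 3 else None)
    best = max(u for _, u in marker_ulvs)
    winners = [m for m, u in marker_ulvs if u == best]
    if len(winners) == 1:
        m = winners[0]
        region = m.arm or m.name
        return Localization(region, [m.name], warning)
    region = "-".join(m.arm or m.name for m in winners)
    return Localization(region, [m.name for m in winners], warning)


@dataclass
class SraResult:
    n_chromosomes: int
    k_recombinants: int
    r_hat: float
    ci_low: float
    ci_high: float

    @property
    def percent(self) -> float:
        return 100.0 * self.r_hat

    @property
    def percent_rounded(self) -> int:
        return round(self.percent)


def sra_estimate(n_animals: int, k_recombinant_chromosomes: int,
                 chromosomes_per_animal: int = 2) -> SraResult:
    """Single-recombinant-analysis recombination fraction: k / n.

    Each homozygous-mutant F2 animal contributes ``chromosomes_per_animal``
    scorable chromosomes; a heterozygous marker genotype is 1 recombinant
    chromosome, homozygous divergent is 2.  The 95% CI is Wilson's.
    """
    n = n_animals * chromosomes_per_animal
    k = k_recombinant_chromosomes
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    r_hat = k / n
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return SraResult(n, k, r_hat, float(lo), float(hi))


def count_recombinant_chromosomes(genotypes: np.ndarray) -> int:
    """Recombinant chromosomes at a marker among homozygous-mutant animals:
    divergent-allele dosage summed over animals."""
    return int(np.asarray(genotypes).sum())


def expected_ulv(r: float) -> float:
    """Analytic expectation of the mutant-pool ULV: (1 - r) / r.

    In a recessive mutant F2 pool the reference allele segregates at
    frequency 1-r per chromosome, so the dosage ratio A:H is (1-r)/r;
    unlinked markers (r = 0.5) give 1."""
    if r <= 0 or r > 0.5:
        raise ValueError("r must be in (0, 0.5]")
    return (1.0 - r) / r


def simulate_bsa_replicates(r: float, pool_size: int, n_replicates: int,
                            noise_sd: float, seed: int) -> np.ndarray:
    """Monte-Carlo ULVs of mutant pools at a given marker-mutation distance.

    Simulates full selfing crosses (two loci: mutation and marker at
    recombination fraction r), selects mutant F2s into pools of
    ``pool_size``, and computes one ULV per replicate.  Used by the
    unlinked-baseline and (1-r)/r calibration checks.
    """
    if not 0 < r <= 0.5:
        raise ValueError("r must be in (0, 0.5]")
    rng = np.random.default_rng(seed)
    ulvs = np.empty(n_replicates)
    # distance with the requested r under Haldane
    d = -50.0 * np.log(1.0 - 2.0 * min(r, 0.499999)) if r < 0.5 else 1e6
    gmap = GeneticMap([Marker("m", "chr1", d)], "chr1", 0.0)
    for i in range(n_replicates):
        need = pool_size
        doses_a = doses_h = 0.0
        while need > 0:
            cohort = simulate_cross(gmap, max(5 * need, 40),
                                    int(rng.integers(0, 2**31 - 1)))
            g = cohort.marker_genotypes("m", mutant_only=True)[:need]
            doses_h += g.sum()
            doses_a += (2 - g).sum()
            need -= len(g)
        noise = (np.exp(rng.normal(0, noise_sd, 2)) if noise_sd > 0
                 else np.ones(2))
        ulvs[i] = (doses_a * noise[0]) / (doses_h * noise[1])
    return ulvs
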