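"""Shared fixtures: synthetic genomes, strains, reads and alignments.

Heavy fixtures are session-scoped so the 1 Mb discovery benchmark and the
breakpoint fixture are generated and aligned exactly once per run.
"""

import pytest

from nemamap.align import align_reads
from nemamap.assays import default_panel
from nemamap.simulate import (SimConfig, derive_strain, generate_reference,
                              simulate_reads)


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def small_fixture():
    """50 kb single-contig genome with default variant densities."""
    cfg = SimConfig(contig_length=(50_000, 50_000), seed=3, coverage=8)
    genome = generate_reference(cfg)
    strain, truth = derive_strain(genome, cfg)
    reads = simulate_reads(strain, cfg)
    return cfg, genome, strain, truth, reads


@pytest.fixture(scope="session")
def small_alignments(small_fixture):
    cfg, genome, strain, truth, reads = small_fixture
    return align_reads(reads, genome)


@pytest.fixture(scope="session")
def mb_fixture():
    """1 Mb genome at the default study conditions (1 SNP / 163 bp,
    coverage 8, 0.1% read error): the discovery benchmark."""
    cfg = SimConfig(n_chromosomes=2, contigs_per_chromosome=2,
                    contig_length=(250_000, 250_000), seed=42, coverage=8)
    genome = generate_reference(cfg)
    strain, truth = derive_strain(genome, cfg)
    reads = simulate_reads(strain, cfg)
    return cfg, genome, strain, truth, reads


@pytest.fixture(scope="session")
def mb_alignments(mb_fixture):
    cfg, genome, strain, truth, reads = mb_fixture
    return align_reads(reads, genome)


@pytest.fixture(scope="session")
def breakpoint_fixture():
    """200 kb error-free fixture dense in medium (50-350 bp) indels."""
    cfg = SimConfig(contig_length=(200_000, 200_000), seed=19, coverage=8,
                    medium_indel_rate=30 / 200_000,
                    medium_indel_size=(50, 350), error_rate=0.0)
    genome = generate_reference(cfg)
    strain, truth = derive_strain(genome, cfg)
    reads = simulate_reads(strain, cfg)
    alignments = align_reads(reads, genome)
    return cfg, genome, strain, truth, alignments


@pytest.fixture(scope="session")
def snip_fixture():
    """30 kb genome whose SNP truth set feeds the snip-SNP screen."""
    cfg = SimConfig(contig_length=(30_000, 30_000), seed=9)
    genome = generate_reference(cfg)
    strain, truth = derive_strain(genome, cfg)
    return genome, truth
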