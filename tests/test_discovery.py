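"""Alignment and SNP/small-indel discovery against the planted truth."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nemamap.align import KmerIndex, align_read, align_reads
from nemamap.discovery import (DiscoverySummary, SnpCall,
                               alignment_stats, call_small_indels, call_snps,
                               dedupe_loci, liftover_agp, liftover_agp_inverse,
                               place_by_flank, substitution_spectrum,
                               summarize_discovery)
from nemamap.simulate import (AgpRow, ReadSet, ReferenceGenome, SimConfig,
                              derive_strain, generate_reference, revcomp,
                              simulate_reads, strain_to_ref)


def _mini_genome(seed=21, length=20_000):
    cfg = SimConfig(contig_length=(length, length), seed=seed, snp_rate=0,
                    small_indel_rate=0, medium_indel_rate=0)
    return generate_reference(cfg)


class TestAlignReads:
    def test_exact_substring_single_block(self):
        g = _mini_genome()
        cid = next(iter(g.contigs))
        read = g.contigs[cid][5_000:5_500]
        aln = align_read(read, g, KmerIndex(g))
        assert aln is not None and len(aln.blocks) == 1
        b = aln.blocks[0]
        assert (b.ref_start, b.ref_end, b.strand) == (5_000, 5_500, "+")
        assert aln.identity == 1.0 and aln.unique

    def test_reverse_strand_read_found(self):
        g = _mini_genome()
        cid = next(iter(g.contigs))
        read = revcomp(g.contigs[cid][7_000:7_400])
        aln = align_read(read, g, KmerIndex(g))
        assert aln is not None
        assert aln.strand == "-"
        assert aln.blocks[0].ref_start == 7_000

    def test_500bp_deletion_gives_two_blocks(self):
        g = _mini_genome()
        cid = next(iter(g.contigs))
        seq = g.contigs[cid]
        read = seq[4_000:4_250] + seq[4_750:5_000]  # strain lacks 500 bp
        aln = align_read(read, g, KmerIndex(g))
        assert aln is not None and len(aln.blocks) == 2
        left, right = sorted(aln.blocks, key=lambda b: b.read_start)
        assert right.ref_start - left.ref_end == 500
        assert right.read_start - left.read_end == 0

    def test_most_reads_align_to_true_origin(self, small_fixture,
                                             small_alignments):
        """>= 99% of alignable fixture reads land at their true origin."""
        cfg, genome, strain, truth, reads = small_fixture
        origin = {r[0]: (r[2], r[3]) for r in reads.reads}
        ok = 0
        for aln in small_alignments:
            # the aligned query is always the forward-strand strain segment
            # (minus-strand reads are aligned as their reverse complement),
            # so block read coordinates map onto strain coordinates directly
            cid, strain_start = origin[aln.read_id]
            b = min(aln.blocks, key=lambda b: b.read_start)
            expect = strain_to_ref(truth, cid, strain_start + b.read_start)
            if aln.contig == cid and abs(b.ref_start - expect) <= 30:
                ok += 1
        assert len(small_alignments) / len(reads) > 0.9
        assert ok / len(small_alignments) >= 0.99

    def test_empty_read_set(self, small_fixture):
        _, genome, *_ = small_fixture
        assert align_reads(ReadSet([]), genome) == []


class TestCallSnps:
    def test_single_mismatch_called(self):
        g = _mini_genome()
        cid = next(iter(g.contigs))
        seq = g.contigs[cid]
        pos = 6_200
        alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[seq[pos]]
        read = seq[6_000:pos] + alt + seq[pos + 1:6_500]
        aln = align_read(read, g, KmerIndex(g))
        calls = call_snps([aln], g, min_quality=0.5)
        assert len(calls) == 1
        c = calls[0]
        assert (c.position, c.ref, c.alt, c.support) == (pos, seq[pos], alt, 1)

    def test_reference_read_gives_no_calls(self):
        g = _mini_genome()
        cid = next(iter(g.contigs))
        aln = align_read(g.contigs[cid][100:600], g, KmerIndex(g))
        assert call_snps([aln], g, min_quality=0.0) == []

    def test_unknown_contig_rejected(self):
        g = _mini_genome()
        cid = next(iter(g.contigs))
        aln = align_read(g.contigs[cid][100:600], g, KmerIndex(g))
        aln.blocks[0].ref_contig = "nope"
        with pytest.raises(ValueError):
            call_snps([aln], g)

    def test_fixture_recall_precision(self, small_fixture, small_alignments):
        _, genome, _, truth, _ = small_fixture
        snps = call_snps(small_alignments, genome)
        indels = call_small_indels(small_alignments, genome)
        snps, indels = dedupe_loci(snps, indels)
        ts = {(v.contig, v.ref_position, v.alt_allele)
              for v in truth if v.var_class == "snp"}
        cs = {(c.contig, c.position, c.alt) for c in snps}
        tp = len(cs & ts)
        assert tp / len(ts) >= 0.95
        assert tp / len(cs) >= 0.95

    def test_no_snp_and_indel_share_a_position(self, small_fixture,
                                               small_alignments):
        _, genome, *_ = small_fixture
        snps, indels = dedupe_loci(call_snps(small_alignments, genome),
                                   call_small_indels(small_alignments, genome))
        snp_pos = {(c.contig, c.position) for c in snps}
        ind_pos = {(c.contig, c.position) for c in indels}
        assert not snp_pos & ind_pos


class TestCallSmallIndels:
    def test_planted_12bp_deletion(self):
        g = _mini_genome(seed=22)
        cid = next(iter(g.contigs))
        seq = g.contigs[cid]
        read = seq[3_000:3_250] + seq[3_262:3_512]
        aln = align_read(read, g, KmerIndex(g))
        calls = call_small_indels([aln], g)
        assert len(calls) == 1
        c = calls[0]
        assert (c.indel_type, c.size) == ("del", 12)

    def test_49bp_insertion_at_class_boundary(self):
        rng = np.random.default_rng(8)
        g = _mini_genome(seed=23)
        cid = next(iter(g.contigs))
        seq = g.contigs[cid]
        ins = "".join("ACGT"[i] for i in rng.integers(0, 4, 49))
        read = seq[3_000:3_250] + ins + seq[3_250:3_450]
        aln = align_read(read, g, KmerIndex(g))
        calls = call_small_indels([aln], g)
        assert [(c.indel_type, c.size) for c in calls] == [("ins", 49)]

    def test_fixture_sizes_in_class_and_recall(self, small_fixture,
                                               small_alignments):
        _, genome, _, truth, _ = small_fixture
        calls = call_small_indels(small_alignments, genome)
        assert all(1 <= c.size <= 49 for c in calls)
        ti = {(v.contig, v.ref_position, v.indel_type, v.size)
              for v in truth if v.var_class == "small_indel"}
        ci = {(c.contig, c.position, c.indel_type, c.size) for c in calls}
        assert len(ci & ti) / len(ti) >= 0.9


class TestSummary:
    @pytest.mark.parametrize("loci,bp,density,per_snp", [
        (23_829, 3_884_127, 6.13, 163),
        (9_111, 4_327_725, 2.11, 475),
        (5_164, 867_552, 5.95, 168),
    ])
    def test_density_arithmetic(self, loci, bp, density, per_snp):
        s = DiscoverySummary.from_counts(loci, bp)
        assert s.density_per_kb == density
        assert s.bp_per_snp == per_snp

    def test_zero_loci(self):
        s = DiscoverySummary.from_counts(0, 1_000)
        assert s.density_per_kb == 0.0 and s.bp_per_snp is None

    def test_zero_bp_with_loci_rejected(self):
        with pytest.raises(ValueError):
            DiscoverySummary.from_counts(10, 0)

    @given(loci=st.integers(1, 10**6), bp=st.integers(1, 10**8))
    @settings(max_examples=200, deadline=None)
    def test_density_identity(self, loci, bp):
        """density_per_kb x bp_per_snp ~ 1000 up to rounding."""
        s = DiscoverySummary.from_counts(loci, bp)
        if s.density_per_kb > 0.1 and s.bp_per_snp > 2:
            assert s.density_per_kb * s.bp_per_snp == pytest.approx(
                1000, rel=0.35)

    def test_from_alignment_stats(self, small_fixture, small_alignments):
        _, genome, *_ = small_fixture
        stats = alignment_stats(small_alignments, genome)
        snps = call_snps(small_alignments, genome)
        s = summarize_discovery(snps, stats)
        assert s.unique_aligned_bp <= genome.total_length
        assert s.spectrum is not None
        assert s.density_per_kb == pytest.approx(
            1000 * len(snps) / s.unique_aligned_bp, abs=0.01)


class TestSpectrum:
    def test_strand_collapsing(self):
        calls = [SnpCall("c", 1, "A", "G", 1, 1.0),
                 SnpCall("c", 2, "T", "C", 1, 1.0)]
        spec = substitution_spectrum(calls)
        assert spec["A:T>G:C"] == 1.0
        assert sum(spec.values()) == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            substitution_spectrum([])

    def test_fixture_bias_recovered(self, small_fixture, small_alignments):
        _, genome, *_ = small_fixture
        snps = call_snps(small_alignments, genome)
        spec = substitution_spectrum(snps)
        assert spec["A:T>G:C"] == pytest.approx(0.571, abs=0.06)

    def test_uniform_bias_gives_flat_spectrum(self):
        cfg = SimConfig(contig_length=(300_000, 300_000), seed=17,
                        spectrum=(1 / 6,) * 6, small_indel_rate=0,
                        medium_indel_rate=0)
        g = generate_reference(cfg)
        _, truth = derive_strain(g, cfg)
        calls = [SnpCall(v.contig, v.ref_position, v.ref_allele,
                         v.alt_allele, 1, 1.0) for v in truth]
        spec = substitution_spectrum(calls)
        for frac in spec.values():
            assert frac == pytest.approx(1 / 6, abs=0.04)


class TestLiftover:
    AGP = [
        AgpRow("chr1", 1000, 2000, "component", component_id="ctgF",
               component_start=0, component_end=1000, orientation="+"),
        AgpRow("chr1", 2000, 2100, "gap", gap_length=100),
        AgpRow("chr1", 2100, 3100, "component", component_id="ctgR",
               component_start=0, component_end=1000, orientation="-"),
    ]

    def test_forward_component(self):
        p = liftover_agp("ctgF", 0, self.AGP)
        assert (p.status, p.chromosome, p.position) == ("placed", "chr1", 1000)

    def test_reverse_component(self):
        p = liftover_agp("ctgR", 0, self.AGP)
        assert (p.status, p.position) == ("placed", 3099)

    def test_unplaced_contig(self):
        assert liftover_agp("ctgX", 5, self.AGP).status == "unplaced"

    def test_position_outside_span_rejected(self):
        with pytest.raises(ValueError):
            liftover_agp("ctgF", 1500, self.AGP)

    def test_roundtrip_identity_random_positions(self):
        """Liftover then inverse is the identity for component positions."""
        cfg = SimConfig(n_chromosomes=3, contigs_per_chromosome=3,
                        contig_length=(5_000, 20_000), seed=31)
        g = generate_reference(cfg)
        rng = np.random.default_rng(0)
        contigs = list(g.contigs)
        for _ in range(2_000):
            cid = contigs[rng.integers(0, len(contigs))]
            pos = int(rng.integers(0, len(g.contigs[cid])))
            p = liftover_agp(cid, pos, g.agp)
            assert p.status == "placed"
            back = liftover_agp_inverse(p.chromosome, p.position, g.agp)
            assert (back.contig, back.contig_position) == (cid, pos)


class TestPlaceByFlank:
    def test_verbatim_flank_placed(self):
        g = _mini_genome(seed=25)
        cid = next(iter(g.contigs))
        p = place_by_flank(g.contigs[cid][8_000:8_200], g)
        assert (p.status, p.contig, p.contig_position) == ("placed", cid, 8_000)

    def test_duplicated_flank_ambiguous(self):
        g = _mini_genome(seed=26)
        cid = next(iter(g.contigs))
        seq = g.contigs[cid]
        dup = seq[:5_000] + seq[1_000:1_300] + seq[5_000:]
        g2 = ReferenceGenome({cid: dup}, [])
        assert place_by_flank(seq[1_050:1_250], g2).status == "ambiguous"

    def test_mutated_flank_still_placed(self):
        g = _mini_genome(seed=27)
        cid = next(iter(g.contigs))
        flank = list(g.contigs[cid][9_000:9_200])
        rng = np.random.default_rng(1)
        for i in rng.choice(200, size=4, replace=False):  # 2% divergence
            flank[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[flank[i]]
        p = place_by_flank("".join(flank), g)
        assert p.status == "placed" and abs(p.contig_position - 9_000) <= 2

    def test_short_flank_rejected(self):
        g = _mini_genome(seed=25)
        with pytest.raises(ValueError):
            place_by_flank("ACGT" * 5, g)
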