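"""RFLP / PLP assay design: digestion, snip-SNP screen, primers, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nemamap.assays import (EnzymePanel, PlpAssay, PrimerFailure,
                            RestrictionEnzyme, default_panel, design_plp,
                            design_primers, digest_amplicon, find_snip_snps,
                            patterns_resolvable, plp_band_sizes, predict_rflp,
                            snip_snp_fraction, summarize_validation,
                            summarize_validation_counts)
from nemamap.discovery import SnpCall
from nemamap.simulate import SimConfig, generate_reference, revcomp

DRA_I = RestrictionEnzyme("DraI", "TTTAAA", 3)
BASES = "ACGT"


def _random_without_site(rng, n, site="TTTAAA"):
    while True:
        s = "".join(BASES[i] for i in rng.integers(0, 4, n))
        if site not in s:
            return s


class TestDigestion:
    def test_bdp3_pattern(self):
        """907 bp amplicon: no site in one strain, one gained cut at 227 in
        the other -> [907] vs [227, 680]."""
        rng = np.random.default_rng(5)
        amp = _random_without_site(rng, 907)
        amp = amp[:224] + "TTTGAA" + amp[230:]
        alt = amp[:227] + "A" + amp[228:]
        assert digest_amplicon(amp, DRA_I) == [907]
        assert digest_amplicon(alt, DRA_I) == [227, 680]

    def test_cb15251_pattern(self):
        """747 bp amplicon with one cut 332 bp in -> [332, 415]."""
        rng = np.random.default_rng(6)
        amp = _random_without_site(rng, 747)
        amp = amp[:329] + "TTTAAA" + amp[335:]
        assert digest_amplicon(amp, DRA_I) == [332, 415]

    def test_non_palindromic_site_cut_on_both_strands(self):
        enz = RestrictionEnzyme("FakeI", "GACGTC"[:5] + "A", 1)  # GACGTA
        amp = "C" * 20 + "GACGTA" + "C" * 20 + revcomp("GACGTA") + "C" * 20
        frags = digest_amplicon(amp, enz)
        assert sum(frags) == len(amp) and len(frags) == 3

    def test_degenerate_iupac_site(self):
        enz = RestrictionEnzyme("HincII", "GTYRAC", 3)
        for mid in ("GTCAAC", "GTTGAC", "GTCGAC", "GTTAAC"):
            frags = digest_amplicon("G" * 30 + mid + "G" * 30, enz)
            assert frags == [33, 33]

    def test_empty_amplicon_rejected(self):
        with pytest.raises(ValueError):
            digest_amplicon("", DRA_I)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=150, deadline=None)
    def test_conservation_and_fragment_count(self, seed, panel):
        """Fragments sum to amplicon length; k cuts give k+1 fragments."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 1_500))
        amp = "".join(BASES[i] for i in rng.integers(0, 4, n))
        enzyme = panel.enzymes[int(rng.integers(0, len(panel)))]
        frags = digest_amplicon(amp, enzyme)
        assert sum(frags) == n
        assert len(frags) == len(enzyme.cut_positions(amp)) + 1


class TestPanel:
    def test_default_panel_loads_30_enzymes(self, panel):
        assert len(panel) == 30
        assert panel.get("DraI").site == "TTTAAA"
        assert panel.get("HindIII").cut_offset == 1

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError):
            EnzymePanel([DRA_I, DRA_I])

    def test_invalid_enzyme_rejected(self):
        with pytest.raises(ValueError):
            RestrictionEnzyme("X", "TTA", 1)  # too short
        with pytest.raises(ValueError):
            RestrictionEnzyme("X", "TTTAAA", 9)  # cut outside site
        with pytest.raises(ValueError):
            RestrictionEnzyme("X", "TTQAAA", 3)  # non-IUPAC


class TestSnipSnpScreen:
    def test_dra_site_gained(self, panel):
        rng = np.random.default_rng(7)
        seq = _random_without_site(rng, 2_000)
        seq = seq[:1_000] + "TTTGAA" + seq[1_006:]
        g = _genome_of(seq)
        snp = SnpCall("ctg", 1_003, "G", "A", 2, 2.0)  # TTTGAA -> TTTAAA
        results = find_snip_snps([snp], g, panel)
        assert len(results) == 1
        assert results[0][1].get("DraI") == "gained"

    def test_no_site_either_allele(self, panel):
        g = _genome_of("ACGTGCATCAGCATGCCGAT" * 50)
        snp = SnpCall("ctg", 500, "A", "T", 2, 2.0)
        snp = SnpCall("ctg", 501, g.contigs["ctg"][501],
                      "A" if g.contigs["ctg"][501] != "A" else "C", 2, 2.0)
        hits = [h for s, h in find_snip_snps([snp], g, panel)]
        # a designed repetitive sequence without any panel site nearby
        assert hits == [] or all("DraI" not in h for h in hits)

    def test_snp_near_contig_end_skipped(self, panel):
        g = _genome_of("ACGT" * 100)
        snp = SnpCall("ctg", 2, "G", "C", 2, 2.0)
        assert find_snip_snps([snp], g, panel) == []

    def test_matches_brute_force_digestion_oracle(self, panel, snip_fixture):
        """Classifier equals digesting full amplicons of both alleles for
        every fixture SNP and every panel enzyme."""
        genome, truth = snip_fixture
        snps = [SnpCall(v.contig, v.ref_position, v.ref_allele, v.alt_allele,
                        2, 2.0) for v in truth if v.var_class == "snp"]
        by_snp = {(s.contig, s.position): h
                  for s, h in find_snip_snps(snps, genome, panel)}
        w = 300
        checked = 0
        for s in snps:
            seq = genome.contigs[s.contig]
            if s.position < w or s.position + w + 1 > len(seq):
                continue
            amp_ref = seq[s.position - w:s.position + w + 1]
            amp_alt = amp_ref[:w] + s.alt + amp_ref[w + 1:]
            for enzyme in panel:
                oracle = (digest_amplicon(amp_ref, enzyme)
                          != digest_amplicon(amp_alt, enzyme))
                mine = enzyme.name in by_snp.get((s.contig, s.position), {})
                assert mine == oracle, (s.position, enzyme.name)
            checked += 1
        assert checked > 100

    def test_fraction_arithmetic(self):
        assert snip_snp_fraction(4_700, 23_829) == 19.72


def _genome_of(seq):
    from nemamap.simulate import ReferenceGenome
    return ReferenceGenome({"ctg": seq}, [])


class TestPrimerDesign:
    def test_unique_locus_constraints_met(self):
        cfg = SimConfig(contig_length=(3_000, 3_000), seed=13)
        g = generate_reference(cfg)
        pp = design_primers(g, "ctg0001", 1_500, 1_501)
        assert 500 <= pp.product_size <= 1_000
        assert 54 <= pp.tm_left <= 56 and 54 <= pp.tm_right <= 56
        assert pp.left_start <= 1_500 < pp.right_end

    def test_primers_unique_in_genome(self):
        cfg = SimConfig(contig_length=(5_000, 5_000), seed=14)
        g = generate_reference(cfg)
        pp = design_primers(g, "ctg0001", 2_500, 2_501)
        seq = g.contigs["ctg0001"]
        for primer in (pp.left, pp.right):
            n = seq.count(primer) + seq.count(revcomp(primer))
            assert n == 1

    def test_infeasible_geometry_fails(self):
        # contig shorter than the minimum product: no pair can exist
        cfg = SimConfig(contig_length=(450, 450), seed=15)
        g = generate_reference(cfg)
        with pytest.raises(PrimerFailure):
            design_primers(g, "ctg0001", 200, 201)

    def test_target_longer_than_max_product_rejected(self):
        cfg = SimConfig(contig_length=(3_000, 3_000), seed=13)
        g = generate_reference(cfg)
        with pytest.raises(ValueError):
            design_primers(g, "ctg0001", 100, 1_500)


class TestRflpAssay:
    def test_pass_on_resolvable_patterns(self, panel):
        rng = np.random.default_rng(17)
        seq = _random_without_site(rng, 3_000)
        seq = seq[:1_500] + "TTTGAA" + seq[1_506:]
        g = _genome_of(seq)
        snp = SnpCall("ctg", 1_503, "G", "A", 2, 2.0)
        assay = predict_rflp(snp, "s1", panel.get("DraI"), g)
        assert assay.status == "pass"
        assert sum(assay.fragments_ref) == assay.primers.product_size
        assert sum(assay.fragments_alt) == assay.primers.product_size
        assert len(assay.fragments_alt) == len(assay.fragments_ref) + 1

    def test_resolvability_rule(self):
        assert patterns_resolvable([747], [332, 415])
        assert not patterns_resolvable([400, 400], [400, 400])
        # all fragments within a few bp: indistinguishable on a gel
        assert not patterns_resolvable([398, 402], [400, 400])

    def test_too_many_bands(self, panel):
        rng = np.random.default_rng(18)
        seq = _random_without_site(rng, 3_000)
        # sites every 60 bp: any conforming amplicon digests into > 4 bands
        for off in range(1_000, 2_000, 60):
            if abs(off - 1_503) > 30:
                seq = seq[:off] + "TTTAAA" + seq[off + 6:]
        seq = seq[:1_503] + "G" + seq[1_504:]  # no site at the SNP itself
        g = _genome_of(seq)
        snp = SnpCall("ctg", 1_503, seq[1_503],
                      "A" if seq[1_503] != "A" else "C", 2, 2.0)
        assay = predict_rflp(snp, "s2", panel.get("DraI"), g)
        assert assay.status in ("too_many_bands", "not_resolvable")
        assert assay.status == "too_many_bands"


class TestPlpAssay:
    @pytest.mark.parametrize("ref_len,kind,size,alt_len", [
        (665, "ins", 250, 915),   # medium insertion
        (247, "del", 32, 215),    # small deletion
    ])
    def test_band_size_arithmetic(self, ref_len, kind, size, alt_len):
        assert plp_band_sizes(ref_len, kind, size) == alt_len

    def test_indel_below_7bp_excluded(self):
        cfg = SimConfig(contig_length=(3_000, 3_000), seed=13)
        g = generate_reference(cfg)
        ind = type("I", (), {"contig": "ctg0001", "position": 1_500,
                             "indel_type": "del", "size": 6})()
        assay = design_plp(ind, "p1", g, "small")
        assert assay.status == "excluded_too_small"

    def test_small_class_design(self):
        cfg = SimConfig(contig_length=(3_000, 3_000), seed=16)
        g = generate_reference(cfg)
        ind = type("I", (), {"contig": "ctg0001", "position": 1_500,
                             "indel_type": "ins", "size": 21})()
        assay = design_plp(ind, "p2", g, "small")
        assert assay.status == "pass"
        assert 200 <= assay.amplicon_ref <= 400
        assert assay.amplicon_alt - assay.amplicon_ref == 21

    def test_medium_deletion_design(self):
        cfg = SimConfig(contig_length=(4_000, 4_000), seed=20)
        g = generate_reference(cfg)
        ind = type("I", (), {"contig": "ctg0001", "position": 2_000,
                             "indel_type": "del", "size": 180})()
        assay = design_plp(ind, "p3", g, "medium")
        assert assay.status == "pass"
        assert 300 <= assay.amplicon_ref <= 800
        assert assay.amplicon_ref - assay.amplicon_alt == 180

    def test_oversized_deletion_infeasible(self):
        cfg = SimConfig(contig_length=(4_000, 4_000), seed=20)
        g = generate_reference(cfg)
        ind = type("I", (), {"contig": "ctg0001", "position": 1_000,
                             "indel_type": "del", "size": 1_900})()
        assert design_plp(ind, "p4", g, "medium").status == "infeasible"


class TestValidationSummary:
    TABLE = {
        "snip_snp": {"pcr_failure": 6, "similar": 12, "different": 2,
                     "false": 0},
        "medium_indel": {"pcr_failure": 10, "similar": 22, "different": 7,
                         "false": 3},
        "small_indel": {"pcr_failure": 1, "similar": 32, "different": 0,
                        "false": 12},
    }

    def test_category_and_total_arithmetic(self):
        s = summarize_validation_counts(self.TABLE)
        assert s.totals["attempted"] == 107
        assert s.totals["successful"] == 90
        assert s.totals["confirmed"] == 75
        assert s.success_rate == 83
        assert s.similar_rate == 73
        assert s.categories["snip_snp"]["successful"] == 14
        assert s.categories["medium_indel"]["successful"] == 32
        assert s.categories["small_indel"]["successful"] == 44

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            summarize_validation([("snip_snp", "maybe")])

    def test_zero_records(self):
        s = summarize_validation([])
        assert s.totals["attempted"] == 0
        assert s.success_rate is None and s.similar_rate is None
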