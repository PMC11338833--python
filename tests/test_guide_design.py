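"""Protospacer enumeration and stop/start guide design.

The designers are checked against a brute-force oracle that tries every
protospacer and every in-window edit subset, applying the edits to the
genome and re-translating the CDS.
"""

import itertools

import numpy as np
import pytest

import gutedit as g
from gutedit.guide_design import SPACER_LENGTH
from gutedit.seqcore import translate_codon

from conftest import random_genome


class TestGuideSpec:
    def test_chemistry_follows_editor(self):
        abe = g.GuideSpec(spacer="A" * 20, editor="ABE")
        cbe = g.GuideSpec(spacer="C" * 20, editor="CBE")
        assert (abe.edited_base, abe.product_base) == ("A", "G")
        assert (cbe.edited_base, cbe.product_base) == ("C", "T")

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"spacer": "A" * 19, "editor": "ABE"},
            {"spacer": "A" * 20, "editor": "XBE"},
            {"spacer": "A" * 20, "editor": "ABE", "window": (0, 8)},
            {"spacer": "A" * 20, "editor": "ABE", "window": (9, 5)},
            {"spacer": "A" * 20, "editor": "ABE", "pam_pattern": "NQG"},
        ],
    )
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            g.GuideSpec(**kwargs)


class TestEnumerate:
    def test_planted_single_site(self):
        spacer = "ATGCCGAAATGCGCTGGTCG"
        genome = g.GenomeSequence("toy", "TTTT" + spacer + "AGG" + "TTTT")
        sites = g.enumerate_protospacers(genome, "NGG")
        plus = [s for s in sites if s.strand == "+"]
        assert len(plus) == 1
        assert plus[0].interval.start == 4
        assert plus[0].protospacer_seq == spacer
        assert plus[0].pam_seq == "AGG"

    def test_no_gc_genome_has_no_ngg(self):
        genome = g.GenomeSequence("at", "AT" * 50)
        assert g.enumerate_protospacers(genome, "NGG") == []

    def test_strand_symmetry_under_revcomp(self):
        rng = np.random.default_rng(11)
        genome = random_genome(rng, 500)
        flipped = g.GenomeSequence(genome.name, g.revcomp(genome.seq))
        fwd = g.enumerate_protospacers(genome)
        rev = g.enumerate_protospacers(flipped)
        assert len(fwd) == len(rev)
        L = len(genome)
        mirrored = sorted(
            (L - s.interval.end, "-" if s.strand == "+" else "+", s.protospacer_seq)
            for s in fwd
        )
        observed = sorted(
            (s.interval.start, s.strand, s.protospacer_seq) for s in rev
        )
        assert mirrored == observed


class TestCoordinateFrame:
    def test_position_mapping_round_trip_both_strands(self):
        iv_plus = g.GenomicInterval("c", 100, 120, "+")
        iv_minus = g.GenomicInterval("c", 100, 120, "-")
        for iv in (iv_plus, iv_minus):
            site = g.ProtospacerSite(
                interval=iv,
                pam_interval=g.GenomicInterval("c", 120, 123, iv.strand)
                if iv.strand == "+"
                else g.GenomicInterval("c", 97, 100, "-"),
                protospacer_seq="A" * 20,
                pam_seq="AGG",
            )
            for p in range(1, 21):
                assert site.protospacer_position(site.genomic_position(p)) == p
        # plus strand: position 1 is the leftmost base; minus: the rightmost
        assert iv_plus.start == 100
        site_plus = g.ProtospacerSite(
            iv_plus, g.GenomicInterval("c", 120, 123, "+"), "A" * 20, "AGG"
        )
        site_minus = g.ProtospacerSite(
            iv_minus, g.GenomicInterval("c", 97, 100, "-"), "A" * 20, "AGG"
        )
        assert site_plus.genomic_position(1) == 100
        assert site_minus.genomic_position(1) == 119


def _brute_force_stop_designs(genome, cds_iv, cds_seq, spec):
    """Oracle: every protospacer x every in-window C subset, re-translated."""
    found = set()
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for site in g.enumerate_protospacers(genome, spec.pam_pattern):
        editable = [
            p for p in range(spec.window[0], spec.window[1] + 1)
            if site.base_at(p) == "C"
        ]
        for r in range(1, len(editable) + 1):
            for subset in itertools.combinations(editable, r):
                seq = list(genome.seq)
                for p in subset:
                    gpos = site.genomic_position(p)
                    seq[gpos] = "T" if site.strand == "+" else comp["T"]
                mutated = "".join(seq[cds_iv.start : cds_iv.end])
                if cds_iv.strand == "-":
                    mutated = g.revcomp(mutated)
                for ci in range(len(mutated) // 3):
                    old = cds_seq[ci * 3 : ci * 3 + 3]
                    new = mutated[ci * 3 : ci * 3 + 3]
                    if new != old and translate_codon(new) == "*" and \
                            translate_codon(old) != "*":
                        found.add(
                            (site.interval.start, site.strand, ci, new)
                        )
    return found


class TestCbeStopDesign:
    def test_constructed_cag_to_tag(self):
        # protospacer: pos2-4 = ATG (CDS start), pos5-7 = CAG; PAM AGG
        proto = "A" + "ATG" + "CAG" + "CTGCTGCTGCTGC"
        genome = g.GenomeSequence("toy", "TTTT" + proto + "AGG" + "TTTT")
        cds_iv = g.GenomicInterval("toy", 5, 23, "+")
        cds_seq = genome.seq[5:23]
        spec = g.GuideSpec(spacer="C" * 20, editor="CBE")
        designs = g.design_cbe_stop_guides(cds_seq, cds_iv, genome, spec)
        assert len(designs) == 1
        d = designs[0]
        assert d.predicted_codon_change == ("CAG", "TAG")
        assert d.edited_positions == (5,)
        assert d.goal == "STOP_INTRODUCTION"

    def test_no_convertible_codons_gives_empty(self):
        # CDS of ATG + GCT repeats: no CAA/CAG/CGA/TGG anywhere in frame
        proto = "A" + "ATG" + "GCTGCTGCTGCTGCT" + "T"
        genome = g.GenomeSequence("toy", "TTTT" + proto + "AGG" + "TTTT")
        cds_iv = g.GenomicInterval("toy", 5, 23, "+")
        spec = g.GuideSpec(spacer="C" * 20, editor="CBE")
        designs = g.design_cbe_stop_guides(
            genome.seq[5:23], cds_iv, genome, spec
        )
        assert designs == []

    def test_tgg_via_antisense_cca_reaches_taa(self):
        # minus-strand protospacer whose positions 5-6 are the CCA cytosines
        q = "AAAA" + "CCA" + "A" * 13
        assert len(q) == 20
        left = "T" * 6
        genome_seq = left + "CCT" + g.revcomp(q) + "T" * 6
        genome = g.GenomeSequence("toy", genome_seq)
        s = len(left) + 3  # protospacer occupies [s, s+20) on the genome
        tgg_start = s + 13
        assert genome.seq[tgg_start : tgg_start + 3] == "TGG"
        cds_iv = g.GenomicInterval("toy", tgg_start - 3, tgg_start + 6, "+")
        cds_seq = genome.seq[cds_iv.start : cds_iv.end]
        spec = g.GuideSpec(spacer="C" * 20, editor="CBE")
        designs = g.design_cbe_stop_guides(cds_seq, cds_iv, genome, spec)
        tgg_products = {
            d.predicted_codon_change[1]
            for d in designs
            if d.predicted_codon_change[0] == "TGG"
        }
        assert tgg_products == {"TAG", "TGA", "TAA"}
        taa = [d for d in designs if d.predicted_codon_change == ("TGG", "TAA")]
        assert taa[0].edited_positions == (5, 6)

    def test_frame_violation_rejected(self):
        genome = g.GenomeSequence("toy", "A" * 50)
        spec = g.GuideSpec(spacer="C" * 20, editor="CBE")
        with pytest.raises(ValueError):
            g.design_cbe_stop_guides(
                "ATGC", g.GenomicInterval("toy", 0, 4), genome, spec
            )

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_on_random_cds(self, seed):
        rng = np.random.default_rng(300 + seed)
        n_codons = int(rng.integers(10, 25))
        body = "".join(
            rng.choice(
                ["CAA", "CAG", "CGA", "TGG", "GCT", "AAA", "CCC", "GAT"],
                size=n_codons,
            )
        )
        cds_seq = "ATG" + body
        flank = 30
        left = "".join(rng.choice(list("ACGT"), size=flank))
        right = "".join(rng.choice(list("ACGT"), size=flank))
        genome = g.GenomeSequence("rand", left + cds_seq + right)
        cds_iv = g.GenomicInterval("rand", flank, flank + len(cds_seq), "+")
        spec = g.GuideSpec(spacer="C" * 20, editor="CBE")
        designs = g.design_cbe_stop_guides(cds_seq, cds_iv, genome, spec)
        got = {
            (d.site.interval.start, d.site.strand, d.codon_index,
             d.predicted_codon_change[1])
            for d in designs
        }
        expected = _brute_force_stop_designs(genome, cds_iv, cds_seq, spec)
        assert got == expected
        # soundness: every design's edits really create the predicted stop
        for d in designs:
            seq = list(genome.seq)
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            for p in d.edited_positions:
                gpos = d.site.genomic_position(p)
                seq[gpos] = "T" if d.site.strand == "+" else comp["T"]
            mutated = "".join(seq[cds_iv.start : cds_iv.end])
            codon = mutated[d.codon_index * 3 : d.codon_index * 3 + 3]
            assert codon == d.predicted_codon_change[1]
            assert translate_codon(codon) == "*"


class TestAbeStartDisruption:
    def _template_case(self, target_window_pos: int):
        """Coding-strand CCT places a template-strand PAM; the template A
        pairing with the start codon's T lands at ``target_window_pos``."""
        c = 40  # genomic start of the ATG
        s = c + 1 - 20 + target_window_pos  # protospacer [s, s+20), minus strand
        length = 90
        seq = ["T"] * length
        seq[c : c + 3] = "ATG"
        seq[s - 3 : s] = "CCT"  # minus-strand AGG PAM
        genome = g.GenomeSequence("toy", "".join(seq))
        cds_iv = g.GenomicInterval("toy", c, c + 30, "+")
        return genome, cds_iv

    def test_template_strand_acg_design(self):
        genome, cds_iv = self._template_case(6)
        spec = g.GuideSpec(spacer="A" * 20, editor="ABE")
        designs = g.design_abe_start_disruption(cds_iv, genome, spec)
        template = [d for d in designs if d.design_class == "template_ACG"]
        assert len(template) == 1
        d = template[0]
        assert d.edited_positions == (6,)
        assert d.predicted_codon_change == ("ATG", "ACG")
        assert d.site.strand == "-"

    def test_coding_strand_gtg_design(self):
        c = 40
        length = 90
        seq = ["T"] * length
        seq[c : c + 3] = "ATG"
        # coding-strand protospacer with start A at position 4: [c-3, c+17)
        seq[c + 17 : c + 20] = "AGG"
        genome = g.GenomeSequence("toy", "".join(seq))
        cds_iv = g.GenomicInterval("toy", c, c + 30, "+")
        spec = g.GuideSpec(spacer="A" * 20, editor="ABE")
        designs = g.design_abe_start_disruption(cds_iv, genome, spec)
        coding = [d for d in designs if d.design_class == "coding_GTG"]
        assert len(coding) == 1
        assert coding[0].edited_positions == (4,)
        assert coding[0].predicted_codon_change == ("ATG", "GTG")
        assert coding[0].site.strand == "+"

    def test_no_reachable_pam_gives_empty(self):
        seq = ["T"] * 80
        seq[40:43] = "ATG"
        genome = g.GenomeSequence("toy", "".join(seq))
        cds_iv = g.GenomicInterval("toy", 40, 70, "+")
        spec = g.GuideSpec(spacer="A" * 20, editor="ABE")
        assert g.design_abe_start_disruption(cds_iv, genome, spec) == []

    def test_non_atg_start_rejected(self):
        genome = g.GenomeSequence("toy", "GTG" + "A" * 60)
        spec = g.GuideSpec(spacer="A" * 20, editor="ABE")
        with pytest.raises(ValueError):
            g.design_abe_start_disruption(
                g.GenomicInterval("toy", 0, 30), genome, spec
            )

    @pytest.mark.parametrize("seed", range(12))
    def test_soundness_and_completeness_vs_brute_force(self, seed):
        rng = np.random.default_rng(500 + seed)
        flank = 40
        left = "".join(rng.choice(list("ACGT"), size=flank))
        right = "".join(rng.choice(list("ACGT"), size=flank))
        body = "".join(rng.choice(list("ACGT"), size=27))
        genome = g.GenomeSequence("rand", left + "ATG" + body + right)
        cds_iv = g.GenomicInterval("rand", flank, flank + 30, "+")
        spec = g.GuideSpec(spacer="A" * 20, editor="ABE")
        designs = g.design_abe_start_disruption(cds_iv, genome, spec)
        # soundness: applying the edit disrupts the ATG
        for d in designs:
            seq = list(genome.seq)
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            for p in d.edited_positions:
                gpos = d.site.genomic_position(p)
                seq[gpos] = "G" if d.site.strand == "+" else comp["G"]
            start = "".join(seq[cds_iv.start : cds_iv.start + 3])
            assert start != "ATG"
            assert start == d.predicted_codon_change[1]
        # completeness: oracle tries every site and every single in-window A
        expected = set()
        for site in g.enumerate_protospacers(genome, spec.pam_pattern):
            for p in range(spec.window[0], spec.window[1] + 1):
                if site.base_at(p) != "A":
                    continue
                gpos = site.genomic_position(p)
                if not cds_iv.start <= gpos < cds_iv.start + 3:
                    continue
                seq = list(genome.seq)
                comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
                seq[gpos] = "G" if site.strand == "+" else comp["G"]
                if "".join(seq[cds_iv.start : cds_iv.start + 3]) != "ATG":
                    expected.add((site.interval.start, site.strand, p))
        got = {
            (d.site.interval.start, d.site.strand, d.edited_positions[0])
            for d in designs
        }
        assert got == expected
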