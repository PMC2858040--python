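"""Site scanning vs brute-force oracle, discrimination mining, digestion."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snprflp.engine import (
    Strand,
    digest,
    genotype_fragment_table,
    mine_discriminating_enzymes,
    scan_sites,
)
from snprflp.primers import design_natural_pair
from snprflp.rebase import RestrictionEnzyme, expansion_cardinality, parse_recognition_site
from snprflp.variants import parse_snp_sequence

from oracle import brute_force_hits

def enz(site: str, name: str = "E") -> RestrictionEnzyme:
    return RestrictionEnzyme(name=name, pattern=parse_recognition_site(site))


def as_tuples(hits):
    return sorted(
        ((h.strand.value, h.match_start, *h.cut_positions) for h in hits),
        key=lambda h: (h[1], h[0]),
    )


class TestScanSites:
    def test_single_ecori_site(self, small_enzymes):
        hits = scan_sites("TTGAATTCAA", small_enzymes["EcoRI"])
        assert as_tuples(hits) == [("SENSE", 2, 3, 7)]

    def test_degenerate_n_matches_any_base(self, small_enzymes):
        hits = scan_sites("GACTC", small_enzymes["HinfI"])
        assert [h.match_start for h in hits if h.strand is Strand.SENSE] == [0]

    def test_sequence_shorter_than_site(self, small_enzymes):
        assert scan_sites("ACGT", small_enzymes["EcoRI"]) == []

    def test_antisense_site_found_with_mirrored_cuts(self, small_enzymes):
        # GAGACC is the bottom-strand BsaI site; cuts land upstream of it
        seq = "TTTTTTTTGAGACCTT"
        hits = scan_sites(seq, small_enzymes["BsaI"])
        assert as_tuples(hits) == [("ANTISENSE", 8, 3, 7)]

    def test_outside_cut_beyond_sequence_discarded(self, small_enzymes):
        # BsaI cuts 7/11 nt from the site start; no room downstream here
        assert scan_sites("GGTCTCA", small_enzymes["BsaI"]) == []

    def test_palindromic_antisense_duplicates_suppressed(self, small_enzymes):
        hits = scan_sites("GAATTC", small_enzymes["EcoRI"])
        assert len(hits) == 1 and hits[0].strand is Strand.SENSE

    @pytest.mark.parametrize("site", ["G^AATTC", "G^ANTC", "GGTCTC(1/5)", "GT^MKAC", "C^YCGRG", "^GATC"])
    def test_matches_brute_force_oracle_on_random_sequences(self, site, rng):
        e = enz(site)
        p = e.pattern
        for length in (30, 200, 2000):
            seq = "".join(rng.choice("ACGT") for _ in range(length))
            expected = brute_force_hits(seq, p.symbols, p.cut_top, p.cut_bottom)
            assert as_tuples(scan_sites(seq, e)) == expected

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        seq=st.text(alphabet="ACGT", min_size=0, max_size=120),
        site=st.sampled_from(
            ["G^AATTC", "T^CGA", "G^ANTC", "C^TNAG", "GGTCTC(1/5)", "GT^MKAC", "GTY^RAC", "GG^CC"]
        ),
    )
    def test_oracle_equivalence_property(self, seq, site):
        e = enz(site)
        assert expansion_cardinality(e.pattern) <= 1024
        expected = brute_force_hits(seq, e.pattern.symbols, e.pattern.cut_top, e.pattern.cut_bottom)
        assert as_tuples(scan_sites(seq, e)) == expected

    def test_strand_closure_under_reverse_complement(self, rng):
        comp = str.maketrans("ACGT", "TGCA")
        for site in ("GGTCTC(1/5)", "GT^MKAC", "CTGCA^G"):
            e = enz(site)
            L = len(e.pattern)
            seq = "".join(rng.choice("ACGT") for _ in range(300))
            n = len(seq)
            rc_seq = seq.translate(comp)[::-1]
            mirrored = sorted(
                (
                    "SENSE" if h.strand is Strand.ANTISENSE else "ANTISENSE",
                    n - h.match_start - L,
                    n - h.cut_positions[1],
                    n - h.cut_positions[0],
                )
                for h in scan_sites(seq, e)
            )
            assert sorted(as_tuples(scan_sites(rc_seq, e))) == mirrored


class TestDigest:
    def test_fragments_between_cuts(self, small_enzymes):
        seq = "T" * 10 + "GAATTC" + "T" * 20  # cut at 11
        prof = digest(seq, small_enzymes["EcoRI"])
        assert prof.fragment_lengths == (11, 25)
        assert sum(prof.fragment_lengths) == prof.amplicon_length == 36

    def test_no_cut_single_fragment(self, small_enzymes):
        prof = digest("T" * 50, small_enzymes["EcoRI"])
        assert prof.fragment_lengths == (50,)

    def test_two_cuts_three_fragments(self, small_enzymes):
        seq = "T" * 5 + "GAATTC" + "T" * 10 + "GAATTC" + "T" * 5
        prof = digest(seq, small_enzymes["EcoRI"])
        assert prof.fragment_lengths == (6, 16, 10)

    def test_conservation_over_random_digests(self, panel, rng):
        for _ in range(300):
            seq = "".join(rng.choice("ACGT") for _ in range(rng.randint(10, 300)))
            e = rng.choice(panel)
            prof = digest(seq, e)
            assert sum(prof.fragment_lengths) == len(seq)
            cuts = len(prof.fragment_lengths) - 1
            assert cuts >= 0


class TestMining:
    def test_allele_specific_site_discriminates(self, small_enzymes):
        t = parse_snp_sequence("TTTTTTT[G/C]AATTCTTTTTT")
        res = mine_discriminating_enzymes(t, 0, [small_enzymes["EcoRI"]])
        assert len(res) == 1
        r = res[0]
        assert r.discriminated_pairs == frozenset({(0, 1)})
        assert r.per_allele_cuts[0] and not r.per_allele_cuts[1]

    def test_triallelic_pairs(self, small_enzymes):
        t = parse_snp_sequence("TTTTTTT[G/C/A]AATTCTTTTTT")
        r, = mine_discriminating_enzymes(t, 0, [small_enzymes["EcoRI"]])
        assert r.discriminated_pairs == frozenset({(0, 1), (0, 2)})

    def test_no_site_anywhere_empty_result(self, small_enzymes):
        t = parse_snp_sequence("TTTTTTT[G/C]TTTTTTTT")
        assert mine_discriminating_enzymes(t, 0, [small_enzymes["EcoRI"]]) == []

    def test_site_far_from_variant_not_reported(self, small_enzymes):
        # constant EcoRI site in the left flank, outside the +-30 nt window
        body = "GAATTC" + "T" * 60 + "[A/G]" + "T" * 40
        t = parse_snp_sequence(body)
        assert mine_discriminating_enzymes(t, 0, [small_enzymes["EcoRI"]]) == []

    def test_indel_coordinate_shift_alone_not_discriminating(self, small_enzymes):
        # EcoRI site downstream of the indel is shifted, not gained or lost
        body = "C" * 40 + "[-/TT]" + "C" * 10 + "GAATTC" + "C" * 30
        t = parse_snp_sequence(body)
        assert mine_discriminating_enzymes(t, 0, [small_enzymes["EcoRI"]]) == []

    def test_indel_destroying_site_discriminates(self, small_enzymes):
        # deletion removes the A that completes GAATTC
        body = "C" * 40 + "G[A/-]ATTC" + "C" * 40
        t = parse_snp_sequence(body)
        r, = mine_discriminating_enzymes(t, 0, [small_enzymes["EcoRI"]])
        assert r.discriminated_pairs == frozenset({(0, 1)})


class TestGenotypeFragmentTable:
    def test_per_allele_profiles(self, small_enzymes):
        body = "ACTTG" * 20 + "[G/C]" + "AATTC" + "ACTTG" * 20
        t = parse_snp_sequence(body)
        pair = design_natural_pair(t, 0)[0]
        profiles = genotype_fragment_table(pair, t, 0, small_enzymes["EcoRI"])
        frag_g = profiles[0].fragment_lengths
        frag_c = profiles[1].fragment_lengths
        assert len(frag_g) == 2 and len(frag_c) == 1
        assert sum(frag_g) == profiles[0].amplicon_length
        # the cut sits one base past the variant G
        vpos_in_amplicon = 100 - pair.forward.template_start
        assert frag_g[0] == vpos_in_amplicon + 1

    def test_indel_amplicon_lengths_differ(self, small_enzymes):
        body = "ACTTG" * 20 + "[-/AGG]" + "ACTTG" * 20
        t = parse_snp_sequence(body)
        pair = design_natural_pair(t, 0)[0]
        profiles = genotype_fragment_table(pair, t, 0, small_enzymes["EcoRI"])
        assert profiles[1].amplicon_length - profiles[0].amplicon_length == 3

    def test_primers_not_bracketing_variant_is_error(self, small_enzymes):
        body = "ACTTG" * 120 + "[A/G]" + "ACTTG" * 8
        t = parse_snp_sequence(body)
        # design a pair on a decoy variant far to the left, then replay on the real one
        decoy = parse_snp_sequence("ACTTG" * 20 + "[A/G]" + "ACTTG" * 48)
        pair = design_natural_pair(decoy, 0)[0]
        with pytest.raises(ValueError, match="bracket"):
            genotype_fragment_table(pair, t, 0, small_enzymes["EcoRI"])
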