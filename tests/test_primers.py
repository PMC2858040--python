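"""Primer thermodynamics, natural pair design, mutagenic (dCAPS) design."""

import random

import pytest

from snprflp.config import DesignConstraints
from snprflp.engine import genotype_fragment_table
from snprflp.primers import (
    PrimerStrand,
    annotate_pair,
    compute_tm,
    design_mutagenic,
    design_natural_pair,
    revcomp,
)
from snprflp.rebase import RestrictionEnzyme, parse_recognition_site
from snprflp.variants import SnpTemplate, Variant, parse_snp_sequence, realize_alleles


def balanced_flank(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


@pytest.fixture()
def centered_template(rng):
    left = balanced_flank(rng, 300)
    right = balanced_flank(rng, 300)
    return SnpTemplate(
        backbone=left + right,
        variants=(Variant(position=300, alleles=("A", "G")),),
        label="centered",
    )


class TestTm:
    def test_hand_computed_20mer(self):
        # 20-mer with 10 G+C at 50 mM Na+:
        # 81.5 + 16.6*log10(0.05) + 0.41*50 - 675/20 = 46.65
        assert compute_tm("AT" * 5 + "GC" * 5, 0.05) == pytest.approx(46.65, abs=0.01)

    def test_gc_counting(self, centered_template):
        out = design_natural_pair(centered_template, 0)
        p = out[0].forward
        assert p.gc_count == sum(p.sequence.count(b) for b in "GC")
        assert p.gc_fraction == pytest.approx(100 * p.gc_count / p.length)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            compute_tm("")

    def test_identical_primers_have_zero_tm_difference(self):
        assert compute_tm("ACGTACGTACGTACGTACGT") == compute_tm("ACGTACGTACGTACGTACGT")


class TestNaturalDesign:
    def test_top_pair_satisfies_all_constraints(self, centered_template):
        c = DesignConstraints()
        out = design_natural_pair(centered_template, 0, c)
        assert out and out.reason is None
        template = realize_alleles(centered_template, 0)[0].sequence
        for pair in out:
            f, r = pair.forward, pair.reverse
            assert f.sequence == template[f.template_start: f.template_start + f.length]
            assert r.sequence == revcomp(template[r.template_start: r.template_start + r.length])
            assert c.primer_len_min <= f.length <= c.primer_len_max
            assert c.gc_min <= f.gc_fraction <= c.gc_max
            assert c.product_min <= pair.reference_product_length <= c.product_max
            assert pair.tm_difference <= c.max_tm_difference
            # neither primer overlaps the variant at backbone position 300
            assert f.template_start + f.length <= 300
            assert r.template_start >= 301

    def test_ranking_prefers_balanced_tm(self, centered_template):
        out = design_natural_pair(centered_template, 0)
        diffs = [p.tm_difference for p in out]
        assert diffs == sorted(diffs)

    def test_short_flank_gives_reason(self, rng):
        t = SnpTemplate(
            backbone=balanced_flank(rng, 15) + balanced_flank(rng, 300),
            variants=(Variant(position=15, alleles=("A", "G")),),
        )
        out = design_natural_pair(t, 0)
        assert not out and out.reason == "flank too short"

    def test_deterministic(self, centered_template):
        a = design_natural_pair(centered_template, 0)
        b = design_natural_pair(centered_template, 0)
        assert a == b

    def test_annotate_is_idempotent(self, centered_template):
        pair = design_natural_pair(centered_template, 0)[0]
        once = annotate_pair(pair, centered_template, 0)
        twice = annotate_pair(once, centered_template, 0)
        assert once == twice == pair

    def test_product_length_equals_coordinate_span(self, centered_template):
        pair = design_natural_pair(centered_template, 0)[0]
        expected = pair.reverse.template_start + pair.reverse.length - pair.forward.template_start
        assert pair.reference_product_length == expected


class TestMutagenicDesign:
    @pytest.fixture()
    def ecori(self):
        return RestrictionEnzyme(name="EcoRI", pattern=parse_recognition_site("G^AATTC"), price=62.0)

    @pytest.fixture()
    def siteless_template(self, rng, ecori):
        """A C/T variant preceded by GACTT: one C->A mismatch yields GAATTC
        on the C allele only; flanks carry no EcoRI site."""
        while True:
            left = balanced_flank(rng, 220)
            right = balanced_flank(rng, 220)
            body = left + "GACTT" + "[C/T]" + right
            if "GAATTC" not in (left + "GACTTC" + right) and "GAATTC" not in (left + "GACTTT" + right):
                return parse_snp_sequence(body, label="dcaps")

    def test_known_mismatch_found(self, siteless_template, ecori):
        out = design_mutagenic(siteless_template, 0, [ecori])
        assert out, out.reason
        for d in out:
            assert d.enabled_enzyme.name == "EcoRI"
            assert d.cutting_alleles == frozenset({0})  # the C allele
            assert d.original_base != d.introduced_base

    def test_hamming_distance_exactly_one(self, siteless_template, ecori):
        template = realize_alleles(siteless_template, 0)[0].sequence
        for d in design_mutagenic(siteless_template, 0, [ecori]):
            f = d.pair.forward
            sub = template[f.template_start: f.template_start + f.length]
            assert sum(a != b for a, b in zip(sub, f.sequence)) == 1

    def test_mismatch_never_at_3prime_terminus(self, siteless_template, ecori):
        for d in design_mutagenic(siteless_template, 0, [ecori]):
            assert d.mismatch_offset < d.pair.forward.length - 1
            # within the configured distance of the 3' end
            assert d.pair.forward.length - 1 - d.mismatch_offset <= DesignConstraints().mismatch_window

    def test_closed_loop_discriminates(self, siteless_template, ecori):
        for d in design_mutagenic(siteless_template, 0, [ecori]):
            profiles = genotype_fragment_table(d.pair, siteless_template, 0, d.enabled_enzyme)
            multisets = {ai: tuple(sorted(p.fragment_lengths)) for ai, p in profiles.items()}
            assert multisets[0] != multisets[1]

    def test_marked_primer_has_single_lowercase(self, siteless_template, ecori):
        d = design_mutagenic(siteless_template, 0, [ecori])[0]
        marked = d.marked_primer_sequence()
        lowers = [c for c in marked if c.islower()]
        assert len(lowers) == 1 and lowers[0] == d.introduced_base.lower()

    def test_deterministic(self, siteless_template, ecori):
        assert design_mutagenic(siteless_template, 0, [ecori]) == design_mutagenic(
            siteless_template, 0, [ecori]
        )

    def test_ranking_non_iupac_before_iupac_on_ties(self, rng):
        # both enzymes enabled by the same mismatch set: AluI AG^CT (concrete)
        # vs HinfI G^ANTC (degenerate) rank concrete first on equal primer keys
        t = parse_snp_sequence(
            balanced_flank(rng, 200) + "GACTT" + "[C/T]" + balanced_flank(rng, 200)
        )
        enz = [
            RestrictionEnzyme(name="Deg", pattern=parse_recognition_site("G^ANTC")),
            RestrictionEnzyme(name="EcoRI", pattern=parse_recognition_site("G^AATTC")),
        ]
        out = design_mutagenic(t, 0, enz)
        if len(out) >= 2:
            keys = [
                (d.pair.tm_difference, d.enabled_enzyme.degeneracy_class.value)
                for d in out
            ]
            for (tm1, cls1), (tm2, cls2) in zip(keys, keys[1:]):
                if tm1 == tm2:
                    assert not (cls1 == "IUPAC" and cls2 == "NON_IUPAC")

    def test_reverse_strand_search_via_both(self, rng, ecori):
        # enabling context only on the antisense side: variant followed by AAGTC
        # (bottom strand reads GACTT+[G/A]-complement), so only strands="both"
        # can place the mismatch
        while True:
            left = balanced_flank(rng, 220)
            right = balanced_flank(rng, 220)
            body = left + "[G/A]" + "AAGTC" + right
            t = parse_snp_sequence(body, label="rev")
            fwd_only = design_mutagenic(t, 0, [ecori])
            if not fwd_only:
                break
        both = design_mutagenic(
            t, 0, [ecori], DesignConstraints(mutagenic_strands="both")
        )
        assert both, both.reason
        d = both[0]
        assert d.mutated_primer is PrimerStrand.REVERSE
        profiles = genotype_fragment_table(d.pair, t, 0, d.enabled_enzyme)
        multisets = {ai: tuple(sorted(p.fragment_lengths)) for ai, p in profiles.items()}
        assert multisets[0] != multisets[1]
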