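"""Restriction-site mining and digest simulation.

The discriminating-enzyme search is the heart of a PCR-RFLP assay: an
enzyme is useful for genotyping a variant when its cut-position pattern
differs between the allele sequences, so that digesting the PCR product
yields allele-specific fragment ladders on a gel.

Sites are matched degenerately (IUPAC symbols match their base sets) on
both strands.  For each allele realization the top-strand cut positions in
a window around the variant are collected and normalized by anchoring to
the variant boundaries: cuts upstream of the site are expressed relative to
the variant start, cuts downstream relative to the variant end.  This makes
the comparison indel-safe — a pure coordinate shift caused by an insertion
or deletion does not by itself count as discrimination (the length
difference of the undigested product is visible anyway and is reported in
the per-genotype fragment table), whereas a genuine gain or loss of a cut
does.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

from .rebase import (
    DegeneracyClass,
    RecognitionPattern,
    RestrictionEnzyme,
    pattern_regex,
    reverse_complement_pattern,
)
from .variants import AlleleRealization, SnpTemplate, realize_alleles

DEFAULT_MINING_WINDOW = 30  # nt each side of the variant span


class Strand(str, Enum):
    SENSE = "SENSE"
    ANTISENSE = "ANTISENSE"


@dataclass(frozen=True)
class EnzymeHit:
    enzyme_name: str
    strand: Strand
    match_start: int
    cut_positions: tuple[int, int]  # (top-strand cut, bottom-strand cut)

    @property
    def cut_top(self) -> int:
        return self.cut_positions[0]


@dataclass(frozen=True)
class DiscriminationResult:
    enzyme: RestrictionEnzyme
    variant_label: str
    per_allele_cuts: Mapping[int, tuple[int, ...]]  # raw top-strand cuts, window-restricted
    discriminated_pairs: frozenset[tuple[int, int]]

    @property
    def degeneracy_class(self) -> DegeneracyClass:
        return self.enzyme.degeneracy_class


@dataclass(frozen=True)
class DigestProfile:
    allele_index: int
    amplicon_length: int
    fragment_lengths: tuple[int, ...]  # left to right along the amplicon


def scan_sites(sequence: str, enzyme: RestrictionEnzyme) -> list[EnzymeHit]:
    """All degenerate matches of the enzyme's site on both strands.

    Antisense hits are matches of the reverse-complement pattern on the given
    (sense) sequence; their cut offsets are pre-mirrored so that
    ``cut_positions`` are always in sense-sequence coordinates.  Hits whose
    cuts fall outside ``[0, len(sequence)]`` (outside cutters near an end)
    are discarded.  For self-complementary sites every antisense hit
    duplicates a sense hit at the same locus and is suppressed.
    """
    hits = _scan_one_strand(sequence, enzyme.pattern, enzyme.name, Strand.SENSE)
    rc = reverse_complement_pattern(enzyme.pattern)
    if rc != enzyme.pattern:
        hits += _scan_one_strand(sequence, rc, enzyme.name, Strand.ANTISENSE)
    hits.sort(key=lambda h: (h.match_start, h.strand.value))
    return hits


def _scan_one_strand(
    sequence: str, pattern: RecognitionPattern, name: str, strand: Strand
) -> list[EnzymeHit]:
    n = len(sequence)
    hits = []
    for m in pattern_regex(pattern).finditer(sequence):
        start = m.start()
        cut_top = start + pattern.cut_top
        cut_bottom = start + pattern.cut_bottom
        if not (0 <= cut_top <= n and 0 <= cut_bottom <= n):
            continue
        hits.append(
            EnzymeHit(
                enzyme_name=name,
                strand=strand,
                match_start=start,
                cut_positions=(cut_top, cut_bottom),
            )
        )
    return hits


def digest(amplicon: str, enzyme: RestrictionEnzyme, allele_index: int = 0) -> DigestProfile:
    """Fragment lengths after complete digestion of ``amplicon``.

    Fragments are the intervals between consecutive distinct top-strand cut
    positions plus the amplicon ends; their lengths always sum to the
    amplicon length.
    """
    n = len(amplicon)
    cuts = sorted({h.cut_top for h in scan_sites(amplicon, enzyme) if 0 < h.cut_top < n})
    bounds = [0, *cuts, n]
    fragments = tuple(b - a for a, b in zip(bounds, bounds[1:]))
    return DigestProfile(allele_index=allele_index, amplicon_length=n, fragment_lengths=fragments)


def _window_cuts(
    realization: AlleleRealization,
    enzyme: RestrictionEnzyme,
    window: int,
) -> tuple[int, ...]:
    """Top-strand cuts of hits whose match interval intersects the
    variant-centred window, in realization coordinates, sorted (multiset)."""
    vs, ve = realization.variant_span
    lo, hi = vs - window, ve + window
    plen = len(enzyme.pattern)
    cuts = [
        h.cut_top
        for h in scan_sites(realization.sequence, enzyme)
        if h.match_start < hi and h.match_start + plen > lo
    ]
    return tuple(sorted(cuts))


def _anchor(cuts: Sequence[int], span: tuple[int, int]) -> tuple[tuple[str, int], ...]:
    """Express cuts relative to the variant boundaries (indel-safe)."""
    vs, ve = span
    out = []
    for c in cuts:
        if c <= vs:
            out.append(("U", c - vs))
        elif c >= ve:
            out.append(("D", c - ve))
        else:
            out.append(("V", c - vs))
    return tuple(sorted(out))


def mine_discriminating_enzymes(
    t: SnpTemplate,
    which: int,
    enzymes: Sequence[RestrictionEnzyme],
    window: int = DEFAULT_MINING_WINDOW,
) -> list[DiscriminationResult]:
    """Enzymes whose cutting differs between alleles of variant ``which``.

    For every enzyme each allele realization is scanned in the window around
    the variant; a result is emitted iff the anchored cut multisets differ
    for at least one allele pair.  Results preserve enzyme table order;
    ranking (class, price) is left to the report layer.
    """
    realizations = realize_alleles(t, which)
    label = f"{t.label or 'template'}:variant{which + 1}"
    results = []
    for enzyme in enzymes:
        cuts = {r.allele_index: _window_cuts(r, enzyme, window) for r in realizations}
        anchored = {
            r.allele_index: _anchor(cuts[r.allele_index], r.variant_span)
            for r in realizations
        }
        pairs = frozenset(
            (i, j)
            for i in cuts
            for j in cuts
            if i < j and anchored[i] != anchored[j]
        )
        if pairs:
            results.append(
                DiscriminationResult(
                    enzyme=enzyme,
                    variant_label=label,
                    per_allele_cuts=cuts,
                    discriminated_pairs=pairs,
                )
            )
    return results


def genotype_fragment_table(
    pair: "PrimerPair",  # noqa: F821 - forward reference into primers module
    t: SnpTemplate,
    which: int,
    enzyme: RestrictionEnzyme,
) -> dict[int, DigestProfile]:
    """Per-allele digest of the PCR product defined by ``pair``.

    The amplicon for each allele runs from the forward primer start to the
    reverse primer 3' coordinate on that allele's realization; for indels
    the downstream coordinate is shifted by the allele-length difference.
    If the pair is a mutagenic design, the introduced mismatch is applied to
    the amplicon before digestion (the mutant primer sequence is
    incorporated into every product during PCR).
    """
    realizations = realize_alleles(t, which)
    ref_len = len(realizations[0].sequence)
    fwd_start = pair.forward.template_start
    rev_end_ref = pair.reverse.template_start + pair.reverse.length
    profiles: dict[int, DigestProfile] = {}
    for r in realizations:
        shift = len(r.sequence) - ref_len
        rev_end = rev_end_ref + shift
        vs, ve = r.variant_span
        if not (fwd_start <= vs and ve <= rev_end) or fwd_start < 0 or rev_end > len(r.sequence):
            raise ValueError("primers do not bracket variant")
        amplicon = r.sequence[fwd_start:rev_end]
        mut = getattr(pair, "mutation", None)
        if mut is not None:
            amplicon = mut.apply_to_amplicon(amplicon)
        profiles[r.allele_index] = digest(amplicon, enzyme, allele_index=r.allele_index)
    return profiles
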