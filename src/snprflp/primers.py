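"""PCR primer design for RFLP genotyping assays.

Two design modes:

* **natural** pairs simply bracket the variant so that an enzyme already
  discriminating the alleles can be read out from the digested product;
* **mutagenic** (dCAPS-style) designs introduce a single deliberate
  mismatch near the 3' end of a primer so that the primer-derived part of
  the amplicon completes a restriction site together with one allele but
  not the other, manufacturing a discriminating cut where none exists
  naturally.

Melting temperatures use the salt-adjusted GC/length formula

    Tm = 81.5 + 16.6*log10([Na+]) + 0.41*GC% - 675/length

which is fully determined by composition and length, adequate for the
15-30 nt oligos designed here.  Coordinates of every primer refer to the
first-listed-allele (reference) realization of its template.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterator, Sequence

import numpy as np

from .config import DesignConstraints
from .engine import genotype_fragment_table
from .rebase import (
    DegeneracyClass,
    RestrictionEnzyme,
    pattern_regex,
    reverse_complement_pattern,
)
from .variants import SnpTemplate, SourceNotation, Variant, realize_alleles

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class PrimerStrand(str, Enum):
    FORWARD = "FORWARD"
    REVERSE = "REVERSE"


def compute_tm(sequence: str, na_molar: float = 0.05) -> float:
    """Salt-adjusted melting temperature (degC) of a concrete oligo."""
    if not sequence:
        raise ValueError("empty sequence has no melting temperature")
    gc = sum(sequence.count(b) for b in "GC")
    gc_pct = 100.0 * gc / len(sequence)
    return 81.5 + 16.6 * math.log10(na_molar) + 0.41 * gc_pct - 675.0 / len(sequence)


@dataclass(frozen=True)
class PrimerCandidate:
    """An annotated primer; FORWARD equals the template substring, REVERSE
    the reverse complement of its template substring."""

    sequence: str
    strand: PrimerStrand
    template_start: int
    length: int
    gc_count: int
    gc_fraction: float
    tm: float


def make_primer(
    template: str,
    start: int,
    length: int,
    strand: PrimerStrand,
    na_molar: float = 0.05,
    sequence: str | None = None,
) -> PrimerCandidate:
    """Build an annotated candidate; ``sequence`` overrides the template
    substring for mutagenic primers."""
    sub = template[start: start + length]
    if len(sub) != length:
        raise ValueError("primer extends past template end")
    if sequence is None:
        sequence = sub if strand is PrimerStrand.FORWARD else revcomp(sub)
    gc = sum(sequence.upper().count(b) for b in "GC")
    return PrimerCandidate(
        sequence=sequence,
        strand=strand,
        template_start=start,
        length=length,
        gc_count=gc,
        gc_fraction=100.0 * gc / length,
        tm=compute_tm(sequence.upper(), na_molar),
    )


@dataclass(frozen=True)
class PrimerMutation:
    """The single deliberate mismatch of a mutagenic primer.

    ``offset`` is 0-based within the primer read 5'->3'; bases are in primer
    space.  The mismatch is never at the 3'-terminal position (offset
    length-1), which polymerases require to be perfectly paired.
    """

    primer: PrimerStrand
    offset: int
    original_base: str
    introduced_base: str

    def apply_to_amplicon(self, amplicon: str) -> str:
        if self.primer is PrimerStrand.FORWARD:
            idx, base = self.offset, self.introduced_base
        else:
            idx = len(amplicon) - 1 - self.offset
            base = self.introduced_base.translate(_COMPLEMENT)
        return amplicon[:idx] + base + amplicon[idx + 1:]


@dataclass(frozen=True)
class PrimerPair:
    forward: PrimerCandidate
    reverse: PrimerCandidate
    product_length: dict[int, int]  # per allele index of the target variant
    tm_difference: float
    mutation: PrimerMutation | None = None

    @property
    def reference_product_length(self) -> int:
        return self.product_length[0]


@dataclass(frozen=True)
class MutagenicDesign:
    pair: PrimerPair
    enabled_enzyme: RestrictionEnzyme
    cutting_alleles: frozenset[int]

    @property
    def mutated_primer(self) -> PrimerStrand:
        assert self.pair.mutation is not None
        return self.pair.mutation.primer

    @property
    def mismatch_offset(self) -> int:
        assert self.pair.mutation is not None
        return self.pair.mutation.offset

    @property
    def original_base(self) -> str:
        return self.pair.mutation.original_base

    @property
    def introduced_base(self) -> str:
        return self.pair.mutation.introduced_base

    def marked_primer_sequence(self) -> str:
        """Primer with the introduced base in lowercase (text rendering of
        the assay sheet's highlighted artificial nucleotide)."""
        mut = self.pair.mutation
        primer = self.pair.forward if mut.primer is PrimerStrand.FORWARD else self.pair.reverse
        s = primer.sequence
        return s[: mut.offset] + s[mut.offset].lower() + s[mut.offset + 1:]


@dataclass(frozen=True)
class DesignOutcome:
    """Ranked designs plus a machine-readable reason when empty."""

    items: tuple
    reason: str | None = None

    def __iter__(self) -> Iterator:
        return iter(self.items)

    def __len__(self) -> int:
        return len(self.items)

    def __getitem__(self, i):
        return self.items[i]

    def __bool__(self) -> bool:
        return bool(self.items)


def annotate_pair(pair: PrimerPair, t: SnpTemplate, which: int,
                  constraints: DesignConstraints = DesignConstraints()) -> PrimerPair:
    """(Re)compute every derived annotation from the primer sequences and
    coordinates; idempotent."""
    realizations = realize_alleles(t, which)
    template = realizations[0].sequence
    fwd = make_primer(template, pair.forward.template_start, pair.forward.length,
                      PrimerStrand.FORWARD, constraints.na_molar,
                      sequence=pair.forward.sequence)
    rev = make_primer(template, pair.reverse.template_start, pair.reverse.length,
                      PrimerStrand.REVERSE, constraints.na_molar,
                      sequence=pair.reverse.sequence)
    products = _per_allele_products(realizations, fwd.template_start,
                                    rev.template_start + rev.length)
    return PrimerPair(
        forward=fwd, reverse=rev, product_length=products,
        tm_difference=abs(fwd.tm - rev.tm), mutation=pair.mutation,
    )


def _per_allele_products(realizations, fwd_start: int, rev_end_ref: int) -> dict[int, int]:
    ref_len = len(realizations[0].sequence)
    return {
        r.allele_index: rev_end_ref + (len(r.sequence) - ref_len) - fwd_start
        for r in realizations
    }


def _forbidden_spans(t: SnpTemplate, which: int) -> list[tuple[int, int]]:
    """Spans of every variant on the reference realization: primers must not
    sit on polymorphic sequence."""
    spans = []
    offset = 0
    for v in t.variants:
        start = v.position + offset
        width = max(len(v.alleles[0]), 1)  # deletion alleles still forbid the junction base
        spans.append((start, start + width))
        offset += len(v.alleles[0])
    return spans


def _enumerate_candidates(
    template: str,
    region_start: int,
    region_end: int,
    strand: PrimerStrand,
    forbidden: Sequence[tuple[int, int]],
    c: DesignConstraints,
) -> list[PrimerCandidate]:
    """All primers with both ends inside [region_start, region_end), passing
    the length and GC constraints and avoiding forbidden spans."""
    n = len(template)
    region_start = max(0, region_start)
    region_end = min(n, region_end)
    arr = np.frombuffer(template.encode(), dtype=np.uint8)
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    gc_prefix = np.concatenate(([0], np.cumsum(is_gc)))
    out = []
    for start in range(region_start, region_end):
        for length in range(c.primer_len_min, c.primer_len_max + 1):
            end = start + length
            if end > region_end:
                break
            if any(start < fe and end > fs for fs, fe in forbidden):
                continue
            gc = int(gc_prefix[end] - gc_prefix[start])
            gc_pct = 100.0 * gc / length
            if not c.gc_min <= gc_pct <= c.gc_max:
                continue
            out.append(make_primer(template, start, length, strand, c.na_molar))
    return out


def _rank_pairs(
    fwds: Sequence[PrimerCandidate],
    revs: Sequence[PrimerCandidate],
    realizations,
    c: DesignConstraints,
    top_k: int,
    mutation: PrimerMutation | None = None,
) -> list[PrimerPair]:
    """Globally rank feasible (forward, reverse) combinations by Tm balance,
    product-size centrality, then leftmost/shortest coordinates."""
    if not fwds or not revs:
        return []
    f_start = np.array([f.template_start for f in fwds])
    f_tm = np.array([f.tm for f in fwds])
    r_end = np.array([r.template_start + r.length for r in revs])
    r_tm = np.array([r.tm for r in revs])
    f_len = np.array([f.length for f in fwds])
    r_len = np.array([r.length for r in revs])

    picked: list[tuple] = []
    chunk = max(1, 4_000_000 // max(1, len(revs)))
    for lo in range(0, len(fwds), chunk):
        hi = min(len(fwds), lo + chunk)
        product = r_end[None, :] - f_start[lo:hi, None]
        tm_diff = np.abs(r_tm[None, :] - f_tm[lo:hi, None])
        ok = (product >= c.product_min) & (product <= c.product_max) & \
             (tm_diff <= c.max_tm_difference)
        fi, ri = np.nonzero(ok)
        if fi.size == 0:
            continue
        key_cols = (
            np.round(tm_diff[fi, ri], 6),
            np.abs(product[fi, ri] - c.product_midpoint),
            f_start[lo + fi], f_len[lo + fi], r_end[ri], r_len[ri],
        )
        order = np.lexsort(key_cols[::-1])[:top_k]
        picked.extend(
            tuple(col[k] for col in key_cols) + (lo + fi[k], ri[k]) for k in order
        )
    picked.sort()
    pairs = []
    for *_key, fi, ri in picked[:top_k]:
        fwd, rev = fwds[int(fi)], revs[int(ri)]
        products = _per_allele_products(realizations, fwd.template_start,
                                        rev.template_start + rev.length)
        pairs.append(PrimerPair(
            forward=fwd, reverse=rev, product_length=products,
            tm_difference=abs(fwd.tm - rev.tm), mutation=mutation,
        ))
    return pairs


def design_natural_pair(
    t: SnpTemplate,
    which: int,
    c: DesignConstraints = DesignConstraints(),
) -> DesignOutcome:
    """Ranked natural primer pairs bracketing variant ``which``.

    Neither primer overlaps any variant span; pairs are ranked by
    (Tm difference, distance of the product size from the range midpoint,
    leftmost forward).  Deterministic for fixed inputs.
    """
    realizations = realize_alleles(t, which)
    ref = realizations[0]
    template = ref.sequence
    vs, ve = ref.variant_span
    forbidden = _forbidden_spans(t, which)

    fwds = _enumerate_candidates(
        template, vs - c.product_max, vs, PrimerStrand.FORWARD, forbidden, c
    )
    fwds = [f for f in fwds if f.template_start + f.length <= vs]
    revs = _enumerate_candidates(
        template, ve, ve + c.product_max, PrimerStrand.REVERSE, forbidden, c
    )
    revs = [r for r in revs if r.template_start >= ve]
    if not fwds or not revs:
        return DesignOutcome((), reason="flank too short")
    pairs = _rank_pairs(fwds, revs, realizations, c, c.max_pairs)
    if not pairs:
        return DesignOutcome((), reason="constraints infeasible")
    return DesignOutcome(tuple(pairs))


# --- mutagenic (dCAPS-style) design ----------------------------------------

def _alleles_cut_by(
    enzyme: RestrictionEnzyme,
    realizations,
    pos: int,
    introduced: str,
) -> frozenset[int]:
    """Alleles whose realization, mutated at ``pos`` (upstream of the
    variant), gains at least one enzyme match overlapping the region from
    the mismatch through the variant."""
    plen = len(enzyme.pattern)
    rc = reverse_complement_pattern(enzyme.pattern)
    cutting = set()
    for r in realizations:
        seq = r.sequence[:pos] + introduced + r.sequence[pos + 1:]
        vs, ve = r.variant_span
        lo, hi = pos, max(ve, vs + 1)  # region of interest (junction for deletions)
        window_lo = max(0, lo - plen + 1)
        window_hi = min(len(seq), hi + plen - 1)
        segment = seq[window_lo:window_hi]
        matched = False
        for pat in (enzyme.pattern,) if rc == enzyme.pattern else (enzyme.pattern, rc):
            for m in pattern_regex(pat).finditer(segment):
                start = window_lo + m.start()
                if start < hi and start + plen > lo:
                    matched = True
                    break
            if matched:
                break
        if matched:
            cutting.add(r.allele_index)
    return frozenset(cutting)


def _fragment_multisets_differ(profiles) -> bool:
    seen = {}
    for ai, p in profiles.items():
        seen[ai] = tuple(sorted(p.fragment_lengths))
    values = list(seen.values())
    return any(a != b for a in values for b in values)


def design_mutagenic(
    t: SnpTemplate,
    which: int,
    enzymes: Sequence[RestrictionEnzyme],
    c: DesignConstraints = DesignConstraints(),
) -> DesignOutcome:
    """Ranked single-mismatch (dCAPS) designs enabling an allele-specific cut.

    The search places each enzyme's recognition pattern across the variant,
    enumerates forward primers whose 3' end abuts or lies within a pattern
    length of the variant, and tries every single-base substitution within
    the last ``mismatch_window`` primer bases (never the 3'-terminal one).
    A design is emitted only when the mutated amplicon is cut for a proper,
    non-empty subset of alleles and the per-allele fragment multisets of the
    replayed digest differ.  Ranking: Tm balance and product-size centrality
    as for natural pairs, then non-degenerate (NON_IUPAC) enzymes before
    degenerate ones, then price ascending (unpriced last).
    """
    outcome = _design_mutagenic_forward(t, which, enzymes, c)
    designs = list(outcome.items)
    if c.mutagenic_strands == "both":
        mt, map_back = _mirror_template(t)
        mirrored = _design_mutagenic_forward(
            mt, len(t.variants) - 1 - which, enzymes, c, verify=False
        )
        for d in mirrored.items:
            mapped = map_back(d)
            try:
                profiles = genotype_fragment_table(mapped.pair, t, which, mapped.enabled_enzyme)
            except ValueError:
                continue
            if _fragment_multisets_differ(profiles):
                designs.append(mapped)
        designs = _rank_designs(designs, c)[: c.max_designs]
    if not designs:
        return DesignOutcome((), reason=outcome.reason or "no enabling mismatch found")
    return DesignOutcome(tuple(designs))


def _design_mutagenic_forward(
    t: SnpTemplate,
    which: int,
    enzymes: Sequence[RestrictionEnzyme],
    c: DesignConstraints,
    verify: bool = True,
) -> DesignOutcome:
    realizations = realize_alleles(t, which)
    ref = realizations[0]
    template = ref.sequence
    vs, ve = ref.variant_span
    n_alleles = len(realizations)
    forbidden = _forbidden_spans(t, which)

    revs = _enumerate_candidates(
        template, ve, ve + c.product_max, PrimerStrand.REVERSE, forbidden, c
    )
    revs = [r for r in revs if r.template_start >= ve]
    if not revs:
        return DesignOutcome((), reason="flank too short")

    candidates: list[MutagenicDesign] = []
    checked: dict[tuple[str, int, str], frozenset[int]] = {}
    any_cut_outside = False
    for enzyme in enzymes:
        plen = len(enzyme.pattern)
        for fend in range(max(c.primer_len_min, vs - plen + 1), vs + 1):
            for d in range(1, c.mismatch_window + 1):
                pos = fend - 1 - d
                if pos < 0 or pos >= vs:
                    continue
                original = template[pos]
                for nb in "ACGT":
                    if nb == original:
                        continue
                    key = (enzyme.name, pos, nb)
                    if key not in checked:
                        checked[key] = _alleles_cut_by(enzyme, realizations, pos, nb)
                    cutting = checked[key]
                    if not cutting or len(cutting) == n_alleles:
                        continue
                    design = _assemble_design(
                        t, which, realizations, enzyme, fend, pos, nb,
                        cutting, revs, forbidden, c,
                    )
                    if design is None:
                        continue
                    if design == "cut outside product":
                        any_cut_outside = True
                        continue
                    candidates.append(design)
    ranked = _rank_designs(candidates, c)
    if not verify:
        if not ranked:
            return DesignOutcome((), reason="no enabling mismatch found")
        return DesignOutcome(tuple(ranked))

    verified: list[MutagenicDesign] = []
    for design in ranked:
        try:
            profiles = genotype_fragment_table(design.pair, t, which, design.enabled_enzyme)
        except ValueError:
            continue
        if _fragment_multisets_differ(profiles):
            verified.append(design)
        if len(verified) >= c.max_designs:
            break
    if not verified:
        reason = "cut outside product" if any_cut_outside and not candidates else \
            "no enabling mismatch found"
        return DesignOutcome((), reason=reason)
    return DesignOutcome(tuple(verified))


def _assemble_design(
    t, which, realizations, enzyme, fend, pos, nb, cutting, revs, forbidden, c,
):
    template = realizations[0].sequence
    best = None
    for flen in range(c.primer_len_min, c.primer_len_max + 1):
        fstart = fend - flen
        if fstart < 0 or pos < fstart:
            continue
        if any(fstart < fe and fend > fs for fs, fe in forbidden):
            continue
        offset = pos - fstart
        if offset == flen - 1:
            continue  # never mutate the 3'-terminal base
        seq = template[fstart:fend]
        mut_seq = seq[:offset] + nb + seq[offset + 1:]
        gc = sum(mut_seq.count(b) for b in "GC")
        gc_pct = 100.0 * gc / flen
        if not c.gc_min <= gc_pct <= c.gc_max:
            continue
        fwd = make_primer(template, fstart, flen, PrimerStrand.FORWARD,
                          c.na_molar, sequence=mut_seq)
        mutation = PrimerMutation(
            primer=PrimerStrand.FORWARD, offset=offset,
            original_base=template[pos], introduced_base=nb,
        )
        pairs = _rank_pairs([fwd], revs, realizations, c, 1, mutation=mutation)
        if not pairs:
            continue
        pair = pairs[0]
        # outside cutters may recognize in-product but cleave beyond it
        if not _cut_within_product(enzyme, pair, realizations, pos, cutting):
            best = best or "cut outside product"
            continue
        design = MutagenicDesign(pair=pair, enabled_enzyme=enzyme, cutting_alleles=cutting)
        if best is None or isinstance(best, str) or _design_key(design, c) < _design_key(best, c):
            best = design
    return best


def _cut_within_product(enzyme, pair, realizations, pos, cutting) -> bool:
    from .engine import scan_sites

    ref_len = len(realizations[0].sequence)
    fwd_start = pair.forward.template_start
    rev_end_ref = pair.reverse.template_start + pair.reverse.length
    mut = pair.mutation
    for r in realizations:
        if r.allele_index not in cutting:
            continue
        rev_end = rev_end_ref + (len(r.sequence) - ref_len)
        amplicon = mut.apply_to_amplicon(r.sequence[fwd_start:rev_end])
        n = len(amplicon)
        if any(0 < h.cut_top < n for h in scan_sites(amplicon, enzyme)):
            return True
    return False


def _class_rank(e: RestrictionEnzyme) -> int:
    return 0 if e.degeneracy_class is DegeneracyClass.NON_IUPAC else 1


def _design_key(d: MutagenicDesign, c: DesignConstraints):
    p = d.pair
    price = d.enabled_enzyme.price
    return (
        round(p.tm_difference, 6),
        abs(p.reference_product_length - c.product_midpoint),
        p.forward.template_start,
        p.forward.length,
        p.reverse.template_start + p.reverse.length,
        _class_rank(d.enabled_enzyme),
        price is None,
        price if price is not None else 0.0,
        d.enabled_enzyme.name,
        d.mismatch_offset,
        d.introduced_base,
    )


def _rank_designs(designs: Sequence[MutagenicDesign], c: DesignConstraints) -> list[MutagenicDesign]:
    return sorted(designs, key=lambda d: _design_key(d, c))


# --- strand mirroring for --mutagenic-strands both ---------------------------

def _mirror_template(t: SnpTemplate):
    """Reverse-complement a template (variants mirrored, alleles rc'd) and
    return it with a function mapping designs back to the original frame."""
    n = len(t.backbone)
    mirrored_variants = tuple(
        Variant(
            position=n - v.position,
            alleles=tuple(revcomp(a) for a in v.alleles),
            source_notation=SourceNotation.BRACKET,
        )
        for v in reversed(t.variants)
    )
    mt = SnpTemplate(backbone=revcomp(t.backbone), variants=mirrored_variants,
                     label=t.label)

    ref_len = n + sum(len(v.alleles[0]) for v in t.variants)

    def flip(p: PrimerCandidate) -> PrimerCandidate:
        strand = (PrimerStrand.REVERSE if p.strand is PrimerStrand.FORWARD
                  else PrimerStrand.FORWARD)
        return replace(p, strand=strand, template_start=ref_len - (p.template_start + p.length))

    def map_back(d: MutagenicDesign) -> MutagenicDesign:
        mut = d.pair.mutation
        new_mut = PrimerMutation(
            primer=PrimerStrand.REVERSE, offset=mut.offset,
            original_base=mut.original_base, introduced_base=mut.introduced_base,
        )
        fwd = flip(d.pair.reverse)   # mirrored reverse becomes original forward
        rev = flip(d.pair.forward)   # mirrored (mutated) forward becomes original reverse
        pair = PrimerPair(
            forward=fwd, reverse=rev, product_length=dict(d.pair.product_length),
            tm_difference=d.pair.tm_difference, mutation=new_mut,
        )
        return MutagenicDesign(pair=pair, enabled_enzyme=d.enabled_enzyme,
                               cutting_alleles=d.cutting_alleles)

    return mt, map_back
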