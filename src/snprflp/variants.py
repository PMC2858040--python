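"""SNP-containing sequence input.

Templates carry polymorphic sites in two grammars:

* bracket notation ``[A/G]``, ``[A/G/T]``, ``[A/C/G/T]``, ``[-/AGG]`` —
  2 to 4 alleles in written order, ``-`` for the deletion allele of an
  indel, multi-base strings for length polymorphisms;
* single-letter IUPAC ambiguity codes (R, Y, S, W, K, M, B, D, H, V) in the
  sequence body, read as bi/tri-allelic sites with alleles in alphabetical
  order.  ``N`` is rejected: four unordered alleles carry no assayable
  information, and an unknown base leaves no concrete template to match.

Constraints enforced at parse time: at most 50 variants per sequence, and
adjacent variants must be separated by a backbone gap strictly greater than
6 nt so that each site keeps at least 7 nt of private flank.

Internally everything is 0-based, half-open; report writers convert to
1-based inclusive coordinates for display.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .rebase import CONCRETE, IUPAC_BASES

MAX_VARIANTS = 50
MIN_VARIANT_GAP = 7  # strictly more than 6 nt of backbone between adjacent sites

# Ambiguity codes usable as variant shorthand (N excluded: uninformative).
AMBIGUITY_CODES = {
    code: tuple(sorted(bases))
    for code, bases in IUPAC_BASES.items()
    if 1 < len(bases) < 4 or code in ("B", "D", "H", "V")
}
AMBIGUITY_CODES = {c: b for c, b in AMBIGUITY_CODES.items() if c != "N"}

# Characters silently dropped by the cleaning filter (whitespace, digits,
# punctuation and any other non-IUPAC symbol).
_KEEP = CONCRETE


class VariantInputError(ValueError):
    """Malformed or constraint-violating variant input."""


class SourceNotation(str, Enum):
    BRACKET = "BRACKET"
    IUPAC_CODE = "IUPAC_CODE"


@dataclass(frozen=True)
class Variant:
    """One polymorphic site: a backbone insertion point plus 2-4 alleles.

    ``position`` indexes the backbone (the template with every variant site
    excised); the deletion allele of an indel is the empty string.
    """

    position: int
    alleles: tuple[str, ...]
    source_notation: SourceNotation = SourceNotation.BRACKET

    def __post_init__(self) -> None:
        if not 2 <= len(self.alleles) <= 4:
            raise VariantInputError(f"variant must have 2-4 alleles, got {len(self.alleles)}")
        if len(set(self.alleles)) != len(self.alleles):
            raise VariantInputError(f"duplicate alleles in {self.alleles}")
        if sum(a == "" for a in self.alleles) > 1:
            raise VariantInputError("at most one deletion allele per variant")
        for a in self.alleles:
            if set(a) - CONCRETE:
                raise VariantInputError(f"allele {a!r} contains non-ACGT characters")

    @property
    def kind(self) -> str:
        """di/tri/tetra-allelic or indel, for report headers."""
        if "" in self.alleles or len({len(a) for a in self.alleles}) > 1:
            return "indel"
        return {2: "di", 3: "tri", 4: "tetra"}[len(self.alleles)]


@dataclass(frozen=True)
class SnpTemplate:
    backbone: str
    variants: tuple[Variant, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if not 1 <= len(self.variants) <= MAX_VARIANTS:
            raise VariantInputError(
                f"template must carry 1-{MAX_VARIANTS} variants, got {len(self.variants)}"
            )
        last = None
        for v in self.variants:
            if not 0 <= v.position <= len(self.backbone):
                raise VariantInputError("variant position outside backbone")
            if last is not None:
                if v.position <= last:
                    raise VariantInputError("variant positions must strictly increase")
                gap = v.position - last
                if gap < MIN_VARIANT_GAP:
                    raise VariantInputError(
                        f"adjacent variants separated by only {gap} backbone nt; "
                        f"flanks of nearby SNPs must not overlap within 6 nt "
                        f"(gap must exceed 6)"
                    )
            last = v.position


@dataclass(frozen=True)
class AlleleRealization:
    """A concrete per-allele sequence with the realized variant located."""

    allele_index: int
    sequence: str
    variant_span: tuple[int, int]  # half-open; empty for the deletion allele

    @property
    def allele(self) -> str:
        return self.sequence[self.variant_span[0]: self.variant_span[1]]


def clean_sequence(text: str) -> tuple[str, int]:
    """Uppercase and strip non-nucleotide symbols (blanks, commas, digits,
    anything outside A/C/G/T) from raw sequence text.

    Applied to the inter-variant segments after the variant grammar has been
    consumed.  Returns ``(cleaned, n_removed)``; an empty result is an error.
    """
    up = text.upper()
    cleaned = "".join(c for c in up if c in _KEEP)
    if not cleaned:
        raise VariantInputError("no nucleotides in input")
    return cleaned, len(up) - len(cleaned)


def _clean_segment(text: str) -> str:
    return "".join(c for c in text.upper() if c in _KEEP)


def parse_snp_sequence(text: str, label: str = "") -> SnpTemplate:
    """Parse one sequence body with >=1 variant in bracket or IUPAC notation."""
    backbone_parts: list[str] = []
    backbone_len = 0
    variants: list[Variant] = []
    i = 0
    segment_start = 0
    up = text.upper()

    def flush(upto: int) -> None:
        nonlocal backbone_len
        seg = _clean_segment(up[segment_start:upto])
        backbone_parts.append(seg)
        backbone_len += len(seg)

    while i < len(up):
        c = up[i]
        if c == "[":
            close = up.find("]", i + 1)
            if close == -1:
                raise VariantInputError(f"unbalanced bracket at offset {i}")
            flush(i)
            variants.append(_parse_bracket(up[i + 1: close], backbone_len))
            i = close + 1
            segment_start = i
        elif c == "]":
            raise VariantInputError(f"unbalanced bracket at offset {i}")
        elif c in AMBIGUITY_CODES:
            flush(i)
            variants.append(
                Variant(
                    position=backbone_len,
                    alleles=AMBIGUITY_CODES[c],
                    source_notation=SourceNotation.IUPAC_CODE,
                )
            )
            i += 1
            segment_start = i
        elif c == "N":
            raise VariantInputError(
                "IUPAC code N is not accepted: an any-base site is uninformative "
                "and leaves no concrete template"
            )
        else:
            i += 1
    flush(len(up))

    if not variants:
        raise VariantInputError("no variant found in sequence")
    if len(variants) > MAX_VARIANTS:
        raise VariantInputError(
            f"{len(variants)} variants exceed the {MAX_VARIANTS}-variant limit"
        )
    return SnpTemplate(backbone="".join(backbone_parts), variants=tuple(variants), label=label)


def _parse_bracket(body: str, position: int) -> Variant:
    raw = body.split("/")
    if not 2 <= len(raw) <= 4:
        raise VariantInputError(
            f"bracket [{body}] must list 2-4 alleles separated by '/'"
        )
    alleles = []
    for a in raw:
        a = a.strip()
        if a == "-":
            alleles.append("")
        elif a and not set(a) - CONCRETE:
            alleles.append(a)
        else:
            raise VariantInputError(f"invalid allele {a!r} in bracket [{body}]")
    return Variant(position=position, alleles=tuple(alleles))


def realize_alleles(t: SnpTemplate, which: int) -> list[AlleleRealization]:
    """Concrete sequences for every allele of variant ``which``, with all
    other variants fixed to their first-listed (reference) allele."""
    if not 0 <= which < len(t.variants):
        raise IndexError(f"variant index {which} out of range")
    out = []
    for ai in range(len(t.variants[which].alleles)):
        out.append(_realize(t, which, ai))
    return out


def _realize(t: SnpTemplate, which: int, allele_index: int) -> AlleleRealization:
    parts: list[str] = []
    prev = 0
    span = (0, 0)
    offset = 0  # cumulative inserted-allele length
    for vi, v in enumerate(t.variants):
        parts.append(t.backbone[prev: v.position])
        allele = v.alleles[allele_index if vi == which else 0]
        start = v.position + offset
        if vi == which:
            span = (start, start + len(allele))
        parts.append(allele)
        offset += len(allele)
        prev = v.position
    parts.append(t.backbone[prev:])
    return AlleleRealization(allele_index=allele_index, sequence="".join(parts), variant_span=span)


# --- FASTA ------------------------------------------------------------------

def read_fasta(stream: TextIO, skip_invariant: bool = True) -> list[SnpTemplate]:
    """Parse a multi-record FASTA whose bodies use the variant grammar.

    Records without any variant are skipped with a warning by default, or
    raise when ``skip_invariant=False``.
    """
    templates = []
    for rec in SeqIO.parse(stream, "fasta"):
        try:
            templates.append(parse_snp_sequence(str(rec.seq), label=rec.id))
        except VariantInputError as exc:
            if "no variant found" in str(exc) and skip_invariant:
                import logging

                logging.getLogger(__name__).warning(
                    "record %s has no variant; skipped", rec.id
                )
                continue
            raise VariantInputError(f"record {rec.id}: {exc}") from exc
    return templates


def template_to_text(t: SnpTemplate) -> str:
    """Render a template back to its sequence body (lossless round-trip)."""
    parts = []
    prev = 0
    for v in t.variants:
        parts.append(t.backbone[prev: v.position])
        if v.source_notation is SourceNotation.IUPAC_CODE:
            code = next(
                c for c, bases in AMBIGUITY_CODES.items() if bases == v.alleles
            )
            parts.append(code)
        else:
            parts.append("[" + "/".join(a or "-" for a in v.alleles) + "]")
        prev = v.position
    parts.append(t.backbone[prev:])
    return "".join(parts)


def write_fasta(templates: Iterable[SnpTemplate], stream: TextIO) -> None:
    records = [
        SeqRecord(Seq(template_to_text(t)), id=t.label or f"template_{i}", description="")
        for i, t in enumerate(templates, start=1)
    ]
    SeqIO.write(records, stream, "fasta")


def templates_to_fasta_str(templates: Sequence[SnpTemplate]) -> str:
    buf = io.StringIO()
    write_fasta(templates, buf)
    return buf.getvalue()
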