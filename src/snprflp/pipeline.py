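"""End-to-end assay construction and report writing.

For every template x variant the pipeline mines discriminating enzymes,
designs natural primer pairs, simulates the per-genotype digest for each
(enzyme, pair) combination, and — when requested or when no natural enzyme
exists — adds mutagenic designs.  Reports carry, for each primer: sequence,
1-based position, length, GC count, GC%, Tm and Tm difference, plus product
length per allele; for each enzyme: recognition site, sense/antisense cut
evidence, degeneracy class, suppliers and price.  JSON is the lossless
canonical format; TSV flattens enzyme x allele-pair rows; TEXT is a
human-readable assay sheet in which the mutagenic base is lowercased.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, TextIO

from .config import DesignConstraints
from .engine import (
    DigestProfile,
    DiscriminationResult,
    genotype_fragment_table,
    mine_discriminating_enzymes,
)
from .primers import (
    DesignOutcome,
    MutagenicDesign,
    PrimerPair,
    design_mutagenic,
    design_natural_pair,
)
from .rebase import (
    RestrictionEnzyme,
    format_recognition_site,
    parse_enzyme_table,
)
from .variants import SnpTemplate, read_fasta

logger = logging.getLogger("snprflp")


@dataclass(frozen=True)
class NaturalAssay:
    result: DiscriminationResult
    pair: PrimerPair | None
    profiles: dict[int, DigestProfile] | None
    note: str | None = None


@dataclass(frozen=True)
class MutagenicAssay:
    design: MutagenicDesign
    profiles: dict[int, DigestProfile]


@dataclass(frozen=True)
class AssayReport:
    label: str
    variant_index: int
    variant_position: int  # on the reference realization, 0-based
    alleles: tuple[str, ...]
    variant_kind: str
    natural: tuple[NaturalAssay, ...] = field(default_factory=tuple)
    mutagenic: tuple[MutagenicAssay, ...] = field(default_factory=tuple)
    natural_reason: str | None = None
    mutagenic_reason: str | None = None


def build_report(
    t: SnpTemplate,
    which: int,
    enzymes: Sequence[RestrictionEnzyme],
    constraints: DesignConstraints = DesignConstraints(),
    mutagenic: str = "auto",
) -> AssayReport:
    """One per-variant report.

    ``mutagenic`` policy: ``"always"`` designs mismatch primers for every
    variant, ``"never"`` skips them entirely, ``"auto"`` (default) designs
    them only when no natural discriminating enzyme was found.
    """
    from .variants import realize_alleles

    ref = realize_alleles(t, which)[0]
    results = mine_discriminating_enzymes(t, which, enzymes, constraints.mining_window)
    results = sorted(
        results,
        key=lambda r: (
            0 if r.degeneracy_class.value == "NON_IUPAC" else 1,
            r.enzyme.price is None,
            r.enzyme.price if r.enzyme.price is not None else 0.0,
            r.enzyme.name,
        ),
    )
    pairs = design_natural_pair(t, which, constraints)
    natural = []
    for res in results:
        if pairs:
            pair = pairs[0]
            try:
                profiles = genotype_fragment_table(pair, t, which, res.enzyme)
                natural.append(NaturalAssay(result=res, pair=pair, profiles=profiles))
            except ValueError as exc:
                natural.append(NaturalAssay(result=res, pair=pair, profiles=None,
                                            note=str(exc)))
        else:
            natural.append(NaturalAssay(result=res, pair=None, profiles=None,
                                        note=pairs.reason))
    mut_assays: tuple[MutagenicAssay, ...] = ()
    mut_reason = None
    if mutagenic == "never":
        mut_reason = "mutagenic design disabled"
    elif mutagenic == "always" or not natural:
        designs: DesignOutcome = design_mutagenic(t, which, enzymes, constraints)
        mut_reason = designs.reason
        assays = []
        for d in designs:
            profiles = genotype_fragment_table(d.pair, t, which, d.enabled_enzyme)
            assays.append(MutagenicAssay(design=d, profiles=profiles))
        mut_assays = tuple(assays)
    return AssayReport(
        label=t.label,
        variant_index=which,
        variant_position=ref.variant_span[0],
        alleles=t.variants[which].alleles,
        variant_kind=t.variants[which].kind,
        natural=tuple(natural),
        mutagenic=mut_assays,
        natural_reason=None if natural else (pairs.reason or "no discriminating enzyme"),
        mutagenic_reason=mut_reason,
    )


def run_pipeline(
    fasta_path: str | Path,
    enzyme_path: str | Path,
    constraints: DesignConstraints = DesignConstraints(),
    mutagenic: str = "auto",
) -> list[AssayReport]:
    """Mine + design for every template x variant in the input FASTA."""
    with open(enzyme_path) as fh:
        enzymes, report = parse_enzyme_table(fh)
    for lineno, text, reason in report.rejected:
        logger.warning("enzyme table line %d rejected (%s): %s", lineno, reason, text)
    with open(fasta_path) as fh:
        templates = read_fasta(fh)
    if not templates:
        raise ValueError("no parseable SNP templates in input")
    reports = []
    for t in templates:
        for which in range(len(t.variants)):
            reports.append(build_report(t, which, enzymes, constraints, mutagenic))
    return reports


# --- serialization ----------------------------------------------------------

def _primer_dict(p) -> dict:
    return {
        "sequence": p.sequence,
        "strand": p.strand.value,
        "position": p.template_start + 1,  # 1-based for display
        "length": p.length,
        "gc_count": p.gc_count,
        "gc_percent": round(p.gc_fraction, 2),
        "tm": round(p.tm, 2),
    }


def _pair_dict(pair: PrimerPair) -> dict:
    return {
        "forward": _primer_dict(pair.forward),
        "reverse": _primer_dict(pair.reverse),
        "tm_difference": round(pair.tm_difference, 2),
        "product_length": {str(k): v for k, v in sorted(pair.product_length.items())},
    }


def _enzyme_dict(e: RestrictionEnzyme) -> dict:
    return {
        "name": e.name,
        "site": format_recognition_site(e.pattern),
        "degeneracy_class": e.degeneracy_class.value,
        "suppliers": "".join(sorted(e.suppliers)),
        "price": e.price,
    }


def _profiles_dict(profiles: dict[int, DigestProfile] | None) -> dict | None:
    if profiles is None:
        return None
    return {
        str(ai): {
            "amplicon_length": p.amplicon_length,
            "fragments": list(p.fragment_lengths),
        }
        for ai, p in sorted(profiles.items())
    }


def report_to_dict(r: AssayReport) -> dict:
    return {
        "label": r.label,
        "variant_index": r.variant_index,
        "variant_position": r.variant_position + 1,
        "alleles": ["-" if a == "" else a for a in r.alleles],
        "variant_kind": r.variant_kind,
        "natural": [
            {
                "enzyme": _enzyme_dict(a.result.enzyme),
                "discriminated_pairs": sorted(map(list, a.result.discriminated_pairs)),
                "per_allele_cuts": {
                    str(k): [c + 1 for c in v]
                    for k, v in sorted(a.result.per_allele_cuts.items())
                },
                "pair": _pair_dict(a.pair) if a.pair else None,
                "digest": _profiles_dict(a.profiles),
                "note": a.note,
            }
            for a in r.natural
        ],
        "natural_reason": r.natural_reason,
        "mutagenic": [
            {
                "enzyme": _enzyme_dict(m.design.enabled_enzyme),
                "pair": _pair_dict(m.design.pair),
                "mutated_primer": m.design.mutated_primer.value,
                "marked_primer": m.design.marked_primer_sequence(),
                "mismatch_offset": m.design.mismatch_offset,
                "original_base": m.design.original_base,
                "introduced_base": m.design.introduced_base,
                "cutting_alleles": sorted(m.design.cutting_alleles),
                "digest": _profiles_dict(m.profiles),
            }
            for m in r.mutagenic
        ],
        "mutagenic_reason": r.mutagenic_reason,
    }


def write_report(
    reports: Sequence[AssayReport], format: str, stream: TextIO
) -> None:
    if format == "JSON":
        json.dump([report_to_dict(r) for r in reports], stream, indent=2, sort_keys=True)
        stream.write("\n")
    elif format == "TSV":
        _write_tsv(reports, stream)
    elif format == "TEXT":
        _write_text(reports, stream)
    else:
        raise ValueError(f"unknown report format {format!r}")


_TSV_COLUMNS = [
    "label", "variant", "mode", "enzyme", "site", "class", "suppliers", "price",
    "allele_i", "allele_j", "forward", "reverse", "tm_f", "tm_r", "tm_diff",
    "product", "fragments_i", "fragments_j",
]


def _write_tsv(reports: Sequence[AssayReport], stream: TextIO) -> None:
    stream.write("\t".join(_TSV_COLUMNS) + "\n")
    for r in reports:
        for a in r.natural:
            for i, j in sorted(a.result.discriminated_pairs):
                _tsv_row(stream, r, "natural", a.result.enzyme, a.pair, a.profiles, i, j)
        for m in r.mutagenic:
            cutting = sorted(m.design.cutting_alleles)
            others = [i for i in range(len(r.alleles)) if i not in cutting]
            for i in cutting:
                for j in others:
                    _tsv_row(stream, r, "mutagenic", m.design.enabled_enzyme,
                             m.design.pair, m.profiles, *sorted((i, j)))


def _tsv_row(stream, r, mode, enzyme, pair, profiles, i, j) -> None:
    def frag(k):
        if profiles is None or k not in profiles:
            return ""
        return "+".join(map(str, profiles[k].fragment_lengths))

    fields = [
        r.label, str(r.variant_index + 1), mode, enzyme.name,
        format_recognition_site(enzyme.pattern), enzyme.degeneracy_class.value,
        "".join(sorted(enzyme.suppliers)),
        "" if enzyme.price is None else f"{enzyme.price:g}",
        str(i), str(j),
        pair.forward.sequence if pair else "",
        pair.reverse.sequence if pair else "",
        f"{pair.forward.tm:.2f}" if pair else "",
        f"{pair.reverse.tm:.2f}" if pair else "",
        f"{pair.tm_difference:.2f}" if pair else "",
        str(pair.reference_product_length) if pair else "",
        frag(i), frag(j),
    ]
    stream.write("\t".join(fields) + "\n")


def _write_text(reports: Sequence[AssayReport], stream: TextIO) -> None:
    for r in reports:
        alleles = "/".join(a or "-" for a in r.alleles)
        stream.write(
            f"== {r.label} variant {r.variant_index + 1} "
            f"pos {r.variant_position + 1} [{alleles}] ({r.variant_kind}) ==\n"
        )
        stream.write("-- natural assays --\n")
        if not r.natural:
            stream.write(f"  none ({r.natural_reason})\n")
        for a in r.natural:
            e = a.result.enzyme
            price = "n/a" if e.price is None else f"{e.price:g}"
            stream.write(
                f"  {e.name} {format_recognition_site(e.pattern)} "
                f"[{e.degeneracy_class.value}] suppliers={''.join(sorted(e.suppliers)) or '-'} "
                f"price={price}\n"
            )
            if a.pair:
                _text_pair(stream, a.pair)
            if a.profiles:
                _text_profiles(stream, a.profiles, r.alleles)
            if a.note:
                stream.write(f"    note: {a.note}\n")
        stream.write("-- mutagenic assays --\n")
        if not r.mutagenic:
            stream.write(f"  none ({r.mutagenic_reason or 'not requested'})\n")
        for m in r.mutagenic:
            e = m.design.enabled_enzyme
            stream.write(
                f"  {e.name} {format_recognition_site(e.pattern)} enabled by "
                f"{m.design.original_base}->{m.design.introduced_base} at primer "
                f"offset {m.design.mismatch_offset + 1} "
                f"({m.design.mutated_primer.value})\n"
            )
            stream.write(f"    marked primer: {m.design.marked_primer_sequence()}\n")
            _text_pair(stream, m.design.pair)
            _text_profiles(stream, m.profiles, r.alleles)
        stream.write("\n")


def _text_pair(stream, pair: PrimerPair) -> None:
    for p in (pair.forward, pair.reverse):
        tag = "F" if p.strand.value == "FORWARD" else "R"
        stream.write(
            f"    {tag} {p.sequence}  pos={p.template_start + 1} len={p.length} "
            f"GC={p.gc_count} GC%={p.gc_fraction:.1f} Tm={p.tm:.2f}\n"
        )
    products = "/".join(str(v) for _, v in sorted(pair.product_length.items()))
    stream.write(f"    Tm-diff={pair.tm_difference:.2f} product={products}\n")


def _text_profiles(stream, profiles, alleles) -> None:
    for ai, p in sorted(profiles.items()):
        allele = alleles[ai] or "-"
        frags = "+".join(map(str, p.fragment_lengths))
        stream.write(f"    allele {allele}: {p.amplicon_length} nt -> {frags}\n")
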