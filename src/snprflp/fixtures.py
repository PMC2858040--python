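"""Deterministic synthetic fixtures: SNP templates and an enzyme panel.

A configurable fraction of generated templates carries a *planted*
allele-discriminating restriction site: one concrete word of a real
enzyme's recognition sequence is embedded so that the first allele
completes the site and the second breaks it (the breaking base is chosen
outside the IUPAC set of the pattern symbol at the variant offset, so no
expansion of the site can match there).  The planted enzyme and allele
pair are recorded as ground truth, letting the discrimination miner be
scored against a known answer.

Flanks are rejection-sampled so the broken allele gains no accidental
match of the planted enzyme across the variant; everything is driven by a
single :class:`random.Random` seed and is byte-identical across runs.
"""

from __future__ import annotations

import io
import json
import random
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .rebase import (
    IUPAC_BASES,
    RestrictionEnzyme,
    parse_enzyme_table,
    pattern_regex,
    reverse_complement_pattern,
    write_enzyme_table,
)
from .variants import SnpTemplate, Variant, templates_to_fasta_str

# Panel of widely used enzymes (site, supplier code N = New England Biolabs,
# indicative per-unit prices).  Mix of blunt/sticky, degenerate and
# non-degenerate sites, plus one outside cutter.
_FIXTURE_TABLE = """\
EcoRI\tG^AATTC\tN\t62
BamHI\tG^GATCC\tN\t62
HindIII\tA^AGCTT\tN\t60
TaqI\tT^CGA\tN\t65
HinfI\tG^ANTC\tN\t60
DdeI\tC^TNAG\tN\t64
AvaI\tC^YCGRG\tN\t66
HaeIII\tGG^CC\tN\t55
AluI\tAG^CT\tN\t58
MboI\t^GATC\tN\t58
PstI\tCTGCA^G\tN\t61
KpnI\tGGTAC^C\tN\t60
AccI\tGT^MKAC\tN\t70
HincII\tGTY^RAC\tN\t64
BsaI\tGGTCTC(1/5)\tN\t75
"""


def default_fixture_enzymes() -> list[RestrictionEnzyme]:
    enzymes, _ = parse_enzyme_table(io.StringIO(_FIXTURE_TABLE))
    return enzymes


DEFAULT_ALLELE_SPEC: Mapping[str, float] = {"2": 0.7, "3": 0.1, "4": 0.1, "indel": 0.1}


@dataclass(frozen=True)
class PlantedTruth:
    label: str
    variant_index: int
    enzyme_name: str
    discriminated_pair: tuple[int, int]

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "variant_index": self.variant_index,
            "enzyme_name": self.enzyme_name,
            "discriminated_pair": list(self.discriminated_pair),
        }


@dataclass(frozen=True)
class FixtureSet:
    templates: tuple[SnpTemplate, ...]
    enzymes: tuple[RestrictionEnzyme, ...]
    ground_truth: tuple[PlantedTruth, ...] = field(default_factory=tuple)

    def fasta(self) -> str:
        return templates_to_fasta_str(self.templates)

    def enzyme_tsv(self) -> str:
        buf = io.StringIO()
        write_enzyme_table(list(self.enzymes), buf)
        return buf.getvalue()

    def ground_truth_json(self) -> str:
        return json.dumps([g.to_dict() for g in self.ground_truth], indent=2)


def _random_flank(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def _plantable_offsets(enzyme: RestrictionEnzyme) -> list[int]:
    """Pattern offsets where a base outside the symbol's set exists, i.e.
    where a single substitution can break every expansion of the site."""
    return [
        i for i, s in enumerate(enzyme.pattern.symbols) if len(IUPAC_BASES[s]) < 4
    ]


def _has_overlapping_match(seq: str, enzyme: RestrictionEnzyme, lo: int, hi: int) -> bool:
    """Any match (either strand) of the enzyme intersecting [lo, hi)?"""
    plen = len(enzyme.pattern)
    patterns = [enzyme.pattern]
    rc = reverse_complement_pattern(enzyme.pattern)
    if rc != enzyme.pattern:
        patterns.append(rc)
    for pat in patterns:
        for m in pattern_regex(pat).finditer(seq):
            if m.start() < hi and m.start() + plen > lo:
                return True
    return False


def _draw_kind(rng: random.Random, allele_spec: Mapping[str, float]) -> str:
    kinds = sorted(allele_spec)
    weights = [allele_spec[k] for k in kinds]
    return rng.choices(kinds, weights=weights, k=1)[0]


def _plant_template(
    rng: random.Random,
    enzymes: Sequence[RestrictionEnzyme],
    flank_len: int,
    kind: str,
    label: str,
    max_tries: int = 200,
) -> tuple[SnpTemplate, PlantedTruth]:
    plantable = [e for e in enzymes if _plantable_offsets(e)]
    for _ in range(max_tries):
        enzyme = rng.choice(plantable)
        symbols = enzyme.pattern.symbols
        offset = rng.choice(_plantable_offsets(enzyme))
        word = "".join(rng.choice(sorted(IUPAC_BASES[s])) for s in symbols)
        site_set = IUPAC_BASES[symbols[offset]]
        breakers = sorted(set("ACGT") - site_set)
        ref = word[offset]
        if kind == "indel":
            alleles: tuple[str, ...] = (ref, "")
        elif kind == "2":
            alleles = (ref, rng.choice(breakers))
        else:
            extra = 1 if kind == "3" else 2
            pool = [b for b in "ACGT" if b != ref]
            rng.shuffle(pool)
            second = next(b for b in pool if b in breakers)
            others = [b for b in pool if b != second][:extra]
            alleles = (ref, second, *others)
        left = _random_flank(rng, flank_len)
        right = _random_flank(rng, flank_len)
        backbone = left + word[:offset] + word[offset + 1:] + right
        vpos = len(left) + offset
        template = SnpTemplate(
            backbone=backbone,
            variants=(Variant(position=vpos, alleles=alleles),),
            label=label,
        )
        # the breaking allele must not accidentally regain a site across the variant
        broken = backbone[:vpos] if kind == "indel" else backbone[:vpos] + alleles[1]
        broken_seq = broken + backbone[vpos:]
        plen = len(enzyme.pattern)
        span_len = len(alleles[1])
        if _has_overlapping_match(
            broken_seq, enzyme, vpos - plen + 1, vpos + span_len + plen - 1
        ):
            continue
        truth = PlantedTruth(
            label=label, variant_index=0, enzyme_name=enzyme.name,
            discriminated_pair=(0, 1),
        )
        return template, truth
    raise RuntimeError(f"could not plant a discriminating site for {label}")


def _random_template(
    rng: random.Random, flank_len: int, kind: str, label: str
) -> SnpTemplate:
    left = _random_flank(rng, flank_len)
    right = _random_flank(rng, flank_len)
    if kind == "indel":
        ins_len = rng.randint(1, 4)
        alleles: tuple[str, ...] = ("".join(rng.choice("ACGT") for _ in range(ins_len)), "")
    else:
        n = int(kind)
        bases = list("ACGT")
        rng.shuffle(bases)
        alleles = tuple(bases[:n])
    return SnpTemplate(
        backbone=left + right,
        variants=(Variant(position=len(left), alleles=alleles),),
        label=label,
    )


def generate_fixture(
    seed: int,
    n_templates: int = 20,
    flank_len: int = 150,
    allele_spec: Mapping[str, float] | None = None,
    planted_fraction: float = 0.5,
    enzymes: Sequence[RestrictionEnzyme] | None = None,
) -> FixtureSet:
    """Deterministic synthetic dataset for a fixed seed.

    ``planted_fraction`` of the templates carry a known discriminating site
    (ground truth recorded); the rest have random variants.  ``flank_len``
    (default 150 nt each side) leaves room for 100-500 nt products around
    the variant; 30 nt is the accepted minimum.
    """
    if flank_len < 30:
        raise ValueError("flank_len must be >= 30")
    rng = random.Random(seed)
    allele_spec = dict(allele_spec or DEFAULT_ALLELE_SPEC)
    enzymes = tuple(enzymes if enzymes is not None else default_fixture_enzymes())
    n_planted = round(n_templates * planted_fraction)
    templates: list[SnpTemplate] = []
    truths: list[PlantedTruth] = []
    for i in range(n_templates):
        kind = _draw_kind(rng, allele_spec)
        label = f"fix{i + 1:04d}"
        if i < n_planted:
            t, truth = _plant_template(rng, enzymes, flank_len, kind, label)
            templates.append(t)
            truths.append(truth)
        else:
            templates.append(_random_template(rng, flank_len, kind, label))
    return FixtureSet(
        templates=tuple(templates), enzymes=enzymes, ground_truth=tuple(truths)
    )
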