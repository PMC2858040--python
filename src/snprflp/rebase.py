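"""Restriction-enzyme table parsing and IUPAC recognition-pattern algebra.

A restriction enzyme is described by a recognition pattern over the 15-letter
IUPAC nucleotide alphabet plus a pair of cut offsets (top and bottom strand,
in nucleotides relative to the pattern start).  Two cut notations are read:

* ``G^AATTC`` — a ``^`` inside the site marks the top-strand cut; the
  bottom-strand cut is placed symmetrically (``len - cut_top``), the
  convention for orthodox palindromic cutters.
* ``GGTCTC(1/5)`` — trailing ``(t/b)`` offsets for enzymes cutting outside
  their site (Type IIS); offsets count past the 3' end of the pattern.

Enzymes are classified as NON_IUPAC when the site uses only A, C, G, T and
IUPAC when it contains any degenerate symbol.
"""

from __future__ import annotations

import itertools
import json
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence, TextIO

IUPAC_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

CONCRETE = frozenset("ACGT")


class DegeneracyClass(str, Enum):
    """Degenerate (IUPAC) vs fully concrete (non-IUPAC) recognition site."""

    NON_IUPAC = "NON_IUPAC"
    IUPAC = "IUPAC"


class EnzymeTableError(ValueError):
    """Hard failure while reading an enzyme table."""


@dataclass(frozen=True)
class RecognitionPattern:
    """An IUPAC recognition site with top/bottom cut offsets.

    Offsets are nucleotide counts from the pattern start; they may be
    negative or exceed the pattern length for outside cutters.
    """

    symbols: str
    cut_top: int
    cut_bottom: int

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError("recognition pattern must be non-empty")
        bad = set(self.symbols) - set(IUPAC_BASES)
        if bad:
            raise ValueError(
                f"non-IUPAC symbol {''.join(sorted(bad))} in pattern {self.symbols!r}"
            )

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def is_palindromic(self) -> bool:
        """True when the reverse complement equals the pattern, offsets included."""
        return reverse_complement_pattern(self) == self


@dataclass(frozen=True)
class RestrictionEnzyme:
    name: str
    pattern: RecognitionPattern
    suppliers: frozenset[str] = field(default_factory=frozenset)
    price: float | None = None

    @property
    def degeneracy_class(self) -> DegeneracyClass:
        return classify_enzyme(self)


def classify_enzyme(enzyme: RestrictionEnzyme) -> DegeneracyClass:
    """NON_IUPAC iff the recognition site uses only the bases A, C, G and T."""
    if set(enzyme.pattern.symbols) <= CONCRETE:
        return DegeneracyClass.NON_IUPAC
    return DegeneracyClass.IUPAC


def reverse_complement_pattern(p: RecognitionPattern) -> RecognitionPattern:
    """IUPAC-aware reverse complement with cut offsets remapped to the
    mirrored coordinate frame.

    A cut ``c`` nucleotides from the pattern start maps to ``len - c`` from
    the start of the reversed pattern, and top/bottom strands swap.  The
    operation is an involution.
    """
    rc = "".join(IUPAC_COMPLEMENT[s] for s in reversed(p.symbols))
    n = len(p.symbols)
    return RecognitionPattern(rc, cut_top=n - p.cut_bottom, cut_bottom=n - p.cut_top)


def expand_pattern(p: RecognitionPattern, cap: int = 65_536) -> set[str]:
    """Cartesian expansion of every degenerate symbol to concrete strings.

    Raises :class:`ValueError` when the expansion cardinality exceeds ``cap``
    (direct degenerate matching should be used instead).
    """
    card = expansion_cardinality(p)
    if card > cap:
        raise ValueError(
            f"expansion cardinality {card} exceeds cap {cap}; "
            "match the degenerate pattern directly"
        )
    return {"".join(t) for t in itertools.product(*(sorted(IUPAC_BASES[s]) for s in p.symbols))}


def expansion_cardinality(p: RecognitionPattern) -> int:
    card = 1
    for s in p.symbols:
        card *= len(IUPAC_BASES[s])
    return card


def pattern_regex(p: RecognitionPattern) -> re.Pattern[str]:
    """Compiled lookahead regex matching every (overlapping) occurrence."""
    body = "".join(
        s if len(IUPAC_BASES[s]) == 1 else "[" + "".join(sorted(IUPAC_BASES[s])) + "]"
        for s in p.symbols
    )
    return re.compile(f"(?=({body}))")


# --- table parsing ----------------------------------------------------------

_SITE_CARET = re.compile(r"^([A-Z]*)\^([A-Z]*)$")
_SITE_OFFSET = re.compile(r"^([A-Z]+)\((-?\d+)/(-?\d+)\)$")


@dataclass
class ParseReport:
    accepted: int = 0
    rejected: list[tuple[int, str, str]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)

    def to_json(self) -> str:
        return json.dumps(
            {
                "accepted": self.accepted,
                "rejected": self.n_rejected,
                "rejections": [
                    {"line": ln, "text": txt, "reason": why}
                    for ln, txt, why in self.rejected
                ],
            },
            indent=2,
        )


def parse_recognition_site(site: str) -> RecognitionPattern:
    """Parse ``G^AATTC`` or ``GGTCTC(1/5)`` into a pattern with offsets."""
    site = site.strip().upper()
    if site.count("^") > 1 or site.count("(") > 1 or ("^" in site and "(" in site):
        raise ValueError("more than one cut descriptor")
    m = _SITE_CARET.match(site)
    if m:
        symbols = m.group(1) + m.group(2)
        cut_top = len(m.group(1))
        return RecognitionPattern(symbols, cut_top, len(symbols) - cut_top)
    m = _SITE_OFFSET.match(site)
    if m:
        symbols = m.group(1)
        return RecognitionPattern(
            symbols,
            cut_top=len(symbols) + int(m.group(2)),
            cut_bottom=len(symbols) + int(m.group(3)),
        )
    letters = set(re.sub(r"[\^()/\d-]", "", site))
    bad = letters - set(IUPAC_BASES)
    if bad:
        raise ValueError(f"non-IUPAC symbol {''.join(sorted(bad))} in site {site!r}")
    if "^" in site or "(" in site or ")" in site:
        raise ValueError(f"malformed cut descriptor in site {site!r}")
    raise ValueError(f"site {site!r} has no cut marker (^ or (t/b))")


def format_recognition_site(p: RecognitionPattern) -> str:
    """Inverse of :func:`parse_recognition_site` (canonical form)."""
    n = len(p.symbols)
    if 0 <= p.cut_top <= n and p.cut_bottom == n - p.cut_top:
        return p.symbols[: p.cut_top] + "^" + p.symbols[p.cut_top:]
    return f"{p.symbols}({p.cut_top - n}/{p.cut_bottom - n})"


def parse_enzyme_table(
    stream: TextIO | Iterable[str],
) -> tuple[list[RestrictionEnzyme], ParseReport]:
    """Read a TSV enzyme table: ``name<TAB>site<TAB>suppliers[<TAB>price]``.

    ``#`` comment lines and blank lines are skipped.  Malformed lines are
    recorded in the parse report with a reason; an empty result is a hard
    error.  Supplier field ``.`` or ``-`` means "no listed supplier"; a
    missing or empty price field means "not commercially priced".
    """
    enzymes: list[RestrictionEnzyme] = []
    report = ParseReport()
    seen: set[str] = set()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        try:
            enzymes.append(_parse_line(stripped, seen))
            report.accepted += 1
        except ValueError as exc:
            report.rejected.append((lineno, stripped, str(exc)))
    if not enzymes:
        raise EnzymeTableError("no enzymes parsed from table")
    return enzymes, report


def _parse_line(line: str, seen: set[str]) -> RestrictionEnzyme:
    fields = [f.strip() for f in re.split(r"\t+", line)]
    if len(fields) < 3:
        raise ValueError("expected at least 3 tab-separated fields (name, site, suppliers)")
    name, site, suppliers_field = fields[0], fields[1], fields[2]
    if not name:
        raise ValueError("empty enzyme name")
    if name in seen:
        raise ValueError(f"duplicate enzyme name {name!r}")
    pattern = parse_recognition_site(site)
    suppliers = frozenset(suppliers_field) - {".", "-"}
    if not all(s.isalpha() for s in suppliers):
        raise ValueError(f"invalid supplier codes {suppliers_field!r}")
    price: float | None = None
    if len(fields) >= 4 and fields[3]:
        price = float(fields[3])
        if price < 0:
            raise ValueError("negative price")
    seen.add(name)
    return RestrictionEnzyme(name=name, pattern=pattern, suppliers=suppliers, price=price)


def write_enzyme_table(enzymes: Sequence[RestrictionEnzyme], stream: TextIO) -> None:
    """Serialize back to the TSV dialect read by :func:`parse_enzyme_table`."""
    stream.write("# name\tsite\tsuppliers\tprice\n")
    for e in enzymes:
        price = "" if e.price is None else f"{e.price:g}"
        suppliers = "".join(sorted(e.suppliers)) or "."
        stream.write(f"{e.name}\t{format_recognition_site(e.pattern)}\t{suppliers}\t{price}\n")
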