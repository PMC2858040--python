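"""Brute-force reference implementations used to check the engine.

Deliberately independent of the package internals: IUPAC tables are
re-declared here, matching is done by expanding the degenerate site to all
concrete words and substring-scanning, and antisense geometry is derived
from first principles (a bottom-strand enzyme's top/bottom cuts mirror
within the site).
"""

from itertools import product as _product

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
COMP = {"A": "T", "C": "G", "G": "C", "T": "A",
        "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
        "B": "V", "V": "B", "D": "H", "H": "D", "N": "N"}


def expand(symbols: str) -> set[str]:
    return {"".join(w) for w in _product(*(IUPAC[s] for s in symbols))}


def revcomp_symbols(symbols: str) -> str:
    return "".join(COMP[s] for s in reversed(symbols))


def substring_starts(seq: str, words: set[str]) -> list[int]:
    out = []
    for w in words:
        start = seq.find(w)
        while start != -1:
            out.append(start)
            start = seq.find(w, start + 1)
    return sorted(set(out))


def brute_force_hits(seq, symbols, cut_top, cut_bottom):
    """Expected (strand, start, cut_top, cut_bottom) tuples for both strands,
    with hits whose cuts leave [0, len] dropped and palindromic antisense
    duplicates suppressed."""
    n, L = len(seq), len(symbols)
    words = expand(symbols)
    rc_symbols = revcomp_symbols(symbols)
    hits = []
    for start in substring_starts(seq, words):
        ct, cb = start + cut_top, start + cut_bottom
        if 0 <= ct <= n and 0 <= cb <= n:
            hits.append(("SENSE", start, ct, cb))
    palindromic = (
        rc_symbols == symbols and (L - cut_bottom, L - cut_top) == (cut_top, cut_bottom)
    )
    if not palindromic:
        for start in substring_starts(seq, expand(rc_symbols)):
            # enzyme on the bottom strand: its own top-strand cut lands on our
            # bottom strand; mirror the offsets within the site
            ct, cb = start + (L - cut_bottom), start + (L - cut_top)
            if 0 <= ct <= n and 0 <= cb <= n:
                hits.append(("ANTISENSE", start, ct, cb))
    return sorted(hits, key=lambda h: (h[1], h[0]))
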