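"""Parse a restriction-enzyme table and inspect the pattern algebra.

The TSV dialect is: name <TAB> site <TAB> supplier-codes <TAB> price.
A ``^`` inside the site marks the top-strand cut; ``(t/b)`` offsets after
the site describe outside cutters (Type IIS).
"""

import io

from snprflp import (
    classify_enzyme,
    expand_pattern,
    parse_enzyme_table,
    reverse_complement_pattern,
)

TABLE = """\
# name\tsite\tsuppliers\tprice
EcoRI\tG^AATTC\tN\t62
HinfI\tG^ANTC\tN\t60
BsaI\tGGTCTC(1/5)\tN\t75
BadEnz\tGAAXTC\tN\t10
"""

enzymes, report = parse_enzyme_table(io.StringIO(TABLE))
print(f"accepted {report.accepted} enzymes, rejected {report.n_rejected}:")
for lineno, text, reason in report.rejected:
    print(f"  line {lineno}: {reason}")

for e in enzymes:
    p = e.pattern
    rc = reverse_complement_pattern(p)
    print(
        f"{e.name:8s} site={p.symbols} cuts=({p.cut_top},{p.cut_bottom}) "
        f"class={classify_enzyme(e).value:9s} rc={rc.symbols} "
        f"expansions={len(expand_pattern(p))}"
    )

# HinfI's N expands to 4 concrete words; its class is therefore IUPAC
# (degenerate), while EcoRI's single word makes it NON_IUPAC.  BsaI cuts
# 1 and 5 nt past its site, so its offsets exceed the pattern length.
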