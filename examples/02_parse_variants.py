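"""Parse SNP-containing sequences in bracket and IUPAC notation.

Bracket alleles keep their written order; IUPAC ambiguity codes expand to
alphabetically ordered alleles; ``-`` inside a bracket is the deletion
allele of an indel.
"""

from snprflp import parse_snp_sequence, realize_alleles

for body in [
    "ACGTACGT[A/G]ACGTACGT",          # di-allelic substitution
    "ACGTACGT[G/C/A]ACGTACGT",        # tri-allelic, written order kept
    "ACGTACGT[-/AGG]ACGTACGT",        # indel: deletion vs 3-nt insertion
    "ACGTACGRTACGT",                  # IUPAC R = A/G
]:
    t = parse_snp_sequence(body, label="demo")
    v = t.variants[0]
    alleles = "/".join(a or "-" for a in v.alleles)
    print(f"{body:32s} -> variant at backbone pos {v.position}, "
          f"alleles {alleles} ({v.kind})")
    for r in realize_alleles(t, 0):
        print(f"    allele {r.allele_index}: {r.sequence}  span={r.variant_span}")

# Each realization is the concrete per-allele sequence the PCR would copy;
# for the deletion allele the variant span is empty and the realization is
# shorter, which the digest simulation accounts for downstream.
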