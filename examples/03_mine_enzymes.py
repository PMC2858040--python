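"""Mine restriction enzymes that discriminate SNP alleles.

An enzyme is reported when its cut-position pattern (both strands, window
of +-30 nt around the variant) differs between alleles — the basis of a
PCR-RFLP genotyping assay.
"""

from snprflp import (
    default_fixture_enzymes,
    mine_discriminating_enzymes,
    parse_snp_sequence,
)

# The G allele completes an EcoRI site (GAATTC); the C and A alleles break it.
t = parse_snp_sequence("TTCAGTCCAT[G/C/A]AATTCTTGGACTGA", label="demo-snp")

for r in mine_discriminating_enzymes(t, 0, default_fixture_enzymes()):
    pairs = ", ".join(f"{i}-{j}" for i, j in sorted(r.discriminated_pairs))
    cuts = {ai: list(c) for ai, c in sorted(r.per_allele_cuts.items())}
    print(f"{r.enzyme.name} ({r.degeneracy_class.value}): "
          f"discriminates allele pairs {pairs}; cuts per allele {cuts}")

# Expected: EcoRI cuts only the G-allele amplicon, so allele pairs 0-1 and
# 0-2 are distinguishable on a gel while 1-2 (C vs A) is not.
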