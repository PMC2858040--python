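"""Mutagenic (dCAPS) primer design when no natural enzyme discriminates.

A single deliberate mismatch near the primer's 3' end completes a
restriction site together with one allele only; the introduced base is
shown in lowercase.
"""

import random

from snprflp import (
    default_fixture_enzymes,
    design_mutagenic,
    genotype_fragment_table,
    mine_discriminating_enzymes,
    parse_snp_sequence,
)

rng = random.Random(4)
flank = lambda n: "".join(rng.choice("ACGT") for _ in range(n))

# GACTT before a C/T SNP: no enzyme cuts either allele naturally, but a
# C->A mismatch in the forward primer turns GACTT+C into G-AATT-C (EcoRI)
# on the C allele only.
body = flank(200) + "GACTT" + "[C/T]" + flank(200)
t = parse_snp_sequence(body, label="dcaps-demo")

enzymes = default_fixture_enzymes()
print("natural enzymes:", [r.enzyme.name for r in mine_discriminating_enzymes(t, 0, enzymes)])

designs = design_mutagenic(t, 0, enzymes)
d = designs[0]
alleles = t.variants[0].alleles
print(f"enzyme enabled: {d.enabled_enzyme.name}")
print(f"marked F primer: {d.marked_primer_sequence()}")
print(f"mismatch {d.original_base}->{d.introduced_base} at primer offset "
      f"{d.mismatch_offset + 1} (never the 3'-terminal base)")
print(f"cutting alleles: {sorted(alleles[i] for i in d.cutting_alleles)}")

profiles = genotype_fragment_table(d.pair, t, 0, d.enabled_enzyme)
for ai, prof in sorted(profiles.items()):
    frags = "+".join(map(str, prof.fragment_lengths))
    print(f"allele {alleles[ai]}: {prof.amplicon_length} nt -> {frags}")

# The C-allele amplicon gains one extra cut from the completed site, so
# it shows one more fragment than the T allele; constant sites shared by
# both alleles (as here) do not affect the genotype call.
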