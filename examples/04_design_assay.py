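"""Design a complete PCR-RFLP assay: primers + digest simulation.

A natural primer pair brackets the variant; the per-allele fragment table
shows what each genotype looks like after digestion.
"""

import random

from snprflp import (
    default_fixture_enzymes,
    design_natural_pair,
    genotype_fragment_table,
    mine_discriminating_enzymes,
    parse_snp_sequence,
)

rng = random.Random(42)
flank = lambda n: "".join(rng.choice("ACGT") for _ in range(n))

# T/C SNP whose T allele completes a DdeI site (CTNAG); 200-nt flanks
body = flank(198) + "C" + "[T/C]" + "GAG" + flank(198)
t = parse_snp_sequence(body, label="rs-demo")

enzymes = default_fixture_enzymes()
results = mine_discriminating_enzymes(t, 0, enzymes)
print("discriminating enzymes:", [r.enzyme.name for r in results])

pairs = design_natural_pair(t, 0)
best = pairs[0]
f, r = best.forward, best.reverse
print(f"F {f.sequence}  pos={f.template_start + 1} len={f.length} "
      f"GC%={f.gc_fraction:.1f} Tm={f.tm:.2f}")
print(f"R {r.sequence}  pos={r.template_start + 1} len={r.length} "
      f"GC%={r.gc_fraction:.1f} Tm={r.tm:.2f}")
print(f"Tm-difference={best.tm_difference:.2f} "
      f"product={best.reference_product_length} nt")

enzyme = results[0].enzyme
profiles = genotype_fragment_table(best, t, 0, enzyme)
for ai, prof in sorted(profiles.items()):
    allele = t.variants[0].alleles[ai] or "-"
    frags = "+".join(map(str, prof.fragment_lengths))
    print(f"allele {allele}: {prof.amplicon_length} nt -> {frags}")

# The cut allele shows two fragments, the uncut allele one undigested
# band; heterozygotes show all three on a gel.
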