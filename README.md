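# snprflp

PCR-RFLP assay design for SNP genotyping, offline and scriptable.

Restriction fragment length polymorphism (RFLP) genotyping reads a SNP out
on an agarose gel: a PCR product spanning the variant is digested with a
restriction enzyme whose cutting differs between the alleles, and the
fragment ladder identifies the genotype. Finding such an enzyme by hand —
checking every degenerate recognition site, on both strands, against every
allele — is tedious and error-prone, and when **no** enzyme discriminates
naturally, a usable assay can still be rescued with a *mutagenic* (dCAPS)
primer: a single deliberate mismatch near the primer's 3' end that
completes a recognition site together with one allele only.

`snprflp` automates both routes for anyone running small-scale genotyping
(association studies, mutation screening, food/microbial typing):

- **variant input** — sequences with `[dNTP1/dNTP2]` bracket alleles
  (2–4 alleles, indels as `-`), or single-letter IUPAC ambiguity codes;
  up to 50 variants per sequence with >6 nt between adjacent sites;
- **enzyme mining** — degenerate (IUPAC) site matching on sense and
  antisense strands, cut-position comparison per allele pair, indel-safe
  coordinate anchoring, enzyme classification (IUPAC vs non-IUPAC sites),
  suppliers and price;
- **primer design** — natural pairs bracketing the variant (length,
  product size, GC%, Tm and Tm-difference constraints) and single-mismatch
  mutagenic designs verified by replaying the digest;
- **digest simulation** — per-genotype amplicon fragment tables.

Primer melting temperatures use the salt-adjusted composition formula
`Tm = 81.5 + 16.6·log10([Na+]) + 0.41·GC% − 675/length`.

## Worked example

```python
from snprflp import (default_fixture_enzymes, mine_discriminating_enzymes,
                     parse_snp_sequence)

t = parse_snp_sequence("TTCAGTCCAT[G/C/A]AATTCTTGGACTGA", label="demo-snp")
for r in mine_discriminating_enzymes(t, 0, default_fixture_enzymes()):
    pairs = ", ".join(f"{i}-{j}" for i, j in sorted(r.discriminated_pairs))
    print(r.enzyme.name, r.degeneracy_class.value, "pairs:", pairs,
          dict(sorted(r.per_allele_cuts.items())))
```

prints

```
EcoRI NON_IUPAC pairs: 0-1, 0-2 {0: (11,), 1: (), 2: ()}
```

meaning: the G allele (index 0) completes the EcoRI site `GAATTC`, giving a
top-strand cut at position 11, while the C and A alleles give none — so
EcoRI distinguishes G from C and G from A on a gel, but cannot tell C from
A apart. The `examples/` directory walks through every capability
(table parsing, variant grammars, mining, full assay design with fragment
tables, dCAPS design); each script prints its results with a note on what
they mean.

## Command line

```bash
snp-rflp fixture --seed 1 --out-dir fx          # synthetic dataset
snp-rflp mine   --fasta fx/templates.fasta --rebase fx/enzymes.tsv
snp-rflp design --fasta fx/templates.fasta --rebase fx/enzymes.tsv \
                --format TEXT --mutagenic
```

Enzyme tables use a small TSV dialect mirroring standard conventions
(`G^AATTC` for within-site cuts, `GGTCTC(1/5)` for outside cutters); see
`docs/enzyme_table_format.md`.

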