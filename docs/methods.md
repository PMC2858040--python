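# Methods

## Problem and model

A PCR-RFLP assay genotypes a known variant by amplifying the region around
it and digesting the product with a restriction enzyme whose cutting
differs between alleles. The package models three objects: a
**recognition pattern** (IUPAC string plus top/bottom cut offsets relative
to the pattern start), a **SNP template** (a concrete backbone with 1–50
polymorphic sites, each carrying 2–4 allele strings; the empty string is a
deletion allele), and a **primer pair** with composition-based
thermodynamic annotations. Everything downstream — mining, digestion,
design — is a pure function of these inputs, so identical inputs always
produce byte-identical reports.

## Site matching

Degenerate matching compiles each pattern to a fixed-length lookahead
regular expression (IUPAC symbol → character class), which finds
overlapping occurrences. Antisense hits are found by matching the
reverse-complement pattern on the sense sequence with cut offsets
remapped to the mirrored frame (`cut' = len − cut`, strands swapped), so
every reported cut is already in sense-sequence coordinates. Hits whose
cut positions fall outside `[0, len]` — outside cutters near a sequence
end — are discarded. For self-complementary patterns the antisense scan
is skipped entirely, since every such hit would duplicate a sense hit.
Equivalence with a brute-force expand-every-word-and-substring-scan
oracle is asserted property-style in the tests and re-measured by the
acceptance script on 500 random sequence/enzyme pairs up to 2 kb.

## Discrimination mining

For the variant under analysis, each allele is realized as a concrete
sequence (all *other* variants fixed to their first-listed allele, the
natural reference in bracket notation). Each realization is scanned and
hits are kept when the match interval intersects a window of ±30 nt
around the variant span (default; configurable). Top-strand cut positions
are then **anchored**: cuts at or upstream of the variant start are
expressed relative to the start, cuts at or downstream of the variant end
relative to the end, cuts inside the span flagged as internal. An enzyme
is reported for an allele pair iff the anchored cut multisets differ.

The anchoring is what makes indels behave sensibly: an insertion shifts
every downstream cut, but shifted-only cuts anchor to identical values,
so a mere length offset does not count as discrimination (the undigested
length difference is visible in the fragment table anyway); a genuinely
gained or lost cut does count. For same-length alleles the anchoring
reduces to plain coordinates.

The ±30 nt default covers all common recognition sites (≤ 8 nt) plus the
largest outside-cutter reach in the bundled panel, while keeping the
assayable signal local to the variant.

## Digestion

Complete digestion is simulated from the distinct top-strand cut
positions strictly inside the amplicon; fragments are the intervals
between consecutive cuts plus the ends, so their lengths always sum to
the amplicon length. Genotype fragment tables rebuild the amplicon per
allele between the forward primer start and the reverse primer 3'
coordinate (shifted by the allele length difference for indels), apply
the mutagenic mismatch when the pair carries one, and digest.

## Primer design

Candidates are enumerated exhaustively within the flanks (never on a
variant span — including the spans of *other* variants in multi-SNP
templates, since a primer on polymorphic sequence would genotype
unpredictably), filtered by length 18–26 nt and GC 20–80%, and paired
under product length 100–500 nt and Tm difference ≤ 5 °C. Pairs are
ranked by Tm difference, then distance of the product size from the range
midpoint (300 nt), then leftmost-forward/shortest coordinates as
deterministic tie-breaks. The product-size constraint is evaluated on the
first-listed allele; per-allele product lengths are reported. Tm is the
salt-adjusted composition formula
`81.5 + 16.6·log10([Na+]) + 0.41·GC% − 675/len` with `[Na+]` = 0.05 M by
default; nearest-neighbour thermodynamics is deliberately out of scope —
the composition formula is fully specified, monotone in the quantities
reported (GC%, length), and adequate for ranking 15–30 nt oligos.

### Mutagenic (dCAPS) search

For each enzyme, the search considers forward primers whose 3' end abuts
or lies within one pattern length of the variant, and every single-base
substitution in the last 5 primer bases excluding the 3'-terminal base
(a terminal mismatch would abolish extension; a mismatch further than
~5 nt from the 3' end destabilizes the primer less but the created site
must reach the variant, so the window also bounds the useful search). A
candidate mutation is kept when the mutated realizations of a *proper,
non-empty* subset of alleles gain an enzyme match overlapping the
mismatch-to-variant region. Each surviving mutation is packaged with the
best reverse primer under the natural-pair criteria, then **verified in a
closed loop**: the design is replayed through the genotype fragment
table and emitted only if the per-allele fragment multisets actually
differ. Ranking follows the natural criteria, then non-degenerate
(NON_IUPAC) enzymes before degenerate ones (cleaner digests), then price
ascending with unpriced enzymes last.

By default only the forward primer is mutated (the conventional
presentation of such assays); `mutagenic_strands: both` additionally
mirrors the template (reverse complement, variants remapped, allele
order preserved), runs the same forward search, and maps designs back as
reverse-primer mutations, re-verifying each in the original frame.

## Synthetic data generator

Fixtures emulate resequenced SNP flanks: uniform random A/C/G/T flanks
(default 150 nt each side — enough for any 100–500 nt product) around a
single variant whose allele count is drawn from a configurable
distribution (default 70% di-, 10% tri-, 10% tetra-allelic, 10% indel).
A configurable fraction of templates (default 50%; 100% where a known
answer is needed) carries a planted site: a concrete word of a real
enzyme's recognition sequence embedded so allele 0 completes it and
allele 1 carries a base outside the IUPAC set at that offset — hence no
expansion of the site can match there — with flanks rejection-sampled so
the broken allele gains no accidental match of the planted enzyme across
the variant. The planted enzyme and allele pair are recorded as ground
truth at generation time, independently of the miner.

What the fixtures do **not** emulate: base-composition bias, repeats and
homopolymers, near-site density of real genomes, sequencing errors, or
linked variants on one haplotype. Passing the planted-recovery and
closed-loop checks therefore demonstrates correctness of the matching,
anchoring and design logic — not recall on any particular genome's
sequence composition.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open internally; reports print 1-based.
- Tm comparisons in ranking are rounded to 10⁻⁶ °C before ordering to
  make float ties deterministic.
- Pattern expansion is capped at 65,536 words; larger requests error and
  point to direct degenerate matching.
- The 6-nt spacing rule is read strictly: adjacent variants must have
  > 6 nt of backbone between them (≥ 7 nt of private flank each).
- IUPAC `N` in a sequence body is rejected — as a variant it is
  uninformative (4 unordered alleles), and as an unknown base it leaves
  no concrete template to match.
- Enzyme-table lines with no cut descriptor, two descriptors, unknown
  symbols or duplicate names are rejected per line with a reason; an
  empty resulting table is a hard error.
- Digest profiles use *distinct* cut positions (a position cut by hits on
  both strands is one physical cut); discrimination comparison keeps the
  multiset of per-hit cuts.

## Problem sizes

The shipped checks use 500 oracle comparisons on sequences up to 2 kb,
200 planted templates for recovery/replay, 100 natural-enzyme-free
templates for the mutagenic closed loop, and 10,000 conservation digests
— sizes at which every rate is measured exactly and the whole suite runs
in a couple of minutes on one CPU.

## Known limitations

- No nearest-neighbour Tm, primer-dimer or hairpin screening; designs
  should be checked with a thermodynamic tool before ordering.
- Complete digestion is assumed: no partial digestion, methylation
  blocking or star activity.
- One mismatch per mutagenic primer; multi-mismatch dCAPS variants are
  not searched.
- Enzymes cutting on both sides of their site, and sites with unknown
  cut positions, are not representable in the enzyme table.
- Multi-variant templates are analyzed one variant at a time with the
  other sites fixed to their first allele; haplotype-aware design is out
  of scope.
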