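# Enzyme table format

`snprflp` reads restriction enzymes from a tab-separated text file, one
enzyme per line:

```
# name	site	suppliers	price
EcoRI	G^AATTC	N	62
HinfI	G^ANTC	N	60
BsaI	GGTCTC(1/5)	N	75
MspA1I	CMG^CKG	N
```

Columns:

1. **name** — unique within the table.
2. **site** — recognition sequence over the 15-letter IUPAC alphabet with
   exactly one cut descriptor:
   - `^` marks the top-strand cut inside the site; the bottom-strand cut
     is placed symmetrically (`len − cut_top`), the convention for
     orthodox palindromic cutters;
   - `(t/b)` after the site gives top/bottom cut offsets counted past the
     site's 3' end, for outside (Type IIS) cutters.
3. **suppliers** — a string of single-letter supplier codes (`.` or `-`
   for none).
4. **price** — optional nonnegative decimal (price per assay unit);
   omitted or empty means "not commercially priced" and such enzymes sort
   last in price rankings.

`#` lines and blank lines are skipped. Malformed lines (unknown symbols,
duplicate names, missing or doubled cut descriptors, negative prices) are
rejected individually and reported with a reason; a table that yields no
enzymes at all is a hard error.

## Converting from REBASE-style listings

Public enzyme listings typically print sites in the same `^` / `(t/b)`
notation used here (e.g. `GACGT^C`, `ACCTGC(4/8)`), so conversion is
usually a matter of extracting the name, site, supplier-code string and
price columns into tabs. Entries this dialect cannot express are not
supported and should be dropped during conversion:

- sites cut on **both** sides (two `(t/b)` groups);
- enzymes with unknown cut positions (site without any descriptor);
- methylation-dependent or nicking behaviour.

Isoschizomers are not grouped: every line is an independent enzyme.
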