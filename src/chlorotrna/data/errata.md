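# Fixture errata and transcription notes

The TSVs in this directory are machine-readable transcriptions of the five
published survey tables on chlorovirus tRNA clusters and codon usage. The
source tables encode gene presence and pseudogene status by cell color, which
is not recoverable from a text rendering; the transcription below therefore
combines the printed spacer numbers and totals with every constraint stated in
the surrounding text. All judgment calls and known internal inconsistencies of
the printed tables are listed here. Nothing in this file is corrected in the
TSVs themselves: the fixtures carry the printed values untouched wherever a
printed value exists.

## Codon-usage table (table5_codon_usage.tsv)

* The ratio column is defined as mean(virus columns)/host column. Recomputing
  it from the printed frequency columns reproduces the printed ratio within
  ±0.015 for 57 of 61 codons. Four codons disagree with the formula and are
  carried as printed, flagged as suspected misprints:
  - GAU: formula gives 2.33, printed 4.56 (gross discrepancy)
  - CUU: formula gives 3.32, printed 2.00
  - AUG: formula gives 1.29, printed 2.04
  - GGG: formula gives 0.49, printed 0.52 (marginal)
* The AN69C column sums to 95.57 rather than ~100, consistent with one or
  more misprinted AN69C entries (a plausible cause of the CUU/AUG rows above).
* The `bold` flag transcribes bold *codon labels* only. The printed table also
  bolds isolated numeric cells (e.g. the GAA ratio 5.70) without bolding the
  codon label; those are not flagged.

## Cluster tables (table1_nc64a.tsv, table2_sag.tsv, table3_pbi.tsv)

* Per-virus gene presence was reconstructed, not read off colors. Hard
  constraints honored exactly: printed per-virus totals (clade sums 147, 137,
  123); spacer count = cluster genes − 1; tRNA-Arg(AGA) in all 41 viruses;
  tRNA-Gly(GGA) in 39/41 (absent from PBCV-1, where a tRNA-Lys substitution is
  footnoted, and from NE-JV-1); three NC64A viruses (MA-1E, CvsA1, CviK1) with
  the clade-maximum 14 genes; Pbi maximum 11 (Fr5L); MA-1E with three
  Lys-AAG copies and AR158 with none; CZ-2 with four Asn-AAC copies; the six
  viruses excluded from the three-marker phylogeny (PBCV-1, NE-JV-1, AR158,
  NE-JV-4, GM0701.1, MN0810.1) each lacking at least one of Tyr/Gly/Arg; the
  SAG orphan tRNA-Thr in all 13 SAG viruses at the printed 29–36 kb distances;
  tRNA-Tyr present in 34/41 viruses, matching the count of intron-bearing
  tRNA-Tyr genes stated in the text.
* Five rows print one or two more spacer numbers than (total − 1) permits:
  KS1B (13 numbers, total 12), IL-3A (11, total 10), NY-2B and IL-5-2s1
  (8, total 8), Canal-1 (8 intra-cluster numbers, total 9 including the
  orphan), ATCV-1 (10, total 11 including the orphan). For these rows the
  excess trailing numbers were dropped; the retained spacers are the leading
  printed values.
* Pseudogene (orange) and substitution (red) cell colors are unrecoverable;
  the `pseudogene` column is all-false and only the two footnoted
  substitutions (PBCV-1 Lys-for-Gly; IL-3A and NE-JV-4 Asn-for-Gln) are
  carried, in the `note` column.
* Orphan distances printed as "36k" etc. are stored as round thousands.

## Cross-table inconsistencies in the source (carried as printed)

* The text says 410 total tRNA genes; the printed per-virus totals sum to 407.
* The text says 17 distinct tRNA identities; the union of the three tables'
  column headings is 18 (amino acid, codon) pairs.
* The clade presence/absence table lists the two clade-private Pbi Thr-ACG
  loci as separate unique rows but merges duplicated loci elsewhere (e.g. the
  multiple Asn-AAC columns); summary code reports identity-level counts plus a
  locus-aware unique count matching the printed 2/3/4 unique-per-clade totals.
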