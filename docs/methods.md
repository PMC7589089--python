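# Methods

`chlorotrna` re-implements, as a tested pipeline, a comparative-genomics
analysis of the tRNA gene clusters carried by chloroviruses — large dsDNA
viruses (family *Phycodnaviridae*) of chlorella-like green algae — and of how
those tRNAs interact with the codon-usage bias (CUB) conflict between an
AT-rich virus genome (~40% GC) and its GC-rich host (~67% GC). This note
records the models, conventions, parameter choices and known limitations.

## Feature model and coordinates

Genomes are single contigs with ordered features (tRNA, CDS, other).
Coordinates are 1-based inclusive everywhere in the model (GenBank
convention); GFF3 and Biopython half-open handling is internal to the
readers/writers. Minus-strand features keep plus-strand coordinates and are
reverse-complemented on sequence retrieval. Intron-bearing tRNA genes are one
feature with two exon sub-intervals that tile the gene span; GenBank `join()`
locations and GFF3 `tRNA`→`exon` hierarchies both collapse to this form, so a
genome serialized both ways parses to the same model (tested). `source` and
`gene` rows are skipped on read because they duplicate the record span or
their children; any other feature type is retained as `other` — cluster
interruption logic must be able to see it. GenBank output pins the LOCUS date
so identical inputs give byte-identical files.

## tRNA semantics

Anticodons are stored 5′→3′ (RNA); the cognate codon is the reverse
complement, an involution asserted over all 64 triplets. Wobble is modeled as
a per-base map at anticodon position 34: by default G34 pairs codon-third
C and U (so tRNA-Tyr(GUA) reads both UAC and UAU) while A/C/U34 are
Watson–Crick only; the map is configuration, and the Watson–Crick partner is
always a member. TilS (tRNA-Ile lysidine synthase) is modeled as a
recognition-set rewrite, not chemistry: on tRNA-Met with anticodon CAU it
relabels the gene Ile/AUA and fixes its recognition set to exactly {AUA},
because lysidinylated C34 pairs A. Only Met(CAU) is a substrate; a second
application is an error.

Identity resolution prefers an `/anticodon` qualifier (either a bare triplet
or the NCBI `(pos:…,aa:Tyr,seq:gta)` form) and falls back to product-string
parsing ("tRNA-Tyr (GTA)"); the source records' qualifier conventions vary,
so both are accepted. Features with neither are kept as identity-unknown with
a warning: they count toward totals but are excluded from favorability and
presence analyses.

Intragenic RNA polymerase III type-2 promoter elements are scanned as two
11-mer IUPAC consensus motifs, Box A `TRGCNNARYNN` and Box B `GTTCGANNCNN`
with up to 2 mismatches. The source survey cites but does not print its
consensus strings, so these literature-canonical defaults are configuration
(`BoxMotifConfig`), not data. A-box hits are reported only 5′ of the best
B-box hit, reflecting promoter geometry.

## Cluster detection

Clustering is greedy left-to-right chaining of the genome-ordered inventory.
A chain extends while (i) the intergenic spacer to the next tRNA —
defined as `start(next) − end(prev) − 1`, the count of nucleotides strictly
between the genes; the tables this reproduces print "nt between two adjacent
tRNAs" — is at most `max_gap_nt`; (ii) the number of intervening non-tRNA
features is 0 (strict mode, the survey definition "no intervening genes; 2 or
more") or at most 3 (relaxed); and (iii) the strand matches, when required.
Chains of ≥ 2 genes are clusters; the rest are orphans with the gap to the
nearest cluster boundary. Relaxed defaults (`max_gap_nt` 2000, ≤ 3
intervening) keep every published row — including interrupted clusters with
1416 and 1142 nt internal gaps — in one cluster while the ~30 kb orphan
tRNA-Thr of the SAG clade never joins. Overlapping tRNA annotations are an
error, never silently merged.

Two derived classifications: the genome-third of a cluster is decided by its
midpoint against thirds of the genome length (closed on the left, so a
midpoint exactly at L/3 is "first"); a cluster is a single-transcript
(co-transcription) candidate iff it is one-stranded, uninterrupted, and all
spacers are ≤ 500 nt.

A note on monotonicity: the number of *chains* is non-increasing in
`max_gap_nt`, but the number of *emitted clusters* is not — two singletons
below the threshold emit zero clusters, then merge into one when the
threshold rises. Tests assert the chain-count version.

## Codon usage and the ratio statistic

Codon frequencies are percentages over counted sense codons in frame 0;
a terminal stop is excluded, internal stops go to a QC side channel, and
ambiguous codons are skipped, so computed 61-row tables sum to exactly 100.
The ratio statistic for codon *c* is R_c = (mean over virus tables of
f_{v,c}) / f_{host,c} — mean first, then the ratio, per the source table's
footnote; with one virus table this is a plain ratio. R_c > 1 means the
codon is virus-favored. A zero host frequency makes R_c undefined (flagged,
never ±inf). Presentation rounding is half-up to two decimals; tests compare
at ±0.015.

Favorability: the recognized-codon set of an inventory is assembled from
strict cognate codons by default (wobble and TilS expansions are flags,
off by default, because strict distinct-codon counting is what reproduces the
published "7 of 11 assist" for PBCV-1); each distinct codon is assisting if
R_c > τ (τ = 1.0), boundary if equal, neutral/host-favoring otherwise.
A per-gene counting mode is provided for sensitivity analysis (three Asn
genes = three assisting genes but one assisting codon). Pseudogenes and
identity-unknown genes are excluded with a warning.

## Clade comparison

Identity granularity is (amino acid, cognate codon) — the column semantics of
the survey tables; anticodon-level granularity would conflate nothing here
but is not needed. Cross-clade categories (common to all three clades, shared
by exactly two, unique to one) are computed at identity level from the
presence matrix, where a clade carries an identity if any member genome does
and pseudogenes count toward presence by default. For identities unique to a
single clade, the unique *gene* count expands each identity by the largest
per-genome copy number in that clade: clade-private duplicated loci (the two
Pbi Thr-ACG loci) are distinguishable positions within that clade's synteny
and are counted separately, which reproduces the published 2/3/4 unique
counts; cross-clade merging stays identity-level because loci in different
clades have no positional correspondence.

Gene-order synteny is scored as normalized longest common subsequence,
2·LCS(a,b)/(|a|+|b|), over identity labels — the source makes only the
qualitative claim (synteny within, not between, clades), so the metric is
this package's choice; tests pin it to an exhaustive-enumeration oracle.
Marker concatenation extracts spliced marker gene sequences per genome in a
fixed order and emits FASTA; genomes missing a marker are skipped with a
warning (six of the 41 survey genomes lack one of Tyr/Gly/Arg), and duplicate
copies resolve to the first in genome order. Alignment and tree building are
out of scope — external tools consume the FASTA.

## Synthetic genomes

The generator emulates the features of the study system that the analysis
actually touches, with exact ground truth:

* tRNA genes are built on a fixed 73 nt scaffold (a canonical cytosolic tRNA
  gene body with the 3′-terminal CCA absent, as in the chlorovirus genes):
  anticodon at positions 34–36, Box A/Box B consensus realized verbatim at
  offsets 7 and 52, optional intron inserted one exonic nucleotide 3′ of the
  anticodon (lengths 10–14 in the study clades), pseudogenes realized as an
  annotation flag plus a two-base anticodon-loop disruption that leaves the
  anticodon and both boxes intact.
* Virus genomes: CDS codons drawn i.i.d. from a configured percent table
  (e.g. the packaged PBCV-1 column), intergenic sequence at a target GC
  (40% virus / 67% host), one cluster per `ClusterSpec` (order, spacers,
  optional interrupting CDS inside a junction, orphans at a stated gap), all
  tRNA genes on one strand. Host genomes are the same minus the cluster.
* Default problem sizes are scaled to the analysis, not to real genomes:
  60–80 kb genomes with ~25 CDSs (real chlorovirus genomes are 290–370 kb
  with ~400 CDSs) keep the full test battery and the acceptance run fast
  while leaving every measured property (GC, codon recovery within binomial
  error, spacer geometry, 30 kb orphan separation) unchanged.
* Identical config + seed gives byte-identical GenBank/GFF3/FASTA/JSON
  output (tested).

What the generator does **not** emulate: codon autocorrelation and
codon-pair bias, GC gradients, tRNA secondary structure (a cloverleaf is not
verified — structure prediction is explicitly out of scope), genome
rearrangement, and multi-contig drafts. Passing tests on synthetic data
therefore demonstrate correctness of the bookkeeping and statistics on
annotations, not annotation discovery from raw sequence.

## Fixtures

Machine-readable transcriptions of the five published tables ship with the
package (checksum-pinned TSVs). The published cluster tables encode gene
presence by cell color, which text extraction loses; per-virus presence was
reconstructed under every hard constraint the text states (printed totals and
their clade sums 147/137/123, Arg-AGA in 41/41, Gly-GGA in 39/41, copy-number
statements, the six marker-lacking viruses, orphan distances). The packaged
errata sidecar (`src/chlorotrna/data/errata.md`) documents every judgment
call and every internal inconsistency of the printed source — notably that
the printed ratio column disagrees with its own formula for four codons
(GAU, CUU, AUG, GGG; 57/61 concordant at ±0.015), that the printed AN69C
frequency column sums to 95.6, that the stated totals 410 and 17 differ from
the computed 407 and 18, and that pseudogene colors are unrecoverable.
Fixtures carry printed values untouched; computations report computed values.

## Numerical conventions

Frequencies use double precision with sums asserted at 1e-9; ratio
comparisons against printed values use ±0.015 (printed precision is two
decimals); presentation rounding is decimal half-up; statistical recovery
assertions use 3σ binomial bounds at the simulated codon counts; argmax ties
in preferred-codon reports are returned as sets, never broken arbitrarily.
All randomness flows through `numpy.random.default_rng` seeded explicitly.
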