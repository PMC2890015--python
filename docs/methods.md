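# Methods

This note documents the models, conventions, numerical choices, and
known limitations behind each stage of the pipeline.

## Coordinate model

All coordinates are 1-based and inclusive, matching FASTA/GFF3/GenBank
conventions; orientation is carried by a strand symbol, never by
reversed coordinates. A multi-contig insert is analyzed in a single
concatenated frame in which ordered contigs are joined by `gap_pad`
(default 100) 'N' characters; gap sentinels mark the padding, the
insert's `total_length` excludes it, and no annotation feature may span
a sentinel. The true inter-contig gap sizes of a partially assembled
insert are unknown in general, so `gap_pad` is a free parameter whose
default is deliberately round; all downstream logic treats the padding
as opaque (codons touching an 'N' are undetermined).

Codon positions are recorded as the genomic coordinate of the codon's
first base *in transcript orientation*: for a minus-strand gene that is
the codon's highest genomic coordinate. This single convention is used
by the inference scan, the prediction tracks, the validation counts, and
the synthetic generator.

## SSR scanning

A tract is a maximal, uninterrupted run of a primitive unit of length
2–5 bp repeated ≥ 5 whole times (`min_repeats`, `max_unit` are
parameters; the defaults reproduce SSRIT run with pentamers as the
maximum unit and five as the minimum repeat count). Mononucleotide runs
are excluded by `min_unit = 2`: the conventional dinucleotide minimum,
and consistent with a motif-class table that lists no mononucleotide
class. Primitivity prevents double-counting ((AT)10 is never also
(ATAT)5); maximality is in whole units, so a trailing partial unit lies
outside the tract; one tract is reported per maximal periodic region and
unit length, anchored at the region's left edge, so phase-shifted
readings of one region are not separate tracts. A single interrupting
base terminates a tract — (TCC)6 TCT (TCC)5 is two tracts — and tracts
never contain 'N'.

Canonical motif classes use the mixed grouping conventional for summary
tables: dinucleotides fold rotations *and* reverse complements together
(AG = AG, GA, CT, TC), trinucleotides fold rotations only (so ACT and
AGT remain distinct classes). The scanner's correctness is asserted
against an independent quadratic brute-force enumerator, exactly, on
randomized sequences over repeat-prone alphabets.

Operational loci chain tracts by single linkage with a *strict*
threshold: an inter-tract gap of `merge_gap − 1` bp or less merges
(default threshold 100, so a gap of exactly 100 bp does not). The locus
is the unit relevant to marker genotyping: nearby tracts would be
amplified by one primer pair.

Density arithmetic rounds the way summary tables print: spacings to
0.1 kb, per-Mb densities and kb/cM to the nearest integer (half-up, not
banker's rounding). The loci-per-cM extrapolation is
`(loci / analyzed bp) × (genome size / map length)`; for the published
inputs (144 loci, 708,363 bp, 206 Mb, 424 cM) this yields ≈ 98.8 — the
formula value is reported as computed.

## Homology-based gene sites

Hits are filtered at the relaxed cutoff (E ≤ 1e−5, default); a site is
tiered *strict* when its best hit clears the conservative cutoff
(E ≤ 1e−10). Same-subject, same-strand hits chain into one site when
their query gap is ≤ `max_chain_gap` (default 2 kb: comfortably above
the largest observed intron, ~0.93 kb, and below typical gene spacing).
Chains from different subjects merge when they overlap by ≥ 50% of the
shorter chain on the same strand, so paralogous database subjects
hitting one physical site do not double-count it. Consequences of these
explicit rules: two same-subject gene copies closer than
`max_chain_gap` would chain into one site, which is why the synthetic
generator places tandem duplicates slightly beyond that distance; with
real data the knob can be lowered when tandem arrays are expected.

Start/stop codon inference anchors on the outermost supporting hits.
The stop codon is the first in-frame TAA/TAG/TGA at or 3′ of the
homology region's 3′ end; the start codon is the 5′-most in-frame ATG
at or 5′ of the region's 5′ end reachable without crossing an in-frame
stop. When top-tier EST evidence spans a boundary, the outward scan is
bounded by the EST extent (the transcript cannot extend past its
evidence); the scan also stops at the insert edge or at a contig gap,
leaving the codon undetermined — with a `contig_break` flag when the
site itself crosses a gap sentinel.

Truncation flags: `artifactual_5p`/`artifactual_3p` when the
transcript-orientation 5′/3′ edge of a site lies within
`boundary_margin` (default 50 bp — a judgment call; the boundary itself
is the cause, no distance is canonical) of an insert end;
`biological` when the predicted protein is < 70% of its homolog's
length (`biological_truncation_ratio`; "substantial shortening" is not
a printed number) and no artifact explains it.

Categories are description-driven and configurable: a TE keyword list
(reverse transcriptase, transposase, polyprotein, retrotransposon,
retroelement, transposon, gag, pol protein) marks `te_related`;
"unknown protein"/"hypothetical" marks `unknown`; a probe pattern match
at ≥ 98% nucleotide identity marks `targeted`.

Tandem duplication reporting pairs non-overlapping sites with the same
best subject (or configured family) separated by at most
`max_intervening` sites, classifying orientation by strand pattern:
same strand = head-to-tail; leftmost on minus = head-to-head
(divergent); leftmost on plus = tail-to-tail (convergent).

## EST support and gene models

Tiering: top at ≥ 95% identity, second in [85, 95), else unclassified —
a partition, asserted as such (95.00 is top; 94.999 is second).

Coverage is judged at the *transcript* level: a spliced EST represents
its transcript across its whole genomic envelope, because its internal
gaps are spliced introns, not missing data. A gene's coding extent is
`complete` when the union of top-tier EST envelopes covers every base
of it (several ESTs may tile it), `partial` on any overlap, `none`
otherwise. An interval-level rule ("segments must cover every base")
would make completeness unattainable for any intron-containing gene;
the envelope rule is the semantics under which multi-intron genes can
be modeled at all. Exon/intron structure still comes only from the
segments: exons are the merged union of top-tier segments clipped to
the codon-to-codon span, introns are the gaps between them, and an EST
whose own internal gap contradicts the pooled intron set raises a
splice-conflict error rather than being silently resolved — such cases
need manual review. Model construction refuses (errors, never guesses)
without complete coverage or determined codons.

EST-only sites: top-tier ESTs overlapping no homology site and no
prediction define new sites (category `est_only`), clustered by
overlap; sites at insert boundaries are flagged artifactual. EST-only
sites count as support in reconciliation but are excluded from gene
counts in density arithmetic and from merger tallies.

## Prediction reconciliation

Support = same-strand overlap of ≥ 1 bp between a predicted gene and a
site (the most permissive reading; a config knob). Per prediction:
`unsupported` (no site), `merger` (≥ 2 merger-eligible sites under one
prediction; TE-related sites are not tallied by default, EST-only
never), `split` (its single site carries ≥ 2 predictions), else
`simple`; merger takes precedence over split so merger counts are
unambiguous. Splits are counted per carved site. Codon validation is
exact coordinate equality (tolerance knob defaulting to 0) counted per
*site*, so a split cannot double-count a codon; sites with undetermined
codons contribute nothing.

## Microsynteny

Reference gene order is inferred from AGI-style locus codes at their
nominal step of 10 (no download needed); a supplied order table
overrides it. Defaults `max_step = 3` and `max_intervening = 2` admit
the classic near-adjacency cases (the largest step in the reference
configurations is 3, e.g. At1g27880 → At1g27850) while staying local.
A pair is `colinear` iff nothing intervenes on the insert and the
reference step is exactly 1; `conserved_microsynteny` iff the step is
within bounds and either something intervenes or the step exceeds 1.
Adjacent sites sharing one locus are a tandem array, not synteny, and
are skipped; sites in multigene-family clusters (several sites sharing
a best locus, as NBS-LRR clusters do) are annotated `family_cluster`
because their apparent colinearity is expected of proximal family
members rather than evidence of conserved order. Detection is symmetric
in scan direction, and raising either bound never removes a pair.

## Synthetic data generator

The generator's defaults are the study conditions: 20 inserts of
29–45 kb; ~6.6 genes per insert (one per ~5.9 kb at the mean insert
length) with 0–9 introns (Poisson mean 2.87) of 84–933 bp; ~8 SSR
tracts per insert (one per ~4.5 kb) drawn from the observed motif-class
spectrum with repeat counts in [5, 38] and ~9% of loci planted as
two-tract clusters < 100 bp apart; TE-keyword sites at 0.65 per insert;
35% of inserts split into 2–3 contigs (2 vs 3 in the observed 2:5
ratio); 25% of targeted genes tandemly duplicated; EST coverage classes
at the observed complete/partial/none proportions (15/40/76 of 131)
with top-tier identities in [95, 100) and second-tier in [85, 95);
about 0.4 EST-only loci per insert; ~6% of gene sites admitted only at
the relaxed E-value tier. Where the source material states no value
(exon codon counts 30–100, EST-only locus length 400–800 bp, spurious
prediction length 300–900 bp, per-model corruption rates), values were
chosen once as field-plausible and are configuration, not code.

Constructions that make recovery exact rather than statistical:

* every planted ORF starts with ATG, ends with a stop codon, and has an
  in-frame stop *guard* immediately 5′ of its ATG, so the outward codon
  scan terminates at the planted boundaries;
* homology hits cover each coding exon exactly, omitting the stop codon
  (a protein alignment ends at the last sense codon);
* background sequence is scrubbed: any accidental tract meeting the
  scan threshold is broken by a point substitution (never touching
  planted tracts, their one-base flank guards, or the planted
  guard/start/stop codons), and each planted tract's flanking bases are
  set to break unit-phase extension, so the scanner's maximal tracts
  equal the planted set exactly;
* tandem duplicates are separated by slightly more than the hit-chaining
  gap so the two copies resolve as two sites;
* prediction corruption (merge of true neighbors, split at an intron
  boundary, miss, spurious in feature-free background, ±1-codon jitter)
  is event-logged, and the expected reconciliation table is computed
  from the event log alone.

What the generator does **not** emulate: realistic nucleotide
composition or codon bias, TE sequence structure (TE sites are ordinary
ORFs with TE-keyword descriptions), sequencing error, imperfect or
compound SSRs, UTRs (the homology, EST, and prediction extents all
derive from the CDS), splice-site motifs, and EST identity as an actual
alignment property (identity is a label, not a simulated divergence).
Passing the recovery suite therefore demonstrates that the pipeline's
logic is exact under its stated rules — not that those rules are robust
to noisy coordinates, partial homology, or ambiguous splicing in real
data, where the conservative error surfaces (splice conflicts,
undetermined codons) are expected to fire more often.

## Problem sizes and determinism

The test suite and the acceptance script run the full 20-insert study
(~700 kb of sequence, 6 prediction tracks) end to end; generation plus
annotation takes a few seconds on one CPU. All randomness flows from a
single integer seed through one `numpy` generator; identical seed and
configuration give byte-identical sequences, files, and reports, and
the report bundle is idempotent (re-running on the same inputs
reproduces identical bytes).

## Known limitations

* Hit chaining cannot separate same-subject gene copies closer than
  `max_chain_gap`, and conversely cannot join exons of one gene farther
  apart than it; the default (2 kb) is a compromise tuned to compact
  plant genomes.
* Start-codon choice prefers the longest open upstream stretch; a
  genuine internal ATG start with a long open 5′ extension would be
  called upstream of the truth.
* The per-cM extrapolation treats the genetic map as uniform; real
  recombination landscapes are not, so loci-per-cM is a genome-wide
  average only.
* The reconciliation's 1 bp support threshold is deliberately
  permissive; a prediction sharing a single base with a site counts as
  supported.
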