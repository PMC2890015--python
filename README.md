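# fosannot

Gene-neighborhood annotation of fosmid-scale genomic inserts, built
around the targeted-fosmid survey of the diploid strawberry *Fragaria
vesca* genome (20 inserts, 708,363 bp, GenBank EU024823–EU024871). The
package is for genome researchers who have per-insert evidence files —
protein-homology (blastx-style) hit tables, ab initio gene-prediction
tracks, and spliced EST alignments — and want a reproducible, testable
pipeline for the annotation arithmetic that is usually done by hand.

## What it computes

* **SSR scanning** — every maximal, uninterrupted tract of a primitive
  repeat unit (unit length 2–5 bp, ≥ 5 repeats; SSRIT-style semantics in
  which `(TCC)6 TCT (TCC)5` is two SSRs), canonical motif classes
  (AG = AG/GA/CT/TC for dinucleotides, rotation-only for trinucleotides),
  and *operational SSR loci*: tracts < 100 bp apart chained into the unit
  a single primer pair would genotype.
* **Homology-based gene sites** — hits filtered at a relaxed cutoff
  E ≤ 1e−5, chained per subject/strand, merged across paralogous
  subjects, tiered *strict* when the best hit clears E ≤ 1e−10;
  categories (targeted / known / unknown / TE-related) from the best
  subject description and probe identity; start/stop codons by scanning
  the reading frame outward from the homology region (stop = first
  in-frame terminator 3′ of the region; start = 5′-most in-frame ATG with
  an open stretch into the region); truncation flags for insert-boundary,
  contig-gap, and biological (pseudogene-like) shortening; tandem
  duplications with head-to-tail / head-to-head / tail-to-tail
  orientation.
* **EST support** — top-tier (≥ 95% identity) vs second-tier (85–94.999%)
  matches; per-gene coverage (complete / partial / none) at the
  transcript level; EST-only gene sites where transcription evidence has
  no protein or prediction support; spliced gene models (exons = merged
  EST segments, introns = the gaps) with intron statistics.
* **Prediction reconciliation** — per ab initio model: unsupported
  predictions, gene mergers (and genes merged), splits, and start/stop
  codons validated by exact agreement with the homology-inferred codon.
* **Microsynteny** — colinear and conserved-microsyntenic gene pairs
  against a reference gene order derived from AGI-style locus codes
  (e.g. At3g54340, nominal step 10) or a supplied order table.
* **Density arithmetic** — insert totals, one gene per *x* kb, SSRs per
  Mb, kb/cM, and marker loci per cM extrapolations.
* **Synthetic data** — a seed-reproducible generator that plants all of
  the above with full ground truth (including corrupted prediction
  tracks), so every stage is tested against exact expected output.

## Worked example

Generate a 20-insert synthetic study and run the full pipeline:

```
fosannot simulate --seed 1 --n-inserts 20 --out demo/data
fosannot run --config demo/data/pipeline.yaml --out demo/out
```

which prints

```
{
  "inserts": 20,
  "gene_sites": 138,
  "ssr_tracts": 158,
  "ssr_loci": 148,
  "errors": {}
}
```

meaning: 138 homology-supported gene sites were inferred across the 20
inserts, and 158 perfect SSR tracts merged into 148 operational marker
loci. `demo/out/` then holds the insert inventory, the per-model
reconciliation table, SSR class and density tables, gene models, a
synteny table, and one five-panel neighborhood summary per insert
(predictions / homology / ESTs / annotated sites / SSRs).

The same stages are available as library calls; for example the
headline density arithmetic of the published insert set:

```python
>>> from fosannot.densities import gene_spacing_kb
>>> from fosannot.study import STUDY_CONTEXT
>>> gene_spacing_kb(120, STUDY_CONTEXT.total_analyzed_bp)   # 120 non-TE gene sites
5.9
>>> from fosannot.ssr import kb_per_cM
>>> kb_per_cM(STUDY_CONTEXT)                                # 206 Mb / 424 cM
486
```

— one protein-coding gene site per 5.9 kb, and 486 kb of physical
distance per centimorgan of genetic map.

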