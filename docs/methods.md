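# Methods

This note records the models and procedures genoweave implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical conventions chosen where a design was open.

## Coordinates and formats

Internally every interval is 0-based half-open on the forward strand; GFF3
I/O converts to and from 1-based inclusive (the conversion `[a,b] ↔
[a−1,b)` is a bijection and is property-tested as a round trip). CDS
segments are stored in ascending coordinate order for both strands; strand
is applied only at sequence extraction, where the ascending concatenation
is reverse-complemented for minus-strand genes. Gene models are CDS-only:
one model per mRNA, no UTRs, and GFF3 feature types other than
gene/mRNA/CDS are ignored. Multiple mRNAs of a gene are separate models
(isoforms); locus logic operates at the model level. `N` bases are legal in
genomes; any codon containing one is excluded from all composition counts,
because including half-defined codons would bias GC3 toward whatever
convention filled the gap.

## Locus integration

Overlap between two same-strand models is computed on *genomic spans*
(introns included), as a fraction of the shorter span. Span overlap rather
than summed-exon overlap is the default because co-location of gene
structures, not exon identity, is what defines a shared locus; exon-level
agreement is far stricter and would split loci whose predictions disagree
on intron boundaries. Summed-exon overlap (against the shorter CDS) is
available as `overlap_mode="exon"` but off by default. Loci are connected
components of the thresholded overlap graph (single linkage), found with a
per-scaffold sort-and-sweep plus union–find (any positive exon overlap
implies span overlap, so the same candidate-pair sweep serves both modes);
tests verify exact agreement with an all-pairs connected-components
oracle.

The threshold sweep runs over 0.60–0.95 in 0.05 steps. The knee is
formalized as: take forward differences of the single-model:multi-model
locus ratio between consecutive thresholds, restricted to thresholds where
the ratio is defined (at least one multi-model locus); select the threshold
just *before* the largest positive difference, ties toward the smaller
threshold. When no positive finite difference exists (e.g. identical
prediction sets, where every locus is multi-model at every threshold) the
selection is undefined and the driver falls back to the conventional 85%.
Restricting to finite ratios matters: when every locus becomes
single-model at the top threshold the ratio diverges, and the divergent
step carries no information about where the ratio *started* climbing.

Evidence filtering (RefSeq-style identity ≥ 50, bit score ≥ 100, query and
subject coverage ≥ 80; transcriptome identity strictly > 90) requires both
evidence classes by default; union mode is available. Filtering precedes
clustering, so locus membership is computed over the supported models.
Representative selection removes hits with E > 1e-10 and hits whose
description contains (case-insensitive substring) any of: predicted,
putative, hypothetical, unnamed, uncharacterized; the member with the
lowest surviving E-value wins, ties broken by higher bit score then model
id, so output is deterministic. Loci with no surviving hit are discarded.
Scaffolds whose best taxonomic hit is bacterial or plastid *and* that lack
support at all three levels (sister genome, transcriptome, newer build)
are removed last.

## Composition statistics

* `GC3 = (C3+G3) / n_codons` over complete N-free codons; `CG3-skew =
  (C3−G3)/(C3+G3)`, undefined (reported as missing, never 0) when
  `C3+G3 = 0`. The sign convention puts cytosine excess positive.
* `ρ_CG = f_CG/(f_C·f_G)` with overlapping dinucleotide counts over
  `len−1` windows and mononucleotide frequencies over all bases; undefined
  when `f_C·f_G = 0`.
* Decile classification sizes are `round(0.1·N)` half-up — so a
  26,059-gene catalogue yields rich/poor sets of exactly 2,606 — with
  floor/ceil available; boundary ties break by gene id to keep the sizes
  exact. Reported thresholds are the min GC3 of the rich set and max GC3
  of the poor set.
* Positional gradients report the raw per-codon-index mean (no smoothing,
  no padding): at index k the GC3 curve averages over genes with ≥ k
  counted codons, the skew curve over genes whose k-th third base is C or
  G. The n-weighted mean of the GC3 curve therefore equals the pooled GC3
  of all counted codons (tested as a conservation check).
* Nucleotide models: multinomial (4 probabilities), position-specific
  multinomial (3×4) and a first-order three-periodic Markov chain (3×4×4),
  all maximum-likelihood with no smoothing by default. The Markov matrices
  are indexed by the codon position of the *current* base; transitions
  cross codon boundaries (position-1 bases condition on the previous
  codon's third base). Contexts never seen in training get a uniform row.
  Sampling and log-likelihood are provided; the first base of a sequence
  is drawn/scored uniformly, since it carries no transition information.
* The category goodness-of-fit test: for category i with background share
  `b_i/B`, the expected rich/poor cells are `|rich|·b_i/B` and
  `|poor|·b_i/B`; the statistic is Pearson's chi-squared over those two
  cells with df = 1, upper-tail p from `scipy.stats.chi2`. Tests check it
  against an independent incomplete-gamma evaluation to 1e-9 relative.

## Intronless genes and sharing

"Full-length ORF" is formalized as: starts with ATG, ends with TAA/TAG/TGA,
length ≡ 0 (mod 3), no internal in-frame stop. A kingdom or eukaryotic
group counts as hit at E ≤ 1e-5 (inclusive, conventional BLAST usage);
group hits imply the eukaryote domain. Sharing categories partition the IG
set: all-three-domains, eukaryote+bacteria, eukaryote+archaea,
eukaryote-only (broken down into all-groups, viridiplantae-only, pairwise
group combinations, or eukaryote-other when no named group is hit), and
ORFan. The ortholog-intronless fraction defaults to the
IG-with-orthologs denominator; the all-IG denominator is available since
published fractions do not always state which was used.

## Resistance genes

The rule table (a gene must contain all domains of its class) is applied
in priority order TNL > CNL > RLK > RLP > Mlo-like > Kinase, so a gene with
both TIR and CC resolves to TNL — TIR is the discriminator between the two
NBS-LRR classes. Kinase requires STK *without* TM/LRR/NBS so that
receptor kinases and NBS-kinases are not double-counted. Pto-style motif
checks (activation domain, autophosphorylation sites, P+1 loop,
N-myristoylation) require curated alignments and are out of computational
scope; the Kinase class here is domain-level only.

CNL clusters: adjacent CNL genes chain when < 200 kb apart (gene start to
gene start by default; end-to-start mode available, since the measuring
points are a convention) with ≤ 8 intervening non-NBS-LRR genes — genes
carrying NBS or LRR do not count against the budget. Clusters are maximal
runs of ≥ 2; because distance and intervening counts are monotone along
the gene order, adjacent-pair chaining equals the all-pairs transitive
closure (verified against a brute-force oracle).

## Synthetic-data generator

The generator emulates, at desk scale, the stated shape of a two-pipeline
plant-genome annotation project. Defaults: 10 scaffolds × 60 kb, background
GC 0.37 (typical of a palm genome), 100 loci, exon counts distributed with
14% mono-exonic and 16% two-exon genes (mean ≈ 4.4), CDS lengths uniform
on 300–2,166 nt (mean ≈ 1,233 nt, matching reported mean CDS lengths),
introns 50–400 nt, per-gene GC3 targets Normal(0.53, 0.13) clipped to
[0,1] with an optional linear per-codon gradient centred mid-gene.
Pipeline emulation drops each true model with probability 0.15, jitters
gene termini with rounded Gaussian noise (sd 10 nt) and splits models with
probability 0.02 — the two mock pipelines thus recover overlapping but
unequal subsets, like real ab-initio vs transcriptome-trained predictors.
Spurious (unmatched) predictions are off by default but available, so
false-merge behaviour can be probed. Every generator draws from a named
CRC32-keyed sub-stream of one seed: adding a generator never shifts
existing streams, and every output is a pure function of the config.

Planted genes are valid ORFs built codon-by-codon: the third base is G/C
with the gene's target probability (so a target of 1.0 gives literally
all-GC third positions), first two bases are uniform with stop codons
rejected by resampling, ATG and a uniform stop cap the ends. Exon
boundaries fall on codon boundaries — a simplification; real introns split
codons. What the generator does *not* emulate: splice-site motifs, repeat
families, isoforms, sequencing error, and — importantly — the fact that
real gene predictors always emit in-frame ORFs: the boundary jitter here
breaks reading frames, so perturbed pipeline models generally fail the
full-ORF test. Recovery of intronless status is therefore validated on the
planted truth models, and a green intronless test establishes correctness
of the ORF logic, not robustness to annotation error. Likewise the
Gaussian-jitter error model is a modelling choice, not an observed
distribution of pipeline disagreements.

Domain planting assigns each selected gene exactly its class architecture
(CNL = CC+NBS+LRR, etc.), Mlo-like genes get 6 or 7 TM helices, all other
genes at most an OTHER domain — so classifier recovery on synthetic
fixtures is exact by construction, and the test establishes the rule
table, not tolerance to missing domain calls.

## Numerical conventions and degenerate inputs

Empty FASTA and empty model lists raise; a header-only GFF3 reads as an
empty model set (needed for the round-trip identity on the empty set).
Invalid evidence rows (out-of-bounds identity/coverage) are dropped with a
logged row number; structurally broken files (missing columns, non-numeric
E-values) raise. Unknown domain labels map to OTHER with a warning.
Undefined ratios (CG3 skew with no C3/G3, ρ_CG with no C or G, sweep
selection with no knee, ortholog fraction with no orthologs) are reported
as missing values, never coerced to 0. All tie-breaks (representative
selection, decile boundaries, locus ids) are by explicit deterministic
keys, so identical inputs give byte-identical outputs.

## Known limitations

* Evidence thresholds are fixed to the published conventions (identity
  ≥ 50, score ≥ 100, coverage ≥ 80, mRNA > 90%, E ≤ 1e-10/1e-5); they are
  arguments, not config files.
* The knee rule is a reproducible proxy for what is, in practice, a visual
  judgement on the sweep curve; on data whose overlap distribution is not
  concentrated the selection can be undefined, and the driver then uses
  85%.
* The intronless analysis assumes the annotation's CDS coordinates are
  frame-accurate (true of real predictors, not of the jittered synthetic
  pipelines).
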