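# Methods

This note documents the models, statistics and numerical choices behind
lncforge, and what the synthetic-data generator does and does not emulate.

## The discovery cascade

Input is an "assembled" transcriptome (GTF of exon models) plus a known
annotation, a genome, and an FPKM matrix with sample-group labels.  The
cascade applies five filters in a fixed order, and every transcript is
attributed its *first* failing stage:

1. **Known-annotation subtraction.**  A transcript is removed when any of
   its exons shares ≥ 1 bp with any exon of the known annotation, on either
   strand.  Strand-blind subtraction is deliberate: antisense transcripts
   that *overlap* a gene exonically are treated as not novel, while
   antisense transcripts merely *near* a gene survive and can later be
   called divergent.
2. **Coding potential.**  A logistic score in [0, 1] over three features —
   longest-ORF length, Fickett TESTCODE statistic, hexamer usage bias —
   with decision threshold 0.364; scores at or above the threshold are
   called coding (the conservative choice for lncRNA discovery).
3. **Length** ≥ 200 nt of exonic (spliced) sequence.
4. **Exon count** ≥ 2 (mono-exonic models are likely assembly artifacts,
   unspliced pre-mRNA or gene extensions).
5. **Expression**: FPKM strictly > 0.1 in at least two samples of the
   designated group (tumor by default).  The comparison is strict at the
   boundary; a transcript at exactly 0.1 everywhere is not expressed.

Retained transcripts are grouped into loci by single-linkage: same
chromosome and strand, ≥ 1 bp exonic overlap, transitively closed.  Locus
ids are assigned in (chromosome, leftmost start, strand) order, making the
assignment deterministic.

**Divergent lncRNAs** are retained transcripts whose first exon (5′-most in
transcript orientation) lies within 2,000 bp of the nearest protein-coding
gene body and whose strand is antisense to that gene.  Distance is measured
exon-to-gene-body; ties between equally near genes break toward the
smaller gene start.

## Coding-potential model

* **ORF definition**: ATG-initiated, in-frame stop-terminated, stop
  included in the length, forward strand of the spliced transcript only,
  longest across the three frames with ties to the leftmost start.
* **Fickett TESTCODE**: the classical 8-parameter statistic combining, for
  each base, a position parameter (max/min+1 of the three codon-phase
  counts) and a content parameter (base fraction), each mapped through the
  published 10-interval lookup tables and weighted.  The tables are
  embedded as constants; a unit test checks them against an independent
  straight-line re-implementation.
* **Hexamer bias**: mean of log(f_coding/f_noncoding) over frame-0 hexamers
  of the longest ORF, stepping by 3; 0 when there is no ORF of ≥ 6 nt.
  Hexamer frequencies are estimated from the two training corpora with +1
  pseudocounts over all 4,096 hexamers.
* **Logistic fit**: features are standardized and the weights are fit with
  an L2-regularized maximum-likelihood logistic regression (scikit-learn,
  C = 1).  The ridge term matters: synthetic corpora are linearly
  separable, and the unpenalized MLE diverges; regularization keeps the
  weights finite without changing the ranking or the thresholded decisions.
* Threshold default 0.364, with scores ≥ threshold called coding.

## Expression statistics

* **Class partition**: per group (tumor / normal / cell line), a feature is
  expressed iff FPKM > 0.1 in ≥ 2 samples of that group; its class is the
  set of groups where it is expressed (tumor-only, tumor+cell_line, …).
* **Outliers**: a (feature, sample) cell is flagged when its FPKM is at
  least k = 10 population SDs (ddof = 0) above the feature's mean across
  the group's samples, the cell itself included in the statistics.  A
  consequence worth knowing: with the cell included, a z-score of k is
  attainable only when the group has more than k² + 1 samples, so 10-SD
  outliers require > 101 samples — the generator enforces this.
* **Differential expression**: Welch (unequal-variance) t-test per feature
  on raw FPKM between ABC- and GCB-labelled tumors, with
  Benjamini–Hochberg adjustment across all tested features and
  significance at q < 0.05.  Zero-variance features with equal means are
  defined to give t = 0, p = 1.  A `log2_offset` option tests
  log2(FPKM + offset) instead; raw scale is the default.
* **Co-expression**: Spearman rho (average ranks) between each lncRNA and
  each protein-coding gene across tumor samples, p-values from the
  t-approximation, one joint BH adjustment over all pairs, edges kept at
  q < 0.2.  Constant vectors are skipped with a warning.
* **Enrichment**: hypergeometric upper-tail tests; Bonferroni across gene
  sets for pathway enrichment, a single hypergeometric for
  knockdown-concordance, whose universe is an explicit required input.

## Genomic context

* **TE summary**: per-transcript base coverage is computed on the *union*
  of TE intervals (overlapping TE copies never double-count);
  `te_derived_percent` = 100 × covered exonic bases / exonic length.
  Any-overlap flags are evaluated per (exon, TE element) pair at 1 bp and
  10 bp thresholds.  First/last exons follow transcript orientation.
  Pre-filtering of repeat classes (e.g. removing low-complexity and
  satellite repeats) is the caller's responsibility; a predicate hook is
  provided.
* **First/last-exon chi-square**: a pooled 2 × 2 table (exon position ×
  TE overlap) over multi-exon transcripts, Pearson chi-square without
  continuity correction; a zero margin returns p = 1 with a warning.
* **Permutation enrichment**: the observed statistic is the number of
  target intervals (enhancers) overlapping ≥ 1 query locus.  Each of N
  shuffles re-places every target uniformly at random on its own
  chromosome, preserving length (genome-wide placement, chromosome drawn
  proportional to length, is available behind a flag); overlaps among
  shuffled targets are allowed.  The empirical p uses the add-one
  estimator (1 + #{null ≥ observed})/(1 + N), so p ∈ (0, 1] and the floor
  at N = 1000 is 1/1001 ≈ 0.001.
* **TSS metaprofile**: strand-oriented mean coverage at offsets −w..+w
  around each transcript's 5′ end; minus-strand windows are reversed so
  positive offsets are downstream.  Out-of-bounds positions contribute
  zeros and stay in the denominator, keeping the per-offset sample size
  constant.

## Mutation and structure

* **Calling**: at each pileup site, coverage is the sum of the four base
  counts; every non-reference base with count/coverage ≥ 0.2 at coverage
  ≥ 8 yields one variant record (both thresholds inclusive; multi-allelic
  sites yield one record per alternate base).
* **Filtering**: keep variants that are exonic in a retained lncRNA, not
  known polymorphisms, and absent from normal samples.
* **Hotspots**: a 100-bp window slid by 1 bp qualifies at ≥ 6 variant
  occurrences (multiplicity across samples counts); strictly overlapping
  qualifying windows merge into maximal hotspot intervals whose count is
  the maximum single-window count inside the run.  Windows are genomic,
  not spliced-transcript, coordinates.
* **Folding**: the MFE is minimized over all nested (pseudoknot-free)
  pairings with hairpin loops of > 3 unpaired bases, under a pure
  pair-energy model: GC = −3, AU = −2, GU = −1 kcal/mol, no stacking or
  loop terms, T treated as U.  This is a deliberate design choice: the
  stabilization analysis needs a consistent, comparable energy, not
  thermodynamic fidelity, and the pair-energy DP is exactly verifiable
  against exhaustive enumeration of structures (which a nearest-neighbor
  model is not).  The DP is O(n³) (numba-compiled); traceback ties break
  deterministically (pairing preferred over leaving a base unpaired, then
  the smallest partner).  Energies are integer multiples of 1 kcal/mol, so
  exact zero deltas are meaningful.
* **Delta-MFE**: each variant is applied alone, in genomic space, to one
  deterministic host transcript (the lexicographically smallest id whose
  exons contain it); delta = MFE(native) − MFE(mutated), positive =
  stabilized.  Novel and control (known-polymorphism) delta samples are
  compared with a two-sided Wilcoxon rank-sum test: exact enumeration for
  ≤ 20 observations per group without ties, otherwise the normal
  approximation with average-rank ties and continuity correction.

## The synthetic-data generator

The generator emulates the statistical structure of a post-assembly lncRNA
study at desk scale; one integer seed drives a hierarchy of child streams
(one per stage), so the fixtures are bit-reproducible and adding a stage
does not perturb earlier draws.

* **Scale**: 4 chromosomes × 900 kb of i.i.d. background sequence;
  ~500 assembled transcripts (120 true lncRNA loci plus isoforms, and four
  decoy classes of ~60–80 each, plus re-assembled copies of known genes);
  the study-sized sample design of 116 tumors (35 ABC / 69 GCB /
  12 unclassified), 8 normals and 30 cell lines.  lncRNA exonic lengths
  are 250–450 nt so that the O(n³) folding of hundreds of variants stays
  in seconds.
* **Sequence classes**: coding-like sequence is a planted ≥ 300 nt ORF of
  codons biased toward G/C third positions (strength `hexamer_divergence`)
  inside random UTRs; non-coding sequence is uniform-random with every ORF
  ≥ 150 nt disrupted by overwriting its start codon with a stop (this
  strictly reduces the ATG count, so disruption always terminates).
  Training corpora for the coding-potential model are drawn from the same
  two sequence models.
* **Decoys** each violate exactly one cascade filter: coding decoys carry
  a long biased ORF; short decoys are < 200 nt; mono-exonic decoys have
  one exon; low-expression decoys exceed 0.1 FPKM in at most one tumor.
  Re-assembled known-gene copies exercise the subtraction stage.
* **Divergent pairs**: a stated fraction of true lncRNAs is placed
  head-to-head with a partner gene at a 200–1,500 bp gap, antisense;
  every other feature keeps > 2 kb of clearance, so the planted pairs are
  exactly the geometrically divergent set.  Isoforms are built by dropping
  terminal exons (a sub-sequence cannot contain an ORF absent from its
  parent, so isoforms stay non-coding); isoforms of divergent lncRNAs only
  drop the 3′ exon so their first exon — and divergent status — is
  preserved.
* **Expression**: expressed (feature, group) blocks draw
  0.12 + LogNormal(0, 1) FPKM truncated at e² ≈ 7.4; silent blocks draw
  Uniform(0, 0.08).  The truncation is what makes exact outlier recovery
  possible: with heavy untruncated tails a natural draw can approach the
  flagging threshold.  Subtype effects multiply ABC (or GCB) tumor columns
  by `de_effect_size` (default 4).  Outlier cells are planted at
  mean + c·SD with c = 1.1·k·√(n/(n−1−k²)) — the minimal offset that still
  registers at k SDs once the planted cell inflates the group statistics —
  and the generator refuses configurations with n_tumor ≤ k² + 1 where no
  such cell exists.  Planted co-expression pairs share a log-scale latent
  factor giving Spearman rho ≈ 0.8.
* **TE architecture**: each true lncRNA receives independent last-exon and
  first-exon TE insertions with marginal probabilities presence·bias and
  presence·(1−bias).  Independence (rather than one last-vs-first coin per
  transcript) keeps the pooled 2 × 2 chi-square null exactly valid at
  bias = 0.5, which the calibration tests rely on.  Uniform background TEs
  are added on top.
* **Enhancers**: a stated fraction is placed to overlap lncRNA locus
  spans, the rest uniformly with chromosome drawn proportional to length —
  the same law as the shuffle null, so with overlap fraction 0 the
  permutation p-value is exactly uniform by exchangeability.
* **Variants**: stabilizing variants are found by brute-force search over
  random single substitutions, accepting the first whose host-transcript
  MFE strictly decreases (an operational definition against the package's
  own energy model, not a thermodynamic claim); neutral variants leave the
  MFE exactly unchanged and carry the known-polymorphism flag, playing the
  dbSNP-control role.  Additional planted classes (normal-sample
  artifacts, intronic variants, sub-threshold pileup sites, and clustered
  hotspot variants) give every filter branch and the hotspot scan planted
  positives.  Pileup summaries are emitted such that threshold calling
  reproduces the planted variant table exactly.
* **Self-audit**: `audit_dataset` re-verifies every planted label by
  construction (decoy properties, divergent geometry, expression classes,
  outlier recovery, fold deltas on a capped subsample, pileup/call
  equivalence) and returns a list of violations; tests require it empty.

### What the generator does *not* emulate

Real read-level noise, assembly fragmentation, FPKM estimation error,
genome repeat structure, realistic TE families, linkage between variants,
and expression correlation structure beyond the planted pairs.  Passing
tests therefore demonstrate that the *pipeline logic and statistics* are
correct and calibrated under controlled conditions — not that the
thresholds would achieve the same precision/recall on real RNA-seq data.

## Numerical choices and edge cases

* All internal coordinates are 0-based half-open; GTF and variant tables
  are converted at the file boundary only.  Chromosome names match by
  exact string comparison.
* Empirical permutation p-values use the add-one estimator and can never
  be 0.  BH q-values are monotone in the p-ranking by construction.
* Welch t on two zero-variance groups: p = 1 at equal means, p = 0
  otherwise.  Wilcoxon on two identical constant samples: p = 1.
* Degenerate chi-square tables (zero margin) return p = 1 with a warning.
* Fold input must be pure A/C/G/T/U; the ORF scanner additionally accepts
  N (an N never matches a start or stop codon).

## Problem sizes and runtimes

The default fixture (seed-fixed) generates in ~45 s, the full pipeline run
on it takes ~25 s, and the complete test suite runs in ~2–3 minutes on one
CPU; `scripts/acceptance.py` completes in ~1.5 minutes.  The dominant cost
is the O(n³) folding of ~500 native and mutated transcript sequences.
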