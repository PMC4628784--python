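# lncforge

**De novo lncRNA discovery and characterization from assembled
transcriptomes.**

Tumor RNA-seq cohorts contain thousands of transcripts that no annotation
knows about, many of them long non-coding RNAs (lncRNAs) with potential
regulatory roles.  Deciding which assembled fragments are credible novel
lncRNAs — rather than assembly noise, unspliced pre-mRNA or unannotated
coding sequence — and then characterizing what they might do, requires a
long chain of filters and statistics that is easy to get subtly wrong.
lncforge packages that chain as a tested library plus a thin CLI, aimed at
computational biologists analyzing bulk transcriptomes of tumors and
matched normal cells.

## What it computes

**Discovery.**  Starting from an assembled transcriptome (GTF), a known
annotation, a genome and an FPKM matrix, the filter cascade retains
transcripts that

1. share no exonic base with any known gene (either strand),
2. score below the coding-potential threshold: a logistic model
   `P(coding) = σ(β₀ + β₁·ORF + β₂·Fickett + β₃·hexamer)` with the
   conventional cutoff 0.364,
3. have spliced length ≥ 200 nt and ≥ 2 exons,
4. show FPKM > 0.1 in ≥ 2 tumor samples,

then groups them into loci (single-linkage exonic overlap) and flags
*divergent* lncRNAs — first exon within 2 kb of a protein-coding gene,
transcribed antisense to it.

**Characterization.**
Expression-class partition across tumor / normal / cell-line groups;
≥ 10 SD expression outliers; ABC-vs-GCB differential expression (Welch t,
Benjamini–Hochberg FDR < 0.05); Spearman co-expression with protein-coding
genes (joint FDR < 0.2) and hypergeometric pathway / knockdown-concordance
enrichment; transposable-element architecture (TE-derived percentage,
first-versus-last-exon chi-square); super-enhancer enrichment by
length-preserving location shuffling with the add-one empirical p,
`p = (1 + #{null ≥ obs}) / (1 + N)`; TSS coverage metaprofiles; threshold
SNV calling (coverage ≥ 8, VAF ≥ 0.2), dbSNP/normal filtering, 100-bp
mutation-hotspot scanning; and RNA-structure stabilization analysis,
`ΔMFE = MFE(native) − MFE(mutated)` under an exact nested-pairing energy
minimization, compared between variant classes by Wilcoxon rank-sum.

**Synthetic data.**  `lncforge.simulate` generates every input the
pipeline consumes — with planted ground truth (true lncRNAs, four decoy
classes each violating exactly one filter, subtype effects, outliers,
biased TE placement, enhancer overlap, structure-stabilizing and
structure-neutral variants) — so the whole chain is testable end to end
without any external data.  See `docs/methods.md` for the models and their
assumptions.

## Worked example

`examples/discover_lncrnas.py` builds a compact synthetic dataset, trains
the coding-potential model on generated corpora and runs the cascade:

```
assembled transcripts : 61
first failing stage    :
  coding          8
  length          8
  exon_count      8
  expression      6
  known_overlap   6
retained lncRNAs       : 25 in 20 loci
precision / recall     : 1.00 / 1.00
divergent lncRNAs      : 8 (planted: 8)
```

Each "first failing stage" line is one decoy class being caught by exactly
the filter it was built to violate; precision and recall of 1.00 mean the
retained set equals the planted truth.  `examples/mutation_stability.py`
shows the structure analysis on one transcript:

```
TLNC_0001 (260 nt), variant chrS1:4797 A>G
  native  MFE  -240.0 kcal/mol  ..(..(.(((((.((....))))(((((((((((((((((...))).))((.(.(((.((...
  mutated MFE  -241.0 kcal/mol  (((((((((.(.(....))).((((.((((((.(.(((((...))).)))).).))(.((...
  delta       +1.0 kcal/mol (positive = stabilized)

stabilizing vs neutral variants: n = 25 vs 25
  median delta   : +1.0 vs +0.0 kcal/mol
  rank-sum p     : 3.32e-11
```

The planted stabilizing variants shift ΔMFE positive while the
polymorphism-like controls sit at zero — the stabilization signature the
mutation analysis is designed to detect.
`examples/enhancer_enrichment.py` runs the permutation test (21/60
enhancers overlap lncRNA loci versus 3.2 expected, p ≈ 0.001).

The same operations are available from the shell:

```bash
lncforge simulate --seed 7 --out fixtures/
lncforge train-model --coding fixtures/train_coding.fa \
    --noncoding fixtures/train_noncoding.fa --out model.json
lncforge discover --assembly fixtures/assembly.gtf --known fixtures/known.gtf \
    --genome fixtures/genome.fa --expr fixtures/expression.tsv \
    --groups fixtures/sample_groups.tsv --model model.json \
    --out-gtf novel.gtf --out-report report.tsv
lncforge run --config pipeline.yaml --seed 1   # full pipeline + manifest
```

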