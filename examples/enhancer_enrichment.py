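"""Permutation test: are enhancers enriched at lncRNA loci?

Places a third of the enhancers so that they overlap planted lncRNA loci
and the rest uniformly, then asks how often 1,000 length-preserving
within-chromosome shuffles of the enhancer set reach the observed overlap
count.  The add-one empirical p floors at 1/1001 when no shuffle does.
"""

from lncforge.context import shuffle_enrichment
from lncforge.simulate import SimulationConfig, simulate_dataset

config = SimulationConfig(
    seed=7, n_known_genes=10, n_true_lncrnas=30, n_coding_decoys=5,
    n_short_decoys=5, n_monoexonic_decoys=5, n_low_expression_decoys=4,
    n_reassembled_known=4, n_stabilizing_variants=5, n_neutral_variants=5,
    n_known_polymorphism_variants=2, n_normal_variants=2, n_intronic_variants=2,
    n_hotspot_clusters=1, n_subthreshold_sites=4, n_outliers=1,
    n_train_coding=60, n_train_noncoding=60,
    n_enhancers=60, enhancer_overlap_fraction=0.3, chromosome_length=500_000,
)
ds = simulate_dataset(config)
loci = [t.span for t in ds.assembly
        if ds.truth.transcript_class[t.transcript_id] == "true_lncRNA"]
result = shuffle_enrichment(loci, ds.enhancers, ds.chrom_sizes, n=1000, seed=1)

print(f"enhancers overlapping lncRNA loci : {result.observed_count} / {len(ds.enhancers)}")
print(f"mean overlap across 1,000 shuffles: {result.null_mean:.1f}")
print(f"empirical p                       : {result.empirical_p:.4g}")
# The observed count combines the planted 30% overlap with chance hits; the
# null mean estimates the chance level alone, and p < 0.001 means no shuffle
# reached the observed count.
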