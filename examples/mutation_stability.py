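"""Do planted mutations stabilize lncRNA secondary structure?

Folds one lncRNA with and without a planted stabilizing substitution
(showing the minimum free energy and dot-bracket structure of each), then
compares the delta-MFE distributions of all planted stabilizing versus
structure-neutral variants with a Wilcoxon rank-sum test.  A positive
delta = MFE(native) - MFE(mutated) means the mutation stabilizes the fold.
"""

from lncforge.folding import fold_mfe
from lncforge.mutation import apply_mutations, delta_mfe_analysis, delta_mfe_for_variants
from lncforge.simulate import SimulationConfig, simulate_dataset

config = SimulationConfig(
    seed=13, n_known_genes=8, n_true_lncrnas=15, n_coding_decoys=4,
    n_short_decoys=4, n_monoexonic_decoys=4, n_low_expression_decoys=3,
    n_reassembled_known=3, n_stabilizing_variants=25, n_neutral_variants=25,
    n_known_polymorphism_variants=3, n_normal_variants=3, n_intronic_variants=3,
    n_hotspot_clusters=1, n_subthreshold_sites=4, n_outliers=1,
    n_train_coding=60, n_train_noncoding=60, n_enhancers=10,
    chromosome_length=400_000,
)
ds = simulate_dataset(config)
hosts = [t for t in ds.assembly
         if ds.truth.transcript_class[t.transcript_id] == "true_lncRNA"
         and "_i" not in t.transcript_id]

stab_keys = set(ds.truth.variants_with_label("stabilizing"))
neut_keys = set(ds.truth.variants_with_label("neutral"))
stab = [v for v in ds.variants if (v.chrom, v.pos, v.alt, v.sample_id) in stab_keys]
neut = [v for v in ds.variants if (v.chrom, v.pos, v.alt, v.sample_id) in neut_keys]

# one transcript, before and after its first stabilizing variant
v = stab[0]
host = next(t for t in hosts if t.chrom == v.chrom
            and any(e.start <= v.pos - 1 < e.end for e in t.exons))
native, mutated = apply_mutations(host, ds.genome, [v])
fn, fm = fold_mfe(native), fold_mfe(mutated)
print(f"{host.transcript_id} ({len(native)} nt), variant {v.chrom}:{v.pos} {v.ref}>{v.alt}")
print(f"  native  MFE {fn.mfe:7.1f} kcal/mol  {fn.dot_bracket()[:60]}...")
print(f"  mutated MFE {fm.mfe:7.1f} kcal/mol  {fm.dot_bracket()[:60]}...")
print(f"  delta       {fn.mfe - fm.mfe:+.1f} kcal/mol (positive = stabilized)")

novel = delta_mfe_for_variants(hosts, ds.genome, stab)
control = delta_mfe_for_variants(hosts, ds.genome, neut)
summary, _stat, p = delta_mfe_analysis(novel, control)
print(f"\nstabilizing vs neutral variants: n = {summary['n_novel']} vs "
      f"{summary['n_control']}")
print(f"  median delta   : {summary['median_novel']:+.1f} vs "
      f"{summary['median_control']:+.1f} kcal/mol")
print(f"  rank-sum p     : {p:.3g}")
# The planted stabilizing set shifts toward positive deltas while the
# neutral (polymorphism-like) controls sit at zero, mirroring the analysis
# direction for tumor variants versus known polymorphisms.
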