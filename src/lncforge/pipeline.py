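"""End-to-end pipeline orchestration from a single configuration.

``run_pipeline`` executes discovery -> expression classification ->
differential expression -> co-expression/enrichment -> TE summary ->
enhancer permutation test -> TSS profile -> variant calling/filtering ->
hotspots -> delta-MFE, skipping any stage whose inputs are absent (each
skip is logged), and writes a manifest with per-stage output checksums and
wall-clock times.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field, fields

import pandas as pd
import yaml

from . import context as ctx
from . import discovery as disc
from . import expression as exprmod
from . import io as lio
from . import mutation as mut
from .coding import CodingPotentialModel, train_coding_model
from .intervals import spliced_sequence

log = logging.getLogger("lncforge")

_INPUT_KEYS = (
    "assembly_gtf", "known_gtf", "genome_fasta", "expression_tsv", "groups_tsv",
    "coding_train_fasta", "noncoding_train_fasta", "model_json", "te_bed",
    "enhancer_bed", "chrom_sizes", "coverage_bedgraph", "pileup_tsv",
    "dbsnp_tsv", "normals_tsv", "gene_sets_gmt",
)


@dataclass
class PipelineConfig:
    """Paths plus every stage threshold, with the study's default values."""

    out_dir: str = "lncforge_out"
    seed: int | None = None
    # input paths (absent/None inputs skip their stages)
    assembly_gtf: str | None = None
    known_gtf: str | None = None
    genome_fasta: str | None = None
    expression_tsv: str | None = None
    groups_tsv: str | None = None
    coding_train_fasta: str | None = None
    noncoding_train_fasta: str | None = None
    model_json: str | None = None
    te_bed: str | None = None
    enhancer_bed: str | None = None
    chrom_sizes: str | None = None
    coverage_bedgraph: str | None = None
    pileup_tsv: str | None = None
    dbsnp_tsv: str | None = None
    normals_tsv: str | None = None
    gene_sets_gmt: str | None = None
    # thresholds
    min_length: int = 200
    min_exons: int = 2
    min_fpkm: float = 0.1
    min_samples: int = 2
    coding_threshold: float = 0.364
    divergent_distance: int = 2000
    de_fdr: float = 0.05
    coexpression_fdr: float = 0.2
    outlier_k: float = 10.0
    te_min_bp: int = 1
    n_shuffles: int = 1000
    tss_halfwidth: int = 2000
    min_coverage: int = 8
    min_vaf: float = 0.2
    hotspot_window: int = 100
    hotspot_min_count: int = 6
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        allowed = {f.name for f in fields(cls)}
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("pipeline runs require an explicit seed")
        for name in ("min_length", "min_exons", "min_samples", "n_shuffles",
                     "hotspot_window", "hotspot_min_count", "min_coverage"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.coding_threshold < 1):
            raise ValueError("coding_threshold must lie in (0,1)")


@dataclass
class RunManifest:
    config: dict
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, outputs: dict, seconds: float, skipped: bool = False,
               extra: dict | None = None) -> None:
        self.stages[stage] = {
            "outputs": {name: _sha256(path) for name, path in outputs.items()},
            "seconds": round(seconds, 3),
            "skipped": skipped,
            **(extra or {}),
        }

    def write(self, path) -> None:
        with open(path, "w") as handle:
            json.dump({"config": self.config, "stages": self.stages}, handle, indent=2)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _have(config: PipelineConfig, *keys) -> bool:
    for key in keys:
        path = getattr(config, key)
        if path is None or not os.path.exists(path):
            return False
    return True


def run_pipeline(config: PipelineConfig) -> RunManifest:
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    os.makedirs(config.out_dir, exist_ok=True)
    manifest = RunManifest(config=asdict(config))
    out = lambda name: os.path.join(config.out_dir, name)  # noqa: E731

    def skip(stage: str, reason: str) -> None:
        log.info("skipping stage %s: %s", stage, reason)
        manifest.record(stage, {}, 0.0, skipped=True, extra={"reason": reason})

    # ------------------------------------------------------------------ model
    model: CodingPotentialModel | None = None
    t0 = time.perf_counter()
    if _have(config, "model_json"):
        model = CodingPotentialModel.from_json(config.model_json)
        manifest.record("model", {"model_json": config.model_json}, time.perf_counter() - t0)
    elif _have(config, "coding_train_fasta", "noncoding_train_fasta"):
        model = train_coding_model(
            config.coding_train_fasta, config.noncoding_train_fasta,
            threshold=config.coding_threshold,
        )
        model.to_json(out("coding_model.json"))
        manifest.record("model", {"model_json": out("coding_model.json")},
                        time.perf_counter() - t0)
    else:
        skip("model", "no model_json and no training corpora")

    # -------------------------------------------------------------- discovery
    retained = []
    divergent_ids: list = []
    genome = None
    expr = None
    if _have(config, "assembly_gtf", "known_gtf", "genome_fasta", "expression_tsv",
             "groups_tsv") and model is not None:
        t0 = time.perf_counter()
        assembly = lio.read_gtf(config.assembly_gtf)
        known = lio.read_gtf(config.known_gtf)
        genome = lio.read_fasta(config.genome_fasta)
        expr = lio.read_expression(config.expression_tsv, config.groups_tsv)
        sequences = {t.transcript_id: spliced_sequence(t, genome) for t in assembly}
        report = disc.filter_cascade(
            assembly, sequences, model, expr, known=known,
            min_length=config.min_length, min_exons=config.min_exons,
            min_fpkm=config.min_fpkm, min_samples=config.min_samples,
        )
        retained = report.retained
        lio.write_gtf(retained, out("novel_lncrnas.gtf"))
        report.table.to_csv(out("filter_report.tsv"), sep="\t")
        divergent = disc.classify_divergent(retained, known,
                                            max_distance=config.divergent_distance)
        divergent_ids = [t.transcript_id for t in divergent]
        pd.Series(divergent_ids, name="transcript_id").to_csv(
            out("divergent_lncrnas.tsv"), sep="\t", index=False)
        manifest.record(
            "discover",
            {"novel_gtf": out("novel_lncrnas.gtf"), "filter_report": out("filter_report.tsv"),
             "divergent": out("divergent_lncrnas.tsv")},
            time.perf_counter() - t0,
            extra={"n_retained": len(retained), "n_loci": report.n_loci,
                   "n_divergent": len(divergent_ids)},
        )
    else:
        skip("discover", "assembly/known/genome/expression inputs incomplete")

    retained_ids = [t.transcript_id for t in retained]

    # ----------------------------------------------------- expression stages
    if expr is not None and retained_ids:
        t0 = time.perf_counter()
        classes = exprmod.partition_expression_classes(
            expr, retained_ids, min_fpkm=config.min_fpkm, min_samples=config.min_samples)
        classes.to_csv(out("expression_classes.tsv"), sep="\t")
        counts = exprmod.count_expressed_per_sample(expr, retained_ids,
                                                    min_fpkm=config.min_fpkm)
        counts.rename("n_expressed").to_csv(out("expressed_per_sample.tsv"), sep="\t")
        outliers = exprmod.flag_outliers(expr, retained_ids, group="tumor",
                                         k=config.outlier_k)
        pd.DataFrame(outliers, columns=["feature", "sample"]).to_csv(
            out("outliers.tsv"), sep="\t", index=False)
        manifest.record(
            "classify-expression",
            {"classes": out("expression_classes.tsv"),
             "per_sample": out("expressed_per_sample.tsv"), "outliers": out("outliers.tsv")},
            time.perf_counter() - t0, extra={"n_outliers": len(outliers)},
        )

        t0 = time.perf_counter()
        if expr.subtypes is not None and len(expr.samples_with_subtype("ABC")) >= 2:
            de = exprmod.differential_expression(expr, retained_ids, alpha=config.de_fdr)
            de.to_csv(out("differential_expression.tsv"), sep="\t", index=False)
            manifest.record("de", {"table": out("differential_expression.tsv")},
                            time.perf_counter() - t0,
                            extra={"n_significant": int(de["significant"].sum())})
        else:
            skip("de", "no subtype labels")

        t0 = time.perf_counter()
        # protein-coding rows = expression features that are not assembly transcripts
        coding_genes = [f for f in expr.features if f not in report.table.index]
        if coding_genes:
            edges = exprmod.coexpression(expr, retained_ids, coding_genes,
                                         fdr=config.coexpression_fdr)
            edges.to_csv(out("coexpression.tsv"), sep="\t", index=False)
            extra = {"n_edges": len(edges)}
            outputs = {"edges": out("coexpression.tsv")}
            if _have(config, "gene_sets_gmt"):
                gene_sets = lio.read_gene_sets(config.gene_sets_gmt)
                universe = set(coding_genes)
                rows = []
                for lnc, partners in exprmod.partner_sets(edges).items():
                    for res in exprmod.enrich_gene_sets(partners, gene_sets, universe,
                                                        query_id=lnc):
                        rows.append(vars(res))
                pd.DataFrame(rows).to_csv(out("enrichment.tsv"), sep="\t", index=False)
                outputs["enrichment"] = out("enrichment.tsv")
            manifest.record("coexpress", outputs, time.perf_counter() - t0, extra=extra)
        else:
            skip("coexpress", "no protein-coding expression rows")
    else:
        skip("classify-expression", "discovery produced no retained set")
        skip("de", "discovery produced no retained set")
        skip("coexpress", "discovery produced no retained set")

    # ----------------------------------------------------------- TE summary
    if _have(config, "te_bed") and retained:
        t0 = time.perf_counter()
        tes = lio.read_bed(config.te_bed)
        summary = ctx.te_summary(retained, tes, min_bp=config.te_min_bp)
        summary.to_csv(out("te_summary.tsv"), sep="\t")
        stat, p, table = ctx.exon_position_te_test(summary)
        manifest.record(
            "te-summary", {"summary": out("te_summary.tsv")}, time.perf_counter() - t0,
            extra={"chi2_stat": stat, "chi2_p": p,
                   "pct_overlap_1bp": float(summary["any_overlap_1bp"].mean() * 100),
                   "pct_overlap_10bp": float(summary["any_overlap_10bp"].mean() * 100),
                   "mean_te_derived_percent": float(summary["te_derived_percent"].mean())},
        )
    else:
        skip("te-summary", "no TE annotation or empty retained set")

    # -------------------------------------------------------- enhancer test
    if _have(config, "enhancer_bed", "chrom_sizes") and retained:
        t0 = time.perf_counter()
        enhancers = lio.read_bed(config.enhancer_bed)
        sizes = lio.read_chrom_sizes(config.chrom_sizes)
        loci = [t.span for t in retained]
        result = ctx.shuffle_enrichment(loci, enhancers, sizes, n=config.n_shuffles,
                                        seed=config.seed)
        payload = {"observed": result.observed_count, "null_mean": result.null_mean,
                   "empirical_p": result.empirical_p, "n_shuffles": result.n_shuffles}
        with open(out("enhancer_test.json"), "w") as handle:
            json.dump(payload, handle, indent=2)
        manifest.record("enhancer-test", {"result": out("enhancer_test.json")},
                        time.perf_counter() - t0, extra=payload)
    else:
        skip("enhancer-test", "no enhancer BED / chrom sizes")

    # ----------------------------------------------------------- TSS profile
    if _have(config, "coverage_bedgraph") and retained:
        t0 = time.perf_counter()
        track = lio.read_bedgraph(config.coverage_bedgraph)
        profile = ctx.tss_metaprofile(retained, track, halfwidth=config.tss_halfwidth)
        pd.DataFrame({"offset": profile.offsets(), "mean_coverage": profile.values}).to_csv(
            out("tss_profile.tsv"), sep="\t", index=False)
        manifest.record("tss-profile", {"profile": out("tss_profile.tsv")},
                        time.perf_counter() - t0)
    else:
        skip("tss-profile", "no coverage track")

    # -------------------------------------------------------------- variants
    filtered = []
    if _have(config, "pileup_tsv") and retained:
        t0 = time.perf_counter()
        pileup = lio.read_pileup(config.pileup_tsv)
        called = mut.call_variants(pileup, min_coverage=config.min_coverage,
                                  min_vaf=config.min_vaf)
        lio.write_variant_table(called, out("called_variants.tsv"))
        dbsnp = lio.read_position_set(config.dbsnp_tsv) if _have(config, "dbsnp_tsv") else set()
        normals = lio.read_position_set(config.normals_tsv) if _have(config, "normals_tsv") else set()
        annotated = [
            mut.VariantRecord(
                chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt, sample_id=v.sample_id,
                coverage=v.coverage, vaf=v.vaf,
                known_polymorphism=v.key in dbsnp, in_normal=v.key in normals,
            )
            for v in called
        ]
        filtered = mut.filter_variants(annotated, retained, dbsnp, normals)
        lio.write_variant_table(filtered, out("filtered_variants.tsv"))
        hotspots = mut.hotspot_scan(filtered, window=config.hotspot_window,
                                    min_count=config.hotspot_min_count)
        pd.DataFrame([vars(h) for h in hotspots]).to_csv(out("hotspots.tsv"), sep="\t",
                                                         index=False)
        manifest.record(
            "variants",
            {"called": out("called_variants.tsv"), "filtered": out("filtered_variants.tsv"),
             "hotspots": out("hotspots.tsv")},
            time.perf_counter() - t0,
            extra={"n_called": len(called), "n_filtered": len(filtered),
                   "n_hotspots": len(hotspots)},
        )
    else:
        skip("variants", "no pileup input")

    # -------------------------------------------------------------- delta-MFE
    if genome is not None and retained and _have(config, "pileup_tsv"):
        t0 = time.perf_counter()
        pileup = lio.read_pileup(config.pileup_tsv)
        called = mut.call_variants(pileup, min_coverage=config.min_coverage,
                                  min_vaf=config.min_vaf)
        dbsnp = lio.read_position_set(config.dbsnp_tsv) if _have(config, "dbsnp_tsv") else set()
        normals = lio.read_position_set(config.normals_tsv) if _have(config, "normals_tsv") else set()
        exonic_novel = mut.filter_variants(called, retained, dbsnp, normals)
        exonic_control = [
            v for v in mut.filter_variants(called, retained, set(), normals)
            if v.key in dbsnp
        ]
        novel_deltas = mut.delta_mfe_for_variants(retained, genome, exonic_novel)
        control_deltas = mut.delta_mfe_for_variants(retained, genome, exonic_control)
        rows = [
            {"transcript_id": d.transcript_id, "chrom": d.variant.chrom,
             "pos": d.variant.pos, "alt": d.variant.alt, "group": group,
             "mfe_native": d.mfe_native, "mfe_mutated": d.mfe_mutated, "delta": d.delta}
            for group, deltas in (("novel", novel_deltas), ("control", control_deltas))
            for d in deltas
        ]
        pd.DataFrame(rows).to_csv(out("delta_mfe.tsv"), sep="\t", index=False)
        if novel_deltas and control_deltas:
            summary, stat, p = mut.delta_mfe_analysis(novel_deltas, control_deltas)
            payload = {**summary, "rank_sum_statistic": stat, "p_value": p}
        else:
            payload = {"note": "one of the delta groups is empty"}
        with open(out("delta_mfe_test.json"), "w") as handle:
            json.dump(payload, handle, indent=2)
        manifest.record("delta-mfe", {"deltas": out("delta_mfe.tsv"),
                                      "test": out("delta_mfe_test.json")},
                        time.perf_counter() - t0, extra=payload)
    else:
        skip("delta-mfe", "genome, retained set or pileup missing")

    manifest.write(out("manifest.json"))
    return manifest
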