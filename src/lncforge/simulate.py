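"""Synthetic-data generator with planted ground truth.

Generates every input the pipeline consumes — genome FASTA, known
annotation, an "assembled" transcriptome containing planted true lncRNAs
plus decoy classes that each violate exactly one cascade filter,
group-structured FPKM matrices with planted subtype effects and outliers,
TE annotations with a planted last-exon placement bias, enhancer sets with
controlled overlap, pileup summaries and variant sets with planted
structure-stabilizing and structure-neutral substitutions — alongside a
:class:`GroundTruth` object that the pipeline never reads.

A single integer seed drives a hierarchical stream (one child stream per
generator stage), so later stages never perturb earlier draws.  Stabilizing
and neutral variants are defined operationally against the package's own
folding energy model: a planted stabilizing variant strictly lowers the
fold MFE of its host transcript, a neutral one leaves it unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .coding import find_longest_orf, longest_orf_span
from .expression import ExpressionMatrix
from .folding import DEFAULT_MODEL, fold_mfe
from .intervals import (
    MINUS,
    PLUS,
    UNSTRANDED,
    CoverageTrack,
    GenomicInterval,
    TranscriptModel,
    ValidationError,
    VariantRecord,
    merge_intervals,
    revcomp,
    spliced_sequence,
)
from .mutation import PileupSite

TRUE_LNCRNA = "true_lncRNA"
CODING_DECOY = "coding_decoy"
SHORT_DECOY = "short_decoy"
MONOEXONIC_DECOY = "monoexonic_decoy"
LOW_EXPRESSION_DECOY = "low_expression_decoy"
KNOWN_GENE = "known_gene"

_STOPS = ("TAA", "TAG", "TGA")
_BASES = np.frombuffer(b"ACGT", dtype="S1")


class ConfigError(ValueError):
    pass


class GenerationError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    """All knobs of the generator; the defaults emulate the study design
    (116 tumors, 8 normal B-cell samples, 30 cell lines; 35 ABC vs 69 GCB
    classified tumors) at a genome scale small enough for desk-top runs."""

    seed: int = 0
    # genome
    n_chromosomes: int = 4
    chromosome_length: int = 900_000
    # features
    n_known_genes: int = 60
    n_true_lncrnas: int = 120
    isoform_fraction: float = 0.3
    divergent_fraction: float = 0.25
    n_coding_decoys: int = 80
    n_short_decoys: int = 80
    n_monoexonic_decoys: int = 80
    n_low_expression_decoys: int = 60
    n_reassembled_known: int = 50
    # samples
    n_tumor: int = 116
    n_normal: int = 8
    n_cellline: int = 30
    n_abc: int = 35
    n_gcb: int = 69
    # expression structure
    de_effect_size: float = 4.0
    de_fraction: float = 0.3
    n_outliers: int = 5
    outlier_sd_multiplier: float = 10.0
    n_coexpressed_pairs: int = 10
    class_fractions: tuple = (0.36, 0.29, 0.05, 0.30)  # tumor-only, t+cl, t+n, all
    # TE / enhancers
    te_last_exon_bias: float = 0.7
    te_presence_prob: float = 0.9
    n_background_tes: int = 60
    n_enhancers: int = 60
    enhancer_overlap_fraction: float = 0.3
    enhancer_length_range: tuple = (1500, 4000)
    # variants
    n_stabilizing_variants: int = 200
    n_neutral_variants: int = 200
    n_known_polymorphism_variants: int = 40
    n_normal_variants: int = 40
    n_intronic_variants: int = 40
    n_hotspot_clusters: int = 3
    n_subthreshold_sites: int = 40
    # coverage track
    tss_peak_halfwidth: int = 200
    tss_peak_height: float = 10.0
    # coding-model training corpora
    hexamer_divergence: float = 4.0
    n_train_coding: int = 500
    n_train_noncoding: int = 500

    def validate(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if f.name.startswith("n_") and isinstance(value, int) and value < 0:
                raise ConfigError(f"{f.name} must be >= 0")
        for name in ("isoform_fraction", "divergent_fraction", "te_last_exon_bias",
                     "te_presence_prob", "enhancer_overlap_fraction", "de_fraction"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ConfigError(f"{name} must be in [0,1], got {value}")
        if self.n_abc + self.n_gcb > self.n_tumor:
            raise ConfigError("n_abc + n_gcb exceeds n_tumor")
        if self.n_outliers > 0:
            k = self.outlier_sd_multiplier
            if self.n_tumor <= k * k + 1:
                raise ConfigError(
                    f"flagging a {k}-SD outlier with the outlier itself included in "
                    f"the group statistics requires more than {k * k + 1:.0f} tumor "
                    f"samples; got {self.n_tumor}"
                )


@dataclass
class GroundTruth:
    """Planted labels; emitted alongside fixtures, never read by the pipeline."""

    transcript_class: dict = field(default_factory=dict)
    subtype_label: dict = field(default_factory=dict)
    expression_class: dict = field(default_factory=dict)
    outliers: list = field(default_factory=list)
    divergent: set = field(default_factory=set)
    divergent_pairs: list = field(default_factory=list)
    te_exon: dict = field(default_factory=dict)
    variant_labels: dict = field(default_factory=dict)  # (chrom,pos,alt,sample) -> label
    coexpressed_pairs: list = field(default_factory=list)
    enhancer_overlap_idx: set = field(default_factory=set)

    def transcripts_of_class(self, label: str) -> list:
        return [tid for tid, c in self.transcript_class.items() if c == label]

    @property
    def true_lncRNAs(self) -> list:
        return self.transcripts_of_class(TRUE_LNCRNA)

    def variants_with_label(self, label: str) -> list:
        return [k for k, v in self.variant_labels.items() if v == label]


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genome: dict
    chrom_sizes: dict
    known: list
    assembly: list
    expression: ExpressionMatrix
    te_elements: list
    enhancers: list
    variants: list
    pileup: list
    dbsnp_sites: set
    normal_sites: set
    coverage: CoverageTrack
    coding_train: list
    noncoding_train: list
    gene_sets: dict
    truth: GroundTruth

    def transcripts_by_id(self) -> dict:
        return {t.transcript_id: t for t in self.assembly}

    def spliced(self, transcript_id: str) -> str:
        return spliced_sequence(self.transcripts_by_id()[transcript_id], self.genome)


# ---------------------------------------------------------------------------
# sequence construction helpers

def _random_seq(rng, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _codon_weights(divergence: float) -> tuple:
    """Biased sense-codon distribution: GC-ending codons up-weighted."""
    codons = []
    weights = []
    for a in "ACGT":
        for b in "ACGT":
            for c in "ACGT":
                codon = a + b + c
                if codon in _STOPS:
                    continue
                codons.append(codon)
                weights.append(1.0 + divergence if c in "GC" else 1.0)
    w = np.array(weights)
    return codons, w / w.sum()


def _coding_like_sequence(rng, total_length: int, divergence: float, min_orf: int = 300) -> str:
    """UTR + (ATG codons stop) + UTR with biased codon usage, ORF >= min_orf."""
    orf_len = max(min_orf, 3 * int(0.7 * total_length / 3))
    orf_len = min(orf_len, 3 * ((total_length - 6) // 3))
    codons, probs = _codon_weights(divergence)
    n_codons = orf_len // 3 - 2
    body = "".join(rng.choice(codons, size=n_codons, p=probs))
    orf = "ATG" + body + _STOPS[rng.integers(0, 3)]
    rest = total_length - len(orf)
    utr5 = rest // 2
    seq = _random_seq(rng, utr5) + orf + _random_seq(rng, rest - utr5)
    # UTR noise may create a longer spurious ORF; that is fine — the planted
    # ORF guarantees orf_length >= min_orf either way
    return seq


def _noncoding_sequence(rng, length: int, max_orf: int = 150) -> str:
    """Uniform-random sequence with every ORF >= max_orf disrupted by an
    in-frame stop codon."""
    seq = list(_random_seq(rng, length))
    for _ in range(200):
        orf_len, start = longest_orf_span("".join(seq))
        if orf_len < max_orf:
            return "".join(seq)
        # overwrite the start codon with a stop: this strictly reduces the
        # number of ATG occurrences, so the loop always terminates
        seq[start:start + 3] = "TAA"
    raise GenerationError("could not disrupt open reading frames in a synthetic sequence")


def _exon_chain(rng, start: int, n_exons: int, exonic_total: int,
                intron_range=(100, 400), min_exon: int = 40):
    """Exon coordinates for a transcript starting at ``start``: ``n_exons``
    sizes summing exactly to ``exonic_total`` (each >= min_exon), with random
    intron gaps."""
    n_exons = max(1, min(n_exons, exonic_total // min_exon))
    extra = exonic_total - n_exons * min_exon
    if n_exons > 1:
        cuts = np.sort(rng.integers(0, extra + 1, size=n_exons - 1))
        parts = np.diff(np.concatenate([[0], cuts, [extra]]))
    else:
        parts = np.array([extra], dtype=np.int64)
    sizes = parts + min_exon
    exons = []
    pos = start
    for i, size in enumerate(sizes):
        exons.append((pos, pos + int(size)))
        pos += int(size)
        if i < n_exons - 1:
            pos += int(rng.integers(*intron_range))
    return exons, pos  # pos = span end


class _Placer:
    """Round-robin, non-overlapping feature placement across chromosomes."""

    def __init__(self, chrom_sizes: dict, rng, gap_min: int = 2500, gap_jitter: int = 2000):
        self.chroms = sorted(chrom_sizes)
        self.sizes = chrom_sizes
        self.cursors = {c: 1000 for c in self.chroms}
        self.rng = rng
        self.gap_min = gap_min
        self.gap_jitter = gap_jitter
        self._next = 0

    def place(self, span: int) -> tuple:
        for _ in range(len(self.chroms)):
            chrom = self.chroms[self._next % len(self.chroms)]
            self._next += 1
            start = self.cursors[chrom]
            if start + span + self.gap_min < self.sizes[chrom] - 1000:
                gap = self.gap_min + int(self.rng.integers(0, self.gap_jitter))
                self.cursors[chrom] = start + span + gap
                return chrom, start
        raise GenerationError("requested features exceed genome capacity")


# ---------------------------------------------------------------------------
# stage 1: genome + known annotation + assembly

def _write_transcript_sequence(genome: dict, tx: TranscriptModel, seq: str) -> None:
    plus = revcomp(seq) if tx.strand == MINUS else seq
    pos = 0
    chrom = genome[tx.chrom]
    for exon in tx.exons:
        chrom[exon.start:exon.end] = plus[pos:pos + exon.length].encode()
        pos += exon.length


def _make_transcript(tid, chrom, strand, exon_pairs, locus=None, attrs=None):
    exons = tuple(GenomicInterval(chrom, s, e, strand) for s, e in exon_pairs)
    return TranscriptModel(transcript_id=tid, chrom=chrom, strand=strand,
                           exons=exons, locus_id=locus, attributes=attrs or {})


def simulate_genome_and_assembly(config: SimulationConfig, rng_genome, rng_features):
    """Genome, known annotation and the assembled transcript pool.

    Returns (genome bytearrays, chrom_sizes, known transcripts, assembly
    transcripts, truth).  The two stages are fused because divergent lncRNAs
    are placed jointly with their partner protein-coding gene.
    """
    truth = GroundTruth()
    chrom_sizes = {f"chrS{i + 1}": config.chromosome_length for i in range(config.n_chromosomes)}
    genome = {
        chrom: bytearray(_random_seq(rng_genome, size).encode())
        for chrom, size in chrom_sizes.items()
    }
    placer = _Placer(chrom_sizes, rng_features)
    known: list = []
    assembly: list = []

    n_divergent = int(round(config.divergent_fraction * config.n_true_lncrnas))
    n_divergent = min(n_divergent, config.n_known_genes, config.n_true_lncrnas)

    def build_gene(gid: str, chrom: str, start: int, strand: str):
        n_exons = int(rng_features.integers(2, 6))
        exonic = int(rng_features.integers(600, 1500))
        exons, end = _exon_chain(rng_features, start, n_exons, exonic)
        gene = _make_transcript(f"{gid}.t1", chrom, strand, exons, locus=gid,
                                attrs={"gene_type": "protein_coding"})
        seq = _coding_like_sequence(rng_features, gene.exonic_length, config.hexamer_divergence)
        _write_transcript_sequence(genome, gene, seq)
        return gene, end

    def build_lncrna(tid: str, chrom: str, start: int, strand: str):
        n_exons = int(rng_features.integers(2, 6))
        exonic = int(rng_features.integers(250, 450))
        exons, end = _exon_chain(rng_features, start, n_exons, exonic, intron_range=(80, 300))
        tx = _make_transcript(tid, chrom, strand, exons)
        seq = _noncoding_sequence(rng_features, tx.exonic_length)
        _write_transcript_sequence(genome, tx, seq)
        return tx, end

    # --- divergent (lncRNA, gene) pairs, placed head-to-head
    gene_counter = 0
    for i in range(n_divergent):
        tid = f"TLNC_{i + 1:04d}"
        gid = f"GENE_{gene_counter + 1:03d}"
        gene_counter += 1
        gap = int(rng_features.integers(200, 1500))
        lnc_span_budget = 450 + 5 * 300 + 100
        chrom, start = placer.place(lnc_span_budget + gap + 1500 + 5 * 400 + 200)
        if rng_features.random() < 0.5:
            lnc, lnc_end = build_lncrna(tid, chrom, start, MINUS)
            gene, _ = build_gene(gid, chrom, lnc_end + gap, PLUS)
        else:
            gene, gene_end = build_gene(gid, chrom, start, MINUS)
            lnc, _ = build_lncrna(tid, chrom, gene_end + gap, PLUS)
        known.append(gene)
        assembly.append(lnc)
        truth.transcript_class[tid] = TRUE_LNCRNA
        truth.divergent.add(tid)
        truth.divergent_pairs.append((tid, gid))

    # --- remaining true lncRNAs, far (> 2 kb) from every gene
    for i in range(n_divergent, config.n_true_lncrnas):
        tid = f"TLNC_{i + 1:04d}"
        strand = PLUS if rng_features.random() < 0.5 else MINUS
        chrom, start = placer.place(450 + 5 * 300)
        lnc, _ = build_lncrna(tid, chrom, start, strand)
        assembly.append(lnc)
        truth.transcript_class[tid] = TRUE_LNCRNA

    # --- standalone known genes
    for i in range(n_divergent, config.n_known_genes):
        gid = f"GENE_{gene_counter + 1:03d}"
        gene_counter += 1
        strand = PLUS if rng_features.random() < 0.5 else MINUS
        chrom, start = placer.place(1500 + 5 * 400)
        gene, _ = build_gene(gid, chrom, start, strand)
        known.append(gene)

    # --- isoforms sharing exons with true lncRNA primaries
    primaries = [t for t in assembly if truth.transcript_class[t.transcript_id] == TRUE_LNCRNA]
    for tx in list(primaries):
        if rng_features.random() >= config.isoform_fraction:
            continue
        candidates = []
        if tx.n_exons >= 3:
            # dropping a terminal exon cannot create an ORF absent from the parent
            drop_last = tx.exons[:-1] if tx.strand == PLUS else tx.exons[1:]
            candidates.append(drop_last)
            if tx.transcript_id not in truth.divergent:
                drop_first = tx.exons[1:] if tx.strand == PLUS else tx.exons[:-1]
                candidates.append(drop_first)
        n_iso = int(rng_features.integers(1, 3))
        made = 0
        for k, exons in enumerate(candidates):
            if made >= n_iso:
                break
            if sum(e.length for e in exons) < 200 or len(exons) < 2:
                continue
            iso_id = f"{tx.transcript_id}_i{k + 1}"
            iso = TranscriptModel(transcript_id=iso_id, chrom=tx.chrom, strand=tx.strand,
                                  exons=tuple(exons))
            assembly.append(iso)
            truth.transcript_class[iso_id] = TRUE_LNCRNA
            if tx.transcript_id in truth.divergent:
                truth.divergent.add(iso_id)
            made += 1

    # --- decoys, each violating exactly one cascade filter
    for i in range(config.n_coding_decoys):
        tid = f"DCOD_{i + 1:04d}"
        strand = PLUS if rng_features.random() < 0.5 else MINUS
        n_exons = int(rng_features.integers(2, 5))
        exonic = int(rng_features.integers(450, 750))
        chrom, start = placer.place(exonic + 4 * 400)
        exons, _ = _exon_chain(rng_features, start, n_exons, exonic)
        tx = _make_transcript(tid, chrom, strand, exons)
        seq = _coding_like_sequence(rng_features, tx.exonic_length, config.hexamer_divergence)
        _write_transcript_sequence(genome, tx, seq)
        assembly.append(tx)
        truth.transcript_class[tid] = CODING_DECOY
    for i in range(config.n_short_decoys):
        tid = f"DSHT_{i + 1:04d}"
        strand = PLUS if rng_features.random() < 0.5 else MINUS
        exonic = int(rng_features.integers(120, 199))
        chrom, start = placer.place(exonic + 300)
        exons, _ = _exon_chain(rng_features, start, 2, exonic, intron_range=(80, 200))
        tx = _make_transcript(tid, chrom, strand, exons)
        _write_transcript_sequence(genome, tx, _noncoding_sequence(rng_features, exonic))
        assembly.append(tx)
        truth.transcript_class[tid] = SHORT_DECOY
    for i in range(config.n_monoexonic_decoys):
        tid = f"DMON_{i + 1:04d}"
        strand = PLUS if rng_features.random() < 0.5 else MINUS
        exonic = int(rng_features.integers(300, 700))
        chrom, start = placer.place(exonic)
        tx = _make_transcript(tid, chrom, strand, [(start, start + exonic)])
        _write_transcript_sequence(genome, tx, _noncoding_sequence(rng_features, exonic))
        assembly.append(tx)
        truth.transcript_class[tid] = MONOEXONIC_DECOY
    for i in range(config.n_low_expression_decoys):
        tid = f"DLOW_{i + 1:04d}"
        strand = PLUS if rng_features.random() < 0.5 else MINUS
        exonic = int(rng_features.integers(250, 500))
        chrom, start = placer.place(exonic + 4 * 300)
        exons, _ = _exon_chain(rng_features, start, int(rng_features.integers(2, 5)), exonic,
                               intron_range=(80, 300))
        tx = _make_transcript(tid, chrom, strand, exons)
        _write_transcript_sequence(genome, tx, _noncoding_sequence(rng_features, exonic))
        assembly.append(tx)
        truth.transcript_class[tid] = LOW_EXPRESSION_DECOY

    # --- re-assembled copies of known genes (subtracted at the first stage)
    for i in range(min(config.n_reassembled_known, len(known))):
        gene = known[i]
        tid = f"DKNW_{i + 1:04d}"
        tx = TranscriptModel(transcript_id=tid, chrom=gene.chrom, strand=gene.strand,
                             exons=gene.exons)
        assembly.append(tx)
        truth.transcript_class[tid] = KNOWN_GENE

    return genome, chrom_sizes, known, assembly, truth


# ---------------------------------------------------------------------------
# stage 2: expression

_EXPR_CLASSES = ("tumor", "tumor+cell_line", "tumor+normal", "tumor+normal+cell_line")
_CLASS_GROUPS = {
    "tumor": {"tumor"},
    "tumor+cell_line": {"tumor", "cell_line"},
    "tumor+normal": {"tumor", "normal"},
    "tumor+normal+cell_line": {"tumor", "normal", "cell_line"},
}
_LOGN_CLIP = math.exp(2.0)  # truncate the log-normal tail so that no natural
# draw can itself sit >= 10 group SDs above the group mean


def _expressed_values(rng, n: int) -> np.ndarray:
    return 0.12 + np.minimum(rng.lognormal(0.0, 1.0, size=n), _LOGN_CLIP)


def _silent_values(rng, n: int) -> np.ndarray:
    return rng.uniform(0.0, 0.08, size=n)


def simulate_expression(config: SimulationConfig, assembly, known_gene_ids, truth: GroundTruth,
                        rng) -> ExpressionMatrix:
    """Group-structured FPKM matrix with planted classes, subtype effects,
    co-expressed pairs and extreme outliers."""
    if config.n_abc + config.n_gcb > config.n_tumor:
        raise ConfigError("n_abc + n_gcb exceeds n_tumor")
    tumor = [f"TUMOR_{i + 1:03d}" for i in range(config.n_tumor)]
    normal = [f"NORMAL_{i + 1:02d}" for i in range(config.n_normal)]
    cell = [f"CELL_{i + 1:02d}" for i in range(config.n_cellline)]
    samples = tumor + normal + cell
    groups = pd.Series(
        ["tumor"] * len(tumor) + ["normal"] * len(normal) + ["cell_line"] * len(cell),
        index=samples,
    )
    subtype_values = (["ABC"] * config.n_abc + ["GCB"] * config.n_gcb
                      + ["unclassified"] * (config.n_tumor - config.n_abc - config.n_gcb))
    subtypes = pd.Series(subtype_values + ["unclassified"] * (len(normal) + len(cell)),
                         index=samples)
    abc_cols = [s for s, v in zip(tumor, subtype_values) if v == "ABC"]
    gcb_cols = [s for s, v in zip(tumor, subtype_values) if v == "GCB"]

    feature_ids = [t.transcript_id for t in assembly] + list(known_gene_ids)
    values = pd.DataFrame(0.0, index=feature_ids, columns=samples)

    # expression class per true-lncRNA locus primary; isoforms inherit
    class_p = np.asarray(config.class_fractions, dtype=float)
    class_p = class_p / class_p.sum()
    primaries = [tid for tid in truth.true_lncRNAs if "_i" not in tid]
    for tid in primaries:
        truth.expression_class[tid] = _EXPR_CLASSES[int(rng.choice(4, p=class_p))]
    for tid in truth.true_lncRNAs:
        if tid not in truth.expression_class:
            truth.expression_class[tid] = truth.expression_class[tid.split("_i")[0]]

    group_cols = {"tumor": tumor, "normal": normal, "cell_line": cell}
    for tx in assembly:
        tid = tx.transcript_id
        label = truth.transcript_class[tid]
        if label == LOW_EXPRESSION_DECOY:
            row = _silent_values(rng, len(samples))
            row[rng.integers(0, len(tumor))] = 0.5  # expressed in exactly one tumor
            values.loc[tid] = row
            continue
        if label == TRUE_LNCRNA:
            expressed_in = _CLASS_GROUPS[truth.expression_class[tid]]
        else:
            expressed_in = {"tumor", "normal", "cell_line"}
        for group, cols in group_cols.items():
            if not cols:
                continue
            if group in expressed_in:
                values.loc[tid, cols] = _expressed_values(rng, len(cols))
            else:
                values.loc[tid, cols] = _silent_values(rng, len(cols))
    for gid in known_gene_ids:
        values.loc[gid] = _expressed_values(rng, len(samples))

    # planted co-expression, subtype effects and outliers on disjoint features
    pool = list(primaries)
    rng.shuffle(pool)
    coexpr = [pool.pop() for _ in range(min(config.n_coexpressed_pairs, len(pool)))]
    outlier_feats = [pool.pop() for _ in range(min(config.n_outliers, len(pool)))]
    gene_pool = list(known_gene_ids)
    for i, tid in enumerate(coexpr):
        gid = gene_pool[i % len(gene_pool)]
        u = rng.normal(0.0, 1.0, size=len(tumor))
        for fid in (tid, gid):
            noise = rng.normal(0.0, 1.0, size=len(tumor))
            values.loc[fid, tumor] = 0.12 + np.minimum(
                np.exp(0.9 * u + 0.45 * noise), _LOGN_CLIP
            )
        truth.coexpressed_pairs.append((tid, gid))

    n_de = int(round(config.de_fraction * len(pool)))
    de_feats = pool[:n_de]
    for i, tid in enumerate(de_feats):
        direction = "ABC-up" if i % 2 == 0 else "GCB-up"
        cols = abc_cols if direction == "ABC-up" else gcb_cols
        if cols and "tumor" in _CLASS_GROUPS[truth.expression_class[tid]]:
            values.loc[tid, cols] *= config.de_effect_size
            truth.subtype_label[tid] = direction

    k = config.outlier_sd_multiplier
    n = len(tumor)
    if outlier_feats and n > k * k + 1:
        # smallest offset c (in pre-modification SDs) such that the planted cell
        # still sits >= k SDs above the mean once it inflates the group stats
        c = 1.1 * k * math.sqrt(n / (n - 1 - k * k))
        for tid in outlier_feats:
            sample = tumor[int(rng.integers(0, n))]
            row = values.loc[tid, tumor].to_numpy(dtype=float)
            value = row.mean() + c * row.std(ddof=0)
            values.loc[tid, sample] = value
            truth.outliers.append((tid, sample))
    return ExpressionMatrix(values=values, groups=groups, subtypes=subtypes)


# ---------------------------------------------------------------------------
# stage 3: TEs, enhancers, coverage

def _place_te_in_exon(exon, rng):
    te_len = int(rng.integers(30, max(31, min(exon.length, 120) + 1)))
    te_len = min(te_len, exon.length)
    start = exon.start + int(rng.integers(0, exon.length - te_len + 1))
    return GenomicInterval(exon.chrom, start, start + te_len, UNSTRANDED)


def _plant_transcript_tes(tx, config, truth, rng) -> list:
    """Independent last/first-exon insertions with marginal probabilities
    presence*bias and presence*(1-bias); independence keeps the pooled 2x2
    chi-square null valid when bias = 0.5."""
    tes = []
    sides = []
    if rng.random() < config.te_presence_prob * config.te_last_exon_bias:
        tes.append(_place_te_in_exon(tx.last_exon, rng))
        sides.append("last")
    if rng.random() < config.te_presence_prob * (1.0 - config.te_last_exon_bias):
        tes.append(_place_te_in_exon(tx.first_exon, rng))
        sides.append("first")
    if sides:
        truth.te_exon[tx.transcript_id] = sides
    return tes


def simulate_te_elements(config: SimulationConfig, transcripts, chrom_sizes, truth: GroundTruth,
                         rng) -> list:
    """Biased per-transcript last/first-exon TE insertions plus uniform
    background elements."""
    tes = []
    for tx in transcripts:
        tes.extend(_plant_transcript_tes(tx, config, truth, rng))
    chroms = sorted(chrom_sizes)
    for _ in range(config.n_background_tes):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        length = int(rng.integers(100, 300))
        start = int(rng.integers(0, chrom_sizes[chrom] - length))
        tes.append(GenomicInterval(chrom, start, start + length, UNSTRANDED))
    return tes


def simulate_te_exon_fixture(n_transcripts: int, bias: float, rng, te_presence: float = 0.9):
    """Light-weight fixture for the first/last-exon TE placement test: 3-exon
    transcripts on one chromosome with biased TE insertion, no background."""
    cfg = SimulationConfig(te_last_exon_bias=bias, te_presence_prob=te_presence)
    transcripts, tes = [], []
    truth = GroundTruth()
    pos = 1000
    for i in range(n_transcripts):
        exons = []
        for _ in range(3):
            length = int(rng.integers(100, 250))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(100, 300))
        tx = _make_transcript(f"T{i + 1:04d}", "chrS1", PLUS if rng.random() < 0.5 else MINUS,
                              exons)
        transcripts.append(tx)
        pos += 1500
        tes.extend(_plant_transcript_tes(tx, cfg, truth, rng))
    return transcripts, tes, truth


def simulate_enhancers(config: SimulationConfig, loci_spans, chrom_sizes, truth: GroundTruth,
                       rng) -> list:
    """Enhancer intervals; a fraction is placed to overlap lncRNA loci,
    the rest uniformly (chromosome drawn proportionally to its length)."""
    lo, hi = config.enhancer_length_range
    chroms = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    n_overlap = int(round(config.enhancer_overlap_fraction * config.n_enhancers))
    enhancers = []
    for i in range(config.n_enhancers):
        length = int(rng.integers(lo, hi + 1))
        if i < n_overlap and loci_spans:
            locus = loci_spans[int(rng.integers(0, len(loci_spans)))]
            low = max(0, locus.start - length + 50)
            high = min(locus.end - 50, chrom_sizes[locus.chrom] - length)
            start = int(rng.integers(low, max(low, high) + 1))
            enhancers.append(GenomicInterval(locus.chrom, start, start + length, UNSTRANDED))
            truth.enhancer_overlap_idx.add(i)
        else:
            chrom = chroms[int(rng.choice(len(chroms), p=sizes / sizes.sum()))]
            start = int(rng.integers(0, chrom_sizes[chrom] - length))
            enhancers.append(GenomicInterval(chrom, start, start + length, UNSTRANDED))
    return enhancers


def simulate_coverage(config: SimulationConfig, transcripts) -> CoverageTrack:
    """H3K4me3-like coverage: a rectangular peak of height ``tss_peak_height``
    and halfwidth ``tss_peak_halfwidth`` at every planted TSS."""
    w = config.tss_peak_halfwidth
    peaks = []
    for tx in transcripts:
        tss = tx.exons[-1].end - 1 if tx.strand == MINUS else tx.exons[0].start
        peaks.append(GenomicInterval(tx.chrom, max(0, tss - w), tss + w, UNSTRANDED))
    merged = merge_intervals(peaks)
    steps = {
        chrom: [(int(s), int(e), config.tss_peak_height) for s, e in zip(*arrays)]
        for chrom, arrays in merged.items()
    }
    return CoverageTrack(steps)


# ---------------------------------------------------------------------------
# stage 4: variants + pileups

def _genomic_position(tx: TranscriptModel, offset: int) -> int:
    """Map a transcript coordinate (5'->3') to a 0-based genomic position."""
    if tx.strand == MINUS:
        offset = tx.exonic_length - 1 - offset
    for exon in tx.exons:
        if offset < exon.length:
            return exon.start + offset
        offset -= exon.length
    raise ValidationError("offset beyond transcript length")


def _tumor_sample(rng, config) -> str:
    return f"TUMOR_{int(rng.integers(0, config.n_tumor)) + 1:03d}"


def _variant_depths(rng) -> tuple:
    coverage = int(rng.integers(10, 61))
    vaf_target = rng.uniform(0.25, 0.85)
    alt = min(coverage, max(int(math.ceil(0.2 * coverage)), int(round(vaf_target * coverage))))
    return coverage, alt


def _record(genome, chrom, pos0, alt, sample, coverage, alt_count, known=False, normal=False):
    ref = chr(genome[chrom][pos0]).upper()
    return VariantRecord(chrom=chrom, pos=pos0 + 1, ref=ref, alt=alt, sample_id=sample,
                         coverage=coverage, vaf=alt_count / coverage,
                         known_polymorphism=known, in_normal=normal)


def simulate_variants(config: SimulationConfig, hosts, genome, truth: GroundTruth, rng,
                      energy_model=DEFAULT_MODEL, search_budget: int = 60):
    """Planted variant classes on true-lncRNA host transcripts.

    Stabilizing variants are found by brute-force search over candidate
    substitutions until the host's fold MFE strictly decreases; neutral
    variants leave the MFE unchanged and are flagged as known polymorphisms
    (they play the dbSNP-control role downstream).
    """
    genome_str = {c: bytes(b).decode() for c, b in genome.items()}
    native_seq = {t.transcript_id: spliced_sequence(t, genome_str) for t in hosts}
    native_mfe = {tid: fold_mfe(seq, energy_model).mfe for tid, seq in native_seq.items()}
    used_positions: set = set()
    variants: list = []

    def search(host, accept, label, known=False):
        seq = native_seq[host.transcript_id]
        for _ in range(search_budget):
            offset = int(rng.integers(0, len(seq)))
            pos0 = _genomic_position(host, offset)
            if (host.chrom, pos0) in used_positions:
                continue
            current = seq[offset]
            alt_tx = "ACGT".replace(current, "")[int(rng.integers(0, 3))]
            mutated = seq[:offset] + alt_tx + seq[offset + 1:]
            delta = native_mfe[host.transcript_id] - fold_mfe(mutated, energy_model).mfe
            if not accept(delta):
                continue
            used_positions.add((host.chrom, pos0))
            alt_genomic = revcomp(alt_tx) if host.strand == MINUS else alt_tx
            coverage, alt_count = _variant_depths(rng)
            v = _record(genome, host.chrom, pos0, alt_genomic, _tumor_sample(rng, config),
                        coverage, alt_count, known=known)
            variants.append(v)
            truth.variant_labels[(v.chrom, v.pos, v.alt, v.sample_id)] = label
            return
        raise GenerationError(
            f"no {label} substitution found for {host.transcript_id} "
            f"within the search budget"
        )

    for i in range(config.n_stabilizing_variants):
        search(hosts[i % len(hosts)], lambda d: d > 1e-9, "stabilizing")
    for i in range(config.n_neutral_variants):
        search(hosts[(i + 1) % len(hosts)], lambda d: abs(d) < 1e-9, "neutral", known=True)

    def random_exonic(host):
        for _ in range(search_budget):
            offset = int(rng.integers(0, host.exonic_length))
            pos0 = _genomic_position(host, offset)
            if (host.chrom, pos0) not in used_positions:
                used_positions.add((host.chrom, pos0))
                return pos0
        raise GenerationError(f"no free exonic position on {host.transcript_id}")

    def random_alt(chrom, pos0):
        current = chr(genome[chrom][pos0]).upper()
        return "ACGT".replace(current, "")[int(rng.integers(0, 3))]

    for i in range(config.n_known_polymorphism_variants):
        host = hosts[i % len(hosts)]
        pos0 = random_exonic(host)
        cov, alt_count = _variant_depths(rng)
        v = _record(genome, host.chrom, pos0, random_alt(host.chrom, pos0),
                    _tumor_sample(rng, config), cov, alt_count, known=True)
        variants.append(v)
        truth.variant_labels[(v.chrom, v.pos, v.alt, v.sample_id)] = "known_polymorphism"
    for i in range(config.n_normal_variants):
        host = hosts[(i + 2) % len(hosts)]
        pos0 = random_exonic(host)
        cov, alt_count = _variant_depths(rng)
        v = _record(genome, host.chrom, pos0, random_alt(host.chrom, pos0),
                    _tumor_sample(rng, config), cov, alt_count, normal=True)
        variants.append(v)
        truth.variant_labels[(v.chrom, v.pos, v.alt, v.sample_id)] = "normal_artifact"

    intronic_hosts = [h for h in hosts if h.n_exons >= 2]
    for i in range(config.n_intronic_variants):
        host = intronic_hosts[i % len(intronic_hosts)]
        j = int(rng.integers(0, host.n_exons - 1))
        intron_start, intron_end = host.exons[j].end, host.exons[j + 1].start
        if intron_end <= intron_start:
            continue
        pos0 = int(rng.integers(intron_start, intron_end))
        if (host.chrom, pos0) in used_positions:
            continue
        used_positions.add((host.chrom, pos0))
        cov, alt_count = _variant_depths(rng)
        v = _record(genome, host.chrom, pos0, random_alt(host.chrom, pos0),
                    _tumor_sample(rng, config), cov, alt_count)
        variants.append(v)
        truth.variant_labels[(v.chrom, v.pos, v.alt, v.sample_id)] = "intronic"

    # clustered novel variants forming mutation hotspots
    cluster_hosts = [h for h in hosts if any(e.length >= 90 for e in h.exons)]
    for c in range(config.n_hotspot_clusters):
        host = cluster_hosts[c % len(cluster_hosts)]
        exon = next(e for e in host.exons if e.length >= 90)
        base = exon.start + int(rng.integers(0, exon.length - 70))
        offsets = rng.choice(70, size=8, replace=False)
        for off in sorted(int(o) for o in offsets):
            pos0 = base + off
            if (host.chrom, pos0) in used_positions:
                continue
            used_positions.add((host.chrom, pos0))
            cov, alt_count = _variant_depths(rng)
            v = _record(genome, host.chrom, pos0, random_alt(host.chrom, pos0),
                        _tumor_sample(rng, config), cov, alt_count)
            variants.append(v)
            truth.variant_labels[(v.chrom, v.pos, v.alt, v.sample_id)] = "hotspot_cluster"

    dbsnp_sites = {v.key for v in variants if v.known_polymorphism}
    normal_sites = {v.key for v in variants if v.in_normal}

    pileup = [
        PileupSite(chrom=v.chrom, pos=v.pos, ref=v.ref, sample_id=v.sample_id,
                   counts={b: 0 for b in "ACGT"} | {v.ref: v.coverage - round(v.vaf * v.coverage),
                                                    v.alt: round(v.vaf * v.coverage)})
        for v in variants
    ]
    for i in range(config.n_subthreshold_sites):
        host = hosts[i % len(hosts)]
        pos0 = random_exonic(host)
        ref = chr(genome[host.chrom][pos0]).upper()
        alt = random_alt(host.chrom, pos0)
        if i % 2 == 0:
            cov, alt_count = 7, 3  # coverage below the calling threshold
        else:
            cov, alt_count = 30, 3  # VAF 0.1 below the calling threshold
        pileup.append(PileupSite(chrom=host.chrom, pos=pos0 + 1, ref=ref,
                                 sample_id=_tumor_sample(rng, config),
                                 counts={b: 0 for b in "ACGT"} | {ref: cov - alt_count,
                                                                  alt: alt_count}))
    return variants, pileup, dbsnp_sites, normal_sites


# ---------------------------------------------------------------------------
# training corpora + calibration matrices

def simulate_training_corpora(config: SimulationConfig, rng, n_coding=None, n_noncoding=None):
    """Coding / non-coding training sequences drawn from the same sequence
    models that emit transcript sequences."""
    n_coding = config.n_train_coding if n_coding is None else n_coding
    n_noncoding = config.n_train_noncoding if n_noncoding is None else n_noncoding
    coding = [
        _coding_like_sequence(rng, int(rng.integers(350, 900)), config.hexamer_divergence)
        for _ in range(n_coding)
    ]
    noncoding = [_noncoding_sequence(rng, int(rng.integers(250, 900)))
                 for _ in range(n_noncoding)]
    return coding, noncoding


def simulate_de_matrix(n_features: int, n_a: int, n_b: int, effect_size: float,
                       n_de: int, rng) -> tuple:
    """Subtype-labelled FPKM matrix for differential-expression calibration.

    Log-normal(0, 1) baseline; the first ``n_de`` features are multiplied by
    ``effect_size`` in the A-labelled samples.  Returns (ExpressionMatrix,
    planted feature ids).
    """
    samples = [f"S{i + 1:03d}" for i in range(n_a + n_b)]
    features = [f"F{i + 1:04d}" for i in range(n_features)]
    mat = rng.lognormal(0.0, 1.0, size=(n_features, n_a + n_b))
    mat[:n_de, :n_a] *= effect_size
    values = pd.DataFrame(mat, index=features, columns=samples)
    groups = pd.Series(["tumor"] * len(samples), index=samples)
    subtypes = pd.Series(["ABC"] * n_a + ["GCB"] * n_b, index=samples)
    return ExpressionMatrix(values=values, groups=groups, subtypes=subtypes), features[:n_de]


# ---------------------------------------------------------------------------
# orchestration

def simulate_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Generate the full fixture set from one config (one seed)."""
    config = config or SimulationConfig()
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(8)
    rng_genome, rng_features, rng_expr, rng_te, rng_enh, rng_var, rng_train, _rng_spare = (
        np.random.default_rng(s) for s in streams
    )
    genome_ba, chrom_sizes, known, assembly, truth = simulate_genome_and_assembly(
        config, rng_genome, rng_features
    )
    gene_ids = sorted({t.locus_id or t.transcript_id for t in known})
    expression = simulate_expression(config, assembly, gene_ids, truth, rng_expr)

    primaries = [t for t in assembly
                 if truth.transcript_class[t.transcript_id] == TRUE_LNCRNA
                 and "_i" not in t.transcript_id]
    te_elements = simulate_te_elements(config, primaries, chrom_sizes, truth, rng_te)
    loci_spans = [t.span for t in primaries]
    enhancers = simulate_enhancers(config, loci_spans, chrom_sizes, truth, rng_enh)
    coverage = simulate_coverage(config, primaries)
    variants, pileup, dbsnp_sites, normal_sites = simulate_variants(
        config, primaries, genome_ba, truth, rng_var
    )
    coding_train, noncoding_train = simulate_training_corpora(config, rng_train)

    gene_sets = _make_gene_sets(gene_ids, truth, rng_train)
    genome = {c: bytes(b).decode() for c, b in genome_ba.items()}
    return SyntheticDataset(
        config=config, genome=genome, chrom_sizes=chrom_sizes, known=known,
        assembly=assembly, expression=expression, te_elements=te_elements,
        enhancers=enhancers, variants=variants, pileup=pileup,
        dbsnp_sites=dbsnp_sites, normal_sites=normal_sites, coverage=coverage,
        coding_train=coding_train, noncoding_train=noncoding_train,
        gene_sets=gene_sets, truth=truth,
    )


def _make_gene_sets(gene_ids, truth: GroundTruth, rng) -> dict:
    """GMT-style sets over known genes: one set collecting the planted
    co-expression partners plus random sets."""
    sets = {}
    partners = sorted({gid for _tid, gid in truth.coexpressed_pairs})
    if partners:
        sets["PLANTED_PARTNER_PROGRAM"] = partners
    ids = list(gene_ids)
    for i in range(4):
        size = min(len(ids), max(5, len(ids) // 4))
        members = sorted(rng.choice(ids, size=size, replace=False).tolist())
        sets[f"RANDOM_SET_{i + 1}"] = members
    return sets


def write_dataset(ds: SyntheticDataset, outdir) -> dict:
    """Write every fixture (and the ground truth) to ``outdir``; returns the
    path map."""
    import os

    from . import io as lio

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genome_fasta": os.path.join(outdir, "genome.fa"),
        "known_gtf": os.path.join(outdir, "known.gtf"),
        "assembly_gtf": os.path.join(outdir, "assembly.gtf"),
        "expression_tsv": os.path.join(outdir, "expression.tsv"),
        "groups_tsv": os.path.join(outdir, "sample_groups.tsv"),
        "te_bed": os.path.join(outdir, "te_elements.bed"),
        "enhancer_bed": os.path.join(outdir, "enhancers.bed"),
        "chrom_sizes": os.path.join(outdir, "genome.sizes"),
        "coverage_bedgraph": os.path.join(outdir, "h3k4me3_like.bedgraph"),
        "variants_tsv": os.path.join(outdir, "variants.tsv"),
        "pileup_tsv": os.path.join(outdir, "pileup.tsv"),
        "dbsnp_tsv": os.path.join(outdir, "dbsnp_like.tsv"),
        "normals_tsv": os.path.join(outdir, "normal_variants.tsv"),
        "coding_train_fasta": os.path.join(outdir, "train_coding.fa"),
        "noncoding_train_fasta": os.path.join(outdir, "train_noncoding.fa"),
        "gene_sets_gmt": os.path.join(outdir, "gene_sets.gmt"),
        "truth_transcripts": os.path.join(outdir, "ground_truth_transcripts.tsv"),
        "truth_variants": os.path.join(outdir, "ground_truth_variants.tsv"),
    }
    lio.write_fasta(ds.genome, paths["genome_fasta"])
    lio.write_gtf(ds.known, paths["known_gtf"])
    lio.write_gtf(ds.assembly, paths["assembly_gtf"])
    lio.write_expression(ds.expression, paths["expression_tsv"], paths["groups_tsv"])
    lio.write_bed(ds.te_elements, paths["te_bed"])
    lio.write_bed(ds.enhancers, paths["enhancer_bed"])
    lio.write_chrom_sizes(ds.chrom_sizes, paths["chrom_sizes"])
    lio.write_bedgraph(ds.coverage, paths["coverage_bedgraph"])
    lio.write_variant_table(ds.variants, paths["variants_tsv"])
    lio.write_pileup(ds.pileup, paths["pileup_tsv"])
    lio.write_position_set(ds.dbsnp_sites, paths["dbsnp_tsv"])
    lio.write_position_set(ds.normal_sites, paths["normals_tsv"])
    lio.write_fasta({f"cod{i}": s for i, s in enumerate(ds.coding_train)},
                    paths["coding_train_fasta"])
    lio.write_fasta({f"non{i}": s for i, s in enumerate(ds.noncoding_train)},
                    paths["noncoding_train_fasta"])
    lio.write_gene_sets(ds.gene_sets, paths["gene_sets_gmt"])
    truth_tx = pd.DataFrame(
        {
            "transcript_id": list(ds.truth.transcript_class),
            "class": list(ds.truth.transcript_class.values()),
            "subtype": [ds.truth.subtype_label.get(t, "") for t in ds.truth.transcript_class],
            "expression_class": [ds.truth.expression_class.get(t, "")
                                 for t in ds.truth.transcript_class],
            "divergent": [t in ds.truth.divergent for t in ds.truth.transcript_class],
        }
    )
    truth_tx.to_csv(paths["truth_transcripts"], sep="\t", index=False)
    truth_var = pd.DataFrame(
        [{"chrom": c, "pos": p, "alt": a, "sample_id": s, "label": label}
         for (c, p, a, s), label in ds.truth.variant_labels.items()]
    )
    truth_var.to_csv(paths["truth_variants"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# generator self-audit

def audit_dataset(ds: SyntheticDataset, max_fold_checks: int = 20) -> list:
    """Verify that every planted label is realized by construction.

    Returns a list of problem descriptions (empty when the dataset is
    internally consistent).  Fold-based labels are re-verified on a capped
    subsample to keep the audit cheap; the full set is exercised by the
    pipeline itself.
    """
    from .expression import flag_outliers
    from .mutation import apply_mutations, call_variants

    problems = []
    by_id = ds.transcripts_by_id()
    tumor_cols = ds.expression.samples_in("tumor")
    known_exons = merge_intervals(e for t in ds.known for e in t.exons)

    for tid, label in ds.truth.transcript_class.items():
        tx = by_id[tid]
        seq = spliced_sequence(tx, ds.genome)
        orf_len, _ = find_longest_orf(seq)
        tumor_expressed = int((ds.expression.values.loc[tid, tumor_cols] > 0.1).sum())
        if label == TRUE_LNCRNA:
            if tx.exonic_length < 200:
                problems.append(f"{tid}: true lncRNA shorter than 200 nt")
            if tx.n_exons < 2:
                problems.append(f"{tid}: true lncRNA is mono-exonic")
            if orf_len >= 150:
                problems.append(f"{tid}: true lncRNA carries a long ORF ({orf_len})")
            if tumor_expressed < 2:
                problems.append(f"{tid}: true lncRNA not tumor-expressed")
            from .intervals import covered_bases

            if any(covered_bases(e, known_exons) for e in tx.exons):
                problems.append(f"{tid}: true lncRNA overlaps known annotation")
        elif label == CODING_DECOY and orf_len < 300:
            problems.append(f"{tid}: coding decoy ORF only {orf_len} nt")
        elif label == SHORT_DECOY and tx.exonic_length >= 200:
            problems.append(f"{tid}: short decoy has length {tx.exonic_length}")
        elif label == MONOEXONIC_DECOY and tx.n_exons != 1:
            problems.append(f"{tid}: mono-exonic decoy has {tx.n_exons} exons")
        elif label == LOW_EXPRESSION_DECOY and tumor_expressed > 1:
            problems.append(f"{tid}: low-expression decoy expressed in {tumor_expressed} tumors")

    gene_bodies = {}
    for t in ds.known:
        gid = t.locus_id or t.transcript_id
        body = gene_bodies.get(gid)
        start = min(t.start, body.start) if body else t.start
        end = max(t.end, body.end) if body else t.end
        gene_bodies[gid] = GenomicInterval(t.chrom, start, end, t.strand)
    for tid, gid in ds.truth.divergent_pairs:
        tx, body = by_id[tid], gene_bodies[gid]
        if tx.first_exon.distance_to(body) > 2000:
            problems.append(f"{tid}: planted divergent pair farther than 2 kb")
        if tx.strand == body.strand:
            problems.append(f"{tid}: planted divergent pair not antisense")

    flagged = set(flag_outliers(ds.expression, list(ds.truth.transcript_class), group="tumor",
                                k=ds.config.outlier_sd_multiplier))
    if flagged != set(ds.truth.outliers):
        problems.append(
            f"outlier recovery mismatch: planted {sorted(ds.truth.outliers)}, "
            f"flagged {sorted(flagged)}"
        )

    variant_by_key = {(v.chrom, v.pos, v.alt, v.sample_id): v for v in ds.variants}
    for label, accept in (("stabilizing", lambda d: d > 0), ("neutral", lambda d: d == 0)):
        keys = ds.truth.variants_with_label(label)[:max_fold_checks]
        for key in keys:
            v = variant_by_key[key]
            host = next(
                t for t in ds.assembly
                if ds.truth.transcript_class[t.transcript_id] == TRUE_LNCRNA
                and "_i" not in t.transcript_id
                and t.chrom == v.chrom
                and any(e.start <= v.pos - 1 < e.end for e in t.exons)
            )
            native, mutated = apply_mutations(host, ds.genome, [v])
            delta = fold_mfe(native).mfe - fold_mfe(mutated).mfe
            if not accept(delta):
                problems.append(f"{key}: {label} variant has delta {delta}")

    called = {(c.chrom, c.pos, c.alt, c.sample_id)
              for c in call_variants(ds.pileup, min_coverage=8, min_vaf=0.2)}
    planted = set(variant_by_key)
    if called != planted:
        problems.append(
            f"pileup/variant mismatch: {len(called - planted)} extra calls, "
            f"{len(planted - called)} missed"
        )
    return problems
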