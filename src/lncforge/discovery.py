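"""The novel-lncRNA filter cascade and its companion classifications.

Stages, in fixed cascade order:

1. ``known_overlap`` — drop any transcript sharing >= 1 exonic bp with the
   known annotation, on either strand;
2. ``coding`` — drop transcripts whose coding-potential score reaches the
   model threshold (default 0.364; the boundary itself counts as coding);
3. ``length`` — keep exonic length >= 200 nt;
4. ``exon_count`` — keep transcripts with >= 2 exons;
5. ``expression`` — keep transcripts with FPKM strictly > 0.1 in at least
   two samples of the designated group (tumor by default).

Every transcript is attributed its first failing stage; retained
transcripts are grouped into loci by single-linkage exonic overlap on the
same chromosome and strand, and divergent lncRNAs are called as those whose
first exon lies within 2 kb of a protein-coding gene body and whose strand
is antisense to that nearest gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coding import CodingPotentialModel, compute_features
from .intervals import (
    MINUS,
    PLUS,
    UNSTRANDED,
    GenomicInterval,
    TranscriptModel,
    ValidationError,
    merge_intervals,
)

STAGE_ORDER = ("known_overlap", "coding", "length", "exon_count", "expression")


@dataclass
class FilterReport:
    """Per-transcript stage outcomes plus the final retained set."""

    table: pd.DataFrame
    retained: list
    locus_assignment: dict
    n_loci: int

    def first_fail(self, transcript_id: str):
        return self.table.loc[transcript_id, "first_fail"]


def _exonic_overlap_bp(transcript: TranscriptModel, merged: dict) -> int:
    from .intervals import covered_bases

    return sum(covered_bases(exon, merged) for exon in transcript.exons)


def subtract_known(transcripts, known_annotation):
    """Partition transcripts into (novel, excluded) by strand-blind exonic overlap.

    A transcript is excluded iff any of its exons overlaps (>= 1 bp) any exon
    of any known transcript, regardless of strand.
    """
    merged = merge_intervals(e for tx in known_annotation for e in tx.exons)
    novel, excluded = [], []
    for tx in transcripts:
        if _exonic_overlap_bp(tx, merged) > 0:
            excluded.append(tx)
        else:
            novel.append(tx)
    return novel, excluded


def filter_cascade(
    transcripts,
    sequences,
    model: CodingPotentialModel,
    expression,
    known=(),
    group: str = "tumor",
    min_length: int = 200,
    min_exons: int = 2,
    min_fpkm: float = 0.1,
    min_samples: int = 2,
) -> FilterReport:
    """Run the full filter cascade and report every stage outcome.

    ``sequences`` maps transcript_id -> spliced sequence; ``expression`` is
    an :class:`~lncforge.expression.ExpressionMatrix` whose features include
    every transcript id.
    """
    missing = [t.transcript_id for t in transcripts if t.transcript_id not in sequences]
    if missing:
        raise ValidationError(f"transcripts without sequence: {missing[:10]}")
    missing = [
        t.transcript_id for t in transcripts if t.transcript_id not in expression.values.index
    ]
    if missing:
        raise ValidationError(f"transcripts absent from expression matrix: {missing[:10]}")
    group_samples = expression.samples_in(group)
    if not group_samples:
        raise ValidationError(f"no samples in group {group!r}")
    known_merged = merge_intervals(e for tx in known for e in tx.exons)

    rows = []
    retained = []
    for tx in transcripts:
        tid = tx.transcript_id
        overlap_bp = _exonic_overlap_bp(tx, known_merged)
        feats = compute_features(sequences[tid], model.hexamer_logratio)
        score = model.score(feats)
        length = tx.exonic_length
        n_exons = tx.n_exons
        values = expression.values.loc[tid, group_samples].to_numpy(dtype=float)
        n_expressed = int(np.sum(values > min_fpkm))
        passes = {
            "known_overlap": overlap_bp == 0,
            "coding": score < model.threshold,
            "length": length >= min_length,
            "exon_count": n_exons >= min_exons,
            "expression": n_expressed >= min_samples,
        }
        first_fail = next((s for s in STAGE_ORDER if not passes[s]), None)
        if first_fail is None:
            retained.append(tx)
        rows.append(
            {
                "transcript_id": tid,
                "known_overlap_bp": overlap_bp,
                "coding_score": score,
                "orf_length": feats.orf_length,
                "fickett_score": feats.fickett_score,
                "hexamer_bias": feats.hexamer_bias,
                "exonic_length": length,
                "n_exons": n_exons,
                "n_expressed_samples": n_expressed,
                **{f"pass_{s}": passes[s] for s in STAGE_ORDER},
                "first_fail": first_fail,
                "retained": first_fail is None,
            }
        )
    table = pd.DataFrame(rows).set_index("transcript_id")
    assignment = group_loci(retained)
    return FilterReport(
        table=table,
        retained=retained,
        locus_assignment=assignment,
        n_loci=len(set(assignment.values())),
    )


def group_loci(transcripts) -> dict:
    """Single-linkage locus grouping by >= 1 bp exonic overlap.

    Two transcripts share a locus iff they are on the same chromosome and
    strand and their exons overlap by at least one base, transitively
    closed.  Locus ids are assigned deterministically in order of
    (chromosome, leftmost start, strand).
    """
    parent = {t.transcript_id: t.transcript_id for t in transcripts}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    by_key: dict[tuple, list] = {}
    for tx in transcripts:
        by_key.setdefault((tx.chrom, tx.strand), []).append(tx)
    for group in by_key.values():
        exons = sorted(
            (e.start, e.end, tx.transcript_id) for tx in group for e in tx.exons
        )
        run_max_end = -1
        run_anchor = None
        for start, end, tid in exons:
            if run_anchor is not None and start < run_max_end:
                union(run_anchor, tid)
            else:
                run_anchor = tid
            run_max_end = max(run_max_end, end)

    clusters: dict[str, list] = {}
    for tx in transcripts:
        clusters.setdefault(find(tx.transcript_id), []).append(tx)
    ordered = sorted(
        clusters.values(),
        key=lambda txs: (txs[0].chrom, min(t.start for t in txs), txs[0].strand),
    )
    assignment = {}
    for i, txs in enumerate(ordered, start=1):
        locus_id = f"LNCLOC_{i:05d}"
        for tx in txs:
            assignment[tx.transcript_id] = locus_id
            tx.locus_id = locus_id
    return assignment


def isoform_counts(locus_assignment: dict) -> pd.Series:
    """Transcripts per locus, indexed by locus id."""
    return pd.Series(locus_assignment).value_counts().sort_index()


def classify_divergent(lncRNAs, known_genes, max_distance: int = 2000) -> list:
    """Divergently transcribed lncRNAs relative to protein-coding genes.

    Step 1: the lncRNA's first exon (5'-most in transcript orientation)
    lies within ``max_distance`` bp of the nearest protein-coding gene body.
    Step 2: the lncRNA strand is antisense to that nearest gene's strand.
    Unstranded lncRNAs are skipped with a warning.  Gene bodies are the
    genomic spans of known transcripts grouped by ``locus_id`` (gene id).
    """
    genes: dict[str, list] = {}
    for tx in known_genes:
        gid = tx.locus_id or tx.transcript_id
        genes.setdefault(gid, []).append(tx)
    gene_bodies = []
    for gid, txs in sorted(genes.items()):
        chrom = txs[0].chrom
        strand = txs[0].strand
        start = min(t.start for t in txs)
        end = max(t.end for t in txs)
        gene_bodies.append((gid, GenomicInterval(chrom, start, end, strand)))

    divergent = []
    for tx in lncRNAs:
        if tx.strand == UNSTRANDED:
            warnings.warn(f"{tx.transcript_id}: unstranded lncRNA skipped in divergent call")
            continue
        first = tx.first_exon
        best = None
        for gid, body in gene_bodies:
            if body.chrom != first.chrom:
                continue
            dist = first.distance_to(body)
            if best is None or dist < best[0] or (dist == best[0] and body.start < best[2].start):
                best = (dist, gid, body)
        if best is None:
            continue
        dist, _gid, body = best
        if dist <= max_distance and (
            (tx.strand == PLUS and body.strand == MINUS)
            or (tx.strand == MINUS and body.strand == PLUS)
        ):
            divergent.append(tx)
    return divergent
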