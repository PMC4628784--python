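"""Genomic-context statistics: interval overlap joins, transposable-element
architecture, super-enhancer permutation enrichment and TSS coverage
metaprofiles.

The TE summary computes, per transcript, whether any exon overlaps a TE (at
a 1 bp and a 10 bp overlap threshold), the TE-derived percentage (fraction
of exonic bases covered by the union of TE intervals) and whether the first
and last exons — in transcript orientation — carry a TE.  The permutation
test re-places every target uniformly at random on its own chromosome,
preserving length, and uses the add-one empirical p-value estimator, so the
smallest attainable p with N shuffles is 1/(N+1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import (
    MINUS,
    UNSTRANDED,
    CoverageTrack,
    GenomicInterval,
    ValidationError,
    covered_bases,
    merge_intervals,
)


@dataclass
class PermutationTestResult:
    observed_count: int
    null_counts: np.ndarray
    n_shuffles: int

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_counts))

    @property
    def empirical_p(self) -> float:
        return (1 + int(np.sum(self.null_counts >= self.observed_count))) / (1 + self.n_shuffles)


@dataclass
class TssProfile:
    halfwidth: int
    values: np.ndarray  # mean coverage at offsets -halfwidth..+halfwidth
    n_transcripts: int

    def offsets(self) -> np.ndarray:
        return np.arange(-self.halfwidth, self.halfwidth + 1)


def overlap_join(set_a, set_b, min_bp: int = 1, stranded: bool = False) -> list:
    """All pairs (index_a, index_b, overlap_bp) with overlap >= ``min_bp``.

    Strand is ignored unless ``stranded`` is set, in which case only
    same-strand pairs are reported (unstranded matches everything).
    """
    by_chrom: dict[str, list] = {}
    for j, iv in enumerate(set_b):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, iv.strand, j))
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    pairs = []
    for i, a in enumerate(set_a):
        if a.chrom not in by_chrom:
            continue
        for start, end, strand, j in by_chrom[a.chrom]:
            if start >= a.end:
                break
            ov = min(a.end, end) - max(a.start, start)
            if ov < min_bp:
                continue
            if stranded and UNSTRANDED not in (a.strand, strand) and a.strand != strand:
                continue
            pairs.append((i, j, ov))
    return pairs


def te_summary(transcripts, te_elements, min_bp: int = 1, exclude=None) -> pd.DataFrame:
    """Per-transcript TE architecture summary.

    ``exclude`` optionally filters TE elements by a predicate (e.g. to drop
    low-complexity or satellite repeats when the caller's TE set carries
    class annotations); by default all elements are used.  Base coverage is
    computed on the union of TE intervals, so overlapping TE copies never
    double-count.
    """
    if exclude is not None:
        te_elements = [te for te in te_elements if not exclude(te)]
    merged = merge_intervals(te_elements)
    by_chrom: dict[str, list] = {}
    for te in te_elements:
        by_chrom.setdefault(te.chrom, []).append(te)

    def exon_max_single_overlap(exon: GenomicInterval) -> int:
        best = 0
        for te in by_chrom.get(exon.chrom, ()):
            best = max(best, exon.overlap_length(te))
        return best

    rows = []
    for tx in transcripts:
        covered = sum(covered_bases(exon, merged) for exon in tx.exons)
        length = tx.exonic_length
        per_exon_best = [exon_max_single_overlap(exon) for exon in tx.exons]
        first_idx = tx.exons.index(tx.first_exon)
        last_idx = tx.exons.index(tx.last_exon)
        rows.append(
            {
                "transcript_id": tx.transcript_id,
                "n_exons": tx.n_exons,
                "exonic_length": length,
                "te_covered_bases": covered,
                "te_derived_percent": 100.0 * covered / length,
                "any_overlap_1bp": max(per_exon_best, default=0) >= 1,
                "any_overlap_10bp": max(per_exon_best, default=0) >= 10,
                "any_overlap_min_bp": max(per_exon_best, default=0) >= min_bp,
                "first_exon_te": per_exon_best[first_idx] >= min_bp,
                "last_exon_te": per_exon_best[last_idx] >= min_bp,
            }
        )
    return pd.DataFrame(rows).set_index("transcript_id")


def exon_position_te_test(summaries: pd.DataFrame):
    """Pooled 2x2 chi-square of TE overlap in first versus last exons.

    Rows of the table are exon position (first / last), columns TE overlap
    (yes / no), pooled over multi-exon transcripts; Pearson chi-square
    without continuity correction.  A zero margin yields p = 1 with a
    warning.  Returns (statistic, p_value, table).
    """
    multi = summaries[summaries["n_exons"] >= 2]
    if len(multi) < 2:
        raise ValidationError("chi-square test requires >= 2 multi-exon transcripts")
    first_yes = int(multi["first_exon_te"].sum())
    last_yes = int(multi["last_exon_te"].sum())
    n = len(multi)
    table = np.array([[first_yes, n - first_yes], [last_yes, n - last_yes]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("degenerate first/last TE table (zero margin); p = 1")
        return 0.0, 1.0, table
    stat, p, _df, _exp = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p), table


def _merged_query_index(query_loci):
    """Per-chromosome merged query intervals with prefix-max ends for fast
    any-overlap queries."""
    merged = merge_intervals(query_loci)
    index = {}
    for chrom, (starts, ends) in merged.items():
        index[chrom] = (starts, np.maximum.accumulate(ends))
    return index


def _count_overlapping(index, chroms, starts, ends) -> int:
    """Number of (chrom, start, end) targets overlapping >= 1 query base."""
    count = 0
    for chrom in np.unique(chroms):
        mask = chroms == chrom
        if chrom not in index:
            continue
        qstarts, qmax_ends = index[chrom]
        s, e = starts[mask], ends[mask]
        idx = np.searchsorted(qstarts, e, side="left") - 1
        hit = (idx >= 0) & (qmax_ends[np.clip(idx, 0, None)] > s)
        count += int(hit.sum())
    return count


def shuffle_enrichment(
    query_loci,
    targets,
    chrom_sizes,
    n: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    same_chromosome: bool = True,
) -> PermutationTestResult:
    """Permutation enrichment of targets (e.g. super-enhancers) in query loci.

    The observed statistic is the number of targets overlapping at least one
    query locus by >= 1 bp.  Each shuffle re-places every target uniformly
    at random, preserving its length — on its own chromosome by default, or
    anywhere in the genome (chromosome drawn proportionally to length) with
    ``same_chromosome=False``.  Overlaps among shuffled targets are allowed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    for t in targets:
        if t.chrom not in chrom_sizes:
            raise ValidationError(f"target chromosome {t.chrom} missing from chrom_sizes")
        if t.length > chrom_sizes[t.chrom]:
            raise ValidationError(f"target longer than chromosome {t.chrom}")
    index = _merged_query_index(query_loci)
    t_chroms = np.array([t.chrom for t in targets])
    t_lengths = np.array([t.length for t in targets], dtype=np.int64)
    t_starts = np.array([t.start for t in targets], dtype=np.int64)
    observed = _count_overlapping(index, t_chroms, t_starts, t_starts + t_lengths)

    chrom_names = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chrom_names], dtype=np.float64)
    null_counts = np.empty(n, dtype=np.int64)
    for rep in range(n):
        if same_chromosome:
            chroms = t_chroms
        else:
            picks = rng.choice(len(chrom_names), size=len(targets), p=sizes / sizes.sum())
            chroms = np.array([chrom_names[i] for i in picks])
        limits = np.array([chrom_sizes[c] for c in chroms], dtype=np.int64) - t_lengths
        starts = rng.integers(0, limits + 1)
        null_counts[rep] = _count_overlapping(index, chroms, starts, starts + t_lengths)
    return PermutationTestResult(observed_count=observed, null_counts=null_counts, n_shuffles=n)


def tss_metaprofile(transcripts, coverage: CoverageTrack, halfwidth: int = 2000) -> TssProfile:
    """Strand-oriented mean coverage around transcript start sites.

    The TSS is the 5' end of the transcript; minus-strand windows are
    reversed so positive offsets are always downstream of the TSS.
    Positions falling outside the covered genome contribute zeros and stay
    in the denominator, keeping the per-offset sample size constant.
    Unstranded transcripts are skipped with a warning.
    """
    offsets = np.arange(-halfwidth, halfwidth + 1)
    total = np.zeros(offsets.shape, dtype=np.float64)
    used = 0
    for tx in transcripts:
        if tx.strand == UNSTRANDED:
            warnings.warn(f"{tx.transcript_id}: unstranded transcript skipped in TSS profile")
            continue
        if tx.strand == MINUS:
            tss = tx.exons[-1].end - 1
            positions = tss - offsets
        else:
            tss = tx.exons[0].start
            positions = tss + offsets
        values = np.zeros(offsets.shape, dtype=np.float64)
        inside = positions >= 0
        values[inside] = coverage.values_at(tx.chrom, positions[inside])
        total += values
        used += 1
    if used == 0:
        raise ValidationError("no stranded transcripts for TSS profile")
    return TssProfile(halfwidth=halfwidth, values=total / used, n_transcripts=used)
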