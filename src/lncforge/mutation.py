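"""SNV calling from pileup summaries, variant filtering, mutation-hotspot
scanning, transcript mutagenesis, and the native-versus-mutated MFE
comparison.

Variant calls use simple coverage and allele-fraction thresholds (default:
total coverage >= 8 and variant allele fraction >= 0.2).  Hotspots are
maximal merged runs of 100-bp windows holding at least six variant
occurrences, counting multiplicity across samples.  The stabilization
analysis folds each transcript natively and with one substitution applied
and reports delta = MFE(native) - MFE(mutated); positive deltas mean the
mutation stabilizes the structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .folding import DEFAULT_MODEL, EnergyModel, fold_mfe
from .intervals import (
    MINUS,
    TranscriptModel,
    ValidationError,
    VariantRecord,
    merge_intervals,
    revcomp,
    spliced_sequence,
)

BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class PileupSite:
    """Per-base read counts at one genomic site in one sample (pos 1-based)."""

    chrom: str
    pos: int
    ref: str
    sample_id: str
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.ref not in BASES:
            raise ValidationError(f"{self.chrom}:{self.pos}: ref base {self.ref!r} not in ACGT")
        for base in BASES:
            if self.counts.get(base, 0) < 0:
                raise ValidationError(f"{self.chrom}:{self.pos}: negative count for {base}")

    @property
    def coverage(self) -> int:
        return sum(self.counts.get(b, 0) for b in BASES)


@dataclass
class Hotspot:
    chrom: str
    start: int  # 0-based half-open genomic interval of the merged windows
    end: int
    mutation_count: int


@dataclass
class DeltaMfe:
    transcript_id: str
    variant: VariantRecord | None
    mfe_native: float
    mfe_mutated: float

    @property
    def delta(self) -> float:
        """Positive when the mutated structure is more stable."""
        return self.mfe_native - self.mfe_mutated


def call_variants(
    pileup_sites: Sequence[PileupSite],
    min_coverage: int = 8,
    min_vaf: float = 0.2,
) -> list:
    """Threshold SNV calling: one record per non-reference base passing both
    the coverage and the allele-fraction cutoffs (both inclusive)."""
    calls = []
    for site in pileup_sites:
        coverage = site.coverage
        if coverage < min_coverage or coverage == 0:
            continue
        for base in BASES:
            if base == site.ref:
                continue
            count = site.counts.get(base, 0)
            if count <= 0:
                continue
            vaf = count / coverage
            if vaf >= min_vaf:
                calls.append(
                    VariantRecord(
                        chrom=site.chrom,
                        pos=site.pos,
                        ref=site.ref,
                        alt=base,
                        sample_id=site.sample_id,
                        coverage=coverage,
                        vaf=vaf,
                    )
                )
    return calls


def filter_variants(
    variants: Sequence[VariantRecord],
    lncRNA_transcripts: Sequence[TranscriptModel],
    known_polymorphisms: set | None = None,
    normal_variants: set | None = None,
) -> list:
    """Tumor-specific novel exonic variants.

    Keeps a variant iff its position falls inside an exon of a retained
    lncRNA, it is not a known polymorphism (record flag or membership of
    ``known_polymorphisms``), and it was not seen in normal samples (record
    flag or membership of ``normal_variants``).  Both sets hold
    (chrom, pos, alt) keys with 1-based positions.
    """
    known_polymorphisms = known_polymorphisms or set()
    normal_variants = normal_variants or set()
    exon_index = merge_intervals(e for tx in lncRNA_transcripts for e in tx.exons)
    kept = []
    for v in variants:
        if v.known_polymorphism or v.key in known_polymorphisms:
            continue
        if v.in_normal or v.key in normal_variants:
            continue
        if not _position_in_exons(v.chrom, v.pos - 1, exon_index):
            continue
        kept.append(v)
    return kept


def _position_in_exons(chrom: str, pos0: int, merged: dict) -> bool:
    if chrom not in merged:
        return False
    starts, ends = merged[chrom]
    i = np.searchsorted(starts, pos0, side="right") - 1
    return i >= 0 and pos0 < ends[i]


def hotspot_scan(
    variants: Sequence[VariantRecord], window: int = 100, min_count: int = 6
) -> list:
    """Sliding-window mutation hotspots.

    A window of ``window`` bp (slid by 1 bp) qualifies when it holds at
    least ``min_count`` variant occurrences, counting multiplicity across
    samples.  Overlapping qualifying windows are merged into maximal
    :class:`Hotspot` intervals whose ``mutation_count`` is the maximum
    single-window count within the run.  Output is independent of input
    order.
    """
    by_chrom: dict[str, list] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v.pos - 1)
    hotspots = []
    for chrom in sorted(by_chrom):
        positions = np.array(sorted(by_chrom[chrom]), dtype=np.int64)
        m = len(positions)
        if m < min_count:
            continue
        # window start range [positions[i+min_count-1] - window + 1, positions[i]]
        # qualifies whenever the i-th and (i+min_count-1)-th occurrences fit in
        # one window
        runs = []  # qualifying start intervals [lo, hi] inclusive
        for i in range(m - min_count + 1):
            far = positions[i + min_count - 1]
            lo = far - window + 1
            hi = positions[i]
            if lo <= hi:
                runs.append((int(lo), int(hi)))
        if not runs:
            continue
        runs.sort()
        merged_runs = [list(runs[0])]
        for lo, hi in runs[1:]:
            # runs of qualifying starts whose windows strictly overlap merge
            if lo <= merged_runs[-1][1] + window - 1:
                merged_runs[-1][1] = max(merged_runs[-1][1], hi)
            else:
                merged_runs.append([lo, hi])
        window_counts = np.searchsorted(positions, positions + window, side="left") - np.arange(m)
        for lo, hi in merged_runs:
            in_run = (positions >= lo) & (positions <= hi)
            count = int(window_counts[in_run].max()) if in_run.any() else min_count
            hotspots.append(
                Hotspot(chrom=chrom, start=max(0, lo), end=hi + window, mutation_count=count)
            )
    return hotspots


def _transcript_offset(transcript: TranscriptModel, genomic_pos0: int) -> int:
    """Map a genomic position (0-based) inside an exon to the transcript
    coordinate (5'->3')."""
    offset = 0
    plus_offset = None
    for exon in transcript.exons:
        if exon.start <= genomic_pos0 < exon.end:
            plus_offset = offset + (genomic_pos0 - exon.start)
            break
        offset += exon.length
    if plus_offset is None:
        raise ValidationError(
            f"{transcript.transcript_id}: position {genomic_pos0 + 1} not exonic"
        )
    if transcript.strand == MINUS:
        return transcript.exonic_length - 1 - plus_offset
    return plus_offset


def apply_mutations(
    transcript: TranscriptModel,
    genome: Mapping[str, str],
    variants: Sequence[VariantRecord],
) -> tuple[str, str]:
    """(native, mutated) spliced transcript sequences.

    Substitutions are applied in genomic space before splicing; each
    variant's reference base must match the genome (guards against fixture
    or genome drift) and must fall in an exon of the transcript.
    """
    native = spliced_sequence(transcript, genome)
    mutated = list(native)
    chrom_seq = genome[transcript.chrom]
    for v in variants:
        if v.chrom != transcript.chrom:
            raise ValidationError(
                f"variant {v.chrom}:{v.pos} not on transcript chromosome {transcript.chrom}"
            )
        pos0 = v.pos - 1
        if chrom_seq[pos0].upper() != v.ref:
            raise ValidationError(
                f"reference mismatch at {v.chrom}:{v.pos}: genome has "
                f"{chrom_seq[pos0].upper()}, variant says {v.ref}"
            )
        offset = _transcript_offset(transcript, pos0)
        alt = revcomp(v.alt) if transcript.strand == MINUS else v.alt
        mutated[offset] = alt
    return native, "".join(mutated)


def delta_mfe_for_variants(
    transcripts: Sequence[TranscriptModel],
    genome: Mapping[str, str],
    variants: Sequence[VariantRecord],
    model: EnergyModel = DEFAULT_MODEL,
) -> list:
    """Per-variant MFE deltas, folding each transcript natively once.

    Each variant is applied alone to exactly one host transcript: when a
    variant position lies in exons shared by several transcripts (isoforms),
    the transcript with the lexicographically smallest id hosts it.
    Variants falling outside every transcript are ignored.
    """
    results = []
    native_cache: dict[str, float] = {}
    ordered = sorted(transcripts, key=lambda t: t.transcript_id)
    for v in variants:
        host = next(
            (
                tx
                for tx in ordered
                if v.chrom == tx.chrom
                and any(e.start <= v.pos - 1 < e.end for e in tx.exons)
            ),
            None,
        )
        if host is None:
            continue
        tid = host.transcript_id
        if tid not in native_cache:
            native_cache[tid] = fold_mfe(spliced_sequence(host, genome), model).mfe
        _nat, mut = apply_mutations(host, genome, [v])
        results.append(
            DeltaMfe(
                transcript_id=tid,
                variant=v,
                mfe_native=native_cache[tid],
                mfe_mutated=fold_mfe(mut, model).mfe,
            )
        )
    return results


def delta_mfe_analysis(novel_deltas, control_deltas):
    """Compare MFE deltas of novel versus control variants.

    Two-sided Wilcoxon rank-sum (Mann-Whitney) test with average-rank tie
    handling; exact enumeration when both samples have <= 20 observations
    and no ties, normal approximation with continuity correction otherwise.
    Returns (summary dict, U statistic, p-value).
    """
    x = np.asarray([d.delta if isinstance(d, DeltaMfe) else d for d in novel_deltas], dtype=float)
    y = np.asarray([d.delta if isinstance(d, DeltaMfe) else d for d in control_deltas], dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both delta samples must be non-empty")
    summary = {
        "n_novel": len(x),
        "n_control": len(y),
        "median_novel": float(np.median(x)),
        "median_control": float(np.median(y)),
        "frac_positive_novel": float(np.mean(x > 0)),
        "frac_positive_control": float(np.mean(y > 0)),
    }
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return summary, float(len(x) * len(y) / 2), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if max(len(x), len(y)) <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return summary, float(res.statistic), float(res.pvalue)
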