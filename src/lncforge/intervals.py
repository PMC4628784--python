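"""Core genomic domain objects shared by every stage of the pipeline.

All coordinates held in memory are 0-based, half-open (BED-like).  The
1-based inclusive conventions of GTF files and variant tables exist only at
the file boundary, inside :mod:`lncforge.io`.  Chromosome names are matched
by exact string comparison; no ``chr`` aliasing is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

PLUS = "+"
MINUS = "-"
UNSTRANDED = "."
STRANDS = frozenset({PLUS, MINUS, UNSTRANDED})

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class ValidationError(ValueError):
    """An in-memory object violates one of its documented invariants."""


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = UNSTRANDED

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chromosome name must be non-empty")
        if self.end <= self.start:
            raise ValidationError(
                f"interval end must exceed start, got [{self.start}, {self.end})"
            )
        if self.start < 0:
            raise ValidationError(f"negative interval start {self.start}")
        if self.strand not in STRANDS:
            raise ValidationError(f"unknown strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        """Bases shared with ``other``; 0 when on different chromosomes."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval", min_bp: int = 1) -> bool:
        return self.overlap_length(other) >= min_bp

    def distance_to(self, other: "GenomicInterval") -> int:
        """Gap in bp between two intervals on the same chromosome (0 if they touch
        or overlap)."""
        if self.chrom != other.chrom:
            raise ValidationError("distance undefined across chromosomes")
        if self.overlap_length(other) > 0:
            return 0
        return max(self.start, other.start) - min(self.end, other.end)


@dataclass
class TranscriptModel:
    """A stranded, (usually) multi-exon transcript model.

    ``exons`` are kept sorted by start and must be pairwise non-overlapping
    and share the transcript's chromosome and strand.  ``locus_id`` is unset
    until locus grouping has been performed.
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: tuple
    locus_id: str | None = None
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.transcript_id:
            raise ValidationError("transcript_id must be non-empty")
        if self.strand not in STRANDS:
            raise ValidationError(f"unknown strand {self.strand!r}")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        if not exons:
            raise ValidationError(f"{self.transcript_id}: transcript has no exons")
        for exon in exons:
            if exon.chrom != self.chrom or exon.strand != self.strand:
                raise ValidationError(
                    f"{self.transcript_id}: exon on {exon.chrom}({exon.strand}) "
                    f"does not match transcript {self.chrom}({self.strand})"
                )
        for left, right in zip(exons, exons[1:]):
            if right.start < left.end:
                raise ValidationError(
                    f"{self.transcript_id}: overlapping exons "
                    f"[{left.start},{left.end}) and [{right.start},{right.end})"
                )
        object.__setattr__(self, "exons", exons)

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def exonic_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def first_exon(self) -> GenomicInterval:
        """The 5'-most exon in transcript orientation."""
        return self.exons[-1] if self.strand == MINUS else self.exons[0]

    @property
    def last_exon(self) -> GenomicInterval:
        """The 3'-most exon in transcript orientation."""
        return self.exons[0] if self.strand == MINUS else self.exons[-1]


@dataclass(frozen=True)
class VariantRecord:
    """A candidate single-nucleotide variant. ``pos`` is 1-based."""

    chrom: str
    pos: int
    ref: str
    alt: str
    sample_id: str
    coverage: int
    vaf: float
    known_polymorphism: bool = False
    in_normal: bool = False

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValidationError(f"{self.chrom}:{self.pos} ref equals alt ({self.ref})")
        if not (0.0 <= self.vaf <= 1.0):
            raise ValidationError(f"{self.chrom}:{self.pos} vaf {self.vaf} outside [0,1]")
        if self.coverage < 0:
            raise ValidationError(f"{self.chrom}:{self.pos} negative coverage")
        if self.pos < 1:
            raise ValidationError(f"position must be 1-based, got {self.pos}")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.alt)


class CoverageTrack:
    """Per-chromosome step function of non-negative coverage values.

    Steps are stored as sorted, non-overlapping ``(start, end, value)``
    triples; positions not covered by any step have value 0.
    """

    def __init__(self, steps: Mapping[str, Iterable[tuple]]):
        self._steps: dict[str, tuple] = {}
        for chrom, triples in steps.items():
            triples = sorted(triples)
            starts = np.array([t[0] for t in triples], dtype=np.int64)
            ends = np.array([t[1] for t in triples], dtype=np.int64)
            values = np.array([t[2] for t in triples], dtype=np.float64)
            if np.any(ends <= starts):
                raise ValidationError(f"{chrom}: empty or inverted coverage step")
            if np.any(starts[1:] < ends[:-1]):
                raise ValidationError(f"{chrom}: overlapping coverage steps")
            if not np.all(np.isfinite(values)) or np.any(values < 0):
                raise ValidationError(f"{chrom}: coverage values must be finite and >= 0")
            self._steps[chrom] = (starts, ends, values)

    @property
    def chroms(self) -> list[str]:
        return list(self._steps)

    def steps(self, chrom: str):
        return self._steps.get(chrom, (np.empty(0, np.int64),) * 2 + (np.empty(0),))

    def values_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Coverage at each (0-based) position; 0 outside all steps."""
        positions = np.asarray(positions, dtype=np.int64)
        if chrom not in self._steps:
            return np.zeros(positions.shape, dtype=np.float64)
        starts, ends, values = self._steps[chrom]
        idx = np.searchsorted(starts, positions, side="right") - 1
        out = np.zeros(positions.shape, dtype=np.float64)
        valid = idx >= 0
        hit = valid & (positions < ends[np.clip(idx, 0, None)])
        out[hit] = values[idx[hit]]
        return out

    def to_triples(self) -> dict:
        return {
            chrom: [(int(s), int(e), float(v)) for s, e, v in zip(*step)]
            for chrom, step in self._steps.items()
        }


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def spliced_sequence(transcript: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Spliced transcript sequence in 5'->3' transcript orientation.

    Exon slices are concatenated in genomic order and reverse-complemented
    for minus-strand transcripts.
    """
    chrom_seq = genome[transcript.chrom]
    parts = [chrom_seq[e.start:e.end] for e in transcript.exons]
    seq = "".join(parts)
    if transcript.strand == MINUS:
        seq = revcomp(seq)
    return seq.upper()


def merge_intervals(intervals: Iterable[GenomicInterval]) -> dict:
    """Union of intervals per chromosome -> sorted (starts, ends) arrays."""
    per_chrom: dict[str, list] = {}
    for iv in intervals:
        per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged = {}
    for chrom, pairs in per_chrom.items():
        pairs.sort()
        starts, ends = [], []
        for s, e in pairs:
            if ends and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        merged[chrom] = (np.array(starts, np.int64), np.array(ends, np.int64))
    return merged


def covered_bases(interval: GenomicInterval, merged: dict) -> int:
    """Bases of ``interval`` covered by a union built with :func:`merge_intervals`."""
    if interval.chrom not in merged:
        return 0
    starts, ends = merged[interval.chrom]
    lo = np.searchsorted(ends, interval.start, side="right")
    hi = np.searchsorted(starts, interval.end, side="left")
    total = 0
    for i in range(lo, hi):
        total += max(0, min(int(ends[i]), interval.end) - max(int(starts[i]), interval.start))
    return total
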