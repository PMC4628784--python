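"""Readers and writers for the external formats the pipeline touches.

Formats: GTF (exon-feature dialect), BED6, FASTA, bedGraph, tab-delimited
expression matrix plus sample-group table, tab-delimited variant tables,
GMT-style gene sets and chromosome-size tables.

GTF and variant-table positions are 1-based inclusive on disk and converted
to the internal 0-based half-open convention on read; everything else is
already 0-based half-open.  FASTA sequence is uppercased on read.
"""

from __future__ import annotations

import re
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .intervals import (
    UNSTRANDED,
    CoverageTrack,
    GenomicInterval,
    TranscriptModel,
    ValidationError,
    VariantRecord,
)


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')

VARIANT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "sample_id",
    "coverage", "vaf", "known_polymorphism", "in_normal",
]


# ---------------------------------------------------------------------------
# GTF

def read_gtf(path) -> list[TranscriptModel]:
    """Read exon feature lines of a GTF file into transcript models.

    Only ``transcript_id`` is required in the attribute column; ``gene_id``
    (when present) becomes ``locus_id`` and any further attributes are kept
    verbatim.  Coordinates are converted from 1-based inclusive to 0-based
    half-open and exons are sorted by start.
    """
    per_tx: dict[str, dict] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 columns, got {len(fields)}")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinate") from exc
            pairs = dict(_GTF_ATTR.findall(attrs))
            if "transcript_id" not in pairs:
                raise ParseError(f"{path}: line {lineno}: missing transcript_id attribute")
            tid = pairs.pop("transcript_id")
            gene_id = pairs.pop("gene_id", None)
            entry = per_tx.setdefault(
                tid, {"chrom": chrom, "strand": strand, "gene_id": gene_id,
                      "attributes": pairs, "exons": []},
            )
            entry["exons"].append((chrom, start_i - 1, end_i, strand))
    transcripts = []
    for tid, entry in per_tx.items():
        for chrom, _s, _e, strand in entry["exons"]:
            if chrom != entry["chrom"] or strand != entry["strand"]:
                raise ValidationError(
                    f"{path}: transcript {tid} has exons on mixed chromosome/strand"
                )
        exons = tuple(
            GenomicInterval(c, s, e, st) for c, s, e, st in sorted(entry["exons"], key=lambda x: x[1])
        )
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                chrom=entry["chrom"],
                strand=entry["strand"],
                exons=exons,
                locus_id=entry["gene_id"],
                attributes=entry["attributes"],
            )
        )
    return transcripts


def write_gtf(transcripts: Sequence[TranscriptModel], path) -> None:
    """Write one exon line per exon, 1-based inclusive, deterministic order."""
    ordered = sorted(transcripts, key=lambda t: (t.chrom, t.start, t.transcript_id))
    with open(path, "w") as handle:
        handle.write("# exon-feature GTF written by lncforge\n")
        for tx in ordered:
            attrs = []
            if tx.locus_id is not None:
                attrs.append(f'gene_id "{tx.locus_id}";')
            attrs.append(f'transcript_id "{tx.transcript_id}";')
            for key, value in tx.attributes.items():
                attrs.append(f'{key} "{value}";')
            attr_str = " ".join(attrs)
            for exon in tx.exons:
                handle.write(
                    f"{tx.chrom}\tlncforge\texon\t{exon.start + 1}\t{exon.end}\t.\t"
                    f"{tx.strand}\t.\t{attr_str}\n"
                )


# ---------------------------------------------------------------------------
# BED / bedGraph

def read_bed(path) -> list[GenomicInterval]:
    """Read a BED3+/BED6 file (0-based half-open; strand from column 6)."""
    intervals = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >=3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if end <= start:
                raise ValidationError(f"{path}: line {lineno}: BED end <= start")
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else UNSTRANDED
            intervals.append(GenomicInterval(chrom, start, end, strand))
    return intervals


def write_bed(intervals: Sequence[GenomicInterval], path, names: Sequence[str] | None = None) -> None:
    if names is None:
        names = [f"iv{i}" for i in range(len(intervals))]
    with open(path, "w") as handle:
        for iv, name in zip(intervals, names):
            handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_bedgraph(path) -> CoverageTrack:
    steps: dict[str, list] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(f"{path}: line {lineno}: expected 4 bedGraph columns")
            chrom, start, end, value = fields
            steps.setdefault(chrom, []).append((int(start), int(end), float(value)))
    return CoverageTrack(steps)


def write_bedgraph(track: CoverageTrack, path) -> None:
    with open(path, "w") as handle:
        for chrom in sorted(track.chroms):
            for start, end, value in track.to_triples()[chrom]:
                handle.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict[str, str]:
    """Read FASTA into a name -> uppercase-sequence map."""
    seqs = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise ValidationError(f"{path}: duplicate FASTA record {record.id}")
        seqs[record.id] = str(record.seq).upper()
    return seqs


def write_fasta(sequences: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as handle:
        for name, seq in sequences.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Expression matrix + sample groups

def read_expression(matrix_path, groups_path):
    """Read an FPKM matrix (features x samples) and its sample-group table.

    The group table is tab-delimited with columns ``sample``, ``group`` and
    optionally ``subtype``.  Every matrix sample must appear in the table.
    """
    from .expression import ExpressionMatrix

    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if values.index.duplicated().any():
        dupes = values.index[values.index.duplicated()].unique().tolist()
        raise ValidationError(f"{matrix_path}: duplicate feature ids {dupes}")
    numeric = values.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = numeric.isna().stack()
        feature, sample = bad[bad].index[0]
        raise ParseError(f"{matrix_path}: non-numeric FPKM at feature {feature}, sample {sample}")
    if (numeric.values < 0).any():
        raise ValidationError(f"{matrix_path}: negative FPKM values are not allowed")
    table = pd.read_csv(groups_path, sep="\t", dtype=str)
    if "sample" not in table.columns or "group" not in table.columns:
        raise ParseError(f"{groups_path}: expected 'sample' and 'group' columns")
    groups = pd.Series(table["group"].values, index=table["sample"].values)
    missing = [s for s in numeric.columns if s not in groups.index]
    if missing:
        raise ValidationError(f"{groups_path}: samples missing from group table: {missing}")
    subtypes = None
    if "subtype" in table.columns:
        subtypes = pd.Series(table["subtype"].fillna("unclassified").values,
                             index=table["sample"].values)
    return ExpressionMatrix(values=numeric, groups=groups, subtypes=subtypes)


def write_expression(expr, matrix_path, groups_path) -> None:
    expr.values.to_csv(matrix_path, sep="\t", index_label="feature")
    table = pd.DataFrame({"sample": expr.groups.index, "group": expr.groups.values})
    if expr.subtypes is not None:
        table["subtype"] = expr.subtypes.reindex(table["sample"]).values
    table.to_csv(groups_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Variant tables

def read_variant_table(path) -> list[VariantRecord]:
    """Read a tab-delimited variant table (1-based positions)."""
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str,
                                               "sample_id": str})
    missing = [c for c in VARIANT_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing variant columns {missing}")
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            VariantRecord(
                chrom=row.chrom,
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                sample_id=row.sample_id,
                coverage=int(row.coverage),
                vaf=float(row.vaf),
                known_polymorphism=bool(row.known_polymorphism),
                in_normal=bool(row.in_normal),
            )
        )
    return records


def write_variant_table(variants: Sequence[VariantRecord], path) -> None:
    frame = pd.DataFrame(
        [
            {
                "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                "sample_id": v.sample_id, "coverage": v.coverage, "vaf": v.vaf,
                "known_polymorphism": int(v.known_polymorphism),
                "in_normal": int(v.in_normal),
            }
            for v in variants
        ],
        columns=VARIANT_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)


def read_position_set(path) -> set[tuple]:
    """Read a (chrom, pos, alt) site list (tab-delimited, 1-based)."""
    sites = set()
    with open(path) as handle:
        header = handle.readline()
        if not header.startswith("chrom"):
            raise ParseError(f"{path}: expected header starting with 'chrom'")
        for line in handle:
            if not line.strip():
                continue
            chrom, pos, alt = line.rstrip("\n").split("\t")[:3]
            sites.add((chrom, int(pos), alt))
    return sites


def write_position_set(sites: Iterable[tuple], path) -> None:
    with open(path, "w") as handle:
        handle.write("chrom\tpos\talt\n")
        for chrom, pos, alt in sorted(sites):
            handle.write(f"{chrom}\t{pos}\t{alt}\n")


# ---------------------------------------------------------------------------
# Pileup summaries

PILEUP_COLUMNS = ["chrom", "pos", "ref", "sample_id", "A", "C", "G", "T"]


def read_pileup(path):
    from .mutation import PileupSite

    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "sample_id": str})
    missing = [c for c in PILEUP_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing pileup columns {missing}")
    return [
        PileupSite(
            chrom=row.chrom, pos=int(row.pos), ref=row.ref, sample_id=row.sample_id,
            counts={"A": int(row.A), "C": int(row.C), "G": int(row.G), "T": int(row.T)},
        )
        for row in frame.itertuples(index=False)
    ]


def write_pileup(sites, path) -> None:
    frame = pd.DataFrame(
        [
            {"chrom": s.chrom, "pos": s.pos, "ref": s.ref, "sample_id": s.sample_id,
             "A": s.counts["A"], "C": s.counts["C"], "G": s.counts["G"], "T": s.counts["T"]}
            for s in sites
        ],
        columns=PILEUP_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene sets (GMT) and chromosome sizes

def read_gene_sets(path) -> dict[str, list]:
    """Read GMT: one set per line as name<TAB>description<TAB>member..."""
    sets: dict[str, list] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected name, description, members")
            name = fields[0]
            if name in sets:
                raise ValidationError(f"{path}: duplicate gene set {name}")
            sets[name] = [g for g in fields[2:] if g]
    return sets


def write_gene_sets(sets: Mapping[str, Sequence[str]], path) -> None:
    with open(path, "w") as handle:
        for name, members in sets.items():
            handle.write("\t".join([name, "na", *members]) + "\n")


def read_chrom_sizes(path) -> dict[str, int]:
    sizes = {}
    with open(path) as handle:
        for line in handle:
            if not line.strip():
                continue
            chrom, size = line.split("\t")[:2]
            sizes[chrom] = int(size)
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as handle:
        for chrom, size in sizes.items():
            handle.write(f"{chrom}\t{size}\n")
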