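"""Filter cascade, annotation subtraction, locus grouping and divergent calls."""

import itertools

import pandas as pd
import pytest

from lncforge.coding import CodingPotentialModel
from lncforge.discovery import (
    classify_divergent,
    filter_cascade,
    group_loci,
    isoform_counts,
    subtract_known,
)
from lncforge.expression import ExpressionMatrix
from lncforge.intervals import GenomicInterval, TranscriptModel, ValidationError
from oracles import loci_brute


def _tx(tid, chrom, strand, pairs, locus=None):
    return TranscriptModel(
        transcript_id=tid, chrom=chrom, strand=strand,
        exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in pairs),
        locus_id=locus,
    )


def _null_model():
    """A model whose score is ~0 for everything (intercept -> -inf side)."""
    table = dict.fromkeys(("".join(p) for p in itertools.product("ACGT", repeat=6)), 0.0)
    return CodingPotentialModel(
        hexamer_logratio=table, intercept=-20.0, coefficients=(0.0, 0.0, 0.0),
        feature_means=(0.0, 0.0, 0.0), feature_scales=(1.0, 1.0, 1.0),
    )


def _expr(feature_ids, tumor_value=1.0, n_tumor=3, n_normal=2, n_cell=2):
    samples = ([f"T{i}" for i in range(n_tumor)] + [f"N{i}" for i in range(n_normal)]
               + [f"C{i}" for i in range(n_cell)])
    values = pd.DataFrame(tumor_value, index=list(feature_ids), columns=samples)
    groups = pd.Series(["tumor"] * n_tumor + ["normal"] * n_normal + ["cell_line"] * n_cell,
                       index=samples)
    return ExpressionMatrix(values=values, groups=groups)


class TestSubtractKnown:
    def test_single_base_exonic_overlap_excludes(self):
        known = [_tx("k", "chr1", "+", [(100, 200)])]
        tx = _tx("t", "chr1", "-", [(199, 300)])  # 1 bp overlap, opposite strand
        novel, excluded = subtract_known([tx], known)
        assert novel == [] and excluded == [tx]

    def test_fully_intronic_transcript_is_retained(self):
        known = [_tx("k", "chr1", "+", [(100, 200), (800, 900)])]
        tx = _tx("t", "chr1", "+", [(300, 400), (500, 600)])
        novel, excluded = subtract_known([tx], known)
        # brute-force confirmation: no exon pair overlaps
        assert all(
            min(e.end, ke.end) - max(e.start, ke.start) <= 0
            for e in tx.exons for ke in known[0].exons
        )
        assert novel == [tx] and excluded == []

    def test_empty_known_retains_everything(self):
        txs = [_tx(f"t{i}", "chr1", "+", [(i * 100, i * 100 + 50)]) for i in range(5)]
        novel, excluded = subtract_known(txs, [])
        assert novel == txs and excluded == []


class TestCascade:
    def test_stage_attribution_mono_exonic(self):
        tx = _tx("t", "chr1", "+", [(0, 5000)])
        expr = _expr(["t"])
        report = filter_cascade([tx], {"t": "A" * 5000}, _null_model(), expr)
        assert report.first_fail("t") == "exon_count"
        assert report.table.loc["t", "pass_length"]

    def test_fpkm_at_threshold_fails_expression(self):
        tx = _tx("t", "chr1", "+", [(0, 150), (300, 500)])
        expr = _expr(["t"], tumor_value=0.1)
        report = filter_cascade([tx], {"t": "ACGT" * 88}, _null_model(), expr)
        assert report.first_fail("t") == "expression"

    def test_missing_expression_feature_is_an_error(self):
        tx = _tx("t", "chr1", "+", [(0, 150), (300, 500)])
        expr = _expr(["other"])
        with pytest.raises(ValidationError, match="t"):
            filter_cascade([tx], {"t": "ACGT" * 88}, _null_model(), expr)

    def test_tightening_thresholds_never_grows_retained_set(
            self, dataset, coding_model, sequences):
        base = filter_cascade(dataset.assembly, sequences, coding_model,
                              dataset.expression, known=dataset.known)
        base_ids = {t.transcript_id for t in base.retained}
        for kwargs in ({"min_length": 300}, {"min_exons": 3}, {"min_fpkm": 0.5},
                       {"min_samples": 10}):
            tighter = filter_cascade(dataset.assembly, sequences, coding_model,
                                     dataset.expression, known=dataset.known, **kwargs)
            assert {t.transcript_id for t in tighter.retained} <= base_ids

    def test_every_excluded_transcript_names_one_first_fail(self, cascade_report):
        table = cascade_report.table
        excluded = table[~table["retained"]]
        assert excluded["first_fail"].notna().all()
        retained = table[table["retained"]]
        assert retained["first_fail"].isna().all()


class TestGroupLoci:
    def test_transitive_single_linkage(self):
        a = _tx("a", "chr1", "+", [(0, 100)])
        b = _tx("b", "chr1", "+", [(50, 150)])
        c = _tx("c", "chr1", "+", [(140, 250)])
        assignment = group_loci([a, b, c])
        assert len(set(assignment.values())) == 1

    def test_opposite_strands_are_different_loci(self):
        a = _tx("a", "chr1", "+", [(0, 100)])
        b = _tx("b", "chr1", "-", [(0, 100)])
        assignment = group_loci([a, b])
        assert assignment["a"] != assignment["b"]

    def test_intron_spanning_transcripts_do_not_merge(self):
        a = _tx("a", "chr1", "+", [(0, 100), (900, 1000)])
        b = _tx("b", "chr1", "+", [(400, 500)])  # inside a's intron
        assignment = group_loci([a, b])
        assert assignment["a"] != assignment["b"]

    def test_matches_brute_force_union_find(self, rng):
        for _ in range(100):
            txs = []
            for i in range(int(rng.integers(2, 25))):
                n_exons = int(rng.integers(1, 4))
                pos = int(rng.integers(0, 2000))
                pairs = []
                for _e in range(n_exons):
                    length = int(rng.integers(10, 200))
                    pairs.append((pos, pos + length))
                    pos += length + int(rng.integers(1, 150))
                txs.append(_tx(f"t{i}", "chr1", "+" if rng.random() < 0.7 else "-", pairs))
            assignment = group_loci(txs)
            groups = {}
            for tid, locus in assignment.items():
                groups.setdefault(locus, set()).add(tid)
            assert {frozenset(g) for g in groups.values()} == loci_brute(txs)

    def test_partition_and_isoform_counts(self, cascade_report):
        assignment = cascade_report.locus_assignment
        assert set(assignment) == {t.transcript_id for t in cascade_report.retained}
        counts = isoform_counts(assignment)
        assert counts.sum() == len(cascade_report.retained)


class TestDivergent:
    def test_antisense_beyond_two_kb_is_not_divergent(self):
        gene = _tx("g", "chr1", "+", [(10_000, 12_000)], locus="G1")
        lnc = _tx("l", "chr1", "-", [(6_500, 6_800), (6_950, 7_000)])
        assert lnc.first_exon.distance_to(gene.span) == 3000
        assert classify_divergent([lnc], [gene]) == []

    def test_sense_nearby_is_not_divergent(self):
        gene = _tx("g", "chr1", "+", [(10_000, 12_000)], locus="G1")
        lnc = _tx("l", "chr1", "+", [(9_200, 9_300), (9_400, 9_500)])
        assert classify_divergent([lnc], [gene]) == []

    def test_antisense_within_two_kb_is_divergent(self):
        gene = _tx("g", "chr1", "+", [(10_000, 12_000)], locus="G1")
        lnc = _tx("l", "chr1", "-", [(9_200, 9_300), (9_400, 9_500)])
        assert [t.transcript_id for t in classify_divergent([lnc], [gene])] == ["l"]

    def test_unstranded_lncrna_skipped_with_warning(self):
        gene = _tx("g", "chr1", "+", [(10_000, 12_000)], locus="G1")
        lnc = _tx("l", "chr1", ".", [(9_200, 9_500)])
        with pytest.warns(UserWarning, match="unstranded"):
            assert classify_divergent([lnc], [gene]) == []
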