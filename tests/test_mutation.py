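"""Variant calling, filtering, hotspot scanning, mutagenesis, delta-MFE."""

import numpy as np
import pytest

from lncforge.intervals import (
    GenomicInterval,
    TranscriptModel,
    ValidationError,
    VariantRecord,
    revcomp,
)
from lncforge.mutation import (
    PileupSite,
    apply_mutations,
    call_variants,
    delta_mfe_analysis,
    filter_variants,
    hotspot_scan,
)
from oracles import hotspot_brute, ranksum_enumerate


def _site(chrom, pos, ref, counts, sample="s1"):
    full = {b: 0 for b in "ACGT"}
    full.update(counts)
    return PileupSite(chrom=chrom, pos=pos, ref=ref, sample_id=sample, counts=full)


def _var(chrom, pos, ref="A", alt="G", sample="s1", known=False, normal=False):
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, sample_id=sample,
                         coverage=20, vaf=0.5, known_polymorphism=known, in_normal=normal)


def _tx(tid, chrom, strand, pairs):
    return TranscriptModel(
        transcript_id=tid, chrom=chrom, strand=strand,
        exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in pairs),
    )


class TestCallVariants:
    def test_coverage_below_eight_is_not_called(self):
        assert call_variants([_site("c1", 10, "A", {"A": 3, "G": 4})]) == []

    def test_vaf_boundary_inclusive(self):
        calls = call_variants([_site("c1", 10, "A", {"A": 8, "G": 2})])
        assert len(calls) == 1
        assert calls[0].vaf == pytest.approx(0.2) and calls[0].alt == "G"

    def test_all_reference_site_yields_no_call(self):
        assert call_variants([_site("c1", 10, "A", {"A": 30})]) == []

    def test_multi_allelic_site_yields_one_record_per_alt(self):
        calls = call_variants([_site("c1", 10, "A", {"A": 2, "G": 5, "T": 5})])
        assert sorted(c.alt for c in calls) == ["G", "T"]

    def test_sub_threshold_vaf_not_called(self):
        assert call_variants([_site("c1", 10, "A", {"A": 27, "G": 3})]) == []


class TestFilterVariants:
    def test_intronic_variant_removed(self):
        tx = _tx("t", "c1", "+", [(100, 200), (300, 400)])
        kept = filter_variants([_var("c1", 250)], [tx])
        assert kept == []

    def test_exonic_variant_in_normal_removed(self):
        tx = _tx("t", "c1", "+", [(100, 200)])
        assert filter_variants([_var("c1", 150, normal=True)], [tx]) == []
        assert filter_variants([_var("c1", 150)], [tx],
                               normal_variants={("c1", 150, "G")}) == []

    def test_known_polymorphism_removed(self):
        tx = _tx("t", "c1", "+", [(100, 200)])
        assert filter_variants([_var("c1", 150, known=True)], [tx]) == []
        assert filter_variants([_var("c1", 150)], [tx],
                               known_polymorphisms={("c1", 150, "G")}) == []

    def test_matches_brute_force_triple_filter(self, rng):
        tx = _tx("t", "c1", "+", [(100, 200), (300, 400)])
        for _ in range(50):
            variants = []
            for _v in range(int(rng.integers(1, 30))):
                pos = int(rng.integers(50, 450))
                variants.append(_var("c1", pos, known=bool(rng.random() < 0.2),
                                     normal=bool(rng.random() < 0.2)))
            dbsnp = {("c1", int(p), "G") for p in rng.integers(50, 450, size=5)}
            normals = {("c1", int(p), "G") for p in rng.integers(50, 450, size=5)}
            kept = filter_variants(variants, [tx], dbsnp, normals)
            expected = [
                v for v in variants
                if (100 <= v.pos - 1 < 200 or 300 <= v.pos - 1 < 400)
                and not v.known_polymorphism and not v.in_normal
                and v.key not in dbsnp and v.key not in normals
            ]
            assert kept == expected


class TestHotspots:
    def test_six_variants_at_one_position(self):
        variants = [_var("c1", 500, sample=f"s{i}") for i in range(6)]
        (spot,) = hotspot_scan(variants)
        assert spot.mutation_count == 6
        assert spot.start <= 499 < spot.end

    def test_five_variants_is_below_threshold(self):
        variants = [_var("c1", 500 + i, sample=f"s{i}") for i in range(5)]
        assert hotspot_scan(variants) == []

    def test_order_invariance(self, rng):
        positions = [int(p) for p in rng.integers(200, 800, size=25)]
        variants = [_var("c1", p, sample=f"s{i}") for i, p in enumerate(positions)]
        shuffled = list(variants)
        rng.shuffle(shuffled)
        a = [(h.chrom, h.start, h.end, h.mutation_count) for h in hotspot_scan(variants)]
        b = [(h.chrom, h.start, h.end, h.mutation_count) for h in hotspot_scan(shuffled)]
        assert a == b

    def test_matches_naive_window_enumeration(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 40))
            positions = sorted(int(p) for p in rng.integers(200, 200 + 600, size=n))
            variants = [_var("c1", p + 1, sample=f"s{i}")
                        for i, p in enumerate(positions)]
            got = [(h.start, h.end, h.mutation_count)
                   for h in hotspot_scan(variants, window=50, min_count=4)]
            assert got == hotspot_brute(positions, window=50, min_count=4)


class TestApplyMutations:
    genome = {"c1": "AAACGTACGTTTGGGCCCAA"}

    def test_zero_variants_identity(self):
        tx = _tx("t", "c1", "+", [(3, 9), (12, 18)])
        native, mutated = apply_mutations(tx, self.genome, [])
        assert native == mutated == "CGTACG" + "GGGCCC"

    def test_single_plus_strand_substitution(self):
        tx = _tx("t", "c1", "+", [(3, 9)])
        v = VariantRecord("c1", 5, "G", "T", "s", 10, 0.5)  # genome[4] == G
        native, mutated = apply_mutations(tx, self.genome, [v])
        diffs = [i for i, (a, b) in enumerate(zip(native, mutated)) if a != b]
        assert diffs == [1] and mutated[1] == "T"

    def test_minus_strand_complement_arithmetic(self):
        tx = _tx("t", "c1", "-", [(3, 9)])
        native = revcomp("CGTACG")
        v = VariantRecord("c1", 4, "C", "T", "s", 10, 0.5)  # genome[3] == C
        got_native, mutated = apply_mutations(tx, self.genome, [v])
        assert got_native == native
        # genomic offset 0 within exon -> transcript offset 5 on minus strand
        assert mutated[5] == revcomp("T") == "A"
        assert [i for i, (a, b) in enumerate(zip(native, mutated)) if a != b] == [5]

    def test_reference_mismatch_names_position(self):
        tx = _tx("t", "c1", "+", [(3, 9)])
        v = VariantRecord("c1", 5, "A", "T", "s", 10, 0.5)
        with pytest.raises(ValidationError, match="c1:5"):
            apply_mutations(tx, self.genome, [v])

    def test_enabling_one_gc_pair_gives_positive_delta(self):
        from lncforge.folding import fold_mfe

        # AAGAAAAcA -> mutating the final-but-one A to C enables one GC pair
        native = "AAGAAAAAA"
        mutated = "AAGAAAACA"
        delta = fold_mfe(native).mfe - fold_mfe(mutated).mfe
        assert delta == pytest.approx(3.0)


class TestDeltaMfeAnalysis:
    def test_identical_samples_give_p1(self):
        _s, _u, p = delta_mfe_analysis([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_disjoint_small_samples_exact(self):
        _s, _u, p = delta_mfe_analysis([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert p == pytest.approx(0.1)  # 2/20 orderings

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(20):
            n1, n2 = int(rng.integers(2, 7)), int(rng.integers(2, 7))
            x = list(rng.normal(size=n1))
            y = list(rng.normal(size=n2))
            _s, _u, p = delta_mfe_analysis(x, y)
            assert p == pytest.approx(ranksum_enumerate(x, y))

    def test_summary_reports_medians_and_sign_fractions(self):
        summary, _u, _p = delta_mfe_analysis([2.0, 3.0, -1.0], [0.0, 0.0, 0.0, -2.0])
        assert summary["median_novel"] == 2.0
        assert summary["median_control"] == 0.0
        assert summary["frac_positive_novel"] == pytest.approx(2 / 3)
        assert summary["frac_positive_control"] == 0.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            delta_mfe_analysis([], [1.0])
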