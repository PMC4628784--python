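"""Interval joins, TE architecture, permutation enrichment, TSS profiles."""

import numpy as np
import pytest

from lncforge.context import (
    exon_position_te_test,
    overlap_join,
    shuffle_enrichment,
    te_summary,
    tss_metaprofile,
)
from lncforge.intervals import CoverageTrack, GenomicInterval, TranscriptModel
from oracles import overlap_brute, te_covered_brute


def _iv(chrom, s, e, strand="."):
    return GenomicInterval(chrom, s, e, strand)


def _tx(tid, chrom, strand, pairs):
    return TranscriptModel(
        transcript_id=tid, chrom=chrom, strand=strand,
        exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in pairs),
    )


def _random_intervals(rng, n, span=2000):
    out = []
    for _ in range(n):
        s = int(rng.integers(0, span))
        out.append(_iv(rng.choice(["c1", "c2"]), s, s + int(rng.integers(1, 200))))
    return out


class TestOverlapJoin:
    def test_edge_arithmetic_and_10bp_dialect(self):
        a, b = [_iv("c1", 10, 20)], [_iv("c1", 19, 30)]
        assert overlap_join(a, b, min_bp=1) == [(0, 0, 1)]
        assert overlap_join(a, b, min_bp=10) == []

    def test_half_open_touching_intervals_do_not_overlap(self):
        assert overlap_join([_iv("c1", 10, 20)], [_iv("c1", 20, 30)]) == []

    def test_matches_all_pairs_brute_force(self, rng):
        for _ in range(100):
            a = _random_intervals(rng, int(rng.integers(1, 30)))
            b = _random_intervals(rng, int(rng.integers(1, 30)))
            assert sorted(overlap_join(a, b)) == sorted(overlap_brute(a, b))

    def test_symmetry_up_to_pair_order(self, rng):
        a = _random_intervals(rng, 20)
        b = _random_intervals(rng, 20)
        fwd = {(i, j, o) for i, j, o in overlap_join(a, b)}
        rev = {(j, i, o) for i, j, o in overlap_join(b, a)}
        assert fwd == rev


class TestTeSummary:
    def test_te_covering_all_exons_is_100_percent(self):
        tx = _tx("t", "c1", "+", [(100, 200), (300, 400)])
        tes = [_iv("c1", 0, 1000)]
        summary = te_summary([tx], tes)
        assert summary.loc["t", "te_derived_percent"] == 100.0
        assert summary.loc["t", "first_exon_te"] and summary.loc["t", "last_exon_te"]

    def test_no_te_on_chromosome(self):
        tx = _tx("t", "c1", "+", [(100, 200), (300, 400)])
        summary = te_summary([tx], [_iv("c9", 0, 1000)])
        assert summary.loc["t", "te_derived_percent"] == 0.0
        assert not summary.loc["t", "any_overlap_1bp"]

    def test_overlapping_te_copies_counted_once(self, rng):
        for _ in range(50):
            tx = _tx("t", "c1", "+", [(0, 150), (250, 420)])
            tes = _random_intervals(rng, int(rng.integers(1, 15)), span=500)
            summary = te_summary([tx], tes)
            expected = te_covered_brute(tx, tes)
            assert summary.loc["t", "te_covered_bases"] == expected

    def test_percent_invariant_under_splitting_te(self):
        tx = _tx("t", "c1", "+", [(100, 300)])
        whole = te_summary([tx], [_iv("c1", 120, 220)])
        split = te_summary([tx], [_iv("c1", 120, 170), _iv("c1", 170, 220)])
        assert (whole.loc["t", "te_derived_percent"]
                == split.loc["t", "te_derived_percent"])

    def test_first_last_follow_transcript_orientation(self):
        tes = [_iv("c1", 100, 150)]  # leftmost exon only
        plus = te_summary([_tx("p", "c1", "+", [(100, 200), (300, 400)])], tes)
        minus = te_summary([_tx("m", "c1", "-", [(100, 200), (300, 400)])], tes)
        assert plus.loc["p", "first_exon_te"] and not plus.loc["p", "last_exon_te"]
        assert minus.loc["m", "last_exon_te"] and not minus.loc["m", "first_exon_te"]


class TestExonPositionChi2:
    def test_equal_counts_give_zero_statistic(self):
        txs = [_tx(f"t{i}", "c1", "+", [(i * 1000, i * 1000 + 100),
                                        (i * 1000 + 200, i * 1000 + 300)])
               for i in range(10)]
        tes = [_iv("c1", i * 1000, i * 1000 + 50) for i in range(5)]
        tes += [_iv("c1", i * 1000 + 200, i * 1000 + 250) for i in range(5, 10)]
        stat, p, table = exon_position_te_test(te_summary(txs, tes))
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_statistic_matches_hand_computation(self):
        # table first: 30 yes / 70 no; last: 70 yes / 30 no
        import pandas as pd

        summary = pd.DataFrame({
            "n_exons": [2] * 100,
            "first_exon_te": [True] * 30 + [False] * 70,
            "last_exon_te": [True] * 70 + [False] * 30,
        })
        stat, p, table = exon_position_te_test(summary)
        observed = np.array([[30, 70], [70, 30]])
        expected = np.outer(observed.sum(1), observed.sum(0)) / observed.sum()
        assert stat == pytest.approx(((observed - expected) ** 2 / expected).sum())

    def test_zero_margin_warns_and_returns_p1(self):
        import pandas as pd

        summary = pd.DataFrame({"n_exons": [2, 2], "first_exon_te": [False, False],
                                "last_exon_te": [False, False]})
        with pytest.warns(UserWarning, match="zero margin"):
            stat, p, _ = exon_position_te_test(summary)
        assert p == 1.0


class TestShuffleEnrichment:
    def test_query_covering_chromosome_gives_p1(self):
        queries = [_iv("c1", 0, 10_000)]
        targets = [_iv("c1", 100, 200), _iv("c1", 5000, 5100)]
        res = shuffle_enrichment(queries, targets, {"c1": 10_000}, n=50, seed=1)
        assert res.observed_count == 2
        assert (res.null_counts == 2).all()
        assert res.empirical_p == 1.0

    def test_add_one_estimator_floor(self):
        # observed beats every shuffle -> p = 1/(n+1), never 0
        queries = [_iv("c1", 0, 100)]
        targets = [_iv("c1", 10, 20)]
        res = shuffle_enrichment(queries, targets, {"c1": 1_000_000}, n=50, seed=2)
        assert res.empirical_p >= 1 / 51
        assert res.empirical_p > 0

    def test_reproducible_under_seed(self):
        queries = [_iv("c1", 1000, 3000)]
        targets = [_iv("c1", 0, 500)] * 5
        a = shuffle_enrichment(queries, targets, {"c1": 50_000}, n=100, seed=3)
        b = shuffle_enrichment(queries, targets, {"c1": 50_000}, n=100, seed=3)
        assert (a.null_counts == b.null_counts).all()

    def test_target_longer_than_chromosome_rejected(self):
        from lncforge.intervals import ValidationError

        with pytest.raises(ValidationError):
            shuffle_enrichment([_iv("c1", 0, 10)], [_iv("c1", 0, 200)], {"c1": 100}, n=5,
                               seed=0)


class TestTssProfile:
    def test_uniform_coverage_gives_flat_profile(self):
        track = CoverageTrack({"c1": [(0, 100_000, 4.0)]})
        txs = [_tx("t", "c1", "+", [(50_000, 50_200), (51_000, 51_100)])]
        profile = tss_metaprofile(txs, track, halfwidth=100)
        assert np.allclose(profile.values, 4.0)

    def test_profile_matches_manual_lookup(self):
        track = CoverageTrack({"c1": [(95, 105, 2.0), (105, 120, 7.0)]})
        tx = _tx("t", "c1", "+", [(100, 300)])
        profile = tss_metaprofile([tx], track, halfwidth=10)
        expected = []
        for off in range(-10, 11):
            pos = 100 + off
            if 95 <= pos < 105:
                expected.append(2.0)
            elif 105 <= pos < 120:
                expected.append(7.0)
            else:
                expected.append(0.0)
        assert np.allclose(profile.values, expected)

    def test_strand_flip_reverses_profile(self):
        track = CoverageTrack({"c1": [(90, 100, 1.0), (100, 130, 6.0)]})
        plus = tss_metaprofile([_tx("p", "c1", "+", [(100, 300)])], track, halfwidth=20)
        # minus-strand transcript with TSS at the same genomic base (end-1=100)
        minus = tss_metaprofile([_tx("m", "c1", "-", [(0, 101)])], track, halfwidth=20)
        assert np.allclose(plus.values, minus.values[::-1])

    def test_unstranded_transcript_skipped(self):
        track = CoverageTrack({"c1": [(0, 1000, 1.0)]})
        txs = [_tx("u", "c1", ".", [(100, 200)]), _tx("p", "c1", "+", [(100, 200)])]
        with pytest.warns(UserWarning, match="unstranded"):
            profile = tss_metaprofile(txs, track, halfwidth=5)
        assert profile.n_transcripts == 1
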