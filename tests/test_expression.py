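"""Expression partitioning, outliers, differential and co-expression,
hypergeometric enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lncforge.expression import (
    ExpressionMatrix,
    coexpression,
    count_expressed_per_sample,
    differential_expression,
    enrich_gene_sets,
    flag_outliers,
    hypergeom_upper_tail,
    knockdown_concordance,
    partition_expression_classes,
)
from lncforge.intervals import ValidationError
from oracles import hypergeom_enumerate, welch_t_brute


def _matrix(values: np.ndarray, n_tumor, n_normal, n_cell, subtypes=None):
    samples = ([f"T{i}" for i in range(n_tumor)] + [f"N{i}" for i in range(n_normal)]
               + [f"C{i}" for i in range(n_cell)])
    features = [f"f{i}" for i in range(values.shape[0])]
    groups = pd.Series(["tumor"] * n_tumor + ["normal"] * n_normal
                       + ["cell_line"] * n_cell, index=samples)
    sub = None
    if subtypes is not None:
        sub = pd.Series(subtypes + ["unclassified"] * (n_normal + n_cell), index=samples)
    return ExpressionMatrix(values=pd.DataFrame(values, index=features, columns=samples),
                            groups=groups, subtypes=sub)


class TestPartition:
    def test_threshold_is_strict(self):
        expr = _matrix(np.full((1, 9), 0.1), 3, 3, 3)
        classes = partition_expression_classes(expr, ["f0"])
        assert classes["f0"] == "none"

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(50):
            values = rng.uniform(0, 0.4, size=(int(rng.integers(1, 15)), 9))
            expr = _matrix(values, 3, 3, 3)
            classes = partition_expression_classes(expr, expr.features)
            for fi, feature in enumerate(expr.features):
                present = []
                for group, cols in (("cell_line", range(6, 9)), ("normal", range(3, 6)),
                                    ("tumor", range(0, 3))):
                    n = sum(values[fi, c] > 0.1 for c in cols)
                    if n >= 2:
                        present.append(group)
                expected = "+".join(sorted(present)) if present else "none"
                assert classes[feature] == expected

    def test_group_smaller_than_min_samples_is_an_error(self):
        expr = _matrix(np.ones((1, 5)), 3, 1, 1)
        with pytest.raises(ValidationError):
            partition_expression_classes(expr, ["f0"])

    def test_planted_classes_recovered(self, dataset):
        classes = partition_expression_classes(dataset.expression,
                                               dataset.truth.true_lncRNAs)
        for tid, expected in dataset.truth.expression_class.items():
            assert classes[tid] == "+".join(sorted(expected.split("+")))


class TestCounts:
    def test_all_zero_matrix(self):
        expr = _matrix(np.zeros((4, 9)), 3, 3, 3)
        assert (count_expressed_per_sample(expr, expr.features) == 0).all()

    def test_single_cell_above_threshold(self):
        values = np.zeros((2, 9))
        values[1, 4] = 5.0
        expr = _matrix(values, 3, 3, 3)
        counts = count_expressed_per_sample(expr, expr.features)
        assert counts["N1"] == 1 and counts.drop("N1").eq(0).all()

    def test_matches_direct_recount(self, rng):
        values = rng.uniform(0, 1, size=(20, 9))
        expr = _matrix(values, 3, 3, 3)
        counts = count_expressed_per_sample(expr, expr.features)
        assert (counts.values == (values > 0.1).sum(axis=0)).all()


class TestOutliers:
    def test_constant_feature_yields_no_flags(self):
        expr = _matrix(np.full((1, 9), 3.0), 5, 2, 2)
        assert flag_outliers(expr, ["f0"], k=10) == []

    def test_boundary_is_inclusive(self):
        # mean 2, population SD exactly 1: the cells at 3.0 sit exactly at
        # mean + 1*SD and must be flagged at k=1 (>= comparison)
        row = np.array([1.0, 1.0, 1.0, 1.0, 3.0, 3.0, 3.0, 3.0])
        expr = _matrix(row[None, :], 8, 0, 0)
        flags = flag_outliers(expr, ["f0"], k=1.0)
        assert set(flags) == {("f0", s) for s in ("T4", "T5", "T6", "T7")}

    def test_scale_equivariance(self, rng):
        values = rng.lognormal(size=(6, 12))
        expr = _matrix(values, 12, 0, 0)
        scaled = _matrix(values * 7.5, 12, 0, 0)
        assert flag_outliers(expr, expr.features, k=2) == flag_outliers(
            scaled, scaled.features, k=2)

    def test_planted_outliers_recovered_exactly(self, dataset):
        flags = flag_outliers(dataset.expression, list(dataset.truth.transcript_class),
                              group="tumor", k=10)
        assert set(flags) == set(dataset.truth.outliers)


class TestDifferentialExpression:
    def test_identical_groups_give_t0_p1(self):
        values = np.ones((3, 8))
        expr = _matrix(values, 8, 0, 0, subtypes=["ABC"] * 4 + ["GCB"] * 4)
        table = differential_expression(expr, expr.features)
        assert (table["t_statistic"] == 0).all() and (table["p_value"] == 1).all()

    def test_matches_hand_computed_welch(self):
        values = np.array([[1.0, 2.0, 3.0, 2.0, 3.0, 4.0]])
        expr = _matrix(values, 6, 0, 0, subtypes=["ABC"] * 3 + ["GCB"] * 3)
        table = differential_expression(expr, expr.features)
        t_ref, dof = welch_t_brute([1, 2, 3], [2, 3, 4])
        assert table.loc[0, "t_statistic"] == pytest.approx(t_ref)
        p_ref = 2 * stats.t.sf(abs(t_ref), dof)
        assert table.loc[0, "p_value"] == pytest.approx(p_ref)

    def test_q_values_monotone_in_p(self, rng):
        values = rng.lognormal(size=(40, 12))
        expr = _matrix(values, 12, 0, 0, subtypes=["ABC"] * 6 + ["GCB"] * 6)
        table = differential_expression(expr, expr.features)
        ordered = table.sort_values("p_value")
        assert (np.diff(ordered["q_value"].values) >= -1e-12).all()
        assert ((table["q_value"] >= table["p_value"] - 1e-12)
                & (table["q_value"] <= 1)).all()


class TestCoexpression:
    def test_perfectly_monotone_pair(self):
        x = np.arange(1.0, 11.0)
        values = np.vstack([x, np.exp(x)])
        expr = _matrix(values, 10, 0, 0)
        edges = coexpression(expr, ["f0"], ["f1"], fdr=1.0)
        assert edges.loc[0, "spearman_rho"] == pytest.approx(1.0)

    def test_reversed_ranks(self):
        x = np.arange(1.0, 11.0)
        values = np.vstack([x, 11.0 - x])
        expr = _matrix(values, 10, 0, 0)
        edges = coexpression(expr, ["f0"], ["f1"], fdr=1.0)
        assert edges.loc[0, "spearman_rho"] == pytest.approx(-1.0)

    def test_monotone_transform_invariance(self, rng):
        base = rng.lognormal(size=(2, 30))
        expr1 = _matrix(base, 30, 0, 0)
        transformed = np.vstack([np.exp(base[0]), base[1] ** 3])
        expr2 = _matrix(transformed, 30, 0, 0)
        e1 = coexpression(expr1, ["f0"], ["f1"], fdr=1.0)
        e2 = coexpression(expr2, ["f0"], ["f1"], fdr=1.0)
        assert e1.loc[0, "spearman_rho"] == pytest.approx(e2.loc[0, "spearman_rho"])

    def test_constant_vector_skipped_with_warning(self):
        values = np.vstack([np.ones(10), np.arange(10.0)])
        expr = _matrix(values, 10, 0, 0)
        with pytest.warns(UserWarning, match="constant"):
            edges = coexpression(expr, ["f0"], ["f1"], fdr=1.0)
        assert edges.empty

    def test_planted_correlation_recovery_and_error_control(self, rng):
        """Planted rho~0.8 pairs are recovered at FDR 0.2; null pairs are
        admitted at roughly the nominal rate on average."""
        n, reps = 100, 30
        recovered, fdp = [], []
        for _ in range(reps):
            u = rng.normal(size=(10, n))
            lnc = np.exp(0.9 * u + 0.45 * rng.normal(size=(10, n)))
            genes = np.vstack([np.exp(0.9 * u + 0.45 * rng.normal(size=(10, n))),
                               rng.lognormal(size=(30, n))])
            values = np.vstack([lnc, genes])
            expr = _matrix(values, n, 0, 0)
            lnc_ids = [f"f{i}" for i in range(10)]
            gene_ids = [f"f{i}" for i in range(10, 50)]
            edges = coexpression(expr, lnc_ids, gene_ids, fdr=0.2)
            planted = {(f"f{i}", f"f{i + 10}") for i in range(10)}
            called = set(zip(edges["lncRNA"], edges["gene"]))
            recovered.append(len(called & planted) / len(planted))
            fdp.append(len(called - planted) / max(1, len(called)))
        assert np.mean(recovered) >= 0.9
        assert np.mean(fdp) <= 0.25


class TestEnrichment:
    def test_partner_set_equals_gene_set(self):
        universe = [f"g{i}" for i in range(10)]
        partner = set(universe[:4])
        results = enrich_gene_sets(partner, {"S": universe[:4]}, universe)
        from math import comb

        assert results[0].p_value == pytest.approx(1 / comb(10, 4))

    def test_empty_partner_set_gives_p1(self):
        universe = [f"g{i}" for i in range(10)]
        results = enrich_gene_sets(set(), {"S": universe[:4]}, universe)
        assert results[0].p_value == 1.0

    def test_empty_universe_is_an_error(self):
        with pytest.raises(ValidationError):
            enrich_gene_sets(set(), {"S": ["g"]}, set())

    def test_expected_overlap_is_never_significant(self, rng):
        universe = [f"g{i}" for i in range(100)]
        for _ in range(20):
            partner = set(rng.choice(universe, size=20, replace=False))
            sets = {"S": list(rng.choice(universe, size=30, replace=False))}
            res = enrich_gene_sets(partner, sets, universe)[0]
            if res.overlap <= 6:  # expectation = 20*30/100 = 6
                assert res.p_value > 0.3

    def test_knockdown_full_overlap_exact_combinatorics(self):
        from math import comb

        universe = [f"g{i}" for i in range(20)]
        s = set(universe[:10])
        res = knockdown_concordance(s, s, universe)
        assert res.p_value == pytest.approx(1 / comb(20, 10))

    def test_hypergeometric_matches_enumeration_small_universes(self, rng):
        for _ in range(25):
            m = int(rng.integers(4, 13))
            na = int(rng.integers(1, m))
            nb = int(rng.integers(1, m))
            k = int(rng.integers(0, min(na, nb) + 1))
            assert hypergeom_upper_tail(k, m, na, nb) == pytest.approx(
                hypergeom_enumerate(m, na, nb, k))

    def test_zero_overlap_tiny_expectation_p_near_one(self):
        res = knockdown_concordance({"g0"}, {"g1"}, [f"g{i}" for i in range(100)])
        assert res.p_value > 0.95
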