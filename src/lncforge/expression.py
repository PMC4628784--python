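"""Expression-matrix statistics for novel lncRNAs.

Covers the expression-class partition across sample groups (tumor / normal
/ cell line), per-sample expressed counts, extreme-expression outlier
flagging, ABC-versus-GCB differential expression (Welch t-test with
Benjamini-Hochberg FDR control), Spearman co-expression against
protein-coding genes, and hypergeometric enrichment of gene sets and
knockdown-response concordance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import ValidationError

TUMOR, NORMAL, CELL_LINE = "tumor", "normal", "cell_line"


@dataclass
class ExpressionMatrix:
    """FPKM values (features x samples) with sample-group and subtype labels."""

    values: pd.DataFrame
    groups: pd.Series
    subtypes: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValidationError("expression matrix contains missing cells")
        if (self.values.values < 0).any():
            raise ValidationError("FPKM values must be non-negative")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ValidationError(f"samples without group label: {missing}")

    @property
    def samples(self) -> list:
        return list(self.values.columns)

    @property
    def features(self) -> list:
        return list(self.values.index)

    def samples_in(self, group: str) -> list:
        return [s for s in self.values.columns if self.groups[s] == group]

    def samples_with_subtype(self, subtype: str) -> list:
        if self.subtypes is None:
            return []
        return [
            s
            for s in self.values.columns
            if s in self.subtypes.index and self.subtypes[s] == subtype
        ]


@dataclass
class EnrichmentResult:
    query_id: str
    gene_set: str
    overlap: int
    query_size: int
    set_size: int
    universe_size: int
    p_value: float
    adjusted_p: float = float("nan")


def partition_expression_classes(
    expr: ExpressionMatrix,
    features,
    min_fpkm: float = 0.1,
    min_samples: int = 2,
    groups=(TUMOR, NORMAL, CELL_LINE),
) -> pd.Series:
    """Per-feature expression class: the subset of groups it is expressed in.

    A feature is expressed in a group iff FPKM > ``min_fpkm`` (strict) in at
    least ``min_samples`` samples of that group.  The class label is a
    '+'-joined sorted tuple of group names ('none' when expressed nowhere).
    """
    for group in groups:
        n = len(expr.samples_in(group))
        if n < min_samples:
            raise ValidationError(f"group {group!r} has {n} samples (< {min_samples})")
    sub = expr.values.loc[list(features)]
    expressed = {}
    for group in groups:
        cols = expr.samples_in(group)
        expressed[group] = (sub[cols] > min_fpkm).sum(axis=1) >= min_samples
    labels = []
    for feature in sub.index:
        present = sorted(g for g in groups if expressed[g][feature])
        labels.append("+".join(present) if present else "none")
    return pd.Series(labels, index=sub.index, name="expression_class")


def count_expressed_per_sample(expr: ExpressionMatrix, features, min_fpkm: float = 0.1) -> pd.Series:
    """Per-sample count of features with FPKM strictly above the threshold."""
    sub = expr.values.loc[list(features)]
    return (sub > min_fpkm).sum(axis=0)


def flag_outliers(
    expr: ExpressionMatrix, features, group: str = TUMOR, k: float = 10.0
) -> list:
    """(feature, sample) pairs with FPKM >= mean + k * SD within the group.

    Mean and SD (population, ddof=0) are computed per feature across the
    group's samples; features with zero SD yield no flags.
    """
    cols = expr.samples_in(group)
    if len(cols) < 3:
        raise ValidationError(f"group {group!r} needs >= 3 samples for outlier flagging")
    sub = expr.values.loc[list(features), cols]
    mat = sub.to_numpy(dtype=float)
    means = mat.mean(axis=1, keepdims=True)
    sds = mat.std(axis=1, ddof=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        flagged = (mat >= means + k * sds) & (sds > 0)
    pairs = []
    for fi, si in zip(*np.nonzero(flagged)):
        pairs.append((sub.index[fi], cols[si]))
    return pairs


def differential_expression(
    expr: ExpressionMatrix,
    features,
    label_a: str = "ABC",
    label_b: str = "GCB",
    alpha: float = 0.05,
    log2_offset: float | None = None,
) -> pd.DataFrame:
    """Welch t-test per feature between two subtype-labelled sample sets.

    Raw FPKM by default; set ``log2_offset`` to test log2(FPKM + offset).
    Benjamini-Hochberg q-values are computed across all tested features;
    rows are sorted by q then p.  Features with zero variance and equal
    means in both groups get t = 0, p = 1 by definition.
    """
    cols_a = expr.samples_with_subtype(label_a)
    cols_b = expr.samples_with_subtype(label_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValidationError(
            f"need >= 2 samples per subtype, got {len(cols_a)} {label_a} / {len(cols_b)} {label_b}"
        )
    sub = expr.values.loc[list(features)]
    a = sub[cols_a].to_numpy(dtype=float)
    b = sub[cols_b].to_numpy(dtype=float)
    if log2_offset is not None:
        a = np.log2(a + log2_offset)
        b = np.log2(b + log2_offset)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    degenerate = ~np.isfinite(t)
    equal_means = np.isclose(mean_a, mean_b)
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate & equal_means, 0.0, t)
        p = np.where(degenerate & equal_means, 1.0, p)
        # zero variance but different means: infinitely strong evidence
        t = np.where(degenerate & ~equal_means, np.sign(mean_a - mean_b) * np.inf, t)
        p = np.where(degenerate & ~equal_means, 0.0, p)
    _reject, q, _, _ = multipletests(p, method="fdr_bh")
    out = pd.DataFrame(
        {
            "feature": sub.index,
            f"mean_{label_a}": mean_a,
            f"mean_{label_b}": mean_b,
            "t_statistic": t,
            "p_value": p,
            "q_value": q,
            "significant": q < alpha,
        }
    )
    return out.sort_values(["q_value", "p_value"], kind="mergesort").reset_index(drop=True)


def _spearman_matrix(x: np.ndarray, y: np.ndarray):
    """Spearman rho between every row of x and every row of y (shared columns)."""
    rx = stats.rankdata(x, axis=1)
    ry = stats.rankdata(y, axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    nx = np.sqrt((rx ** 2).sum(axis=1))
    ny = np.sqrt((ry ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rx @ ry.T) / np.outer(nx, ny)
    return rho, nx == 0, ny == 0


def coexpression(
    expr: ExpressionMatrix,
    lncRNAs,
    coding_genes,
    fdr: float = 0.2,
    group: str = TUMOR,
) -> pd.DataFrame:
    """Significant Spearman co-expression edges between lncRNAs and genes.

    Average-rank ties, p-values from the t-approximation, and a single
    Benjamini-Hochberg adjustment across all lncRNA x gene pairs jointly.
    Constant vectors have undefined rho and are skipped with a warning.
    Returns edges with q < ``fdr``.
    """
    cols = expr.samples_in(group)
    if len(cols) < 5:
        raise ValidationError(f"co-expression requires >= 5 samples, got {len(cols)}")
    n = len(cols)
    x = expr.values.loc[list(lncRNAs), cols].to_numpy(dtype=float)
    y = expr.values.loc[list(coding_genes), cols].to_numpy(dtype=float)
    rho, const_x, const_y = _spearman_matrix(x, y)
    if const_x.any() or const_y.any():
        skipped = [f for f, c in zip(lncRNAs, const_x) if c]
        skipped += [g for g, c in zip(coding_genes, const_y) if c]
        warnings.warn(f"constant expression vectors skipped in co-expression: {skipped[:5]}")
    valid = ~np.outer(const_x, const_y)
    rho_flat = rho[valid]
    r = np.clip(rho_flat, -1 + 1e-12, 1 - 1e-12)
    t = r * np.sqrt((n - 2) / (1 - r ** 2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(rho_flat) >= 1.0 - 1e-12] = 0.0
    _rej, q, _, _ = multipletests(p, method="fdr_bh")
    li, gi = np.nonzero(valid)
    lnc_list, gene_list = list(lncRNAs), list(coding_genes)
    edges = pd.DataFrame(
        {
            "lncRNA": [lnc_list[i] for i in li],
            "gene": [gene_list[j] for j in gi],
            "spearman_rho": rho_flat,
            "p_value": p,
            "q_value": q,
        }
    )
    return edges[edges["q_value"] < fdr].sort_values(
        ["q_value", "p_value"], kind="mergesort"
    ).reset_index(drop=True)


def partner_sets(edges: pd.DataFrame) -> dict:
    """Per-lncRNA sets of significantly co-expressed genes."""
    return {lnc: set(sub["gene"]) for lnc, sub in edges.groupby("lncRNA")}


def hypergeom_upper_tail(overlap: int, universe: int, size_a: int, size_b: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(universe, size_a, size_b)."""
    return float(stats.hypergeom.sf(overlap - 1, universe, size_a, size_b))


def enrich_gene_sets(partner_set, gene_sets, universe, query_id: str = "query") -> list:
    """Hypergeometric enrichment of a partner set in each gene set.

    Bonferroni adjustment across gene sets.  ``partner_set`` must be a
    subset of ``universe``; gene sets are intersected with the universe.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    partner_set = set(partner_set)
    if not partner_set <= universe:
        raise ValidationError("partner set is not contained in the universe")
    results = []
    m = len(gene_sets)
    for name, members in gene_sets.items():
        members = set(members) & universe
        overlap = len(partner_set & members)
        p = hypergeom_upper_tail(overlap, len(universe), len(members), len(partner_set))
        results.append(
            EnrichmentResult(
                query_id=query_id,
                gene_set=name,
                overlap=overlap,
                query_size=len(partner_set),
                set_size=len(members),
                universe_size=len(universe),
                p_value=p,
                adjusted_p=min(1.0, p * m),
            )
        )
    return sorted(results, key=lambda r: (r.p_value, r.gene_set))


def knockdown_concordance(correlated_set, responsive_set, universe) -> EnrichmentResult:
    """Hypergeometric upper-tail test of the overlap between two lncRNA sets.

    Typical use: lncRNAs negatively correlated with a repressor versus
    lncRNAs upregulated upon its knockdown, within the universe of all
    tested lncRNAs.
    """
    universe = set(universe)
    correlated_set, responsive_set = set(correlated_set), set(responsive_set)
    if not (correlated_set <= universe and responsive_set <= universe):
        raise ValidationError("both sets must be contained in the universe")
    overlap = len(correlated_set & responsive_set)
    p = hypergeom_upper_tail(overlap, len(universe), len(correlated_set), len(responsive_set))
    return EnrichmentResult(
        query_id="knockdown_concordance",
        gene_set="responsive",
        overlap=overlap,
        query_size=len(correlated_set),
        set_size=len(responsive_set),
        universe_size=len(universe),
        p_value=p,
        adjusted_p=p,
    )
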