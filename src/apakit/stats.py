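"""Statistical kernel shared by the APA, decay and motif modules.

Exact tests (Fisher, hypergeometric overlap, small-sample rank tests) are
delegated to scipy, which enumerates exactly where feasible; this module owns
the conventions (two-tailed definitions, tail directions, degenerate-input
handling) so callers never touch scipy directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 contingency table; rows = group, columns = feature present/absent."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty contingency table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass(frozen=True)
class OverlapResult:
    """Hypergeometric overlap of two gene sets drawn from a finite universe."""

    n_a: int
    n_b: int
    n_universe: int
    n_intersection: int
    fraction_a: float
    p_enrich: float


def fisher_exact_2x2(table: ContingencyTable2x2) -> tuple[float, float]:
    """Two-tailed Fisher's exact test.

    Returns ``(odds_ratio, p)`` where the odds ratio is the sample odds
    ratio ad/bc (``inf`` when bc = 0) and the two-tailed p sums all tables
    with point probability <= that of the observed table at fixed margins.
    A degenerate table (a zero row or column) carries no information and
    returns p = 1 with a warning.
    """
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        warnings.warn("degenerate 2x2 table (zero margin); p = 1 by convention")
        bc = table.b * table.c
        odds = np.inf if bc == 0 else table.a * table.d / bc
        return odds, 1.0
    res = sps.fisher_exact(arr, alternative="two-sided")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def hypergeom_overlap(
    n_universe: int, n_a: int, n_b: int, n_intersection: int
) -> OverlapResult:
    """Upper-tail hypergeometric enrichment P[X >= n_intersection].

    X counts the overlap of a random size-``n_b`` draw from the universe with
    a fixed set of size ``n_a``; the reported tail includes the observed value.
    """
    if not (0 <= n_intersection <= min(n_a, n_b)):
        raise ValueError("intersection exceeds a set size (or is negative)")
    if max(n_a, n_b) > n_universe:
        raise ValueError("set larger than universe")
    p = float(sps.hypergeom.sf(n_intersection - 1, n_universe, n_a, n_b))
    frac = n_intersection / n_a if n_a else float("nan")
    return OverlapResult(n_a, n_b, n_universe, n_intersection, frac, min(p, 1.0))


def rank_tests(
    x: np.ndarray, y: np.ndarray, paired: bool, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Wilcoxon signed-rank (paired) or rank-sum / Mann-Whitney (unpaired).

    Exact null enumeration is used at small sample sizes, the tie-corrected
    normal approximation otherwise. Paired data in which every difference is
    zero give p = 1 (no evidence of a shift).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if x.shape != y.shape:
            raise ValueError("paired samples must have equal length")
        d = x - y
        d = d[d != 0]
        if d.size == 0:
            return 0.0, 1.0
        if d.size <= 20:
            # exact sign-flip enumeration; valid with tied differences,
            # where the tabulated exact null is not
            return _exact_signed_rank(d, alternative)
        res = sps.wilcoxon(x, y, alternative=alternative, method="auto")
    else:
        res = sps.mannwhitneyu(x, y, alternative=alternative, method="auto")
    return float(res.statistic), float(res.pvalue)


def _exact_signed_rank(d: np.ndarray, alternative: str) -> tuple[float, float]:
    """Exact signed-rank p over all 2^n sign assignments (meet-in-the-middle).

    Midranks handle tied |differences|; the two-sided p doubles the smaller
    tail (each tail including the observed statistic), capped at 1.
    """
    r = sps.rankdata(np.abs(d))
    w = float(r[d > 0].sum())

    def subset_sums(ranks: np.ndarray) -> np.ndarray:
        k = len(ranks)
        bits = (np.arange(2**k)[:, None] >> np.arange(k)) & 1
        return bits @ ranks

    half = len(r) // 2
    total = subset_sums(r[:half])[:, None] + subset_sums(r[half:])[None, :]
    n_all = total.size
    tol = 1e-9
    p_le = np.count_nonzero(total <= w + tol) / n_all
    p_ge = np.count_nonzero(total >= w - tol) / n_all
    if alternative == "two-sided":
        p = min(1.0, 2.0 * min(p_le, p_ge))
    elif alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return w, float(p)


def geneset_rank_test(
    logfc: dict[str, float], set_members: set[str], min_set_size: int = 5
) -> tuple[str, float]:
    """Rank-sum comparison of in-set vs out-of-set log fold-changes.

    Returns ``(direction, p)`` where direction is ``"up"`` when the in-set
    median exceeds the out-of-set median. Requires at least ``min_set_size``
    genes on each side with defined logFC.
    """
    inset = np.array([v for g, v in logfc.items() if g in set_members], dtype=float)
    outset = np.array([v for g, v in logfc.items() if g not in set_members], dtype=float)
    inset = inset[np.isfinite(inset)]
    outset = outset[np.isfinite(outset)]
    if len(inset) < min_set_size or len(outset) < min_set_size:
        raise ValueError(
            f"need >= {min_set_size} genes with defined logFC on each side "
            f"(got {len(inset)} in-set, {len(outset)} out-of-set)"
        )
    _, p = rank_tests(inset, outset, paired=False)
    direction = "up" if np.median(inset) > np.median(outset) else "down"
    return direction, p


def geneset_rank_tests(
    logfc: dict[str, float], sets: dict[str, set[str]], min_set_size: int = 5
) -> pd.DataFrame:
    """Run :func:`geneset_rank_test` over many sets with BH correction.

    Sets failing the size gate are skipped (reported with NaN p)."""
    rows = []
    for set_id, members in sets.items():
        try:
            direction, p = geneset_rank_test(logfc, members, min_set_size)
        except ValueError:
            warnings.warn(f"gene set {set_id!r} skipped (too few usable genes)")
            rows.append({"set_id": set_id, "direction": "NA", "p": np.nan})
            continue
        rows.append({"set_id": set_id, "direction": direction, "p": p})
    df = pd.DataFrame(rows).set_index("set_id")
    tested = df["p"].notna()
    df["p_adj"] = np.nan
    if tested.any():
        df.loc[tested, "p_adj"] = bh_adjust(df.loc[tested, "p"].to_numpy())
    return df


def median_of_ratios_normalize(
    gene_counts: pd.DataFrame,
) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors (DESeq-style) and the normalized matrix.

    The reference for each gene is its geometric mean across samples; only
    genes positive in every sample contribute. The size factor of a sample is
    the median of its count/reference ratios; normalized counts are raw
    counts divided by the sample's size factor.
    """
    counts = gene_counts.to_numpy(dtype=float)
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; "
            "add a pseudocount or filter samples"
        )
    ref = counts[all_positive]
    log_geo_mean = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geo_mean[:, None]
    size_factors = pd.Series(
        np.exp(np.median(ratios, axis=0)), index=gene_counts.columns, name="size_factor"
    )
    normalized = gene_counts / size_factors
    return size_factors, normalized


@dataclass
class AnovaTukeyResult:
    f_statistic: float
    p_omnibus: float
    group_means: pd.Series
    pairwise: pd.DataFrame  # columns: group_a, group_b, p_adj


def anova_tukey(groups: dict[str, np.ndarray]) -> AnovaTukeyResult:
    """One-way ANOVA with Tukey HSD pairwise comparisons.

    Degenerate input with zero variance everywhere and equal means returns
    p = 1 (no evidence against equality).
    """
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    means = pd.Series([a.mean() for a in arrays], index=labels, name="mean")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        pairwise = pd.DataFrame(
            [
                {"group_a": labels[i], "group_b": labels[j], "p_adj": 1.0}
                for i in range(len(labels))
                for j in range(i + 1, len(labels))
            ]
        )
        return AnovaTukeyResult(0.0, 1.0, means, pairwise)
    f_stat, p = sps.f_oneway(*arrays)
    if np.isnan(p) and f_stat <= 1e-12:
        # rounding can drive the F statistic a hair below zero when the
        # between-group variance is exactly zero
        f_stat, p = 0.0, 1.0
    tk = sps.tukey_hsd(*arrays)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            rows.append(
                {"group_a": labels[i], "group_b": labels[j], "p_adj": float(tk.pvalue[i, j])}
            )
    return AnovaTukeyResult(float(f_stat), float(p), means, pd.DataFrame(rows))


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj
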