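"""FPKM arithmetic, expression binning, two-library differential expression,
cross-platform intersection with microarray z-scores, and GO enrichment.

The two-library test (no replicates) is a two-sided exact binomial test of a
gene's count in library A among its pooled counts, against the proportion
expected from the library sizes. DE calls require P < 0.001 and a linear
fold change > 2 (|log2 FC| > 1); the cross-platform set additionally
requires a microarray breed z-score with |z| > 1.65.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

FPKM_BINS = ((0, 1), (1, 10), (10, 100), (100, 1000), (1000, 10000),
             (10000, math.inf))
FPKM_BIN_LABELS = ("<1", "[1,10)", "[10,100)", "[100,1000)",
                   "[1000,10000)", ">=10000")

POS_INF = math.inf
NEG_INF = -math.inf
UNDEF = math.nan


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    fragment_count: int
    exonic_length: int
    fpkm: float

    def __post_init__(self) -> None:
        if self.fragment_count < 0 or self.fpkm < 0:
            raise ValueError(f"{self.gene_id}: negative count or FPKM")


@dataclass(frozen=True)
class DECall:
    gene_id: str
    log2_fc: float  # ±inf sentinels allowed
    p_value: float
    called: bool


def fpkm(count: int, exonic_length_bp: int, total_mapped_fragments: int) -> float:
    """Fragments per kilobase of exon per million mapped fragments."""
    if exonic_length_bp <= 0:
        raise ValueError("exonic_length_bp must be positive")
    if total_mapped_fragments <= 0:
        raise ValueError("total_mapped_fragments must be positive")
    return count / (exonic_length_bp / 1e3) / (total_mapped_fragments / 1e6)


def bin_expression(fpkms) -> pd.Series:
    """Histogram of FPKM values over half-open decade bins [lo, hi)."""
    x = np.asarray(list(fpkms), dtype=float)
    counts = [
        int(np.sum((x >= lo) & (x < hi))) for lo, hi in FPKM_BINS
    ]
    return pd.Series(counts, index=list(FPKM_BIN_LABELS), name="n_genes")


def log2_fold_change(fpkm_a: float, fpkm_b: float) -> float:
    """log2(a/b) with ±inf sentinels for zero denominators/numerators and
    NaN when both are zero (excluded from correlations)."""
    if fpkm_a < 0 or fpkm_b < 0:
        raise ValueError("FPKM values must be non-negative")
    if fpkm_a == 0 and fpkm_b == 0:
        return UNDEF
    if fpkm_b == 0:
        return POS_INF
    if fpkm_a == 0:
        return NEG_INF
    return math.log2(fpkm_a / fpkm_b)


def de_test_counts(k_a: int, k_b: int, N_a: int, N_b: int) -> float:
    """Two-sided exact binomial p-value for a two-library count comparison.

    Tests k_a successes among k_a + k_b trials against the null proportion
    N_a / (N_a + N_b) set by the library sizes. Returns 1.0 for genes with
    no counts.
    """
    if N_a <= 0 or N_b <= 0:
        raise ValueError("library sizes must be positive")
    if k_a < 0 or k_b < 0 or k_a > N_a or k_b > N_b:
        raise ValueError("invalid counts")
    n = k_a + k_b
    if n == 0:
        return 1.0
    return float(stats.binomtest(k_a, n, N_a / (N_a + N_b)).pvalue)


def call_de(
    table: pd.DataFrame,
    p_threshold: float = 0.001,
    fc_threshold: float = 2.0,
    min_count: int = 40,
) -> list[DECall]:
    """DE calls from a count table with columns gene_id, count_a, count_b
    and optionally fpkm_a/fpkm_b (else library-size-normalised counts).

    A gene is expressed when count_a + count_b ≥ ``min_count``; it is called
    DE when p < ``p_threshold`` and its linear fold change exceeds
    ``fc_threshold`` in either direction.
    """
    N_a = int(table["count_a"].sum())
    N_b = int(table["count_b"].sum())
    out = []
    log2_thr = math.log2(fc_threshold)
    for row in table.itertuples():
        k_a, k_b = int(row.count_a), int(row.count_b)
        if k_a + k_b < min_count:
            continue
        if hasattr(row, "fpkm_a"):
            lfc = log2_fold_change(row.fpkm_a, row.fpkm_b)
        else:
            lfc = log2_fold_change(k_a / N_a if N_a else 0.0, k_b / N_b if N_b else 0.0)
        p = de_test_counts(k_a, k_b, N_a, N_b)
        called = p < p_threshold and (math.isinf(lfc) or abs(lfc) > log2_thr)
        out.append(DECall(row.gene_id, lfc, p, called))
    return out


def intersect_platforms(
    de_calls, z_scores: pd.Series | dict, z_threshold: float = 1.65
) -> dict:
    """Genes called DE by sequencing AND with |microarray z| > threshold.

    Returns the intersection plus the per-platform set sizes for a
    Venn-style summary.
    """
    z = pd.Series(z_scores)
    de_set = {c.gene_id for c in de_calls if c.called}
    z_set = {g for g, v in z.items() if abs(v) > z_threshold}
    inter = sorted(de_set & z_set)
    return {
        "intersection": inter,
        "n_intersection": len(inter),
        "n_de_seq": len(de_set),
        "n_de_array": len(z_set),
    }


def go_fisher(
    de_genes, background_genes, term_map: dict, adjust: bool = False
) -> pd.DataFrame:
    """Two-sided Fisher's exact test of each GO term's representation among
    DE genes versus the background.

    ``term_map`` maps term id -> iterable of gene ids. Raw p-values are
    reported; Benjamini-Hochberg adjustment is optional and off by default.
    """
    de = set(de_genes)
    bg = set(background_genes)
    if not bg:
        raise ValueError("background gene set is empty")
    if not de <= bg:
        raise ValueError("DE genes must be a subset of the background")
    rows = []
    for term, genes in term_map.items():
        g = set(genes) & bg
        a = len(de & g)               # DE, in term
        b = len(de) - a               # DE, not in term
        c = len(g) - a                # background-only, in term
        d = len(bg) - len(de) - c     # background-only, not in term
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append({"term": term, "de_in_term": a, "bg_in_term": len(g),
                     "p_value": float(p)})
    df = pd.DataFrame(rows, columns=["term", "de_in_term", "bg_in_term", "p_value"])
    if adjust and len(df):
        df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df


def expression_correlation(values_a, values_b) -> float:
    """Pearson correlation after dropping non-finite pairs (the infinite
    fold-change sentinels and NaNs). Returns NaN when fewer than 3 finite
    pairs remain or a vector is constant."""
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if a.size < 3 or np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(stats.pearsonr(a, b)[0])
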