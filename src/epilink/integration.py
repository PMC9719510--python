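"""Fold-change integration statistics.

Pearson correlation of paired (mRNA log2FC, signal log2FC) values per
region class, quadrant proportions of the same scatter, and
hypergeometric overlap enrichment between differential-peak genes and
differential-expression genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .study_stats import GeneSet


@dataclass
class IntegrationResult:
    """Correlation and quadrant summary for one region class.

    Quadrants follow the usual orientation on a (x = mRNA log2FC,
    y = signal log2FC) scatter: Q1 (+,+), Q2 (-,+), Q3 (-,-), Q4 (+,-).
    Points on either axis are excluded from the fractions and counted
    in ``n_excluded_on_axis``.
    """

    region_class: str
    n_genes: int
    pearson_r: float
    pearson_p: float
    quadrant_fractions: tuple[float, float, float, float]
    n_excluded_on_axis: int

    @property
    def significant(self) -> bool:
        return self.pearson_p < 0.05

    @property
    def significance_label(self) -> str:
        return "NS" if self.pearson_p >= 0.05 else f"p={self.pearson_p:.3g}"


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with the two-sided p-value from
    t = r * sqrt(n-2) / sqrt(1-r^2) on n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError(f"need n >= 3 pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: constant input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def quadrant_proportions(
    x: Sequence[float], y: Sequence[float]
) -> tuple[tuple[float, float, float, float], int]:
    """Fractions of points per quadrant, excluding on-axis points.

    Returns ((Q1, Q2, Q3, Q4), n_excluded). With every point on an
    axis the fractions are undefined and reported as NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    on_axis = (x == 0) | (y == 0)
    n_excluded = int(on_axis.sum())
    xs, ys = x[~on_axis], y[~on_axis]
    n = len(xs)
    if n == 0:
        return (float("nan"),) * 4, n_excluded
    q1 = int(((xs > 0) & (ys > 0)).sum())
    q2 = int(((xs < 0) & (ys > 0)).sum())
    q3 = int(((xs < 0) & (ys < 0)).sum())
    q4 = int(((xs > 0) & (ys < 0)).sum())
    return (q1 / n, q2 / n, q3 / n, q4 / n), n_excluded


@dataclass
class OverlapEnrichment:
    """2x2 overlap of two gene sets within a universe."""

    universe_size: int
    n_set_a: int
    n_set_b: int
    n_overlap: int
    odds_ratio: float
    pvalue: float


def overlap_enrichment(
    set_a: GeneSet | Iterable[str],
    set_b: GeneSet | Iterable[str],
    universe: GeneSet | Iterable[str],
) -> OverlapEnrichment:
    """One-sided hypergeometric over-enrichment of the overlap of two
    gene sets drawn from a common universe, with a Haldane 0.5
    correction on the odds ratio when a contingency cell is zero."""
    a = set(set_a.gene_ids if isinstance(set_a, GeneSet) else set_a)
    b = set(set_b.gene_ids if isinstance(set_b, GeneSet) else set_b)
    u = set(universe.gene_ids if isinstance(universe, GeneSet) else universe)
    if not u:
        raise ValueError("empty universe")
    if not a <= u or not b <= u:
        raise ValueError("both sets must be subsets of the universe")
    n, na, nb = len(u), len(a), len(b)
    k = len(a & b)
    n11, n10, n01 = k, na - k, nb - k
    n00 = n - na - nb + k
    cells = np.array([n11, n10, n01, n00], dtype=float)
    if np.any(cells == 0):
        cells = cells + 0.5
    odds_ratio = (cells[0] * cells[3]) / (cells[1] * cells[2])
    pvalue = float(stats.hypergeom.sf(k - 1, n, na, nb))
    return OverlapEnrichment(
        universe_size=n,
        n_set_a=na,
        n_set_b=nb,
        n_overlap=k,
        odds_ratio=float(odds_ratio),
        pvalue=min(pvalue, 1.0),
    )


def correlate_expression_signal(
    expression_fc: pd.DataFrame,
    region_fc: pd.DataFrame,
    region_class: str = "summed",
    gene_set: GeneSet | None = None,
) -> IntegrationResult:
    """Correlate per-gene mRNA log2FC with per-gene signal log2FC.

    ``expression_fc`` needs columns gene_id and log2fc; ``region_fc``
    is either the long-format output of
    :func:`epilink.peak_integration.gene_region_avg_log2fc` (select one
    ``region_class``) or the summed-counts table
    (``region_class="summed"``, column summed_log2fc). Genes are
    inner-joined: a gene with no observed peak in the class is dropped
    rather than imputed at zero. Fewer than 3 joined genes is an error
    reporting the join size.
    """
    expr = expression_fc[["gene_id", "log2fc"]].rename(columns={"log2fc": "mrna_log2fc"})
    if gene_set is not None:
        expr = expr[expr["gene_id"].isin(set(gene_set.gene_ids))]
    if region_class == "summed":
        sig = region_fc[["gene_id", "summed_log2fc"]].rename(
            columns={"summed_log2fc": "signal_log2fc"}
        )
    else:
        sel = region_fc[region_fc["region_class"] == region_class]
        sig = sel[["gene_id", "avg_log2fc"]].rename(columns={"avg_log2fc": "signal_log2fc"})
    joined = expr.merge(sig, on="gene_id", how="inner")
    if len(joined) < 3:
        raise ValueError(
            f"region class {region_class!r}: only {len(joined)} genes joined "
            "between expression and signal tables (need >= 3)"
        )
    x = joined["mrna_log2fc"].to_numpy()
    y = joined["signal_log2fc"].to_numpy()
    r, p = pearson_correlation(x, y)
    fractions, excluded = quadrant_proportions(x, y)
    return IntegrationResult(
        region_class=region_class,
        n_genes=len(joined),
        pearson_r=r,
        pearson_p=p,
        quadrant_fractions=fractions,
        n_excluded_on_axis=excluded,
    )


def integration_table(results: Iterable[IntegrationResult]) -> pd.DataFrame:
    """One row per region class, percentages on the 0-100 scale."""
    rows = []
    for res in results:
        q = res.quadrant_fractions
        rows.append(
            {
                "region_class": res.region_class,
                "n_genes": res.n_genes,
                "pearson_r": res.pearson_r,
                "pearson_p": res.pearson_p,
                "significance": res.significance_label,
                "q1_pct": 100 * q[0],
                "q2_pct": 100 * q[1],
                "q3_pct": 100 * q[2],
                "q4_pct": 100 * q[3],
                "n_excluded_on_axis": res.n_excluded_on_axis,
            }
        )
    return pd.DataFrame(rows)
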