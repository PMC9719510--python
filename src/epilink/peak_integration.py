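"""Consensus peaks, count normalisation, and per-gene fold-change statistics.

The differential engine here is a deliberately simple, documented
stand-in for a negative-binomial count model: median-of-ratios size
factors, a Welch t-test on log2(normalized count + 1) when replicates
allow it, and Benjamini-Hochberg adjustment across all consensus peaks.
The quantities the rest of the pipeline consumes are the two per-gene
aggregations:

* ``gene_summed_fc`` -- log2 fold change of the summed normalized
  counts of all peaks at a gene locus (promoter_5utr + genebody), and
* ``gene_region_avg_log2fc`` -- per gene and region class, the mean of
  the per-peak log2 fold changes regardless of significance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome_model import (
    GENEBODY,
    INTERGENIC,
    PROMOTER,
    GenomicInterval,
    RegionPartition,
    assign_region,
    merge_intervals,
)


@dataclass
class ConsensusPeaks:
    """Merged peak union across conditions, with per-peak provenance."""

    peaks: list[GenomicInterval]
    provenance: list[tuple[str, ...]]

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for p, prov in zip(self.peaks, self.provenance):
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{','.join(prov)}\n")


def build_consensus_peaks(
    peak_sets: Mapping[str, Sequence[GenomicInterval]]
) -> ConsensusPeaks:
    """Merge peak calls from all conditions into disjoint consensus peaks.

    The result is the interval union of all inputs; each consensus peak
    records which conditions contributed at least one overlapping call.
    Output is invariant to the order in which conditions are supplied.
    """
    merged = merge_intervals(p for peaks in peak_sets.values() for p in peaks)
    per_cond = {cond: merge_intervals(peaks) for cond, peaks in peak_sets.items()}
    provenance: list[tuple[str, ...]] = []
    for peak in merged:
        conds = [
            cond
            for cond in sorted(per_cond)
            if any(
                iv.chrom == peak.chrom and iv.start < peak.end and iv.end > peak.start
                for iv in per_cond[cond]
            )
        ]
        provenance.append(tuple(conds))
    return ConsensusPeaks(peaks=merged, provenance=provenance)


def read_peaks_bed(source) -> list[GenomicInterval]:
    """Read BED3+/narrowPeak; columns beyond chrom/start/end are ignored."""
    out = []
    close = False
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        source = open(source)
        close = True
    try:
        for lineno, line in enumerate(source, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"BED line {lineno}: expected >= 3 columns")
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2])))
    finally:
        if close:
            source.close()
    return out


# ---------------------------------------------------------------------------
# annotation

def annotate_peaks(
    peaks: Sequence[GenomicInterval],
    partition: RegionPartition,
    ids: Sequence[str] | None = None,
    rule: str = "midpoint",
    intergenic_nearest: bool = True,
) -> pd.DataFrame:
    """Assign each peak a region class and a gene.

    Promoter/genebody peaks get the gene owning the region (closest TSS
    on ties). Distal intergenic peaks carry no region-owning gene; when
    ``intergenic_nearest`` is set (default) they are attributed to the
    nearest-TSS gene, the convention of standard peak annotators, so
    that intergenic signal can still enter per-gene statistics.
    """
    if ids is None:
        ids = [f"{p.chrom}:{p.start}-{p.end}" for p in peaks]
    if len(ids) != len(peaks):
        raise ValueError("ids and peaks length mismatch")
    rows = []
    for pid, peak in zip(ids, peaks):
        region_class, gid = assign_region(peak, partition, rule=rule)
        if region_class == INTERGENIC and gid is None and intergenic_nearest:
            gid = partition.nearest_gene(peak.chrom, peak.midpoint)
        rows.append((pid, peak.chrom, peak.start, peak.end, region_class, gid))
    df = pd.DataFrame(
        rows, columns=["peak_id", "chrom", "start", "end", "region_class", "gene_id"]
    ).set_index("peak_id")
    return df


def map_counts_to_consensus(
    counts: pd.DataFrame, consensus: ConsensusPeaks
) -> pd.DataFrame:
    """Re-key a raw count table (chrom/start/end + sample columns) onto
    consensus peaks by midpoint containment; counts of called peaks that
    map to the same consensus peak are summed. Rows mapping to no
    consensus peak are dropped with a warning.
    """
    sample_cols = [c for c in counts.columns if c not in ("chrom", "start", "end")]
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[int]]] = {}
    for chrom in {p.chrom for p in consensus.peaks}:
        idx = [i for i, p in enumerate(consensus.peaks) if p.chrom == chrom]
        by_chrom[chrom] = (
            np.array([consensus.peaks[i].start for i in idx]),
            np.array([consensus.peaks[i].end for i in idx]),
            idx,
        )
    target = np.full(len(counts), -1, dtype=int)
    mids = ((counts["start"].to_numpy() + counts["end"].to_numpy()) // 2).astype(int)
    for r, (chrom, mid) in enumerate(zip(counts["chrom"].to_numpy(), mids)):
        if chrom not in by_chrom:
            continue
        starts, ends, idx = by_chrom[chrom]
        k = int(np.searchsorted(starts, mid, side="right")) - 1
        if k >= 0 and mid < ends[k]:
            target[r] = idx[k]
    unmapped = int((target < 0).sum())
    if unmapped:
        warnings.warn(f"{unmapped} counted peak(s) map to no consensus peak; dropped")
    ids = [f"{p.chrom}:{p.start}-{p.end}" for p in consensus.peaks]
    out = pd.DataFrame(0, index=ids, columns=sample_cols, dtype=float)
    grouped = (
        counts.loc[target >= 0, sample_cols]
        .groupby(target[target >= 0])
        .sum()
    )
    for i, row in grouped.iterrows():
        out.iloc[int(i)] = row
    return out


# ---------------------------------------------------------------------------
# normalisation and differential statistics

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    The reference for each peak is the geometric mean of its counts
    over samples (peaks with any zero excluded); a sample's factor is
    the median of its count/reference ratios. When no all-positive
    peak exists, library-size factors (column sum over the geometric
    mean of column sums) are used instead, with a warning.
    """
    m = counts.to_numpy(dtype=float)
    if m.size == 0 or m.sum() == 0:
        raise ValueError("all-zero count matrix: size factors undefined")
    positive = (m > 0).all(axis=1)
    if positive.any():
        logm = np.log(m[positive])
        log_ref = logm.mean(axis=1)
        factors = np.exp(np.median(logm - log_ref[:, None], axis=0))
    else:
        warnings.warn(
            "no peak with all-positive counts; falling back to library-size factors"
        )
        colsum = m.sum(axis=0)
        if np.any(colsum == 0):
            bad = counts.columns[colsum == 0][0]
            raise ValueError(f"sample {bad!r} has zero total counts")
        factors = colsum / np.exp(np.mean(np.log(colsum)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


@dataclass
class PeakDifferential:
    """Per-peak log2 fold change and significance of the stand-in test.

    ``table`` columns: log2fc, pvalue, padj, significant_up,
    significant_down. With fewer than two replicates per condition no
    test is possible: p-values are NaN, ``pvalue_proxy`` is True, and
    significance is proxied by |log2fc| >= 1.
    """

    table: pd.DataFrame
    alpha: float
    conditions: tuple[str, str]
    pvalue_proxy: bool = False


def _split_by_condition(
    columns: Sequence[str],
    sample_condition: Mapping[str, str],
    conditions: tuple[str, str] | None,
) -> tuple[tuple[str, str], list[str], list[str]]:
    missing = [c for c in columns if c not in sample_condition]
    if missing:
        raise ValueError(f"samples without condition label: {missing}")
    if conditions is None:
        found = sorted({sample_condition[c] for c in columns})
        if len(found) != 2:
            raise ValueError(f"expected exactly 2 conditions, found {found}")
        conditions = (found[0], found[1])
    cond1, cond2 = conditions
    g1 = [c for c in columns if sample_condition[c] == cond1]
    g2 = [c for c in columns if sample_condition[c] == cond2]
    if not g1 or not g2:
        raise ValueError(f"condition missing among samples: {conditions}")
    return conditions, g1, g2


def peak_log2fc(
    counts: pd.DataFrame,
    factors: pd.Series,
    sample_condition: Mapping[str, str],
    conditions: tuple[str, str] | None = None,
    pseudocount: float = 1.0,
    alpha: float = 0.05,
) -> PeakDifferential:
    """Per-peak log2 fold change (condition2 over condition1) and Welch test.

    Counts are divided by size factors; the fold change is
    log2((mean2 + pc) / (mean1 + pc)). With >= 2 replicates per
    condition a two-sided Welch t-test on log2(normalized + 1) is run
    per peak and BH-adjusted across peaks; exactly-equal groups with
    zero variance get p = 1 (or p = 0 if the means differ with zero
    variance on both sides).
    """
    conditions, g1, g2 = _split_by_condition(counts.columns, sample_condition, conditions)
    norm = counts / factors.reindex(counts.columns)
    mean1 = norm[g1].mean(axis=1).to_numpy()
    mean2 = norm[g2].mean(axis=1).to_numpy()
    log2fc = np.log2((mean2 + pseudocount) / (mean1 + pseudocount))
    n1, n2 = len(g1), len(g2)
    if n1 >= 2 and n2 >= 2:
        a = np.log2(norm[g1].to_numpy() + 1.0)
        b = np.log2(norm[g2].to_numpy() + 1.0)
        res = stats.ttest_ind(b, a, axis=1, equal_var=False)
        pvalue = np.asarray(res.pvalue, dtype=float)
        degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
        equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
        pvalue = np.where(degenerate, np.where(equal_means, 1.0, 0.0), pvalue)
        pvalue = np.where(np.isnan(pvalue), 1.0, pvalue)
        padj = multipletests(pvalue, method="fdr_bh")[1]
        sig = padj < alpha
        proxy = False
    else:
        pvalue = np.full(len(counts), np.nan)
        padj = np.full(len(counts), np.nan)
        sig = np.abs(log2fc) >= 1.0
        proxy = True
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": pvalue,
            "padj": padj,
            "significant_up": sig & (log2fc > 0),
            "significant_down": sig & (log2fc < 0),
        },
        index=counts.index,
    )
    return PeakDifferential(
        table=table, alpha=alpha, conditions=conditions, pvalue_proxy=proxy
    )


def gene_summed_fc(
    annotation: pd.DataFrame,
    counts: pd.DataFrame,
    factors: pd.Series,
    sample_condition: Mapping[str, str],
    conditions: tuple[str, str] | None = None,
    pseudocount: float = 1.0,
    classes: Iterable[str] = (PROMOTER, GENEBODY),
) -> pd.DataFrame:
    """Per-gene log2 fold change of summed peak counts at the gene locus.

    The "gene locus" is the set of peaks assigned to the gene's
    promoter_5utr or genebody classes. Normalized counts are averaged
    over replicates within each condition, summed over the locus peaks,
    and the statistic is log2((sum2 + pc) / (sum1 + pc)). Genes with no
    assigned peak are absent from the output.
    """
    conditions, g1, g2 = _split_by_condition(counts.columns, sample_condition, conditions)
    norm = counts / factors.reindex(counts.columns)
    per_cond = pd.DataFrame(
        {"c1": norm[g1].mean(axis=1), "c2": norm[g2].mean(axis=1)}
    )
    keep = annotation[
        annotation["region_class"].isin(set(classes)) & annotation["gene_id"].notna()
    ]
    joined = keep.join(per_cond, how="inner")
    if joined.empty:
        return pd.DataFrame(columns=["gene_id", "summed_log2fc", "n_peaks"])
    g = joined.groupby("gene_id", sort=True)
    s1, s2 = g["c1"].sum(), g["c2"].sum()
    out = pd.DataFrame(
        {
            "gene_id": s1.index,
            "summed_log2fc": np.log2((s2 + pseudocount) / (s1 + pseudocount)),
            "n_peaks": g.size(),
        }
    ).reset_index(drop=True)
    return out


def gene_region_avg_log2fc(
    differential: PeakDifferential,
    annotation: pd.DataFrame,
    mode: str = "mean_log2fc",
) -> pd.DataFrame:
    """Per gene and region class, the average fold change of its peaks.

    Default ``mean_log2fc`` averages the per-peak log2 fold changes
    (all observed peaks, regardless of significance). The alternative
    ``log2_mean_ratio`` reading — log2 of the mean linear fold change —
    is available behind this switch. Returns long-format rows
    (gene_id, region_class, avg_log2fc, n_peaks); a (gene, class) with
    no peaks is simply absent.
    """
    if mode not in ("mean_log2fc", "log2_mean_ratio"):
        raise ValueError(f"unknown mode {mode!r}")
    keep = annotation[annotation["gene_id"].notna()]
    joined = keep.join(differential.table[["log2fc"]], how="inner")
    if joined.empty:
        return pd.DataFrame(columns=["gene_id", "region_class", "avg_log2fc", "n_peaks"])
    g = joined.groupby(["gene_id", "region_class"], sort=True)
    if mode == "mean_log2fc":
        avg = g["log2fc"].mean()
    else:
        avg = np.log2(g["log2fc"].apply(lambda v: np.mean(2.0 ** v)))
    out = avg.rename("avg_log2fc").reset_index()
    out["n_peaks"] = g.size().to_numpy()
    return out
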