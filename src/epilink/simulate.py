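"""Synthetic study generator with planted ground truth.

Emulates the inputs of a two-condition chromatin-signal / RNA-seq
integration study on a toy genome: non-overlapping gene models with
exon/UTR substructure, peak calls per region class with
negative-binomial replicate counts, step-function coverage tracks, and
a gene-level differential-expression table whose mRNA log2 fold
changes carry a planted correlation with the region-class regulatory
effects. Everything is deterministic under the seed.

The regulatory model: each gene g has an independent latent effect
e_{g,c} ~ Normal(0, effect_sd) per region class c; condition-2 counts
of a peak in class c of gene g are scaled by 2**e_{g,c}. The mRNA
log2FC is built from the standardised class effects z_{g,c} as

    y_g = s * ( sum_c rho_c z_{g,c} + sqrt(1 - sum_c rho_c^2) eps_g )

so that corr(y, e_{.,c}) = rho_c by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genome_model import (
    GENEBODY,
    INTERGENIC,
    PROMOTER,
    REGION_CLASSES,
    GeneModel,
    GenomicInterval,
)
from .signal_quant import SignalTrack
from .study_stats import DifferentialExpressionTable

_GENOME_STREAM, _PEAK_STREAM, _EXPR_STREAM, _TRACK_STREAM = 11, 22, 33, 44


def _default_rates() -> dict[str, float]:
    return {PROMOTER: 2.0, GENEBODY: 1.0, INTERGENIC: 0.5}


def _default_rho() -> dict[str, float]:
    return {PROMOTER: 0.8, GENEBODY: 0.0, INTERGENIC: 0.0}


@dataclass
class SyntheticConfig:
    """Study conditions for the generator (defaults are the conditions
    every recovery experiment in this package runs under)."""

    seed: int = 0
    n_genes: int = 500
    chrom: str = "chr1"
    chrom_length: int | None = None  # auto-sized unless given
    gene_length_range: tuple[int, int] = (4000, 12000)
    intergap_range: tuple[int, int] = (20000, 40000)
    promoter_window: tuple[int, int] = (3000, 3000)
    peak_rates: dict[str, float] = field(default_factory=_default_rates)
    peak_width_range: tuple[int, int] = (200, 1000)
    baseline_mean: float = 200.0
    baseline_log2_sd: float = 0.7
    dispersion: float = 20.0  # NB size parameter; var = mu + mu^2/dispersion
    n_replicates: int = 2
    conditions: tuple[str, str] = ("ctrl", "ko")
    planted_rho: dict[str, float] = field(default_factory=_default_rho)
    effect_sd: float = 1.5
    mrna_log2fc_sd: float = 1.5
    fraction_significant: float = 0.4
    decoy_biotype_fraction: float = 0.1
    fpkm_log2_mean: float = 4.5
    fpkm_log2_sd: float = 1.5
    fpkm_rep_log2_sd: float = 0.2
    track_background: float = 0.0
    track_gene_level: float = 1.0
    track_tes_skew: float = 0.0  # 0 = flat body; 1 = linear rise toward TES

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for cls, rho in self.planted_rho.items():
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"planted_rho[{cls}]={rho} outside [-1, 1]")
        if sum(r * r for r in self.planted_rho.values()) > 1.0 + 1e-12:
            raise ValueError("sum of squared planted_rho values exceeds 1")
        for name in ("baseline_mean", "dispersion", "mrna_log2fc_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.effect_sd < 0:
            raise ValueError("effect_sd must be >= 0")
        if self.effect_sd == 0 and any(r != 0 for r in self.planted_rho.values()):
            raise ValueError("nonzero planted_rho requires effect_sd > 0")
        if not 0 <= self.fraction_significant <= 1:
            raise ValueError("fraction_significant must be in [0, 1]")
        if not 0 <= self.decoy_biotype_fraction <= 1:
            raise ValueError("decoy_biotype_fraction must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """Planted ground truth, filled in as generation stages run."""

    gene_effects: pd.DataFrame  # index gene_id, one column per region class
    peak_truth: pd.DataFrame  # peak_id, gene_id, region_class, multiplier
    mrna_log2fc: pd.Series | None = None
    expected_significant: frozenset[str] | None = None


@dataclass
class SyntheticPeakData:
    """Generated peak calls and replicate count matrix."""

    peaks: list[GenomicInterval]
    peak_ids: list[str]
    counts: pd.DataFrame  # index peak_id, columns sample names
    sample_condition: dict[str, str]
    condition_peaks: dict[str, list[GenomicInterval]]


# ---------------------------------------------------------------------------
# genome

def generate_genome(config: SyntheticConfig) -> list[GeneModel]:
    """Place non-overlapping genes with 2-8 exons and terminal UTRs."""
    rng = np.random.default_rng([config.seed, _GENOME_STREAM])
    genes: list[GeneModel] = []
    cursor = 10_000
    width = len(str(config.n_genes))
    n_decoy = round(config.decoy_biotype_fraction * config.n_genes)
    decoy_idx = set(
        rng.choice(config.n_genes, size=n_decoy, replace=False).tolist()
    ) if n_decoy else set()
    for i in range(config.n_genes):
        gap = int(rng.integers(config.intergap_range[0], config.intergap_range[1] + 1))
        start = cursor + gap
        length = int(rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1))
        end = start + length
        strand = "+" if rng.random() < 0.5 else "-"
        k = int(rng.integers(2, 9))
        nseg = 2 * k - 1
        min_seg = 80
        w = rng.dirichlet(np.ones(nseg)) * (length - min_seg * nseg)
        lengths = (np.floor(w) + min_seg).astype(int)
        lengths[-1] += length - int(lengths.sum())
        bounds = start + np.concatenate([[0], np.cumsum(lengths)])
        exon_pairs = [(int(bounds[j]), int(bounds[j + 1])) for j in range(0, nseg, 2)]
        first_len = exon_pairs[0][1] - exon_pairs[0][0]
        last_len = exon_pairs[-1][1] - exon_pairs[-1][0]
        u_left = min(200, first_len // 2)
        u_right = min(200, last_len // 2)
        left = (exon_pairs[0][0], exon_pairs[0][0] + u_left)
        right = (exon_pairs[-1][1] - u_right, exon_pairs[-1][1])
        u5, u3 = ((left,), (right,)) if strand == "+" else ((right,), (left,))
        gid = f"gene_{i + 1:0{width}d}"
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=config.chrom,
                strand=strand,
                exons=[GenomicInterval(config.chrom, s, e, strand) for s, e in exon_pairs],
                utr5=[GenomicInterval(config.chrom, s, e, strand) for s, e in u5],
                utr3=[GenomicInterval(config.chrom, s, e, strand) for s, e in u3],
                biotype="lincRNA" if i in decoy_idx else "protein_coding",
            )
        )
        cursor = end
    needed = cursor + 10_000
    if config.chrom_length is not None and config.chrom_length < needed:
        raise ValueError(
            f"chrom_length={config.chrom_length} too small; need >= {needed}"
        )
    return genes


def genome_extent(genes: list[GeneModel]) -> int:
    return max(g.span[1] for g in genes) + 10_000


# ---------------------------------------------------------------------------
# peaks and counts

def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    p = dispersion / (dispersion + mu)
    return rng.negative_binomial(dispersion, p)


def generate_peaks_and_counts(
    genome: list[GeneModel], config: SyntheticConfig
) -> tuple[SyntheticPeakData, SyntheticTruth]:
    """Plant peaks per gene per region class and draw replicate counts.

    Peak midpoints are placed so that midpoint assignment recovers the
    intended class: inside the promoter window, inside the gene body
    clear of the promoter, or upstream of the promoter window in the
    intergenic gap adjacent to the gene (which also makes the gene the
    nearest TSS). Condition-2 counts are scaled by the gene's
    class-level multiplier 2**effect.
    """
    rng = np.random.default_rng([config.seed, _PEAK_STREAM])
    up, down = config.promoter_window
    wlo, whi = config.peak_width_range
    effects = pd.DataFrame(
        rng.normal(0.0, config.effect_sd, size=(len(genome), len(REGION_CLASSES)))
        if config.effect_sd > 0
        else np.zeros((len(genome), len(REGION_CLASSES))),
        index=[g.gene_id for g in genome],
        columns=list(REGION_CLASSES),
    )
    peak_rows: list[tuple[str, str, int, int, float]] = []  # gid, class, start, end, mult
    for g in genome:
        span_s, span_e = g.span
        if g.strand == "+":
            prom = (g.tss - up, g.tss + down)
            body = (g.tss + down, span_e)
            inter_anchor, inter_sign = prom[0], -1
        else:
            prom = (g.tss - down, g.tss + up)
            body = (span_s, g.tss - down)
            inter_anchor, inter_sign = prom[1], +1
        windows = {
            PROMOTER: (prom[0] + 150, prom[1] - 150),
            GENEBODY: (body[0] + 150, body[1] - 150),
        }
        for cls in (PROMOTER, GENEBODY, INTERGENIC):
            n_peaks = int(rng.poisson(config.peak_rates.get(cls, 0.0)))
            mult = float(2.0 ** effects.at[g.gene_id, cls])
            for _ in range(n_peaks):
                if cls == INTERGENIC:
                    off = rng.uniform(500, 5000)
                    mid = inter_anchor + inter_sign * off
                else:
                    lo, hi = windows[cls]
                    if hi <= lo:
                        continue
                    mid = rng.uniform(lo, hi)
                width = int(rng.integers(wlo, whi + 1))
                s = max(0, int(mid) - width // 2)
                peak_rows.append((g.gene_id, cls, s, s + width, mult))
    peak_rows.sort(key=lambda r: (r[2], r[3], r[0]))
    n_peaks_total = len(peak_rows)
    pid_width = max(5, len(str(n_peaks_total)))
    peak_ids = [f"peak_{i + 1:0{pid_width}d}" for i in range(n_peaks_total)]
    peaks = [GenomicInterval(config.chrom, s, e) for _, _, s, e, _ in peak_rows]
    mult = np.array([m for *_, m in peak_rows])
    mu = config.baseline_mean * 2.0 ** rng.normal(0.0, config.baseline_log2_sd, n_peaks_total)
    cond1, cond2 = config.conditions
    samples: list[str] = []
    sample_condition: dict[str, str] = {}
    columns: dict[str, np.ndarray] = {}
    for cond, m in ((cond1, mu), (cond2, mu * mult)):
        for r in range(1, config.n_replicates + 1):
            name = f"{cond}_{r}"
            samples.append(name)
            sample_condition[name] = cond
            columns[name] = _nb_draw(rng, m, config.dispersion)
    counts = pd.DataFrame(columns, index=peak_ids)
    truth = SyntheticTruth(
        gene_effects=effects,
        peak_truth=pd.DataFrame(
            {
                "peak_id": peak_ids,
                "gene_id": [gid for gid, *_ in peak_rows],
                "region_class": [cls for _, cls, *_ in peak_rows],
                "multiplier": mult,
            }
        ).set_index("peak_id"),
    )
    data = SyntheticPeakData(
        peaks=peaks,
        peak_ids=peak_ids,
        counts=counts,
        sample_condition=sample_condition,
        condition_peaks={cond1: list(peaks), cond2: list(peaks)},
    )
    return data, truth


# ---------------------------------------------------------------------------
# expression

def generate_expression(
    genome: list[GeneModel], truth: SyntheticTruth, config: SyntheticConfig
) -> DifferentialExpressionTable:
    """Gene DE table with planted mRNA log2FC / region-effect correlation.

    The planted p-values are generated, not fitted: the
    ``fraction_significant`` genes with the largest |log2FC| get small
    p-values (< 0.01); all others are uniform on [0.05, 1). Biotypes
    come from the gene models (a decoy fraction is non-coding). Updates
    ``truth`` with the mRNA log2FC vector and the bookkept set of genes
    satisfying the three significance-filter criteria.
    """
    rng = np.random.default_rng([config.seed, _EXPR_STREAM])
    gene_ids = [g.gene_id for g in genome]
    n = len(gene_ids)
    rho = np.array([config.planted_rho.get(c, 0.0) for c in REGION_CLASSES])
    if config.effect_sd > 0:
        z = truth.gene_effects.loc[gene_ids, list(REGION_CLASSES)].to_numpy() / config.effect_sd
    else:
        z = np.zeros((n, len(REGION_CLASSES)))
    resid = np.sqrt(max(0.0, 1.0 - float(rho @ rho)))
    y = config.mrna_log2fc_sd * (z @ rho + resid * rng.standard_normal(n))

    base = 2.0 ** rng.normal(config.fpkm_log2_mean, config.fpkm_log2_sd, n)
    cond1, cond2 = config.conditions
    condition_samples = {
        cond: [f"{cond}_rna_{r}" for r in range(1, config.n_replicates + 1)]
        for cond in (cond1, cond2)
    }
    fpkm: dict[str, np.ndarray] = {}
    for s in condition_samples[cond1]:
        fpkm[s] = base * 2.0 ** rng.normal(0.0, config.fpkm_rep_log2_sd, n)
    for s in condition_samples[cond2]:
        fpkm[s] = base * 2.0 ** (y + rng.normal(0.0, config.fpkm_rep_log2_sd, n))

    n_sig = round(config.fraction_significant * n)
    order = np.argsort(-np.abs(y), kind="stable")
    pvalue = np.empty(n)
    pvalue[order[:n_sig]] = 10.0 ** (-rng.uniform(2.5, 8.0, n_sig))
    pvalue[order[n_sig:]] = rng.uniform(0.05, 1.0, n - n_sig)

    data = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "biotype": [g.biotype for g in genome],
            "log2fc": y,
            "pvalue": pvalue,
        }
    )
    for cond in (cond1, cond2):
        for s in condition_samples[cond]:
            data[f"fpkm_{s}"] = fpkm[s]
    table = DifferentialExpressionTable(data=data, condition_samples=condition_samples)

    mean1 = np.column_stack([fpkm[s] for s in condition_samples[cond1]]).mean(axis=1)
    mean2 = np.column_stack([fpkm[s] for s in condition_samples[cond2]]).mean(axis=1)
    passing = (
        (pvalue < 0.05)
        & np.array([g.biotype == "protein_coding" for g in genome])
        & ((mean1 > 5.0) | (mean2 > 5.0))
    )
    truth.mrna_log2fc = pd.Series(y, index=gene_ids, name="mrna_log2fc")
    truth.expected_significant = frozenset(np.array(gene_ids)[passing].tolist())
    return table


# ---------------------------------------------------------------------------
# coverage tracks

def generate_signal_track(
    genome: list[GeneModel], truth: SyntheticTruth, config: SyntheticConfig
) -> dict[str, SignalTrack]:
    """Step-function coverage per condition: flat background plus
    elevated gene bodies; with ``track_tes_skew`` > 0 the body signal
    rises linearly toward the TES (the depositing-with-elongation
    shape of gene-body marks). Condition 2 scales each gene body by
    its genebody-class multiplier."""
    n_seg = 10
    cond1, cond2 = config.conditions
    extent = genome_extent(genome)
    tracks: dict[str, SignalTrack] = {}
    for cond in (cond1, cond2):
        steps: list[tuple[str, float, float, float]] = []
        cursor = 0
        for g in sorted(genome, key=lambda g: g.span[0]):
            s, e = g.span
            if config.track_background > 0 and s > cursor:
                steps.append((config.chrom, cursor, s, config.track_background))
            level = config.track_gene_level
            if cond == cond2:
                level *= float(2.0 ** truth.gene_effects.at[g.gene_id, GENEBODY])
            bounds = np.linspace(s, e, n_seg + 1)
            for i in range(n_seg):
                frac = (i + 0.5) / n_seg  # position along genome, left to right
                tfrac = frac if g.strand == "+" else 1.0 - frac
                v = level * (1.0 + config.track_tes_skew * (tfrac - 0.5))
                if v > 0:
                    steps.append((config.chrom, float(bounds[i]), float(bounds[i + 1]), v))
            cursor = e
        if config.track_background > 0 and cursor < extent:
            steps.append((config.chrom, cursor, extent, config.track_background))
        tracks[cond] = SignalTrack.from_steps(steps, chroms=[config.chrom])
    return tracks


# ---------------------------------------------------------------------------
# file bundle

def write_gtf(genes: list[GeneModel], path) -> None:
    """Deterministic GTF writer (1-based, closed coordinates)."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.span[0], g.gene_id)):
            s, e = g.span
            attrs = (
                f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1"; '
                f'gene_biotype "{g.biotype}";'
            )
            def row(feature: str, a: int, b: int) -> str:
                return (
                    f"{g.chrom}\tepilink\t{feature}\t{a + 1}\t{b}\t.\t{g.strand}\t.\t{attrs}\n"
                )
            fh.write(row("gene", s, e))
            fh.write(row("transcript", s, e))
            for ex in g.exons:
                fh.write(row("exon", ex.start, ex.end))
            for u in g.utr5:
                fh.write(row("five_prime_utr", u.start, u.end))
            for u in g.utr3:
                fh.write(row("three_prime_utr", u.start, u.end))


def write_bundle(config: SyntheticConfig, outdir) -> dict[str, Path]:
    """Generate the full synthetic study and write it as plain-text files.

    Returns the paths written, including a ready-to-run pipeline config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = generate_genome(config)
    data, truth = generate_peaks_and_counts(genome, config)
    de = generate_expression(genome, truth, config)
    tracks = generate_signal_track(genome, truth, config)

    paths: dict[str, Path] = {}
    paths["annotation"] = outdir / "genes.gtf"
    write_gtf(genome, paths["annotation"])

    cond1, cond2 = config.conditions
    for cond in (cond1, cond2):
        p = outdir / f"peaks_{cond}.bed"
        with open(p, "w") as fh:
            for pk in data.condition_peaks[cond]:
                fh.write(f"{pk.chrom}\t{pk.start}\t{pk.end}\n")
        paths[f"peaks_{cond}"] = p
        tp = outdir / f"coverage_{cond}.bedgraph"
        tracks[cond].write_bedgraph(tp)
        paths[f"coverage_{cond}"] = tp

    paths["counts"] = outdir / "counts.tsv"
    meta = "; ".join(
        f"{cond}={','.join(s for s, c in data.sample_condition.items() if c == cond)}"
        for cond in (cond1, cond2)
    )
    with open(paths["counts"], "w") as fh:
        fh.write(f"# conditions: {meta}\n")
        tbl = data.counts.copy()
        tbl.insert(0, "chrom", [p.chrom for p in data.peaks])
        tbl.insert(1, "start", [p.start for p in data.peaks])
        tbl.insert(2, "end", [p.end for p in data.peaks])
        tbl.to_csv(fh, sep="\t", index_label="peak_id")

    paths["de_table"] = outdir / "expression.tsv"
    de.write_tsv(paths["de_table"])

    paths["truth_gene_effects"] = outdir / "truth_gene_effects.tsv"
    eff = truth.gene_effects.copy()
    eff["mrna_log2fc"] = truth.mrna_log2fc
    eff.to_csv(paths["truth_gene_effects"], sep="\t", index_label="gene_id", float_format="%.6g")
    paths["truth_peaks"] = outdir / "truth_peaks.tsv"
    truth.peak_truth.to_csv(paths["truth_peaks"], sep="\t", float_format="%.6g")

    paths["pipeline_config"] = outdir / "pipeline_config.yaml"
    # paths relative to the config file itself, so the bundle is relocatable
    cfg = {
        "annotation": paths["annotation"].name,
        "peaks": {cond1: paths[f"peaks_{cond1}"].name, cond2: paths[f"peaks_{cond2}"].name},
        "counts": paths["counts"].name,
        "coverage": {cond1: paths[f"coverage_{cond1}"].name},
        "de_table": paths["de_table"].name,
        "outdir": "results",
        "promoter_window": list(config.promoter_window),
        "seed": config.seed,
    }
    with open(paths["pipeline_config"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return paths
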