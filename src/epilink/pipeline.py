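"""Stage orchestration: annotation -> partition -> consensus peaks ->
normalisation -> per-gene fold changes -> DE filtering/top-N ->
correlation, quadrants, and overlap enrichment -> report files."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .genome_model import (
    GENEBODY,
    PROMOTER,
    REGION_CLASSES,
    partition_regions,
    read_gene_annotation,
    write_partition_bed,
)
from .integration import (
    IntegrationResult,
    OverlapEnrichment,
    correlate_expression_signal,
    integration_table,
    overlap_enrichment,
)
from .peak_integration import (
    annotate_peaks,
    build_consensus_peaks,
    gene_region_avg_log2fc,
    gene_summed_fc,
    map_counts_to_consensus,
    peak_log2fc,
    read_peaks_bed,
    size_factors,
)
from .signal_quant import SignalTrack, metagene_profile
from .simulate import (
    SyntheticConfig,
    generate_expression,
    generate_genome,
    generate_peaks_and_counts,
)
from .study_stats import (
    derive_signature,
    filter_significant_genes,
    read_de_tsv,
    top_changed_genes,
)

log = logging.getLogger("epilink")


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""


@dataclass
class RunReport:
    """Machine-readable run summary with reconcilable stage counts."""

    stage_counts: dict = field(default_factory=dict)
    integration: dict[str, IntegrationResult] = field(default_factory=dict)
    skipped_classes: dict[str, str] = field(default_factory=dict)
    overlap_up: OverlapEnrichment | None = None
    overlap_down: OverlapEnrichment | None = None
    fingerprint: str = ""
    version: str = __version__

    def to_dict(self) -> dict:
        def enc(obj):
            if obj is None:
                return None
            return {k: list(v) if isinstance(v, tuple) else v for k, v in vars(obj).items()}

        return {
            "version": self.version,
            "fingerprint": self.fingerprint,
            "stage_counts": self.stage_counts,
            "integration": {cls: enc(res) for cls, res in self.integration.items()},
            "skipped_classes": self.skipped_classes,
            "overlap_up": enc(self.overlap_up),
            "overlap_down": enc(self.overlap_down),
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _fingerprint(config: PipelineConfig) -> str:
    h = hashlib.sha256()
    h.update(repr(sorted(vars(config).items(), key=lambda kv: kv[0])).encode())
    for key in ("annotation", "counts", "de_table"):
        h.update(Path(getattr(config, key)).read_bytes())
    for cond in sorted(config.peaks):
        h.update(Path(config.peaks[cond]).read_bytes())
    return h.hexdigest()[:16]


def _read_counts_tsv(path) -> tuple[pd.DataFrame, dict[str, str]]:
    sample_condition: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# conditions:"):
                for part in line.split(":", 1)[1].split(";"):
                    cond, samples = part.strip().split("=")
                    for s in samples.split(","):
                        sample_condition[s] = cond
    df = pd.read_csv(path, sep="\t", comment="#", index_col="peak_id")
    return df, sample_condition


def run_integration(config: PipelineConfig) -> RunReport:
    """Execute all stages and write result files under ``config.outdir``.

    Deterministic for identical inputs and config. Stage errors are
    re-raised as :class:`PipelineError` naming the stage.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(fingerprint=_fingerprint(config))
    cond1, cond2 = config.conditions

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r}: {exc}") from exc
        return wrap

    genes = stage("annotation")(read_gene_annotation, config.annotation)
    report.stage_counts["genes"] = len(genes)
    log.info("annotation: %d genes", len(genes))

    partition = stage("partition")(partition_regions, genes, config.promoter_window)
    stage("partition")(write_partition_bed, partition, out / "region_partition.bed")

    peak_sets = {
        cond: stage("merge-peaks")(read_peaks_bed, path)
        for cond, path in config.peaks.items()
    }
    consensus = stage("merge-peaks")(build_consensus_peaks, peak_sets)
    consensus.to_bed(out / "consensus_peaks.bed")
    report.stage_counts["consensus_peaks"] = len(consensus)
    log.info("consensus: %d peaks", len(consensus))

    raw_counts, sample_condition = stage("quantify")(_read_counts_tsv, config.counts)
    counts = stage("quantify")(map_counts_to_consensus, raw_counts, consensus)
    factors = stage("quantify")(size_factors, counts)
    diff = stage("quantify")(
        peak_log2fc,
        counts,
        factors,
        sample_condition,
        (cond1, cond2),
        config.pseudocount,
        config.alpha,
    )

    ann = stage("annotate")(
        annotate_peaks, consensus.peaks, partition, None, config.assignment_rule
    )
    class_counts = ann["region_class"].value_counts().to_dict()
    report.stage_counts["peaks_per_class"] = {
        cls: int(class_counts.get(cls, 0)) for cls in REGION_CLASSES
    }
    diff.table.join(ann[["region_class", "gene_id"]]).to_csv(
        out / "peak_differential.tsv", sep="\t", index_label="peak_id", float_format="%.6g"
    )

    summed = stage("gene-fc")(
        gene_summed_fc, ann, counts, factors, sample_condition, (cond1, cond2), config.pseudocount
    )
    summed.to_csv(out / "gene_summed_fc.tsv", sep="\t", index=False, float_format="%.6g")
    region_fc = stage("gene-fc")(gene_region_avg_log2fc, diff, ann)
    region_fc.to_csv(out / "gene_region_fc.tsv", sep="\t", index=False, float_format="%.6g")
    report.stage_counts["genes_with_locus_peaks"] = int(len(summed))

    de = stage("filter-genes")(read_de_tsv, config.de_table)
    filtered = stage("filter-genes")(
        filter_significant_genes, de, config.p_cutoff, config.fpkm_cutoff
    )
    filtered.write_tsv(out / "filtered_genes.tsv")
    report.stage_counts["genes_de_input"] = int(len(de.data))
    report.stage_counts["genes_filtered"] = int(len(filtered.data))
    if config.top_n is None:
        gene_set = None
    elif config.rank_by == "pvalue":
        gene_set = stage("filter-genes")(top_changed_genes, filtered, config.top_n)
    else:  # top-N both directions ranked by |fold change|
        gene_set = stage("filter-genes")(
            derive_signature,
            filtered,
            1.0,  # p already filtered
            1.0,
            "both",
            config.top_n,
            "fold_change",
        )
    if gene_set is not None:
        gene_set.write(out / "gene_set.txt")
        report.stage_counts["gene_set_size"] = len(gene_set)

    overlap = set(de.data["gene_id"]) & {g.gene_id for g in genes}
    if not overlap:
        raise PipelineError(
            "stage 'integrate': DE table gene_ids are disjoint from the "
            "annotation (0 genes joined)"
        )

    expr_fc = filtered.data[["gene_id", "log2fc"]]
    for cls in config.region_classes:
        table = summed if cls == "summed" else region_fc
        try:
            res = correlate_expression_signal(expr_fc, table, cls, gene_set=gene_set)
        except ValueError as exc:
            report.skipped_classes[cls] = str(exc)
            log.warning("integration skipped for %s: %s", cls, exc)
            continue
        report.integration[cls] = res
    if not report.integration:
        raise PipelineError(
            "stage 'integrate': no region class had enough joined genes; "
            f"details: {report.skipped_classes}"
        )
    itab = integration_table(report.integration.values())
    itab.to_csv(out / "integration.tsv", sep="\t", index=False, float_format="%.6g")
    report.stage_counts["genes_joined_per_class"] = {
        cls: res.n_genes for cls, res in report.integration.items()
    }

    locus_ann = ann[ann["region_class"].isin((PROMOTER, GENEBODY))]
    universe = sorted(set(de.data["gene_id"]))
    sig_up = sorted(
        set(
            locus_ann.join(diff.table)["gene_id"][
                locus_ann.join(diff.table)["significant_up"]
            ].dropna()
        )
        & set(universe)
    )
    sig_down = sorted(
        set(
            locus_ann.join(diff.table)["gene_id"][
                locus_ann.join(diff.table)["significant_down"]
            ].dropna()
        )
        & set(universe)
    )
    mrna_up = sorted(filtered.data["gene_id"][filtered.data["log2fc"] > 0])
    mrna_down = sorted(filtered.data["gene_id"][filtered.data["log2fc"] < 0])
    report.overlap_up = stage("overlap")(overlap_enrichment, sig_up, mrna_up, universe)
    report.overlap_down = stage("overlap")(overlap_enrichment, sig_down, mrna_down, universe)

    for cond, path in config.coverage.items():
        track = stage("metagene")(SignalTrack.read_bedgraph, path)
        profile = stage("metagene")(
            metagene_profile,
            track,
            genes,
            config.body_bins,
            config.flank_bp,
            config.flank_bin_bp,
            True,
            cond,
        )
        profile.to_frame().to_csv(
            out / f"metagene_{cond}.tsv", sep="\t", index=False, float_format="%.6g"
        )

    report.write_json(out / "report.json")
    return report


# ---------------------------------------------------------------------------
# in-memory recovery experiment (synthetic study -> estimated correlations)

def planted_correlation_estimates(
    config: SyntheticConfig,
    classes: tuple[str, ...] = REGION_CLASSES,
) -> dict[str, IntegrationResult]:
    """Run the analysis pipeline on a freshly generated synthetic study
    and return the estimated per-class correlation between mRNA log2FC
    and average peak log2FC, over all genes (no significance selection,
    so the estimate is comparable to the planted correlation).
    """
    genome = generate_genome(config)
    data, truth = generate_peaks_and_counts(genome, config)
    de = generate_expression(genome, truth, config)
    partition = partition_regions(genome, config.promoter_window)
    ann = annotate_peaks(data.peaks, partition, ids=data.peak_ids)
    factors = size_factors(data.counts)
    diff = peak_log2fc(
        data.counts, factors, data.sample_condition, conditions=config.conditions
    )
    region_fc = gene_region_avg_log2fc(diff, ann)
    expr_fc = de.data[["gene_id", "log2fc"]]
    return {
        cls: correlate_expression_signal(expr_fc, region_fc, cls) for cls in classes
    }
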