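# Methods

## Coordinate conventions and region partition

All internal coordinates are 0-based, half-open; GTF input (1-based,
closed) is converted on read, BED12 is native. One model is kept per
gene — the longest-span transcript when several are annotated.

The genome is partitioned, per gene, into **promoter_5utr** and
**genebody**, with **distal_intergenic** as the implicit complement:

- promoter_5utr = strand-aware window (default 3000 bp upstream, 3000 bp
  downstream of the TSS, clipped at 0) ∪ annotated 5'UTR;
- genebody = (TSS..TES span ∪ annotated 3'UTR) − promoter_5utr.

The promoter window width is configurable; ±3 kb is the common default
of standard peak annotators. A peak is assigned by its midpoint with
precedence promoter_5utr > genebody > distal_intergenic; when the
midpoint lies in the same class of several (overlapping) genes, the
gene with the smallest |midpoint − TSS| wins, ties broken by
lexicographic gene_id, so assignment is deterministic. An
``any_overlap`` rule (same precedence, any overlap instead of the
midpoint) is available. Midpoint assignment is the default because it
makes fragment/peak attribution additive and unambiguous.

Distal intergenic peaks carry no region-owning gene. For per-gene
statistics they are attributed to the nearest-TSS gene at annotation
time (`annotate_peaks(..., intergenic_nearest=True)`), the convention
of standard annotators; without this the intergenic class could never
enter a per-gene correlation. The flag can be switched off.

Interval merging is a plain union with bookended intervals (end ==
next start) merged, mirroring the default of the usual interval tools.

## Signal quantification

Coverage is a per-chromosome step function (the in-memory form of a
bedGraph); uncovered positions are 0. RPKM normalization multiplies a
per-base read-count density by 1e9 / library_size. Metagene profiles
split each gene's TSS..TES span into `body_bins` (default 100)
equal-fraction bins and the ±`flank_bp` (default 2000) flanks into
`flank_bp / flank_bin_bp` (default 50 bp) native-resolution bins;
per-bin means are computed on fractional overlaps, minus-strand
vectors are reversed before averaging, and the profile is the mean over
genes. Whether a "cumulative curve" denotes the running sum or the
aggregate mean curve is ambiguous in common usage, so both are
produced: the mean profile is the default output and the running sum
is attached under a flag. Fragment-in-peak counting uses fragment
midpoints against disjoint (merged) peaks, half-open, so each fragment
counts for at most one peak.

## Count normalization and the differential stand-in

Size factors are median-of-ratios: the reference for each peak is the
geometric mean of its counts across samples (peaks with any zero
excluded); a sample's factor is the median of its count/reference
ratios. With no all-positive peak the code falls back to library-size
factors (column sum over the geometric mean of column sums), logged.

Per-peak differential statistics are deliberately a simple, documented
stand-in rather than a negative-binomial fit — the quantity of interest
downstream is the aggregation and correlation arithmetic, and the
stand-in sits behind a narrow interface (counts, factors, condition
map in; log2FC, p, BH-adjusted p, flags out) so a heavier engine can be
swapped in. Fold change is log2((mean₂ + pc)/(mean₁ + pc)) on
size-factor-normalized counts with pseudocount 1 by default (the
pseudocount bounds log ratios for near-zero peaks; it deliberately
breaks exact invariance to global count rescaling, which holds at
pc = 0). With ≥ 2 replicates per condition a two-sided Welch t-test on
log2(normalized + 1) is run per peak and BH-adjusted across all
consensus peaks jointly; groups that are exactly equal with zero
variance get p = 1 (p = 0 when the means differ with zero variance on
both sides). With fewer replicates, p-values are absent and
significance is proxied by |log2FC| ≥ 1, flagged as a proxy. Note the
Welch test with the Satterthwaite degrees of freedom is conservative at
very small n: its measured null false-positive rate at α = 0.05 with 3
replicates per condition is ≈ 0.035 (it is ≈ 0.034 even on exactly
normal data), which the acceptance checks measure over ~21k simulated
peaks.

## Per-gene fold-change aggregations

Two aggregations are produced:

- **Summed-counts statistic**: per gene, normalized counts are averaged
  over replicates within each condition, summed over the peaks assigned
  to the gene's locus, and the statistic is log2((sum₂ + pc)/(sum₁ + pc)).
  "Gene locus" means peaks in the promoter_5utr or genebody classes of
  that gene; a TSS−x..TES+x window definition is possible by widening
  the promoter window. Genes with no assigned peak are absent, not zero.
- **Region-average statistic**: per gene and region class, the
  arithmetic mean of the per-peak log2 fold changes, all observed peaks
  regardless of significance. The phrase "fold of all observed peaks
  signals divided by the number of observed peaks" admits a second
  reading — log2 of the mean linear fold change — which is implemented
  behind `mode="log2_mean_ratio"`; the mean-of-log2FC reading is the
  default because it matches the "average log2(FC)" axis convention.

## Integration statistics

For a caller-supplied gene set (the selection policy varies between
analyses — all signature genes in one, the top-200 significantly
changed genes by p-value in another — so it is an argument, not
hard-coded), genes are inner-joined between the expression table and
the per-gene signal table for one region class: genes with no observed
peak in that class are dropped and counted, not imputed at zero,
because an average of observed peaks is only defined where peaks were
observed. Pearson's R uses the product-moment formula with the
two-sided p-value from t = R√(n−2)/√(1−R²) on n−2 df (the standard
practice of common statistics software); results with p ≥ 0.05 are
labelled "NS". Quadrant fractions classify genes by the sign pair of
(mRNA log2FC, signal log2FC); points on either axis are excluded from
the fractions and reported as an excluded count. Overlap enrichment
between differential-peak genes and differential-expression genes uses
the one-sided hypergeometric upper tail on the 2×2 table within the DE
universe — the overlap test is this package's choice, as the usual
descriptions of such overlaps do not name one — with a Haldane 0.5
correction on the odds ratio when a cell is zero.

Note that selecting genes by significance before correlating
conditions on |mRNA log2FC| extremes and therefore inflates |R|
relative to an unselected population; the parameter-recovery checks
below use the unselected gene population for exactly this reason.

## Expression-table rules

The significance filter keeps genes with p < 0.05, protein-coding
biotype, and mean FPKM > 5 in at least one of the two condition groups
(per-condition mean over replicates; genes with missing biotype are
excluded with a warning). Signatures apply a p cutoff and a linear
fold-change cutoff (≥ 2 in the requested direction by default) and can
be truncated to the top N ranked by p-value or |fold change|; ranking
ties are resolved by the other key, then gene_id. Z-scores standardize
within each sample (column), Z = (x − μ_j)/σ_j with the n−1 sample
standard deviation (the denominator is not universally specified; the
per-gene heatmap convention is available behind `mode="gene"` but is
not the default). The colitis histology score sums four parameters —
lamina-propria infiltration 1–3, goblet-cell loss 0–2, erosion 0–2,
submucosal spread 0–2 — to a total in [1, 9].

## The synthetic-study generator

The generator emulates the input bundle of a two-condition study and is
the package's validation substrate. Defaults (the study conditions used
by all recovery experiments): 500 genes on one chromosome, gene spans
4–12 kb separated by 20–40 kb gaps, 2–8 exons with terminal 5'/3' UTRs,
10% of genes non-coding decoys; Poisson peak counts per gene per class
with means 2 (promoter), 1 (gene body), 0.5 (intergenic) and widths
200–1000 bp; negative-binomial replicate counts with baseline mean 200
(per-peak lognormal spread, log2 sd 0.7) and dispersion 20 — typical
consensus-peak count scales for tagmentation-based assays — with 2
replicates per condition.

Each gene carries an independent latent effect e_{g,c} ~ N(0, effect_sd)
per region class (effect_sd 1.5); condition-2 counts of peaks in class
c of gene g are scaled by 2^{e_{g,c}}. Peak midpoints are placed so that
midpoint assignment recovers the intended class (intergenic peaks sit
0.5–5 kb upstream of the promoter window, which also makes their gene
the nearest TSS). The mRNA log2FC is built from the standardized class
effects as y = s·(Σ_c ρ_c z_c + √(1 − Σ_c ρ_c²)·ε), s = 1.5, so
corr(y, e_{·,c}) = ρ_c exactly in population. Planted p-values are
generated, not fitted: the 40% of genes with the largest |y| receive
p < 0.01 and the rest are uniform on [0.05, 1), so filter outcomes are
known at generation time; this is bookkeeping for testing filters, not
a statistical claim. FPKM values are lognormal around 2^4.5 with
replicate noise (log2 sd 0.2) and condition-2 means shifted by y.

What the generator does **not** emulate: read-level noise, mappability
and GC artifacts, peak-caller boundary error, correlated effects
between region classes, isoform structure, and realistic p-value/effect
joint distributions. Passing recovery tests therefore demonstrates that
the pipeline's arithmetic recovers planted structure under idealized
sampling noise, not that it is robust to real-data artifacts.

## Recovery and calibration results the tests compute

With the default conditions, the estimated promoter-class R over all
genes attenuates only slightly from count noise (≈ 0.985 multiplicative,
i.e. mean estimated R ≈ 0.79 for planted ρ = 0.8); the acceptance
checks assert single-seed recovery within ±0.15 and a 50-seed mean
within ±0.05 of ρ ∈ {−0.8, 0, 0.8}, region specificity
(|R_intergenic| < 0.2 when ρ is planted only in the promoter class),
null quadrant fractions of 1/4 within three binomial standard errors,
and the Welch stand-in's null false-positive rate within 0.05 ± 0.02.
Problem sizes (500 genes per study, 50 seeds; ~21k peaks for the null
rate) were chosen to make those sampling bands tight at desk scale.

## Degenerate inputs and tie-breaks

Empty annotation streams yield empty collections; records with
end ≤ start are rejected with a warning naming the line; structurally
malformed lines raise a parse error naming the line. Peaks on
chromosomes absent from the partition are distal_intergenic with a
warning. Constant input to the correlation or to a Z-score column is an
error (undefined), not a silent NaN. All orderings that could tie
(assignment, rankings, gene sets) have deterministic lexicographic
tie-breaks, and every generator stage draws from its own seeded stream,
so identical configs produce byte-identical files.
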