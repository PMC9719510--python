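"""Gene annotation parsing, interval algebra, and region partitioning.

This module owns the genomic coordinate conventions of the package
(0-based, half-open everywhere; GTF is converted on read) and the
partition of the genome into the three region classes used throughout
the integration analysis:

* ``promoter_5utr`` -- a strand-aware window around the TSS (default
  +/-3000 bp) plus any annotated 5'UTR,
* ``genebody`` -- the TSS..TES span plus annotated 3'UTR, minus the
  promoter class,
* ``distal_intergenic`` -- everything else.

Peak-to-class assignment is by peak midpoint with precedence
promoter_5utr > genebody > distal_intergenic; when the midpoint falls
in the same class of several genes, the gene whose TSS is closest wins
(ties broken by gene_id).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from intervaltree import IntervalTree

PROMOTER = "promoter_5utr"
GENEBODY = "genebody"
INTERGENIC = "distal_intergenic"
REGION_CLASSES = (PROMOTER, GENEBODY, INTERGENIC)


class AnnotationParseError(ValueError):
    """Raised for malformed annotation input (message names the line)."""


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A 0-based, half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class GeneModel:
    """One gene = one transcript model (longest-span transcript if several).

    ``tss``/``tes`` are derived from the exon span and the strand:
    on ``+`` the TSS is the leftmost exon start, on ``-`` it is the
    rightmost exon end (half-open convention, so the TSS of a minus
    strand gene equals the span end coordinate).
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    utr5: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)
    biotype: str = "unknown"
    tss: int = field(init=False)
    tes: int = field(init=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: needs at least one exon")
        self.exons = sorted(self.exons, key=lambda e: (e.start, e.end))
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
        s, e = self.span
        for u in list(self.utr5) + list(self.utr3):
            if u.start < s or u.end > e:
                raise ValueError(f"gene {self.gene_id}: UTR outside exon span")
        if self.strand == "+":
            self.tss, self.tes = s, e
        else:
            self.tss, self.tes = e, s

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0].start, self.exons[-1].end


# ---------------------------------------------------------------------------
# pair-level interval algebra ((start, end) tuples; shared by partitioning)

def _merge_pairs(pairs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(pairs):
        if e <= s:
            continue
        if out and s <= out[-1][1]:  # bookended intervals merge too
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _subtract_pairs(
    pairs: Sequence[tuple[int, int]], minus: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    minus = _merge_pairs(minus)
    for s, e in _merge_pairs(pairs):
        cur = s
        for ms, me in minus:
            if me <= cur or ms >= e:
                continue
            if ms > cur:
                out.append((cur, ms))
            cur = max(cur, me)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: disjoint, sorted by (chrom, start), strand dropped.

    Bookended intervals (end == next start) merge, mirroring the default
    behaviour of bedtools merge.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        for s, e in _merge_pairs(by_chrom[chrom]):
            out.append(GenomicInterval(chrom, s, e))
    return out


# ---------------------------------------------------------------------------
# annotation parsing

_GTF_ATTR = re.compile(r'(\S+)\s+"([^"]*)"')
_UTR5_FEATURES = {"five_prime_utr", "5UTR", "five_prime_UTR"}
_UTR3_FEATURES = {"three_prime_utr", "3UTR", "three_prime_UTR"}


def _iter_lines(source) -> Iterator[str]:
    if hasattr(source, "read"):
        yield from source
    elif isinstance(source, (str, Path)):
        with open(source) as fh:
            yield from fh
    else:
        yield from source


def _sniff_format(fields: list[str]) -> str:
    if len(fields) >= 12 and fields[1].isdigit() and fields[2].isdigit():
        return "bed12"
    if len(fields) == 9 and fields[3].lstrip("-").isdigit() and fields[4].lstrip("-").isdigit():
        return "gtf"
    raise AnnotationParseError(
        "cannot determine annotation format (expected GTF or BED12)"
    )


def read_gene_annotation(source, fmt: str | None = None) -> list[GeneModel]:
    """Parse gene models from GTF (1-based, closed) or BED12 (0-based, half-open).

    Coordinates are normalised to 0-based half-open. Biotype is taken from
    the ``gene_biotype``/``gene_type`` GTF attribute when present, else
    ``"unknown"``. One model is kept per gene: the longest-span transcript.
    Records with end <= start are rejected with a warning; structurally
    malformed lines raise :class:`AnnotationParseError` naming the line.
    """
    lines = [(i, ln.rstrip("\n")) for i, ln in enumerate(_iter_lines(source), 1)]
    data = [(i, ln) for i, ln in lines if ln.strip() and not ln.startswith(("#", "track", "browser"))]
    if not data:
        return []
    if fmt is None:
        fmt = _sniff_format(data[0][1].split("\t"))
    if fmt == "gtf":
        return _parse_gtf(data)
    if fmt == "bed12":
        return _parse_bed12(data)
    raise ValueError(f"unknown annotation format {fmt!r}")


def _parse_gtf(data: list[tuple[int, str]]) -> list[GeneModel]:
    genes: dict[str, dict] = {}
    for lineno, line in data:
        f = line.split("\t")
        if len(f) != 9:
            raise AnnotationParseError(
                f"line {lineno}: expected 9 tab-separated GTF fields, got {len(f)}"
            )
        feature = f[2]
        if feature == "exon":
            kind = "exon"
        elif feature in _UTR5_FEATURES:
            kind = "utr5"
        elif feature in _UTR3_FEATURES:
            kind = "utr3"
        elif feature in ("gene", "transcript", "mRNA"):
            kind = None  # interval not kept, but attributes (biotype) are
        else:
            continue
        try:
            start, end = int(f[3]) - 1, int(f[4])  # 1-based closed -> 0-based half-open
        except ValueError as exc:
            raise AnnotationParseError(f"line {lineno}: non-numeric coordinates") from exc
        if end <= start:
            warnings.warn(f"line {lineno}: record with end <= start rejected")
            continue
        attrs = dict(_GTF_ATTR.findall(f[8]))
        gid = attrs.get("gene_id")
        if not gid:
            raise AnnotationParseError(f"line {lineno}: missing gene_id attribute")
        g = genes.setdefault(
            gid, {"chrom": f[0], "strand": f[6], "biotype": "unknown", "tx": {}}
        )
        biotype = attrs.get("gene_biotype") or attrs.get("gene_type")
        if biotype and g["biotype"] == "unknown":
            g["biotype"] = biotype
        if kind is None:
            continue
        tid = attrs.get("transcript_id", "")
        tx = g["tx"].setdefault(tid, {"exon": [], "utr5": [], "utr3": []})
        tx[kind].append((start, end))

    out: list[GeneModel] = []
    for gid in sorted(genes):
        g = genes[gid]
        if g["strand"] not in ("+", "-"):
            warnings.warn(f"gene {gid}: unstranded record skipped")
            continue
        with_exons = {t: v for t, v in g["tx"].items() if v["exon"]}
        if not with_exons:
            warnings.warn(f"gene {gid}: no exon records, skipped")
            continue
        # longest-span transcript; deterministic tie-break on transcript id
        tid = min(
            with_exons,
            key=lambda t: (
                -(max(e for _, e in with_exons[t]["exon"]) - min(s for s, _ in with_exons[t]["exon"])),
                t,
            ),
        )
        tx = with_exons[tid]
        chrom = g["chrom"]
        out.append(
            GeneModel(
                gene_id=gid,
                chrom=chrom,
                strand=g["strand"],
                exons=[GenomicInterval(chrom, s, e, g["strand"]) for s, e in _merge_pairs(tx["exon"])],
                utr5=[GenomicInterval(chrom, s, e, g["strand"]) for s, e in _merge_pairs(tx["utr5"])],
                utr3=[GenomicInterval(chrom, s, e, g["strand"]) for s, e in _merge_pairs(tx["utr3"])],
                biotype=g["biotype"],
            )
        )
    return out


def _parse_bed12(data: list[tuple[int, str]]) -> list[GeneModel]:
    out: list[GeneModel] = []
    for lineno, line in data:
        f = line.split("\t")
        if len(f) < 12:
            raise AnnotationParseError(
                f"line {lineno}: expected 12 BED12 fields, got {len(f)}"
            )
        try:
            start, end = int(f[1]), int(f[2])
            thick_s, thick_e = int(f[6]), int(f[7])
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
        except ValueError as exc:
            raise AnnotationParseError(f"line {lineno}: non-numeric BED12 field") from exc
        if end <= start:
            warnings.warn(f"line {lineno}: record with end <= start rejected")
            continue
        if len(sizes) != n_blocks or len(offsets) != n_blocks:
            raise AnnotationParseError(f"line {lineno}: block count mismatch")
        chrom, name, strand = f[0], f[3], f[5]
        if strand not in ("+", "-"):
            warnings.warn(f"line {lineno}: unstranded BED12 record skipped")
            continue
        exon_pairs = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
        utr_left: list[tuple[int, int]] = []
        utr_right: list[tuple[int, int]] = []
        if thick_e > thick_s:  # coding; exonic parts outside thick region are UTR
            for es, ee in exon_pairs:
                if es < thick_s:
                    utr_left.append((es, min(ee, thick_s)))
                if ee > thick_e:
                    utr_right.append((max(es, thick_e), ee))
        u5, u3 = (utr_left, utr_right) if strand == "+" else (utr_right, utr_left)
        out.append(
            GeneModel(
                gene_id=name,
                chrom=chrom,
                strand=strand,
                exons=[GenomicInterval(chrom, s, e, strand) for s, e in exon_pairs],
                utr5=[GenomicInterval(chrom, s, e, strand) for s, e in u5 if e > s],
                utr3=[GenomicInterval(chrom, s, e, strand) for s, e in u3 if e > s],
            )
        )
    return sorted(out, key=lambda g: (g.chrom, g.span[0], g.gene_id))


# ---------------------------------------------------------------------------
# region partition

@dataclass
class RegionPartition:
    """Per-gene promoter_5utr / genebody intervals plus lookup structures.

    Positions covered by no class belong to the implicit
    ``distal_intergenic`` class. Per gene, the two explicit classes are
    disjoint by construction (genebody is computed minus the promoter).
    """

    genes: dict[str, GeneModel]
    promoter_window: tuple[int, int]
    promoter: dict[str, list[tuple[int, int]]]
    genebody: dict[str, list[tuple[int, int]]]
    _trees: dict[str, dict[str, IntervalTree]] = field(repr=False, default_factory=dict)
    _tss_index: dict[str, tuple[np.ndarray, list[str]]] = field(repr=False, default_factory=dict)

    @property
    def chromosomes(self) -> set[str]:
        return set(self._trees)

    def tree(self, chrom: str, region_class: str) -> IntervalTree:
        return self._trees.get(chrom, {}).get(region_class, IntervalTree())

    def nearest_gene(self, chrom: str, pos: int) -> str | None:
        """Gene with TSS closest to ``pos`` (ties -> lexicographic gene_id)."""
        if chrom not in self._tss_index:
            return None
        tss, ids = self._tss_index[chrom]
        d = np.abs(tss - pos)
        dmin = d.min()
        return min(ids[i] for i in np.flatnonzero(d == dmin))


def partition_regions(
    genes: Iterable[GeneModel], promoter_window: tuple[int, int] = (3000, 3000)
) -> RegionPartition:
    """Build the promoter_5utr / genebody / distal_intergenic partition.

    ``promoter_window`` is (upstream bp, downstream bp) relative to the
    TSS, applied strand-aware. The promoter class is the window union
    the annotated 5'UTR; the genebody is (TSS..TES span union 3'UTR)
    minus the promoter class.
    """
    up, down = promoter_window
    if up < 0 or down < 0:
        raise ValueError("promoter window sizes must be >= 0")
    gene_map: dict[str, GeneModel] = {}
    promoter: dict[str, list[tuple[int, int]]] = {}
    genebody: dict[str, list[tuple[int, int]]] = {}
    trees: dict[str, dict[str, IntervalTree]] = {}
    tss_acc: dict[str, list[tuple[int, str]]] = {}
    for g in genes:
        if g.gene_id in gene_map:
            raise ValueError(f"duplicate gene_id {g.gene_id!r}")
        gene_map[g.gene_id] = g
        if g.strand == "+":
            win = (g.tss - up, g.tss + down)
        else:
            win = (g.tss - down, g.tss + up)
        win = (max(0, win[0]), max(0, win[1]))
        prom = _merge_pairs([win] + [(u.start, u.end) for u in g.utr5])
        body = _subtract_pairs(
            [g.span] + [(u.start, u.end) for u in g.utr3], prom
        )
        promoter[g.gene_id] = prom
        genebody[g.gene_id] = body
        ctrees = trees.setdefault(
            g.chrom, {PROMOTER: IntervalTree(), GENEBODY: IntervalTree()}
        )
        for s, e in prom:
            ctrees[PROMOTER].addi(s, e, g.gene_id)
        for s, e in body:
            ctrees[GENEBODY].addi(s, e, g.gene_id)
        tss_acc.setdefault(g.chrom, []).append((g.tss, g.gene_id))
    tss_index = {
        chrom: (
            np.array([t for t, _ in sorted(pairs)], dtype=np.int64),
            [gid for _, gid in sorted(pairs)],
        )
        for chrom, pairs in tss_acc.items()
    }
    return RegionPartition(
        genes=gene_map,
        promoter_window=(up, down),
        promoter=promoter,
        genebody=genebody,
        _trees=trees,
        _tss_index=tss_index,
    )


def assign_region(
    peak: GenomicInterval, partition: RegionPartition, rule: str = "midpoint"
) -> tuple[str, str | None]:
    """Assign a peak to (region class, gene_id or None).

    With the default ``midpoint`` rule a peak belongs to the class
    containing its midpoint; with ``any_overlap`` any overlap counts,
    still with promoter > genebody precedence. distal_intergenic peaks
    return gene ``None`` here (a nearest-TSS attribution for intergenic
    peaks is done at annotation time in :mod:`epilink.peak_integration`).
    """
    if rule not in ("midpoint", "any_overlap"):
        raise ValueError(f"unknown assignment rule {rule!r}")
    if peak.chrom not in partition.chromosomes:
        warnings.warn(
            f"peak chromosome {peak.chrom!r} absent from partition; "
            "assigned distal_intergenic"
        )
        return INTERGENIC, None
    mid = peak.midpoint
    for region_class in (PROMOTER, GENEBODY):
        tree = partition.tree(peak.chrom, region_class)
        hits = tree[mid] if rule == "midpoint" else tree.overlap(peak.start, peak.end)
        gids = {iv.data for iv in hits}
        if gids:
            best = min(
                gids, key=lambda gid: (abs(mid - partition.genes[gid].tss), gid)
            )
            return region_class, best
    return INTERGENIC, None


def write_partition_bed(partition: RegionPartition, path) -> None:
    """Write the explicit classes as BED6 (name = class:gene_id)."""
    rows = []
    for gid in partition.genes:
        strand = partition.genes[gid].strand
        chrom = partition.genes[gid].chrom
        for cls, pairs in ((PROMOTER, partition.promoter[gid]), (GENEBODY, partition.genebody[gid])):
            for s, e in pairs:
                rows.append((chrom, s, e, f"{cls}:{gid}", 0, strand))
    rows.sort()
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")
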