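"""Coverage-track quantification.

A :class:`SignalTrack` is a per-chromosome step function (sorted,
non-overlapping ``(start, end, value)`` steps; uncovered positions are
zero), the in-memory form of a bedGraph. On top of it this module
provides RPKM normalisation, interval sums/means, scaled metagene
profiles, and fragment-in-peak counting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_model import GeneModel, GenomicInterval


class SignalTrack:
    """Step-wise per-base signal density (non-negative), one array triple per chromosome."""

    def __init__(self, steps: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self.steps: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in steps.items():
            starts = np.asarray(starts, dtype=float)
            ends = np.asarray(ends, dtype=float)
            values = np.asarray(values, dtype=float)
            if np.any(ends <= starts):
                raise ValueError(f"{chrom}: empty or inverted step")
            if np.any(values < 0):
                raise ValueError(f"{chrom}: negative signal value")
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"{chrom}: overlapping steps")
            self.steps[chrom] = (starts, ends, values)

    @classmethod
    def from_steps(
        cls,
        steps: Iterable[tuple[str, float, float, float]],
        chroms: Iterable[str] = (),
    ) -> "SignalTrack":
        """Build from an iterable of (chrom, start, end, value) tuples.

        ``chroms`` registers chromosomes that should exist even with no
        covered positions (all-zero track).
        """
        acc: dict[str, list[tuple[float, float, float]]] = {c: [] for c in chroms}
        for chrom, s, e, v in steps:
            if v == 0:
                acc.setdefault(chrom, [])
                continue
            acc.setdefault(chrom, []).append((s, e, v))
        return cls(
            {
                c: (
                    np.array([s for s, _, _ in rows]),
                    np.array([e for _, e, _ in rows]),
                    np.array([v for _, _, v in rows]),
                )
                for c, rows in acc.items()
            }
        )

    @classmethod
    def read_bedgraph(cls, source) -> "SignalTrack":
        """Read a 4-column bedGraph (0-based half-open)."""
        rows = []
        if isinstance(source, (str, Path)):
            fh = open(source)
            close = True
        else:
            fh, close = source, False
        try:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                if len(f) < 4:
                    raise ValueError(f"bedGraph line {lineno}: expected 4 columns")
                rows.append((f[0], float(f[1]), float(f[2]), float(f[3])))
        finally:
            if close:
                fh.close()
        return cls.from_steps(rows)

    def write_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.steps):
                starts, ends, values = self.steps[chrom]
                for s, e, v in zip(starts, ends, values):
                    fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{v:.6g}\n")

    def scale(self, factor: float) -> "SignalTrack":
        return SignalTrack(
            {c: (s.copy(), e.copy(), v * factor) for c, (s, e, v) in self.steps.items()}
        )

    def _cumulative_at(self, chrom: str, xs: np.ndarray) -> np.ndarray:
        """Integral of the step function from -inf to each x (vectorised)."""
        starts, ends, values = self.steps[chrom]
        xs = np.asarray(xs, dtype=float)
        if len(starts) == 0:
            return np.zeros_like(xs)
        cum = np.concatenate([[0.0], np.cumsum(values * (ends - starts))])
        k = np.searchsorted(ends, xs, side="right")  # steps fully left of x
        out = cum[k]
        kk = np.minimum(k, len(starts) - 1)
        partial = np.where(
            (k < len(starts)) & (xs > starts[kk]), (xs - starts[kk]) * values[kk], 0.0
        )
        return out + partial

    def range_sum(self, chrom: str, start: float, end: float) -> float:
        if chrom not in self.steps or end <= start:
            return 0.0
        f = self._cumulative_at(chrom, np.array([start, end], dtype=float))
        return float(f[1] - f[0])


def rpkm_normalize(raw_track: SignalTrack, library_size: float) -> SignalTrack:
    """Convert per-base read-count density to RPKM.

    Each step value v (reads per base) becomes v * 1e9 / library_size,
    i.e. per-base density expressed per kilobase per million fragments.
    """
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    return raw_track.scale(1e9 / library_size)


def interval_signal(
    track: SignalTrack, interval: GenomicInterval, mode: str = "sum"
) -> float:
    """Sum or mean of the track over an interval; uncovered bases count as 0."""
    if mode not in ("sum", "mean"):
        raise ValueError(f"unknown mode {mode!r}")
    if interval.chrom not in track.steps:
        warnings.warn(f"chromosome {interval.chrom!r} absent from track; signal 0")
        return 0.0
    total = track.range_sum(interval.chrom, interval.start, interval.end)
    return total if mode == "sum" else total / interval.length


@dataclass
class MetageneProfile:
    """Mean signal over a gene set after scaling gene bodies to common bins."""

    values: np.ndarray
    flank_bins_up: int
    body_bins: int
    flank_bins_down: int
    gene_set_label: str = ""
    cumulative: np.ndarray | None = None

    def __post_init__(self) -> None:
        expected = self.flank_bins_up + self.body_bins + self.flank_bins_down
        if len(self.values) != expected:
            raise ValueError("profile length does not match bin layout")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("profile values must be finite and >= 0")

    @property
    def body_values(self) -> np.ndarray:
        return self.values[self.flank_bins_up : self.flank_bins_up + self.body_bins]

    def to_frame(self) -> pd.DataFrame:
        n_up, n_body = self.flank_bins_up, self.body_bins
        segment = (
            ["upstream"] * n_up + ["body"] * n_body + ["downstream"] * self.flank_bins_down
        )
        df = pd.DataFrame(
            {"bin": np.arange(len(self.values)), "segment": segment, "mean": self.values}
        )
        if self.cumulative is not None:
            df["cumulative"] = self.cumulative
        return df


def _gene_bin_boundaries(
    gene: GeneModel, body_bins: int, flank_bp: int, flank_bin_bp: int
) -> np.ndarray:
    """Left-to-right genomic bin boundaries: left flank, scaled body, right flank."""
    s, e = gene.span
    n_flank = flank_bp // flank_bin_bp
    left = s - flank_bp + flank_bin_bp * np.arange(n_flank + 1, dtype=float)
    body = s + (e - s) * np.arange(1, body_bins, dtype=float) / body_bins
    right = e + flank_bin_bp * np.arange(n_flank + 1, dtype=float)
    return np.concatenate([left, body, right])


def metagene_profile(
    track: SignalTrack,
    genes: Sequence[GeneModel],
    body_bins: int = 100,
    flank_bp: int = 2000,
    flank_bin_bp: int = 50,
    cumulative: bool = False,
    gene_set_label: str = "",
) -> MetageneProfile:
    """Strand-aware scaled metagene profile (mean per bin over genes).

    Each gene's TSS..TES span is split into ``body_bins`` equal-fraction
    bins; flanks of ``flank_bp`` are binned at ``flank_bin_bp`` native
    resolution. Minus-strand gene vectors are reversed before averaging
    so that the profile always reads TSS -> TES. If ``cumulative`` is
    set, the running sum of the mean profile is attached as well.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("metagene_profile requires a non-empty gene set")
    if body_bins < 1:
        raise ValueError("body_bins must be >= 1")
    if flank_bp % flank_bin_bp:
        raise ValueError("flank_bp must be a multiple of flank_bin_bp")
    n_flank = flank_bp // flank_bin_bp
    total_bins = 2 * n_flank + body_bins
    acc = np.zeros(total_bins)
    for gene in genes:
        bounds = _gene_bin_boundaries(gene, body_bins, flank_bp, flank_bin_bp)
        if gene.chrom in track.steps:
            f = track._cumulative_at(gene.chrom, bounds)
            sums = np.diff(f)
        else:
            sums = np.zeros(total_bins)
        widths = np.diff(bounds)
        vec = sums / widths
        if gene.strand == "-":
            vec = vec[::-1]
        acc += vec
    mean = acc / len(genes)
    return MetageneProfile(
        values=mean,
        flank_bins_up=n_flank,
        body_bins=body_bins,
        flank_bins_down=n_flank,
        gene_set_label=gene_set_label,
        cumulative=np.cumsum(mean) if cumulative else None,
    )


def count_fragments_in_peaks(
    fragments: Mapping[str, Sequence[GenomicInterval]],
    peaks: Sequence[GenomicInterval],
) -> pd.DataFrame:
    """Per-peak, per-sample fragment counts (fragment midpoint containment).

    Peaks must be disjoint (merge them first); each fragment is then
    counted for at most one peak — the one containing its midpoint,
    half-open, so a midpoint exactly at a peak start counts and one at
    the peak end does not.
    """
    ordered = sorted(peaks, key=lambda p: (p.chrom, p.start, p.end))
    for a, b in zip(ordered, ordered[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise ValueError(
                "peaks overlap; run merge_intervals / build_consensus_peaks first"
            )
    index = [f"{p.chrom}:{p.start}-{p.end}" for p in peaks]
    row_of = {(p.chrom, p.start, p.end): i for i, p in enumerate(peaks)}
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[int]]] = {}
    for chrom in {p.chrom for p in peaks}:
        cp = [p for p in ordered if p.chrom == chrom]
        by_chrom[chrom] = (
            np.array([p.start for p in cp]),
            np.array([p.end for p in cp]),
            [row_of[(p.chrom, p.start, p.end)] for p in cp],
        )
    counts = np.zeros((len(peaks), len(fragments)), dtype=int)
    for j, sample in enumerate(fragments):
        for frag in fragments[sample]:
            if frag.chrom not in by_chrom:
                continue
            starts, ends, rows = by_chrom[frag.chrom]
            mid = frag.midpoint
            k = int(np.searchsorted(starts, mid, side="right")) - 1
            if k >= 0 and mid < ends[k]:
                counts[rows[k], j] += 1
    return pd.DataFrame(counts, index=index, columns=list(fragments))
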