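"""Gene-level statistical rules of the study.

Differential-expression filtering (three criteria: p < 0.05,
protein-coding biotype, mean FPKM > 5 in at least one condition),
signature derivation with p/fold-change cutoffs and top-N truncation,
per-sample Z-scores, and the four-parameter colitis histology rubric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

PROTEIN_CODING = "protein_coding"


@dataclass
class DifferentialExpressionTable:
    """Per-gene expression table: one row per gene_id.

    ``data`` carries gene_id, biotype, log2fc, pvalue and one
    ``fpkm_<sample>`` column per sample; ``condition_samples`` maps the
    two condition labels to their sample names, in (baseline,
    treatment) order.
    """

    data: pd.DataFrame
    condition_samples: dict[str, list[str]]

    def __post_init__(self) -> None:
        required = {"gene_id", "biotype", "log2fc", "pvalue"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"DE table missing columns: {sorted(missing)}")
        if self.data["gene_id"].duplicated().any():
            raise ValueError("DE table has duplicate gene_id rows")
        if len(self.condition_samples) != 2:
            raise ValueError("exactly two conditions required")
        p = self.data["pvalue"].to_numpy(dtype=float)
        if np.any((p <= 0) | (p > 1)):
            raise ValueError("pvalue must lie in (0, 1]")
        for cond, samples in self.condition_samples.items():
            for s in samples:
                col = f"fpkm_{s}"
                if col not in self.data.columns:
                    raise ValueError(f"missing FPKM column {col!r} for condition {cond}")
                if (self.data[col] < 0).any():
                    raise ValueError(f"negative FPKM in column {col!r}")

    @property
    def conditions(self) -> tuple[str, str]:
        c = list(self.condition_samples)
        return c[0], c[1]

    def fpkm_columns(self, condition: str) -> list[str]:
        return [f"fpkm_{s}" for s in self.condition_samples[condition]]

    def mean_fpkm(self, condition: str) -> pd.Series:
        return self.data[self.fpkm_columns(condition)].mean(axis=1)

    def fpkm_matrix(self) -> pd.DataFrame:
        """Gene x sample FPKM matrix (index gene_id, columns sample names)."""
        cols, names = [], []
        for cond in self.condition_samples:
            for s in self.condition_samples[cond]:
                cols.append(f"fpkm_{s}")
                names.append(s)
        m = self.data.set_index("gene_id")[cols]
        m.columns = names
        return m

    def write_tsv(self, path) -> None:
        meta = "; ".join(
            f"{cond}={','.join(samples)}" for cond, samples in self.condition_samples.items()
        )
        with open(path, "w") as fh:
            fh.write(f"# conditions: {meta}\n")
            self.data.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_de_tsv(
    path, condition_samples: Mapping[str, Sequence[str]] | None = None
) -> DifferentialExpressionTable:
    """Read a DE TSV; condition/sample layout comes from the header
    comment written by :meth:`DifferentialExpressionTable.write_tsv`
    unless supplied explicitly."""
    path = Path(path)
    parsed: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# conditions:"):
                for part in line.split(":", 1)[1].split(";"):
                    cond, samples = part.strip().split("=")
                    parsed[cond] = samples.split(",")
    if condition_samples is None:
        if not parsed:
            raise ValueError(
                f"{path}: no '# conditions:' header and no condition_samples given"
            )
        condition_samples = parsed
    data = pd.read_csv(path, sep="\t", comment="#")
    return DifferentialExpressionTable(
        data=data, condition_samples={c: list(s) for c, s in condition_samples.items()}
    )


def filter_significant_genes(
    table: DifferentialExpressionTable,
    p_cutoff: float = 0.05,
    fpkm_cutoff: float = 5.0,
) -> DifferentialExpressionTable:
    """Keep significantly changed genes by the study's three criteria:
    p-value below ``p_cutoff``, protein-coding biotype, and mean FPKM
    above ``fpkm_cutoff`` in at least one of the two conditions.
    Genes with missing biotype are excluded with a warning.
    """
    cond1, cond2 = table.conditions
    df = table.data
    missing = df["biotype"].isna()
    if missing.any():
        warnings.warn(f"{int(missing.sum())} gene(s) with missing biotype excluded")
    keep = (
        (df["pvalue"] < p_cutoff)
        & (df["biotype"] == PROTEIN_CODING)
        & (
            (table.mean_fpkm(cond1) > fpkm_cutoff)
            | (table.mean_fpkm(cond2) > fpkm_cutoff)
        )
    )
    return replace(table, data=df[keep].reset_index(drop=True))


@dataclass
class GeneSet:
    """A labelled, duplicate-free gene list plus its derivation metadata."""

    label: str
    gene_ids: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError(f"gene set {self.label!r} contains duplicates")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gid: str) -> bool:
        return gid in set(self.gene_ids)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# label: {self.label}\n")
            for k in sorted(self.metadata):
                fh.write(f"# {k}: {self.metadata[k]}\n")
            for gid in self.gene_ids:
                fh.write(gid + "\n")

    @classmethod
    def read(cls, path) -> "GeneSet":
        label, meta, ids = "", {}, []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("# label:"):
                    label = line.split(":", 1)[1].strip()
                elif line.startswith("#"):
                    k, _, v = line[1:].partition(":")
                    meta[k.strip()] = v.strip()
                elif line:
                    ids.append(line)
        return cls(label=label, gene_ids=tuple(ids), metadata=meta)


def derive_signature(
    table: DifferentialExpressionTable,
    p_cutoff: float = 0.05,
    fc_cutoff: float = 2.0,
    direction: str = "up",
    top_n: int | None = None,
    rank_by: str = "pvalue",
    label: str = "signature",
) -> GeneSet:
    """Signature gene set: p-value and linear fold-change cutoffs, then
    optional top-N truncation by p-value or |fold change|.

    ``fc_cutoff`` is on the linear scale (2 means two-fold). Direction
    ``up`` keeps fold change >= cutoff, ``down`` keeps <= 1/cutoff,
    ``both`` keeps either. Ties are broken by the other ranking key,
    then gene_id.
    """
    if direction not in ("up", "down", "both"):
        raise ValueError(f"unknown direction {direction!r}")
    if rank_by not in ("pvalue", "fold_change"):
        raise ValueError(f"unknown rank_by {rank_by!r}")
    if fc_cutoff <= 0:
        raise ValueError("fc_cutoff must be > 0 (linear scale)")
    df = table.data.copy()
    fc = 2.0 ** df["log2fc"].to_numpy(dtype=float)
    if direction == "up":
        dir_ok = fc >= fc_cutoff
    elif direction == "down":
        dir_ok = fc <= 1.0 / fc_cutoff
    else:
        dir_ok = (fc >= fc_cutoff) | (fc <= 1.0 / fc_cutoff)
    df = df[(df["pvalue"] < p_cutoff) & dir_ok].copy()
    df["abs_l2fc"] = df["log2fc"].abs()
    if rank_by == "pvalue":
        df = df.sort_values(["pvalue", "abs_l2fc", "gene_id"], ascending=[True, False, True])
    else:
        df = df.sort_values(["abs_l2fc", "pvalue", "gene_id"], ascending=[False, True, True])
    if top_n is not None:
        if top_n > len(df):
            warnings.warn(
                f"top_n={top_n} exceeds {len(df)} qualifying genes; returning all"
            )
        df = df.head(top_n)
    return GeneSet(
        label=label,
        gene_ids=tuple(df["gene_id"]),
        metadata={
            "p_cutoff": p_cutoff,
            "fc_cutoff": fc_cutoff,
            "direction": direction,
            "top_n": top_n,
            "rank_by": rank_by,
            "n": len(df),
        },
    )


def top_changed_genes(
    table: DifferentialExpressionTable, n: int, rank_by: str = "pvalue"
) -> GeneSet:
    """Top-n most significantly changed genes, both directions, ranked
    by ascending p-value (ties: larger |log2fc| first, then gene_id).
    Intended to run on a table already passed through
    :func:`filter_significant_genes`.
    """
    if rank_by != "pvalue":
        raise ValueError("top_changed_genes ranks by pvalue")
    if n < 0:
        raise ValueError("n must be >= 0")
    df = table.data.copy()
    if n > len(df):
        warnings.warn(f"n={n} exceeds table size {len(df)}; returning all genes")
    df["abs_l2fc"] = df["log2fc"].abs()
    df = df.sort_values(["pvalue", "abs_l2fc", "gene_id"], ascending=[True, False, True])
    sel = df.head(n)
    return GeneSet(
        label=f"top{n}_by_pvalue",
        gene_ids=tuple(sel["gene_id"]),
        metadata={"n": len(sel), "rank_by": "pvalue"},
    )


def zscore_by_sample(fpkm: pd.DataFrame, mode: str = "sample") -> pd.DataFrame:
    """Standard scores of an FPKM matrix.

    Default standardises within each sample (column): Z = (x - mu) / sigma
    with mu and sigma (n-1 denominator) over the genes of that sample.
    ``mode="gene"`` standardises within rows instead (the common heatmap
    convention, not the default here).
    """
    if mode not in ("sample", "gene"):
        raise ValueError(f"unknown mode {mode!r}")
    m = fpkm if mode == "sample" else fpkm.T
    mu = m.mean(axis=0)
    sd = m.std(axis=0, ddof=1)
    bad = sd[(sd == 0) | sd.isna()]
    if len(bad):
        raise ValueError(
            f"constant FPKM column: cannot standardise sample {bad.index[0]!r}"
        )
    z = (m - mu) / sd
    return z if mode == "sample" else z.T


@dataclass(frozen=True)
class HistologyScore:
    """Colitis histology score: four parameters summed (maximum total 9).

    Parameters and their printed ranges: inflammatory infiltration in
    the lamina propria 1-3; goblet cell loss 0-2; mucosal erosion to
    ulceration 0-2; submucosal spread to transmural involvement 0-2.
    """

    infiltration: int
    goblet_loss: int
    erosion: int
    submucosal_spread: int

    @property
    def total(self) -> int:
        return self.infiltration + self.goblet_loss + self.erosion + self.submucosal_spread


_HISTOLOGY_RANGES = {
    "infiltration": (1, 3),
    "goblet_loss": (0, 2),
    "erosion": (0, 2),
    "submucosal_spread": (0, 2),
}


def histology_colitis_score(
    infiltration: int, goblet_loss: int, erosion: int, submucosal_spread: int
) -> HistologyScore:
    """Build a validated colitis histology score from the four parameters."""
    values = {
        "infiltration": infiltration,
        "goblet_loss": goblet_loss,
        "erosion": erosion,
        "submucosal_spread": submucosal_spread,
    }
    for name, v in values.items():
        lo, hi = _HISTOLOGY_RANGES[name]
        if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
            raise ValueError(f"{name} must be an integer in [{lo}, {hi}]")
        if not (lo <= v <= hi):
            raise ValueError(f"{name}={v} out of range [{lo}, {hi}]")
    return HistologyScore(**values)
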