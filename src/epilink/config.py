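"""Pipeline configuration: a plain YAML document validated into a typed object."""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .genome_model import REGION_CLASSES


class ConfigError(ValueError):
    """Raised for unparseable, unknown, missing, or out-of-range config values."""


@dataclass
class PipelineConfig:
    annotation: Path
    peaks: dict[str, Path]  # exactly two conditions, (baseline, treatment) order
    counts: Path
    de_table: Path
    coverage: dict[str, Path] = field(default_factory=dict)
    outdir: Path = Path("epilink_out")
    conditions: tuple[str, str] | None = None  # default: order of the peaks mapping
    promoter_window: tuple[int, int] = (3000, 3000)
    pseudocount: float = 1.0
    alpha: float = 0.05
    p_cutoff: float = 0.05
    fpkm_cutoff: float = 5.0
    top_n: int | None = 200
    rank_by: str = "pvalue"
    region_classes: tuple[str, ...] = REGION_CLASSES
    assignment_rule: str = "midpoint"
    body_bins: int = 100
    flank_bp: int = 2000
    flank_bin_bp: int = 50
    seed: int = 0
    verbosity: str = "info"

    def __post_init__(self) -> None:
        if self.conditions is None:
            self.conditions = tuple(self.peaks)  # type: ignore[assignment]


_REQUIRED = ("annotation", "peaks", "counts", "de_table")
_PATH_KEYS = ("annotation", "counts", "de_table")


def validate_config(source) -> PipelineConfig:
    """Parse and validate a pipeline config.

    ``source`` may be a path to a YAML file, YAML text, or a dict.
    Unknown keys are rejected with a closest-match suggestion; missing
    required paths and out-of-range numeric values raise
    :class:`ConfigError`. Relative paths resolve against the config
    file's directory.
    """
    base = Path(".")
    if isinstance(source, dict):
        raw = dict(source)
    else:
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source):
            path = Path(source)
            base = path.parent
            text = path.read_text()
        else:
            text = source
        raw = yaml.safe_load(text)
        if not isinstance(raw, dict):
            raise ConfigError("config document must be a mapping")

    known = {f.name for f in fields(PipelineConfig)}
    for key in raw:
        if key not in known:
            hint = difflib.get_close_matches(key, sorted(known), n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigError(f"unknown config key {key!r}{suggestion}")
    for key in _REQUIRED:
        if key not in raw:
            raise ConfigError(f"missing required config key {key!r}")

    def as_path(v) -> Path:
        p = Path(v)
        return p if p.is_absolute() else base / p

    kwargs: dict = {}
    for key in _PATH_KEYS:
        p = as_path(raw[key])
        if not p.exists():
            raise ConfigError(f"{key}: path does not exist: {p}")
        kwargs[key] = p
    if not isinstance(raw["peaks"], dict) or len(raw["peaks"]) != 2:
        raise ConfigError("peaks must map exactly two condition names to BED paths")
    kwargs["peaks"] = {}
    for cond, v in raw["peaks"].items():
        p = as_path(v)
        if not p.exists():
            raise ConfigError(f"peaks[{cond}]: path does not exist: {p}")
        kwargs["peaks"][cond] = p
    if "coverage" in raw:
        if not isinstance(raw["coverage"], dict):
            raise ConfigError("coverage must map condition names to bedGraph paths")
        kwargs["coverage"] = {}
        for cond, v in raw["coverage"].items():
            p = as_path(v)
            if not p.exists():
                raise ConfigError(f"coverage[{cond}]: path does not exist: {p}")
            kwargs["coverage"][cond] = p
    if "outdir" in raw:
        kwargs["outdir"] = as_path(raw["outdir"])
    if "conditions" in raw:
        conds = tuple(raw["conditions"])
        if len(conds) != 2 or set(conds) != set(kwargs["peaks"]):
            raise ConfigError("conditions must list the two peak condition names")
        kwargs["conditions"] = conds

    def check_range(key, value, lo, hi, lo_open=False):
        ok = (value > lo if lo_open else value >= lo) and value <= hi
        if not ok:
            bracket = "(" if lo_open else "["
            raise ConfigError(f"{key}={value} out of range {bracket}{lo}, {hi}]")
        return value

    if "alpha" in raw:
        kwargs["alpha"] = check_range("alpha", float(raw["alpha"]), 0, 1, lo_open=True)
    if "p_cutoff" in raw:
        kwargs["p_cutoff"] = check_range("p_cutoff", float(raw["p_cutoff"]), 0, 1, lo_open=True)
    if "fpkm_cutoff" in raw:
        kwargs["fpkm_cutoff"] = check_range("fpkm_cutoff", float(raw["fpkm_cutoff"]), 0, 1e12)
    if "pseudocount" in raw:
        kwargs["pseudocount"] = check_range("pseudocount", float(raw["pseudocount"]), 0, 1e12)
    if "top_n" in raw:
        if raw["top_n"] is not None:
            kwargs["top_n"] = int(check_range("top_n", int(raw["top_n"]), 0, 10**9))
        else:
            kwargs["top_n"] = None
    if "rank_by" in raw:
        if raw["rank_by"] not in ("pvalue", "fold_change"):
            raise ConfigError(f"rank_by must be 'pvalue' or 'fold_change', got {raw['rank_by']!r}")
        kwargs["rank_by"] = raw["rank_by"]
    if "promoter_window" in raw:
        win = tuple(int(x) for x in raw["promoter_window"])
        if len(win) != 2 or any(x < 0 for x in win):
            raise ConfigError("promoter_window must be two non-negative integers")
        kwargs["promoter_window"] = win
    if "region_classes" in raw:
        cls = tuple(raw["region_classes"])
        bad = [c for c in cls if c not in REGION_CLASSES and c != "summed"]
        if bad:
            raise ConfigError(f"unknown region classes: {bad}")
        kwargs["region_classes"] = cls
    if "assignment_rule" in raw:
        if raw["assignment_rule"] not in ("midpoint", "any_overlap"):
            raise ConfigError("assignment_rule must be 'midpoint' or 'any_overlap'")
        kwargs["assignment_rule"] = raw["assignment_rule"]
    for key in ("body_bins", "flank_bp", "flank_bin_bp", "seed"):
        if key in raw:
            kwargs[key] = int(check_range(key, int(raw[key]), 0 if key == "seed" else 1, 10**9))
    if "verbosity" in raw:
        kwargs["verbosity"] = str(raw["verbosity"])
    return PipelineConfig(**kwargs)
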