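"""Analysis configuration: every tunable threshold of the pipeline.

Defaults encode the study design this package implements: differential
calling at |FC| >= 1.5 with BH FDR < 0.05, co-expression edges at
|r| >= 0.8 with p <= 0.05, a 300-kb cis window, top-200 prediction pairs
and top-30 terms for guilt-by-association function prediction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigError

#: Significance modes for co-expression edges: raw Pearson p or BH q.
CORR_ADJUST_MODES = ("raw", "bh")


@dataclass
class AnalysisConfig:
    """Thresholds and sizes for every stage of the analysis.

    Parameters
    ----------
    fc_threshold:
        Minimum absolute linear fold change for differential calling
        (inclusive, ``>=``).
    fdr_threshold:
        BH FDR cutoff for differential calling (exclusive, ``<``).
    corr_r_threshold:
        Minimum absolute Pearson r for a co-expression edge (inclusive).
    corr_p_threshold:
        Significance cutoff for a co-expression edge (inclusive, ``<=``).
    corr_adjust:
        ``"raw"`` gates edges on the raw Pearson p-value, ``"bh"`` on the
        BH q-value computed within each lncRNA's edge family.
    cis_window:
        Genomic window, in bp, up- and downstream of a lncRNA within which
        an mRNA is a cis candidate (inter-interval gap <= window).
    top_pairs / top_terms:
        Sizes of the prediction-pair pool and the reported term list in
        guilt-by-association function prediction.
    top_correlates:
        Number of most-correlated mRNAs kept per lncRNA (heatmaps, network
        candidate genes).
    top_selected:
        Number of ranked differential probes flagged per biotype.
    """

    fc_threshold: float = 1.5
    fdr_threshold: float = 0.05
    corr_r_threshold: float = 0.8
    corr_p_threshold: float = 0.05
    corr_adjust: str = "raw"
    cis_window: int = 300_000
    cis_p_threshold: float = 0.05
    enrich_p_threshold: float = 0.05
    tf_p_threshold: float = 0.05
    top_pairs: int = 200
    top_terms: int = 30
    top_correlates: int = 30
    top_selected: int = 200
    min_term_size: int = 3
    max_term_size: int = 2000
    welch: bool = False
    bh_global: bool = False
    trans_restrict_to_de: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fc_threshold < 1:
            raise ConfigError("fc_threshold is a linear ratio and must be >= 1")
        for name in ("fdr_threshold", "corr_p_threshold", "cis_p_threshold",
                     "enrich_p_threshold", "tf_p_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigError(f"{name} must lie in (0, 1], got {v!r}")
        if not 0 <= self.corr_r_threshold <= 1:
            raise ConfigError("corr_r_threshold must lie in [0, 1]")
        if self.corr_adjust not in CORR_ADJUST_MODES:
            raise ConfigError(
                f"corr_adjust must be one of {CORR_ADJUST_MODES}, got {self.corr_adjust!r}")
        if self.cis_window < 0:
            raise ConfigError("cis_window must be >= 0")
        for name in ("top_pairs", "top_terms", "top_correlates", "top_selected",
                     "min_term_size"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.max_term_size < self.min_term_size:
            raise ConfigError("max_term_size must be >= min_term_size")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        """Load a config from a one-document YAML file; absent keys keep defaults."""
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a mapping at the top level")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def asdict(self) -> dict:
        return dataclasses.asdict(self)
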