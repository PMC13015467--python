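"""Global analysis parameters.

Every numeric threshold used across the pipeline lives here so that a single
configuration file can override any of them. Defaults reflect the analysis
conditions of the glioma long-read cohort study this package models:
a 50 bp breakpoint window for merging redundant caller output, a minimum of
3 supporting reads, a 200 bp "near exon" margin for intronic breakpoints,
DepMap essentiality cutoffs (dependency probability >= 0.9, gene effect
<= -1), the proportional breakpoint-proximity rule (10% of gene length,
clamped to [500, 2000] bp), a 100 bp structural tolerance for isoform
boundary comparison, and the differential-expression significance gates
(FDR <= 0.05, |log2FC| >= 1) with the count-based expression filter
(>= 10 counts in at least min-group-size samples and >= 15 total).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any

import yaml


@dataclass(frozen=True)
class Parameters:
    dedup_window_bp: int = 50
    min_support_reads: int = 3
    near_exon_bp: int = 200
    dep_prob_min: float = 0.9
    gene_effect_max: float = -1.0
    prox_fraction: float = 0.10
    prox_min_bp: int = 500
    prox_max_bp: int = 2000
    boundary_tol_bp: int = 100
    de_fdr_max: float = 0.05
    de_abs_lfc_min: float = 1.0
    expr_min_count: int = 10
    expr_min_total: int = 15
    glioma_keywords: frozenset[str] = frozenset(
        {"glioma", "astrocytoma", "glioblastoma", "oligodendroglioma", "cns"}
    )
    glioma_exclusions: frozenset[str] = frozenset({"paraganglioma"})
    mane_tag: str = "MANE_Select"
    mito_chroms: frozenset[str] = frozenset({"chrM", "MT", "chrMT", "M"})

    def __post_init__(self) -> None:
        positive = [
            self.dedup_window_bp,
            self.min_support_reads,
            self.near_exon_bp,
            self.dep_prob_min,
            self.prox_fraction,
            self.prox_min_bp,
            self.prox_max_bp,
            self.boundary_tol_bp,
            self.de_fdr_max,
            self.de_abs_lfc_min,
            self.expr_min_count,
            self.expr_min_total,
        ]
        if any(v <= 0 for v in positive):
            raise ValueError("all thresholds except gene_effect_max must be positive")
        if self.prox_min_bp > self.prox_max_bp:
            raise ValueError("prox_min_bp must not exceed prox_max_bp")

    def override(self, **kwargs: Any) -> "Parameters":
        """Return a copy with the given fields replaced."""
        coerced = {}
        for f in fields(self):
            if f.name not in kwargs:
                continue
            value = kwargs[f.name]
            if f.name in ("glioma_keywords", "glioma_exclusions", "mito_chroms"):
                if isinstance(value, str):
                    value = [v.strip() for v in value.split(",") if v.strip()]
                value = frozenset(str(v).lower() if f.name != "mito_chroms" else str(v)
                                  for v in value)
            coerced[f.name] = value
        unknown = set(kwargs) - set(coerced)
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        return replace(self, **coerced)


def load_parameters(path: str | Path) -> Parameters:
    """Load a flat key-value config (YAML mapping) overriding any default.

    Keys may use the dotted ``params.<name>`` namespace or bare names.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a flat key-value mapping")
    flat = {}
    for key, value in raw.items():
        name = key.split(".", 1)[1] if key.startswith("params.") else key
        flat[name] = value
    return Parameters().override(**flat)


DEFAULT_PARAMS = Parameters()
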