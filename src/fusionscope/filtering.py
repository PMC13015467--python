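"""Multistep fusion filtering cascade with a per-stage audit trail.

Harmonized ensemble fusion calls are reduced to a high-confidence set by a
fixed sequence of gates: a cancer-gene gate (at least one partner on the
fusion panel or in the Cancer Gene Census), a minimum read-support gate,
a blacklist of recurrent technical artifact classes (pseudogenes, ribosomal
proteins, HLA genes, mitochondrial fusions), a strand-consistency check,
subtraction of gene pairs also seen in healthy brain tissue controls, and
finally removal of fusions whose breakpoints are all intronic / intergenic /
unannotated. Every removal is attributed to exactly one stage in the audit.

Strand consistency: a call is dropped when its reported breakpoint strands
contradict the annotated strands of both partner genes, i.e. when the
reported orientation cannot produce a 5'->3' chimeric transcript reading
gene5 then gene3. Calls with unknown strands or unannotated genes pass with
a warning flag (fail-open), so caller outputs lacking strand information are
not silently discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Optional

import pandas as pd

from .breakpoints import AnnotatedFusion, annotate_fusion, drop_unannotatable
from .harmonize import FusionCall, FusionKey
from .model import GenomeAnnotation
from .params import DEFAULT_PARAMS, Parameters


class ConfigurationError(ValueError):
    pass


@dataclass
class GeneClassSets:
    panel_genes: set[str] = field(default_factory=set)
    census_genes: set[str] = field(default_factory=set)
    pseudogenes: set[str] = field(default_factory=set)
    ribosomal_genes: set[str] = field(default_factory=set)
    hla_genes: set[str] = field(default_factory=set)
    mito_genes: set[str] = field(default_factory=set)
    control_pairs: set[tuple[str, str]] = field(default_factory=set)

    @staticmethod
    def read_gene_list(path: str | Path) -> set[str]:
        """One gene symbol per line; blank lines and '#' comments ignored."""
        out = set()
        for line in Path(path).read_text().splitlines():
            sym = line.strip()
            if sym and not sym.startswith("#"):
                out.add(sym)
        return out

    @staticmethod
    def read_control_pairs(path: str | Path) -> set[tuple[str, str]]:
        """TSV with two gene columns; pairs stored unordered."""
        df = pd.read_csv(path, sep="\t")
        cols = list(df.columns[:2])
        return {
            tuple(sorted((str(a), str(b))))
            for a, b in zip(df[cols[0]], df[cols[1]])
        }


@dataclass
class FilterAudit:
    """Ordered record of (stage, n_in, n_out, removed keys) for each stage."""

    stages: list[tuple[str, int, int, list[FusionKey]]] = field(default_factory=list)

    def record(self, stage: str, n_in: int, n_out: int,
               removed: list[FusionKey]) -> None:
        if n_out > n_in:
            raise ValueError("audit stage cannot gain calls")
        if self.stages and self.stages[-1][2] != n_in:
            raise ValueError("audit stages must chain: n_in must equal previous n_out")
        self.stages.append((stage, n_in, n_out, removed))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for stage, n_in, n_out, removed in self.stages:
            rows.append({
                "stage": stage, "n_in": n_in, "n_out": n_out,
                "n_removed": n_in - n_out,
                "removed": ";".join(
                    f"{k.sample_id}:{k.genes[0]}--{k.genes[1]}" for k in removed
                ),
            })
        return pd.DataFrame(rows)

    @property
    def removals(self) -> dict[str, list[FusionKey]]:
        return {stage: removed for stage, _, _, removed in self.stages}


def gene_list_gate(calls: list[FusionCall], sets: GeneClassSets) -> list[FusionCall]:
    """Keep calls with at least one partner on the panel or in the census."""
    allowed = sets.panel_genes | sets.census_genes
    if not allowed:
        raise ConfigurationError("panel/census gene lists are empty")
    return [c for c in calls if c.gene5 in allowed or c.gene3 in allowed]


def support_filter(calls: list[FusionCall],
                   min_reads: int = DEFAULT_PARAMS.min_support_reads) -> list[FusionCall]:
    """Keep calls with read support at or above the minimum (inclusive)."""
    return [c for c in calls if c.support_reads >= min_reads]


def blacklist_filter(calls: list[FusionCall], sets: GeneClassSets,
                     params: Parameters = DEFAULT_PARAMS) -> list[FusionCall]:
    """Drop pseudogene / ribosomal / HLA partners and mitochondrial fusions."""
    bad_genes = sets.pseudogenes | sets.ribosomal_genes | sets.hla_genes
    out = []
    for c in calls:
        if c.gene5 in bad_genes or c.gene3 in bad_genes:
            continue
        if c.bp5.chrom in params.mito_chroms or c.bp3.chrom in params.mito_chroms:
            continue
        if c.gene5 in sets.mito_genes or c.gene3 in sets.mito_genes:
            continue
        out.append(c)
    return out


def strand_consistency_filter(calls: list[FusionCall],
                              annotation: GenomeAnnotation) -> list[FusionCall]:
    """Drop calls whose reported strands contradict the annotated gene strands."""
    out = []
    for c in calls:
        g5 = annotation.get(c.gene5)
        g3 = annotation.get(c.gene3)
        if g5 is None or g3 is None:
            out.append(replace(c, flags=c.flags | {"strand_unverified"}))
            continue
        r5, r3 = c.bp5.strand, c.bp3.strand
        if r5 == "unknown" or r3 == "unknown":
            out.append(replace(c, flags=c.flags | {"strand_unknown"}))
            continue
        # A 5'->3' chimera reading gene5 then gene3 traverses each partner in
        # its own transcription direction; reported segment strands must
        # match the annotated strands.
        if r5 == g5.strand and r3 == g3.strand:
            out.append(c)
    return out


def control_subtraction(calls: list[FusionCall],
                        control_pairs: set[tuple[str, str]]) -> list[FusionCall]:
    """Drop calls whose unordered gene pair was seen in control tissue."""
    return [
        c for c in calls
        if tuple(sorted((c.gene5, c.gene3))) not in control_pairs
    ]


def apply_cascade(
    calls: list[FusionCall],
    sets: GeneClassSets,
    annotation: GenomeAnnotation,
    params: Parameters = DEFAULT_PARAMS,
) -> tuple[list[AnnotatedFusion], FilterAudit]:
    """Run the full filtering cascade, returning survivors and the audit.

    Stage order: gene gate -> support -> blacklist -> strand consistency ->
    control subtraction -> breakpoint-class drop. The first four gates and
    control subtraction are mutually independent set intersections; the
    final stage requires breakpoint annotation, which the survivors carry
    out of the cascade.
    """
    audit = FilterAudit()

    def run(stage: str, fn: Callable[[list[FusionCall]], list[FusionCall]],
            current: list[FusionCall]) -> list[FusionCall]:
        result = fn(current)
        # identity can change across a stage (flags added), so removals are a
        # multiset difference on the flag-free signature
        def sig(c: FusionCall):
            return (c.key, c.bp5, c.bp3, c.support_reads, c.callers)

        from collections import Counter

        kept_sig = Counter(sig(c) for c in result)
        removed = []
        for c in current:
            if kept_sig[sig(c)] > 0:
                kept_sig[sig(c)] -= 1
            else:
                removed.append(c.key)
        audit.record(stage, len(current), len(result), removed)
        return result

    current = run("gene_list_gate", lambda cs: gene_list_gate(cs, sets), calls)
    current = run("support_filter",
                  lambda cs: support_filter(cs, params.min_support_reads), current)
    current = run("blacklist_filter",
                  lambda cs: blacklist_filter(cs, sets, params), current)
    current = run("strand_consistency",
                  lambda cs: strand_consistency_filter(cs, annotation), current)
    current = run("control_subtraction",
                  lambda cs: control_subtraction(cs, sets.control_pairs), current)

    tier_cache: dict = {}
    annotated = [annotate_fusion(c, annotation, params, tier_cache) for c in current]
    retained = drop_unannotatable(annotated)
    audit.record(
        "breakpoint_class_drop", len(annotated), len(retained),
        [f.call.key for f in annotated
         if (f.call.key, f.call.bp5, f.call.bp3)
         not in {(r.call.key, r.call.bp5, r.call.bp3) for r in retained}],
    )
    return retained, audit
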