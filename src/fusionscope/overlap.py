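"""Overlap of fusion breakpoints with transcript isoform boundaries.

A genuine fusion leaves an isoform-level footprint: premature transcript
termination in the 5' partner gene near the breakpoint, and novel
transcription initiation in the 3' partner gene near its breakpoint. An
isoform boundary is "non-canonical" when it differs by more than the
structural tolerance (default 100 bp) from the canonical transcript of the
gene — the MANE Select transcript when present, otherwise the longest
protein-coding transcript. Non-canonical ends of 5'-partner isoforms and
non-canonical starts of 3'-partner isoforms count as breakpoint-proximal
when they fall within a proportional distance threshold of the breakpoint:
10% of the gene length, clamped to a 500 bp floor and a 2 kb ceiling.

A fusion whose 5' and 3' partners both show a breakpoint-proximal boundary
in the same sample is flagged as having a fusion-like isoform pattern. An
expression-asymmetry annotation (lowly expressed 5' partner, highly
expressed 3' partner) can be attached for context but is never used as a
filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .breakpoints import AnnotatedFusion
from .model import GeneModel, GenomeAnnotation, TierSelection, gene_length, select_transcript_tiers
from .novel import IsoformRecord
from .params import DEFAULT_PARAMS, Parameters


@dataclass(frozen=True)
class OverlapHit:
    fusion_name: str
    sample_id: str
    role: str  # 5prime | 3prime
    isoform_id: str
    boundary_kind: str  # noncanonical_end | noncanonical_start
    distance_bp: int
    threshold_bp: int
    same_sample: bool
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if self.distance_bp > self.threshold_bp:
            raise ValueError("hit distance exceeds its threshold")
        expected = {"5prime": "noncanonical_end", "3prime": "noncanonical_start"}
        if expected[self.role] != self.boundary_kind:
            raise ValueError(
                f"role {self.role} must pair with {expected[self.role]}"
            )


def proximity_threshold(gene_length_bp: int,
                        params: Parameters = DEFAULT_PARAMS) -> int:
    """Breakpoint search radius: 10% of gene length clamped to [500, 2000] bp."""
    if gene_length_bp < 1:
        raise ValueError("gene length must be >= 1")
    raw = params.prox_fraction * gene_length_bp
    return int(min(max(raw, params.prox_min_bp), params.prox_max_bp))


def noncanonical_boundary(
    isoform: IsoformRecord,
    gene: GeneModel,
    tiers: Optional[TierSelection] = None,
    tol: int = DEFAULT_PARAMS.boundary_tol_bp,
) -> tuple[set[str], bool]:
    """Which ends of an isoform deviate from the canonical transcript.

    Returns (kinds, low_confidence). Both ends are evaluated in
    transcription direction; a boundary is non-canonical when it differs by
    more than ``tol`` bp from the canonical transcript's corresponding end.
    Genes without a MANE or coding transcript fall back to the longest
    transcript overall and the result is flagged low-confidence.
    """
    if tiers is None:
        tiers = select_transcript_tiers(gene)
    canonical = tiers.tier1 or tiers.tier2
    low_confidence = False
    if canonical is None:
        canonical = sorted(
            tiers.tier3, key=lambda t: (-t.spliced_length, t.transcript_id)
        )[0]
        low_confidence = True
    kinds: set[str] = set()
    if abs(isoform.tx_start - canonical.tx_start()) > tol:
        kinds.add("noncanonical_start")
    if abs(isoform.tx_end - canonical.tx_end()) > tol:
        kinds.add("noncanonical_end")
    return kinds, low_confidence


def breakpoint_proximal_isoforms(
    fusion: AnnotatedFusion,
    isoforms: Iterable[IsoformRecord],
    annotation: GenomeAnnotation,
    params: Parameters = DEFAULT_PARAMS,
    same_sample_only: bool = True,
) -> list[OverlapHit]:
    """Isoforms with non-canonical boundaries near a fusion's breakpoints.

    For the 5' gene, non-canonical ends within the clamped threshold of the
    5' breakpoint; for the 3' gene, non-canonical starts within the
    threshold of the 3' breakpoint. With ``same_sample_only`` (the default)
    only isoforms from the fusion-bearing sample are reported; hits always
    carry the ``same_sample`` flag either way.
    """
    call = fusion.call
    hits: list[OverlapHit] = []
    for role, gene_name, bp, kind in (
        ("5prime", call.gene5, call.bp5, "noncanonical_end"),
        ("3prime", call.gene3, call.bp3, "noncanonical_start"),
    ):
        gene = annotation.get(gene_name)
        if gene is None:
            continue
        tiers = select_transcript_tiers(gene)
        threshold = proximity_threshold(gene_length(gene), params)
        for iso in isoforms:
            if iso.gene != gene_name:
                continue
            same = iso.sample_id == call.sample_id
            if same_sample_only and not same:
                continue
            kinds, low_conf = noncanonical_boundary(
                iso, gene, tiers, params.boundary_tol_bp
            )
            if kind not in kinds:
                continue
            boundary = iso.tx_end if kind == "noncanonical_end" else iso.tx_start
            distance = abs(boundary - bp.pos)
            if distance <= threshold:
                hits.append(
                    OverlapHit(
                        fusion_name=call.name, sample_id=iso.sample_id, role=role,
                        isoform_id=iso.isoform_id, boundary_kind=kind,
                        distance_bp=distance, threshold_bp=threshold,
                        same_sample=same, low_confidence=low_conf,
                    )
                )
    return hits


def fusion_like_pattern(
    hits: list[OverlapHit],
    expr_summary: Optional[pd.DataFrame] = None,
    gene_of_isoform: Optional[dict[str, str]] = None,
    low_pct: float = 25.0,
    high_pct: float = 75.0,
    rank_col: Optional[str] = None,
) -> pd.DataFrame:
    """Per-fusion fusion-like flags from role-paired overlap hits.

    A fusion is fusion-like when it has at least one 5'-role hit and at
    least one 3'-role hit in the same sample. When an expression summary
    with percentile ranks is supplied, an expression-asymmetry annotation
    (5' partner below ``low_pct``, 3' partner above ``high_pct``) is
    attached; it is context only and never filters the flag.
    """
    rows = []
    by_fusion: dict[str, list[OverlapHit]] = {}
    for h in hits:
        by_fusion.setdefault(h.fusion_name, []).append(h)
    for fusion_name in sorted(by_fusion):
        fhits = by_fusion[fusion_name]
        samples5 = {h.sample_id for h in fhits if h.role == "5prime"}
        samples3 = {h.sample_id for h in fhits if h.role == "3prime"}
        shared = samples5 & samples3
        asym = None
        if expr_summary is not None and rank_col is not None and gene_of_isoform:
            def rank_of(role):
                iso_ids = [h.isoform_id for h in fhits if h.role == role]
                ranks = [
                    float(expr_summary.loc[i, rank_col])
                    for i in iso_ids if i in expr_summary.index
                ]
                return min(ranks) if role == "5prime" and ranks else (
                    max(ranks) if ranks else None
                )
            r5, r3 = rank_of("5prime"), rank_of("3prime")
            if r5 is not None and r3 is not None:
                asym = bool(r5 <= low_pct and r3 >= high_pct)
        rows.append({
            "fusion": fusion_name,
            "fusion_like": bool(shared),
            "n_hits_5prime": len(samples5),
            "n_hits_3prime": len(samples3),
            "shared_samples": ";".join(sorted(shared)),
            "expression_asymmetry": asym,
        })
    return pd.DataFrame(
        rows,
        columns=["fusion", "fusion_like", "n_hits_5prime", "n_hits_3prime",
                 "shared_samples", "expression_asymmetry"],
    )


def hits_to_frame(hits: Iterable[OverlapHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "fusion": h.fusion_name, "sample": h.sample_id, "role": h.role,
                "isoform_id": h.isoform_id, "kind": h.boundary_kind,
                "distance": h.distance_bp, "threshold": h.threshold_bp,
                "same_sample": h.same_sample, "low_confidence": h.low_confidence,
            }
            for h in hits
        ],
        columns=["fusion", "sample", "role", "isoform_id", "kind", "distance",
                 "threshold", "same_sample", "low_confidence"],
    )
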