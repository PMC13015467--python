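"""Tiered breakpoint region classification.

Each fusion breakpoint is located against its partner gene's transcript
models in a three-tier order: the MANE Select transcript, then the longest
protein-coding transcript, then all annotated transcripts. Within a
transcript a position is classified as CDS, 5'/3' UTR, or exon of a
non-coding transcript; outside all exons it is intronic. Escalation to the
next tier occurs only when the current tier yields an intronic (or absent)
call, so an exonic tier-1 classification is never downgraded.

Intronic breakpoints within 200 bp of an exon boundary are reclassified as
"near exon" and counted with CDS as potentially functional, reflecting both
alignment ambiguity at exon-intron junctions and the splice-proximal bias of
genuine fusion junctions. Fusions with both breakpoints intronic,
intergenic, or unannotated carry no usable transcript context and are
dropped from downstream analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional

import pandas as pd

from .harmonize import FusionCall
from .model import (
    GeneModel,
    GenomeAnnotation,
    GenomicPosition,
    TierSelection,
    TranscriptModel,
    select_transcript_tiers,
)
from .params import DEFAULT_PARAMS, Parameters

REGION_CLASSES = (
    "CDS", "UTR5", "UTR3", "noncoding_exon", "near_exon",
    "intronic", "intergenic", "unannotated",
)
EXONIC_CLASSES = frozenset({"CDS", "UTR5", "UTR3", "noncoding_exon"})
FUNCTIONAL_CLASSES = frozenset({"CDS", "near_exon"})
UNINFORMATIVE_CLASSES = frozenset({"intronic", "intergenic", "unannotated"})

TIER_LABELS = ("MANE", "longest_coding", "any_transcript", "none")


@dataclass(frozen=True)
class BreakpointAnnotation:
    region_class: str
    tier_used: str
    distance_to_nearest_exon_boundary: Optional[int] = None
    transcript_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region class {self.region_class!r}")
        if self.tier_used not in TIER_LABELS:
            raise ValueError(f"unknown tier {self.tier_used!r}")
        no_tier = self.region_class in ("intergenic", "unannotated")
        if no_tier != (self.tier_used == "none"):
            raise ValueError(
                f"tier_used=none must pair with intergenic/unannotated, got "
                f"{self.region_class}/{self.tier_used}"
            )


@dataclass(frozen=True)
class AnnotatedFusion:
    call: FusionCall
    ann5: BreakpointAnnotation
    ann3: BreakpointAnnotation
    functional_any: bool = False
    functional_both: bool = False


def _classify_in_transcript(pos: int, t: TranscriptModel) -> Optional[tuple[str, int]]:
    """Classify pos within one transcript; None if outside the transcript span.

    Returns (region_class, distance_to_nearest_exon_boundary).
    """
    span = t.span
    if pos < span.start or pos > span.end:
        return None
    dist = t.distance_to_exon_boundary(pos)
    exon = t.exon_containing(pos)
    if exon is None:
        return ("intronic", dist)
    if not t.has_cds:
        return ("noncoding_exon", dist)
    if t.cds_start <= pos <= t.cds_end:
        return ("CDS", dist)
    if pos < t.cds_start:
        return ("UTR5" if t.strand == "+" else "UTR3", dist)
    return ("UTR3" if t.strand == "+" else "UTR5", dist)


def classify_breakpoint(
    pos: GenomicPosition,
    gene: Optional[GeneModel],
    tiers: Optional[TierSelection] = None,
) -> BreakpointAnnotation:
    """Classify a breakpoint against its gene's tiered transcript models.

    Escalates MANE -> longest coding -> all transcripts, stopping at the
    first tier giving a non-intronic, non-absent class. A position inside the
    gene span but exonic in no transcript is intronic (reported at the
    highest tier that contains it); outside the span it is intergenic; a gene
    absent from the annotation is unannotated.
    """
    if gene is None:
        return BreakpointAnnotation("unannotated", "none")
    if pos.chrom != gene.chrom:
        return BreakpointAnnotation("intergenic", "none")
    span = gene.span
    if pos.pos < span.start or pos.pos > span.end:
        return BreakpointAnnotation("intergenic", "none")
    if tiers is None:
        tiers = select_transcript_tiers(gene)

    intronic_fallback: Optional[BreakpointAnnotation] = None
    tier_iter: list[tuple[str, list[TranscriptModel]]] = []
    if tiers.tier1 is not None:
        tier_iter.append(("MANE", [tiers.tier1]))
    if tiers.tier2 is not None and (tiers.tier1 is None or
                                    tiers.tier2.transcript_id != tiers.tier1.transcript_id):
        tier_iter.append(("longest_coding", [tiers.tier2]))
    tier_iter.append(("any_transcript", tiers.tier3))

    for tier_name, transcripts in tier_iter:
        for t in transcripts:
            res = _classify_in_transcript(pos.pos, t)
            if res is None:
                continue
            region, dist = res
            if region in EXONIC_CLASSES:
                return BreakpointAnnotation(region, tier_name, dist, t.transcript_id)
            if intronic_fallback is None:
                intronic_fallback = BreakpointAnnotation(
                    "intronic", tier_name, dist, t.transcript_id
                )
    if intronic_fallback is not None:
        return intronic_fallback
    # Inside the gene span but outside every transcript span: intronic
    # relative to the gene body, anchored to the nearest exon boundary.
    dist = min(t.distance_to_exon_boundary(pos.pos) for t in tiers.tier3)
    nearest = min(tiers.tier3,
                  key=lambda t: (t.distance_to_exon_boundary(pos.pos), t.transcript_id))
    return BreakpointAnnotation("intronic", "any_transcript", dist,
                                nearest.transcript_id)


def reclassify_near_exon(
    ann: BreakpointAnnotation, near_exon_bp: int = DEFAULT_PARAMS.near_exon_bp
) -> BreakpointAnnotation:
    """Intronic breakpoints within near_exon_bp of an exon boundary become near_exon.

    All other classes are fixed points, so the operation is idempotent.
    """
    if (
        ann.region_class == "intronic"
        and ann.distance_to_nearest_exon_boundary is not None
        and ann.distance_to_nearest_exon_boundary <= near_exon_bp
    ):
        return replace(ann, region_class="near_exon")
    return ann


def functional_flags(fusion: AnnotatedFusion) -> AnnotatedFusion:
    """Set the potentially-functional flags from CDS/near-exon membership."""
    f5 = fusion.ann5.region_class in FUNCTIONAL_CLASSES
    f3 = fusion.ann3.region_class in FUNCTIONAL_CLASSES
    return replace(fusion, functional_any=f5 or f3, functional_both=f5 and f3)


def annotate_fusion(
    call: FusionCall,
    annotation: GenomeAnnotation,
    params: Parameters = DEFAULT_PARAMS,
    tier_cache: Optional[dict[str, TierSelection]] = None,
) -> AnnotatedFusion:
    """Classify both breakpoints of a call and set functional flags."""
    def one(gene_name: str, pos: GenomicPosition) -> BreakpointAnnotation:
        gene = annotation.get(gene_name)
        tiers = None
        if gene is not None and tier_cache is not None:
            tiers = tier_cache.get(gene.gene_id)
            if tiers is None:
                tiers = select_transcript_tiers(gene)
                tier_cache[gene.gene_id] = tiers
        ann = classify_breakpoint(pos, gene, tiers)
        return reclassify_near_exon(ann, params.near_exon_bp)

    fused = AnnotatedFusion(call, one(call.gene5, call.bp5), one(call.gene3, call.bp3))
    return functional_flags(fused)


def drop_unannotatable(fusions: list[AnnotatedFusion]) -> list[AnnotatedFusion]:
    """Remove fusions with both breakpoints intronic, intergenic, or unannotated."""
    return [
        f for f in fusions
        if not (
            f.ann5.region_class in UNINFORMATIVE_CLASSES
            and f.ann3.region_class in UNINFORMATIVE_CLASSES
        )
    ]


def summarize_breakpoint_classes(fusions: list[AnnotatedFusion]) -> dict[str, pd.DataFrame]:
    """Per-role (5'/3') class fractions and tier-usage fractions.

    CDS and near-exon are pooled into one "CDS/near_exon" category, the
    potentially functional class.
    """
    if not fusions:
        return {"classes": pd.DataFrame(), "tiers": pd.DataFrame()}

    def pool(cls: str) -> str:
        return "CDS/near_exon" if cls in FUNCTIONAL_CLASSES else cls

    rows = []
    for f in fusions:
        rows.append({"role": "5prime", "region": pool(f.ann5.region_class),
                     "tier": f.ann5.tier_used})
        rows.append({"role": "3prime", "region": pool(f.ann3.region_class),
                     "tier": f.ann3.tier_used})
    df = pd.DataFrame(rows)
    classes = (
        df.groupby(["role", "region"]).size().unstack(fill_value=0)
        .apply(lambda r: r / r.sum(), axis=1)
    )
    tiers = (
        df.groupby(["role", "tier"]).size().unstack(fill_value=0)
        .apply(lambda r: r / r.sum(), axis=1)
    )
    return {"classes": classes, "tiers": tiers}


def annotated_to_frame(fusions: Iterable[AnnotatedFusion]) -> pd.DataFrame:
    from .harmonize import calls_to_frame

    base = calls_to_frame([f.call for f in fusions])
    extra = pd.DataFrame(
        [
            {
                "class5": f.ann5.region_class, "tier5": f.ann5.tier_used,
                "dist5": f.ann5.distance_to_nearest_exon_boundary,
                "class3": f.ann3.region_class, "tier3": f.ann3.tier_used,
                "dist3": f.ann3.distance_to_nearest_exon_boundary,
                "functional_any": f.functional_any,
                "functional_both": f.functional_both,
            }
            for f in fusions
        ]
    )
    return pd.concat([base.reset_index(drop=True), extra.reset_index(drop=True)], axis=1)
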