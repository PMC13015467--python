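import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fusionscope.breakpoints import (
    AnnotatedFusion,
    BreakpointAnnotation,
    annotate_fusion,
    classify_breakpoint,
    drop_unannotatable,
    functional_flags,
    reclassify_near_exon,
    summarize_breakpoint_classes,
)
from fusionscope.harmonize import FusionCall
from fusionscope.model import GenomicPosition

from .conftest import make_gene, make_transcript


def pos(p, chrom="chr1"):
    return GenomicPosition(chrom, p)


def interval_membership_oracle(p, t):
    """Direct interval-scan classification of p against one transcript."""
    if p < t.span.start or p > t.span.end:
        return None
    in_exon = any(e.start <= p <= e.end for e in t.exons)
    if not in_exon:
        return "intronic"
    if not t.has_cds:
        return "noncoding_exon"
    if t.cds_start <= p <= t.cds_end:
        return "CDS"
    before_cds = p < t.cds_start
    if t.strand == "+":
        return "UTR5" if before_cds else "UTR3"
    return "UTR3" if before_cds else "UTR5"


@pytest.mark.parametrize("strand", ["+", "-"])
def test_classification_matches_interval_oracle_scan(strand):
    """Scan every base of a window around a gene against the oracle."""
    t = make_transcript(strand=strand, mane=True)
    gene = make_gene(strand=strand, transcripts=[t])
    for p in range(900, 2801):
        got = classify_breakpoint(pos(p), gene)
        expected = interval_membership_oracle(p, t)
        if expected is None:
            assert got.region_class == "intergenic"
            assert got.tier_used == "none"
        else:
            assert got.region_class == expected, f"pos {p}"
            assert got.tier_used == "MANE"
            # reported distance agrees with a direct minimum
            d = min(min(abs(p - e.start), abs(p - e.end)) for e in t.exons)
            assert got.distance_to_nearest_exon_boundary == d


def test_unannotated_and_wrong_chrom():
    gene = make_gene()
    assert classify_breakpoint(pos(1500), None).region_class == "unannotated"
    assert classify_breakpoint(pos(1500, "chr9"), gene).region_class == "intergenic"


def test_tier_escalation_only_on_intronic():
    # MANE transcript lacks the middle exon; a position exonic only in the
    # longer non-MANE coding transcript escalates out of intronic.
    mane = make_transcript("T1.1", exons=((1001, 1200), (2401, 2700)),
                           cds=(1101, 2500), mane=True)
    full = make_transcript("T1.2")  # includes (1601, 1900)
    gene = make_gene(transcripts=[mane, full])
    got = classify_breakpoint(pos(1700), gene)
    assert got.region_class == "CDS"
    assert got.tier_used == "longest_coding"
    assert got.transcript_id == "T1.2"
    # but an exonic MANE call never escalates
    got2 = classify_breakpoint(pos(1100), gene)
    assert got2.tier_used == "MANE"


def test_intronic_reported_at_highest_containing_tier():
    t = make_transcript(mane=True)
    gene = make_gene(transcripts=[t])
    got = classify_breakpoint(pos(1400), gene)
    assert got.region_class == "intronic"
    assert got.tier_used == "MANE"


def test_near_exon_reclassification_and_idempotence():
    ann = BreakpointAnnotation("intronic", "MANE", 150, "T1.1")
    out = reclassify_near_exon(ann, 200)
    assert out.region_class == "near_exon"
    assert reclassify_near_exon(out, 200) == out  # idempotent
    far = BreakpointAnnotation("intronic", "MANE", 201, "T1.1")
    assert reclassify_near_exon(far, 200).region_class == "intronic"
    cds = BreakpointAnnotation("CDS", "MANE", 0, "T1.1")
    assert reclassify_near_exon(cds, 200) == cds


@given(st.sampled_from(["CDS", "UTR5", "UTR3", "noncoding_exon", "intronic"]),
       st.integers(0, 400))
@settings(max_examples=60, deadline=None)
def test_reclassify_idempotent_property(cls, dist):
    ann = BreakpointAnnotation(cls, "MANE", dist, "T")
    once = reclassify_near_exon(ann)
    assert reclassify_near_exon(once) == once


def test_annotation_invariant_tier_none():
    with pytest.raises(ValueError):
        BreakpointAnnotation("CDS", "none")
    with pytest.raises(ValueError):
        BreakpointAnnotation("intergenic", "MANE")


def fusion_with(ann5_class, ann3_class):
    call = FusionCall("S1", "A", "B", pos(1100), pos(5200, "chr2"), 5,
                      frozenset({"longgf"}))
    def mk(cls):
        tier = "none" if cls in ("intergenic", "unannotated") else "MANE"
        return BreakpointAnnotation(cls, tier, 0 if tier != "none" else None)
    return functional_flags(AnnotatedFusion(call, mk(ann5_class), mk(ann3_class)))


def test_functional_flags():
    f = fusion_with("CDS", "near_exon")
    assert f.functional_any and f.functional_both
    f = fusion_with("CDS", "UTR3")
    assert f.functional_any and not f.functional_both
    f = fusion_with("UTR5", "intronic")
    assert not f.functional_any


def test_drop_unannotatable():
    keep = fusion_with("CDS", "intronic")
    drop = fusion_with("intronic", "intergenic")
    out = drop_unannotatable([keep, drop])
    assert out == [keep]
    assert drop_unannotatable(out) == out  # idempotent


def test_annotate_fusion_end_to_end(simple_annotation):
    call = FusionCall("S1", "GENEA", "GENEB", pos(1150), pos(5900, "chr2"),
                      5, frozenset({"longgf"}))
    f = annotate_fusion(call, simple_annotation)
    assert f.ann5.region_class == "CDS"
    assert f.ann3.region_class == "CDS"
    assert f.functional_both


def test_summarize_pools_functional_classes():
    fusions = [fusion_with("CDS", "UTR3"), fusion_with("near_exon", "UTR3")]
    summary = summarize_breakpoint_classes(fusions)
    classes = summary["classes"]
    assert classes.loc["5prime", "CDS/near_exon"] == 1.0
    assert classes.loc["3prime", "UTR3"] == 1.0
    # fractions sum to 1 per role
    assert classes.sum(axis=1).round(9).eq(1.0).all()
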