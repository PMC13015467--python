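import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fusionscope.constructs import (
    AssemblyError,
    FusionConstruct,
    apply_5utr_rule,
    assemble_fusion_cdna,
    design_construct,
    genomic_to_spliced,
    junction_microhomology,
    orf_analysis,
    select_reference_transcript,
    snap_to_exon,
    spliced_sequence,
    spliced_to_genomic,
)
from fusionscope.model import ExonInterval, GenomicPosition, TranscriptModel

from .conftest import make_gene, make_transcript

# Hand-built two-gene genome with clean CDS structure:
# chr1 gene5 '+': exon 1-30, CDS 7-24 (ATG GCC GCA GCT CCT GAC), stop TAA 25-27
# chr2 gene3 '+': exon 1-36, CDS 10-24 (ATG AAA GAA GAC GAT), stop TAA 25-27
GENOME = {
    "chr1": "AAAAAA" + "ATGGCCGCAGCTCCTGAC" + "TAA" + "AAA",
    "chr2": "CCCCCCCCC" + "ATGAAAGAAGACGAT" + "TAA" + "GGGGGGGGG",
}

T5 = TranscriptModel("T5.1", "G5", "+", [ExonInterval(1, 30)],
                     cds_start=7, cds_end=24, is_mane=True,
                     is_protein_coding=True)
T3 = TranscriptModel("T3.1", "G3", "+", [ExonInterval(1, 36)],
                     cds_start=10, cds_end=24, is_mane=True,
                     is_protein_coding=True)
GENE5 = make_gene("G5", "FIVE", "chr1", "+", [T5])
GENE3 = make_gene("G3", "THREE", "chr2", "+", [T3])


def bp(chrom, p):
    return GenomicPosition(chrom, p, "+")


# --- coordinate mapping ----------------------------------------------------

@st.composite
def transcripts(draw):
    n = draw(st.integers(1, 5))
    exons, pos = [], draw(st.integers(1, 100))
    for _ in range(n):
        length = draw(st.integers(1, 50))
        exons.append(ExonInterval(pos, pos + length - 1))
        pos += length + draw(st.integers(1, 40))
    strand = draw(st.sampled_from(["+", "-"]))
    return TranscriptModel("T", "G", strand, exons)


@given(transcripts(), st.data())
@settings(max_examples=120, deadline=None)
def test_spliced_genomic_inverse(t, data):
    idx = data.draw(st.integers(0, t.spliced_length - 1))
    g = spliced_to_genomic(t, idx)
    assert genomic_to_spliced(t, g) == idx
    # every exonic genomic position round-trips the other way too
    for e in t.exons:
        for p in (e.start, e.end):
            assert spliced_to_genomic(t, genomic_to_spliced(t, p)) == p


def test_genomic_to_spliced_intronic_is_none():
    t = make_transcript()
    assert genomic_to_spliced(t, 1400) is None
    with pytest.raises(IndexError):
        spliced_to_genomic(t, t.spliced_length)


def test_spliced_sequence_strands():
    seq = spliced_sequence(T5, GENOME, "chr1")
    assert seq == GENOME["chr1"]
    minus = TranscriptModel("Tm", "G", "-", [ExonInterval(1, 6)])
    genome = {"c": "ATGCCA"}
    assert spliced_sequence(minus, genome, "c") == "TGGCAT"


def test_snap_to_exon():
    t = make_transcript()  # exons up to 1200, 1601.., ...
    assert snap_to_exon(t, 1150, 200) == 1150  # already exonic
    assert snap_to_exon(t, 1250, 200) == 1200  # nearest boundary
    assert snap_to_exon(t, 1450, 200) == 1601  # 151 vs 250
    assert snap_to_exon(t, 1450, 100) is None


# --- assembly --------------------------------------------------------------

def test_assemble_exact_sequence():
    c = assemble_fusion_cdna("FIVE::THREE", T5, T3, bp("chr1", 18),
                             bp("chr2", 13), GENOME)
    assert c.cdna == "ATGGCCGCAGCT" + "AAAGAAGACGAT" + "TAA" + "GGGGGGGGG"
    assert c.junction_offset == 12
    assert c.phase3 == 0
    assert c.natural_stop_idx == 24
    assert c.ref3_upstream == "CCCCCCCCCATG"


def test_assembly_prefix_suffix_substrings():
    c = assemble_fusion_cdna("F", T5, T3, bp("chr1", 20), bp("chr2", 15),
                             GENOME)
    assert c.cdna[:c.junction_offset] in spliced_sequence(T5, GENOME, "chr1")
    assert c.cdna[c.junction_offset:] in spliced_sequence(T3, GENOME, "chr2")
    # suffix runs to the transcript end
    assert spliced_sequence(T3, GENOME, "chr2").endswith(
        c.cdna[c.junction_offset:])


def test_assemble_rejects_utr5_breakpoint():
    with pytest.raises(AssemblyError, match="UTR rule"):
        assemble_fusion_cdna("F", T5, T3, bp("chr1", 3), bp("chr2", 13),
                             GENOME)


def test_5utr_rule_carries_full_cds():
    c = apply_5utr_rule("F", T5, T3, bp("chr1", 3), bp("chr2", 13), GENOME)
    assert c.cdna.startswith("ATGGCCGCAGCTCCTGAC")  # full CDS, stop excluded
    assert c.junction_offset == 18
    assert c.utr5_rule
    with pytest.raises(AssemblyError):
        apply_5utr_rule("F", T5, T3, bp("chr1", 18), bp("chr2", 13), GENOME)


def test_3prime_breakpoint_at_transcript_start_appends_full_t3():
    c = assemble_fusion_cdna("F", T5, T3, bp("chr1", 18), bp("chr2", 1),
                             GENOME)
    assert c.cdna[c.junction_offset:] == GENOME["chr2"]


# --- ORF analysis ----------------------------------------------------------

def test_orf_in_frame_no_premature_stop():
    c = orf_analysis(assemble_fusion_cdna(
        "F", T5, T3, bp("chr1", 18), bp("chr2", 13), GENOME))
    assert c.frame_status == "in_frame"
    assert c.premature_stop_pos is None  # first stop is the natural one
    assert c.orf_protein == "MAAAKEDD"


def test_orf_out_of_frame():
    c = orf_analysis(assemble_fusion_cdna(
        "F", T5, T3, bp("chr1", 18), bp("chr2", 14), GENOME))
    assert c.frame_status == "out_of_frame"


def test_orf_5utr_rule_frame_label():
    in_frame = orf_analysis(apply_5utr_rule(
        "F", T5, T3, bp("chr1", 3), bp("chr2", 13), GENOME))
    assert in_frame.frame_status == "in_frame"
    shifted = orf_analysis(apply_5utr_rule(
        "F", T5, T3, bp("chr1", 3), bp("chr2", 14), GENOME))
    assert shifted.frame_status == "out_of_frame_5UTR_rule"


def test_orf_premature_stop_detected():
    # in-frame junction whose 3' segment begins with a stop codon well
    # before the 3' gene's natural stop
    genome = {
        "chr1": GENOME["chr1"],
        "chr2": "CCCCCCCCC" + "ATGTAAGAAGACGAT" + "TAA" + "GGGGGGGGG",
    }
    c = orf_analysis(assemble_fusion_cdna(
        "F", T5, T3, bp("chr1", 18), bp("chr2", 13), genome))
    assert c.frame_status == "in_frame"
    assert c.natural_stop_idx == 24  # natural stop at codon 8
    assert c.premature_stop_pos == 4  # TAA right after the junction
    assert c.orf_protein == "MAAA"
    assert len(c.orf_protein) == c.premature_stop_pos


def orf_oracle(cdna, jo, phase3, natural_stop_idx, utr5_rule):
    """Independent codon-scan oracle for frame/premature-stop analysis."""
    stops = {"TAA", "TAG", "TGA"}
    in_frame = phase3 is not None and jo % 3 == phase3
    frame = ("in_frame" if in_frame
             else "out_of_frame_5UTR_rule" if utr5_rule else "out_of_frame")
    first = next((i for i in range(len(cdna) // 3)
                  if cdna[3 * i:3 * i + 3] in stops), None)
    natural = None
    if in_frame and natural_stop_idx is not None and natural_stop_idx % 3 == 0:
        natural = natural_stop_idx // 3
    premature = first if first is not None and (
        natural is None or first < natural) else None
    return frame, premature


@given(st.text(alphabet="ACGT", min_size=4, max_size=60), st.data())
@settings(max_examples=150, deadline=None)
def test_orf_matches_codon_scan_oracle(cdna, data):
    jo = data.draw(st.integers(1, len(cdna) - 1))
    phase3 = data.draw(st.sampled_from([None, 0, 1, 2]))
    natural = data.draw(st.one_of(st.none(), st.integers(0, len(cdna))))
    utr5 = data.draw(st.booleans())
    c = FusionConstruct("F", "T5", "T3", cdna, jo, utr5_rule=utr5,
                        phase3=phase3, natural_stop_idx=natural)
    out = orf_analysis(c)
    frame, premature = orf_oracle(cdna, jo, phase3, natural, utr5)
    assert out.frame_status == frame
    assert out.premature_stop_pos == premature
    # translation stops at the first stop codon (or runs to the end)
    stops = {"TAA", "TAG", "TGA"}
    first = next((i for i in range(len(cdna) // 3)
                  if cdna[3 * i:3 * i + 3] in stops), None)
    assert len(out.orf_protein) == (first if first is not None
                                    else len(cdna) // 3)


# --- microhomology ---------------------------------------------------------

def mh_oracle(seg5, ref3):
    k = 0
    for i in range(1, min(len(seg5), len(ref3)) + 1):
        if seg5[-i:] == ref3[-i:]:
            k = i
        else:
            break
    # exhaustive: largest k with suffix equality
    best = 0
    for i in range(min(len(seg5), len(ref3)), 0, -1):
        if seg5[-i:] == ref3[-i:]:
            best = i
            break
    return best


@given(st.text(alphabet="ACG", min_size=1, max_size=20),
       st.text(alphabet="ACG", min_size=0, max_size=20))
@settings(max_examples=200, deadline=None)
def test_microhomology_matches_exhaustive_oracle(seg5, ref3):
    c = FusionConstruct("F", "T5", "T3", seg5 + "T", len(seg5),
                        ref3_upstream=ref3)
    assert junction_microhomology(c) == mh_oracle(seg5, ref3)


def test_microhomology_known_case():
    # seg5 ends GCAGCT; ref3 upstream ends TTAGCT -> shared suffix AGCT
    c = FusionConstruct("F", "T5", "T3", "AAGCAGCT" + "X", 8,
                        ref3_upstream="TTAGCT")
    assert junction_microhomology(c) == 4
    c0 = FusionConstruct("F", "T5", "T3", "AAAA" + "X", 4, ref3_upstream="CCCC")
    assert junction_microhomology(c0) == 0


# --- selection and end-to-end ---------------------------------------------

def test_select_reference_transcript_prefers_cds_tier():
    t = select_reference_transcript(GENE5, bp("chr1", 18))
    assert t.transcript_id == "T5.1"
    with pytest.raises(Exception):
        select_reference_transcript(GENE5, bp("chr1", 500))


def test_design_construct_end_to_end():
    c = design_construct("FIVE::THREE", GENE5, GENE3, bp("chr1", 18),
                         bp("chr2", 13), GENOME)
    assert c.frame_status == "in_frame"
    assert c.orf_protein == "MAAAKEDD"
    assert c.microhomology_len == mh_oracle("ATGGCCGCAGCT", "CCCCCCCCCATG")


def test_design_construct_routes_utr5():
    c = design_construct("FIVE::THREE", GENE5, GENE3, bp("chr1", 3),
                         bp("chr2", 14), GENOME)
    assert c.utr5_rule
    assert c.frame_status == "out_of_frame_5UTR_rule"


def test_construct_junction_invariant():
    with pytest.raises(AssemblyError):
        FusionConstruct("F", "a", "b", "ACGT", 0)
    with pytest.raises(AssemblyError):
        FusionConstruct("F", "a", "b", "ACGT", 4)
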