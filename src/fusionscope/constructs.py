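"""Breakpoint-defined fusion construct design and ORF analysis.

A fusion cDNA joins the 5' partner's spliced sequence, from its CDS start
(ATG) through the last base at or before the 5' breakpoint, to the 3'
partner's spliced sequence from the first base at or after the 3' breakpoint
through its transcript end. Constructs therefore express breakpoint-defined
ORFs rather than full-length fusion transcripts. Reference transcripts are
chosen tier-first (MANE, longest coding, then all) preferring transcripts in
which the breakpoint lies in the CDS or within 200 bp of an exon boundary;
near-exon breakpoints are snapped to the nearest exon boundary of the
selected transcript before splicing.

When the 5' breakpoint lies in the 5' UTR, no translated 5' moiety would
remain under the default rule, so the construct instead carries the entire
5' gene CDS (stop codon excluded) fused to the 3' partner sequence
downstream of its breakpoint; the 5' moiety is then intact and in frame by
construction, and the frame status of such constructs is reported as
``out_of_frame_5UTR_rule`` whenever the 3' segment does not continue the
reading frame natively.

ORF analysis translates from the construct's first base in frame 0. The
junction is in frame when the first 3'-segment base occupies the same codon
phase in the construct as in the 3' gene's native CDS. The first stop codon
preceding the 3' gene's natural stop is a premature stop, and the reported
protein is the translation upstream of it, mimicking the likely translation
product. Junction microhomology is the maximal run of bases immediately 5'
of the junction present in both partners' reference sequences at their
breakpoints — bases that cannot be assigned to either gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from Bio.Seq import Seq

from .breakpoints import _classify_in_transcript
from .model import GeneModel, GenomicPosition, TierSelection, TranscriptModel, select_transcript_tiers
from .params import DEFAULT_PARAMS, Parameters


class SelectionError(ValueError):
    pass


class AssemblyError(ValueError):
    pass


FRAME_STATUSES = ("in_frame", "out_of_frame_5UTR_rule", "out_of_frame")


@dataclass
class FusionConstruct:
    fusion_name: str
    transcript5: str
    transcript3: str
    cdna: str
    junction_offset: int  # 0-based index of the first 3'-gene base
    frame_status: Optional[str] = None
    premature_stop_pos: Optional[int] = None  # 0-based codon index
    orf_protein: str = ""
    microhomology_len: int = 0
    utr5_rule: bool = False
    # native-frame context captured at assembly time
    phase3: Optional[int] = None  # codon phase of the first 3' base in its CDS
    natural_stop_idx: Optional[int] = None  # construct nt index of t3's stop codon
    ref3_upstream: str = ""  # t3 reference bases immediately 5' of its breakpoint

    def __post_init__(self) -> None:
        if not (0 < self.junction_offset < len(self.cdna)):
            raise AssemblyError(
                f"junction offset {self.junction_offset} outside cdna of "
                f"length {len(self.cdna)}"
            )


def spliced_sequence(t: TranscriptModel, genome: dict[str, str], chrom: str) -> str:
    """The transcript's spliced sequence, 5'->3' in transcription direction."""
    seq = genome[chrom]
    parts = [seq[e.start - 1:e.end] for e in t.exons]
    spliced = "".join(parts)
    if t.strand == "-":
        spliced = str(Seq(spliced).reverse_complement())
    return spliced


def genomic_to_spliced(t: TranscriptModel, pos: int) -> Optional[int]:
    """0-based spliced index of a genomic position; None when intronic."""
    offset = 0
    for e in t.exons:
        if e.contains(pos):
            fwd = offset + (pos - e.start)
            if t.strand == "-":
                return t.spliced_length - 1 - fwd
            return fwd
        offset += len(e)
    return None


def spliced_to_genomic(t: TranscriptModel, idx: int) -> int:
    """Genomic coordinate of a 0-based spliced index (inverse of genomic_to_spliced)."""
    if not 0 <= idx < t.spliced_length:
        raise IndexError(f"spliced index {idx} outside transcript {t.transcript_id}")
    fwd = idx if t.strand == "+" else t.spliced_length - 1 - idx
    offset = 0
    for e in t.exons:
        if fwd < offset + len(e):
            return e.start + (fwd - offset)
        offset += len(e)
    raise AssertionError("unreachable")


def snap_to_exon(t: TranscriptModel, pos: int, max_dist: int) -> Optional[int]:
    """Snap an intronic position to its nearest exon boundary within max_dist."""
    if t.exon_containing(pos) is not None:
        return pos
    best = None
    best_d = max_dist + 1
    for e in t.exons:
        for boundary in (e.start, e.end):
            d = abs(pos - boundary)
            if d < best_d or (d == best_d and (best is None or boundary < best)):
                best, best_d = boundary, d
    return best if best_d <= max_dist else None


def select_reference_transcript(
    gene: GeneModel,
    breakpoint: GenomicPosition,
    tiers: Optional[TierSelection] = None,
    params: Parameters = DEFAULT_PARAMS,
) -> TranscriptModel:
    """Tier-first transcript choice for construct assembly.

    Prefers the highest-tier transcript in which the breakpoint classifies
    as CDS or near-exon (intronic within 200 bp of an exon boundary); when
    none qualifies, falls back to the highest-tier transcript that contains
    the breakpoint at all (e.g. in a UTR).
    """
    if tiers is None:
        tiers = select_transcript_tiers(gene)
    ordered: list[TranscriptModel] = []
    for t in ([tiers.tier1] if tiers.tier1 else []) + \
             ([tiers.tier2] if tiers.tier2 else []) + \
             sorted(tiers.tier3, key=lambda t: (-t.spliced_length, t.transcript_id)):
        if all(t.transcript_id != o.transcript_id for o in ordered):
            ordered.append(t)
    fallback = None
    for t in ordered:
        res = _classify_in_transcript(breakpoint.pos, t)
        if res is None:
            continue
        region, dist = res
        if region == "CDS" or (region == "intronic" and dist <= params.near_exon_bp):
            return t
        if fallback is None:
            fallback = t
    if fallback is not None:
        return fallback
    raise SelectionError(
        f"no transcript of {gene.gene_name} contains breakpoint {breakpoint}"
    )


def _cds_spliced_bounds(t: TranscriptModel) -> tuple[int, int]:
    """(start, end) 0-based spliced indices of the translated region."""
    if not t.has_cds:
        raise AssemblyError(f"transcript {t.transcript_id} lacks a CDS")
    if t.strand == "+":
        s = genomic_to_spliced(t, t.cds_start)
        e = genomic_to_spliced(t, t.cds_end)
    else:
        s = genomic_to_spliced(t, t.cds_end)
        e = genomic_to_spliced(t, t.cds_start)
    assert s is not None and e is not None
    return s, e


def _spliced_index(t: TranscriptModel, pos: int, near_exon_bp: int, label: str) -> int:
    snapped = snap_to_exon(t, pos, near_exon_bp)
    if snapped is None:
        raise AssemblyError(
            f"{label} breakpoint at {pos} not representable on transcript "
            f"{t.transcript_id} (deep intronic beyond the near-exon margin)"
        )
    idx = genomic_to_spliced(t, snapped)
    assert idx is not None
    return idx


def _finalize_assembly(
    fusion_name: str,
    t5: TranscriptModel,
    t3: TranscriptModel,
    seg5: str,
    spliced3: str,
    idx3: int,
    utr5_rule: bool,
) -> FusionConstruct:
    seg3 = spliced3[idx3:]
    if not seg5 or not seg3:
        raise AssemblyError(f"{fusion_name}: empty fusion segment")
    phase3 = natural_stop_idx = None
    if t3.has_cds:
        cds3_start, cds3_end = _cds_spliced_bounds(t3)
        if idx3 >= cds3_start:
            phase3 = (idx3 - cds3_start) % 3
        # the stop codon occupies the 3 bases after the translated region
        stop_start = cds3_end + 1
        if idx3 <= stop_start and stop_start + 2 < len(spliced3):
            natural_stop_idx = len(seg5) + (stop_start - idx3)
    return FusionConstruct(
        fusion_name=fusion_name,
        transcript5=t5.transcript_id,
        transcript3=t3.transcript_id,
        cdna=seg5 + seg3,
        junction_offset=len(seg5),
        utr5_rule=utr5_rule,
        phase3=phase3,
        natural_stop_idx=natural_stop_idx,
        ref3_upstream=spliced3[:idx3],
    )


def assemble_fusion_cdna(
    fusion_name: str,
    t5: TranscriptModel,
    t3: TranscriptModel,
    bp5: GenomicPosition,
    bp3: GenomicPosition,
    genome: dict[str, str],
    chrom5: Optional[str] = None,
    chrom3: Optional[str] = None,
    params: Parameters = DEFAULT_PARAMS,
) -> FusionConstruct:
    """Join the 5' CDS-through-breakpoint segment to the 3' from-breakpoint tail."""
    chrom5 = chrom5 or bp5.chrom
    chrom3 = chrom3 or bp3.chrom
    spliced5 = spliced_sequence(t5, genome, chrom5)
    spliced3 = spliced_sequence(t3, genome, chrom3)
    cds5_start, _ = _cds_spliced_bounds(t5)
    idx5 = _spliced_index(t5, bp5.pos, params.near_exon_bp, "5'")
    if idx5 < cds5_start:
        raise AssemblyError(
            f"{fusion_name}: 5' breakpoint upstream of the CDS start "
            f"(apply the 5' UTR rule instead)"
        )
    idx3 = _spliced_index(t3, bp3.pos, params.near_exon_bp, "3'")
    seg5 = spliced5[cds5_start:idx5 + 1]
    return _finalize_assembly(fusion_name, t5, t3, seg5, spliced3, idx3, False)


def apply_5utr_rule(
    fusion_name: str,
    t5: TranscriptModel,
    t3: TranscriptModel,
    bp5: GenomicPosition,
    bp3: GenomicPosition,
    genome: dict[str, str],
    chrom5: Optional[str] = None,
    chrom3: Optional[str] = None,
    params: Parameters = DEFAULT_PARAMS,
) -> FusionConstruct:
    """5'-UTR breakpoint: carry the entire 5' CDS, then the 3' tail."""
    chrom5 = chrom5 or bp5.chrom
    chrom3 = chrom3 or bp3.chrom
    spliced5 = spliced_sequence(t5, genome, chrom5)
    spliced3 = spliced_sequence(t3, genome, chrom3)
    cds5_start, cds5_end = _cds_spliced_bounds(t5)
    idx5 = _spliced_index(t5, bp5.pos, params.near_exon_bp, "5'")
    if idx5 >= cds5_start:
        raise AssemblyError(
            f"{fusion_name}: 5' breakpoint is not in the 5' UTR; "
            f"use assemble_fusion_cdna"
        )
    idx3 = _spliced_index(t3, bp3.pos, params.near_exon_bp, "3'")
    seg5 = spliced5[cds5_start:cds5_end + 1]
    return _finalize_assembly(fusion_name, t5, t3, seg5, spliced3, idx3, True)


STOP_CODONS = {"TAA", "TAG", "TGA"}


def orf_analysis(construct: FusionConstruct) -> FusionConstruct:
    """Fill frame status, premature stop position, and the translated ORF."""
    cdna = construct.cdna
    if len(cdna) < 3:
        raise AssemblyError("cdna shorter than one codon")
    jo = construct.junction_offset
    in_frame = construct.phase3 is not None and jo % 3 == construct.phase3
    if in_frame:
        frame = "in_frame"
    elif construct.utr5_rule:
        frame = "out_of_frame_5UTR_rule"
    else:
        frame = "out_of_frame"

    n_codons = len(cdna) // 3
    first_stop: Optional[int] = None
    for i in range(n_codons):
        if cdna[3 * i:3 * i + 3] in STOP_CODONS:
            first_stop = i
            break
    natural_codon = None
    if in_frame and construct.natural_stop_idx is not None \
            and construct.natural_stop_idx % 3 == 0:
        natural_codon = construct.natural_stop_idx // 3

    premature: Optional[int] = None
    if first_stop is not None and (natural_codon is None or first_stop < natural_codon):
        premature = first_stop

    end = first_stop if first_stop is not None else n_codons
    protein = str(Seq(cdna[: 3 * end]).translate())
    return replace(
        construct,
        frame_status=frame,
        premature_stop_pos=premature,
        orf_protein=protein,
    )


def junction_microhomology(
    construct: FusionConstruct,
    ref5: Optional[str] = None,
    ref3_upstream: Optional[str] = None,
) -> int:
    """Maximal junction run assignable to either partner gene.

    The largest k such that the k bases immediately 5' of the junction equal
    both the last k bases of the 5' reference segment and the k reference
    bases of the 3' gene immediately preceding its breakpoint.
    """
    seg5 = construct.cdna[: construct.junction_offset]
    if ref5 is None:
        ref5 = seg5
    if ref3_upstream is None:
        ref3_upstream = construct.ref3_upstream
    kmax = min(len(seg5), len(ref5), len(ref3_upstream))
    for k in range(kmax, 0, -1):
        if seg5[-k:] == ref5[-k:] == ref3_upstream[-k:]:
            return k
    return 0


def design_construct(
    fusion_name: str,
    gene5: GeneModel,
    gene3: GeneModel,
    bp5: GenomicPosition,
    bp3: GenomicPosition,
    genome: dict[str, str],
    params: Parameters = DEFAULT_PARAMS,
) -> FusionConstruct:
    """End-to-end construct design for one fusion.

    Selects reference transcripts, routes 5'-UTR breakpoints through the
    UTR rule, then runs ORF and microhomology analysis.
    """
    t5 = select_reference_transcript(gene5, bp5, params=params)
    t3 = select_reference_transcript(gene3, bp3, params=params)
    res5 = _classify_in_transcript(bp5.pos, t5)
    region5 = res5[0] if res5 else None
    builder = apply_5utr_rule if region5 == "UTR5" else assemble_fusion_cdna
    construct = builder(
        fusion_name, t5, t3, bp5, bp3, genome,
        chrom5=gene5.chrom, chrom3=gene3.chrom, params=params,
    )
    construct = orf_analysis(construct)
    return replace(construct, microhomology_len=junction_microhomology(construct))
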