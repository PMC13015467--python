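"""Genomic data model: genes, transcripts, exons, and tiered transcript selection.

Coordinates are 1-based and fully closed throughout (GTF convention); any
half-open arithmetic is internal to individual functions. The coding span of
a transcript (``cds_start``/``cds_end``) covers the translated region only,
excluding the stop codon, matching GENCODE CDS semantics.

Transcript selection for breakpoint annotation and construct design is
tiered: the MANE Select transcript first, then the longest protein-coding
transcript (maximal summed exon length, ties broken by smallest
transcript_id), and finally all annotated transcripts.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import gffutils
from Bio import SeqIO

from .params import DEFAULT_PARAMS

STRANDS = ("+", "-", "unknown")


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass(frozen=True, order=True)
class GenomicPosition:
    chrom: str
    pos: int
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}")

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}"


@dataclass(frozen=True, order=True)
class ExonInterval:
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"exon start {self.start} > end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    strand: str
    exons: list[ExonInterval]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None
    is_mane: bool = False
    is_protein_coding: bool = False

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: overlapping exons {a} and {b}"
                )
        if (self.cds_start is None) != (self.cds_end is None):
            raise AnnotationError(
                f"transcript {self.transcript_id}: partial CDS coordinates"
            )
        if self.cds_start is not None:
            if not any(e.contains(self.cds_start) for e in self.exons) or not any(
                e.contains(self.cds_end) for e in self.exons
            ):
                raise AnnotationError(
                    f"transcript {self.transcript_id}: CDS outside exon union"
                )

    @property
    def span(self) -> ExonInterval:
        return ExonInterval(self.exons[0].start, self.exons[-1].end)

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def has_cds(self) -> bool:
        return self.cds_start is not None

    def exon_containing(self, pos: int) -> Optional[ExonInterval]:
        for e in self.exons:
            if e.contains(pos):
                return e
        return None

    def distance_to_exon_boundary(self, pos: int) -> int:
        """Minimum distance from pos to any exon start or end."""
        return min(min(abs(pos - e.start), abs(pos - e.end)) for e in self.exons)

    def tx_start(self) -> int:
        """Transcript start in transcription direction (5' end)."""
        return self.span.start if self.strand == "+" else self.span.end

    def tx_end(self) -> int:
        """Transcript end in transcription direction (3' end)."""
        return self.span.end if self.strand == "+" else self.span.start


@dataclass
class GeneModel:
    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    biotype: str
    transcripts: list[TranscriptModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise AnnotationError(f"gene {self.gene_id} has no transcripts")

    @property
    def span(self) -> ExonInterval:
        return ExonInterval(
            min(t.span.start for t in self.transcripts),
            max(t.span.end for t in self.transcripts),
        )


@dataclass
class TierSelection:
    tier1: Optional[TranscriptModel]
    tier2: Optional[TranscriptModel]
    tier3: list[TranscriptModel]


class GenomeAnnotation:
    """Gene-indexed annotation with lookup by gene name or gene id."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: dict[str, GeneModel] = {}
        self.by_name: dict[str, GeneModel] = {}
        for g in genes:
            self.genes[g.gene_id] = g
            self.by_name[g.gene_name] = g

    def __len__(self) -> int:
        return len(self.genes)

    def get(self, name_or_id: str) -> Optional[GeneModel]:
        return self.by_name.get(name_or_id) or self.genes.get(name_or_id)

    def __iter__(self):
        return iter(self.genes.values())


def select_transcript_tiers(gene: GeneModel, mane_tag: str = "MANE_Select") -> TierSelection:
    """Tiered transcript choice: MANE, then longest coding, then all.

    Tier 2 is the protein-coding transcript of maximal spliced (summed exon)
    length; ties break to the lexicographically smallest transcript_id so the
    selection is deterministic.
    """
    tier3 = sorted(gene.transcripts, key=lambda t: t.transcript_id)
    mane = [t for t in tier3 if t.is_mane]
    tier1 = mane[0] if mane else None
    coding = [t for t in tier3 if t.is_protein_coding]
    tier2 = None
    if coding:
        tier2 = sorted(coding, key=lambda t: (-t.spliced_length, t.transcript_id))[0]
    return TierSelection(tier1=tier1, tier2=tier2, tier3=tier3)


def gene_length(gene: GeneModel) -> int:
    """Genomic gene length: span end - span start + 1 over all transcripts."""
    span = gene.span
    return span.end - span.start + 1


def _validate_gtf_lines(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise AnnotationError(
                f"GTF parse error at line {lineno}: expected 9 columns, got {len(cols)}"
            )
        try:
            start, end = int(cols[3]), int(cols[4])
        except ValueError:
            raise AnnotationError(
                f"GTF parse error at line {lineno}: non-integer coordinates"
            ) from None
        if end < start:
            raise AnnotationError(
                f"GTF parse error at line {lineno}: end {end} < start {start}"
            )


def read_annotation(gtf: str | Path, mane_tag: str | None = None) -> GenomeAnnotation:
    """Read a GENCODE-style GTF (path or literal text) into a GenomeAnnotation.

    MANE status is read from the configurable ``tag`` attribute value
    (default ``MANE_Select``); biotype from ``gene_type``/``transcript_type``
    (``gene_biotype``/``transcript_biotype`` accepted as dialect fallbacks).
    """
    mane_tag = mane_tag or DEFAULT_PARAMS.mane_tag
    if isinstance(gtf, Path) or (isinstance(gtf, str) and "\t" not in gtf and Path(gtf).exists()):
        text = Path(gtf).read_text()
    else:
        text = str(gtf)
    _validate_gtf_lines(text)
    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    def attr(feature, *names, default=""):
        for n in names:
            if n in feature.attributes:
                return feature.attributes[n][0]
        return default

    genes: list[GeneModel] = []
    for gf in db.features_of_type("gene"):
        gene_id = attr(gf, "gene_id")
        transcripts = []
        for tf in db.children(gf, featuretype="transcript", order_by="start"):
            exons = [
                ExonInterval(e.start, e.end)
                for e in db.children(tf, featuretype="exon", order_by="start")
            ]
            if not exons:
                raise AnnotationError(
                    f"transcript {attr(tf, 'transcript_id')} has no exons"
                )
            cds = [c for c in db.children(tf, featuretype="CDS", order_by="start")]
            cds_start = min(c.start for c in cds) if cds else None
            cds_end = max(c.end for c in cds) if cds else None
            tags = tf.attributes.get("tag", [])
            biotype = attr(tf, "transcript_type", "transcript_biotype")
            t = TranscriptModel(
                transcript_id=attr(tf, "transcript_id"),
                gene_id=gene_id,
                strand=tf.strand if tf.strand in ("+", "-") else "unknown",
                exons=exons,
                cds_start=cds_start,
                cds_end=cds_end,
                is_mane=mane_tag in tags,
                is_protein_coding=(biotype == "protein_coding") or bool(cds),
            )
            if t.span.start < gf.start or t.span.end > gf.end:
                raise AnnotationError(
                    f"transcript {t.transcript_id} exons outside gene span of {gene_id}"
                )
            transcripts.append(t)
        if not transcripts:
            continue
        genes.append(
            GeneModel(
                gene_id=gene_id,
                gene_name=attr(gf, "gene_name", default=gene_id),
                chrom=gf.seqid,
                strand=gf.strand if gf.strand in ("+", "-") else "unknown",
                biotype=attr(gf, "gene_type", "gene_biotype"),
                transcripts=transcripts,
            )
        )
    return GenomeAnnotation(genes)


def write_annotation(annotation: GenomeAnnotation, mane_tag: str | None = None) -> str:
    """Serialize a GenomeAnnotation back to GTF text.

    Feature coordinates round-trip exactly through read_annotation.
    """
    mane_tag = mane_tag or DEFAULT_PARAMS.mane_tag
    out = io.StringIO()

    def row(chrom, feat, start, end, strand, attrs):
        attr_str = " ".join(f'{k} "{v}";' for k, v in attrs)
        out.write(
            f"{chrom}\tfusionscope\t{feat}\t{start}\t{end}\t.\t{strand}\t.\t{attr_str}\n"
        )

    for gene in annotation:
        span = gene.span
        row(gene.chrom, "gene", span.start, span.end, gene.strand,
            [("gene_id", gene.gene_id), ("gene_name", gene.gene_name),
             ("gene_type", gene.biotype)])
        for t in gene.transcripts:
            attrs = [("gene_id", gene.gene_id), ("transcript_id", t.transcript_id),
                     ("gene_name", gene.gene_name),
                     ("transcript_type",
                      "protein_coding" if t.is_protein_coding else gene.biotype or "lncRNA")]
            if t.is_mane:
                attrs.append(("tag", mane_tag))
            row(gene.chrom, "transcript", t.span.start, t.span.end, t.strand, attrs)
            for e in t.exons:
                row(gene.chrom, "exon", e.start, e.end, t.strand, attrs)
            if t.has_cds:
                for e in t.exons:
                    s = max(e.start, t.cds_start)
                    en = min(e.end, t.cds_end)
                    if s <= en:
                        row(gene.chrom, "CDS", s, en, t.strand, attrs)
    return out.getvalue()


def read_fasta(fasta: str | Path) -> dict[str, str]:
    """Read a FASTA (path or literal text) into a chrom -> sequence dict."""
    if isinstance(fasta, Path) or (
        isinstance(fasta, str) and not fasta.startswith(">") and Path(fasta).exists()
    ):
        handle: io.TextIOBase | str = str(fasta)
        records = SeqIO.parse(handle, "fasta")
    else:
        records = SeqIO.parse(io.StringIO(str(fasta)), "fasta")
    return {rec.id: str(rec.seq).upper() for rec in records}
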