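"""Seeded synthetic-data generators with known ground truth.

The generators stand in for a long-read glioma cohort so that every pipeline
stage is testable without downloads: a GENCODE-style annotation with MANE
tags and CDS/UTR structure on two synthetic chromosomes plus a mitochondrial
contig; multi-caller fusion call tables with breakpoint jitter (default
20 bp, under half the 50 bp merge window so true multi-caller emissions
always merge), reciprocal echoes, and planted artifact classes each removed
by exactly one pipeline stage; and isoform/expression fixtures with planted
structural clusters (separated by more than twice the 100 bp tolerance so
cluster recovery is exact), fusion-like truncations at planted breakpoints,
and differential-expression tables with controlled between-method agreement.

All randomness flows from a single integer seed through numpy's Generator;
coordinates are integer arithmetic, so a fixed seed reproduces outputs
byte-identically.

What the generator does not emulate: read-level error profiles, alignment
artifacts, transcript-level count overdispersion structure of real tissue,
and the correlated caller errors of real ensembles. Results on synthetic
data demonstrate correctness of the bookkeeping and rules, not detection
performance on real cohorts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .constructs import genomic_to_spliced, spliced_to_genomic
from .filtering import GeneClassSets
from .harmonize import CALLER_SCHEMAS
from .model import (
    ExonInterval,
    GeneModel,
    GenomeAnnotation,
    GenomicPosition,
    TranscriptModel,
    write_annotation,
)
from .novel import IsoformRecord, exons_to_chain
from .params import DEFAULT_PARAMS, Parameters

CALLERS = ("longgf", "jaffal", "fusionseeker")
ARTIFACT_CLASSES = (
    "true", "low_support", "blacklisted", "control_shared",
    "unannotatable", "reciprocal_echo",
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class PlantedFusion:
    sample_id: str
    gene5: str
    gene3: str
    chrom5: str
    pos5: int
    chrom3: str
    pos3: int
    support: int
    artifact_class: str


@dataclass
class PlantedDEIsoform:
    isoform_id: str
    log2_fc: float
    stratum: str  # consensus | a_only | b_only | discordant


@dataclass
class PlantedTruncation:
    fusion_name: str
    sample_id: str
    gene: str
    role: str  # 5prime | 3prime
    isoform_id: str
    boundary_pos: int
    distance_bp: int


@dataclass
class TruthSet:
    seed: int
    fusions: list[PlantedFusion] = field(default_factory=list)
    de_isoforms: list[PlantedDEIsoform] = field(default_factory=list)
    truncations: list[PlantedTruncation] = field(default_factory=list)
    control_pairs: list[list[str]] = field(default_factory=list)

    def true_pairs(self) -> set[tuple[str, tuple[str, str]]]:
        return {
            (f.sample_id, tuple(sorted((f.gene5, f.gene3))))
            for f in self.fusions
            if f.artifact_class == "true"
        }

    def artifact_pairs(self) -> set[tuple[str, tuple[str, str]]]:
        true = self.true_pairs()
        return {
            (f.sample_id, tuple(sorted((f.gene5, f.gene3))))
            for f in self.fusions
            if f.artifact_class not in ("true", "reciprocal_echo")
        } - true

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "fusions": [asdict(f) for f in self.fusions],
                "de_isoforms": [asdict(d) for d in self.de_isoforms],
                "truncations": [asdict(t) for t in self.truncations],
                "control_pairs": self.control_pairs,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthSet":
        raw = json.loads(text)
        return cls(
            seed=raw["seed"],
            fusions=[PlantedFusion(**f) for f in raw["fusions"]],
            de_isoforms=[PlantedDEIsoform(**d) for d in raw["de_isoforms"]],
            truncations=[PlantedTruncation(**t) for t in raw["truncations"]],
            control_pairs=[list(p) for p in raw["control_pairs"]],
        )


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> list[str]:
    return list(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _set_spliced_base(genome: dict[str, list[str]], chrom: str,
                      t: TranscriptModel, idx: int, base: str) -> None:
    g = spliced_to_genomic(t, idx)
    if t.strand == "-":
        base = base.translate(_COMPLEMENT)
    genome[chrom][g - 1] = base


def _get_spliced_base(genome: dict[str, list[str]], chrom: str,
                      t: TranscriptModel, idx: int) -> str:
    g = spliced_to_genomic(t, idx)
    base = genome[chrom][g - 1]
    if t.strand == "-":
        base = base.translate(_COMPLEMENT)
    return base


def _write_clean_cds(genome: dict[str, list[str]], chrom: str,
                     t: TranscriptModel, cds_s_idx: int, cds_e_idx: int,
                     rng: np.random.Generator) -> None:
    """Force ATG...no-internal-stops...<stop> on the spliced CDS."""
    for i, b in enumerate("ATG"):
        _set_spliced_base(genome, chrom, t, cds_s_idx + i, b)
    n_codons = (cds_e_idx - cds_s_idx + 1) // 3
    for c in range(1, n_codons):
        start = cds_s_idx + 3 * c
        codon = "".join(
            _get_spliced_base(genome, chrom, t, start + k) for k in range(3)
        )
        if codon in _STOPS:
            for k, b in enumerate("GCA"):
                _set_spliced_base(genome, chrom, t, start + k, b)
    for k, b in enumerate("TAA"):
        _set_spliced_base(genome, chrom, t, cds_e_idx + 1 + k, b)


def simulate_annotation(
    n_genes: int,
    seed: int,
    pseudo_frac: float = 0.06,
    ribo_frac: float = 0.06,
    hla_frac: float = 0.04,
    n_mito_genes: Optional[int] = None,
) -> tuple[str, str, GenomeAnnotation]:
    """Generate (GTF text, FASTA text, GenomeAnnotation) for n_genes genes.

    Genes are laid out without overlap on two synthetic chromosomes plus a
    mitochondrial contig; each gene carries 1-4 transcripts (the primary one
    optionally MANE-tagged) with 1-8 exons, and coding genes get a CDS whose
    spliced sequence starts with ATG, contains no internal stop codon, and
    is followed by a TAA stop, so ORF analysis behaves as on real
    transcripts. A configurable fraction of genes carry pseudogene /
    ribosomal / HLA-style names and biotypes.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    if n_mito_genes is None:
        n_mito_genes = 2 if n_genes >= 20 else 0
    n_pseudo = int(round(pseudo_frac * n_genes))
    n_ribo = int(round(ribo_frac * n_genes))
    n_hla = int(round(hla_frac * n_genes))
    n_normal = n_genes - n_pseudo - n_ribo - n_hla - n_mito_genes
    if n_normal < 1:
        raise ValueError("class fractions leave no ordinary genes")

    specs: list[tuple[str, str, str]] = []  # (name, biotype, chrom_class)
    for i in range(n_normal):
        specs.append((f"GENE{i + 1:03d}", "protein_coding", "nuclear"))
    for i in range(n_pseudo):
        specs.append((f"PSG{i + 1}P", "processed_pseudogene", "nuclear"))
    for i in range(n_ribo):
        specs.append((f"RPL{i + 1}S", "protein_coding", "nuclear"))
    for i in range(n_hla):
        specs.append((f"HLA-S{i + 1}", "protein_coding", "nuclear"))
    for i in range(n_mito_genes):
        specs.append((f"MT-S{i + 1}", "protein_coding", "chrM"))

    cursors = {"chrS1": 10_000, "chrS2": 10_000, "chrM": 500}
    genes: list[GeneModel] = []
    cds_jobs: list[tuple[str, TranscriptModel, int, int]] = []
    nuclear_toggle = 0
    for gi, (name, biotype, chrom_class) in enumerate(specs):
        if chrom_class == "chrM":
            chrom = "chrM"
        else:
            chrom = "chrS1" if nuclear_toggle % 2 == 0 else "chrS2"
            nuclear_toggle += 1
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 9))
        start = cursors[chrom]
        exons = []
        pos = start
        for _ in range(n_exons):
            elen = int(rng.integers(150, 401))
            exons.append(ExonInterval(pos, pos + elen - 1))
            pos += elen + int(rng.integers(400, 1501))
        cursors[chrom] = exons[-1].end + int(rng.integers(5_000, 15_001))

        coding = biotype == "protein_coding" and rng.random() < 0.9
        primary = TranscriptModel(
            transcript_id=f"T{gi + 1:03d}.1", gene_id=f"G{gi + 1:03d}",
            strand=strand, exons=list(exons),
        )
        cds_s_idx = cds_e_idx = None
        if coding:
            total = primary.spliced_length
            u5 = int(rng.integers(30, min(150, max(31, total // 5))))
            # leave >= 9 bp 3' UTR after the stop codon
            max_cds = total - u5 - 12
            if max_cds >= 30:
                cds_len = (int(rng.integers(30, max_cds + 1)) // 3) * 3
                cds_s_idx, cds_e_idx = u5, u5 + cds_len - 1
                g_a = spliced_to_genomic(primary, cds_s_idx)
                g_b = spliced_to_genomic(primary, cds_e_idx)
                primary.cds_start, primary.cds_end = min(g_a, g_b), max(g_a, g_b)
                primary.is_protein_coding = True
        primary.is_mane = coding and rng.random() < 0.85
        transcripts = [primary]

        n_alt = int(rng.integers(0, 4))
        for ai in range(n_alt):
            if len(exons) < 2:
                break
            if rng.random() < 0.5:
                alt_exons = exons[:-1]
            else:
                alt_exons = exons[1:]
            alt = TranscriptModel(
                transcript_id=f"T{gi + 1:03d}.{ai + 2}", gene_id=f"G{gi + 1:03d}",
                strand=strand, exons=list(alt_exons),
            )
            if primary.has_cds:
                lo, hi = alt.span.start, alt.span.end
                if lo <= primary.cds_start and primary.cds_end <= hi:
                    alt.cds_start, alt.cds_end = primary.cds_start, primary.cds_end
                    alt.is_protein_coding = True
            transcripts.append(alt)

        genes.append(
            GeneModel(
                gene_id=f"G{gi + 1:03d}", gene_name=name, chrom=chrom,
                strand=strand, biotype=biotype, transcripts=transcripts,
            )
        )
        if cds_s_idx is not None:
            cds_jobs.append((chrom, primary, cds_s_idx, cds_e_idx))

    lengths = {c: cursors[c] + 10_000 for c in cursors}
    genome = {c: _random_seq(rng, n) for c, n in lengths.items()}
    for chrom, t, s_idx, e_idx in cds_jobs:
        _write_clean_cds(genome, chrom, t, s_idx, e_idx, rng)

    annotation = GenomeAnnotation(genes)
    gtf_text = write_annotation(annotation)
    fasta_parts = []
    for chrom in sorted(genome):
        seq = "".join(genome[chrom])
        wrapped = "\n".join(seq[i:i + 80] for i in range(0, len(seq), 80))
        fasta_parts.append(f">{chrom}\n{wrapped}\n")
    return gtf_text, "".join(fasta_parts), annotation


def derive_gene_classes(annotation: GenomeAnnotation) -> GeneClassSets:
    """Deterministic gene class assignment from the synthetic naming scheme.

    Pseudogene / ribosomal / HLA / mitochondrial membership follows the name
    prefix and contig; the fusion panel is the first tenth of ordinary
    coding genes (sorted by name) and the census the first six tenths, so a
    clear majority of ordinary genes are cancer-listed and a reserve of
    unlisted genes remains for gate testing.
    """
    sets = GeneClassSets()
    ordinary = []
    for g in annotation:
        name = g.gene_name
        if name.startswith("PSG"):
            sets.pseudogenes.add(name)
        elif name.startswith("RPL"):
            sets.ribosomal_genes.add(name)
        elif name.startswith("HLA-"):
            sets.hla_genes.add(name)
        elif g.chrom == "chrM":
            sets.mito_genes.add(name)
        elif any(t.has_cds for t in g.transcripts):
            ordinary.append(name)
    ordinary.sort()
    n = len(ordinary)
    sets.panel_genes = set(ordinary[: max(1, n // 10)])
    sets.census_genes = set(ordinary[: max(1, (6 * n) // 10)])
    return sets


# ---------------------------------------------------------------------------
# fusion calls
# ---------------------------------------------------------------------------

def _cds_breakpoint(gene: GeneModel, rng: np.random.Generator,
                    margin: int = 25) -> Optional[int]:
    """A position deep inside a CDS exon (>= margin from exon/CDS edges)."""
    t = gene.transcripts[0]
    if not t.has_cds:
        return None
    windows = []
    for e in t.exons:
        lo = max(e.start, t.cds_start) + margin
        hi = min(e.end, t.cds_end) - margin
        if hi - lo >= 10:
            windows.append((lo, hi))
    if not windows:
        return None
    lo, hi = windows[int(rng.integers(0, len(windows)))]
    return int(rng.integers(lo, hi + 1))


def _deep_intronic_breakpoint(gene: GeneModel, near_exon_bp: int = 200) -> Optional[int]:
    """A position > near_exon_bp from every exon boundary of every transcript."""
    t = gene.transcripts[0]
    for a, b in zip(t.exons, t.exons[1:]):
        mid = (a.end + b.start) // 2
        if all(
            tr.distance_to_exon_boundary(mid) > near_exon_bp
            for tr in gene.transcripts
        ):
            return mid
    return None


def _support(rng: np.random.Generator) -> int:
    return 3 + int(rng.poisson(1.8))


def simulate_fusion_calls(
    annotation: GenomeAnnotation,
    n_true: int,
    n_artifacts: int,
    jitter_bp: int = 20,
    seed: int = 0,
    n_samples: int = 8,
    sets: Optional[GeneClassSets] = None,
) -> tuple[dict[str, pd.DataFrame], TruthSet]:
    """Emit per-caller fusion call tables with a matching TruthSet.

    True fusions join two census-listed coding genes at mid-CDS breakpoints
    and are emitted by 1-3 callers with uniform breakpoint jitter of at most
    ``jitter_bp`` per partner, occasional within-caller exact duplicates, and
    occasional lower-support reciprocal echoes. Artifact classes cycle
    through low_support, blacklisted, control_shared, unannotatable and
    reciprocal_echo, each constructed so exactly one pipeline stage removes
    it.
    """
    if jitter_bp > 25:
        raise ValueError("jitter_bp must be <= 25 so true emissions merge")
    rng = np.random.default_rng(seed)
    if sets is None:
        sets = derive_gene_classes(annotation)
    samples = [f"S{i + 1:02d}" for i in range(n_samples)]

    census_genes = [
        annotation.get(name) for name in sorted(sets.census_genes)
    ]
    usable = [
        g for g in census_genes
        if g is not None and _cds_breakpoint(g, np.random.default_rng(0)) is not None
    ]
    if len(usable) < 4:
        raise ValueError("annotation too small to plant fusions")
    blacklisted_pool = sorted(sets.pseudogenes | sets.ribosomal_genes | sets.hla_genes)
    unlisted = [
        g.gene_name for g in annotation
        if g.gene_name not in sets.census_genes
        and not g.gene_name.startswith(("PSG", "RPL", "HLA-", "MT-"))
    ]

    truth = TruthSet(seed=seed)
    rows: dict[str, list[dict]] = {c: [] for c in CALLERS}
    used_pairs: set[tuple[str, str]] = set()

    def pick_pair(pool: list[GeneModel]) -> tuple[GeneModel, GeneModel]:
        for _ in range(200):
            i, j = rng.choice(len(pool), size=2, replace=False)
            a, b = pool[int(i)], pool[int(j)]
            key = tuple(sorted((a.gene_name, b.gene_name)))
            if key not in used_pairs:
                used_pairs.add(key)
                return a, b
        raise RuntimeError("could not find an unused gene pair")

    def emit(caller: str, sample: str, g5: str, c5: str, p5: int, s5: str,
             g3: str, c3: str, p3: int, s3: str, support: int) -> None:
        m = CALLER_SCHEMAS[caller]
        rows[caller].append({
            m["sample_id"]: sample, m["gene5"]: g5, m["chrom5"]: c5,
            m["pos5"]: p5, m["strand5"]: s5, m["gene3"]: g3, m["chrom3"]: c3,
            m["pos3"]: p3, m["strand3"]: s3, m["support"]: support,
        })

    def emit_event(sample: str, g5: GeneModel, p5: int, g3: GeneModel, p3: int,
                   support: int, n_callers: int, jitter: int,
                   duplicate: bool = False) -> None:
        caller_idx = rng.choice(len(CALLERS), size=n_callers, replace=False)
        for k, ci in enumerate(sorted(int(c) for c in caller_idx)):
            caller = CALLERS[ci]
            j5 = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
            j3 = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
            sup = support if k == 0 else max(1, support - int(rng.integers(0, 2)))
            emit(caller, sample, g5.gene_name, g5.chrom, p5 + j5, g5.strand,
                 g3.gene_name, g3.chrom, p3 + j3, g3.strand, sup)
            if duplicate and k == 0:
                emit(caller, sample, g5.gene_name, g5.chrom, p5 + j5, g5.strand,
                     g3.gene_name, g3.chrom, p3 + j3, g3.strand, sup)

    # --- true fusions -----------------------------------------------------
    for ti in range(n_true):
        g5, g3 = pick_pair(usable)
        p5 = _cds_breakpoint(g5, rng)
        p3 = _cds_breakpoint(g3, rng)
        sample = samples[int(rng.integers(0, len(samples)))]
        support = _support(rng)
        n_callers = int(rng.integers(1, 4))
        emit_event(sample, g5, p5, g3, p3, support, n_callers, jitter_bp,
                   duplicate=rng.random() < 0.25)
        truth.fusions.append(PlantedFusion(
            sample, g5.gene_name, g3.gene_name, g5.chrom, p5, g3.chrom, p3,
            support, "true",
        ))
        if rng.random() < 0.3 and support > 1:
            echo_sup = int(rng.integers(1, support))
            emit_event(sample, g3, p3, g5, p5, echo_sup, 1, jitter_bp)
            truth.fusions.append(PlantedFusion(
                sample, g3.gene_name, g5.gene_name, g3.chrom, p3, g5.chrom, p5,
                echo_sup, "reciprocal_echo",
            ))

    # --- artifacts --------------------------------------------------------
    cycle = ["low_support", "blacklisted", "control_shared", "unannotatable",
             "reciprocal_echo"]
    for ai in range(n_artifacts):
        cls = cycle[ai % len(cycle)]
        sample = samples[int(rng.integers(0, len(samples)))]
        if cls == "low_support":
            g5, g3 = pick_pair(usable)
            p5, p3 = _cds_breakpoint(g5, rng), _cds_breakpoint(g3, rng)
            sup = int(rng.integers(1, 3))
            emit_event(sample, g5, p5, g3, p3, sup, 1, jitter_bp)
            truth.fusions.append(PlantedFusion(
                sample, g5.gene_name, g3.gene_name, g5.chrom, p5, g3.chrom, p3,
                sup, cls))
        elif cls == "blacklisted" and blacklisted_pool:
            g5, _ = pick_pair(usable)
            bad_name = blacklisted_pool[ai % len(blacklisted_pool)]
            bad = annotation.get(bad_name)
            p5 = _cds_breakpoint(g5, rng)
            e = bad.transcripts[0].exons[0]
            p3 = (e.start + e.end) // 2
            used_pairs.add(tuple(sorted((g5.gene_name, bad_name))))
            emit_event(sample, g5, p5, bad, p3, _support(rng), 1, jitter_bp)
            truth.fusions.append(PlantedFusion(
                sample, g5.gene_name, bad_name, g5.chrom, p5, bad.chrom, p3,
                3, cls))
        elif cls == "control_shared":
            g5, g3 = pick_pair(usable)
            p5, p3 = _cds_breakpoint(g5, rng), _cds_breakpoint(g3, rng)
            emit_event(sample, g5, p5, g3, p3, _support(rng), 1, jitter_bp)
            truth.fusions.append(PlantedFusion(
                sample, g5.gene_name, g3.gene_name, g5.chrom, p5, g3.chrom, p3,
                3, cls))
            truth.control_pairs.append(
                sorted([g5.gene_name, g3.gene_name])
            )
        elif cls == "unannotatable":
            planted = False
            for _ in range(50):
                g5, g3 = pick_pair(usable)
                p5 = _deep_intronic_breakpoint(g5)
                p3 = _deep_intronic_breakpoint(g3)
                if p3 is None:
                    p3 = g3.span.end + 5000  # intergenic fallback
                if p5 is None:
                    p5 = g5.span.end + 5000
                emit_event(sample, g5, p5, g3, p3, _support(rng), 1, 0)
                truth.fusions.append(PlantedFusion(
                    sample, g5.gene_name, g3.gene_name, g5.chrom, p5,
                    g3.chrom, p3, 3, cls))
                planted = True
                break
            if not planted:
                continue
        else:  # reciprocal_echo artifact: echo of a fresh true-style event
            g5, g3 = pick_pair(usable)
            p5, p3 = _cds_breakpoint(g5, rng), _cds_breakpoint(g3, rng)
            support = max(4, _support(rng))
            emit_event(sample, g5, p5, g3, p3, support, 2, jitter_bp)
            truth.fusions.append(PlantedFusion(
                sample, g5.gene_name, g3.gene_name, g5.chrom, p5, g3.chrom, p3,
                support, "true"))
            echo_sup = int(rng.integers(1, support))
            emit_event(sample, g3, p3, g5, p5, echo_sup, 1, jitter_bp)
            truth.fusions.append(PlantedFusion(
                sample, g3.gene_name, g5.gene_name, g3.chrom, p3, g5.chrom, p5,
                echo_sup, cls))

    tables = {}
    for caller in CALLERS:
        m = CALLER_SCHEMAS[caller]
        cols = [m[k] for k in ("sample_id", "gene5", "chrom5", "pos5", "strand5",
                               "gene3", "chrom3", "pos3", "strand3", "support")]
        tables[caller] = pd.DataFrame(rows[caller], columns=cols)
    return tables, truth


# ---------------------------------------------------------------------------
# isoform / expression fixtures
# ---------------------------------------------------------------------------

def _truncate_chain_end(t: TranscriptModel, boundary: int) -> Optional[list[ExonInterval]]:
    """Chain ending (in transcription direction) at the genomic boundary."""
    if t.strand == "+":
        out = [e for e in t.exons if e.end < boundary]
        hit = t.exon_containing(boundary)
        if hit is not None and hit.start <= boundary:
            out.append(ExonInterval(hit.start, boundary))
    else:
        out = []
        hit = t.exon_containing(boundary)
        if hit is not None:
            out.append(ExonInterval(boundary, hit.end))
        out.extend(e for e in t.exons if e.start > boundary)
    return out or None


def _truncate_chain_start(t: TranscriptModel, boundary: int) -> Optional[list[ExonInterval]]:
    """Chain starting (in transcription direction) at the genomic boundary."""
    if t.strand == "+":
        out = []
        hit = t.exon_containing(boundary)
        if hit is not None:
            out.append(ExonInterval(boundary, hit.end))
        out.extend(e for e in t.exons if e.start > boundary)
    else:
        out = [e for e in t.exons if e.end < boundary]
        hit = t.exon_containing(boundary)
        if hit is not None:
            out.append(ExonInterval(hit.start, boundary))
    return out or None


def simulate_isoform_fixtures(
    annotation: GenomeAnnotation,
    truth: TruthSet,
    n_samples_per_group: int = 5,
    seed: int = 0,
    tol: int = 100,
    n_cluster_genes: int = 6,
    n_de: int = 8,
    params: Parameters = DEFAULT_PARAMS,
) -> dict:
    """Isoform structures, counts, and DE tables with planted ground truth.

    Returns a dict with keys ``structures`` (isoform structure table),
    ``counts`` (isoform x sample counts), ``lengths``, ``labels`` (sample ->
    group), ``de_a``/``de_b`` (two method result tables), and the truth set
    updated in place with DE and truncation plants.

    Novel structural clusters per gene are separated by 3*tol so recovery is
    exact; within-cluster jitter is at most 30 bp. For half of the planted
    true fusions, the 5' gene gets a novel isoform terminating at (or within
    a short offset of) the 5' breakpoint and the 3' gene a novel isoform
    initiating near the 3' breakpoint, in the fusion-bearing sample.
    """
    rng = np.random.default_rng(seed)
    glioma_samples = sorted({f.sample_id for f in truth.fusions}) or [
        f"S{i + 1:02d}" for i in range(n_samples_per_group)
    ]
    pad = 1
    while len(glioma_samples) < n_samples_per_group:
        candidate = f"S{pad:02d}"
        pad += 1
        if candidate not in glioma_samples:
            glioma_samples.append(candidate)
    glioma_samples.sort()
    glioma_samples = glioma_samples[:max(n_samples_per_group, len(glioma_samples))]
    control_samples = [f"C{i + 1:02d}" for i in range(n_samples_per_group)]
    all_samples = glioma_samples + control_samples
    labels = pd.Series(
        ["glioma"] * len(glioma_samples) + ["control"] * len(control_samples),
        index=all_samples, name="group",
    )

    fusion_genes = {f.gene5 for f in truth.fusions} | {f.gene3 for f in truth.fusions}
    coding = [
        g for g in annotation
        if g.chrom != "chrM" and any(t.has_cds for t in g.transcripts)
        and not g.gene_name.startswith(("PSG", "RPL", "HLA-"))
    ]
    coding.sort(key=lambda g: g.gene_name)

    records: list[IsoformRecord] = []
    # known isoforms (reference structures), one record per coding gene
    for g in coding:
        t = g.transcripts[0]
        records.append(IsoformRecord(
            isoform_id=t.transcript_id, gene=g.gene_name,
            sample_id=glioma_samples[0], strand=g.strand,
            exons=tuple(t.exons), novelty="known",
        ))

    # planted novel clusters on non-fusion genes
    cluster_pool = [g for g in coding if g.gene_name not in fusion_genes]
    cluster_truth: dict[str, dict[str, int]] = {}
    for g in cluster_pool[:n_cluster_genes]:
        t = g.transcripts[0]
        n_clusters = int(rng.integers(1, 4))
        for c in range(n_clusters):
            shift = (c + 1) * 3 * tol
            base = [ExonInterval(e.start + shift, e.end + shift) for e in t.exons]
            n_members = int(rng.integers(3, 7))
            for m in range(n_members):
                jit = [int(rng.integers(-30, 31)) for _ in range(2 * len(base))]
                exons = []
                for ei, e in enumerate(base):
                    s = e.start + jit[2 * ei]
                    en = e.end + jit[2 * ei + 1]
                    if en - s < 20:
                        en = s + 20
                    exons.append(ExonInterval(s, en))
                fixed = []
                prev_end = 0
                for e in exons:
                    s = max(e.start, prev_end + 1)
                    fixed.append(ExonInterval(s, max(e.end, s)))
                    prev_end = fixed[-1].end
                iso_id = f"NOV_{g.gene_name}_c{c}_m{m}"
                records.append(IsoformRecord(
                    isoform_id=iso_id, gene=g.gene_name,
                    sample_id=glioma_samples[m % len(glioma_samples)],
                    strand=g.strand, exons=tuple(fixed),
                    novelty="NIC" if rng.random() < 0.5 else "NNIC",
                ))
                cluster_truth.setdefault(g.gene_name, {})[iso_id] = c

    # fusion-like truncations for planted true fusions whose partner genes
    # are unique to one fusion (so a truncation can never hit another event)
    from .model import select_transcript_tiers

    gene_usage: dict[str, int] = {}
    for f in truth.fusions:
        if f.artifact_class in ("true",):
            gene_usage[f.gene5] = gene_usage.get(f.gene5, 0) + 1
            gene_usage[f.gene3] = gene_usage.get(f.gene3, 0) + 1
    true_fusions = [
        f for f in truth.fusions
        if f.artifact_class == "true"
        and gene_usage.get(f.gene5, 0) == 1 and gene_usage.get(f.gene3, 0) == 1
    ]
    chosen = true_fusions[: max(1, (len(true_fusions) + 1) // 2)] if true_fusions else []
    offsets = [0, 60, 160]
    for fi, f in enumerate(chosen):
        fusion_name = f"{f.gene5}::{f.gene3}"
        planted_here: list[tuple[IsoformRecord, PlantedTruncation]] = []
        ok = True
        for role, gene_name, bp in (
            ("5prime", f.gene5, f.pos5), ("3prime", f.gene3, f.pos3),
        ):
            gene = annotation.get(gene_name)
            if gene is None:
                ok = False
                break
            t = gene.transcripts[0]
            tiers = select_transcript_tiers(gene)
            canonical = tiers.tier1 or tiers.tier2 or t
            canon_ref = (canonical.tx_end() if role == "5prime"
                         else canonical.tx_start())
            sign = -1 if (t.strand == "+") == (role == "5prime") else 1
            placed = None
            for d in (offsets[fi % len(offsets)], 0):
                boundary = bp + sign * d
                chain = (_truncate_chain_end(t, boundary) if role == "5prime"
                         else _truncate_chain_start(t, boundary))
                if chain is None:
                    continue
                actual = (
                    (chain[-1].end if t.strand == "+" else chain[0].start)
                    if role == "5prime"
                    else (chain[0].start if t.strand == "+" else chain[-1].end)
                )
                distance = abs(actual - bp)
                # must be detectable: non-canonical and inside the smallest
                # possible search radius
                if distance <= params.prox_min_bp - 50 and \
                        abs(actual - canon_ref) > params.boundary_tol_bp + 10:
                    placed = (chain, actual, distance)
                    break
            if placed is None:
                ok = False
                break
            chain, actual, distance = placed
            iso_id = f"TRUNC_{gene_name}_{role}_{fi}"
            planted_here.append((
                IsoformRecord(
                    isoform_id=iso_id, gene=gene_name, sample_id=f.sample_id,
                    strand=t.strand, exons=tuple(chain), novelty="NIC",
                ),
                PlantedTruncation(
                    fusion_name=fusion_name, sample_id=f.sample_id,
                    gene=gene_name, role=role, isoform_id=iso_id,
                    boundary_pos=actual, distance_bp=distance,
                ),
            ))
        if ok and len(planted_here) == 2:
            for rec, tr in planted_here:
                records.append(rec)
                truth.truncations.append(tr)

    structures = pd.DataFrame(
        [
            {
                "isoform_id": r.isoform_id, "gene": r.gene, "sample": r.sample_id,
                "strand": r.strand, "novelty": r.novelty,
                "exons": exons_to_chain(r.exons),
            }
            for r in records
        ],
        columns=["isoform_id", "gene", "sample", "strand", "novelty", "exons"],
    )

    # counts on known isoforms, with planted DE
    iso_ids = [g.transcripts[0].transcript_id for g in coding]
    lengths = pd.Series(
        [g.transcripts[0].spliced_length for g in coding], index=iso_ids,
        name="length",
    )
    base_mean = rng.uniform(30, 200, size=len(iso_ids))
    counts = pd.DataFrame(index=iso_ids, columns=all_samples, dtype=int)
    lfc_map: dict[str, float] = {}
    strata: dict[str, str] = {}
    n_de = min(n_de, len(iso_ids) // 2)
    de_pick = list(iso_ids[:4 * n_de // 2][: 2 * n_de])
    for i, iso in enumerate(de_pick[:n_de]):
        lfc = float(rng.uniform(1.5, 3.0)) * (1 if i % 2 == 0 else -1)
        lfc_map[iso] = lfc
        strata[iso] = "consensus"
    extra = de_pick[n_de:]
    for i, iso in enumerate(extra):
        strata[iso] = ("a_only", "b_only", "discordant")[i % 3]
    for j, iso in enumerate(iso_ids):
        mu = base_mean[j]
        lfc = lfc_map.get(iso, 0.0)
        for s in all_samples:
            m = mu * (2.0 ** lfc) if labels[s] == "glioma" else mu
            counts.loc[iso, s] = int(rng.negative_binomial(20, 20 / (20 + m)))
    counts = counts.astype(int)

    # two DE result tables with controlled agreement
    rows_a, rows_b = [], []
    for iso in iso_ids:
        stratum = strata.get(iso, "null")
        if stratum == "consensus":
            lfc = lfc_map[iso]
            la = lfc + float(rng.normal(0, 0.15))
            lb = lfc + float(rng.normal(0, 0.15))
            fa = float(rng.uniform(1e-4, 0.04))
            fb = float(rng.uniform(1e-4, 0.04))
        elif stratum == "a_only":
            la, fa = 2.0 + float(rng.normal(0, 0.2)), float(rng.uniform(1e-4, 0.04))
            lb, fb = 0.3, float(rng.uniform(0.2, 0.9))
        elif stratum == "b_only":
            la, fa = 0.2, float(rng.uniform(0.2, 0.9))
            lb, fb = -2.0 + float(rng.normal(0, 0.2)), float(rng.uniform(1e-4, 0.04))
        elif stratum == "discordant":
            la, fa = 1.8, float(rng.uniform(1e-4, 0.04))
            lb, fb = -1.8, float(rng.uniform(1e-4, 0.04))
        else:
            la = float(rng.normal(0, 0.3))
            lb = float(rng.normal(0, 0.3))
            fa = float(rng.uniform(0.1, 1.0))
            fb = float(rng.uniform(0.1, 1.0))
        rows_a.append({"isoform_id": iso, "log2_fc": la, "fdr": fa})
        rows_b.append({"isoform_id": iso, "log2_fc": lb, "fdr": fb})
        if stratum in ("consensus", "a_only", "b_only", "discordant"):
            truth.de_isoforms.append(PlantedDEIsoform(
                isoform_id=iso,
                log2_fc=lfc_map.get(iso, 0.0),
                stratum=stratum,
            ))

    return {
        "structures": structures,
        "records": records,
        "counts": counts,
        "lengths": lengths,
        "labels": labels,
        "de_a": pd.DataFrame(rows_a),
        "de_b": pd.DataFrame(rows_b),
        "cluster_truth": cluster_truth,
        "truth": truth,
    }


# ---------------------------------------------------------------------------
# workspace
# ---------------------------------------------------------------------------

def simulate_workspace(
    out_dir: str | Path,
    n_genes: int = 50,
    n_true: int = 10,
    n_artifacts: int = 10,
    n_samples_per_group: int = 5,
    jitter_bp: int = 20,
    seed: int = 0,
) -> Path:
    """Write a self-contained analysis workspace with ground truth.

    The directory holds the annotation (GTF), genome (FASTA), per-caller
    fusion call TSVs, resource files (gene lists, census table with
    tumour-type annotations, DepMap-style matrices, CNS partner list,
    control pairs, blacklists), isoform structure and count tables, two DE
    result tables, group labels, and ``truth.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    gtf, fasta, annotation = simulate_annotation(n_genes, seed)
    (out / "annotation.gtf").write_text(gtf)
    (out / "genome.fa").write_text(fasta)

    sets = derive_gene_classes(annotation)
    tables, truth = simulate_fusion_calls(
        annotation, n_true, n_artifacts, jitter_bp=jitter_bp,
        seed=int(rng.integers(0, 2**31 - 1)),
        n_samples=max(4, n_samples_per_group), sets=sets,
    )
    for caller, df in tables.items():
        df.to_csv(out / f"calls_{caller}.tsv", sep="\t", index=False)

    fixtures = simulate_isoform_fixtures(
        annotation, truth, n_samples_per_group=n_samples_per_group,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    fixtures["structures"].to_csv(out / "isoforms.tsv", sep="\t", index=False)
    fixtures["counts"].rename_axis("isoform_id").to_csv(
        out / "counts.tsv", sep="\t")
    fixtures["lengths"].rename_axis("isoform_id").to_frame().to_csv(
        out / "lengths.tsv", sep="\t")
    fixtures["labels"].rename_axis("sample").to_frame().to_csv(
        out / "labels.tsv", sep="\t")
    fixtures["de_a"].to_csv(out / "de_edger.tsv", sep="\t", index=False)
    fixtures["de_b"].to_csv(out / "de_deseq2.tsv", sep="\t", index=False)

    # resources
    def write_list(name: str, items) -> None:
        (out / name).write_text("".join(f"{x}\n" for x in sorted(items)))

    write_list("panel_genes.txt", sets.panel_genes)
    write_list("pseudogenes.txt", sets.pseudogenes)
    write_list("ribosomal_genes.txt", sets.ribosomal_genes)
    write_list("hla_genes.txt", sets.hla_genes)

    census_rows = []
    tumour_types = [
        "glioblastoma", "astrocytoma", "oligodendroglioma", "CNS tumour",
        "paraganglioma", "leukaemia", "melanoma", "breast carcinoma",
    ]
    census_sorted = sorted(sets.census_genes)
    for i, gene in enumerate(census_sorted):
        k = int(rng.integers(1, 3))
        idx = rng.choice(len(tumour_types), size=k, replace=False)
        census_rows.append({
            "gene": gene,
            "tumour_types": ", ".join(tumour_types[int(x)] for x in sorted(idx)),
        })
    pd.DataFrame(census_rows).to_csv(out / "census.tsv", sep="\t", index=False)

    half = len(census_sorted) // 2
    write_list("oncogenes.txt", census_sorted[:half])
    write_list("tsgs.txt", census_sorted[half:])
    write_list("cns_partners.txt", census_sorted[::3])

    pd.DataFrame(
        [{"gene_a": a, "gene_b": b} for a, b in sorted(map(tuple, truth.control_pairs))],
        columns=["gene_a", "gene_b"],
    ).to_csv(out / "control_pairs.tsv", sep="\t", index=False)

    lines = [f"GLI_{i + 1}" for i in range(4)] + [f"OTHER_{i + 1}" for i in range(3)]
    gene_names = sorted(g.gene_name for g in annotation)
    dep = pd.DataFrame(
        rng.uniform(0, 0.6, size=(len(gene_names), len(lines))),
        index=gene_names, columns=lines,
    )
    eff = pd.DataFrame(
        rng.normal(-0.2, 0.3, size=(len(gene_names), len(lines))),
        index=gene_names, columns=lines,
    )
    essential = census_sorted[::4]
    for g in essential:
        dep.loc[g, "GLI_1"] = float(rng.uniform(0.92, 0.99))
        eff.loc[g, "GLI_2"] = float(rng.uniform(-2.5, -1.1))
    dep.round(4).rename_axis("gene").to_csv(out / "depmap_dependency.tsv", sep="\t")
    eff.round(4).rename_axis("gene").to_csv(out / "depmap_effect.tsv", sep="\t")
    (out / "depmap_lines.txt").write_text("".join(
        f"{l}\n" for l in lines if l.startswith("GLI_")))

    (out / "truth.json").write_text(truth.to_json())
    return out
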