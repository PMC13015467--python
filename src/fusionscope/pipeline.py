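"""End-to-end pipeline over an analysis workspace directory.

A workspace is a directory of plain-text inputs (annotation GTF, genome
FASTA, per-caller fusion call TSVs, resource gene lists and matrices,
isoform structure/count tables, DE result tables, sample labels) as written
by :func:`fusionscope.synthetic.simulate_workspace`. The pipeline harmonizes
the ensemble calls, runs the filtering cascade with its audit, prioritizes
the survivors against cancer/glioma resources, performs the isoform
analyses (expression filter, TPM, consensus DE, novel-structure clustering,
breakpoint-isoform overlap), designs fusion cDNA constructs, and writes one
TSV per stage plus a JSON summary into the output directory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .breakpoints import AnnotatedFusion, annotated_to_frame, summarize_breakpoint_classes
from .constructs import AssemblyError, SelectionError, design_construct
from .filtering import FilterAudit, GeneClassSets, apply_cascade
from .harmonize import calls_to_frame, harmonize, normalize_calls
from .isoforms import (
    compute_tpm,
    consensus_de,
    consensus_to_frame,
    expression_filter,
    expression_summaries,
)
from .model import GenomeAnnotation, read_annotation, read_fasta
from .novel import (
    group_all_genes,
    groups_to_frame,
    rank_genes_by_novel_structures,
    records_from_frame,
)
from .overlap import breakpoint_proximal_isoforms, fusion_like_pattern, hits_to_frame
from .params import DEFAULT_PARAMS, Parameters
from .prioritize import (
    Resources,
    annotate_fusion_genes,
    build_glioma_subset,
    depmap_essentiality,
    prioritized_to_frame,
    summarize_prioritization,
)

CALLER_FILES = {
    "longgf": "calls_longgf.tsv",
    "jaffal": "calls_jaffal.tsv",
    "fusionseeker": "calls_fusionseeker.tsv",
}


class WorkspaceError(FileNotFoundError):
    pass


@dataclass
class PipelineResult:
    harmonized: list
    fusions: list[AnnotatedFusion]
    audit: FilterAudit
    prioritized: list
    consensus: list
    groups: list
    overlap_hits: list
    fusion_like: pd.DataFrame
    constructs: pd.DataFrame
    summary: dict = field(default_factory=dict)


def _require(workspace: Path, name: str) -> Path:
    p = workspace / name
    if not p.exists():
        raise WorkspaceError(f"workspace is missing {name}")
    return p


def load_gene_class_sets(workspace: Path,
                         annotation: GenomeAnnotation,
                         params: Parameters) -> GeneClassSets:
    sets = GeneClassSets(
        panel_genes=GeneClassSets.read_gene_list(_require(workspace, "panel_genes.txt")),
        pseudogenes=GeneClassSets.read_gene_list(_require(workspace, "pseudogenes.txt")),
        ribosomal_genes=GeneClassSets.read_gene_list(
            _require(workspace, "ribosomal_genes.txt")),
        hla_genes=GeneClassSets.read_gene_list(_require(workspace, "hla_genes.txt")),
        control_pairs=GeneClassSets.read_control_pairs(
            _require(workspace, "control_pairs.tsv")),
    )
    census = pd.read_csv(_require(workspace, "census.tsv"), sep="\t")
    sets.census_genes = set(census["gene"].astype(str))
    sets.mito_genes = {
        g.gene_name for g in annotation if g.chrom in params.mito_chroms
    }
    return sets


def load_resources(workspace: Path, sets: GeneClassSets,
                   params: Parameters) -> Resources:
    census = pd.read_csv(_require(workspace, "census.tsv"), sep="\t")
    dep = pd.read_csv(_require(workspace, "depmap_dependency.tsv"),
                      sep="\t", index_col=0)
    eff = pd.read_csv(_require(workspace, "depmap_effect.tsv"),
                      sep="\t", index_col=0)
    lines = [
        l.strip()
        for l in _require(workspace, "depmap_lines.txt").read_text().splitlines()
        if l.strip()
    ]
    return Resources(
        panel_genes=set(sets.panel_genes),
        census_genes=set(sets.census_genes),
        glioma_subset=build_glioma_subset(
            census, params.glioma_keywords, params.glioma_exclusions),
        oncogenes=GeneClassSets.read_gene_list(_require(workspace, "oncogenes.txt")),
        tsgs=GeneClassSets.read_gene_list(_require(workspace, "tsgs.txt")),
        depmap=depmap_essentiality(dep, eff, lines, params),
        cns_partners=GeneClassSets.read_gene_list(
            _require(workspace, "cns_partners.txt")),
    )


def design_all_constructs(
    fusions: list[AnnotatedFusion],
    annotation: GenomeAnnotation,
    genome: dict[str, str],
    params: Parameters = DEFAULT_PARAMS,
) -> pd.DataFrame:
    """Construct design for every fusion, one row per call.

    Fusions whose breakpoints cannot be represented on any transcript (deep
    intronic, non-coding 5' partner) are reported with a status instead of a
    sequence; design failures never abort the run.
    """
    rows = []
    for f in fusions:
        call = f.call
        g5, g3 = annotation.get(call.gene5), annotation.get(call.gene3)
        row = {
            "fusion": call.name, "sample_id": call.sample_id,
            "status": "ok", "transcript5": "", "transcript3": "",
            "cdna_length": 0, "junction_offset": 0, "frame_status": "",
            "premature_stop_codon": "", "microhomology_len": 0,
            "utr5_rule": False, "protein_length": 0,
        }
        if g5 is None or g3 is None:
            row["status"] = "gene_unannotated"
            rows.append(row)
            continue
        try:
            c = design_construct(call.name, g5, g3, call.bp5, call.bp3,
                                 genome, params)
        except (AssemblyError, SelectionError) as exc:
            row["status"] = f"failed: {exc}"
            rows.append(row)
            continue
        row.update({
            "transcript5": c.transcript5, "transcript3": c.transcript3,
            "cdna_length": len(c.cdna), "junction_offset": c.junction_offset,
            "frame_status": c.frame_status,
            "premature_stop_codon": ("" if c.premature_stop_pos is None
                                     else c.premature_stop_pos),
            "microhomology_len": c.microhomology_len,
            "utr5_rule": c.utr5_rule, "protein_length": len(c.orf_protein),
        })
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["fusion", "sample_id", "status", "transcript5", "transcript3",
                 "cdna_length", "junction_offset", "frame_status",
                 "premature_stop_codon", "microhomology_len", "utr5_rule",
                 "protein_length"],
    )


def run_pipeline(
    workspace: str | Path,
    out_dir: Optional[str | Path] = None,
    params: Parameters = DEFAULT_PARAMS,
) -> PipelineResult:
    """Run every analysis stage over a workspace directory.

    When ``out_dir`` is given, per-stage TSVs and ``summary.json`` are
    written there; the in-memory result is returned either way.
    """
    workspace = Path(workspace)
    annotation = read_annotation(_require(workspace, "annotation.gtf"),
                                 params.mane_tag)
    genome = read_fasta(_require(workspace, "genome.fa"))

    # 1. harmonize ensemble calls
    calls = []
    for caller, fname in CALLER_FILES.items():
        p = workspace / fname
        if not p.exists():
            continue
        df = pd.read_csv(p, sep="\t")
        if len(df):
            calls.extend(normalize_calls(df, caller))
    if not calls:
        raise WorkspaceError("no fusion calls found in workspace")
    harmonized = harmonize(calls, params.dedup_window_bp)

    # 2. filtering cascade with audit
    sets = load_gene_class_sets(workspace, annotation, params)
    fusions, audit = apply_cascade(harmonized, sets, annotation, params)

    # 3. prioritization
    resources = load_resources(workspace, sets, params)
    prioritized = annotate_fusion_genes(fusions, resources, params)

    # 4. isoform expression + consensus DE
    counts = pd.read_csv(_require(workspace, "counts.tsv"), sep="\t", index_col=0)
    lengths = pd.read_csv(_require(workspace, "lengths.tsv"), sep="\t",
                          index_col=0)["length"]
    labels = pd.read_csv(_require(workspace, "labels.tsv"), sep="\t",
                         index_col=0)["group"]
    retained_ids = expression_filter(counts, labels, params)
    tpm = compute_tpm(counts, lengths)
    expr_summary = expression_summaries(tpm, labels)
    de_a = pd.read_csv(_require(workspace, "de_edger.tsv"), sep="\t")
    de_b = pd.read_csv(_require(workspace, "de_deseq2.tsv"), sep="\t")
    consensus = consensus_de(
        de_a[de_a["isoform_id"].isin(retained_ids)],
        de_b[de_b["isoform_id"].isin(retained_ids)],
        params,
    )

    # 5. novel isoform clustering
    structures = pd.read_csv(_require(workspace, "isoforms.tsv"), sep="\t")
    records = records_from_frame(structures)
    novel_records = [r for r in records if r.novelty != "known"]
    groups = group_all_genes(novel_records, params.boundary_tol_bp)
    ranking = rank_genes_by_novel_structures(groups)

    # 6. breakpoint-isoform overlap
    hits = []
    for f in fusions:
        hits.extend(breakpoint_proximal_isoforms(f, novel_records, annotation,
                                                 params))
    fusion_like = fusion_like_pattern(hits)

    # 7. construct design
    constructs = design_all_constructs(fusions, annotation, genome, params)

    summary = {
        "n_input_calls": len(calls),
        "n_harmonized": len(harmonized),
        "n_filtered": len(fusions),
        "audit": [
            {"stage": s, "n_in": n_in, "n_out": n_out}
            for s, n_in, n_out, _ in audit.stages
        ],
        "n_expression_retained": len(retained_ids),
        "n_consensus_de": len(consensus),
        "n_novel_groups": len(groups),
        "n_overlap_hits": len(hits),
        "n_fusion_like": int(fusion_like["fusion_like"].sum())
        if len(fusion_like) else 0,
        "n_constructs_ok": int((constructs["status"] == "ok").sum()),
    }

    result = PipelineResult(
        harmonized=harmonized, fusions=fusions, audit=audit,
        prioritized=prioritized, consensus=consensus, groups=groups,
        overlap_hits=hits, fusion_like=fusion_like, constructs=constructs,
        summary=summary,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        calls_to_frame(harmonized).to_csv(
            out / "harmonized_calls.tsv", sep="\t", index=False)
        audit.to_frame().to_csv(out / "filter_audit.tsv", sep="\t", index=False)
        annotated_to_frame(fusions).to_csv(
            out / "filtered_fusions.tsv", sep="\t", index=False)
        prioritized_to_frame(prioritized).to_csv(
            out / "prioritized_fusions.tsv", sep="\t", index=False)
        prios = summarize_prioritization(prioritized)
        if len(prios):
            prios.to_csv(out / "prioritization_summary.tsv", sep="\t")
        bp_summary = summarize_breakpoint_classes(fusions)
        if len(bp_summary["classes"]):
            bp_summary["classes"].to_csv(
                out / "breakpoint_classes.tsv", sep="\t")
            bp_summary["tiers"].to_csv(out / "breakpoint_tiers.tsv", sep="\t")
        tpm.rename_axis("isoform_id").to_csv(out / "tpm.tsv", sep="\t")
        expr_summary.rename_axis("isoform_id").to_csv(
            out / "expression_summary.tsv", sep="\t")
        consensus_to_frame(consensus).to_csv(
            out / "consensus_de.tsv", sep="\t", index=False)
        groups_to_frame(groups).to_csv(
            out / "novel_groups.tsv", sep="\t", index=False)
        ranking.to_csv(out / "novel_gene_ranking.tsv", sep="\t", index=False)
        hits_to_frame(hits).to_csv(out / "overlap_hits.tsv", sep="\t", index=False)
        fusion_like.to_csv(out / "fusion_like.tsv", sep="\t", index=False)
        constructs.to_csv(out / "constructs.tsv", sep="\t", index=False)
        (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return result
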