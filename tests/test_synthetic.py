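import json

import pandas as pd
import pytest

from fusionscope.constructs import spliced_sequence
from fusionscope.harmonize import normalize_calls
from fusionscope.model import read_annotation, read_fasta
from fusionscope.synthetic import (
    ARTIFACT_CLASSES,
    CALLERS,
    TruthSet,
    derive_gene_classes,
    simulate_annotation,
    simulate_fusion_calls,
    simulate_isoform_fixtures,
    simulate_workspace,
)


def test_annotation_deterministic():
    g1, f1, _ = simulate_annotation(25, seed=9)
    g2, f2, _ = simulate_annotation(25, seed=9)
    assert g1 == g2 and f1 == f2
    g3, _, _ = simulate_annotation(25, seed=10)
    assert g3 != g1


def test_annotation_counts_and_classes(sim_annotation):
    _, _, annotation = sim_annotation
    assert len(annotation) == 40
    sets = derive_gene_classes(annotation)
    assert sets.pseudogenes and sets.ribosomal_genes and sets.hla_genes
    assert sets.mito_genes  # n_genes >= 20 plants mitochondrial genes
    assert sets.panel_genes <= sets.census_genes


def test_annotation_clean_cds(sim_annotation):
    """Every coding transcript translates ATG...no-internal-stop, stop after."""
    gtf, fasta, annotation = sim_annotation
    genome = read_fasta(fasta)
    checked = 0
    for g in annotation:
        t = g.transcripts[0]
        if not t.has_cds:
            continue
        seq = spliced_sequence(t, genome, g.chrom)
        from fusionscope.constructs import genomic_to_spliced
        if t.strand == "+":
            s = genomic_to_spliced(t, t.cds_start)
            e = genomic_to_spliced(t, t.cds_end)
        else:
            s = genomic_to_spliced(t, t.cds_end)
            e = genomic_to_spliced(t, t.cds_start)
        cds = seq[s:e + 1]
        assert len(cds) % 3 == 0
        assert cds.startswith("ATG")
        stops = {"TAA", "TAG", "TGA"}
        assert all(cds[i:i + 3] not in stops for i in range(0, len(cds) - 3, 3))
        assert seq[e + 1:e + 4] == "TAA"
        checked += 1
    assert checked >= 10


def test_annotation_round_trips_through_gtf(sim_annotation):
    gtf, _, annotation = sim_annotation
    back = read_annotation(gtf)
    assert len(back) == len(annotation)


def test_fusion_calls_schema_and_truth(sim_annotation):
    _, _, annotation = sim_annotation
    tables, truth = simulate_fusion_calls(annotation, n_true=6, n_artifacts=5,
                                          seed=3)
    assert set(tables) == set(CALLERS)
    for caller, df in tables.items():
        if len(df):
            calls = normalize_calls(df, caller)
            assert all(c.support_reads >= 1 for c in calls)
    classes = {f.artifact_class for f in truth.fusions}
    assert classes <= set(ARTIFACT_CLASSES)
    assert len(truth.true_pairs()) >= 6
    # artifact pairs never overlap true pairs
    assert not (truth.true_pairs() & truth.artifact_pairs())


def test_fusion_calls_jitter_bounded(sim_annotation):
    _, _, annotation = sim_annotation
    tables, truth = simulate_fusion_calls(annotation, n_true=8, n_artifacts=0,
                                          jitter_bp=20, seed=4)
    planted = {(f.sample_id, f.gene5, f.gene3): f for f in truth.fusions}
    for caller, df in tables.items():
        for c in normalize_calls(df, caller):
            key = (c.sample_id, c.gene5, c.gene3)
            if key in planted:
                f = planted[key]
                assert abs(c.bp5.pos - f.pos5) <= 20
                assert abs(c.bp3.pos - f.pos3) <= 20


def test_fusion_calls_rejects_oversized_jitter(sim_annotation):
    _, _, annotation = sim_annotation
    with pytest.raises(ValueError):
        simulate_fusion_calls(annotation, 2, 0, jitter_bp=30)


def test_truth_json_round_trip(sim_annotation):
    _, _, annotation = sim_annotation
    _, truth = simulate_fusion_calls(annotation, 4, 5, seed=8)
    fixtures = simulate_isoform_fixtures(annotation, truth, seed=8)
    back = TruthSet.from_json(truth.to_json())
    assert back == truth


def test_isoform_fixture_contents(sim_annotation):
    _, _, annotation = sim_annotation
    _, truth = simulate_fusion_calls(annotation, 4, 0, seed=5)
    fx = simulate_isoform_fixtures(annotation, truth, seed=5)
    labels = fx["labels"]
    assert set(labels.unique()) == {"glioma", "control"}
    assert not labels.index.duplicated().any()
    assert (fx["counts"].columns == labels.index).all()
    # planted consensus DE isoforms recover through the consensus rule
    from fusionscope.isoforms import consensus_de

    cons = {r.isoform_id for r in consensus_de(fx["de_a"], fx["de_b"])}
    planted = {d.isoform_id for d in truth.de_isoforms
               if d.stratum == "consensus"}
    assert cons == planted
    # cluster truth members exist in the structure table
    table_ids = set(fx["structures"]["isoform_id"])
    for gene, members in fx["cluster_truth"].items():
        assert set(members) <= table_ids


def test_workspace_files_and_determinism(tmp_path):
    ws1 = simulate_workspace(tmp_path / "a", n_genes=30, n_true=4,
                             n_artifacts=5, seed=77)
    ws2 = simulate_workspace(tmp_path / "b", n_genes=30, n_true=4,
                             n_artifacts=5, seed=77)
    expected = [
        "annotation.gtf", "genome.fa", "calls_longgf.tsv", "calls_jaffal.tsv",
        "calls_fusionseeker.tsv", "isoforms.tsv", "counts.tsv", "lengths.tsv",
        "labels.tsv", "de_edger.tsv", "de_deseq2.tsv", "panel_genes.txt",
        "pseudogenes.txt", "ribosomal_genes.txt", "hla_genes.txt",
        "census.tsv", "oncogenes.txt", "tsgs.txt", "cns_partners.txt",
        "control_pairs.tsv", "depmap_dependency.tsv", "depmap_effect.tsv",
        "depmap_lines.txt", "truth.json",
    ]
    for name in expected:
        assert (ws1 / name).exists(), name
        assert (ws1 / name).read_text() == (ws2 / name).read_text(), name


def test_census_fixture_supports_glioma_subset(sim_workspace):
    from fusionscope.prioritize import build_glioma_subset

    census = pd.read_csv(sim_workspace / "census.tsv", sep="\t")
    subset = build_glioma_subset(census)
    assert subset  # at least one glioma-listed gene
    # a paraganglioma-only gene never enters the subset
    para_only = census[census["tumour_types"] == "paraganglioma"]
    assert not (set(para_only["gene"]) & subset)
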