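"""Shared fixtures: hand-built annotations and session-scoped simulations."""

from __future__ import annotations

import pytest

from fusionscope.model import (
    ExonInterval,
    GeneModel,
    GenomeAnnotation,
    TranscriptModel,
)


def make_transcript(
    transcript_id="T1.1",
    gene_id="G1",
    strand="+",
    exons=((1001, 1200), (1601, 1900), (2401, 2700)),
    cds=(1101, 2500),
    mane=False,
):
    t = TranscriptModel(
        transcript_id=transcript_id,
        gene_id=gene_id,
        strand=strand,
        exons=[ExonInterval(s, e) for s, e in exons],
        cds_start=cds[0] if cds else None,
        cds_end=cds[1] if cds else None,
        is_mane=mane,
        is_protein_coding=cds is not None,
    )
    return t


def make_gene(
    gene_id="G1",
    gene_name="GENEA",
    chrom="chr1",
    strand="+",
    transcripts=None,
    biotype="protein_coding",
):
    if transcripts is None:
        transcripts = [make_transcript(gene_id=gene_id, strand=strand, mane=True)]
    return GeneModel(
        gene_id=gene_id, gene_name=gene_name, chrom=chrom, strand=strand,
        biotype=biotype, transcripts=transcripts,
    )


@pytest.fixture
def simple_gene():
    return make_gene()


@pytest.fixture
def simple_annotation(simple_gene):
    other = make_gene(
        gene_id="G2", gene_name="GENEB", chrom="chr2", strand="-",
        transcripts=[make_transcript(
            transcript_id="T2.1", gene_id="G2", strand="-",
            exons=((5001, 5300), (5801, 6100)), cds=(5101, 6000), mane=True,
        )],
    )
    return GenomeAnnotation([simple_gene, other])


@pytest.fixture(scope="session")
def sim_annotation():
    from fusionscope.synthetic import simulate_annotation

    gtf, fasta, annotation = simulate_annotation(n_genes=40, seed=101)
    return gtf, fasta, annotation


@pytest.fixture(scope="session")
def sim_workspace(tmp_path_factory):
    from fusionscope.synthetic import simulate_workspace

    out = tmp_path_factory.mktemp("workspace")
    return simulate_workspace(out / "ws", n_genes=50, n_true=10,
                              n_artifacts=10, seed=202)


@pytest.fixture(scope="session")
def pipeline_run(sim_workspace, tmp_path_factory):
    from fusionscope.pipeline import run_pipeline

    out = tmp_path_factory.mktemp("pipeline_out")
    return run_pipeline(sim_workspace, out), out
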