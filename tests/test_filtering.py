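import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fusionscope.filtering import (
    ConfigurationError,
    FilterAudit,
    GeneClassSets,
    apply_cascade,
    blacklist_filter,
    control_subtraction,
    gene_list_gate,
    strand_consistency_filter,
    support_filter,
)
from fusionscope.harmonize import FusionCall
from fusionscope.model import GenomicPosition
from fusionscope.params import DEFAULT_PARAMS


def call(sample="S1", g5="GENEA", g3="GENEB", p5=1150, p3=5900, support=5,
         c5="chr1", c3="chr2", s5="+", s3="-"):
    return FusionCall(
        sample_id=sample, gene5=g5, gene3=g3,
        bp5=GenomicPosition(c5, p5, s5), bp3=GenomicPosition(c3, p3, s3),
        support_reads=support, callers=frozenset({"longgf"}),
    )


@pytest.fixture
def sets():
    return GeneClassSets(
        panel_genes={"GENEA"},
        census_genes={"GENEA", "GENEB", "GENEC"},
        pseudogenes={"PSG1P"},
        ribosomal_genes={"RPL1S"},
        hla_genes={"HLA-X"},
        mito_genes={"MT-X"},
        control_pairs={("GENEA", "GENEC")},
    )


def test_gene_gate(sets):
    keep = call()
    drop = call(g5="NOTLISTED", g3="ALSONOT")
    partial = call(g5="NOTLISTED", g3="GENEB")
    assert gene_list_gate([keep, drop, partial], sets) == [keep, partial]


def test_gene_gate_empty_lists_raise():
    with pytest.raises(ConfigurationError):
        gene_list_gate([call()], GeneClassSets())


def test_support_filter_inclusive_threshold():
    keep = call(support=3)
    drop = call(support=2)
    assert support_filter([keep, drop], 3) == [keep]


def test_blacklist_filter(sets):
    ok = call()
    pseudo = call(g3="PSG1P")
    ribo = call(g5="RPL1S")
    hla = call(g3="HLA-X")
    mito_chrom = call(c3="chrM")
    mito_gene = call(g3="MT-X")
    out = blacklist_filter([ok, pseudo, ribo, hla, mito_chrom, mito_gene], sets)
    assert out == [ok]


def test_strand_consistency(simple_annotation):
    # GENEA is '+', GENEB is '-'
    consistent = call(s5="+", s3="-")
    contradicting = call(s5="-", s3="-")
    unknown = call(s5="unknown", s3="-")
    unannotated = call(g5="MISSING", s5="-", s3="-")
    out = strand_consistency_filter(
        [consistent, contradicting, unknown, unannotated], simple_annotation)
    kept = {(c.gene5, c.bp5.strand) for c in out}
    assert ("GENEA", "+") in kept
    assert ("GENEA", "-") not in kept  # contradiction dropped
    # fail-open cases pass with flags
    flagged = {c.gene5: c.flags for c in out if c.flags}
    assert "strand_unknown" in flagged["GENEA"]
    assert "strand_unverified" in flagged["MISSING"]


def test_control_subtraction_unordered(sets):
    fwd = call(g5="GENEA", g3="GENEC")
    rev = call(g5="GENEC", g3="GENEA")
    keep = call()
    out = control_subtraction([fwd, rev, keep], sets.control_pairs)
    assert out == [keep]


def test_filters_idempotent(sets, simple_annotation):
    calls = [call(), call(support=2), call(g3="PSG1P"), call(g5="GENEC")]
    for fn in (
        lambda cs: gene_list_gate(cs, sets),
        lambda cs: support_filter(cs),
        lambda cs: blacklist_filter(cs, sets),
        lambda cs: control_subtraction(cs, sets.control_pairs),
    ):
        once = fn(calls)
        assert fn(once) == once


def test_audit_chaining_invariants():
    audit = FilterAudit()
    audit.record("a", 10, 7, [])
    with pytest.raises(ValueError):
        audit.record("b", 9, 5, [])  # n_in must chain from previous n_out
    audit.record("b", 7, 7, [])
    with pytest.raises(ValueError):
        audit.record("c", 7, 8, [])  # cannot gain calls


def test_cascade_monotone_and_audit_complete(sets, simple_annotation):
    calls = [
        call(),                       # survives everything
        call(support=1),              # support
        call(g3="PSG1P"),             # blacklist
        call(g5="GENEC", g3="GENEA", p5=5900, p3=1150,
             c5="chr2", c3="chr1", s5="-", s3="+"),  # control pair
        call(g5="ZZZ", g3="YYY"),     # gene gate
    ]
    kept, audit = apply_cascade(calls, sets, simple_annotation)
    ns = [(s, n_in, n_out) for s, n_in, n_out, _ in audit.stages]
    # monotone non-increase and complete chaining
    assert ns[0][1] == len(calls)
    for (_, n_in, n_out), (_, n_in2, _) in zip(ns, ns[1:]):
        assert n_out <= n_in and n_in2 == n_out
    assert ns[-1][2] == len(kept)
    # every removal attributed to exactly one stage
    total_removed = sum(n_in - n_out for _, n_in, n_out in ns)
    assert total_removed == len(calls) - len(kept)
    removed_keys = [k for _, _, _, r in audit.stages for k in r]
    assert len(removed_keys) == total_removed
    assert kept[0].call.pair == ("GENEA", "GENEB")


@given(st.randoms(), st.integers(0, 5))
@settings(max_examples=30, deadline=None)
def test_cascade_permutation_invariant(rnd, extra):
    sets = GeneClassSets(
        panel_genes={"GENEA"}, census_genes={"GENEA", "GENEB", "GENEC"},
        pseudogenes={"PSG1P"}, control_pairs={("GENEA", "GENEC")},
    )
    from .conftest import make_gene, make_transcript
    from fusionscope.model import GenomeAnnotation

    annotation = GenomeAnnotation([
        make_gene(),
        make_gene(gene_id="G2", gene_name="GENEB", chrom="chr2", strand="-",
                  transcripts=[make_transcript(
                      "T2.1", "G2", "-", ((5001, 5300), (5801, 6100)),
                      (5101, 6000), mane=True)]),
    ])
    calls = [
        call(), call(support=1), call(g3="PSG1P"),
        call(sample="S2", p5=1160, p3=5910),
    ][: 2 + extra % 3]
    kept1, _ = apply_cascade(calls, sets, annotation)
    shuffled = list(calls)
    rnd.shuffle(shuffled)
    kept2, _ = apply_cascade(shuffled, sets, annotation)
    key = lambda f: (f.call.sample_id, f.call.pair, f.call.bp5, f.call.bp3)
    assert sorted(map(key, kept1)) == sorted(map(key, kept2))


def test_read_gene_list_and_pairs(tmp_path):
    p = tmp_path / "genes.txt"
    p.write_text("# comment\nGENEA\n\nGENEB\n")
    assert GeneClassSets.read_gene_list(p) == {"GENEA", "GENEB"}
    q = tmp_path / "pairs.tsv"
    q.write_text("gene_a\tgene_b\nB\tA\nA\tC\n")
    assert GeneClassSets.read_control_pairs(q) == {("A", "B"), ("A", "C")}
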