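import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fusionscope.harmonize import (
    CALLER_SCHEMAS,
    FusionCall,
    FusionKey,
    SchemaError,
    calls_to_frame,
    collapse_reciprocals,
    dedup_exact,
    dedup_window,
    frame_to_calls,
    harmonize,
    normalize_calls,
    unique_fusions,
)
from fusionscope.model import GenomicPosition


def call(sample="S1", g5="A", g3="B", p5=1000, p3=2000, support=5,
         callers=("longgf",), c5="chr1", c3="chr2", s5="+", s3="+"):
    return FusionCall(
        sample_id=sample, gene5=g5, gene3=g3,
        bp5=GenomicPosition(c5, p5, s5), bp3=GenomicPosition(c3, p3, s3),
        support_reads=support, callers=frozenset(callers),
    )


# --- normalization ---------------------------------------------------------

def test_normalize_each_dialect():
    for caller, m in CALLER_SCHEMAS.items():
        df = pd.DataFrame([{
            m["sample_id"]: "S1", m["gene5"]: "A", m["chrom5"]: "chr1",
            m["pos5"]: 100, m["strand5"]: "+", m["gene3"]: "B",
            m["chrom3"]: "chr2", m["pos3"]: 200, m["strand3"]: "-",
            m["support"]: 7,
        }])
        calls = normalize_calls(df, caller)
        assert len(calls) == 1
        c = calls[0]
        assert c.pair == ("A", "B") and c.support_reads == 7
        assert c.callers == frozenset({caller})
        assert c.bp5 == GenomicPosition("chr1", 100, "+")


def test_normalize_unknown_caller_raises():
    with pytest.raises(SchemaError):
        normalize_calls(pd.DataFrame([{"x": 1}]), "novelcaller")


def test_normalize_missing_column_raises():
    df = pd.DataFrame([{"sample": "S1"}])
    with pytest.raises(SchemaError, match="longgf"):
        normalize_calls(df, "longgf")


def test_normalize_accepts_normalized_schema():
    df = calls_to_frame([call()])
    out = normalize_calls(df.drop(columns=["callers", "reciprocal_of"]).assign(),
                          "anything")
    assert out[0].pair == ("A", "B")


def test_normalize_non_numeric_support():
    m = CALLER_SCHEMAS["longgf"]
    df = pd.DataFrame([{
        m["sample_id"]: "S1", m["gene5"]: "A", m["chrom5"]: "chr1",
        m["pos5"]: 100, m["strand5"]: "+", m["gene3"]: "B",
        m["chrom3"]: "chr2", m["pos3"]: 200, m["strand3"]: "-",
        m["support"]: "many",
    }])
    with pytest.raises(ValueError, match="support"):
        normalize_calls(df, "longgf")


# --- exact dedup -----------------------------------------------------------

def test_dedup_exact_collapses_identical():
    a = call(support=5)
    out = dedup_exact([a, call(support=3)])
    assert len(out) == 1
    assert out[0].support_reads == 5  # keeps max support


def test_dedup_exact_keeps_distinct_callers():
    out = dedup_exact([call(callers=("longgf",)), call(callers=("jaffal",))])
    assert len(out) == 2


def test_dedup_exact_idempotent():
    calls = [call(), call(support=3), call(p5=1500)]
    once = dedup_exact(calls)
    assert dedup_exact(once) == once


# --- window dedup with brute-force oracle ----------------------------------

def oracle_single_linkage(calls, window):
    """Exhaustive single-linkage clustering for the window-merge oracle."""
    groups = {}
    for c in calls:
        groups.setdefault((c.sample_id, c.gene5, c.gene3), []).append(c)
    n_clusters = 0
    cluster_of = {}
    for key, members in groups.items():
        # start singleton clusters, then merge until fixpoint
        clusters = [[m] for m in members]
        changed = True
        while changed:
            changed = False
            for i in range(len(clusters)):
                for j in range(i + 1, len(clusters)):
                    if any(
                        a.bp5.chrom == b.bp5.chrom and a.bp3.chrom == b.bp3.chrom
                        and abs(a.bp5.pos - b.bp5.pos) <= window
                        and abs(a.bp3.pos - b.bp3.pos) <= window
                        for a in clusters[i] for b in clusters[j]
                    ):
                        clusters[i].extend(clusters.pop(j))
                        changed = True
                        break
                if changed:
                    break
        n_clusters += len(clusters)
    return n_clusters


@st.composite
def call_lists(draw):
    n = draw(st.integers(1, 12))
    out = []
    for i in range(n):
        out.append(call(
            sample=draw(st.sampled_from(["S1", "S2"])),
            g5=draw(st.sampled_from(["A", "B"])),
            g3=draw(st.sampled_from(["C", "D"])),
            p5=draw(st.integers(1000, 1300)),
            p3=draw(st.integers(5000, 5300)),
            support=draw(st.integers(1, 9)),
            callers=(draw(st.sampled_from(["longgf", "jaffal", "fusionseeker"])),),
        ))
    return out


@given(call_lists(), st.integers(10, 120))
@settings(max_examples=120, deadline=None)
def test_dedup_window_matches_oracle(calls, window):
    merged = dedup_window(calls, window)
    assert len(merged) == oracle_single_linkage(calls, window)
    # support of each survivor is the max over a cluster, never below input max
    assert max(c.support_reads for c in merged) == max(
        c.support_reads for c in calls)


@given(call_lists(), st.integers(10, 120), st.randoms())
@settings(max_examples=60, deadline=None)
def test_dedup_window_order_invariant_and_idempotent(calls, window, rnd):
    merged = dedup_window(calls, window)
    shuffled = list(calls)
    rnd.shuffle(shuffled)
    assert dedup_window(shuffled, window) == merged
    assert dedup_window(merged, window) == merged


def test_dedup_window_merges_callers_union():
    a = call(callers=("longgf",), support=5)
    b = call(p5=1030, p3=2020, callers=("jaffal",), support=4)
    out = dedup_window([a, b], 50)
    assert len(out) == 1
    assert out[0].callers == frozenset({"longgf", "jaffal"})
    assert out[0].support_reads == 5
    assert out[0].bp5.pos == 1000  # representative = max support member


def test_dedup_window_does_not_merge_across_genes_or_samples():
    assert len(dedup_window([call(), call(g3="C")], 50)) == 2
    assert len(dedup_window([call(), call(sample="S2")], 50)) == 2


# --- reciprocal collapse ---------------------------------------------------

def test_reciprocal_collapse_keeps_higher_support():
    fwd = call(support=8)
    rev = call(g5="B", g3="A", p5=2010, p3=1010, support=3,
               c5="chr2", c3="chr1")
    out = collapse_reciprocals([fwd, rev], 50)
    assert len(out) == 1
    assert out[0].pair == ("A", "B")
    assert out[0].reciprocal_of == "B::A"


def test_reciprocal_collapse_tie_keeps_both():
    fwd = call(support=5)
    rev = call(g5="B", g3="A", p5=2000, p3=1000, support=5,
               c5="chr2", c3="chr1")
    out = collapse_reciprocals([fwd, rev], 50)
    assert len(out) == 2
    assert all(c.reciprocal_of is not None for c in out)


def test_reciprocal_outside_window_untouched():
    fwd = call(support=8)
    rev = call(g5="B", g3="A", p5=2500, p3=1500, support=3,
               c5="chr2", c3="chr1")
    assert len(collapse_reciprocals([fwd, rev], 50)) == 2


def test_reciprocal_collapse_idempotent():
    calls = [call(support=8),
             call(g5="B", g3="A", p5=2010, p3=1010, support=3,
                  c5="chr2", c3="chr1")]
    once = collapse_reciprocals(calls, 50)
    assert collapse_reciprocals(once, 50) == once


# --- composition / io ------------------------------------------------------

def test_harmonize_full_stack():
    calls = [
        call(support=5), call(support=5),                      # exact dup
        call(p5=1020, p3=2010, support=6, callers=("jaffal",)),  # window merge
        call(g5="B", g3="A", p5=2005, p3=1005, support=2,
             c5="chr2", c3="chr1"),                            # reciprocal echo
    ]
    out = harmonize(calls, 50)
    assert len(out) == 1
    assert out[0].support_reads == 6
    assert unique_fusions(out) == {FusionKey.of("S1", "A", "B")}


def test_frame_round_trip():
    calls = [call(), call(g5="X", g3="Y", callers=("jaffal", "longgf"))]
    back = frame_to_calls(calls_to_frame(calls))
    assert back == calls


def test_call_validation():
    with pytest.raises(ValueError):
        call(support=0)
    with pytest.raises(ValueError):
        FusionCall("S1", "A", "B", GenomicPosition("chr1", 1),
                   GenomicPosition("chr2", 2), 5, frozenset())
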