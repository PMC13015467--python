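"""Harmonization of multi-caller fusion output.

Ensemble long-read fusion calling (LongGF, JAFFAL, FusionSeeker) reports the
same underlying event many times: exact duplicates within a caller, jittered
breakpoints across callers, and reciprocal orientations of one rearrangement.
Calls are reduced in two steps: (1) exact duplicates within a caller are
collapsed, and calls of the same gene pair whose breakpoints agree within a
50 bp window for both partners are merged across callers; (2) reciprocal
fusions (same partners, reversed orientation, breakpoints within 50 bp) are
collapsed to the orientation with higher read support, keeping both when
support is tied.

Window merging uses single-linkage chaining so the result is independent of
input order; the surviving representative is the member with maximal read
support (ties: smallest breakpoint coordinates), its caller set the union of
the members, and its support the maximum over members (callers largely count
overlapping read sets, so summing would double-count evidence).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import pandas as pd

from .model import GenomicPosition

# Column-name dialects for emulated caller outputs. Keys are the normalized
# schema; values per caller map normalized -> raw column.
CALLER_SCHEMAS: dict[str, dict[str, str]] = {
    "longgf": {
        "sample_id": "sample", "gene5": "gene1", "chrom5": "chr1", "pos5": "pos1",
        "strand5": "strand1", "gene3": "gene2", "chrom3": "chr2", "pos3": "pos2",
        "strand3": "strand2", "support": "num_reads",
    },
    "jaffal": {
        "sample_id": "sample", "gene5": "fusion_gene_5", "chrom5": "chrom_5",
        "pos5": "base_5", "strand5": "strand_5", "gene3": "fusion_gene_3",
        "chrom3": "chrom_3", "pos3": "base_3", "strand3": "strand_3",
        "support": "spanning_reads",
    },
    "fusionseeker": {
        "sample_id": "sample", "gene5": "geneA", "chrom5": "chromA", "pos5": "bpA",
        "strand5": "strandA", "gene3": "geneB", "chrom3": "chromB", "pos3": "bpB",
        "strand3": "strandB", "support": "supportreads",
    },
}

NORMALIZED_COLUMNS = [
    "sample_id", "gene5", "chrom5", "pos5", "strand5",
    "gene3", "chrom3", "pos3", "strand3", "support", "callers",
]


class SchemaError(ValueError):
    pass


@dataclass(frozen=True)
class FusionKey:
    """Per-sample unordered gene pair identifying a unique fusion event."""

    sample_id: str
    genes: tuple[str, str]

    @classmethod
    def of(cls, sample_id: str, gene_a: str, gene_b: str) -> "FusionKey":
        return cls(sample_id=sample_id, genes=tuple(sorted((gene_a, gene_b))))


@dataclass(frozen=True)
class FusionCall:
    sample_id: str
    gene5: str
    gene3: str
    bp5: GenomicPosition
    bp3: GenomicPosition
    support_reads: int
    callers: frozenset[str]
    reciprocal_of: Optional[str] = None
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.support_reads < 1:
            raise ValueError(f"support_reads must be >= 1, got {self.support_reads}")
        if not self.callers:
            raise ValueError("callers must be non-empty")
        if not self.gene5 or not self.gene3:
            raise ValueError("gene names must be non-empty")

    @property
    def key(self) -> FusionKey:
        return FusionKey.of(self.sample_id, self.gene5, self.gene3)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene5, self.gene3)

    @property
    def name(self) -> str:
        return f"{self.gene5}::{self.gene3}"


def normalize_calls(raw_table: pd.DataFrame, caller_name: str,
                    column_map: Optional[dict[str, str]] = None) -> list[FusionCall]:
    """Turn one caller's raw table into FusionCall records.

    ``column_map`` maps normalized column names to the caller's raw column
    names; built-in maps exist for the emulated longgf/jaffal/fusionseeker
    dialects and tables already in the normalized schema need no map.
    """
    if column_map is None:
        if all(c in raw_table.columns for c in NORMALIZED_COLUMNS[:-1]):
            column_map = {c: c for c in NORMALIZED_COLUMNS[:-1]}
        elif caller_name.lower() in CALLER_SCHEMAS:
            column_map = CALLER_SCHEMAS[caller_name.lower()]
        else:
            raise SchemaError(f"no column map known for caller {caller_name!r}")
    missing = [raw for raw in column_map.values() if raw not in raw_table.columns]
    if missing:
        raise SchemaError(f"{caller_name}: missing required column(s) {missing}")

    calls = []
    for _, row in raw_table.iterrows():
        def get(norm):
            return row[column_map[norm]]

        try:
            support = int(get("support"))
        except (TypeError, ValueError):
            raise ValueError(
                f"{caller_name}: non-numeric read support {get('support')!r}"
            ) from None
        calls.append(
            FusionCall(
                sample_id=str(get("sample_id")),
                gene5=str(get("gene5")),
                gene3=str(get("gene3")),
                bp5=GenomicPosition(str(get("chrom5")), int(get("pos5")),
                                    str(get("strand5"))),
                bp3=GenomicPosition(str(get("chrom3")), int(get("pos3")),
                                    str(get("strand3"))),
                support_reads=support,
                callers=frozenset({caller_name}),
            )
        )
    return calls


def dedup_exact(calls: list[FusionCall]) -> list[FusionCall]:
    """Collapse exact duplicates (identical genes and breakpoints) per caller."""
    seen: dict[tuple, FusionCall] = {}
    for c in calls:
        for caller in sorted(c.callers):
            key = (c.sample_id, caller, c.gene5, c.gene3,
                   c.bp5.chrom, c.bp5.pos, c.bp3.chrom, c.bp3.pos)
            prev = seen.get(key)
            if prev is None or c.support_reads > prev.support_reads:
                seen[key] = c
    # Re-collapse across the per-caller expansion without touching
    # cross-caller near-duplicates (those belong to dedup_window).
    out: dict[tuple, FusionCall] = {}
    for c in seen.values():
        key = (c.sample_id, frozenset(c.callers), c.gene5, c.gene3,
               c.bp5.chrom, c.bp5.pos, c.bp3.chrom, c.bp3.pos)
        prev = out.get(key)
        if prev is None or c.support_reads > prev.support_reads:
            out[key] = c
    return sorted(out.values(), key=_sort_key)


def _sort_key(c: FusionCall):
    return (c.sample_id, c.gene5, c.gene3, c.bp5.chrom, c.bp5.pos,
            c.bp3.chrom, c.bp3.pos, -c.support_reads)


def _within_window(a: FusionCall, b: FusionCall, window_bp: int) -> bool:
    return (
        a.bp5.chrom == b.bp5.chrom
        and a.bp3.chrom == b.bp3.chrom
        and abs(a.bp5.pos - b.bp5.pos) <= window_bp
        and abs(a.bp3.pos - b.bp3.pos) <= window_bp
    )


def _merge_cluster(members: list[FusionCall]) -> FusionCall:
    rep = sorted(
        members,
        key=lambda c: (-c.support_reads, c.bp5.pos, c.bp3.pos, sorted(c.callers)),
    )[0]
    callers = frozenset().union(*(c.callers for c in members))
    flags = frozenset().union(*(c.flags for c in members))
    return replace(rep, callers=callers, flags=flags,
                   support_reads=max(c.support_reads for c in members))


def dedup_window(calls: list[FusionCall], window_bp: int = 50) -> list[FusionCall]:
    """Merge same-pair calls whose breakpoints agree within window_bp.

    Single-linkage: A-B and B-C within the window chains A, B, C into one
    cluster even when A-C exceeds it, making the result order-independent.
    """
    by_group: dict[tuple, list[FusionCall]] = {}
    for c in sorted(calls, key=_sort_key):
        by_group.setdefault((c.sample_id, c.gene5, c.gene3), []).append(c)

    merged: list[FusionCall] = []
    for group in by_group.values():
        n = len(group)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if _within_window(group[i], group[j], window_bp):
                    parent[find(i)] = find(j)
        clusters: dict[int, list[FusionCall]] = {}
        for i, c in enumerate(group):
            clusters.setdefault(find(i), []).append(c)
        merged.extend(_merge_cluster(m) for m in clusters.values())
    return sorted(merged, key=_sort_key)


def collapse_reciprocals(calls: list[FusionCall], window_bp: int = 50) -> list[FusionCall]:
    """Drop the lower-support orientation of each reciprocal pair.

    A reciprocal pair is the same gene partners in reversed orientation with
    the respective breakpoints within window_bp. Ties in read support keep
    both orientations; survivors of a collapse record the dropped orientation
    in ``reciprocal_of``.
    """
    calls = sorted(calls, key=_sort_key)
    dropped: set[int] = set()
    annotate: dict[int, str] = {}
    for i in range(len(calls)):
        if i in dropped:
            continue
        a = calls[i]
        for j in range(i + 1, len(calls)):
            if j in dropped:
                continue
            b = calls[j]
            if a.sample_id != b.sample_id:
                continue
            if (a.gene5, a.gene3) != (b.gene3, b.gene5):
                continue
            if not (
                a.bp5.chrom == b.bp3.chrom
                and a.bp3.chrom == b.bp5.chrom
                and abs(a.bp5.pos - b.bp3.pos) <= window_bp
                and abs(a.bp3.pos - b.bp5.pos) <= window_bp
            ):
                continue
            if a.support_reads > b.support_reads:
                dropped.add(j)
                annotate[i] = b.name
            elif b.support_reads > a.support_reads:
                dropped.add(i)
                annotate[j] = a.name
            else:
                annotate[i] = b.name
                annotate[j] = a.name
    out = []
    for i, c in enumerate(calls):
        if i in dropped:
            continue
        if i in annotate and c.reciprocal_of is None:
            c = replace(c, reciprocal_of=annotate[i])
        out.append(c)
    return out


def unique_fusions(calls: Iterable[FusionCall]) -> set[FusionKey]:
    """Per-sample distinct unordered gene pairs among harmonized calls."""
    return {c.key for c in calls}


def harmonize(calls: list[FusionCall], window_bp: int = 50) -> list[FusionCall]:
    """Full harmonization: exact dedup, window dedup, reciprocal collapse."""
    return collapse_reciprocals(dedup_window(dedup_exact(calls), window_bp), window_bp)


def calls_to_frame(calls: Iterable[FusionCall]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": c.sample_id, "gene5": c.gene5, "chrom5": c.bp5.chrom,
            "pos5": c.bp5.pos, "strand5": c.bp5.strand, "gene3": c.gene3,
            "chrom3": c.bp3.chrom, "pos3": c.bp3.pos, "strand3": c.bp3.strand,
            "support": c.support_reads, "callers": ";".join(sorted(c.callers)),
            "reciprocal_of": c.reciprocal_of or "",
        }
        for c in calls
    ]
    return pd.DataFrame(rows, columns=NORMALIZED_COLUMNS + ["reciprocal_of"])


def frame_to_calls(df: pd.DataFrame) -> list[FusionCall]:
    calls = []
    for _, row in df.iterrows():
        calls.append(
            FusionCall(
                sample_id=str(row["sample_id"]),
                gene5=str(row["gene5"]),
                gene3=str(row["gene3"]),
                bp5=GenomicPosition(str(row["chrom5"]), int(row["pos5"]),
                                    str(row["strand5"])),
                bp3=GenomicPosition(str(row["chrom3"]), int(row["pos3"]),
                                    str(row["strand3"])),
                support_reads=int(row["support"]),
                callers=frozenset(str(row["callers"]).split(";")),
                reciprocal_of=(str(row["reciprocal_of"]) or None)
                if "reciprocal_of" in row and pd.notna(row["reciprocal_of"])
                and str(row["reciprocal_of"]) else None,
            )
        )
    return calls
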