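"""Structural clustering of novel transcript isoforms across samples.

Novel isoforms ("novel in catalog" / "novel not in catalog") recur across
tumour samples with small boundary jitter. To find recurrent structures,
isoforms of a gene are first partitioned by exon count, then clustered with
a greedy seed-and-extend pass: a record joins an existing group when its
transcription-direction start lies within the tolerance (default 100 bp) of
the group representative's start and every corresponding exon boundary lies
within the tolerance of the representative's, the representative being the
running mean of member coordinates. Because running means can drift, a
post-hoc validation pass splits off any member violating the tolerance
against the final representative and re-clusters those records. Records are
sorted by start coordinate before clustering so the outcome is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .model import ExonInterval

NOVELTY_CLASSES = ("known", "NIC", "NNIC")


@dataclass(frozen=True)
class IsoformRecord:
    isoform_id: str
    gene: str
    sample_id: str
    strand: str
    exons: tuple[ExonInterval, ...]
    novelty: str = "known"
    tpm: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError("isoform needs at least one exon")
        object.__setattr__(self, "exons", tuple(sorted(self.exons)))
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise ValueError(f"isoform {self.isoform_id}: overlapping exons")
        if self.novelty not in NOVELTY_CLASSES:
            raise ValueError(f"unknown novelty class {self.novelty!r}")

    @property
    def boundaries(self) -> list[int]:
        out = []
        for e in self.exons:
            out.extend((e.start, e.end))
        return out

    @property
    def tx_start(self) -> int:
        """5' end in transcription direction."""
        return self.exons[0].start if self.strand == "+" else self.exons[-1].end

    @property
    def tx_end(self) -> int:
        """3' end in transcription direction."""
        return self.exons[-1].end if self.strand == "+" else self.exons[0].start


@dataclass
class IsoformGroup:
    gene: str
    exon_count: int
    members: list[IsoformRecord] = field(default_factory=list)
    _sums: list[float] = field(default_factory=list)

    @property
    def representative(self) -> list[int]:
        """Mean boundary coordinates, rounded half-up to integers."""
        n = len(self.members)
        return [math.floor(s / n + 0.5) for s in self._sums]

    @property
    def representative_exons(self) -> list[ExonInterval]:
        rep = self.representative
        return [ExonInterval(rep[i], rep[i + 1]) for i in range(0, len(rep), 2)]

    def rep_tx_start(self, strand: str) -> float:
        n = len(self.members)
        return (self._sums[0] if strand == "+" else self._sums[-1]) / n

    def add(self, record: IsoformRecord) -> None:
        bounds = record.boundaries
        if self.members:
            if len(bounds) != len(self._sums):
                raise ValueError("exon count mismatch within group")
            for i, b in enumerate(bounds):
                self._sums[i] += b
        else:
            self._sums = [float(b) for b in bounds]
        self.members.append(record)

    def fits(self, record: IsoformRecord, tol: int) -> bool:
        if 2 * record.exons.__len__() != len(self._sums):
            return False
        n = len(self.members)
        rep = [s / n for s in self._sums]
        strand = self.members[0].strand
        rep_start = rep[0] if strand == "+" else rep[-1]
        if abs(record.tx_start - rep_start) > tol:
            return False
        return all(abs(b - r) <= tol for b, r in zip(record.boundaries, rep))


def _cluster_pass(records: list[IsoformRecord], gene: str, tol: int) -> list[IsoformGroup]:
    groups: list[IsoformGroup] = []
    for rec in records:
        placed = False
        for g in groups:
            if g.fits(rec, tol):
                g.add(rec)
                placed = True
                break
        if not placed:
            g = IsoformGroup(gene=gene, exon_count=len(rec.exons))
            g.add(rec)
            groups.append(g)
    return groups


def group_novel_isoforms(records: list[IsoformRecord], tol: int = 100) -> list[IsoformGroup]:
    """Partition one gene's novel isoform records into structural groups.

    Records must all belong to the same gene (mixed-gene input is an error;
    use :func:`group_all_genes` for a full table). The returned groups form a
    partition, and every member satisfies the tolerance against the final
    group representative (violators after mean drift are split off and
    re-clustered in a second pass).
    """
    if not records:
        return []
    genes = {r.gene for r in records}
    if len(genes) > 1:
        raise ValueError(f"mixed-gene input to a single grouping call: {sorted(genes)}")
    gene = genes.pop()

    by_count: dict[int, list[IsoformRecord]] = {}
    for r in sorted(records, key=lambda r: (len(r.exons), r.tx_start, r.isoform_id)):
        by_count.setdefault(len(r.exons), []).append(r)

    out: list[IsoformGroup] = []
    for recs in by_count.values():
        groups = _cluster_pass(recs, gene, tol)
        # post-hoc validation against the final (mean-drifted) representative
        stable: list[IsoformGroup] = []
        spilled: list[IsoformRecord] = []
        for g in groups:
            ok = IsoformGroup(gene=gene, exon_count=g.exon_count)
            n = len(g.members)
            rep = [s / n for s in g._sums]
            strand = g.members[0].strand
            rep_start = rep[0] if strand == "+" else rep[-1]
            for m in g.members:
                if (abs(m.tx_start - rep_start) <= tol
                        and all(abs(b - r) <= tol
                                for b, r in zip(m.boundaries, rep))):
                    ok.add(m)
                else:
                    spilled.append(m)
            if ok.members:
                stable.append(ok)
        if spilled:
            stable.extend(_cluster_pass(
                sorted(spilled, key=lambda r: (r.tx_start, r.isoform_id)), gene, tol
            ))
        out.extend(stable)
    return out


def group_all_genes(records: Iterable[IsoformRecord], tol: int = 100) -> list[IsoformGroup]:
    """Cluster a multi-gene record table gene by gene."""
    by_gene: dict[str, list[IsoformRecord]] = {}
    for r in records:
        by_gene.setdefault(r.gene, []).append(r)
    out: list[IsoformGroup] = []
    for gene in sorted(by_gene):
        out.extend(group_novel_isoforms(by_gene[gene], tol))
    return out


def dominant_structure_per_gene(groups: list[IsoformGroup]) -> dict[str, IsoformGroup]:
    """The most abundant novel structure per gene.

    Ties in member count break to the earliest representative start.
    """
    best: dict[str, IsoformGroup] = {}
    for g in groups:
        rep_start = min(g.representative)
        cur = best.get(g.gene)
        if cur is None:
            best[g.gene] = g
            continue
        cur_start = min(cur.representative)
        if (len(g.members), -rep_start) > (len(cur.members), -cur_start):
            best[g.gene] = g
    return best


def rank_genes_by_novel_structures(groups: list[IsoformGroup]) -> pd.DataFrame:
    """Genes ordered by their number of distinct novel structures (desc).

    Equal counts rank alphabetically.
    """
    counts: dict[str, int] = {}
    members: dict[str, int] = {}
    for g in groups:
        counts[g.gene] = counts.get(g.gene, 0) + 1
        members[g.gene] = members.get(g.gene, 0) + len(g.members)
    rows = [
        {"gene": gene, "n_structures": counts[gene], "n_isoforms": members[gene]}
        for gene in sorted(counts, key=lambda g: (-counts[g], g))
    ]
    return pd.DataFrame(rows, columns=["gene", "n_structures", "n_isoforms"])


def chain_to_exons(chain: str) -> tuple[ExonInterval, ...]:
    """Parse an exon chain string "start-end,start-end,..."."""
    exons = []
    for part in chain.split(","):
        s, e = part.split("-")
        exons.append(ExonInterval(int(s), int(e)))
    return tuple(exons)


def exons_to_chain(exons: Iterable[ExonInterval]) -> str:
    return ",".join(f"{e.start}-{e.end}" for e in exons)


def records_from_frame(df: pd.DataFrame) -> list[IsoformRecord]:
    """Read isoform structures from the TSV schema
    (isoform_id, gene, sample, strand, novelty, exons)."""
    recs = []
    for _, row in df.iterrows():
        recs.append(
            IsoformRecord(
                isoform_id=str(row["isoform_id"]),
                gene=str(row["gene"]),
                sample_id=str(row["sample"]),
                strand=str(row["strand"]),
                exons=chain_to_exons(str(row["exons"])),
                novelty=str(row["novelty"]),
                tpm=float(row["tpm"]) if "tpm" in row and pd.notna(row["tpm"]) else None,
            )
        )
    return recs


def groups_to_frame(groups: list[IsoformGroup]) -> pd.DataFrame:
    rows = [
        {
            "gene": g.gene,
            "exon_count": g.exon_count,
            "n_members": len(g.members),
            "representative": exons_to_chain(g.representative_exons),
            "members": ";".join(sorted(m.isoform_id for m in g.members)),
        }
        for g in groups
    ]
    return pd.DataFrame(
        rows, columns=["gene", "exon_count", "n_members", "representative", "members"]
    )
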