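"""Curated fusion table packaged with the library.

The package ships a small curated table of fusions that were selected for
in vivo functional testing, together with their Sanger-refined breakpoints,
tumour grade, gene-list involvement and phenotype outcome. The involvement
column uses a compact grammar ("Gene1 CHOP and CCG", "Both CCG", ...) that
is parsed here into per-partner boolean flags; the phenotype column is "-"
or an "&"-joined subset of the measured readouts.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd

PANEL_LABEL = "CHOP"
CENSUS_LABEL = "CCG"
PHENOTYPE_READOUTS = ("VNC Area", "VNC Length")

_FIXTURE = "curated_fusions.tsv"


class CuratedTableError(ValueError):
    pass


@dataclass(frozen=True)
class CuratedFusion:
    fusion: str
    gene5: str
    gene3: str
    breakpoint1: str
    breakpoint2: str
    grade: str
    clinical_indication: str
    involvement: str
    panel_gene5: bool
    panel_gene3: bool
    census_gene5: bool
    census_gene3: bool
    phenotypes: tuple[str, ...]

    @property
    def panel_any(self) -> bool:
        return self.panel_gene5 or self.panel_gene3

    @property
    def census_any(self) -> bool:
        return self.census_gene5 or self.census_gene3

    @property
    def phenotype_any(self) -> bool:
        return bool(self.phenotypes)


def parse_involvement(text: str) -> dict[str, bool]:
    """Parse "<Gene1|Gene2|Both> <CHOP|CCG>[ and <CHOP|CCG>]" into flags."""
    parts = text.strip().split()
    grammar = f"expected '<Gene1|Gene2|Both> <{PANEL_LABEL}|{CENSUS_LABEL}>[ and ...]'"
    if not parts:
        raise CuratedTableError(f"empty involvement field; {grammar}")
    subject, rest = parts[0], parts[1:]
    if subject not in ("Gene1", "Gene2", "Both"):
        raise CuratedTableError(f"bad involvement subject {subject!r}; {grammar}")
    lists = [tok for tok in rest if tok != "and"]
    if not lists or len(lists) != len(rest) - rest.count("and") or any(
        tok not in (PANEL_LABEL, CENSUS_LABEL) for tok in lists
    ):
        raise CuratedTableError(f"bad involvement lists in {text!r}; {grammar}")
    flags = {
        "panel_gene5": False, "panel_gene3": False,
        "census_gene5": False, "census_gene3": False,
    }
    roles = {"Gene1": ("gene5",), "Gene2": ("gene3",), "Both": ("gene5", "gene3")}
    for token in lists:
        key = "panel" if token == PANEL_LABEL else "census"
        for role in roles[subject]:
            flags[f"{key}_{role}"] = True
    return flags


def parse_phenotypes(text: str) -> tuple[str, ...]:
    """Parse "-" or an "&"-joined subset of the phenotype readouts."""
    text = text.strip()
    if text == "-":
        return ()
    readouts = tuple(p.strip() for p in text.split("&"))
    for r in readouts:
        if r not in PHENOTYPE_READOUTS:
            raise CuratedTableError(
                f"unknown phenotype readout {r!r}; expected one of {PHENOTYPE_READOUTS}"
            )
    if len(set(readouts)) != len(readouts):
        raise CuratedTableError(f"duplicate phenotype readout in {text!r}")
    return readouts


def load_curated_table(path: Optional[Path] = None) -> list[CuratedFusion]:
    """Load the packaged curated fusion table (or one from ``path``)."""
    if path is not None:
        text = Path(path).read_text()
    else:
        text = (resources.files("fusionscope") / "data" / _FIXTURE).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    from io import StringIO

    df = pd.read_csv(StringIO("\n".join(lines)), sep="\t", dtype=str)
    required = {"fusion", "breakpoint1", "breakpoint2", "grade",
                "clinical_indication", "involvement", "phenotype"}
    missing = required - set(df.columns)
    if missing:
        raise CuratedTableError(f"curated table missing columns: {sorted(missing)}")
    rows = []
    for _, row in df.iterrows():
        fusion = str(row["fusion"])
        if "::" not in fusion:
            raise CuratedTableError(f"fusion name {fusion!r} lacks '::' separator")
        gene5, gene3 = fusion.split("::", 1)
        grade = str(row["grade"])
        if grade not in ("HGG", "LGG"):
            raise CuratedTableError(f"unknown grade {grade!r} for {fusion}")
        flags = parse_involvement(str(row["involvement"]))
        rows.append(
            CuratedFusion(
                fusion=fusion, gene5=gene5, gene3=gene3,
                breakpoint1=str(row["breakpoint1"]),
                breakpoint2=str(row["breakpoint2"]),
                grade=grade,
                clinical_indication=str(row["clinical_indication"]),
                involvement=str(row["involvement"]),
                phenotypes=parse_phenotypes(str(row["phenotype"])),
                **flags,
            )
        )
    if len({r.fusion for r in rows}) != len(rows):
        raise CuratedTableError("duplicate fusion names in curated table")
    return rows


def summarize_curated_table(rows: list[CuratedFusion]) -> dict:
    """Headline counts for the curated table."""
    by_grade: dict[str, int] = {}
    for r in rows:
        by_grade[r.grade] = by_grade.get(r.grade, 0) + 1
    by_readout = {
        readout: sum(readout in r.phenotypes for r in rows)
        for readout in PHENOTYPE_READOUTS
    }
    return {
        "n_fusions": len(rows),
        "n_panel_any": sum(r.panel_any for r in rows),
        "n_census_any": sum(r.census_any for r in rows),
        "n_phenotype_any": sum(r.phenotype_any for r in rows),
        "n_by_grade": by_grade,
        "n_by_readout": by_readout,
    }


def curated_to_frame(rows: list[CuratedFusion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "fusion": r.fusion, "gene5": r.gene5, "gene3": r.gene3,
                "breakpoint1": r.breakpoint1, "breakpoint2": r.breakpoint2,
                "grade": r.grade,
                "panel_any": r.panel_any, "census_any": r.census_any,
                "phenotypes": "&".join(r.phenotypes) if r.phenotypes else "-",
            }
            for r in rows
        ],
        columns=["fusion", "gene5", "gene3", "breakpoint1", "breakpoint2",
                 "grade", "panel_any", "census_any", "phenotypes"],
    )
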