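"""Prioritization of fusion partner genes against cancer and glioma resources.

Each partner gene is annotated for membership in a clinical fusion panel, the
Cancer Gene Census, a glioma-specific census subset (keyword-extracted from
tumour-type annotations), oncogene / tumour-suppressor lists (union over the
cited sources; a gene may be both), CNS-recurrent fusion partner lists, and
DepMap-style essentiality summaries over glioma cell lines: the maximum
dependency probability (>= 0.9 flags a highly essential candidate) and the
minimum gene effect score (<= -1 flags a potential glioma-essential gene).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .breakpoints import AnnotatedFusion
from .params import DEFAULT_PARAMS, Parameters


class SchemaError(ValueError):
    pass


@dataclass(frozen=True)
class GeneEvidence:
    in_panel: bool = False
    in_census: bool = False
    in_glioma_subset: bool = False
    is_oncogene: bool = False
    is_tsg: bool = False
    max_dependency_prob: Optional[float] = None
    min_gene_effect: Optional[float] = None
    depmap_essential: bool = False
    depmap_effect_hit: bool = False
    cns_fusion_partner: bool = False


@dataclass(frozen=True)
class PrioritizedFusion:
    fusion: AnnotatedFusion
    evidence5: GeneEvidence
    evidence3: GeneEvidence
    onc_tsg_link: bool = False


@dataclass
class Resources:
    panel_genes: set[str] = field(default_factory=set)
    census_genes: set[str] = field(default_factory=set)
    glioma_subset: set[str] = field(default_factory=set)
    oncogenes: set[str] = field(default_factory=set)
    tsgs: set[str] = field(default_factory=set)
    depmap: Optional[pd.DataFrame] = None  # index gene, cols max_dep/min_effect
    cns_partners: set[str] = field(default_factory=set)


def build_glioma_subset(
    census_table: pd.DataFrame,
    keywords: Iterable[str] = DEFAULT_PARAMS.glioma_keywords,
    exclusions: Iterable[str] = DEFAULT_PARAMS.glioma_exclusions,
    gene_col: str = "gene",
    tumour_col: str = "tumour_types",
) -> set[str]:
    """Extract census genes whose tumour-type annotations match glioma keywords.

    Tumour-type fields are tokenized on commas/semicolons/slashes; a token
    matches when any keyword is a case-insensitive substring of it and the
    token does not contain an excluded term, so "glioma" inside
    "paraganglioma" never matches.
    """
    for col in (gene_col, tumour_col):
        if col not in census_table.columns:
            raise SchemaError(f"census table lacks required column {col!r}")
    kw = [k.lower() for k in keywords]
    ex = [e.lower() for e in exclusions]
    out: set[str] = set()
    for gene, types in zip(census_table[gene_col], census_table[tumour_col]):
        if not isinstance(types, str):
            continue
        for token in re.split(r"[,;/]", types):
            token = token.strip().lower()
            if not token:
                continue
            if any(e in token for e in ex):
                continue
            if any(k in token for k in kw):
                out.add(str(gene))
                break
    return out


def depmap_essentiality(
    dep_matrix: pd.DataFrame,
    effect_matrix: pd.DataFrame,
    cell_line_filter: Iterable[str],
    params: Parameters = DEFAULT_PARAMS,
) -> pd.DataFrame:
    """Summarize per-gene essentiality over the selected glioma cell lines.

    Matrices are gene rows x cell-line columns. Returns a frame indexed by
    gene with columns ``max_dep``, ``min_effect``, ``essential`` (max
    dependency probability at or above the 0.9 cutoff) and ``effect_hit``
    (minimum gene effect at or below -1).
    """
    lines = [l for l in cell_line_filter if l in dep_matrix.columns]
    if not lines:
        raise SchemaError("no selected cell line present in the dependency matrix")
    max_dep = dep_matrix[lines].max(axis=1)
    eff_lines = [l for l in cell_line_filter if l in effect_matrix.columns]
    min_eff = effect_matrix[eff_lines].min(axis=1)
    genes = sorted(set(max_dep.index) | set(min_eff.index))
    df = pd.DataFrame(index=genes)
    df["max_dep"] = max_dep.reindex(genes)
    df["min_effect"] = min_eff.reindex(genes)
    df["essential"] = df["max_dep"] >= params.dep_prob_min
    df["effect_hit"] = df["min_effect"] <= params.gene_effect_max
    return df


def gene_evidence(gene: str, resources: Resources,
                  params: Parameters = DEFAULT_PARAMS) -> GeneEvidence:
    max_dep = min_eff = None
    essential = effect_hit = False
    if resources.depmap is not None and gene in resources.depmap.index:
        row = resources.depmap.loc[gene]
        max_dep = None if pd.isna(row["max_dep"]) else float(row["max_dep"])
        min_eff = None if pd.isna(row["min_effect"]) else float(row["min_effect"])
        essential = max_dep is not None and max_dep >= params.dep_prob_min
        effect_hit = min_eff is not None and min_eff <= params.gene_effect_max
    return GeneEvidence(
        in_panel=gene in resources.panel_genes,
        in_census=gene in resources.census_genes,
        in_glioma_subset=gene in resources.glioma_subset,
        is_oncogene=gene in resources.oncogenes,
        is_tsg=gene in resources.tsgs,
        max_dependency_prob=max_dep,
        min_gene_effect=min_eff,
        depmap_essential=essential,
        depmap_effect_hit=effect_hit,
        cns_fusion_partner=gene in resources.cns_partners,
    )


def annotate_fusion_genes(
    fusions: list[AnnotatedFusion],
    resources: Resources,
    params: Parameters = DEFAULT_PARAMS,
) -> list[PrioritizedFusion]:
    """Attach per-partner gene evidence and the oncogene--TSG link flag."""
    out = []
    cache: dict[str, GeneEvidence] = {}
    for f in fusions:
        ev5 = cache.setdefault(f.call.gene5,
                               gene_evidence(f.call.gene5, resources, params))
        ev3 = cache.setdefault(f.call.gene3,
                               gene_evidence(f.call.gene3, resources, params))
        link = (ev5.is_oncogene and ev3.is_tsg) or (ev3.is_oncogene and ev5.is_tsg)
        out.append(PrioritizedFusion(f, ev5, ev3, onc_tsg_link=link))
    return out


_CATEGORIES = [
    ("panel", "in_panel"),
    ("census", "in_census"),
    ("glioma_subset", "in_glioma_subset"),
    ("oncogene", "is_oncogene"),
    ("tsg", "is_tsg"),
    ("depmap_essential", "depmap_essential"),
    ("depmap_effect", "depmap_effect_hit"),
    ("cns_partner", "cns_fusion_partner"),
]


def summarize_prioritization(fusions: list[PrioritizedFusion]) -> pd.DataFrame:
    """Cohort fractions of fusions with each evidence category.

    ``frac_any`` counts fusions with at least one flagged partner;
    ``frac_both`` requires both. Recurrent-partner style categories are also
    reported as unique-gene fractions (``frac_genes``) since counting
    conventions differ between any-partner and unique-gene readings.
    """
    if not fusions:
        return pd.DataFrame()
    n = len(fusions)
    genes: dict[str, GeneEvidence] = {}
    for f in fusions:
        genes[f.fusion.call.gene5] = f.evidence5
        genes[f.fusion.call.gene3] = f.evidence3
    rows = []
    for label, attr in _CATEGORIES:
        any_n = sum(
            1 for f in fusions
            if getattr(f.evidence5, attr) or getattr(f.evidence3, attr)
        )
        both_n = sum(
            1 for f in fusions
            if getattr(f.evidence5, attr) and getattr(f.evidence3, attr)
        )
        gene_n = sum(1 for ev in genes.values() if getattr(ev, attr))
        rows.append({
            "category": label, "n_any": any_n, "frac_any": any_n / n,
            "n_both": both_n, "frac_both": both_n / n,
            "n_genes": gene_n, "frac_genes": gene_n / len(genes),
        })
    link_n = sum(1 for f in fusions if f.onc_tsg_link)
    rows.append({
        "category": "onc_tsg_link", "n_any": link_n, "frac_any": link_n / n,
        "n_both": link_n, "frac_both": link_n / n,
        "n_genes": math.nan, "frac_genes": math.nan,
    })
    return pd.DataFrame(rows).set_index("category")


def prioritized_to_frame(fusions: Iterable[PrioritizedFusion]) -> pd.DataFrame:
    from .breakpoints import annotated_to_frame

    fusions = list(fusions)
    base = annotated_to_frame([f.fusion for f in fusions])
    extra_rows = []
    for f in fusions:
        row = {}
        for role, ev in (("5", f.evidence5), ("3", f.evidence3)):
            for label, attr in _CATEGORIES:
                row[f"{label}{role}"] = getattr(ev, attr)
        row["onc_tsg_link"] = f.onc_tsg_link
        extra_rows.append(row)
    return pd.concat(
        [base.reset_index(drop=True), pd.DataFrame(extra_rows)], axis=1
    )
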