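"""Isoform expression bookkeeping and the two-method consensus DE merge.

The differential-expression fits themselves (edgeR quasi-likelihood, DESeq2
Wald) are consumed as result tables rather than re-fit here; the operations
this module owns are the count-based expression filter applied before those
fits, TPM computation, group-level expression summaries with percentile
ranks, and the consensus rule that retains isoforms significant in both
methods with concordant fold-change direction, reporting the mean log2 fold
change and the maximum FDR across methods.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .params import DEFAULT_PARAMS, Parameters


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class ConsensusDERow:
    isoform_id: str
    mean_log2_fc: float
    max_fdr: float
    direction: str  # up | down


def compute_tpm(counts: pd.DataFrame, effective_lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million from a counts matrix (isoforms x samples).

    tpm_i = (count_i / length_i) / sum_j (count_j / length_j) * 1e6 per
    sample; a sample with no expressed isoform gets an all-zero column.
    Undetected transcripts carry a TPM of zero.
    """
    lengths = effective_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths[lengths.isna()].index[:5])
        raise ValueError(f"effective length missing for isoform(s) {missing}")
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be positive")
    if (counts < 0).any().any():
        raise ValueError("counts must be non-negative")
    rate = counts.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    tpm = rate.div(denom.where(denom > 0, 1.0), axis=1) * 1e6
    return tpm


def expression_filter(
    counts: pd.DataFrame,
    group_labels: pd.Series,
    params: Parameters = DEFAULT_PARAMS,
) -> list[str]:
    """Count-based pre-filter for differential expression.

    An isoform is retained when it has >= ``expr_min_count`` counts in at
    least min-group-size samples and >= ``expr_min_total`` counts summed over
    all samples in the comparison.
    """
    labels = group_labels.reindex(counts.columns)
    if labels.isna().any():
        raise ConfigurationError("every sample column needs a group label")
    sizes = labels.value_counts()
    if len(sizes) < 2:
        raise ConfigurationError("expression filter needs >= 2 groups")
    if (sizes == 0).any():
        raise ConfigurationError("groups must be non-empty")
    min_group = int(sizes.min())
    n_high = (counts >= params.expr_min_count).sum(axis=1)
    total = counts.sum(axis=1)
    keep = (n_high >= min_group) & (total >= params.expr_min_total)
    return list(counts.index[keep])


def _check_de_table(df: pd.DataFrame, label: str) -> pd.DataFrame:
    required = {"isoform_id", "log2_fc", "fdr"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{label}: DE table missing column(s) {sorted(missing)}")
    if df["isoform_id"].duplicated().any():
        dup = df.loc[df["isoform_id"].duplicated(), "isoform_id"].iloc[0]
        raise ValueError(f"{label}: duplicate isoform_id {dup!r}")
    if ((df["fdr"] < 0) | (df["fdr"] > 1)).any():
        raise ValueError(f"{label}: FDR values must lie in [0, 1]")
    return df.set_index("isoform_id")


def consensus_de(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    params: Parameters = DEFAULT_PARAMS,
) -> list[ConsensusDERow]:
    """High-confidence consensus differentially expressed isoforms.

    Keeps isoforms significant in both methods (FDR or adjusted p-value
    <= 0.05 and |log2FC| >= 1, both inclusive) with the same fold-change
    sign; reports the mean log2FC and the maximum significance value.
    """
    a = _check_de_table(results_a, "method A")
    b = _check_de_table(results_b, "method B")

    def significant(df: pd.DataFrame) -> pd.DataFrame:
        return df[(df["fdr"] <= params.de_fdr_max)
                  & (df["log2_fc"].abs() >= params.de_abs_lfc_min)]

    sa, sb = significant(a), significant(b)
    shared = sorted(set(sa.index) & set(sb.index))
    rows = []
    for iso in shared:
        la, lb = float(sa.loc[iso, "log2_fc"]), float(sb.loc[iso, "log2_fc"])
        if np.sign(la) != np.sign(lb):
            continue
        rows.append(
            ConsensusDERow(
                isoform_id=iso,
                mean_log2_fc=(la + lb) / 2.0,
                max_fdr=max(float(sa.loc[iso, "fdr"]), float(sb.loc[iso, "fdr"])),
                direction="up" if la > 0 else "down",
            )
        )
    return rows


def consensus_to_frame(rows: Sequence[ConsensusDERow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"isoform_id": r.isoform_id, "mean_log2_fc": r.mean_log2_fc,
             "max_fdr": r.max_fdr, "direction": r.direction}
            for r in rows
        ],
        columns=["isoform_id", "mean_log2_fc", "max_fdr", "direction"],
    )


def expression_summaries(
    tpm: pd.DataFrame,
    group_labels: pd.Series,
    groups: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-group mean TPM and percentile ranks per isoform.

    Percentile ranks use midranks for ties, scaled to (0, 100]: rank 100
    marks the most highly expressed isoform within a group's mean-TPM
    distribution.
    """
    labels = group_labels.reindex(tpm.columns)
    if labels.isna().any():
        raise ConfigurationError("every sample column needs a group label")
    if groups is None:
        groups = sorted(labels.unique())
    out = pd.DataFrame(index=tpm.index)
    for g in groups:
        cols = [c for c in tpm.columns if labels[c] == g]
        mean = tpm[cols].mean(axis=1)
        out[f"mean_tpm_{g}"] = mean
        out[f"pct_rank_{g}"] = rankdata(mean.to_numpy(), method="average") / len(mean) * 100.0
    return out
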