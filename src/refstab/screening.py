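"""In-silico screening of candidate reference genes from abundance matrices.

Candidates are transcripts whose expression, measured as TPM across the
samples of a tissue group, varies little: the screening statistic is the
coefficient of variation CV% = 100 * SD / mean, computed over all member
samples of the group pooled, with the sample (n-1) standard deviation.
A transcript passes a group when its CV is strictly below the group's
cutoff; transcripts must first clear an expression floor (abundance
strictly above the floor in every sample) and carry an annotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TpmMatrix",
    "TissueGrouping",
    "GroupSummary",
    "apply_expression_floor",
    "compute_group_cv",
    "screen_candidates",
    "shared_across_groups",
    "summarize_group",
]


@dataclass
class TpmMatrix:
    """Transcript abundances (TPM, transcripts x samples) with tissue labels."""

    values: pd.DataFrame
    tissue: pd.Series
    gene_name: pd.Series | None = None  # transcript -> gene symbol
    annotated: pd.Series | None = None  # transcript -> bool

    def __post_init__(self) -> None:
        if (self.values.to_numpy(dtype=float) < 0).any():
            raise ValueError("negative abundances in TPM matrix")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate transcript IDs")
        missing = self.values.columns.difference(self.tissue.index)
        if len(missing):
            raise ValueError(f"samples without tissue label: {sorted(missing)}")

    @property
    def transcripts(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass
class TissueGrouping:
    """Named tissue groups with per-group CV cutoffs (percent)."""

    groups: dict[str, list[str]]
    cutoffs: dict[str, float] = field(default_factory=dict)
    role: str = "screen"

    def __post_init__(self) -> None:
        for name, members in self.groups.items():
            if not members:
                raise ValueError(f"group {name!r} has no member tissues")
        for name, cut in self.cutoffs.items():
            if not cut > 0:
                raise ValueError(f"cutoff for {name!r} must be positive")

    def members(self, group: str) -> list[str]:
        if group not in self.groups:
            raise KeyError(f"unknown group: {group!r}")
        return self.groups[group]

    def cutoff(self, group: str) -> float:
        if group not in self.cutoffs:
            raise KeyError(f"no CV cutoff defined for group {group!r}")
        return self.cutoffs[group]


@dataclass
class GroupSummary:
    """Summary of a group's candidate CV distribution."""

    group: str
    n_transcripts: int
    n_genes: int
    mean_cv: float
    cv_min: float
    cv_max: float
    counts_below: dict[float, int] = field(default_factory=dict)


def apply_expression_floor(matrix: TpmMatrix, floor: float) -> TpmMatrix:
    """Keep transcripts with abundance strictly greater than ``floor`` in every sample."""
    if floor < 0:
        raise ValueError("expression floor must be >= 0")
    keep = (matrix.values > floor).all(axis=1)
    if not keep.any():
        warnings.warn("expression floor removed every transcript", stacklevel=2)
    sub = matrix.values.loc[keep]
    return TpmMatrix(
        sub,
        tissue=matrix.tissue,
        gene_name=None if matrix.gene_name is None else matrix.gene_name.reindex(sub.index),
        annotated=None if matrix.annotated is None else matrix.annotated.reindex(sub.index),
    )


def compute_group_cv(matrix: TpmMatrix, grouping: TissueGrouping, group: str) -> pd.DataFrame:
    """CV% per transcript over the pooled samples of one tissue group.

    Returns a record table with columns ``transcript_id, gene, group,
    cv_percent, undefined``; transcripts with a zero group mean have an
    undefined CV and are flagged and excluded from ``cv_percent``.
    """
    members = set(grouping.members(group))
    cols = [s for s in matrix.samples if matrix.tissue[s] in members]
    if len(cols) < 2:
        raise ValueError(f"group {group!r} needs >= 2 member samples, found {len(cols)}")
    sub = matrix.values[cols]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    undefined = mean == 0
    cv = pd.Series(np.nan, index=sub.index, dtype=float)
    cv[~undefined] = 100.0 * sd[~undefined] / mean[~undefined]
    genes = (matrix.gene_name.reindex(sub.index)
             if matrix.gene_name is not None
             else pd.Series(sub.index, index=sub.index))
    return pd.DataFrame(
        {
            "transcript_id": sub.index,
            "gene": genes.to_numpy(),
            "group": group,
            "cv_percent": cv.to_numpy(),
            "undefined": undefined.to_numpy(),
        }
    ).reset_index(drop=True)


def screen_candidates(records: pd.DataFrame, grouping: TissueGrouping,
                      annotated: pd.Series | None = None) -> pd.DataFrame:
    """Flag records passing their group's CV cutoff (strict ``<``).

    Non-annotated transcripts (``annotated`` False, or a missing gene name
    when no annotation flags are supplied) are dropped before flagging, as
    are records with undefined CV.
    """
    table = records.copy()
    if "undefined" in table.columns:
        table = table[~table["undefined"].astype(bool)].drop(columns="undefined")
    if annotated is not None:
        ann = annotated.reindex(table["transcript_id"]).fillna(False).to_numpy(dtype=bool)
        table = table[ann]
    else:
        table = table[table["gene"].notna()]
    unknown = set(table["group"]) - set(grouping.cutoffs)
    if unknown:
        raise KeyError(f"no CV cutoff defined for groups: {sorted(unknown)}")
    cutoffs = table["group"].map(grouping.cutoffs)
    table["passes_cutoff"] = table["cv_percent"].to_numpy() < cutoffs.to_numpy()
    return table.reset_index(drop=True)


def shared_across_groups(table: pd.DataFrame) -> list[str]:
    """Gene names whose transcript ID appears in more than one group, sorted."""
    if table.empty:
        return []
    per_transcript = table.groupby("transcript_id")["group"].nunique()
    shared_ids = per_transcript.index[per_transcript > 1]
    genes = table.loc[table["transcript_id"].isin(shared_ids), "gene"]
    return sorted(set(genes))


def summarize_group(table: pd.DataFrame, group: str,
                    thresholds: tuple[float, ...] = ()) -> GroupSummary:
    """Mean/min/max CV and transcript/gene counts for one group's records.

    ``thresholds`` adds strict ``cv < t`` transcript counts to the summary.
    """
    sub = table[table["group"] == group]
    if sub.empty:
        raise ValueError(f"no records for group {group!r}")
    cv = sub["cv_percent"]
    return GroupSummary(
        group=group,
        n_transcripts=len(sub),
        n_genes=sub["gene"].nunique(),
        mean_cv=float(cv.mean()),
        cv_min=float(cv.min()),
        cv_max=float(cv.max()),
        counts_below={t: int((cv < t).sum()) for t in thresholds},
    )
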