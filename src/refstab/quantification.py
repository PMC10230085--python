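"""Efficiency-corrected relative quantification against a calibrator tissue.

The expression of a target gene in a sample, relative to a calibrator
tissue and normalized by one or more reference genes, follows the
efficiency-corrected ratio

    ratio = E_t^(Ct_t,cal - Ct_t,s) / GM_r [ E_r^(Ct_r,cal - Ct_r,s) ]

where E is the per-gene amplification factor (2.0 at 100% efficiency),
Ct_.,cal is the gene's mean Ct across the calibrator tissue's samples, and
GM is the geometric mean over the reference genes. With E = 2 everywhere
this reduces exactly to the familiar 2^-ddCt formula.

Group comparison runs a one-way ANOVA on log2 ratios across tissues
followed by all pairwise two-sample t tests with Bonferroni adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .stability import CtMatrix, ct_to_quantity

__all__ = [
    "ComparisonResult",
    "normalization_factor",
    "pfaffl_ratio",
    "compare_groups",
]


@dataclass
class ComparisonResult:
    """One-way ANOVA plus Bonferroni-adjusted pairwise tissue contrasts."""

    target: str | None
    anova_f: float
    anova_p: float
    pairwise: pd.DataFrame  # tissue_a, tissue_b, p_raw, p_adj, significant
    alpha: float = 0.05


def normalization_factor(ct: CtMatrix, references) -> pd.Series:
    """Per-sample geometric mean of the reference genes' relative quantities."""
    refs = list(references)
    if not refs:
        raise ValueError("need at least one reference gene")
    missing = set(refs) - set(ct.genes)
    if missing:
        raise KeyError(f"reference genes absent from Ct matrix: {sorted(missing)}")
    q = ct_to_quantity(ct).loc[refs]
    if (q.to_numpy() <= 0).any():
        raise ValueError("non-positive reference quantity")
    return pd.Series(np.exp(np.log(q.to_numpy()).mean(axis=0)), index=ct.samples)


def pfaffl_ratio(ct: CtMatrix, target: str, references, calibrator: str,
                 efficiencies: pd.Series | None = None) -> pd.DataFrame:
    """Efficiency-corrected relative expression of ``target`` vs. the calibrator.

    Parameters
    ----------
    ct
        Complete mean-Ct matrix with tissue labels.
    references
        Reference gene(s); with several, their per-sample correction terms
        are combined by geometric mean.
    calibrator
        Tissue label used as the reference condition; each gene's calibrator
        Ct is the mean over that tissue's samples (i.e. across animals).
    efficiencies
        Optional per-gene amplification factors overriding the matrix's own
        (default 2.0 everywhere).

    Returns a table with one row per sample: ``target, sample, tissue,
    ratio``; the calibrator tissue's rows average ~1 by construction.
    """
    refs = list(references)
    genes_needed = [target] + refs
    missing = set(genes_needed) - set(ct.genes)
    if missing:
        raise KeyError(f"genes absent from Ct matrix: {sorted(missing)}")
    if ct.tissue is None:
        raise ValueError("Ct matrix needs tissue labels for calibration")
    cal_samples = [s for s in ct.samples if ct.tissue[s] == calibrator]
    if not cal_samples:
        raise ValueError(f"calibrator tissue {calibrator!r} has no samples")
    sub = ct.values.loc[genes_needed]
    if sub[cal_samples].isna().any().any():
        raise ValueError("missing calibrator measurement for a required gene")

    eff = ct.gene_efficiencies()
    if efficiencies is not None:
        eff.update(efficiencies)
    if (eff.loc[genes_needed] <= 1).any():
        raise ValueError("amplification factors must exceed 1")

    cal_ct = sub[cal_samples].mean(axis=1)
    delta = cal_ct.to_numpy()[:, None] - sub.to_numpy()  # (genes, samples)
    log2e = np.log2(eff.loc[genes_needed].to_numpy())[:, None]
    log2_terms = log2e * delta
    log2_target = log2_terms[0]
    log2_ref = log2_terms[1:].mean(axis=0)  # geometric mean over references
    ratio = np.exp2(log2_target - log2_ref)

    return pd.DataFrame(
        {
            "target": target,
            "sample": ct.samples,
            "tissue": ct.tissue.reindex(ct.samples).to_numpy(),
            "ratio": ratio,
        }
    ).reset_index(drop=True)


def compare_groups(ratios: pd.DataFrame, alpha: float = 0.05) -> ComparisonResult:
    """ANOVA across tissues on log2 ratios, then Bonferroni pairwise t tests.

    ``ratios`` needs columns ``tissue`` and ``ratio`` (positive); the
    Bonferroni family is the set of pairwise tissue comparisons for this
    target. Tests are two-tailed.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if (ratios["ratio"] <= 0).any():
        raise ValueError("ratios must be positive")
    tissues = list(pd.unique(ratios["tissue"]))
    if len(tissues) < 2:
        raise ValueError("need at least 2 tissues to compare")
    groups = {t: np.log2(ratios.loc[ratios["tissue"] == t, "ratio"].to_numpy())
              for t in tissues}
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("every tissue needs at least 2 observations")
    if all(np.ptp(v) == 0 for v in groups.values()):
        raise ValueError("degenerate design: zero within-group variance everywhere")

    f_stat, anova_p = stats.f_oneway(*groups.values())

    pairs = list(combinations(tissues, 2))
    n_comp = len(pairs)
    rows = []
    for a, b in pairs:
        t_res = stats.ttest_ind(groups[a], groups[b], equal_var=True)
        p_adj = min(1.0, float(t_res.pvalue) * n_comp)
        rows.append((a, b, float(t_res.pvalue), p_adj, p_adj < alpha))
    pairwise = pd.DataFrame(
        rows, columns=["tissue_a", "tissue_b", "p_raw", "p_adj", "significant"]
    )
    target = ratios["target"].iloc[0] if "target" in ratios.columns else None
    return ComparisonResult(target, float(f_stat), float(anova_p), pairwise, alpha)
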