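"""Expression-stability algorithms for candidate reference genes.

Four rankings operating on a matrix of mean quantification cycles
(Ct, genes x samples):

* geNorm -- average pairwise variation M with stepwise exclusion and the
  pairwise-variation series V(n/n+1);
* NormFinder -- model-based variance decomposition (ungrouped estimator by
  default, tissue-grouped variant opt-in);
* BestKeeper -- raw-Ct descriptive statistics and correlation with the
  per-sample geometric-mean index;
* comparative delta-Ct -- mean standard deviation of pairwise Ct differences.

All methods agree on the convention that *lower* stability values mean *more*
stable expression, and every ranking assigns rank 1 to the most stable gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ranking import rank_values

__all__ = [
    "CtMatrix",
    "StabilityTable",
    "GenormResult",
    "BestkeeperResult",
    "reduce_replicates",
    "ct_to_quantity",
    "genorm",
    "normfinder",
    "bestkeeper",
    "delta_ct",
    "run_all_methods",
]

DEFAULT_EFFICIENCY = 2.0  # amplification factor per cycle at 100% efficiency


@dataclass
class CtMatrix:
    """Mean quantification cycles for a gene x sample panel.

    Parameters
    ----------
    values
        DataFrame of mean Ct values, genes as rows, samples as columns.
    tissue
        Optional mapping sample id -> tissue label.
    efficiency
        Optional per-gene amplification factor (fold increase per cycle,
        e.g. 2.0 at 100% efficiency). Genes without an entry fall back to 2.0.
    replicates
        Optional long-format table of technical replicates with columns
        ``sample, gene, replicate, ct``; kept for provenance, all
        computations use ``values``.
    """

    values: pd.DataFrame
    tissue: pd.Series | None = None
    efficiency: pd.Series | None = None
    replicates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene IDs in Ct matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample IDs in Ct matrix")
        finite = np.isfinite(self.values.to_numpy(dtype=float)) | self.values.isna().to_numpy()
        if not finite.all():
            raise ValueError("non-finite Ct values present")
        if self.efficiency is not None and (self.efficiency <= 1).any():
            raise ValueError("amplification factors must exceed 1 (fold per cycle)")
        if self.tissue is not None:
            missing = self.values.columns.difference(self.tissue.index)
            if len(missing):
                raise ValueError(f"samples without tissue label: {sorted(missing)}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def gene_efficiencies(self) -> pd.Series:
        """Per-gene amplification factor, defaulting to 2.0."""
        eff = pd.Series(DEFAULT_EFFICIENCY, index=self.genes, dtype=float)
        if self.efficiency is not None:
            eff.update(self.efficiency)
        return eff

    def subset_tissues(self, tissues) -> "CtMatrix":
        """Restrict to samples whose tissue label is in ``tissues``."""
        if self.tissue is None:
            raise ValueError("Ct matrix carries no tissue labels")
        keep = [s for s in self.samples if self.tissue[s] in set(tissues)]
        if not keep:
            raise ValueError(f"no samples for tissues {sorted(set(tissues))}")
        return CtMatrix(
            self.values[keep],
            tissue=self.tissue[keep],
            efficiency=self.efficiency,
            replicates=None if self.replicates is None
            else self.replicates[self.replicates["sample"].isin(keep)],
        )

    def subset_genes(self, genes) -> "CtMatrix":
        return CtMatrix(
            self.values.loc[list(genes)],
            tissue=self.tissue,
            efficiency=self.efficiency,
            replicates=None if self.replicates is None
            else self.replicates[self.replicates["gene"].isin(set(genes))],
        )

    def dropna(self) -> "CtMatrix":
        """Drop genes with any missing cell (the algorithms require complete data)."""
        return CtMatrix(self.values.dropna(axis=0), tissue=self.tissue,
                        efficiency=self.efficiency, replicates=self.replicates)


@dataclass
class StabilityTable:
    """Per-gene stability values and ranks for one method (1 = most stable)."""

    method: str
    values: pd.Series
    ranks: pd.Series
    group: str | None = None
    n_samples: int | None = None

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.ranks = self.ranks.astype(float)
        if not self.values.index.equals(self.ranks.index):
            self.ranks = self.ranks.reindex(self.values.index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "method": self.method,
                "gene": self.values.index,
                "value": self.values.to_numpy(),
                "rank": self.ranks.to_numpy(),
            }
        )


@dataclass
class GenormResult:
    """Full geNorm output: elimination trace, final pair, V series."""

    stability: StabilityTable
    m_per_round: list[pd.Series]
    elimination_order: list[str]
    final_pair: tuple[str, str]
    pairwise_variation: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))


@dataclass
class BestkeeperResult:
    stability: StabilityTable
    descriptives: pd.DataFrame
    index: pd.Series  # per-sample geometric mean of Ct across genes


def reduce_replicates(ct_long: pd.DataFrame, tissue: pd.Series | None = None,
                      efficiency: pd.Series | None = None) -> CtMatrix:
    """Average technical replicates to one mean Ct per (gene, sample).

    ``ct_long`` must have columns ``sample, gene, ct`` (``replicate`` is
    optional and only used for duplicate detection upstream).
    """
    required = {"sample", "gene", "ct"}
    if not required.issubset(ct_long.columns):
        raise ValueError(f"long Ct table needs columns {sorted(required)}")
    wide = ct_long.pivot_table(index="gene", columns="sample", values="ct",
                               aggfunc="mean")
    wide = wide.loc[pd.unique(ct_long["gene"]), pd.unique(ct_long["sample"])]
    wide.index.name = None
    wide.columns.name = None
    return CtMatrix(wide, tissue=tissue, efficiency=efficiency,
                    replicates=ct_long.copy())


def ct_to_quantity(ct: CtMatrix) -> pd.DataFrame:
    """Efficiency-scaled relative quantities Q = E^(min Ct - Ct), max 1 per gene."""
    eff = ct.gene_efficiencies()
    delta = ct.values.min(axis=1).to_numpy()[:, None] - ct.values.to_numpy()
    q = np.power(eff.to_numpy()[:, None], delta)
    return pd.DataFrame(q, index=ct.genes, columns=ct.samples)


def _log2_quantities(ct: CtMatrix) -> pd.DataFrame:
    eff = ct.gene_efficiencies()
    delta = ct.values.min(axis=1).to_numpy()[:, None] - ct.values.to_numpy()
    return pd.DataFrame(np.log2(eff.to_numpy())[:, None] * delta,
                        index=ct.genes, columns=ct.samples)


def _check_complete(ct: CtMatrix, op: str) -> None:
    if ct.values.isna().any().any():
        raise ValueError(
            f"{op} requires a complete Ct matrix; drop genes/samples with "
            "missing cells (see CtMatrix.dropna) before calling"
        )


def _pairwise_sd(y: np.ndarray) -> np.ndarray:
    """k x k matrix of SD over samples of row differences (ddof=1)."""
    diffs = y[:, None, :] - y[None, :, :]
    return diffs.std(axis=2, ddof=1)


def genorm(ct: CtMatrix) -> GenormResult:
    """geNorm stepwise stability analysis.

    The gene-stability measure M_j is the mean, over all partner genes k, of
    the standard deviation across samples of the log2 expression ratio
    Q_j/Q_k. The gene with the largest M is removed and M recomputed until
    two genes remain; those two are the most stable pair and share rank 1.

    Also returns the pairwise variation V(n/n+1) between normalization
    factors built from the n and n+1 most stable genes, geNorm's criterion
    for how many reference genes are needed.
    """
    _check_complete(ct, "geNorm")
    genes = list(ct.genes)
    if len(genes) < 3:
        raise ValueError("geNorm requires at least 3 genes")
    if len(ct.samples) < 2:
        raise ValueError("geNorm requires at least 2 samples")

    y_full = _log2_quantities(ct)
    remaining = list(genes)
    m_per_round: list[pd.Series] = []
    elimination: list[str] = []
    values = pd.Series(np.nan, index=pd.Index(genes), dtype=float)

    while len(remaining) >= 2:
        y = y_full.loc[remaining].to_numpy()
        k = len(remaining)
        sd = _pairwise_sd(y)
        m = pd.Series(sd.sum(axis=1) / (k - 1), index=remaining)
        m_per_round.append(m)
        if k == 2:
            values[remaining] = m
            break
        # remove the least stable gene; ties broken by gene id for determinism
        worst = m.sort_index().idxmax()
        values[worst] = m[worst]
        elimination.append(worst)
        remaining.remove(worst)

    final_pair = tuple(sorted(remaining))
    # stability order: final pair first, then reverse elimination
    stable_order = list(final_pair) + elimination[::-1]
    # ranks: joint pair at 1, then dense 2, 3, ...
    ranks = pd.Series(index=pd.Index(genes), dtype=float)
    ranks[list(final_pair)] = 1.0
    for i, g in enumerate(elimination[::-1]):
        ranks[g] = 2.0 + i

    # pairwise variation V(n/n+1)
    v_vals, v_labels = [], []
    for n in range(2, len(genes)):
        nf_n = y_full.loc[stable_order[:n]].mean(axis=0)
        nf_n1 = y_full.loc[stable_order[: n + 1]].mean(axis=0)
        v_vals.append(float((nf_n - nf_n1).std(ddof=1)))
        v_labels.append(f"V{n}/{n + 1}")
    pairwise_variation = pd.Series(v_vals, index=v_labels, dtype=float)

    table = StabilityTable("genorm", values, ranks, n_samples=len(ct.samples))
    return GenormResult(table, m_per_round, elimination, final_pair,
                        pairwise_variation)


def normfinder(ct: CtMatrix, groups: pd.Series | None = None) -> StabilityTable:
    """NormFinder model-based stability.

    Ungrouped default: on y = log2 quantities, each sample column is centred
    on its across-gene mean; z_i is the sample variance of gene i's centred
    profile, and the per-gene variance estimate is

        sigma_i^2 = max(0, (z_i - sum_l z_l / (k (k - 1))) * k / (k - 2)),

    an unbiased estimator under the additive gene + sample + noise model.
    The stability value is sigma_i (a standard deviation, in log2 units).

    With ``groups`` (sample -> group label, e.g. tissues), an opt-in grouped
    variant applies the same estimator within each group and adds the
    inter-group deviation of gene means; see the methods documentation.
    """
    _check_complete(ct, "NormFinder")
    k = len(ct.genes)
    if k < 3:
        raise ValueError("NormFinder needs at least 3 genes (k >= 3)")
    if len(ct.samples) < 3:
        raise ValueError("NormFinder needs at least 3 samples")
    y = _log2_quantities(ct)

    if groups is None:
        var = _normfinder_variances(y.to_numpy())
        stab = pd.Series(np.sqrt(var), index=ct.genes)
    else:
        groups = groups.reindex(ct.samples)
        if groups.isna().any():
            raise ValueError("every sample needs a group label")
        labels = groups.unique()
        if len(labels) < 2:
            raise ValueError("grouped NormFinder needs >= 2 groups")
        d = y - y.mean(axis=0)  # centre on per-sample across-gene mean
        group_means = {}
        intra = {}
        for lab in labels:
            cols = groups.index[groups == lab]
            if len(cols) < 2:
                raise ValueError(f"group {lab!r} has fewer than 2 samples")
            sub = d[cols]
            group_means[lab] = sub.mean(axis=1)
            intra[lab] = pd.Series(
                _normfinder_variances(y[cols].to_numpy()), index=ct.genes
            )
        gm = pd.DataFrame(group_means)
        gm = gm.sub(gm.mean(axis=1), axis=0)  # gene-wise deviation across groups
        stab = pd.Series(0.0, index=ct.genes)
        for lab in labels:
            n_g = int((groups == lab).sum())
            stab += gm[lab].abs() + np.sqrt(intra[lab] / n_g)
        stab /= len(labels)

    ranks = rank_values(stab, ties="average")
    return StabilityTable("normfinder", stab, ranks, n_samples=len(ct.samples))


def _normfinder_variances(y: np.ndarray) -> np.ndarray:
    k = y.shape[0]
    d = y - y.mean(axis=0, keepdims=True)
    z = d.var(axis=1, ddof=1)
    return np.maximum(0.0, (z - z.sum() / (k * (k - 1))) * k / (k - 2))


def bestkeeper(ct: CtMatrix) -> BestkeeperResult:
    """BestKeeper descriptive stability on raw Ct values.

    Per gene: arithmetic mean, min, max, SD (mean absolute deviation from
    the arithmetic mean -- the method's published convention), CV% =
    100*SD/mean, and Pearson correlation with the BestKeeper index (the
    per-sample geometric mean of Ct across genes). Genes are ranked by SD
    ascending; SD > 1 cycle is flagged as inconsistent.
    """
    _check_complete(ct, "BestKeeper")
    if len(ct.genes) < 2:
        raise ValueError("BestKeeper needs at least 2 genes")
    if len(ct.samples) < 3:
        raise ValueError("BestKeeper needs at least 3 samples")
    vals = ct.values
    mean = vals.mean(axis=1)
    mad = (vals.sub(mean, axis=0)).abs().mean(axis=1)
    index = pd.Series(
        np.exp(np.log(vals.to_numpy()).mean(axis=0)), index=ct.samples
    )
    r = vals.apply(lambda row: _pearson(row.to_numpy(), index.to_numpy()), axis=1)
    desc = pd.DataFrame(
        {
            "n": len(ct.samples),
            "mean_ct": mean,
            "min_ct": vals.min(axis=1),
            "max_ct": vals.max(axis=1),
            "sd": mad,
            "cv_percent": 100.0 * mad / mean,
            "r_index": r,
            "inconsistent": mad > 1.0,
        }
    )
    ranks = rank_values(mad, ties="average")
    table = StabilityTable("bestkeeper", mad, ranks, n_samples=len(ct.samples))
    return BestkeeperResult(table, desc, index)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc, yc = x - x.mean(), y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        # degenerate: at least one constant vector; perfect-tracking convention
        return 1.0 if np.allclose(xc, yc) else np.nan
    return float((xc * yc).sum() / denom)


def delta_ct(ct: CtMatrix) -> StabilityTable:
    """Comparative delta-Ct stability.

    For each ordered gene pair (i, j != i) take the standard deviation
    across samples of Ct_i - Ct_j; gene i's stability is the mean of those
    SDs over partners j. The gene with the lowest mean SD is the most
    stable.
    """
    _check_complete(ct, "delta-Ct")
    if len(ct.genes) < 2:
        raise ValueError("delta-Ct needs at least 2 genes")
    if len(ct.samples) < 2:
        raise ValueError("delta-Ct needs at least 2 samples")
    y = ct.values.to_numpy()
    sd = _pairwise_sd(y)
    k = len(ct.genes)
    stab = pd.Series(sd.sum(axis=1) / (k - 1), index=ct.genes)
    ranks = rank_values(stab, ties="average")
    return StabilityTable("deltact", stab, ranks, n_samples=len(ct.samples))


def run_all_methods(ct: CtMatrix, methods=("genorm", "normfinder", "bestkeeper", "deltact"),
                    group: str | None = None) -> dict[str, StabilityTable]:
    """Run the requested stability methods and tag results with a group name."""
    out: dict[str, StabilityTable] = {}
    for name in methods:
        if name == "genorm":
            table = genorm(ct).stability
        elif name == "normfinder":
            table = normfinder(ct)
        elif name == "bestkeeper":
            table = bestkeeper(ct).stability
        elif name == "deltact":
            table = delta_ct(ct)
        else:
            raise ValueError(f"unknown stability method: {name!r}")
        table.group = group
        out[name] = table
    return out
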