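"""Comprehensive ranking of reference genes by geometric mean of ranks.

Each stability algorithm orders the candidate genes on its own scale; the
comprehensive (RefFinder-style) ranking reduces every method to ranks,
takes the geometric mean of each gene's ranks across methods, and orders
genes by that geometric mean (smaller = more stable).
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = ["rank_values", "rank_method", "reffinder_aggregate"]


def rank_values(values: pd.Series, ties: str = "average") -> pd.Series:
    """Rank stability values ascending (1 = most stable).

    ``ties`` follows pandas conventions; ``"average"`` is the standard tie
    rule, ``"dense"`` implements the geNorm joint-pair convention where the
    final pair shares rank 1 and the next gene takes rank 2.
    """
    if values.isna().any():
        raise ValueError("cannot rank: missing stability values")
    return values.rank(method=ties, ascending=True)


def rank_method(stability, ties: str | None = None) -> pd.Series:
    """Gene -> rank for one method's stability table.

    Accepts a :class:`~refstab.stability.StabilityTable` (its precomputed
    ranks are returned as-is unless ``ties`` overrides the convention) or a
    plain Series of stability values.
    """
    if hasattr(stability, "values") and hasattr(stability, "method"):
        if ties is None:
            return stability.ranks.copy()
        return rank_values(stability.values, ties=ties)
    return rank_values(stability, ties=ties or "average")


def reffinder_aggregate(rankings) -> pd.DataFrame:
    """Geometric-mean-of-ranks aggregation across >= 2 methods.

    Parameters
    ----------
    rankings
        Either a mapping ``method name -> Series(gene -> rank)`` or an
        iterable of StabilityTable objects. All methods must cover the
        identical gene set.

    Returns
    -------
    DataFrame indexed by gene with one ``rank_<method>`` column per method,
    ``geomean``, and ``final_rank`` (ascending by geometric mean, ties
    broken by gene ID for deterministic output).
    """
    ranks = _as_rank_mapping(rankings)
    if len(ranks) < 2:
        raise ValueError("comprehensive ranking needs at least 2 methods")
    methods = list(ranks)
    reference = set(ranks[methods[0]].index)
    for name in methods[1:]:
        other = set(ranks[name].index)
        if other != reference:
            missing = sorted(reference ^ other)
            raise ValueError(
                f"gene sets differ between methods ({methods[0]!r} vs {name!r}); "
                f"symmetric difference: {missing}"
            )

    table = pd.DataFrame({f"rank_{m}": ranks[m] for m in methods})
    table = table.sort_index()
    log_ranks = np.log(table.to_numpy(dtype=float))
    table["geomean"] = np.exp(log_ranks.mean(axis=1))
    order = table["geomean"].sort_values(kind="mergesort").index  # index is sorted: ties -> gene ID
    table.loc[order, "final_rank"] = np.arange(1, len(table) + 1, dtype=float)
    return table.loc[order]


def _as_rank_mapping(rankings) -> dict[str, pd.Series]:
    if isinstance(rankings, Mapping):
        return {str(k): pd.Series(v) for k, v in rankings.items()}
    if isinstance(rankings, Iterable):
        out: dict[str, pd.Series] = {}
        for item in rankings:
            if not hasattr(item, "method"):
                raise TypeError("expected StabilityTable objects or a mapping of ranks")
            out[item.method] = item.ranks
        return out
    raise TypeError("unsupported rankings input")
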