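"""Primer amplification-efficiency estimation from dilution series.

A standard curve plots mean Ct against log10 template concentration for a
serial dilution; the slope m of the ordinary least-squares line gives the
amplification efficiency

    E% = (10^(-1/m) - 1) * 100,

100% meaning perfect doubling per cycle (m = -1/log10(2) ~ -3.32). Assays
are accepted when E falls inside a QC band (98-102% by default, inclusive);
failures are flagged, not discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DilutionSeries",
    "EfficiencyRecord",
    "fit_dilution",
    "efficiency_from_slope",
    "evaluate_series",
    "qc_filter",
]


@dataclass
class DilutionSeries:
    """One primer pair's standard curve: (concentration, mean Ct) points."""

    primer_id: str
    concentration: np.ndarray  # template amount, e.g. ng/uL
    ct: np.ndarray             # mean Ct per dilution point

    def __post_init__(self) -> None:
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.ct = np.asarray(self.ct, dtype=float)
        if self.concentration.shape != self.ct.shape:
            raise ValueError("concentration and ct must have equal length")
        if (self.concentration <= 0).any():
            raise ValueError("concentrations must be positive")
        if len(np.unique(self.concentration)) < 2:
            raise ValueError("need at least 2 distinct concentrations")
        if not np.isfinite(self.ct).all():
            raise ValueError("non-finite Ct in dilution series")

    @classmethod
    def from_replicates(cls, primer_id: str, table: pd.DataFrame) -> "DilutionSeries":
        """Average replicate Cts per concentration (columns: concentration, ct)."""
        mean = table.groupby("concentration")["ct"].mean().sort_index(ascending=False)
        return cls(primer_id, mean.index.to_numpy(), mean.to_numpy())


@dataclass
class EfficiencyRecord:
    primer_id: str
    slope: float
    intercept: float
    r_squared: float
    efficiency_percent: float
    qc_pass: bool | None = None


def fit_dilution(series: DilutionSeries) -> tuple[float, float, float]:
    """OLS fit of Ct on log10(concentration): returns (slope, intercept, r^2)."""
    x = np.log10(series.concentration)
    fit = stats.linregress(x, series.ct)
    # r is nan when Ct is constant; a flat line still has a defined slope of 0
    r2 = float(fit.rvalue**2) if np.isfinite(fit.rvalue) else 0.0
    return float(fit.slope), float(fit.intercept), r2


def efficiency_from_slope(m: float) -> float:
    """Amplification efficiency in percent, E = (10^(-1/m) - 1) * 100."""
    if m == 0:
        raise ValueError("slope must be non-zero")
    if m > 0:
        warnings.warn(
            "positive standard-curve slope: implausible assay "
            "(Ct should decrease with template amount)",
            stacklevel=2,
        )
    return float((10.0 ** (-1.0 / m) - 1.0) * 100.0)


def evaluate_series(series: DilutionSeries, low: float = 98.0,
                    high: float = 102.0) -> EfficiencyRecord:
    """Fit one dilution series and apply the QC band."""
    m, b, r2 = fit_dilution(series)
    e = efficiency_from_slope(m)
    return EfficiencyRecord(series.primer_id, m, b, r2, e,
                            qc_pass=bool(low <= e <= high))


def qc_filter(records, low: float = 98.0, high: float = 102.0) -> list[EfficiencyRecord]:
    """Set the (inclusive) QC flag on each record; failures are kept, flagged."""
    if not low < high:
        raise ValueError("QC band requires low < high")
    out = []
    for rec in records:
        rec.qc_pass = bool(low <= rec.efficiency_percent <= high)
        out.append(rec)
    return out


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "primer_id": [r.primer_id for r in records],
            "slope": [r.slope for r in records],
            "intercept": [r.intercept for r in records],
            "r_squared": [r.r_squared for r in records],
            "efficiency_percent": [r.efficiency_percent for r in records],
            "qc_pass": [r.qc_pass for r in records],
        }
    )
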