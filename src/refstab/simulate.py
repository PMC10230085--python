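"""Synthetic qPCR and RNA-seq data with known ground truth.

Every downstream stage of the pipeline (screening, efficiency QC, stability
ranking, quantification) is exercised against data generated here, where the
stable/unstable status of each gene, the tissue effect sizes, and the true
amplification efficiencies are known by construction.

The Ct generator follows an additive random-effects model on the cycle scale:

    Ct(g, t, a, r) = B_g + D_{g,t} + A_a + eps_{g,t,a,r}

with gene baseline B_g uniform on a plausible Ct window, a tissue effect
D_{g,t} drawn once per (gene, tissue) and shared across animals (structured,
tissue-specific instability rather than i.i.d. noise), an animal random
effect A_a, and technical-replicate noise eps. Planted "stable" genes get a
small tissue-effect SD and "unstable" genes a large one; the generator
returns the truth so rank-recovery can be scored.

The default design mirrors a 12-tissue x 5-animal x 3-replicate panel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .efficiency import DilutionSeries
from .stability import CtMatrix, reduce_replicates

__all__ = [
    "DEFAULT_TISSUES",
    "SimDesign",
    "SyntheticTruth",
    "simulate_ct_matrix",
    "simulate_tpm_matrix",
    "simulate_dilution_series",
]

# Tissue vocabulary of the octopus panel: central brain masses (SEM, SUB, OL),
# peripheral ganglia (GG, StG), gill, mantle muscle, arm pieces and tips.
DEFAULT_TISSUES = (
    "SEM", "SUB", "OL", "GG", "StG", "GILL", "MANT",
    "ARM_R1", "ARM_R4", "MUSC_R1", "Tip_R1", "Tip_R4",
)


@dataclass
class SimDesign:
    """Parameters of the synthetic Ct panel (all SDs in Ct cycles)."""

    n_genes: int = 20
    n_tissues: int = 12
    n_animals: int = 5
    n_tech_reps: int = 3
    baseline_ct_range: tuple[float, float] = (18.0, 32.0)
    sigma_stable: float = 0.1
    sigma_unstable: float = 1.5
    frac_stable: float = 0.25
    sigma_animal: float = 0.3
    sigma_tech: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_genes, self.n_tissues, self.n_animals, self.n_tech_reps)
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        sds = (self.sigma_stable, self.sigma_unstable, self.sigma_animal, self.sigma_tech)
        if any(not math.isfinite(s) or s < 0 for s in sds):
            raise ValueError("all SDs must be finite and >= 0")
        if not 0.0 <= self.frac_stable <= 1.0:
            raise ValueError("frac_stable must lie in [0, 1]")
        lo, hi = self.baseline_ct_range
        if not (math.isfinite(lo) and math.isfinite(hi) and lo <= hi):
            raise ValueError("invalid baseline Ct range")

    def tissue_labels(self) -> list[str]:
        if self.n_tissues <= len(DEFAULT_TISSUES):
            return list(DEFAULT_TISSUES[: self.n_tissues])
        return [f"T{i + 1:02d}" for i in range(self.n_tissues)]


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated panel: per-gene class and realized SDs."""

    table: pd.DataFrame  # index gene; columns is_stable, tissue_effect_sd, baseline

    @property
    def stable_genes(self) -> list[str]:
        return list(self.table.index[self.table["is_stable"]])

    @property
    def ordering(self) -> list[str]:
        """Genes from most to least stable by realized tissue-effect SD."""
        return list(self.table["tissue_effect_sd"].sort_values(kind="mergesort").index)


def simulate_ct_matrix(design: SimDesign) -> tuple[CtMatrix, SyntheticTruth]:
    """Draw a replicate-level Ct panel and its ground truth.

    Samples are named ``<tissue>_A<animal>``; the returned matrix carries the
    full technical-replicate table and the per-cell mean Ct (the averaging
    itself is done by :func:`refstab.stability.reduce_replicates`).
    """
    rng = np.random.default_rng(design.seed)
    genes = [f"g{i + 1:03d}" for i in range(design.n_genes)]
    tissues = design.tissue_labels()
    animals = [f"A{a + 1}" for a in range(design.n_animals)]

    n_stable = int(round(design.frac_stable * design.n_genes))
    is_stable = np.zeros(design.n_genes, dtype=bool)
    is_stable[:n_stable] = True

    lo, hi = design.baseline_ct_range
    baseline = rng.uniform(lo, hi, size=design.n_genes)
    sds = np.where(is_stable, design.sigma_stable, design.sigma_unstable)
    tissue_eff = rng.normal(0.0, 1.0, size=(design.n_genes, design.n_tissues)) * sds[:, None]
    animal_eff = rng.normal(0.0, design.sigma_animal, size=design.n_animals)
    noise = rng.normal(
        0.0, design.sigma_tech,
        size=(design.n_genes, design.n_tissues, design.n_animals, design.n_tech_reps),
    ) if design.sigma_tech > 0 else np.zeros(
        (design.n_genes, design.n_tissues, design.n_animals, design.n_tech_reps)
    )

    ct = (
        baseline[:, None, None, None]
        + tissue_eff[:, :, None, None]
        + animal_eff[None, None, :, None]
        + noise
    )

    records = []
    for gi, g in enumerate(genes):
        for ti, t in enumerate(tissues):
            for ai, a in enumerate(animals):
                sample = f"{t}_{a}"
                for r in range(design.n_tech_reps):
                    records.append((sample, t, a, g, r + 1, ct[gi, ti, ai, r]))
    long = pd.DataFrame(
        records, columns=["sample", "tissue", "animal", "gene", "replicate", "ct"]
    )

    tissue_map = (
        long[["sample", "tissue"]].drop_duplicates().set_index("sample")["tissue"]
    )
    matrix = reduce_replicates(long, tissue=tissue_map)

    realized_sd = tissue_eff.std(axis=1, ddof=1) if design.n_tissues > 1 else np.zeros(design.n_genes)
    truth = SyntheticTruth(
        pd.DataFrame(
            {
                "is_stable": is_stable,
                "tissue_effect_sd": realized_sd,
                "baseline": baseline,
            },
            index=pd.Index(genes, name="gene"),
        )
    )
    return matrix, truth


def simulate_tpm_matrix(n_transcripts: int, tissues, target_cv, seed: int,
                        log10_mean_range: tuple[float, float] = (0.5, 3.0)):
    """Lognormal TPM abundances with a controlled coefficient of variation.

    Parameters
    ----------
    tissues
        Sequence of tissue labels, one per sample (samples are named
        ``s0001`` onward).
    target_cv
        Target CV in percent, scalar or one value per transcript. The
        lognormal log-SD solves CV = sqrt(exp(sigma^2) - 1), so realized
        CVs converge to the target as samples grow.
    """
    from .screening import TpmMatrix

    target = np.broadcast_to(np.asarray(target_cv, dtype=float), (n_transcripts,)).copy()
    if (target < 0).any():
        raise ValueError("target CV must be >= 0")
    tissues = list(tissues)
    n_samples = len(tissues)
    rng = np.random.default_rng(seed)

    cv_frac = target / 100.0
    sigma = np.sqrt(np.log1p(cv_frac**2))
    log10_median = rng.uniform(*log10_mean_range, size=n_transcripts)
    mu = np.log(10.0**log10_median)
    z = rng.normal(size=(n_transcripts, n_samples))
    values = np.exp(mu[:, None] + sigma[:, None] * z)

    transcripts = [f"tr{i + 1:05d}" for i in range(n_transcripts)]
    samples = [f"s{j + 1:04d}" for j in range(n_samples)]
    frame = pd.DataFrame(values, index=transcripts, columns=samples)
    tissue_map = pd.Series(tissues, index=samples)
    gene_name = pd.Series([f"gene_{t}" for t in transcripts], index=transcripts)
    return TpmMatrix(frame, tissue=tissue_map, gene_name=gene_name,
                     annotated=pd.Series(True, index=frame.index))


def simulate_dilution_series(true_eff_percent: float, intercept_ct: float,
                             concentrations, noise_sd: float, seed: int,
                             primer_id: str = "primer") -> DilutionSeries:
    """Standard-curve points with a known true amplification efficiency.

    Ct = intercept + m * log10(conc) + noise with m = -1/log10(1 + E/100),
    so a perfectly doubling assay (E = 100) loses ~3.32 cycles per decade.
    """
    if not 0.0 < true_eff_percent <= 150.0:
        raise ValueError("true efficiency must lie in (0, 150] percent")
    conc = np.asarray(concentrations, dtype=float)
    if (conc <= 0).any():
        raise ValueError("concentrations must be positive")
    if noise_sd < 0:
        raise ValueError("noise SD must be >= 0")
    m = -1.0 / math.log10(1.0 + true_eff_percent / 100.0)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=conc.shape) if noise_sd > 0 else 0.0
    ct = intercept_ct + m * np.log10(conc) + noise
    return DilutionSeries(primer_id, conc, ct)
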