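"""Pipeline configuration and end-to-end orchestration.

``run_pipeline`` wires the stages together: candidate screening on a TPM
matrix, primer-efficiency QC, the four stability algorithms per tissue
group, comprehensive ranking, and (optionally) relative quantification of
target genes. Inputs may come from files or from the synthetic generator;
every output table plus a JSON run log (seed, parameters, versions) lands
in the output directory, and a rerun with the same seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .efficiency import evaluate_series, records_to_frame
from .io import write_stability_table, write_table
from .quantification import compare_groups, pfaffl_ratio
from .ranking import reffinder_aggregate
from .screening import TissueGrouping, compute_group_cv, screen_candidates, summarize_group
from .simulate import SimDesign, simulate_ct_matrix, simulate_dilution_series, simulate_tpm_matrix
from .stability import run_all_methods

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline",
           "default_screen_grouping", "default_stability_groups"]

logger = logging.getLogger("refstab")

# Tissues covered by the transcriptome screen (no GILL/MANT/Tip_R4 there).
SCREEN_TISSUES = ["OL", "SEM", "SUB", "Tip_R1", "ARM_R1", "MUSC_R1",
                  "ARM_R4", "StG", "GG"]

NERVOUS = ["SEM", "SUB", "OL", "GG", "StG"]
ALLEX = NERVOUS + ["GILL", "MANT", "ARM_R1", "ARM_R4", "MUSC_R1"]
ADULT_ALL = ALLEX + ["Tip_R1", "Tip_R4"]


def default_screen_grouping() -> TissueGrouping:
    """Screening groups with CV cutoffs in percent (Adult is looser at 20%)."""
    return TissueGrouping(
        groups={
            "Adult": list(SCREEN_TISSUES),
            "Brain": ["SEM", "SUB", "OL"],
            "Nervous": ["SEM", "SUB", "OL", "StG", "GG"],
            "Arm": ["Tip_R1", "ARM_R1", "ARM_R4", "MUSC_R1"],
        },
        cutoffs={"Adult": 20.0, "Brain": 15.0, "Nervous": 15.0, "Arm": 15.0},
        role="screen",
    )


def default_stability_groups() -> dict[str, list[str]]:
    """Stability groups of increasing biological variability."""
    return {"Nervous": list(NERVOUS), "Allex": list(ALLEX), "Adult": list(ADULT_ALL)}


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str | Path = "refstab_out"
    design: SimDesign = field(default_factory=SimDesign)
    methods: tuple[str, ...] = ("genorm", "normfinder", "bestkeeper", "deltact")
    efficiency_band: tuple[float, float] = (98.0, 102.0)
    alpha: float = 0.05
    expression_floor: float = 1.5
    screen_grouping: TissueGrouping = field(default_factory=default_screen_grouping)
    stability_groups: dict[str, list[str]] = field(default_factory=default_stability_groups)
    # quantification (optional): empty targets means the stage is skipped
    targets: tuple[str, ...] = ()
    references: tuple[str, ...] = ()
    calibrator: str | None = None
    # synthetic-TPM knobs for the screening stage
    n_transcripts: int = 300
    tpm_replicates: int = 3

    def validate(self) -> None:
        low, high = self.efficiency_band
        if not low < high:
            raise ValueError("efficiency band requires low < high")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        known = set(self.design.tissue_labels())
        for name, members in self.stability_groups.items():
            unknown = set(members) - known
            if unknown:
                raise ValueError(
                    f"stability group {name!r} references unknown tissues: {sorted(unknown)}"
                )
        if self.targets:
            if not self.references:
                raise ValueError("quantification requested but no reference genes named")
            if self.calibrator is None:
                raise ValueError("quantification requested but no calibrator tissue named")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "design" in raw and isinstance(raw["design"], dict):
            raw["design"] = SimDesign(**raw["design"])
        if "screen_grouping" in raw and isinstance(raw["screen_grouping"], dict):
            raw["screen_grouping"] = TissueGrouping(**raw["screen_grouping"])
        for key in ("methods", "targets", "references", "efficiency_band"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage and the cause."""


def _stage(name):
    def decorate(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrap with stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return decorate


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute screen -> efficiency -> stability -> rank -> quantify.

    Returns a report bundle (dict of in-memory results) and writes all
    tables plus ``run_log.json`` to ``config.outdir``.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    ct, truth = _simulate_stage(config)
    bundle["truth"] = truth
    write_table(ct.values.rename_axis("gene").reset_index(), outdir / "ct_matrix.csv")
    truth_out = truth.table.rename_axis("gene").reset_index()
    write_table(truth_out, outdir / "ct_truth.csv")

    bundle["screen"] = _screen_stage(config, outdir)
    bundle["efficiency"] = _efficiency_stage(config, ct, outdir)
    bundle["stability"], bundle["ranking"] = _stability_stage(config, ct, outdir)
    if config.targets:
        bundle["quantification"] = _quantify_stage(config, ct, outdir)

    log = {
        "refstab_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "parameters": _jsonable(dataclasses.asdict(config)),
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    logger.info("pipeline complete; outputs in %s", outdir)
    return bundle


@_stage("simulate")
def _simulate_stage(config):
    design = dataclasses.replace(config.design, seed=config.seed)
    return simulate_ct_matrix(design)


@_stage("screen")
def _screen_stage(config, outdir):
    from .screening import apply_expression_floor

    grouping = config.screen_grouping
    tissues = [t for t in grouping.groups["Adult"] for _ in range(config.tpm_replicates)]
    rng = np.random.default_rng(config.seed + 1)
    target_cv = rng.uniform(5.0, 60.0, size=config.n_transcripts)
    tpm = simulate_tpm_matrix(config.n_transcripts, tissues, target_cv,
                              seed=config.seed + 2)
    tpm = apply_expression_floor(tpm, config.expression_floor)
    records = pd.concat(
        [compute_group_cv(tpm, grouping, g) for g in grouping.groups],
        ignore_index=True,
    )
    candidates = screen_candidates(records, grouping, annotated=tpm.annotated)
    write_table(candidates, outdir / "screen_candidates.csv")
    summaries = [summarize_group(candidates, g) for g in grouping.groups]
    summary_df = pd.DataFrame([dataclasses.asdict(s) for s in summaries]).drop(
        columns="counts_below"
    )
    write_table(summary_df, outdir / "screen_summary.csv")
    return candidates


@_stage("efficiency")
def _efficiency_stage(config, ct, outdir):
    low, high = config.efficiency_band
    concentrations = [10.0, 2.5, 0.625, 0.15625]  # four-fold dilution ladder
    rng = np.random.default_rng(config.seed + 3)
    records = []
    for i, gene in enumerate(ct.genes):
        true_e = float(rng.uniform(95.0, 105.0))
        series = simulate_dilution_series(
            true_e, intercept_ct=24.0, concentrations=concentrations,
            noise_sd=0.05, seed=config.seed + 100 + i, primer_id=gene,
        )
        records.append(evaluate_series(series, low=low, high=high))
    frame = records_to_frame(records)
    write_table(frame, outdir / "efficiency.csv")
    return frame


@_stage("stability")
def _stability_stage(config, ct, outdir):
    stability_out: dict[str, dict] = {}
    ranking_out: dict[str, pd.DataFrame] = {}
    for group, tissues in config.stability_groups.items():
        sub = ct.subset_tissues(tissues)
        tables = run_all_methods(sub, methods=config.methods, group=group)
        for name, table in tables.items():
            write_stability_table(table, outdir / f"stability_{group}_{name}.csv")
        comp = reffinder_aggregate(list(tables.values()))
        write_table(comp.rename_axis("gene").reset_index(),
                    outdir / f"comprehensive_{group}.csv")
        stability_out[group] = tables
        ranking_out[group] = comp
    return stability_out, ranking_out


@_stage("quantify")
def _quantify_stage(config, ct, outdir):
    ratio_frames, comparison_rows = [], []
    for target in config.targets:
        ratios = pfaffl_ratio(ct, target, config.references, config.calibrator)
        ratio_frames.append(ratios)
        result = compare_groups(ratios, alpha=config.alpha)
        pw = result.pairwise.copy()
        pw.insert(0, "target", target)
        pw["anova_f"] = result.anova_f
        pw["anova_p"] = result.anova_p
        comparison_rows.append(pw)
    ratios_all = pd.concat(ratio_frames, ignore_index=True)
    comparisons = pd.concat(comparison_rows, ignore_index=True)
    write_table(ratios_all, outdir / "expression_ratios.csv")
    write_table(comparisons, outdir / "group_comparisons.csv")
    return {"ratios": ratios_all, "comparisons": comparisons}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
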