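"""Full-study orchestration: multi-exposure x multi-outcome MR with FDR control.

For every exposure the pipeline selects instruments, harmonizes them against
each outcome, runs the primary IVW analysis (Wald ratio at k = 1) plus the
MR-Egger and weighted-median sensitivity analyses (skipped with a reason when
k < 3), computes instrument-strength diagnostics with the weak-instrument
flag at combined F < 10, applies Benjamini-Hochberg adjustment to the primary
p-values — by default within each exposure's outcome panel — and reports
results on the odds-ratio scale, optionally per unit *lower* exposure.

Per-cell failures are recorded in the report, not raised.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import mr_estimators as mre
from .exceptions import ConfigurationError, DomainError, MRTargetError
from .instrument_selection import InstrumentStrength, LDMatrix, combined_strength, select_instruments
from .summary_data import (
    DEFAULT_PALINDROMIC_EAF_WINDOW,
    GeneRegion,
    SummaryDataset,
    harmonize,
    read_summary_stats,
)

logger = logging.getLogger(__name__)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Sorted ascending, each p(i) is scaled by m/i, the running minimum is
    enforced from the largest rank down, and values are capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("bh_adjust requires a non-empty list")
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise DomainError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


@dataclass(frozen=True)
class EstimatorSettings:
    variance_model: str = "multiplicative_random"
    n_boot: int = 1000
    bootstrap_seed: int = 2024


@dataclass(frozen=True)
class ExposureConfig:
    name: str
    path: str
    trait_type: str = "quantitative"
    region: Optional[GeneRegion] = None
    p_threshold: float = 5e-8
    r2_threshold: float = 0.1
    inference_policy: str = "fdr"  # fdr | nominal


@dataclass(frozen=True)
class OutcomeConfig:
    name: str
    path: str
    trait_type: str = "binary"


@dataclass
class AnalysisConfig:
    exposures: list[ExposureConfig]
    outcomes: list[OutcomeConfig]
    ld_path: str
    estimator: EstimatorSettings = field(default_factory=EstimatorSettings)
    fdr_alpha: float = 0.05
    fdr_family: str = "per_exposure"  # per_exposure | global
    report_lowering: bool = True
    palindromic_eaf_window: float = DEFAULT_PALINDROMIC_EAF_WINDOW
    allow_strand_flip: bool = True
    seed: int = 2024

    def __post_init__(self) -> None:
        if not self.exposures or not self.outcomes:
            raise ConfigurationError("need at least one exposure and one outcome")
        if not (0 < self.fdr_alpha < 1):
            raise ConfigurationError("fdr_alpha must lie in (0, 1)")
        if self.fdr_family not in ("per_exposure", "global"):
            raise ConfigurationError("fdr_family must be per_exposure or global")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            exposures = []
            for e in raw["exposures"]:
                region = None
                if e.get("region"):
                    region = GeneRegion.parse(e["region"], flank=int(e.get("flank", 0)))
                exposures.append(
                    ExposureConfig(
                        name=e["name"],
                        path=e["path"],
                        trait_type=e.get("trait_type", "quantitative"),
                        region=region,
                        p_threshold=float(e.get("p_threshold", 5e-8)),
                        r2_threshold=float(e.get("r2_threshold", 0.1)),
                        inference_policy=e.get("inference_policy", "fdr"),
                    )
                )
            outcomes = [
                OutcomeConfig(name=o["name"], path=o["path"], trait_type=o.get("trait_type", "binary"))
                for o in raw["outcomes"]
            ]
            est = raw.get("estimator", {})
            return cls(
                exposures=exposures,
                outcomes=outcomes,
                ld_path=raw["ld_path"],
                estimator=EstimatorSettings(
                    variance_model=est.get("variance_model", "multiplicative_random"),
                    n_boot=int(est.get("n_boot", 1000)),
                    bootstrap_seed=int(est.get("bootstrap_seed", 2024)),
                ),
                fdr_alpha=float(raw.get("fdr_alpha", 0.05)),
                fdr_family=raw.get("fdr_family", "per_exposure"),
                report_lowering=bool(raw.get("report_lowering", True)),
                palindromic_eaf_window=float(
                    raw.get("palindromic_eaf_window", DEFAULT_PALINDROMIC_EAF_WINDOW)
                ),
                allow_strand_flip=bool(raw.get("allow_strand_flip", True)),
                seed=int(raw.get("seed", 2024)),
            )
        except KeyError as exc:
            raise ConfigurationError(f"analysis config missing key: {exc}") from exc


@dataclass
class CellResult:
    """One exposure x outcome cell of the analysis grid."""

    exposure: str
    outcome: str
    k: int = 0
    primary: Optional[mre.MREstimate] = None
    odds_ratio: Optional[mre.ORResult] = None
    p_adjusted: Optional[float] = None
    weighted_median: Optional[mre.MREstimate] = None
    egger_slope: Optional[mre.MREstimate] = None
    egger_intercept: Optional[mre.MREstimate] = None
    sensitivity_note: Optional[str] = None  # e.g. "unavailable (<3 SNPs)"
    pleiotropy_flag: bool = False  # Egger intercept p < 0.05
    inference_policy: str = "fdr"
    error: Optional[str] = None


@dataclass
class AnalysisReport:
    cells: list[CellResult]
    strength: dict[str, InstrumentStrength]
    provenance: dict

    def report_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            row = {
                "exposure": c.exposure,
                "outcome": c.outcome,
                "k": c.k,
                "inference_policy": c.inference_policy,
                "error": c.error,
            }
            if c.primary is not None:
                row.update(
                    method=c.primary.method,
                    beta=c.primary.beta,
                    se=c.primary.se,
                    pvalue=c.primary.pvalue,
                    ci_low=c.primary.ci_low,
                    ci_high=c.primary.ci_high,
                    cochran_q=c.primary.cochran_q,
                    p_adjusted=c.p_adjusted,
                )
            if c.odds_ratio is not None:
                row.update(
                    odds_ratio=c.odds_ratio.or_point,
                    or_ci_low=c.odds_ratio.or_low,
                    or_ci_high=c.odds_ratio.or_high,
                    or_direction=c.odds_ratio.direction,
                )
            rows.append(row)
        return pd.DataFrame(rows)

    def sensitivity_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            for label, est in (
                ("weighted_median", c.weighted_median),
                ("egger_slope", c.egger_slope),
                ("egger_intercept", c.egger_intercept),
            ):
                row = {"exposure": c.exposure, "outcome": c.outcome, "method": label}
                if est is None:
                    row["note"] = c.sensitivity_note or c.error or "unavailable"
                else:
                    row.update(
                        beta=est.beta, se=est.se, pvalue=est.pvalue,
                        ci_low=est.ci_low, ci_high=est.ci_high, df_used=est.df_used,
                    )
                    if label == "egger_intercept":
                        row["pleiotropy_flag"] = c.pleiotropy_flag
                rows.append(row)
        return pd.DataFrame(rows)

    def strength_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "exposure": name,
                    "k": s.k,
                    "n": s.n,
                    "combined_r2": s.combined_r2,
                    "combined_F": s.combined_F,
                    "weak_instruments": s.is_weak,
                }
                for name, s in self.strength.items()
            ]
        )

    def forest_frame(self) -> pd.DataFrame:
        """Long-format table ready for forest plotting (OR scale)."""
        rows = []
        for c in self.cells:
            if c.odds_ratio is None:
                continue
            rows.append(
                {
                    "exposure": c.exposure,
                    "outcome": c.outcome,
                    "or": c.odds_ratio.or_point,
                    "or_low": c.odds_ratio.or_low,
                    "or_high": c.odds_ratio.or_high,
                    "pvalue": c.primary.pvalue,
                    "p_adjusted": c.p_adjusted,
                }
            )
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, dict):
                return {k: encode(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [encode(v) for v in obj]
            return obj

        return {
            "provenance": encode(self.provenance),
            "strength": encode(self.strength),
            "cells": encode(self.cells),
        }

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.report_frame().to_csv(outdir / "report.tsv", sep="\t", index=False)
        self.sensitivity_frame().to_csv(outdir / "sensitivity.tsv", sep="\t", index=False)
        self.strength_frame().to_csv(outdir / "strength.tsv", sep="\t", index=False)
        self.forest_frame().to_csv(outdir / "forest.tsv", sep="\t", index=False)
        with open(outdir / "report.json", "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2)


def _analyze_cell(config: AnalysisConfig, exp_cfg: ExposureConfig,
                  instruments: SummaryDataset, out_cfg: OutcomeConfig,
                  outcome: SummaryDataset) -> CellResult:
    cell = CellResult(exposure=exp_cfg.name, outcome=out_cfg.name,
                      inference_policy=exp_cfg.inference_policy)
    harmonized = harmonize(
        instruments,
        outcome,
        palindromic_eaf_window=config.palindromic_eaf_window,
        allow_strand_flip=config.allow_strand_flip,
    )
    k = len(harmonized)
    cell.k = k
    if k == 0:
        cell.error = "no instruments retained after harmonization"
        return cell
    if k == 1:
        cell.primary = mre.wald_ratio(harmonized.variants[0])
    else:
        cell.primary = mre.ivw(harmonized, variance_model=config.estimator.variance_model)
    cell.odds_ratio = mre.to_odds_ratio(
        cell.primary,
        report_lowering=config.report_lowering,
        per_sd=exp_cfg.trait_type == "quantitative",
    )
    if k < mre.MIN_SENSITIVITY_K:
        cell.sensitivity_note = "unavailable (<3 SNPs)"
    else:
        cell.weighted_median = mre.weighted_median(
            harmonized, n_boot=config.estimator.n_boot, seed=config.estimator.bootstrap_seed
        )
        egger = mre.mr_egger(harmonized)
        if egger is not None:
            cell.egger_slope, cell.egger_intercept = egger
            cell.pleiotropy_flag = cell.egger_intercept.pvalue < 0.05
    return cell


def run_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Execute the exposure x outcome grid and return the assembled report."""
    ld = LDMatrix.read_tsv(config.ld_path)
    outcomes: dict[str, SummaryDataset] = {
        o.name: read_summary_stats(o.path, trait_name=o.name, trait_type=o.trait_type)
        for o in config.outcomes
    }

    cells: list[CellResult] = []
    strength: dict[str, InstrumentStrength] = {}
    for exp_cfg in config.exposures:
        try:
            exposure = read_summary_stats(
                exp_cfg.path, trait_name=exp_cfg.name, trait_type=exp_cfg.trait_type
            )
            instruments = select_instruments(
                exposure,
                p_threshold=exp_cfg.p_threshold,
                ld=ld,
                r2_threshold=exp_cfg.r2_threshold,
                region=exp_cfg.region,
            )
            strength[exp_cfg.name] = combined_strength(instruments)
            if strength[exp_cfg.name].is_weak:
                logger.warning("%s: weak instruments (combined F = %.2f < 10)",
                               exp_cfg.name, strength[exp_cfg.name].combined_F)
        except MRTargetError as exc:
            logger.error("exposure %s failed: %s", exp_cfg.name, exc)
            for out_cfg in config.outcomes:
                cells.append(CellResult(exposure=exp_cfg.name, outcome=out_cfg.name,
                                        inference_policy=exp_cfg.inference_policy,
                                        error=str(exc)))
            continue
        for out_cfg in config.outcomes:
            try:
                cells.append(_analyze_cell(config, exp_cfg, instruments, out_cfg,
                                           outcomes[out_cfg.name]))
            except MRTargetError as exc:
                logger.error("cell %s x %s failed: %s", exp_cfg.name, out_cfg.name, exc)
                cells.append(CellResult(exposure=exp_cfg.name, outcome=out_cfg.name,
                                        inference_policy=exp_cfg.inference_policy,
                                        error=str(exc)))

    # BH adjustment of primary p-values, per exposure family or globally.
    if config.fdr_family == "global":
        families = {"__all__": [c for c in cells if c.primary is not None]}
    else:
        families = {}
        for c in cells:
            if c.primary is not None:
                families.setdefault(c.exposure, []).append(c)
    for members in families.values():
        if not members:
            continue
        adjusted = bh_adjust([c.primary.pvalue for c in members])
        for c, p_adj in zip(members, adjusted):
            c.p_adjusted = float(p_adj)

    provenance = {
        "config": {
            "ld_path": config.ld_path,
            "fdr_alpha": config.fdr_alpha,
            "fdr_family": config.fdr_family,
            "report_lowering": config.report_lowering,
            "palindromic_eaf_window": config.palindromic_eaf_window,
            "allow_strand_flip": config.allow_strand_flip,
            "seed": config.seed,
            "estimator": dataclasses.asdict(config.estimator),
            "exposures": [
                {
                    "name": e.name,
                    "path": e.path,
                    "p_threshold": e.p_threshold,
                    "r2_threshold": e.r2_threshold,
                    "region": None if e.region is None else
                        f"{e.region.chrom}:{e.region.start}-{e.region.end}(+/-{e.region.flank})",
                    "inference_policy": e.inference_policy,
                }
                for e in config.exposures
            ],
            "outcomes": [{"name": o.name, "path": o.path} for o in config.outcomes],
        },
    }
    return AnalysisReport(cells=cells, strength=strength, provenance=provenance)
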