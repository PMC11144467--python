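"""Synthetic two-sample GWAS summary statistics with known ground truth.

Statistics are simulated directly at the summary level (no individual-level
genotypes): per-variant effect estimates are drawn from their normal-theory
sampling distributions, with standard errors implied by allele frequency and
sample size. The outcome is a rare binary trait on the log-odds scale with a
case/control structure mirroring large biobank disease GWAS, so outcome
signals are realistically weak relative to the exposure.

One integer seed drives everything; per-stage generators are derived
deterministically from it, so identical configs give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .instrument_selection import LDMatrix
from .summary_data import SummaryDataset, VariantRecord

# Non-palindromic allele pairs assigned round-robin so harmonization never
# drops simulated variants as ambiguous.
_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))

_P_FLOOR = 1e-300  # keep p-values inside (0, 1] after underflow


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for a paired exposure/outcome simulation.

    ``theta`` is the true causal effect of the exposure on the outcome
    (log-odds per exposure SD); ``exposure_r2`` is the total exposure
    variance explained by the simulated variants.
    """

    seed: int
    k_variants: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_exposure: int = 100_000
    n_outcome_cases: int = 360
    n_outcome_controls: int = 307_206
    theta: float = 0.0
    exposure_r2: float = 0.05
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    ld_block_size: int = 1
    ld_rho: float = 0.0
    chrom: str = "1"
    pos_start: int = 1_000_000
    pos_step: int = 1_000

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not (0 < self.exposure_r2 < 1):
            raise ValueError("exposure_r2 must lie in (0, 1)")
        if min(self.k_variants, self.n_exposure, self.n_outcome_cases, self.n_outcome_controls) < 1:
            raise ValueError("all counts must be positive")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.pleiotropy_sd < 0:
            raise ValueError("pleiotropy_sd must be >= 0")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must lie in [0, 1)")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth parameters behind one simulated dataset pair."""

    theta: float
    beta_exposure: np.ndarray  # true per-allele exposure effects
    pleiotropy: np.ndarray  # per-variant direct effects on the outcome


@dataclass
class SimOutput:
    """Paired synthetic datasets, their LD matrix, and the generating truth."""

    exposure: SummaryDataset
    outcome: SummaryDataset
    ld: LDMatrix
    truth: SimTruth
    config: SimConfig = field(repr=False, default=None)


def _block_ld(variant_ids: list[str], block_size: int, rho: float) -> LDMatrix:
    k = len(variant_ids)
    r = np.eye(k)
    for start in range(0, k, block_size):
        stop = min(start + block_size, k)
        r[start:stop, start:stop] = rho
    np.fill_diagonal(r, 1.0)
    return LDMatrix(variant_ids=variant_ids, r=r)


def _records(ids, chrom, positions, alleles, eafs, betas, ses, ns) -> list[VariantRecord]:
    pvals = np.clip(2.0 * stats.norm.sf(np.abs(betas / ses)), _P_FLOOR, 1.0)
    return [
        VariantRecord(
            variant_id=ids[j],
            chrom=chrom,
            pos=int(positions[j]),
            effect_allele=alleles[j][0],
            other_allele=alleles[j][1],
            eaf=float(eafs[j]),
            beta=float(betas[j]),
            se=float(ses[j]),
            pvalue=float(pvals[j]),
            n=int(ns),
        )
        for j in range(len(ids))
    ]


def simulate_two_sample(config: SimConfig) -> SimOutput:
    """Generate paired exposure/outcome summary statistics with known truth.

    MAFs are uniform on ``maf_range``; true per-allele exposure effects are
    Gaussian, rescaled so the summed explained variance
    ``sum 2*maf*(1-maf)*beta^2`` equals ``exposure_r2`` exactly. Estimates
    are drawn as ``N(beta, se)`` with ``se = 1/sqrt(2*maf*(1-maf)*n)`` for
    the quantitative exposure and
    ``se = 1/sqrt(2*maf*(1-maf)*n_eff*phi*(1-phi))`` for the binary outcome
    (``phi`` = case fraction). True outcome log-odds effects are
    ``theta * beta + alpha`` with per-variant pleiotropy ``alpha`` set by
    ``pleiotropy_mode``.
    """
    streams = np.random.SeedSequence(config.seed).spawn(4)
    rng_arch = np.random.default_rng(streams[0])  # MAFs, effects
    rng_exp = np.random.default_rng(streams[1])  # exposure sampling noise
    rng_plei = np.random.default_rng(streams[2])  # pleiotropic effects
    rng_out = np.random.default_rng(streams[3])  # outcome sampling noise

    k = config.k_variants
    ids = [f"rs{j + 1:06d}" for j in range(k)]
    positions = config.pos_start + config.pos_step * np.arange(k)
    alleles = [_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)] for j in range(k)]

    maf = rng_arch.uniform(*config.maf_range, size=k)
    het = 2.0 * maf * (1.0 - maf)
    # Effect alleles are oriented to raise the exposure (half-normal true
    # effects), so directional pleiotropy keeps a well-defined sign under the
    # exposure-positive orientation used by the Egger regression.
    raw = np.abs(rng_arch.standard_normal(k))
    raw[raw == 0] = 1.0
    beta_x = raw * np.sqrt(config.exposure_r2 / float(het @ raw**2))

    se_x = 1.0 / np.sqrt(het * config.n_exposure)
    beta_hat_x = beta_x + rng_exp.standard_normal(k) * se_x

    if config.pleiotropy_mode == "none":
        alpha = np.zeros(k)
    else:
        mean = config.pleiotropy_mean if config.pleiotropy_mode == "directional" else 0.0
        alpha = rng_plei.normal(mean, config.pleiotropy_sd, size=k)

    n_eff = config.n_outcome_cases + config.n_outcome_controls
    phi = config.n_outcome_cases / n_eff
    beta_y = config.theta * beta_x + alpha
    se_y = 1.0 / np.sqrt(het * n_eff * phi * (1.0 - phi))
    beta_hat_y = beta_y + rng_out.standard_normal(k) * se_y

    exposure = SummaryDataset(
        trait_name="exposure",
        trait_type="quantitative",
        records=_records(ids, config.chrom, positions, alleles, maf, beta_hat_x, se_x, config.n_exposure),
        n_total=config.n_exposure,
    )
    outcome = SummaryDataset(
        trait_name="outcome",
        trait_type="binary",
        records=_records(ids, config.chrom, positions, alleles, maf, beta_hat_y, se_y, n_eff),
        n_total=n_eff,
        n_cases=config.n_outcome_cases,
    )
    ld = _block_ld(ids, config.ld_block_size, config.ld_rho)
    truth = SimTruth(theta=config.theta, beta_exposure=beta_x, pleiotropy=alpha)
    return SimOutput(exposure=exposure, outcome=outcome, ld=ld, truth=truth, config=config)


def simulate_coloc_region(
    n_variants: int,
    causal_config: str,
    effect_z: float = 8.0,
    ld_rho: float = 0.0,
    seed: int = 0,
    ld_block_size: int = 5,
    n_sample: int = 50_000,
    maf: float = 0.3,
) -> tuple[SummaryDataset, SummaryDataset]:
    """Simulate a regional dataset pair with a planted causal configuration.

    ``causal_config`` is one of ``shared`` (one causal variant affecting both
    traits), ``distinct`` (different causal variants in different LD blocks),
    ``trait1_only``, or ``none``. The causal variant's expected |z| is
    ``effect_z``; expected z-scores and the sampling noise are both
    propagated through the block-LD structure.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    if causal_config not in ("shared", "distinct", "trait1_only", "none"):
        raise ValueError(f"unknown causal_config {causal_config!r}")
    if causal_config == "distinct" and n_variants < ld_block_size + 1:
        raise ValueError("distinct configuration needs variants in at least two LD blocks")

    rng = np.random.default_rng(seed)
    ids = [f"rs{j + 1:06d}" for j in range(n_variants)]
    ld = _block_ld(ids, ld_block_size, ld_rho)
    r = ld.r
    chol = np.linalg.cholesky(r + 1e-10 * np.eye(n_variants))

    idx1 = 0
    idx2 = idx1 if causal_config == "shared" else ld_block_size  # next block
    z1_true = np.zeros(n_variants)
    z2_true = np.zeros(n_variants)
    if causal_config in ("shared", "distinct", "trait1_only"):
        z1_true = effect_z * r[:, idx1]
    if causal_config == "shared":
        z2_true = effect_z * r[:, idx1]
    elif causal_config == "distinct":
        z2_true = effect_z * r[:, idx2]

    z1 = z1_true + chol @ rng.standard_normal(n_variants)
    z2 = z2_true + chol @ rng.standard_normal(n_variants)

    se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n_sample)
    positions = 1_000_000 + 1_000 * np.arange(n_variants)
    alleles = [_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)] for j in range(n_variants)]
    mafs = np.full(n_variants, maf)
    trait1 = SummaryDataset(
        trait_name="trait1",
        trait_type="quantitative",
        records=_records(ids, "1", positions, alleles, mafs, z1 * se, np.full(n_variants, se), n_sample),
        n_total=n_sample,
    )
    trait2 = SummaryDataset(
        trait_name="trait2",
        trait_type="quantitative",
        records=_records(ids, "1", positions, alleles, mafs, z2 * se, np.full(n_variants, se), n_sample),
        n_total=n_sample,
    )
    return trait1, trait2
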