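"""Causal-effect estimators for two-sample Mendelian randomization.

The primary estimator is the inverse-variance-weighted (IVW) combination of
per-variant Wald ratios, equivalent to weighted least squares through the
origin of outcome effects on exposure effects. Sensitivity estimators are
MR-Egger (weighted regression with a free intercept; a non-zero intercept
indicates directional pleiotropy) and the weighted median (consistent when at
least half the instrument weight comes from valid variants). Both sensitivity
estimators require at least three instruments and return ``None`` — an
explicit "unavailable" signal — below that.

Reference distributions: IVW and the weighted median use the standard normal;
MR-Egger uses Student's t with k - 2 degrees of freedom. The distribution
actually used is recorded in ``MREstimate.df_used`` (0 means normal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .exceptions import CollinearityError, DegenerateInstrumentError, NoInstrumentsError
from .summary_data import HarmonizedInstruments, HarmonizedVariant

#: Minimum instrument count for the sensitivity estimators.
MIN_SENSITIVITY_K = 3

#: Normal critical value used for 95% intervals on the odds-ratio scale.
Z_95 = 1.96


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate with its inference metadata.

    ``df_used`` declares the reference distribution: 0 for standard normal,
    otherwise the degrees of freedom of the t distribution used.
    """

    method: str  # ivw | egger_slope | egger_intercept | weighted_median | wald
    beta: float
    se: float
    pvalue: float
    ci_low: float
    ci_high: float
    k: int
    df_used: int = 0
    cochran_q: Optional[float] = None


@dataclass(frozen=True)
class ORResult:
    """An estimate re-expressed as an odds ratio with a 95% CI."""

    or_point: float
    or_low: float
    or_high: float
    direction: str  # per-1-SD-lower | per-unit-lower | per-1-SD-higher | per-unit-higher


def wald_pvalue(beta: float, se: float, df: int = 0) -> float:
    """Two-sided p-value of ``beta / se`` under the declared reference.

    ``df = 0`` selects the standard normal; any positive ``df`` selects
    Student's t with that many degrees of freedom.
    """
    if not se > 0:
        raise ValueError("se must be positive")
    z = abs(beta) / se
    if df > 0:
        return float(min(1.0, 2.0 * stats.t.sf(z, df)))
    return float(min(1.0, 2.0 * stats.norm.sf(z)))


def _finish(method: str, beta: float, se: float, k: int, df: int = 0,
            cochran_q: Optional[float] = None) -> MREstimate:
    crit = stats.t.ppf(0.975, df) if df > 0 else stats.norm.ppf(0.975)
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        pvalue=wald_pvalue(beta, se, df),
        ci_low=float(beta - crit * se),
        ci_high=float(beta + crit * se),
        k=k,
        df_used=df,
        cochran_q=cochran_q,
    )


def wald_ratio(instrument: HarmonizedVariant) -> MREstimate:
    """Single-instrument ratio estimate: beta_out / beta_exp.

    The first-order standard error ``se_out / |beta_exp|`` ignores
    uncertainty in the exposure effect, matching the IVW limit at k = 1.
    """
    if instrument.beta_exp == 0:
        raise DegenerateInstrumentError(f"{instrument.variant_id}: exposure effect is zero")
    beta = instrument.beta_out / instrument.beta_exp
    se = instrument.se_out / abs(instrument.beta_exp)
    return _finish("wald", beta, se, k=1)


def ivw(instruments: HarmonizedInstruments,
        variance_model: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted estimate (weighted LS through the origin).

    ``variance_model`` is ``fixed`` or ``multiplicative_random``; the random
    model inflates the fixed-effect SE by ``max(1, sqrt(Q / (k - 1)))`` where
    Q is Cochran's heterogeneity statistic.
    """
    if variance_model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown variance_model {variance_model!r}")
    k = len(instruments)
    if k == 0:
        raise NoInstrumentsError("ivw requires at least one instrument")
    bx, _, by, sy = (np.asarray(a, dtype=float) for a in instruments.arrays())
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    if denom == 0:
        raise DegenerateInstrumentError("all exposure effects are zero")
    beta = float(np.sum(w * bx * by)) / denom
    se = denom**-0.5
    q = float(np.sum(w * (by - beta * bx) ** 2))
    if variance_model == "multiplicative_random" and k > 1:
        se *= max(1.0, math.sqrt(q / (k - 1)))
    return _finish("ivw", beta, se, k=k, cochran_q=q)


def mr_egger(instruments: HarmonizedInstruments) -> Optional[tuple[MREstimate, MREstimate]]:
    """MR-Egger regression: (slope, intercept) estimates, or ``None`` if k < 3.

    Instruments are first oriented so every exposure effect is non-negative
    (negating both members of a pair), then outcome effects are regressed on
    exposure effects with weights 1/se_out^2 and a free intercept. Standard
    errors use the weighted residual scale floored at 1; inference is on t
    with k - 2 degrees of freedom. The intercept p-value is the test for
    directional pleiotropy.
    """
    k = len(instruments)
    if k < MIN_SENSITIVITY_K:
        return None
    bx, _, by, sy = (np.asarray(a, dtype=float) for a in instruments.arrays())
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    x, y = bx * flip, by * flip
    w = 1.0 / sy**2

    sw = w.sum()
    swx = (w * x).sum()
    swy = (w * y).sum()
    swxx = (w * x * x).sum()
    swxy = (w * x * y).sum()
    det = sw * swxx - swx**2
    if det <= 0 or not np.isfinite(det) or math.isclose(det, 0.0, abs_tol=1e-30):
        raise CollinearityError("exposure effects are degenerate (no spread after orientation)")
    slope = (sw * swxy - swx * swy) / det
    intercept = (swy - slope * swx) / sw
    resid = y - intercept - slope * x
    scale = max(1.0, math.sqrt(float((w * resid**2).sum()) / (k - 2)))
    se_slope = math.sqrt(sw / det) * scale
    se_intercept = math.sqrt(swxx / det) * scale
    df = k - 2
    return (
        _finish("egger_slope", slope, se_slope, k=k, df=df),
        _finish("egger_intercept", intercept, se_intercept, k=k, df=df),
    )


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise weighted median with linear interpolation at cumulative weight 0.5.

    ``ratios`` and ``weights`` are (B, k); returns shape (B,).
    """
    order = np.argsort(ratios, axis=1)
    r = np.take_along_axis(ratios, order, axis=1)
    w = np.take_along_axis(weights, order, axis=1)
    w = w / w.sum(axis=1, keepdims=True)
    s = np.cumsum(w, axis=1) - 0.5 * w  # midpoint cumulative weights
    j = np.sum(s < 0.5, axis=1)  # first index with s >= 0.5
    k = ratios.shape[1]
    j = np.clip(j, 0, k - 1)
    rows = np.arange(ratios.shape[0])
    est = r[rows, j].copy()
    interior = (j > 0) & (s[rows, np.maximum(j - 1, 0)] < 0.5)
    if np.any(interior):
        ji = j[interior]
        ri = rows[interior]
        s0, s1 = s[ri, ji - 1], s[ri, ji]
        r0, r1 = r[ri, ji - 1], r[ri, ji]
        frac = np.where(s1 > s0, (0.5 - s0) / np.where(s1 > s0, s1 - s0, 1.0), 0.0)
        est[interior] = r0 + (r1 - r0) * frac
    return est


def weighted_median(instruments: HarmonizedInstruments, n_boot: int = 1000,
                    seed: int = 2024) -> Optional[MREstimate]:
    """Weighted-median estimate, or ``None`` if k < 3.

    Per-variant ratios beta_out/beta_exp are weighted proportionally to
    beta_exp^2 / se_out^2 (the IVW weights on the ratio scale); the estimate
    interpolates the weighted median. The standard error is the SD of the
    estimate over ``n_boot`` parametric-bootstrap resamples drawing both
    exposure and outcome effects from their normal sampling distributions;
    inference is normal.
    """
    k = len(instruments)
    if k < MIN_SENSITIVITY_K:
        return None
    bx, sx, by, sy = (np.asarray(a, dtype=float) for a in instruments.arrays())
    if np.any(bx == 0):
        raise DegenerateInstrumentError("weighted_median requires non-zero exposure effects")
    ratios = (by / bx)[None, :]
    weights = (bx**2 / sy**2)[None, :]
    point = float(_weighted_median(ratios, weights)[0])

    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(n_boot, k))
    by_b = rng.normal(by, sy, size=(n_boot, k))
    bx_b[bx_b == 0] = np.finfo(float).tiny  # guard exact zeros in resamples
    boot = _weighted_median(by_b / bx_b, bx_b**2 / sy**2)
    se = float(np.std(boot, ddof=1))
    if se == 0:
        se = np.finfo(float).tiny  # degenerate: all resampled estimates identical
    return _finish("weighted_median", point, se, k=k)


def from_odds_ratio(or_point: float, or_low: float, or_high: float) -> tuple[float, float]:
    """Recover (log-OR, SE) from an odds ratio and its 95% CI.

    The SE is the CI half-width on the log scale divided by 1.96; the inverse
    of :func:`to_odds_ratio` up to CI rounding.
    """
    if not (0 < or_low < or_high):
        raise ValueError("CI bounds must be positive with or_low < or_high")
    beta = math.log(or_point)
    se = (math.log(or_high) - math.log(or_low)) / (2.0 * Z_95)
    return beta, se


def to_odds_ratio(estimate: MREstimate, report_lowering: bool = True,
                  per_sd: bool = True) -> ORResult:
    """Exponentiate a log-odds estimate into an OR with a 95% CI.

    When ``report_lowering`` the sign of beta is flipped first, so the OR is
    per 1-SD (or unit) *lower* genetically predicted exposure.
    """
    beta = -estimate.beta if report_lowering else estimate.beta
    unit = "1-SD" if per_sd else "unit"
    direction = f"per-{unit}-{'lower' if report_lowering else 'higher'}"
    return ORResult(
        or_point=math.exp(beta),
        or_low=math.exp(beta - Z_95 * estimate.se),
        or_high=math.exp(beta + Z_95 * estimate.se),
        direction=direction,
    )
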