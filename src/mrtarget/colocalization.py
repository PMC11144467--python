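"""Bayesian colocalization of two association signals in a gene region.

Per-variant evidence is summarized by an approximate Bayes factor computed
from the estimate and its standard error under a normal prior on the true
effect. The five single-causal-variant configurations are enumerated:

* H0 — no causal variant for either trait;
* H1/H2 — a causal variant for trait 1 / trait 2 only;
* H3 — distinct causal variants for the two traits;
* H4 — one shared causal variant.

All Bayes-factor sums are carried in log space via log-sum-exp, since
per-variant factors overflow double precision at genome-wide z-scores.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import logsumexp

from .exceptions import NoInstrumentsError
from .summary_data import SummaryDataset

logger = logging.getLogger(__name__)

#: Default prior SD of a true effect: quantitative traits (SD units).
DEFAULT_PRIOR_SD_QUANTITATIVE = 0.15
#: Default prior SD of a true effect: binary traits (log-odds units).
DEFAULT_PRIOR_SD_BINARY = 0.20


@dataclass(frozen=True)
class ColocPriors:
    """Per-variant causal priors and prior effect variances.

    ``w1`` / ``w2`` are the prior variances of a true effect for trait 1 /
    trait 2; leave ``None`` to resolve from each trait's type (0.15^2 for
    quantitative, 0.20^2 for binary).
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    w1: Optional[float] = None
    w2: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 < self.p12 <= min(self.p1, self.p2) and max(self.p1, self.p2) < 1):
            raise ValueError("priors must satisfy 0 < p12 <= p1, p2 < 1")
        for w in (self.w1, self.w2):
            if w is not None and not w > 0:
                raise ValueError("prior effect variances must be positive")


@dataclass
class ColocResult:
    """Posterior probabilities of the five configurations plus per-variant log-ABFs."""

    pp_h0: float
    pp_h1: float
    pp_h2: float
    pp_h3: float
    pp_h4: float
    labf1: np.ndarray
    labf2: np.ndarray
    variant_ids: list[str] = field(default_factory=list)
    priors: Optional[ColocPriors] = None

    @property
    def n_variants(self) -> int:
        return len(self.labf1)

    def posteriors(self) -> dict[str, float]:
        return {
            "pp_h0": self.pp_h0,
            "pp_h1": self.pp_h1,
            "pp_h2": self.pp_h2,
            "pp_h3": self.pp_h3,
            "pp_h4": self.pp_h4,
        }


def log_abf(beta: float, se: float, W: float) -> float:
    """Log approximate Bayes factor for association at one variant.

    With sampling variance ``V = se**2``, prior effect variance ``W`` and
    z = beta/se, returns ``0.5*ln(V/(V+W)) + 0.5*z**2*W/(V+W)`` — the log
    Bayes factor of association against the null.
    """
    if not se > 0:
        raise ValueError("se must be positive")
    if not W > 0:
        raise ValueError("W must be positive")
    V = se * se
    z = beta / se
    return 0.5 * math.log(V / (V + W)) + 0.5 * z * z * W / (V + W)


def _resolve_w(explicit: Optional[float], trait_type: str) -> float:
    if explicit is not None:
        return explicit
    sd = DEFAULT_PRIOR_SD_BINARY if trait_type == "binary" else DEFAULT_PRIOR_SD_QUANTITATIVE
    return sd * sd


def colocalize(
    region_exp: SummaryDataset,
    region_out: SummaryDataset,
    priors: Optional[ColocPriors] = None,
) -> ColocResult:
    """Enumerate the five causal configurations over a shared region.

    The datasets are intersected on ``variant_id``; allele orientation is
    irrelevant because the evidence depends on z only through z**2. With
    per-variant log Bayes factors ``b1j``, ``b2j`` the (unnormalized)
    configuration scores are::

        S0 = 1
        S1 = p1 * sum_j exp(b1j)
        S2 = p2 * sum_j exp(b2j)
        S3 = p1*p2 * (sum_j exp(b1j) * sum_j exp(b2j) - sum_j exp(b1j + b2j))
        S4 = p12 * sum_j exp(b1j + b2j)

    and posteriors are Si / sum(S), computed in log space.

    Raises
    ------
    NoInstrumentsError
        If the two datasets share no variant.
    """
    if priors is None:
        priors = ColocPriors()
    out_index = region_out._index()
    shared = [r for r in region_exp.records if r.variant_id in out_index]
    if not shared:
        raise NoInstrumentsError("colocalize: datasets share no variants")

    w1 = _resolve_w(priors.w1, region_exp.trait_type)
    w2 = _resolve_w(priors.w2, region_out.trait_type)
    ids = [r.variant_id for r in shared]
    labf1 = np.array([log_abf(r.beta, r.se, w1) for r in shared])
    labf2 = np.array([log_abf(out_index[i].beta, out_index[i].se, w2) for i in ids])

    lsum1 = logsumexp(labf1)
    lsum2 = logsumexp(labf2)
    lsum12 = logsumexp(labf1 + labf2)

    l0 = 0.0
    l1 = math.log(priors.p1) + lsum1
    l2 = math.log(priors.p2) + lsum2
    l4 = math.log(priors.p12) + lsum12
    # S3 on log scale: log(exp(a) - exp(b)) with a = lsum1+lsum2 >= b = lsum12
    # only when cross terms dominate; clamp to -inf (S3 = 0) otherwise.
    a, b = lsum1 + lsum2, lsum12
    if len(shared) == 1 or b >= a:
        if len(shared) > 1 and b > a + 1e-9:
            logger.warning("colocalize: H3 term rounded below 0; clamped to 0")
        l3 = -math.inf
    else:
        l3 = math.log(priors.p1) + math.log(priors.p2) + a + math.log1p(-math.exp(b - a))

    logs = np.array([l0, l1, l2, l3, l4])
    norm = logsumexp(logs)
    pp = np.exp(logs - norm)
    return ColocResult(
        pp_h0=float(pp[0]),
        pp_h1=float(pp[1]),
        pp_h2=float(pp[2]),
        pp_h3=float(pp[3]),
        pp_h4=float(pp[4]),
        labf1=labf1,
        labf2=labf2,
        variant_ids=ids,
        priors=priors,
    )
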