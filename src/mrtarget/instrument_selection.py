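"""Instrument selection and instrument-strength diagnostics.

Selection keeps genome-wide-significant variants (strict p < threshold),
optionally restricted to a flanked gene region, and greedily prunes them to a
pairwise-uncorrelated set (r-squared below threshold) in ascending p-value
order — the standard clumping convention, made deterministic by breaking ties
on variant id.

Strength statistics follow the summary-data formulas
``F = (beta / se)^2``, ``r2 = F / (n - 2 + F)`` per variant, and
``F = ((n - k - 1) / k) * R2 / (1 - R2)`` for the combined instrument, with
``R2`` the sum of per-variant r2. Combined F below 10 conventionally flags
weak instruments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import DomainError, NoInstrumentsError
from .summary_data import GeneRegion, SummaryDataset, VariantRecord

logger = logging.getLogger(__name__)

#: Combined-F threshold below which instruments are conventionally called weak.
WEAK_F_THRESHOLD = 10.0


@dataclass
class LDMatrix:
    """Pairwise LD correlations (r, not r-squared) for a set of variants."""

    variant_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.variant_ids)
        if self.r.shape != (k, k):
            raise ValueError(f"LD matrix shape {self.r.shape} does not match {k} ids")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-6):
            raise ValueError("LD matrix must have unit diagonal")
        if np.any(np.abs(self.r) > 1.0 + 1e-8):
            raise ValueError("LD correlations must lie in [-1, 1]")
        self._pos = {vid: i for i, vid in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._pos

    def r2(self, id_a: str, id_b: str) -> float:
        """Squared correlation between two variants."""
        return float(self.r[self._pos[id_a], self._pos[id_b]] ** 2)

    def submatrix(self, variant_ids: list[str]) -> "LDMatrix":
        idx = [self._pos[v] for v in variant_ids]
        return LDMatrix(variant_ids=list(variant_ids), r=self.r[np.ix_(idx, idx)])

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.r, columns=self.variant_ids).to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t")
        return cls(variant_ids=[str(c) for c in df.columns], r=df.to_numpy(dtype=float))


@dataclass
class InstrumentStrength:
    """Per-variant and combined F / R-squared diagnostics for an instrument set."""

    variant_ids: list[str]
    F: np.ndarray
    r2: np.ndarray
    combined_r2: float
    combined_F: float
    n: int
    k: int

    @property
    def is_weak(self) -> bool:
        return self.combined_F < WEAK_F_THRESHOLD


def select_instruments(
    dataset: SummaryDataset,
    p_threshold: float,
    ld: LDMatrix,
    r2_threshold: float,
    region: Optional[GeneRegion] = None,
) -> SummaryDataset:
    """Select significant, mutually uncorrelated instruments.

    Candidates must satisfy ``pvalue < p_threshold`` (strict) and, when a
    region is given, fall inside its flanked window. Candidates absent from
    the LD matrix are excluded with a warning rather than assumed
    independent. Greedy pruning processes candidates by ascending p-value
    (ties by variant id) and keeps a variant iff its r-squared with every
    already-kept variant is below ``r2_threshold``. The returned dataset
    preserves the input record order.

    Raises
    ------
    NoInstrumentsError
        If no variant survives.
    """
    candidates = [r for r in dataset.records if r.pvalue < p_threshold]
    if region is not None:
        candidates = [r for r in candidates if region.contains(r.chrom, r.pos)]
    missing_ld = [r.variant_id for r in candidates if r.variant_id not in ld]
    if missing_ld:
        logger.warning(
            "%d significant variant(s) absent from the LD matrix were excluded: %s%s",
            len(missing_ld),
            ", ".join(missing_ld[:5]),
            "..." if len(missing_ld) > 5 else "",
        )
        candidates = [r for r in candidates if r.variant_id in ld]

    candidates.sort(key=lambda r: (r.pvalue, r.variant_id))
    kept: list[VariantRecord] = []
    for cand in candidates:
        if all(ld.r2(cand.variant_id, k.variant_id) < r2_threshold for k in kept):
            kept.append(cand)
    if not kept:
        raise NoInstrumentsError(
            f"{dataset.trait_name}: no instruments at p < {p_threshold:g}"
            + (f" in region {region.chrom}:{region.window_start}-{region.window_end}" if region else "")
        )
    return dataset.subset(r.variant_id for r in kept)


def snp_strength(record: VariantRecord) -> tuple[float, float]:
    """Per-variant instrument strength: ``F = (beta/se)^2``, ``r2 = F / (n - 2 + F)``."""
    if record.n <= 2:
        raise DomainError(f"{record.variant_id}: n must exceed 2 for the r2 formula")
    F = (record.beta / record.se) ** 2
    return F, F / (record.n - 2 + F)


def combined_strength(instruments: SummaryDataset, n: Optional[int] = None) -> InstrumentStrength:
    """Combined instrument strength over a selected instrument set.

    ``R2`` is the sum of per-variant r2; the combined F-statistic is
    ``((n - k - 1) / k) * R2 / (1 - R2)`` with ``n`` the exposure GWAS sample
    size (``n_total`` unless overridden) and ``k`` the number of instruments.

    Raises
    ------
    NoInstrumentsError
        If the instrument set is empty.
    DomainError
        If the summed R-squared reaches 1.
    """
    k = len(instruments)
    if k < 1:
        raise NoInstrumentsError("combined_strength requires at least one instrument")
    if n is None:
        n = instruments.n_total
    per = [snp_strength(r) for r in instruments.records]
    F = np.array([f for f, _ in per])
    r2 = np.array([v for _, v in per])
    combined_r2 = float(r2.sum())
    if combined_r2 >= 1.0:
        raise DomainError(f"combined R2 = {combined_r2:.4f} >= 1")
    combined_F = ((n - k - 1) / k) * combined_r2 / (1.0 - combined_r2)
    return InstrumentStrength(
        variant_ids=instruments.variant_ids(),
        F=F,
        r2=r2,
        combined_r2=combined_r2,
        combined_F=float(combined_F),
        n=int(n),
        k=k,
    )
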