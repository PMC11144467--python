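"""Domain types, file I/O, and allele harmonization for two-sample GWAS summary statistics.

Coordinates are 1-based and region windows are closed intervals. Input files
are tab-separated with a header row; column names follow GWAS-SSF conventions
by default and can be remapped via ``column_map``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pandas as pd

from .exceptions import ConfigurationError, EmptyInputError, NoInstrumentsError

logger = logging.getLogger(__name__)

_BASES = {"A", "C", "G", "T"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Default column names for summary-statistics TSV files (GWAS-SSF-like).
DEFAULT_COLUMNS: Mapping[str, str] = {
    "variant_id": "variant_id",
    "chrom": "chromosome",
    "pos": "base_pair_location",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "effect_allele_frequency",
    "beta": "beta",
    "se": "standard_error",
    "pvalue": "p_value",
    "n": "n",
}

#: Default half-width of the allele-frequency window inside which palindromic
#: variants are considered unresolvable and dropped.
DEFAULT_PALINDROMIC_EAF_WINDOW = 0.08


@dataclass(frozen=True)
class VariantRecord:
    """One GWAS association: per-allele effect of a variant on a trait.

    ``beta`` is in SD units for quantitative traits and log-odds for binary
    traits. ``eaf`` may be ``None`` when the source file lacks frequencies.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: Optional[float]
    beta: float
    se: float
    pvalue: float
    n: int

    def __post_init__(self) -> None:
        if self.effect_allele not in _BASES or self.other_allele not in _BASES:
            raise ValueError(f"{self.variant_id}: alleles must be single bases A/C/G/T")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: effect and other allele are identical")
        if not (self.se > 0) or not math.isfinite(self.se):
            raise ValueError(f"{self.variant_id}: se must be positive and finite")
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            raise ValueError(f"{self.variant_id}: eaf must lie in (0, 1)")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"{self.variant_id}: p-value must lie in (0, 1]")
        if self.pos < 1:
            raise ValueError(f"{self.variant_id}: position must be >= 1")
        if self.n < 1:
            raise ValueError(f"{self.variant_id}: sample size must be positive")
        if not math.isfinite(self.beta):
            raise ValueError(f"{self.variant_id}: beta must be finite")

    @property
    def is_palindromic(self) -> bool:
        """True for A/T and G/C variants, whose strand cannot be read off alleles."""
        return self.other_allele == _COMPLEMENT[self.effect_allele]


@dataclass
class SummaryDataset:
    """An ordered collection of :class:`VariantRecord` for one trait."""

    trait_name: str
    trait_type: str  # "quantitative" | "binary"
    records: list[VariantRecord]
    n_total: int
    n_cases: Optional[int] = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        ids = [r.variant_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError(f"{self.trait_name}: duplicate variant ids")
        if self.n_cases is not None and self.n_cases >= self.n_total:
            raise ValueError(f"{self.trait_name}: n_cases must be < n_total")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self.records)

    def variant_ids(self) -> list[str]:
        return [r.variant_id for r in self.records]

    def get(self, variant_id: str) -> VariantRecord:
        return self._index()[variant_id]

    def _index(self) -> dict[str, VariantRecord]:
        return {r.variant_id: r for r in self.records}

    def subset(self, variant_ids: Iterable[str]) -> "SummaryDataset":
        """Restrict to the given ids, preserving this dataset's record order."""
        keep = set(variant_ids)
        return replace(self, records=[r for r in self.records if r.variant_id in keep])

    def to_frame(self, column_map: Optional[Mapping[str, str]] = None) -> pd.DataFrame:
        cols = dict(DEFAULT_COLUMNS if column_map is None else column_map)
        data = {
            cols["variant_id"]: [r.variant_id for r in self.records],
            cols["chrom"]: [r.chrom for r in self.records],
            cols["pos"]: [r.pos for r in self.records],
            cols["effect_allele"]: [r.effect_allele for r in self.records],
            cols["other_allele"]: [r.other_allele for r in self.records],
            cols["eaf"]: [r.eaf for r in self.records],
            cols["beta"]: [r.beta for r in self.records],
            cols["se"]: [r.se for r in self.records],
            cols["pvalue"]: [r.pvalue for r in self.records],
            cols["n"]: [r.n for r in self.records],
        }
        return pd.DataFrame(data)


@dataclass(frozen=True)
class GeneRegion:
    """A gene's genomic footprint plus a symmetric flank, as closed intervals."""

    chrom: str
    start: int
    end: int
    flank: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start must be <= end")
        if self.flank < 0:
            raise ValueError("flank must be >= 0")

    @property
    def window_start(self) -> int:
        return max(1, self.start - self.flank)

    @property
    def window_end(self) -> int:
        return self.end + self.flank

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.window_start <= pos <= self.window_end

    @classmethod
    def parse(cls, text: str, flank: int = 0) -> "GeneRegion":
        """Parse ``chrom:start-end`` (commas and whitespace tolerated)."""
        try:
            chrom, span = text.split(":")
            lo, hi = span.replace(",", "").replace(" ", "").split("-")
            return cls(chrom=chrom.strip(), start=int(lo), end=int(hi), flank=flank)
        except (ValueError, AttributeError) as exc:
            raise ConfigurationError(f"cannot parse region {text!r}; expected chrom:start-end") from exc


@dataclass(frozen=True)
class HarmonizedVariant:
    """One allele-aligned exposure/outcome effect pair."""

    variant_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: Optional[float]
    eaf_out: Optional[float]
    action_taken: str  # none | swapped | strand_flipped


@dataclass
class HarmonizedInstruments:
    """Allele-aligned exposure/outcome pairs ready for causal-effect estimation."""

    variants: list[HarmonizedVariant]
    dropped: list[tuple[str, str]] = field(default_factory=list)  # (variant_id, reason)

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self) -> Iterator[HarmonizedVariant]:
        return iter(self.variants)

    @property
    def n_intersection(self) -> int:
        return len(self.variants) + len(self.dropped)

    def arrays(self):
        """Return (beta_exp, se_exp, beta_out, se_out) as float lists."""
        bx = [v.beta_exp for v in self.variants]
        sx = [v.se_exp for v in self.variants]
        by = [v.beta_out for v in self.variants]
        sy = [v.se_out for v in self.variants]
        return bx, sx, by, sy

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": [v.variant_id for v in self.variants],
                "beta_exp": [v.beta_exp for v in self.variants],
                "se_exp": [v.se_exp for v in self.variants],
                "beta_out": [v.beta_out for v in self.variants],
                "se_out": [v.se_out for v in self.variants],
                "eaf_exp": [v.eaf_exp for v in self.variants],
                "eaf_out": [v.eaf_out for v in self.variants],
                "action_taken": [v.action_taken for v in self.variants],
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "HarmonizedInstruments":
        df = pd.read_csv(path, sep="\t")
        required = {"variant_id", "beta_exp", "se_exp", "beta_out", "se_out"}
        missing = required - set(df.columns)
        if missing:
            raise ConfigurationError(f"harmonized TSV missing columns: {sorted(missing)}")
        variants = []
        for row in df.itertuples(index=False):
            variants.append(
                HarmonizedVariant(
                    variant_id=str(row.variant_id),
                    beta_exp=float(row.beta_exp),
                    se_exp=float(row.se_exp),
                    beta_out=float(row.beta_out),
                    se_out=float(row.se_out),
                    eaf_exp=_opt_float(getattr(row, "eaf_exp", None)),
                    eaf_out=_opt_float(getattr(row, "eaf_out", None)),
                    action_taken=str(getattr(row, "action_taken", "none")),
                )
            )
        return cls(variants=variants)


def _opt_float(x) -> Optional[float]:
    if x is None:
        return None
    x = float(x)
    return None if math.isnan(x) else x


def read_summary_stats(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    trait_name: str = "trait",
    trait_type: str = "quantitative",
    n_total: Optional[int] = None,
    n_cases: Optional[int] = None,
) -> SummaryDataset:
    """Read a tab-separated summary-statistics file into a :class:`SummaryDataset`.

    Rows violating record invariants (se <= 0, eaf outside (0,1), ...) are
    rejected; the rejection count is logged. ``n_total`` defaults to the
    maximum per-variant ``n``.

    Raises
    ------
    ConfigurationError
        If a mandatory mapped column is absent from the header.
    EmptyInputError
        If no row passes validation.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype={cols["chrom"]: str})
    mandatory = [k for k in DEFAULT_COLUMNS if k != "eaf"]
    missing = [cols[k] for k in mandatory if cols[k] not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing mandatory column(s) {missing}")
    has_eaf = cols["eaf"] in df.columns

    records: list[VariantRecord] = []
    n_rejected = 0
    for row in df.to_dict("records"):
        try:
            eaf = _opt_float(row[cols["eaf"]]) if has_eaf else None
            records.append(
                VariantRecord(
                    variant_id=str(row[cols["variant_id"]]),
                    chrom=str(row[cols["chrom"]]),
                    pos=int(row[cols["pos"]]),
                    effect_allele=str(row[cols["effect_allele"]]).upper(),
                    other_allele=str(row[cols["other_allele"]]).upper(),
                    eaf=eaf,
                    beta=float(row[cols["beta"]]),
                    se=float(row[cols["se"]]),
                    pvalue=float(row[cols["pvalue"]]),
                    n=int(row[cols["n"]]),
                )
            )
        except (ValueError, TypeError) as exc:
            n_rejected += 1
            logger.debug("rejected row: %s", exc)
    if n_rejected:
        logger.warning("%s: rejected %d of %d rows failing invariants", path, n_rejected, len(df))
    if not records:
        raise EmptyInputError(f"{path}: no valid summary-statistic rows")
    if n_total is None:
        n_total = max(r.n for r in records)
    return SummaryDataset(
        trait_name=trait_name,
        trait_type=trait_type,
        records=records,
        n_total=n_total,
        n_cases=n_cases,
    )


def write_summary_stats(dataset: SummaryDataset, path, column_map: Optional[Mapping[str, str]] = None) -> None:
    """Write a dataset as a tab-separated file re-readable by :func:`read_summary_stats`."""
    dataset.to_frame(column_map).to_csv(path, sep="\t", index=False)


def _match_orientation(exp: VariantRecord, out: VariantRecord, allow_strand_flip: bool) -> Optional[str]:
    """Classify the outcome's allele orientation relative to the exposure.

    Returns one of ``none`` (same orientation), ``swapped`` (effect/other
    exchanged, with or without a strand flip), ``strand_flipped`` (other
    strand, same orientation), or ``None`` when the allele pairs cannot be
    reconciled. Palindromic variants are handled by the caller.
    """
    ea, oa = exp.effect_allele, exp.other_allele
    if (out.effect_allele, out.other_allele) == (ea, oa):
        return "none"
    if (out.effect_allele, out.other_allele) == (oa, ea):
        return "swapped"
    if allow_strand_flip:
        cea, coa = _COMPLEMENT[out.effect_allele], _COMPLEMENT[out.other_allele]
        if (cea, coa) == (ea, oa):
            return "strand_flipped"
        if (cea, coa) == (oa, ea):
            return "swapped"
    return None


def harmonize(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    palindromic_eaf_window: float = DEFAULT_PALINDROMIC_EAF_WINDOW,
    allow_strand_flip: bool = True,
) -> HarmonizedInstruments:
    """Align outcome effect alleles to the exposure's and pair the effects.

    Matching is by ``variant_id`` only. When the outcome's alleles are
    exchanged relative to the exposure, ``beta_out`` is negated and
    ``eaf_out`` replaced by ``1 - eaf_out``. Complementary-strand matches
    are resolved by complementing the outcome's alleles first (when
    ``allow_strand_flip``). Palindromic variants (A/T, G/C) whose eaf on
    either side lies within ``0.5 ± palindromic_eaf_window`` — or lacks an
    eaf on either side — are dropped; outside that window the frequencies
    decide the orientation.

    Raises
    ------
    NoInstrumentsError
        If the id-intersection of the two datasets is empty.
    """
    if not (0 <= palindromic_eaf_window < 0.5):
        raise ValueError("palindromic_eaf_window must lie in [0, 0.5)")
    out_index = outcome._index()
    shared = [r for r in exposure.records if r.variant_id in out_index]
    if not shared:
        raise NoInstrumentsError(
            f"no shared variants between {exposure.trait_name!r} and {outcome.trait_name!r}"
        )

    w = palindromic_eaf_window
    retained: list[HarmonizedVariant] = []
    dropped: list[tuple[str, str]] = []
    for exp in shared:
        out = out_index[exp.variant_id]
        if exp.is_palindromic or out.is_palindromic:
            if exp.is_palindromic != out.is_palindromic:
                dropped.append((exp.variant_id, "allele_mismatch"))
                continue
            ambiguous = any(
                eaf is None or abs(eaf - 0.5) <= w for eaf in (exp.eaf, out.eaf)
            )
            if ambiguous:
                dropped.append((exp.variant_id, "palindromic"))
                continue
            # Letters are strand-symmetric here: orient by allele labels, then
            # let the frequencies overrule when they disagree across 0.5.
            same_labels = (out.effect_allele, out.other_allele) == (exp.effect_allele, exp.other_allele)
            comp_labels = (out.effect_allele, out.other_allele) == (exp.other_allele, exp.effect_allele)
            if not (same_labels or comp_labels):
                dropped.append((exp.variant_id, "allele_mismatch"))
                continue
            beta_out, eaf_out = out.beta, out.eaf
            action = "none"
            if comp_labels:
                beta_out, eaf_out = -beta_out, 1.0 - eaf_out
                action = "swapped"
            if (exp.eaf - 0.5) * (eaf_out - 0.5) < 0:
                beta_out, eaf_out = -beta_out, 1.0 - eaf_out
                action = "swapped" if action == "none" else "strand_flipped"
        else:
            action = _match_orientation(exp, out, allow_strand_flip)
            if action is None:
                dropped.append((exp.variant_id, "allele_mismatch"))
                continue
            beta_out, eaf_out = out.beta, out.eaf
            if action == "swapped":
                beta_out = -beta_out
                eaf_out = None if eaf_out is None else 1.0 - eaf_out
        retained.append(
            HarmonizedVariant(
                variant_id=exp.variant_id,
                beta_exp=exp.beta,
                se_exp=exp.se,
                beta_out=beta_out,
                se_out=out.se,
                eaf_exp=exp.eaf,
                eaf_out=eaf_out,
                action_taken=action,
            )
        )
    return HarmonizedInstruments(variants=retained, dropped=dropped)
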