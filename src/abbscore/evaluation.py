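"""Worked-example arithmetic for validation and enrichment summaries.

Small, exact computations on printed count tables: true/false-positive
rates of Sanger-validated calls per confidence bin (failed experiments
excluded from the TP/FP denominator), observed/expected enrichment ratios
of flagged positions in variant databases, and the transition-transversion
ratio of an SNV set.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
from scipy import stats


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, the convention of printed tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SangerBinCounts:
    """Sanger validation outcome counts for one confidence bin."""

    label: str
    n_snvs: int
    tp: int
    fp: int
    failed: int

    def __post_init__(self):
        if self.tp + self.fp + self.failed != self.n_snvs:
            raise ValueError("tp + fp + failed must equal n_snvs")


@dataclass(frozen=True)
class SangerRates:
    tp_rate: Optional[float]  # percent, 2 decimals; None when undefined
    fp_rate: Optional[float]
    fail_rate: float


def sanger_rates(c: SangerBinCounts) -> SangerRates:
    """TP/FP rates on conclusive experiments only; fail rate on all."""
    fail = round_half_up(100.0 * c.failed / c.n_snvs) if c.n_snvs else 0.0
    conclusive = c.tp + c.fp
    if conclusive == 0:
        return SangerRates(None, None, fail)
    return SangerRates(
        tp_rate=round_half_up(100.0 * c.tp / conclusive),
        fp_rate=round_half_up(100.0 * c.fp / conclusive),
        fail_rate=fail,
    )


@dataclass(frozen=True)
class EnrichmentInput:
    """Flagged-position counts in a database vs the exome background."""

    db_total: int
    db_flagged: int
    bg_total: int
    bg_flagged: int

    def __post_init__(self):
        if not (0 < self.db_total and 0 < self.bg_total):
            raise ValueError("totals must be positive")
        if self.db_flagged > self.db_total or self.bg_flagged > self.bg_total:
            raise ValueError("flagged counts cannot exceed totals")


@dataclass(frozen=True)
class EnrichmentResult:
    observed_freq: float
    ratio: Optional[float]  # None when the background has no flagged sites
    chi_square_p: float


def enrichment_ratio(e: EnrichmentInput) -> EnrichmentResult:
    """Observed flagged frequency, obs/exp ratio against the background
    frequency, and the Pearson chi-square p (no continuity correction)."""
    obs = e.db_flagged / e.db_total
    if e.bg_flagged == 0:
        ratio = None
    else:
        ratio = obs / (e.bg_flagged / e.bg_total)
    table = np.array(
        [
            [e.db_flagged, e.db_total - e.db_flagged],
            [e.bg_flagged, e.bg_total - e.bg_flagged],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        p = 1.0
    else:
        p = float(stats.chi2_contingency(table, correction=False)[1])
    return EnrichmentResult(obs, ratio, p)


_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def titv_ratio(variants: Sequence[tuple[str, str]]) -> Optional[float]:
    """Transition/transversion ratio of (ref, alt) SNV pairs; None when
    there are no transversions."""
    ti = tv = 0
    for ref, alt in variants:
        pair = frozenset((ref.upper(), alt.upper()))
        if len(pair) != 2 or not pair <= set("ACGT"):
            raise ValueError(f"not a SNV substitution: {ref}>{alt}")
        if pair in _TRANSITIONS:
            ti += 1
        else:
            tv += 1
    if tv == 0:
        return None
    return ti / tv


# Printed validation and enrichment inputs: Sanger outcomes per confidence
# bin and flagged-position counts per public database against the exome
# background. Used by the eval-tables workflow as worked examples.
SANGER_VALIDATION_BINS = (
    SangerBinCounts("high", 42, 38, 0, 4),
    SangerBinCounts("medium", 73, 55, 10, 8),
    SangerBinCounts("low", 46, 20, 9, 17),
    SangerBinCounts("very_low", 48, 21, 21, 6),
)

EXOME_BACKGROUND = {"total": 81_609_944, "flagged": 20_725}

DATABASE_ENRICHMENT_INPUTS = {
    "dbSNP": EnrichmentInput(3_172_724, 12_787, EXOME_BACKGROUND["total"], EXOME_BACKGROUND["flagged"]),
    "EVS": EnrichmentInput(1_840_709, 1_114, EXOME_BACKGROUND["total"], EXOME_BACKGROUND["flagged"]),
    "1000GP": EnrichmentInput(2_653_982, 4_690, EXOME_BACKGROUND["total"], EXOME_BACKGROUND["flagged"]),
    "ExAC": EnrichmentInput(2_662_396, 3_510, EXOME_BACKGROUND["total"], EXOME_BACKGROUND["flagged"]),
}
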