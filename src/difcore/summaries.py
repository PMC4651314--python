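"""Small desk-statistics helpers for run-summary tables.

These reproduce the arithmetic behind typical sequencing summary tables:
base-retention percentages, annotation shares, and average contig lengths,
all rounded half-up to the number of decimals such tables print.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "percent_half_up", "annotation_share_pct", "average_length"]


def round_half_up(value: float, decimals: int) -> float:
    """Round with ties away from zero (spreadsheet convention), not banker's."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def percent_half_up(numerator: float, denominator: float, decimals: int = 2) -> float:
    """100 * numerator / denominator rounded half-up."""
    if denominator == 0:
        raise ValueError("denominator must be non-zero")
    quantum = Decimal(1).scaleb(-decimals)
    ratio = Decimal(100) * Decimal(repr(numerator)) / Decimal(repr(denominator))
    return float(ratio.quantize(quantum, rounding=ROUND_HALF_UP))


def annotation_share_pct(n_annotated: int, n_total: int) -> float:
    """Share of annotated genes among all genes, percent to 1 decimal."""
    return percent_half_up(n_annotated, n_total, decimals=1)


def average_length(total_bases: int, n_contigs: int) -> float:
    """Mean contig length in bp to 2 decimals (total characters / contigs)."""
    if n_contigs <= 0:
        raise ValueError("n_contigs must be positive")
    quantum = Decimal("0.01")
    return float((Decimal(total_bases) / Decimal(n_contigs)).quantize(quantum, rounding=ROUND_HALF_UP))
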