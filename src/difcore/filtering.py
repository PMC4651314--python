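"""Read-level quality filtering of FASTQ input.

A read is discarded iff strictly more than 5% of its bases are ambiguous
(N/n) or strictly more than 30% of its bases fall below Q20 (Phred+33).
Both thresholds are parameters; the defaults encode the strict ">" rules.
Adapter trimming is expected upstream — the filter assumes adapter-free
reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from .summaries import percent_half_up

__all__ = ["FilterStats", "read_passes", "filter_records", "filter_fastq", "retention_stats"]

AMBIGUOUS = frozenset("Nn")
PHRED_OFFSET = 33


@dataclass
class FilterStats:
    """Raw-vs-clean accounting in the style of a run-statistics table."""

    reads_before: int = 0
    reads_after: int = 0
    bases_before: int = 0
    bases_after: int = 0

    @property
    def retention_pct(self) -> float:
        """Base retention, percent, rounded half-up to 2 decimals."""
        return retention_stats(self.bases_before, self.bases_after)


def read_passes(
    seq: str,
    qual: str,
    max_n_frac: float = 0.05,
    min_q: int = 20,
    max_lowq_frac: float = 0.30,
) -> bool:
    """True iff the read survives both the N-fraction and low-quality rules."""
    length = len(seq)
    if length == 0:
        return False
    n_count = sum(1 for b in seq if b in AMBIGUOUS)
    if n_count / length > max_n_frac:
        return False
    lowq = sum(1 for c in qual if ord(c) - PHRED_OFFSET < min_q)
    return not lowq / length > max_lowq_frac


def filter_records(
    records: Iterable[tuple[str, str, str]],
    max_n_frac: float = 0.05,
    min_q: int = 20,
    max_lowq_frac: float = 0.30,
) -> Iterator[tuple[tuple[str, str, str], bool, FilterStats]]:
    """Yield (record, kept, running_stats) for a stream of FASTQ records.

    Records are (title, sequence, quality). The same ``FilterStats`` object
    is updated and yielded throughout; its final state is the file summary.
    Filtering is per-read, so output content is independent of read order.
    """
    stats = FilterStats()
    for idx, (title, seq, qual) in enumerate(records):
        if len(seq) != len(qual):
            raise ValueError(
                f"record {idx} ({title}): sequence length {len(seq)} != quality length {len(qual)}"
            )
        kept = read_passes(seq, qual, max_n_frac, min_q, max_lowq_frac)
        stats.reads_before += 1
        stats.bases_before += len(seq)
        if kept:
            stats.reads_after += 1
            stats.bases_after += len(seq)
        yield (title, seq, qual), kept, stats


def filter_fastq(
    fastq_in,
    fastq_out,
    max_n_frac: float = 0.05,
    min_q: int = 20,
    max_lowq_frac: float = 0.30,
) -> FilterStats:
    """Filter a FASTQ file (gzip transparent) and write the retained reads."""
    from . import io as dio

    stats = FilterStats()
    kept_records = []
    for record, kept, stats in filter_records(
        dio.read_fastq(fastq_in), max_n_frac, min_q, max_lowq_frac
    ):
        if kept:
            kept_records.append(record)
    dio.write_fastq(fastq_out, kept_records)
    return stats


def retention_stats(bases_before: int, bases_after: int) -> float:
    """100 * after / before, rounded half-up to 2 decimals."""
    if bases_before <= 0:
        raise ValueError("bases_before must be positive")
    if not 0 <= bases_after <= bases_before:
        raise ValueError("bases_after must lie in [0, bases_before]")
    return percent_half_up(bases_after, bases_before, decimals=2)
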