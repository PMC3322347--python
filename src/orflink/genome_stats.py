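"""Assembly- and ORF-level quality metrics.

Draft-genome quality is summarized by contig N50, deviation of %GC from 50%
(a proxy for per-read information content and assembly difficulty), and the
extent of ORF fragmentation (counts and percentage of partial ORFs, mean
predicted protein length).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from orflink.io_formats import ContigRecord, IntegrityError, OrfRecord, OrflinkError


class DomainError(OrflinkError):
    """An operation was applied outside its mathematical domain."""


@dataclass(frozen=True)
class GenomeStats:
    genome_id: str
    n_contigs: int
    total_bp: int
    n50: int
    gc_fraction: float
    gc_deviation: float
    n_complete_orfs: int
    n_partial_orfs: int
    pct_partial: float  # full precision; round at reporting time
    mean_orf_length_aa: float


def compute_n50(contig_lengths: Sequence[int]) -> int:
    """Smallest contig length L such that contigs of length >= L hold at
    least half the assembly.

    When the running sum first meets exactly half the total, that contig's
    length is the N50.
    """
    if not contig_lengths:
        raise DomainError("N50 of an empty assembly is undefined")
    if any(x <= 0 for x in contig_lengths):
        raise DomainError("contig lengths must be positive")
    half = sum(contig_lengths) / 2.0
    running = 0
    for length in sorted(contig_lengths, reverse=True):
        running += length
        if running >= half:
            return length
    raise AssertionError("unreachable")  # pragma: no cover


def gc_counts(sequence: str) -> tuple[int, int]:
    """(G+C count, unambiguous A/C/G/T count) of one sequence; N and other
    ambiguity codes contribute to neither."""
    counts = Counter(sequence.upper())
    gc = counts["G"] + counts["C"]
    return gc, gc + counts["A"] + counts["T"]


def compute_gc_deviation(contigs: Sequence[ContigRecord]) -> tuple[float, float]:
    """Pooled GC fraction over all contigs and its absolute deviation from 0.5."""
    gc_total = 0
    acgt_total = 0
    for contig in contigs:
        gc, acgt = gc_counts(contig.sequence)
        gc_total += gc
        acgt_total += acgt
    if acgt_total == 0:
        raise DomainError("no unambiguous A/C/G/T bases; GC fraction undefined")
    frac = gc_total / acgt_total
    return frac, abs(frac - 0.5)


def summarize_orfs(orfs: Sequence[OrfRecord]) -> tuple[int, int, float, float]:
    """(n_complete, n_partial, pct_partial, mean_orf_length_aa).

    An ORF is partial when its truncation state is anything but intact.
    Percentages and the mean are returned at full precision; empty input
    yields NaN for both ratios.
    """
    n_partial = sum(1 for o in orfs if o.is_partial)
    n_complete = len(orfs) - n_partial
    if orfs:
        pct_partial = 100.0 * n_partial / len(orfs)
        mean_len = sum(o.length_aa for o in orfs) / len(orfs)
    else:
        pct_partial = math.nan
        mean_len = math.nan
    return n_complete, n_partial, pct_partial, mean_len


def round_pct(value: float, ndigits: int = 1) -> float:
    """Round half-up at reporting time (so 77.05 -> 77.1, not banker's 77.0)."""
    if math.isnan(value):
        return value
    scale = 10**ndigits
    return math.floor(value * scale + 0.5) / scale


def genome_report(contigs: Sequence[ContigRecord], orfs: Sequence[OrfRecord]) -> GenomeStats:
    """Aggregate all per-genome metrics; contigs and ORFs must agree on genome."""
    if not contigs:
        raise DomainError("genome_report requires at least one contig")
    genome_ids = {c.genome_id for c in contigs} | {o.genome_id for o in orfs}
    if len(genome_ids) != 1:
        raise IntegrityError(f"contigs and ORFs mix genome ids: {sorted(genome_ids)}")
    contig_ids = {c.contig_id for c in contigs}
    for orf in orfs:
        if orf.contig_id not in contig_ids:
            raise IntegrityError(f"ORF {orf.orf_id} references unknown contig {orf.contig_id}")
    gc_fraction, gc_deviation = compute_gc_deviation(contigs)
    n_complete, n_partial, pct_partial, mean_len = summarize_orfs(orfs)
    return GenomeStats(
        genome_id=genome_ids.pop(),
        n_contigs=len(contigs),
        total_bp=sum(c.length for c in contigs),
        n50=compute_n50([c.length for c in contigs]),
        gc_fraction=gc_fraction,
        gc_deviation=gc_deviation,
        n_complete_orfs=n_complete,
        n_partial_orfs=n_partial,
        pct_partial=pct_partial,
        mean_orf_length_aa=mean_len,
    )
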