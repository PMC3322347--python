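"""Annotation-bias quantification and fragment-set correction.

ORF fragmentation distorts annotation statistics two ways: fragments may be
too short to hit their domain/orthology database (under-annotation), and
several fragments of one gene may each be annotated separately
(over-annotation).  This module measures annotation rates, applies the
fragment-set correction (a linked set counts once, annotated if ANY member
is), correlates rates with genome-quality proxies, and profiles partial vs
complete ORFs by annotation category.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from orflink.genome_stats import DomainError, GenomeStats
from orflink.io_formats import AnnotationTable, FragmentSet, OrfRecord
from orflink.linkage import merge_inventory


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int


@dataclass(frozen=True)
class CategoryProfile:
    """Per-category percentages of annotated complete vs partial ORFs,
    pooled across genomes, with a per-genome breakdown for inspection."""

    pooled: dict[str, tuple[float, float]]  # category -> (pct_complete, pct_partial)
    per_genome: dict[str, dict[str, tuple[float, float]]]
    n_complete_annotated: int
    n_partial_annotated: int


def annotation_rate(table: AnnotationTable, orfs: Sequence[OrfRecord]) -> float:
    """Percent of all ORFs carrying at least one annotation term."""
    if not orfs:
        raise DomainError("annotation rate of an empty proteome is undefined")
    annotated = sum(1 for o in orfs if table.is_annotated(o.orf_id))
    return 100.0 * annotated / len(orfs)


def corrected_annotation_rate(
    table: AnnotationTable, orfs: Sequence[OrfRecord], sets: Sequence[FragmentSet]
) -> float:
    """Annotation rate after collapsing each fragment set to one unit.

    A merged unit is annotated iff any member is; this is what removes the
    duplicate annotations that fragments of one gene otherwise contribute.
    """
    units = merge_inventory(orfs, sets)
    if not units:
        raise DomainError("annotation rate of an empty inventory is undefined")
    annotated = sum(
        1 for u in units if any(table.is_annotated(m) for m in u.member_ids)
    )
    return 100.0 * annotated / len(units)


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation with a two-sided p-value from the t distribution
    on n-2 degrees of freedom."""
    if len(x) != len(y):
        raise DomainError("pearson requires equal-length vectors")
    if len(x) < 3:
        raise DomainError("pearson requires at least three observations")
    xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise DomainError("pearson is undefined for zero-variance input")
    res = stats.pearsonr(xa, ya)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue), n=len(x))


def category_profile(
    tables: Mapping[str, AnnotationTable],
    orfs_by_genome: Mapping[str, Sequence[OrfRecord]],
    category_map: Mapping[str, str],
) -> CategoryProfile:
    """Category composition of annotated partial vs complete ORFs.

    Counts are pooled across genomes within each ORF class before converting
    to percentages, because per-genome percentages are unstable when a
    genome has only a handful of partial ORFs.  Terms missing from the
    category map raise a warning and pool under ``unclassified``.
    """
    def count_one(
        table: AnnotationTable, orfs: Sequence[OrfRecord]
    ) -> tuple[dict[str, int], dict[str, int], int, int]:
        complete_counts: dict[str, int] = {}
        partial_counts: dict[str, int] = {}
        n_complete = n_partial = 0
        for orf in orfs:
            terms = table.terms_for(orf.orf_id)
            if not terms:
                continue
            cats = set()
            for term in terms:
                if term not in category_map:
                    warnings.warn(f"term {term!r} missing from category map; using 'unclassified'")
                cats.add(category_map.get(term, "unclassified"))
            target = partial_counts if orf.is_partial else complete_counts
            if orf.is_partial:
                n_partial += 1
            else:
                n_complete += 1
            for cat in cats:
                target[cat] = target.get(cat, 0) + 1
        return complete_counts, partial_counts, n_complete, n_partial

    pooled_complete: dict[str, int] = {}
    pooled_partial: dict[str, int] = {}
    total_complete = total_partial = 0
    per_genome: dict[str, dict[str, tuple[float, float]]] = {}
    for genome_id, table in tables.items():
        cc, pc, nc, np_ = count_one(table, orfs_by_genome[genome_id])
        for cat, n in cc.items():
            pooled_complete[cat] = pooled_complete.get(cat, 0) + n
        for cat, n in pc.items():
            pooled_partial[cat] = pooled_partial.get(cat, 0) + n
        total_complete += nc
        total_partial += np_
        per_genome[genome_id] = {
            cat: (
                100.0 * cc.get(cat, 0) / nc if nc else float("nan"),
                100.0 * pc.get(cat, 0) / np_ if np_ else float("nan"),
            )
            for cat in set(cc) | set(pc)
        }
    pooled = {
        cat: (
            100.0 * pooled_complete.get(cat, 0) / total_complete
            if total_complete
            else float("nan"),
            100.0 * pooled_partial.get(cat, 0) / total_partial
            if total_partial
            else float("nan"),
        )
        for cat in set(pooled_complete) | set(pooled_partial)
    }
    return CategoryProfile(
        pooled=pooled,
        per_genome=per_genome,
        n_complete_annotated=total_complete,
        n_partial_annotated=total_partial,
    )


@dataclass(frozen=True)
class ImpactRow:
    quality_metric: str  # 'pct_partial' or 'mean_orf_length'
    corrected: bool
    excluded_genome: str | None
    result: CorrelationResult


def quality_vs_annotation_report(
    stats_list: Sequence[GenomeStats],
    rates: Sequence[float],
    corrected_rates: Sequence[float] | None = None,
    exclude_genome_id: str | None = None,
) -> list[ImpactRow]:
    """Correlate annotation rates with both genome-quality proxies.

    Produces the %-partial-vs-rate and mean-ORF-length-vs-rate correlations
    for the uncorrected rates and, when supplied, the set-corrected rates;
    when ``exclude_genome_id`` is given, leave-that-genome-out rows are
    appended (useful when one outlier assembly dominates the trend).
    """
    if len(stats_list) < 3:
        raise DomainError("need at least three genomes to correlate")
    if len(rates) != len(stats_list):
        raise DomainError("one rate per genome is required")

    def rows_for(keep: list[int], excluded: str | None) -> list[ImpactRow]:
        out = []
        pct = [stats_list[i].pct_partial for i in keep]
        mol = [stats_list[i].mean_orf_length_aa for i in keep]
        panels: list[tuple[bool, Sequence[float]]] = [(False, rates)]
        if corrected_rates is not None:
            panels.append((True, corrected_rates))
        for corrected, values in panels:
            vv = [values[i] for i in keep]
            out.append(ImpactRow("pct_partial", corrected, excluded, pearson(pct, vv)))
            out.append(ImpactRow("mean_orf_length", corrected, excluded, pearson(mol, vv)))
        return out

    all_idx = list(range(len(stats_list)))
    rows = rows_for(all_idx, None)
    if exclude_genome_id is not None:
        keep = [i for i in all_idx if stats_list[i].genome_id != exclude_genome_id]
        if len(keep) == len(all_idx):
            raise DomainError(f"genome {exclude_genome_id!r} not found for exclusion")
        rows.extend(rows_for(keep, exclude_genome_id))
    return rows
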