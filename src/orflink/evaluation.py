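"""Scaffold-based validation of fragment sets and threshold grid search.

Scaffolds (ordered, oriented contig layouts) are independent of the
homology evidence used for linkage, so they serve as ground truth: two
linked fragments are a true positive when their contigs are consecutive in
one scaffold and each fragment's truncated end faces the inter-contig gap.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from orflink.io_formats import (
    FragmentSet,
    HitRecord,
    IntegrityError,
    OrfRecord,
    ScaffoldCollection,
)
from orflink.homology import search_proteome
from orflink.linkage import LinkageParams, link_against_references


class LinkClass(enum.Enum):
    TRUE = "true"
    FALSE = "false"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class EvaluationResult:
    genome_id: str
    n_linked_fragments: int
    n_true: int
    n_false: int
    n_unknown: int
    pct_true_of_partial: float
    pct_false_of_partial: float


@dataclass(frozen=True)
class GridPoint:
    params: LinkageParams
    n_linked: int
    n_true: int
    n_false: int
    true_fraction: float


def _scaffold_edge(contig_edge: str, orientation: str) -> str:
    """Map a contig-coordinate edge to a scaffold-coordinate edge."""
    if orientation == "+":
        return contig_edge
    return "left" if contig_edge == "right" else "right"


def classify_pair(
    frag_1: OrfRecord,
    frag_2: OrfRecord,
    scaffolds: ScaffoldCollection,
    require_orientation: bool = True,
) -> LinkClass:
    """Judge one linked fragment pair against scaffold adjacency.

    TRUE: the fragments sit on distinct contigs at consecutive ranks of one
    scaffold, and (unless ``require_orientation`` is off) each fragment's
    truncated side faces the gap between the two contigs once contig
    orientation is applied.  FALSE: both contigs are scaffold-placed but the
    condition fails.  UNKNOWN: either contig is unplaced.
    """
    p1 = scaffolds.placement(frag_1.contig_id)
    p2 = scaffolds.placement(frag_2.contig_id)
    if p1 is None or p2 is None:
        return LinkClass.UNKNOWN
    (scf1, e1), (scf2, e2) = p1, p2
    if scf1 != scf2 or e1.contig_id == e2.contig_id:
        return LinkClass.FALSE
    if abs(e1.rank - e2.rank) != 1:
        return LinkClass.FALSE
    if not require_orientation:
        return LinkClass.TRUE
    lower, lower_orf = (e1, frag_1) if e1.rank < e2.rank else (e2, frag_2)
    upper, upper_orf = (e2, frag_2) if e1.rank < e2.rank else (e1, frag_1)
    lower_edges = {_scaffold_edge(e, lower.orientation) for e in lower_orf.truncated_contig_edges()}
    upper_edges = {_scaffold_edge(e, upper.orientation) for e in upper_orf.truncated_contig_edges()}
    if "right" in lower_edges and "left" in upper_edges:
        return LinkClass.TRUE
    return LinkClass.FALSE


def classify_fragments(
    sets: Sequence[FragmentSet],
    orfs_by_id: Mapping[str, OrfRecord],
    scaffolds: ScaffoldCollection,
    require_orientation: bool = True,
) -> dict[str, LinkClass]:
    """Per-fragment verdicts: TRUE when every pair the fragment participates
    in (consecutive members in reference order) is TRUE, FALSE when any is
    FALSE, UNKNOWN otherwise."""
    verdicts: dict[str, LinkClass] = {}
    for fs in sets:
        pair_classes: dict[str, list[LinkClass]] = {m: [] for m in fs.members}
        for m1, m2 in itertools.pairwise(fs.members):
            cls = classify_pair(orfs_by_id[m1], orfs_by_id[m2], scaffolds, require_orientation)
            pair_classes[m1].append(cls)
            pair_classes[m2].append(cls)
        for member, classes in pair_classes.items():
            if any(c is LinkClass.FALSE for c in classes):
                verdicts[member] = LinkClass.FALSE
            elif all(c is LinkClass.TRUE for c in classes):
                verdicts[member] = LinkClass.TRUE
            else:
                verdicts[member] = LinkClass.UNKNOWN
    return verdicts


def evaluate_sets(
    sets: Sequence[FragmentSet],
    orfs: Sequence[OrfRecord],
    scaffolds: ScaffoldCollection,
    partial_total: int,
    require_orientation: bool = True,
) -> EvaluationResult:
    """Fragment-level true/false-link rates against scaffold truth.

    Percentages use the genome's partial-ORF total as denominator, matching
    how linkage efficacy is reported per genome.
    """
    if partial_total == 0 and sets:
        raise IntegrityError("nonempty fragment sets but zero partial ORFs reported")
    orfs_by_id = {o.orf_id: o for o in orfs}
    for fs in sets:
        for m in fs.members:
            if m not in orfs_by_id:
                raise IntegrityError(f"set {fs.set_id} references unknown ORF {m}")
    verdicts = classify_fragments(sets, orfs_by_id, scaffolds, require_orientation)
    n_true = sum(1 for v in verdicts.values() if v is LinkClass.TRUE)
    n_false = sum(1 for v in verdicts.values() if v is LinkClass.FALSE)
    n_unknown = sum(1 for v in verdicts.values() if v is LinkClass.UNKNOWN)
    genome_id = sets[0].genome_id if sets else (orfs[0].genome_id if orfs else "")
    return EvaluationResult(
        genome_id=genome_id,
        n_linked_fragments=len(verdicts),
        n_true=n_true,
        n_false=n_false,
        n_unknown=n_unknown,
        pct_true_of_partial=100.0 * n_true / partial_total if partial_total else 0.0,
        pct_false_of_partial=100.0 * n_false / partial_total if partial_total else 0.0,
    )


def grid_search(
    target_orfs: Sequence[OrfRecord],
    reference_proteomes: Sequence[Sequence[OrfRecord]],
    scaffolds: ScaffoldCollection,
    identity_grid: Sequence[float],
    overlap_grid: Sequence[float],
    spread_grid: Sequence[float],
    base_params: LinkageParams = LinkageParams(),
    hit_tables: Sequence[Iterable[HitRecord]] | None = None,
    require_orientation: bool = True,
) -> list[GridPoint]:
    """Run the full linkage + evaluation pipeline over a threshold grid.

    Hit tables are computed once (they do not depend on the thresholds, which
    are applied downstream), so the grid only re-runs filtering, assembly and
    validation.  Output order follows the grid order (identity outermost).
    """
    if not (identity_grid and overlap_grid and spread_grid):
        raise IntegrityError("all three grids must be non-empty")
    if hit_tables is None:
        fragments = [o for o in target_orfs if o.is_partial]
        hit_tables = [list(search_proteome(fragments, ref)) for ref in reference_proteomes]
    else:
        hit_tables = [list(h) for h in hit_tables]
    partial_total = sum(1 for o in target_orfs if o.is_partial)
    points: list[GridPoint] = []
    for ident in identity_grid:
        for overlap in overlap_grid:
            for spread in spread_grid:
                params = replace(
                    base_params,
                    min_identity_pct=ident,
                    min_overlap_frac=overlap,
                    max_identity_spread_pct=spread,
                )
                sets, _ = link_against_references(
                    target_orfs, reference_proteomes, hit_tables, params
                )
                result = evaluate_sets(
                    sets, target_orfs, scaffolds, partial_total, require_orientation
                )
                points.append(
                    GridPoint(
                        params=params,
                        n_linked=result.n_linked_fragments,
                        n_true=result.n_true,
                        n_false=result.n_false,
                        true_fraction=(
                            result.n_true / result.n_linked_fragments
                            if result.n_linked_fragments
                            else 0.0
                        ),
                    )
                )
    return points


def grid_to_rows(points: Sequence[GridPoint]) -> list[dict[str, float]]:
    """Long-format rows (one per grid point) for TSV export / surface plots."""
    return [
        {
            "min_identity_pct": p.params.min_identity_pct,
            "min_overlap_frac": p.params.min_overlap_frac,
            "max_identity_spread_pct": p.params.max_identity_spread_pct,
            "n_linked": p.n_linked,
            "n_true": p.n_true,
            "n_false": p.n_false,
            "true_fraction": p.true_fraction,
        }
        for p in points
    ]
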