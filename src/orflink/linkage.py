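"""Homology-based linkage of partial ORFs into fragment sets.

A gene split across contig ends yields several truncated predicted proteins.
When a related genome carries the complete homolog, those fragments align to
disjoint stretches of it; this module recruits such fragments into "fragment
sets" — groups of partial ORFs from one genome inferred to derive from a
single gene — subject to four stringency thresholds:

(i)   minimum percent identity between fragment and reference homolog;
(ii)  minimum fraction of the fragment that must align to the reference;
(iii) maximum spread of the members' identities to the shared reference
      (true fragments of one gene should resemble it about equally);
(iv)  maximum number of amino acids by which members may overlap on the
      reference (large overlaps indicate paralogs, not pieces of one gene).

Biological sanity constraints apply on top: at most two members truncated at
a single end (one missing its start, one missing its stop — fragments
missing both ends are interior pieces and unlimited), and, by default, the
start-containing member must be leftmost on the reference and the
stop-containing member rightmost.

Searches run reciprocally between genome pairs, and across multiple
reference proteomes a fragment's set is replaced whenever another reference
supports an alternative set with a higher mean identity.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from orflink.io_formats import (
    FragmentSet,
    HitRecord,
    IntegrityError,
    OrfRecord,
    Truncation,
)
from orflink.homology import search_proteome


@dataclass(frozen=True)
class LinkageParams:
    """Stringency thresholds for fragment-set assembly (see module docs)."""

    min_identity_pct: float = 30.0
    min_overlap_frac: float = 0.70
    max_identity_spread_pct: float = 40.0
    max_fragment_overlap_aa: int = 10
    max_single_end_truncated: int = 2
    enforce_end_order: bool = True
    overlap_on: str = "fragment"  # or "reference": denominator of threshold (ii)

    def __post_init__(self) -> None:
        if self.min_identity_pct < 0 or self.max_identity_spread_pct < 0:
            raise IntegrityError("identity thresholds must be non-negative")
        if not (0.0 < self.min_overlap_frac <= 1.0):
            raise IntegrityError("min_overlap_frac must lie in (0, 1]")
        if self.max_fragment_overlap_aa < 0:
            raise IntegrityError("max_fragment_overlap_aa must be non-negative")
        if self.overlap_on not in ("fragment", "reference"):
            raise IntegrityError("overlap_on must be 'fragment' or 'reference'")


@dataclass(frozen=True)
class CandidatePlacement:
    """One fragment aligned onto one complete reference protein."""

    fragment_id: str
    reference_protein_id: str
    reference_genome_id: str
    pident: float
    ref_start: int  # aa, 1-based inclusive on the reference
    ref_end: int
    frag_coverage: float
    bitscore: float


def candidate_placements(
    fragments: Sequence[OrfRecord],
    hits: Iterable[HitRecord],
    reference_orfs: Sequence[OrfRecord],
    params: LinkageParams = LinkageParams(),
) -> list[CandidatePlacement]:
    """Filter fragment->reference hits into placement candidates.

    Only hits onto COMPLETE reference proteins survive, with identity and
    coverage thresholds applied; one placement (the highest-scoring hit) is
    kept per (fragment, reference) pair.
    """
    frag_by_id = {f.orf_id: f for f in fragments}
    ref_by_id = {r.orf_id: r for r in reference_orfs}
    best: dict[tuple[str, str], CandidatePlacement] = {}
    for hit in hits:
        frag = frag_by_id.get(hit.query_id)
        ref = ref_by_id.get(hit.subject_id)
        if frag is None or ref is None:
            continue
        if ref.is_partial:
            continue
        if hit.pident < params.min_identity_pct:
            continue
        if params.overlap_on == "fragment":
            coverage = (hit.q_end - hit.q_start + 1) / frag.length_aa
        else:
            coverage = (hit.s_end - hit.s_start + 1) / ref.length_aa
        frag_coverage = (hit.q_end - hit.q_start + 1) / frag.length_aa
        if coverage < params.min_overlap_frac:
            continue
        key = (hit.query_id, hit.subject_id)
        placement = CandidatePlacement(
            fragment_id=hit.query_id,
            reference_protein_id=hit.subject_id,
            reference_genome_id=ref.genome_id,
            pident=hit.pident,
            ref_start=hit.s_start,
            ref_end=hit.s_end,
            frag_coverage=frag_coverage,
            bitscore=hit.bitscore,
        )
        current = best.get(key)
        if current is None or placement.bitscore > current.bitscore:
            best[key] = placement
    out = list(best.values())
    out.sort(key=lambda p: (p.reference_protein_id, -p.pident, p.fragment_id))
    return out


def _interval_overlap(a: CandidatePlacement, b: CandidatePlacement) -> int:
    return min(a.ref_end, b.ref_end) - max(a.ref_start, b.ref_start) + 1


def _end_order_ok(
    members: Sequence[CandidatePlacement], truncations: Mapping[str, Truncation]
) -> bool:
    ordered = sorted(members, key=lambda p: (p.ref_start, p.fragment_id))
    last = len(ordered) - 1
    for idx, placement in enumerate(ordered):
        t = truncations[placement.fragment_id]
        # a member still holding its start (3'-truncated) must be leftmost;
        # a member still holding its stop (5'-truncated) must be rightmost
        if t is Truncation.THREE_PRIME and idx != 0:
            return False
        if t is Truncation.FIVE_PRIME and idx != last:
            return False
    return True


def assemble_sets_for_reference(
    placements: Sequence[CandidatePlacement],
    truncations: Mapping[str, Truncation],
    params: LinkageParams = LinkageParams(),
    genome_id: str = "",
) -> list[FragmentSet]:
    """Greedy deterministic assembly of fragment sets on one reference.

    Placements are visited by descending identity (ties by fragment id); the
    best unused placement seeds a set and later placements join when they
    pass the overlap cap against every member, the identity-spread cap
    against the seed, the single-end truncation budget, and (optionally) the
    end-order constraint.  Only sets with at least two members are emitted;
    seeding repeats until every placement has been considered.
    """
    if not placements:
        return []
    ref_ids = {(p.reference_protein_id, p.reference_genome_id) for p in placements}
    if len(ref_ids) != 1:
        raise IntegrityError("assemble_sets_for_reference requires a single reference protein")
    ref_protein, ref_genome = next(iter(ref_ids))

    order = sorted(placements, key=lambda p: (-p.pident, p.fragment_id))
    used: set[str] = set()
    sets: list[FragmentSet] = []
    serial = 0
    for seed in order:
        if seed.fragment_id in used:
            continue
        members = [seed]
        for cand in order:
            if cand.fragment_id in used or cand.fragment_id == seed.fragment_id:
                continue
            if any(m.fragment_id == cand.fragment_id for m in members):
                continue
            if any(_interval_overlap(m, cand) > params.max_fragment_overlap_aa for m in members):
                continue
            if abs(cand.pident - seed.pident) > params.max_identity_spread_pct:
                continue
            single_ended = sum(
                1 for m in [*members, cand] if truncations[m.fragment_id].single_ended
            )
            if single_ended > params.max_single_end_truncated:
                continue
            if params.enforce_end_order and not _end_order_ok([*members, cand], truncations):
                continue
            members.append(cand)
        for m in members:
            used.add(m.fragment_id)
        if len(members) >= 2:
            serial += 1
            ordered = sorted(members, key=lambda p: (p.ref_start, p.fragment_id))
            sets.append(
                FragmentSet(
                    set_id=f"{genome_id}|{ref_genome}|{ref_protein}|{serial}",
                    genome_id=genome_id,
                    members=[p.fragment_id for p in ordered],
                    member_identities=[p.pident for p in ordered],
                    reference_protein_id=ref_protein,
                    reference_genome_id=ref_genome,
                )
            )
    return sets


def candidate_sets_against_reference(
    target_orfs: Sequence[OrfRecord],
    reference_orfs: Sequence[OrfRecord],
    hits: Iterable[HitRecord] | None = None,
    params: LinkageParams = LinkageParams(),
) -> list[FragmentSet]:
    """All candidate sets for one target proteome against one reference
    proteome (before cross-reference conflict resolution)."""
    fragments = [o for o in target_orfs if o.is_partial]
    if not fragments:
        return []
    if hits is None:
        hits = search_proteome(fragments, reference_orfs)
    placements = candidate_placements(fragments, hits, reference_orfs, params)
    truncations = {o.orf_id: o.truncation for o in target_orfs}
    by_ref: dict[str, list[CandidatePlacement]] = defaultdict(list)
    for p in placements:
        by_ref[p.reference_protein_id].append(p)
    genome_id = target_orfs[0].genome_id
    sets: list[FragmentSet] = []
    for ref_protein in sorted(by_ref):
        sets.extend(
            assemble_sets_for_reference(by_ref[ref_protein], truncations, params, genome_id)
        )
    return sets


def resolve_conflicts(candidate_sets: Sequence[FragmentSet]) -> list[FragmentSet]:
    """Globally resolve sets sharing fragments, keeping higher mean identity.

    Ties prefer larger sets, then the lexicographically smallest
    (reference genome, reference protein).  The procedure sorts once and
    sweeps, so it is independent of input order.
    """
    ranked = sorted(
        candidate_sets,
        key=lambda s: (
            -s.mean_identity,
            -len(s),
            s.reference_genome_id,
            s.reference_protein_id,
            s.set_id,
        ),
    )
    taken: set[str] = set()
    kept: list[FragmentSet] = []
    for fs in ranked:
        if any(m in taken for m in fs.members):
            continue
        taken.update(fs.members)
        kept.append(fs)
    kept.sort(key=lambda s: s.set_id)
    return kept


def link_fragments(
    orfs_a: Sequence[OrfRecord],
    orfs_b: Sequence[OrfRecord],
    hits_ab: Iterable[HitRecord] | None = None,
    hits_ba: Iterable[HitRecord] | None = None,
    params: LinkageParams = LinkageParams(),
) -> tuple[list[FragmentSet], list[FragmentSet]]:
    """Reciprocal linkage between two proteomes.

    Fragments of genome A are recruited onto complete proteins of genome B
    and vice versa; within each genome conflicting sets are resolved by mean
    identity.
    """
    genomes_a = {o.genome_id for o in orfs_a}
    genomes_b = {o.genome_id for o in orfs_b}
    if genomes_a & genomes_b:
        raise IntegrityError(f"genome id collision between inputs: {genomes_a & genomes_b}")
    sets_a = resolve_conflicts(
        candidate_sets_against_reference(orfs_a, orfs_b, hits_ab, params)
    )
    sets_b = resolve_conflicts(
        candidate_sets_against_reference(orfs_b, orfs_a, hits_ba, params)
    )
    return sets_a, sets_b


@dataclass(frozen=True)
class ReferenceContribution:
    reference_genome_id: str
    n_new_fragments: int  # fragments newly linked once this reference is added
    cumulative_fragments: int


def link_against_references(
    target_orfs: Sequence[OrfRecord],
    reference_proteomes: Sequence[Sequence[OrfRecord]],
    hit_tables: Sequence[Iterable[HitRecord]] | None = None,
    params: LinkageParams = LinkageParams(),
) -> tuple[list[FragmentSet], list[ReferenceContribution]]:
    """Accumulate fragment sets over an ordered series of reference genomes.

    References are processed in the caller's order (typically decreasing
    AAI); after each one, conflicts are re-resolved over ALL candidates seen
    so far, so a later reference can replace an earlier set when it offers a
    higher mean identity to the shared fragments.  The per-reference counts
    of newly linked fragments trace a cumulative linkage curve.
    """
    if hit_tables is not None and len(hit_tables) != len(reference_proteomes):
        raise IntegrityError("one hit table per reference proteome is required")
    candidates: list[FragmentSet] = []
    contributions: list[ReferenceContribution] = []
    linked_before: set[str] = set()
    final: list[FragmentSet] = []
    for idx, ref_orfs in enumerate(reference_proteomes):
        hits = hit_tables[idx] if hit_tables is not None else None
        new_sets = candidate_sets_against_reference(target_orfs, ref_orfs, hits, params)
        candidates.extend(new_sets)
        final = resolve_conflicts(candidates)
        linked_now = {m for fs in final for m in fs.members}
        ref_genome = ref_orfs[0].genome_id if ref_orfs else f"reference_{idx}"
        contributions.append(
            ReferenceContribution(
                reference_genome_id=ref_genome,
                n_new_fragments=len(linked_now - linked_before),
                cumulative_fragments=len(linked_now),
            )
        )
        linked_before = linked_now
    return final, contributions


@dataclass(frozen=True)
class MergedUnit:
    """One gene-level unit of the corrected inventory: either an intact ORF
    or a linked fragment set counted once."""

    unit_id: str
    member_ids: tuple[str, ...]

    @property
    def merged(self) -> bool:
        return len(self.member_ids) > 1


def merge_inventory(
    orfs: Sequence[OrfRecord], sets: Sequence[FragmentSet]
) -> list[MergedUnit]:
    """Collapse each fragment set to a single unit; unlinked ORFs pass through.

    The corrected inventory has ``n_orfs - sum(len(set) - 1)`` units.
    """
    orf_ids = {o.orf_id for o in orfs}
    seen: set[str] = set()
    units: list[MergedUnit] = []
    for fs in sets:
        for member in fs.members:
            if member in seen:
                raise IntegrityError(f"fragment {member} appears in more than one set")
            if member not in orf_ids:
                raise IntegrityError(f"set {fs.set_id} references unknown ORF {member}")
            seen.add(member)
        units.append(MergedUnit(unit_id=fs.set_id, member_ids=tuple(fs.members)))
    for orf in orfs:
        if orf.orf_id not in seen:
            units.append(MergedUnit(unit_id=orf.orf_id, member_ids=(orf.orf_id,)))
    return units
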