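"""Whole-proteome homology machinery.

Best-hit selection, bidirectional best hits (BBH), average amino acid
identity (AAI) with identity/coverage filters, an AAI-derived distance
matrix, neighbor joining, and a built-in Smith-Waterman protein aligner so
that fixtures and small analyses need no external search tool.

AAI is the mean percent identity over filtered BBH protein pairs between two
genomes and serves as a whole-genome relatedness measure (95-96% AAI roughly
corresponds to the conventional bacterial species boundary).
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from orflink.io_formats import HitRecord, IntegrityError, OrfRecord, OrflinkError


class AlignmentError(OrflinkError):
    pass


# ---------------------------------------------------------------------------
# Built-in pairwise local aligner
# ---------------------------------------------------------------------------

def _make_aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # BLAST-style affine cost: a gap of length k costs open + k*extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def align_pair(
    seq_a: str,
    seq_b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    query_id: str = "query",
    subject_id: str = "subject",
) -> HitRecord:
    """Best local alignment of two protein sequences as a HitRecord.

    Percent identity is identities over all alignment columns (including
    gap columns); the bitscore field carries the raw alignment score, which
    is sufficient for ranking hits among themselves.
    """
    if not seq_a or not seq_b:
        raise AlignmentError("align_pair requires non-empty sequences")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    alignment = aligner.align(seq_a, seq_b)[0]
    blocks_q, blocks_s = alignment.aligned
    identities = 0
    aligned_cols = 0
    gap_cols = 0
    gap_opens = 0
    prev_q_end = prev_s_end = None
    for (qs, qe), (ss, se) in zip(blocks_q, blocks_s):
        if prev_q_end is not None:
            dq = qs - prev_q_end
            ds = ss - prev_s_end
            gap_cols += dq + ds
            gap_opens += (dq > 0) + (ds > 0)
        for qa, sa in zip(seq_a[qs:qe], seq_b[ss:se]):
            identities += qa == sa
        aligned_cols += qe - qs
        prev_q_end, prev_s_end = qe, se
    total_cols = int(aligned_cols + gap_cols)
    return HitRecord(
        query_id=query_id,
        subject_id=subject_id,
        pident=float(100.0 * identities / total_cols) if total_cols else 0.0,
        align_len=total_cols,
        mismatches=int(aligned_cols - identities),
        gap_opens=int(gap_opens),
        q_start=int(blocks_q[0][0]) + 1,
        q_end=int(blocks_q[-1][1]),
        s_start=int(blocks_s[0][0]) + 1,
        s_end=int(blocks_s[-1][1]),
        evalue=0.0,
        bitscore=float(alignment.score),
    )


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def search_proteome(
    queries: Sequence[OrfRecord],
    subjects: Sequence[OrfRecord],
    k: int = 4,
    max_candidates: int = 5,
    min_shared_kmers: int = 2,
) -> list[HitRecord]:
    """All-vs-all protein search with a shared-k-mer prefilter.

    Each query is aligned (align_pair) only against the ``max_candidates``
    subjects sharing the most k-mers with it, which keeps whole-proteome
    searches tractable without an external search tool.  Self-comparisons
    (identical ids) are skipped.
    """
    index: dict[str, list[int]] = defaultdict(list)
    for idx, subject in enumerate(subjects):
        for kmer in _kmer_set(subject.aa_sequence, k):
            index[kmer].append(idx)
    hits: list[HitRecord] = []
    for query in queries:
        shared: Counter[int] = Counter()
        for kmer in _kmer_set(query.aa_sequence, k):
            for idx in index.get(kmer, ()):
                shared[idx] += 1
        candidates = [
            idx
            for idx, count in shared.most_common()
            if count >= min_shared_kmers and subjects[idx].orf_id != query.orf_id
        ][:max_candidates]
        for idx in candidates:
            hits.append(
                align_pair(
                    query.aa_sequence,
                    subjects[idx].aa_sequence,
                    query_id=query.orf_id,
                    subject_id=subjects[idx].orf_id,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# Best hits, BBH, AAI
# ---------------------------------------------------------------------------

def best_hit_per_query(hits: Iterable[HitRecord]) -> dict[str, HitRecord]:
    """Highest-bitscore hit per query; ties broken by lowest e-value, then
    lexicographically smallest subject id."""
    best: dict[str, HitRecord] = {}
    for hit in hits:
        current = best.get(hit.query_id)
        if current is None:
            best[hit.query_id] = hit
            continue
        key_new = (-hit.bitscore, hit.evalue, hit.subject_id)
        key_old = (-current.bitscore, current.evalue, current.subject_id)
        if key_new < key_old:
            best[hit.query_id] = hit
    return best


def bidirectional_best_hits(
    best_ab: Mapping[str, HitRecord], best_ba: Mapping[str, HitRecord]
) -> list[tuple[str, str, HitRecord, HitRecord]]:
    """Pairs (a, b) where a's best hit is b and b's best hit is a."""
    pairs = []
    for a_id, hit_ab in best_ab.items():
        b_id = hit_ab.subject_id
        hit_ba = best_ba.get(b_id)
        if hit_ba is not None and hit_ba.subject_id == a_id:
            pairs.append((a_id, b_id, hit_ab, hit_ba))
    pairs.sort(key=lambda p: p[0])
    return pairs


@dataclass(frozen=True)
class AaiParams:
    """Filters applied to BBH pairs before averaging identities."""

    min_identity_pct: float = 30.0
    min_coverage_frac: float = 0.70  # of BOTH protein lengths
    complete_only: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.min_coverage_frac <= 1.0):
            raise IntegrityError("min_coverage_frac must lie in (0, 1]")


@dataclass(frozen=True)
class AaiResult:
    genome_a: str
    genome_b: str
    aai: float  # NaN when no pair survives the filters
    n_pairs: int

    @property
    def defined(self) -> bool:
        return self.n_pairs > 0


def compute_aai(
    bbh_pairs: Sequence[tuple[str, str, HitRecord, HitRecord]],
    orfs_a: Sequence[OrfRecord],
    orfs_b: Sequence[OrfRecord],
    params: AaiParams = AaiParams(),
) -> AaiResult:
    """AAI over BBH pairs passing the identity/coverage/completeness filters.

    A pair is kept when (optionally) both members are intact proteins, both
    directional hits reach the identity threshold, and both hits span at
    least ``min_coverage_frac`` of BOTH protein lengths.  The per-pair
    identity is the mean of the two directional identities, and the AAI is
    the unweighted mean over kept pairs.
    """
    len_a = {o.orf_id: o for o in orfs_a}
    len_b = {o.orf_id: o for o in orfs_b}
    genome_a = orfs_a[0].genome_id if orfs_a else "A"
    genome_b = orfs_b[0].genome_id if orfs_b else "B"
    identities = []
    for a_id, b_id, hit_ab, hit_ba in bbh_pairs:
        orf_a = len_a.get(a_id)
        orf_b = len_b.get(b_id)
        if orf_a is None or orf_b is None:
            raise IntegrityError(f"BBH pair ({a_id}, {b_id}) references unknown ORFs")
        if params.complete_only and (orf_a.is_partial or orf_b.is_partial):
            continue
        if hit_ab.pident < params.min_identity_pct or hit_ba.pident < params.min_identity_pct:
            continue
        min_cov = params.min_coverage_frac
        need = max(orf_a.length_aa, orf_b.length_aa) * min_cov
        if hit_ab.align_len < need or hit_ba.align_len < need:
            continue
        identities.append((hit_ab.pident + hit_ba.pident) / 2.0)
    if not identities:
        return AaiResult(genome_a, genome_b, math.nan, 0)
    return AaiResult(genome_a, genome_b, sum(identities) / len(identities), len(identities))


def aai_between_proteomes(
    orfs_a: Sequence[OrfRecord],
    orfs_b: Sequence[OrfRecord],
    params: AaiParams = AaiParams(),
    hits_ab: Sequence[HitRecord] | None = None,
    hits_ba: Sequence[HitRecord] | None = None,
) -> AaiResult:
    """Convenience wrapper: search (if needed), take BBHs, compute AAI."""
    if hits_ab is None:
        hits_ab = search_proteome(orfs_a, orfs_b)
    if hits_ba is None:
        hits_ba = search_proteome(orfs_b, orfs_a)
    pairs = bidirectional_best_hits(best_hit_per_query(hits_ab), best_hit_per_query(hits_ba))
    return compute_aai(pairs, orfs_a, orfs_b, params)


# ---------------------------------------------------------------------------
# Distance matrix and neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    ids: list[str]
    data: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise IntegrityError("distance matrix shape does not match taxon count")
        if not np.allclose(self.data, self.data.T, atol=1e-9):
            raise IntegrityError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.data), 0.0, atol=1e-9):
            raise IntegrityError("distance matrix diagonal is not zero")
        if (self.data < -1e-9).any():
            raise IntegrityError("distance matrix has negative entries")

    def get(self, a: str, b: str) -> float:
        return float(self.data[self.ids.index(a), self.ids.index(b)])


def aai_matrix(genome_ids: Sequence[str], results: Iterable[AaiResult]) -> DistanceMatrix:
    """Distance matrix with d(a, b) = 100 - AAI(a, b).

    When both search directions were computed as separate results, their
    AAIs are averaged ("double-sided"), making the matrix symmetric by
    construction.
    """
    per_pair: dict[frozenset[str], list[float]] = defaultdict(list)
    for res in results:
        if not res.defined:
            raise IntegrityError(f"AAI undefined for pair ({res.genome_a}, {res.genome_b})")
        per_pair[frozenset((res.genome_a, res.genome_b))].append(res.aai)
    n = len(genome_ids)
    data = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            key = frozenset((genome_ids[i], genome_ids[j]))
            if key not in per_pair:
                raise IntegrityError(
                    f"missing AAI for pair ({genome_ids[i]}, {genome_ids[j]})"
                )
            values = per_pair[key]
            d = 100.0 - sum(values) / len(values)
            data[i, j] = data[j, i] = max(d, 0.0)
    return DistanceMatrix(list(genome_ids), data)


@dataclass
class _Node:
    label: str  # lexicographically smallest leaf underneath; used for ties
    newick: str


def nj_tree(dm: DistanceMatrix) -> str:
    """Neighbor-joining tree (newick, unrooted) from a distance matrix.

    Standard Q-criterion agglomeration with the usual branch-length
    formulas; joins with tied Q pick the lexicographically smallest taxon
    pair, and negative branch lengths are clamped to zero, so the output is
    deterministic.  For additive matrices the clamping never triggers and
    the generating tree is recovered exactly.
    """
    n = len(dm.ids)
    if n < 2:
        raise IntegrityError("neighbor joining requires at least two taxa")
    if n == 2:
        half = dm.data[0, 1] / 2.0
        return f"({dm.ids[0]}:{half:.10g},{dm.ids[1]}:{half:.10g});"

    nodes = [_Node(label=t, newick=t) for t in dm.ids]
    dist: list[list[float]] = [list(row) for row in dm.data]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist[i][j] for j in active if j != i) for i in active}
        best_key = None
        best_pair = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dist[i][j] - r[i] - r[j]
                labels = sorted((nodes[i].label, nodes[j].label))
                key = (q, labels[0], labels[1])
                if best_key is None or key < best_key:
                    best_key = key
                    best_pair = (i, j)
        i, j = best_pair  # type: ignore[misc]
        d_ij = dist[i][j]
        li = d_ij / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d_ij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new_label = min(nodes[i].label, nodes[j].label)
        first, second = ((i, li), (j, lj))
        if nodes[j].label < nodes[i].label:
            first, second = ((j, lj), (i, li))
        newick = (
            f"({nodes[first[0]].newick}:{first[1]:.10g},"
            f"{nodes[second[0]].newick}:{second[1]:.10g})"
        )
        u = len(nodes)
        nodes.append(_Node(label=new_label, newick=newick))
        for row in dist:
            row.append(0.0)
        new_row = [0.0] * (u + 1)
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = (dist[i][k] + dist[j][k] - d_ij) / 2.0
        dist.append(new_row)
        for k in active:
            dist[k][u] = new_row[k]
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    li = (dist[i][j] + dist[i][k] - dist[j][k]) / 2.0
    lj = (dist[i][j] + dist[j][k] - dist[i][k]) / 2.0
    lk = (dist[i][k] + dist[j][k] - dist[i][j]) / 2.0
    parts = sorted(
        [(nodes[i], max(li, 0.0)), (nodes[j], max(lj, 0.0)), (nodes[k], max(lk, 0.0))],
        key=lambda p: p[0].label,
    )
    inner = ",".join(f"{node.newick}:{length:.10g}" for node, length in parts)
    return f"({inner});"
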