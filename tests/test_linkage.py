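import random
from dataclasses import replace

import pytest

from orflink.io_formats import FragmentSet, IntegrityError, Truncation
from orflink.linkage import (
    CandidatePlacement,
    LinkageParams,
    assemble_sets_for_reference,
    candidate_placements,
    candidate_sets_against_reference,
    link_against_references,
    link_fragments,
    merge_inventory,
    resolve_conflicts,
)
from orflink.synth_fixtures import FixtureConfig, linkage_recall, make_fixture
from tests.conftest import mk_hit, mk_orf


def placement(frag, pident=95.0, ref=(1, 150), ref_protein="R", ref_genome="rg", bitscore=None):
    return CandidatePlacement(
        fragment_id=frag,
        reference_protein_id=ref_protein,
        reference_genome_id=ref_genome,
        pident=pident,
        ref_start=ref[0],
        ref_end=ref[1],
        frag_coverage=1.0,
        bitscore=bitscore if bitscore is not None else pident,
    )


class TestCandidatePlacements:
    def setup_method(self):
        self.frag = mk_orf("f1", genome="g", seq="M" * 100, trunc=Truncation.THREE_PRIME)
        self.ref_complete = mk_orf("r1", genome="rg", seq="M" * 300)
        self.ref_partial = mk_orf("r2", genome="rg", seq="M" * 300, trunc=Truncation.BOTH)

    def test_good_hit_kept(self):
        hit = mk_hit("f1", "r1", pident=95, q=(1, 100), s=(1, 100))
        out = candidate_placements([self.frag], [hit], [self.ref_complete, self.ref_partial])
        assert len(out) == 1
        assert out[0].frag_coverage == pytest.approx(1.0)

    def test_partial_reference_dropped(self):
        hit = mk_hit("f1", "r2", pident=95, q=(1, 100), s=(1, 100))
        assert candidate_placements([self.frag], [hit], [self.ref_partial]) == []

    def test_low_identity_dropped(self):
        hit = mk_hit("f1", "r1", pident=20, q=(1, 100), s=(1, 100))
        assert candidate_placements([self.frag], [hit], [self.ref_complete]) == []

    def test_low_fragment_coverage_dropped(self):
        hit = mk_hit("f1", "r1", pident=95, q=(1, 50), s=(1, 50))  # 50% of fragment
        assert candidate_placements([self.frag], [hit], [self.ref_complete]) == []

    def test_best_bitscore_per_pair(self):
        weak = mk_hit("f1", "r1", pident=90, q=(1, 100), s=(1, 100), bitscore=100)
        strong = mk_hit("f1", "r1", pident=95, q=(1, 100), s=(101, 200), bitscore=200)
        out = candidate_placements([self.frag], [weak, strong], [self.ref_complete])
        assert len(out) == 1 and out[0].ref_start == 101


class TestAssembleSets:
    def test_two_way_split_linked(self):
        trunc = {"f1": Truncation.THREE_PRIME, "f2": Truncation.FIVE_PRIME}
        placements = [placement("f1", 100, (1, 150)), placement("f2", 100, (151, 300))]
        (fs,) = assemble_sets_for_reference(placements, trunc, genome_id="g")
        assert fs.members == ["f1", "f2"]
        assert fs.mean_identity == pytest.approx(100.0)

    def test_three_way_split_with_interior_piece(self):
        trunc = {
            "f1": Truncation.THREE_PRIME,
            "f2": Truncation.BOTH,
            "f3": Truncation.FIVE_PRIME,
        }
        placements = [
            placement("f1", 98, (1, 100)),
            placement("f2", 97, (101, 200)),
            placement("f3", 99, (201, 300)),
        ]
        (fs,) = assemble_sets_for_reference(placements, trunc, genome_id="g")
        assert fs.members == ["f1", "f2", "f3"]

    def test_heavily_overlapping_fragments_not_linked(self):
        """Two fragments covering the same reference stretch are paralogs or
        alternative calls, not pieces of one gene."""
        trunc = {"f1": Truncation.THREE_PRIME, "f2": Truncation.THREE_PRIME}
        placements = [placement("f1", 98, (1, 200)), placement("f2", 97, (1, 200))]
        assert assemble_sets_for_reference(placements, trunc, genome_id="g") == []

    def test_small_overlap_within_cap_allowed(self):
        trunc = {"f1": Truncation.THREE_PRIME, "f2": Truncation.FIVE_PRIME}
        placements = [placement("f1", 98, (1, 155)), placement("f2", 97, (150, 300))]
        params = LinkageParams(max_fragment_overlap_aa=10)
        (fs,) = assemble_sets_for_reference(placements, trunc, params, genome_id="g")
        assert len(fs) == 2

    def test_identity_spread_cap(self):
        trunc = {"f1": Truncation.THREE_PRIME, "f2": Truncation.FIVE_PRIME}
        placements = [placement("f1", 95, (1, 150)), placement("f2", 50, (151, 300))]
        assert assemble_sets_for_reference(placements, trunc, genome_id="g") == []
        relaxed = LinkageParams(max_identity_spread_pct=50)
        assert len(assemble_sets_for_reference(placements, trunc, relaxed, genome_id="g")) == 1

    def test_truncation_budget_limits_single_ended_members(self):
        """At most two members may be truncated at a single end; interior
        (both-end) fragments are unlimited."""
        trunc = {
            "f1": Truncation.THREE_PRIME,
            "f2": Truncation.FIVE_PRIME,
            "f3": Truncation.FIVE_PRIME,
        }
        placements = [
            placement("f1", 98, (1, 100)),
            placement("f2", 98, (101, 200)),
            placement("f3", 97, (201, 300)),
        ]
        params = LinkageParams(enforce_end_order=False)
        sets = assemble_sets_for_reference(placements, trunc, params, genome_id="g")
        assert max(len(s) for s in sets) == 2

    def test_end_order_keeps_start_fragment_leftmost(self):
        # a start-containing (3'-truncated) fragment cannot sit to the right
        # of another member on the reference
        trunc = {"f1": Truncation.THREE_PRIME, "f2": Truncation.BOTH}
        placements = [placement("f1", 98, (151, 300)), placement("f2", 98, (1, 150))]
        assert assemble_sets_for_reference(placements, trunc, genome_id="g") == []
        loose = LinkageParams(enforce_end_order=False)
        assert len(assemble_sets_for_reference(placements, trunc, loose, genome_id="g")) == 1


def fs(set_id, members, idents, ref="R", refg="rg"):
    return FragmentSet(set_id, "g", members, idents, ref, refg)


class TestResolveConflicts:
    def test_disjoint_sets_all_kept(self):
        sets = [fs("a", ["f1", "f2"], [90, 90]), fs("b", ["f3", "f4"], [80, 80])]
        assert len(resolve_conflicts(sets)) == 2

    def test_higher_mean_identity_wins(self):
        worse = fs("a", ["f1", "f2"], [85, 85])
        better = fs("b", ["f1", "f3"], [92, 92])
        kept = resolve_conflicts([worse, better])
        assert [s.set_id for s in kept] == ["b"]

    def test_tie_prefers_larger_set(self):
        two = fs("a", ["f1", "f2"], [90, 90])
        three = fs("b", ["f1", "f3", "f4"], [90, 90, 90])
        kept = resolve_conflicts([two, three])
        assert [s.set_id for s in kept] == ["b"]

    def test_order_independent(self):
        sets = [
            fs("a", ["f1", "f2"], [85, 85]),
            fs("b", ["f1", "f3"], [92, 92]),
            fs("c", ["f3", "f4"], [99, 99]),
        ]
        for seed in range(5):
            shuffled = sets[:]
            random.Random(seed).shuffle(shuffled)
            assert resolve_conflicts(shuffled) == resolve_conflicts(sets)


class TestLinkFragments:
    def test_no_fragments_no_sets(self):
        a = [mk_orf("a1", genome="ga", seq="M" * 90)]
        b = [mk_orf("b1", genome="gb", seq="M" * 90)]
        assert link_fragments(a, b) == ([], [])

    def test_genome_collision_rejected(self):
        a = [mk_orf("a1", genome="g", seq="M" * 90)]
        with pytest.raises(IntegrityError):
            link_fragments(a, a)

    def test_split_planted_in_one_genome_only(self, small_fixture):
        bundle, reference = small_fixture
        sets_a, sets_b = link_fragments(bundle.orfs, reference)
        assert sets_b == []  # the reference proteome is complete
        assert sets_a
        _, _, recall = linkage_recall(sets_a, bundle.truth)
        assert recall >= 0.9


class TestLinkAgainstReferences:
    def test_single_reference_equals_direct_run(self, small_fixture):
        bundle, reference = small_fixture
        direct, _ = link_fragments(bundle.orfs, reference)
        multi, contribs = link_against_references(bundle.orfs, [reference])
        assert multi == direct
        assert contribs[0].cumulative_fragments == sum(len(s) for s in direct)

    def test_second_reference_adds_links_monotonically(self):
        """A second, closer reference can only grow the cumulative count."""
        config = FixtureConfig(seed=21, n_genes=40, reference_divergence=0.35)
        bundle, far_ref = make_fixture(config)
        near_ref = make_fixture(replace(config, reference_divergence=0.05))[1]
        near_ref = [replace(o, genome_id="near", orf_id="near_" + o.orf_id) for o in near_ref]
        _, contribs = link_against_references(bundle.orfs, [far_ref, near_ref])
        assert contribs[1].cumulative_fragments >= contribs[0].cumulative_fragments
        assert contribs[1].n_new_fragments >= 0

    def test_higher_identity_reference_replaces_sets(self, small_fixture):
        """Adding a closer reference after a distant one replaces set
        provenance without shrinking the linked-fragment count."""
        bundle, near = small_fixture
        far = make_fixture(
            replace(bundle.config, reference_divergence=0.25, reference_genome_id="far")
        )[1]
        far = [replace(o, orf_id="far_" + o.orf_id) for o in far]
        sets, contribs = link_against_references(bundle.orfs, [far, near])
        assert contribs[1].cumulative_fragments >= contribs[0].cumulative_fragments
        # the closer reference should win most conflicts
        near_backed = sum(1 for s in sets if s.reference_genome_id == near[0].genome_id)
        assert near_backed > len(sets) / 2


class TestProperties:
    def test_emitted_sets_respect_all_caps(self, small_fixture):
        bundle, reference = small_fixture
        params = LinkageParams()
        sets = candidate_sets_against_reference(bundle.orfs, reference, params=params)
        trunc = {o.orf_id: o.truncation for o in bundle.orfs}
        for s in sets:
            singles = sum(1 for m in s.members if trunc[m].single_ended)
            assert singles <= params.max_single_end_truncated
            spread = max(s.member_identities) - min(s.member_identities)
            assert spread <= 2 * params.max_identity_spread_pct  # seed-relative cap
            assert len(s) >= 2

    def test_determinism_under_input_reordering(self, small_fixture):
        bundle, reference = small_fixture
        base = candidate_sets_against_reference(bundle.orfs, reference)
        shuffled_orfs = bundle.orfs[:]
        random.Random(4).shuffle(shuffled_orfs)
        shuffled_ref = reference[:]
        random.Random(5).shuffle(shuffled_ref)
        again = candidate_sets_against_reference(shuffled_orfs, shuffled_ref)
        assert again == base

    def test_raising_identity_threshold_never_links_more(self, small_fixture):
        bundle, reference = small_fixture
        counts = []
        for ident in (30.0, 60.0, 90.0, 99.0):
            sets, _ = link_against_references(
                bundle.orfs, [reference], params=LinkageParams(min_identity_pct=ident)
            )
            counts.append(sum(len(s) for s in sets))
        assert counts == sorted(counts, reverse=True)


class TestMergeInventory:
    def test_merge_arithmetic(self):
        orfs = [mk_orf(f"o{i}") for i in range(10)]
        sets = [fs("s", ["o0", "o1"], [95, 95])]
        units = merge_inventory(orfs, sets)
        assert len(units) == 9
        assert sum(u.merged for u in units) == 1

    def test_no_sets_identity(self):
        orfs = [mk_orf(f"o{i}") for i in range(4)]
        units = merge_inventory(orfs, [])
        assert sorted(u.unit_id for u in units) == sorted(o.orf_id for o in orfs)

    def test_overlapping_sets_rejected(self):
        orfs = [mk_orf(f"o{i}") for i in range(4)]
        sets = [fs("s1", ["o0", "o1"], [95, 95]), fs("s2", ["o1", "o2"], [95, 95])]
        with pytest.raises(IntegrityError):
            merge_inventory(orfs, sets)

    def test_perfect_recovery_restores_gene_count(self):
        """With a zero-divergence reference every fragment set collapses to
        its source gene, so merged units equal the original gene count."""
        config = FixtureConfig(seed=13, n_genes=50, reference_divergence=0.0)
        bundle, reference = make_fixture(config)
        # only count genes with no dropped pieces and full recovery potential
        sets, _ = link_against_references(bundle.orfs, [reference])
        units = merge_inventory(bundle.orfs, sets)
        n_genes_with_orfs = len(
            {o.orf_id.rsplit("_c", 1)[0] for o in bundle.orfs}
        )
        assert len(units) == n_genes_with_orfs
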