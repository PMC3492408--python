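import random

import pytest

from ryrmap.fragment_assign import ObservedFragment
from ryrmap.labeling_inference import (
    Exclusion,
    ExclusionList,
    InferenceError,
    TopologyAnnotation,
    TopologyInterval,
    filter_motifs,
    refine_regions,
)
from ryrmap.motif_scan import MotifHit


def frag(fid, span=None, labeled=True, parent=None):
    return ObservedFragment(
        fragment_id=fid, labeled=labeled, parent_id=parent, span=span
    )


def hit(start, end, pid="WALKER_A"):
    return MotifHit(pattern_id=pid, start=start, end=end, matched="G" * (end - start + 1))


class TestRefineRegions:
    def test_single_labeled_fragment_is_its_own_region(self):
        regions, _ = refine_regions([frag("a", (10, 100))])
        assert [(r.start, r.end) for r in regions] == [(10, 100)]

    def test_labeled_child_narrows_parent(self):
        regions, audit = refine_regions(
            [frag("p", (1, 100)), frag("c", (20, 100), parent="p")]
        )
        assert [(r.start, r.end) for r in regions] == [(20, 100)]
        assert any(e.rule == "R1:intersect" for e in audit)

    def test_unlabeled_child_subtracted(self):
        # the labeled sibling keeps the parent from being demoted under R3
        fragments = [
            frag("p", (1, 100)),
            frag("c", (1, 100), parent="p"),
            frag("u", (1, 40), labeled=False, parent="p"),
        ]
        regions, audit = refine_regions(fragments)
        assert [(r.start, r.end) for r in regions] == [(41, 100)]
        assert any(e.rule == "R2:subtract" for e in audit)

    def test_c_terminal_window_shrinks_subtracted_span(self):
        fragments = [
            frag("p", (1, 100)),
            frag("c", (1, 100), parent="p"),
            frag("u", (1, 40), labeled=False, parent="p"),
        ]
        regions, _ = refine_regions(fragments, c_term_window=5)
        assert [(r.start, r.end) for r in regions] == [(36, 100)]

    def test_demotion_when_all_products_unlabeled(self):
        fragments = [
            frag("p", (1, 100)),
            frag("u1", (1, 40), labeled=False, parent="p"),
            frag("u2", (50, 100), labeled=False, parent="p"),
        ]
        regions, audit = refine_regions(fragments)
        assert regions == []
        assert any(e.rule == "R3:demoted" for e in audit)
        # with the flag off, the fragment survives (minus unlabeled spans)
        regions_off, _ = refine_regions(fragments, demote_on_unlabeled_products=False)
        assert [(r.start, r.end) for r in regions_off] == [(41, 49)]

    def test_demotion_works_from_parentage_alone(self):
        # products with unknown spans still drive R3
        fragments = [
            frag("p", (1, 100)),
            frag("u1", None, labeled=False, parent="p"),
            frag("u2", None, labeled=False, parent="p"),
        ]
        regions, audit = refine_regions(fragments)
        assert regions == []
        assert any(e.rule == "R3:demoted" for e in audit)

    def test_overlapping_regions_merged(self):
        regions, audit = refine_regions(
            [frag("a", (10, 60)), frag("b", (50, 90))]
        )
        assert [(r.start, r.end) for r in regions] == [(10, 90)]
        assert set(regions[0].supporting_fragments) == {"a", "b"}
        assert any(e.rule == "R4:merge" for e in audit)

    def test_cyclic_graph_rejected(self):
        fragments = [
            frag("a", (1, 50), parent="b"),
            frag("b", (1, 50), parent="a"),
        ]
        with pytest.raises(InferenceError, match="cyclic"):
            refine_regions(fragments)

    def test_child_span_outside_parent_rejected(self):
        with pytest.raises(InferenceError, match="not contained"):
            refine_regions([frag("p", (10, 50)), frag("c", (5, 20), parent="p")])

    def test_order_independence(self, fixture_fragments):
        expected, _ = refine_regions(fixture_fragments)
        rng = random.Random(0)
        for _ in range(10):
            shuffled = list(fixture_fragments)
            rng.shuffle(shuffled)
            regions, _ = refine_regions(shuffled)
            assert regions == expected

    def test_study_fixture_three_regions_without_sequence(self, fixture_fragments):
        """The printed fragment table alone yields the three labeled regions."""
        regions, audit = refine_regions(fixture_fragments)
        assert [(r.start, r.end) for r in regions] == [
            (427, 1302), (2402, 2795), (4476, 5037),
        ]
        assert any(
            e.rule == "R3:demoted" and e.subject == "fragment 7" for e in audit
        )


class TestTopology:
    def test_default_cytoplasmic(self):
        topo = TopologyAnnotation()
        assert topo.compartment_of(1) == "cytoplasmic"
        assert topo.is_fully_cytoplasmic(1, 1000)

    def test_interval_lookup(self, fixture_topology):
        assert fixture_topology.compartment_of(4000) == "transmembrane"
        assert fixture_topology.compartment_of(4605) == "luminal"
        assert fixture_topology.compartment_of(5000) == "cytoplasmic"
        assert not fixture_topology.is_fully_cytoplasmic(4602, 4607)

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(InferenceError, match="overlapping"):
            TopologyAnnotation(
                intervals=(
                    TopologyInterval(1, 10, "transmembrane"),
                    TopologyInterval(5, 20, "luminal"),
                )
            )


class TestFilterMotifs:
    REGIONS = [frag("a", (100, 200)), frag("b", (300, 400))]

    def _regions(self):
        regions, audit = refine_regions(self.REGIONS)
        return regions, audit

    def test_empty_hit_list_all_noncanonical(self):
        regions, _ = self._regions()
        calls = filter_motifs([], regions)
        assert calls.candidate_motifs == []
        assert [(r.start, r.end) for r in calls.noncanonical_regions] == [
            (100, 200), (300, 400),
        ]

    def test_straddling_hit_excluded(self):
        regions, _ = self._regions()
        calls = filter_motifs([hit(195, 204)], regions)
        assert calls.candidate_motifs == []
        assert any(e.rule == "not_contained" for e in calls.audit_log)

    def test_exclusion_overlap_logged_with_reason(self):
        regions, _ = self._regions()
        excl = ExclusionList(exclusions=(Exclusion(148, 155, "mutagenesis"),))
        calls = filter_motifs([hit(150, 155)], regions, exclusions=excl)
        assert calls.candidate_motifs == []
        assert any(e.rule == "excluded:mutagenesis" for e in calls.audit_log)

    def test_topology_exclusion(self):
        regions, _ = self._regions()
        topo = TopologyAnnotation(
            intervals=(TopologyInterval(154, 154, "luminal"),)
        )
        calls = filter_motifs([hit(150, 155), hit(310, 315)], regions, topology=topo)
        assert [(h.start, h.end) for h in calls.candidate_motifs] == [(310, 315)]
        assert any(e.rule == "topology:luminal" for e in calls.audit_log)

    def test_surviving_motifs_lie_in_regions(self):
        regions, _ = self._regions()
        calls = filter_motifs([hit(150, 155), hit(500, 505)], regions)
        for h in calls.candidate_motifs:
            assert any(r.start <= h.start and h.end <= r.end for r in regions)


class TestMonotonicity:
    def _motifs(self, fragments, exclusions=None):
        from ryrmap.fixtures import published_motif_spans

        hits = [
            hit(int(r.start), int(r.end), pid=r.pattern_id)
            for r in published_motif_spans().itertuples()
        ]
        regions, audit = refine_regions(fragments)
        calls = filter_motifs(hits, regions, exclusions=exclusions, audit_log=audit)
        return {(h.start, h.end) for h in calls.candidate_motifs}

    def test_adding_unlabeled_fragment_never_grows_motif_set(
        self, fixture_fragments
    ):
        base = self._motifs(fixture_fragments)
        extra = frag("u99", (1000, 1302), labeled=False, parent="3")
        narrowed = self._motifs([*fixture_fragments, extra])
        assert narrowed <= base
        assert (1081, 1084) not in narrowed and (1195, 1200) not in narrowed

    def test_adding_exclusion_never_grows_motif_set(self, fixture_fragments):
        base = self._motifs(fixture_fragments)
        excl = ExclusionList(exclusions=(Exclusion(699, 706, "mutagenesis"),))
        reduced = self._motifs(fixture_fragments, exclusions=excl)
        assert reduced <= base
        assert (699, 704) not in reduced and (701, 706) not in reduced
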