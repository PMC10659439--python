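"""Graph construction, translon derivation and shift arithmetic."""

import random

import networkx as nx
import pytest

from rdgkit import (
    BranchAnnotation,
    ShiftSite,
    Transcript,
    build_rdg,
    classify_shift,
    derive_translon,
    find_start_stop_orfs,
    reinitiation_eligible_starts,
)
from rdgkit.errors import AnnotationError, PolicyError, UnsupportedShiftError
from rdgkit.simulate import fixture_rdg, make_fixture

from _oracles import random_transcript_and_annotation


class TestClassifyShift:
    @pytest.mark.parametrize(
        "i,s,offset,label",
        [
            (100, 101, 1, "+1 frameshifting"),
            (100, 99, -1, "-1 frameshifting"),
            (100, 102, 2, "+2 frameshifting"),
            (100, 97, -3, "-3 frameshifting"),
            (100, 150, 50, "bypass(50)"),
        ],
    )
    def test_offset_and_label(self, i, s, offset, label):
        c = classify_shift(i, s)
        assert c.offset == offset and c.label == label

    def test_backward_jump_rejected(self):
        with pytest.raises(UnsupportedShiftError):
            classify_shift(100, 96)

    def test_zero_offset_rejected(self):
        with pytest.raises(AnnotationError):
            classify_shift(100, 100)


class TestDeriveTranslon:
    def test_simple_translon_counts_codons_including_stop(self):
        # AUG + 8 codons + stop = 10 codons, positions 1..30
        t = Transcript("x", "AUG" + "GCC" * 8 + "UAA" + "GCC")
        a = BranchAnnotation(starts=(1,), reinit_max_codons=10)
        tr = derive_translon(t, 1, a)
        assert tr.start_pos == 1 and tr.end_pos == 30
        assert tr.n_codons == 10 and tr.reinit_competent
        a_strict = a.with_(reinit_max_codons=9)
        assert not derive_translon(t, 1, a_strict).reinit_competent

    def test_readthrough_extends_through_sec_stop(self, gpx4):
        t, a = make_fixture("gpx4_like")
        tr = derive_translon(t, 4, a)
        assert [e.kind for e in tr.events] == ["readthrough"]
        assert tr.end_pos == 66  # past the UGA, to the next in-frame stop
        assert len(tr.segments) == 2  # sec stop is a segment boundary

    def test_frameshift_yields_trans_frame_segments(self):
        t, a = make_fixture("peg10_like")
        tr = derive_translon(t, 4, a)
        assert [e.kind for e in tr.events] == ["shift"]
        assert len(tr.segments) == 2
        f0, f1 = tr.segments
        assert f1.frame != f0.frame
        assert f1.begin == f0.end - 3  # -1 shift: one-base step back

    def test_unannotated_start_rejected(self):
        t = Transcript("x", "AUGGCCUAA")
        with pytest.raises(AnnotationError):
            derive_translon(t, 4, BranchAnnotation(starts=(1,)))

    def test_matches_start_stop_orf_when_no_events(self):
        """Cross-module consistency: an event-free translon is exactly the
        Start-Stop ORF at the same start."""
        rng = random.Random(7)
        for _ in range(30):
            t, a = random_transcript_and_annotation(rng)
            a = a.with_(secs=(), shifts=())
            orfs = {o.first: o for o in find_start_stop_orfs(t)}
            for x in a.starts:
                tr = derive_translon(t, x, a)
                if tr.stop_terminated:
                    assert orfs[x].last == tr.end_pos
                else:
                    assert x not in orfs


class TestBuildRdg:
    def test_empty_annotation_gives_single_scan_path(self):
        t = Transcript("x", "GCC" * 30)
        rdg = build_rdg(t, BranchAnnotation())
        assert rdg.branch_nodes() == []
        assert rdg.translons == {}
        assert rdg.graph.number_of_edges() == 1

    def test_fig3_topology(self, fig3):
        assert len(fig3.branch_nodes()) == 3
        assert len(fig3.translons) == 3

    def test_rdg_is_acyclic_and_connected_on_random_annotations(self):
        rng = random.Random(11)
        for _ in range(60):
            t, a = random_transcript_and_annotation(rng)
            rdg = build_rdg(t, a)
            g = rdg.graph
            assert nx.is_directed_acyclic_graph(g)
            for node in g.nodes:
                assert node == ("cap",) or nx.has_path(g, ("cap",), node)
                assert g.out_degree(node) > 0 or node[0] in ("end3", "dissoc")

    def test_scan_only_skeleton_remains_without_event_edges(self, fig3):
        """Dropping every initiate edge leaves exactly the unproductive
        scan path from cap to the 3' end."""
        g = fig3.graph.copy()
        g.remove_edges_from(
            [
                (u, v)
                for u, v, d in g.edges(data=True)
                if d["kind"] in ("initiate", "readthrough", "shift")
            ]
        )
        node, length = ("cap",), 0
        while g.out_degree(node):
            node = next(iter(g.successors(node)))
            length += 1
        assert node == ("end3",)
        assert length == 1 + len(fig3.annotation.starts)

    def test_deterministic_start_is_not_a_branch(self):
        t = Transcript("x", "G" + "AUG" + "GCC" * 20 + "UAA")
        a = BranchAnnotation(starts=(2,), deterministic_starts={2})
        rdg = build_rdg(t, a)
        assert rdg.branch_nodes() == []
        assert len(rdg.translons) == 1

    def test_out_of_bounds_annotation_rejected(self):
        t = Transcript("x", "AUGGCCUAA")
        with pytest.raises(AnnotationError):
            build_rdg(t, BranchAnnotation(starts=(1, 300)))


class TestReinitiationEligibility:
    def term_after_short_uorf(self, rdg):
        return next(
            n
            for n in rdg.termination_nodes()
            if rdg.graph.nodes[n].get("reinit_competent")
        )

    def test_zero_recharge_allows_all_downstream_starts(self):
        rdg = fixture_rdg("delayed_reinit")
        term = self.term_after_short_uorf(rdg)
        got = reinitiation_eligible_starts(rdg, term, 0)
        assert [x for _, x in got] == [43, 193]

    def test_recharge_distance_selects_start(self):
        rdg = fixture_rdg("delayed_reinit")
        term = self.term_after_short_uorf(rdg)
        assert [x for _, x in reinitiation_eligible_starts(rdg, term, 20)] == [43, 193]
        assert [x for _, x in reinitiation_eligible_starts(rdg, term, 100)] == [193]

    def test_distance_beyond_transcript_gives_empty_list(self):
        rdg = fixture_rdg("delayed_reinit")
        term = self.term_after_short_uorf(rdg)
        assert reinitiation_eligible_starts(rdg, term, 10_000) == []

    def test_non_competent_termination_is_a_policy_error(self):
        rdg = fixture_rdg("delayed_reinit")
        long_term = next(
            n
            for n in rdg.termination_nodes()
            if not rdg.graph.nodes[n].get("reinit_competent")
        )
        with pytest.raises(PolicyError):
            reinitiation_eligible_starts(rdg, long_term, 0)


def test_translon_identity_is_path_independent(fig3):
    """The translon reached by re-initiation is the same object as the one
    reached by direct leaky scanning."""
    from rdgkit import enumerate_paths

    paths = enumerate_paths(fig3)
    cds = [p.translons for p in paths if "T3" in p.translons]
    assert len(cds) == 2  # via re-initiation and via double scan-through
    seg = fig3.translons["T3"].segments
    assert all(fig3.translons["T3"].segments == seg for _ in cds)
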