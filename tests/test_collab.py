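"""Protocol state machine, simulator, counterfactual replay, contrast map."""

import numpy as np
import pytest

from arborkit.collab import (
    AnnotationEvent,
    EditLog,
    ProtocolState,
    ProtocolViolation,
    agreement,
    apply_event,
    contrast_projection_map,
    is_complete,
    replay,
    revoke_cross_edits,
    simulate_collaboration,
    state_to_tree,
)
from arborkit.compare import match_length
from arborkit.swc import total_length
from conftest import random_tree


def _add(t, user, sid, geom, parent="SOMA", lineage=None):
    return AnnotationEvent(t, user, "add", sid, geom, parent, lineage)


GEOM = [(0.0, 0.0, 2.0, 1.0), (0.0, 0.0, 4.0, 1.0)]


class TestProtocolRules:
    def test_self_confirm_rejected(self):
        s = ProtocolState()
        apply_event(s, _add(1, "A", "s1", GEOM))
        with pytest.raises(ProtocolViolation) as exc:
            apply_event(s, AnnotationEvent(2, "A", "confirm", "s1"))
        assert exc.value.kind == "self_confirm"
        assert s.segments["s1"].status == "unvalidated"

    def test_extending_own_unvalidated_segment_allowed(self):
        s = ProtocolState()
        apply_event(s, _add(1, "B", "s1", GEOM))
        apply_event(s, _add(2, "B", "s2", [(0, 0, 6, 1)], ("s1", 1)))
        assert "s2" in s.segments

    def test_extending_others_unconfirmed_segment_rejected(self):
        s = ProtocolState()
        apply_event(s, _add(1, "A", "s1", GEOM))
        with pytest.raises(ProtocolViolation) as exc:
            apply_event(s, _add(2, "B", "s2", [(0, 0, 6, 1)], ("s1", 1)))
        assert exc.value.kind == "unconfirmed_parent"

    def test_extending_confirmed_segment_allowed(self):
        s = ProtocolState()
        apply_event(s, _add(1, "A", "s1", GEOM))
        apply_event(s, AnnotationEvent(2, "B", "confirm", "s1"))
        apply_event(s, _add(3, "B", "s2", [(0, 0, 6, 1)], ("s1", 1)))
        assert s.segments["s1"].confirmer == "B"

    def test_cross_delete_requires_anchor(self):
        s = ProtocolState()
        apply_event(s, _add(1, "A", "s1", GEOM))
        apply_event(s, _add(2, "A", "s2", [(0, 0, 6, 1)], ("s1", 1)))
        # s2 extends A's unconfirmed s1: B may not delete it yet
        with pytest.raises(ProtocolViolation):
            apply_event(s, AnnotationEvent(3, "B", "delete", "s2"))
        apply_event(s, AnnotationEvent(4, "B", "confirm", "s1"))
        apply_event(s, AnnotationEvent(5, "B", "delete", "s2"))
        assert s.segments["s2"].status == "deleted"

    def test_own_delete_always_allowed(self):
        s = ProtocolState()
        apply_event(s, _add(1, "A", "s1", GEOM))
        apply_event(s, _add(2, "A", "s2", [(0, 0, 6, 1)], ("s1", 1)))
        apply_event(s, AnnotationEvent(3, "A", "delete", "s2"))
        assert s.segments["s2"].status == "deleted"

    def test_delete_cascades_to_children(self):
        s = ProtocolState()
        apply_event(s, _add(1, "A", "s1", GEOM))
        apply_event(s, _add(2, "A", "s2", [(0, 0, 6, 1)], ("s1", 1)))
        apply_event(s, AnnotationEvent(3, "A", "delete", "s1"))
        assert s.segments["s2"].status == "deleted"

    def test_unknown_segment(self):
        with pytest.raises(ProtocolViolation) as exc:
            apply_event(ProtocolState(), AnnotationEvent(1, "A", "confirm", "nope"))
        assert exc.value.kind == "unknown_segment"


class TestCompletionAndAgreement:
    def test_empty_state_complete(self):
        assert is_complete(ProtocolState())

    def test_unvalidated_segment_blocks_completion(self):
        s = ProtocolState()
        apply_event(s, _add(1, "A", "s1", GEOM))
        assert not is_complete(s)
        apply_event(s, AnnotationEvent(2, "B", "confirm", "s1"))
        assert is_complete(s)

    def test_agreement_ratio(self):
        s = ProtocolState()
        # s1: 30 um, confirmed; s2 (A's own extension): 10 um, unvalidated
        apply_event(s, _add(1, "A", "s1", [(0, 0, 10, 1), (0, 0, 20, 1), (0, 0, 30, 1)]))
        apply_event(s, _add(2, "A", "s2", [(0, 0, 40, 1)], ("s1", 2)))
        apply_event(s, AnnotationEvent(3, "B", "confirm", "s1"))
        assert agreement(s) == pytest.approx(0.75)

    def test_agreement_empty_rejected(self):
        with pytest.raises(ValueError):
            agreement(ProtocolState())


class TestSimulator:
    def test_single_annotator_rejected(self):
        truth = random_tree(0)
        with pytest.raises(ValueError):
            simulate_collaboration(truth, [{"error_rate": 0, "confirm_diligence": 1}], 0)

    def test_perfect_annotators_reach_perfect_accuracy(self):
        truth = random_tree(1)
        log = simulate_collaboration(
            truth, [{"error_rate": 0.0, "confirm_diligence": 1.0}] * 2, seed=7
        )
        state = replay(log)
        assert is_complete(state)
        rep = match_length(state_to_tree(state), truth, 2.0)
        assert rep.accuracy == pytest.approx(1.0)
        assert agreement(state) == 1.0

    def test_same_seed_identical_logs(self):
        truth = random_tree(2)
        anns = [{"error_rate": 0.15, "confirm_diligence": 0.85}] * 3
        a = simulate_collaboration(truth, anns, seed=3)
        b = simulate_collaboration(truth, anns, seed=3)
        assert [e.to_json() for e in a.events] == [e.to_json() for e in b.events]

    def test_every_event_passes_protocol_replay(self):
        truth = random_tree(3)
        log = simulate_collaboration(
            truth, [{"error_rate": 0.3, "confirm_diligence": 0.7}] * 3, seed=9
        )
        replay(log)  # raises on any protocol violation

    def test_jsonl_roundtrip(self, tmp_path):
        truth = random_tree(4)
        log = simulate_collaboration(
            truth, [{"error_rate": 0.1, "confirm_diligence": 0.9}] * 2, seed=5
        )
        p = tmp_path / "log.jsonl"
        log.write_jsonl(p)
        log2 = EditLog.read_jsonl(p)
        assert [e.to_json() for e in log2.events] == [e.to_json() for e in log.events]
        assert log2.soma == log.soma


class TestRevokeCrossEdits:
    def test_no_cross_edits_identical_to_replay(self):
        truth = random_tree(5)
        log = simulate_collaboration(
            truth, [{"error_rate": 0.0, "confirm_diligence": 1.0}] * 2, seed=1
        )
        collab = state_to_tree(replay(log))
        noncollab = revoke_cross_edits(log)
        assert match_length(collab, noncollab, 1.0).accuracy == pytest.approx(1.0)

    def test_cross_deleted_branch_restored(self):
        events = [
            _add(1, "A", "s1", GEOM),
            AnnotationEvent(2, "B", "confirm", "s1"),
            _add(3, "A", "bad", [(5, 5, 4, 1), (9, 9, 4, 1)], ("s1", 1)),
            AnnotationEvent(4, "B", "delete", "bad"),
        ]
        log = EditLog(events=events)
        collab = state_to_tree(replay(log))
        noncollab = revoke_cross_edits(log)
        assert total_length(noncollab) > total_length(collab)

    def test_own_delete_not_revoked(self):
        events = [
            _add(1, "A", "s1", GEOM),
            _add(2, "A", "bad", [(5, 5, 4, 1)], ("s1", 1)),
            AnnotationEvent(3, "A", "delete", "bad"),
        ]
        log = EditLog(events=events)
        noncollab = revoke_cross_edits(log)
        collab = state_to_tree(replay(log))
        assert total_length(noncollab) == pytest.approx(total_length(collab))


class TestContrastProjectionMap:
    def test_identical_trees_all_regions_neutral(self):
        t = random_tree(6)
        regions = np.ones((128, 128, 128), dtype=np.int32)
        result = contrast_projection_map(t, t, regions)
        assert all(v["dominant_symbol"] == "o" for v in result.values())

    def test_added_branch_marks_its_region(self):
        from arborkit.swc import NeuronNode, NeuronTree

        base = [NeuronNode(1, 1, 10, 10, 10, 1, -1),
                NeuronNode(2, 2, 20, 10, 10, 1, 1)]
        noncollab = NeuronTree(base, unit="voxel")
        collab = NeuronTree(
            base + [NeuronNode(3, 2, 20, 30, 10, 1, 2)], unit="voxel"
        )
        regions = np.ones((40, 40, 40), dtype=np.int32)
        # the added branch runs from y=10 to y=30; its first couple of
        # voxels sit within the match threshold of the shared structure, so
        # the unmatched mass starts past y~12
        regions[:, 12:, :] = 7
        result = contrast_projection_map(collab, noncollab, regions)
        assert result[7]["dominant_symbol"] == "+"
        assert result[1]["dominant_symbol"] == "o"

    def test_added_length_conserved_across_regions(self):
        from arborkit.synthetic import make_region_labels

        a = random_tree(7)
        b = random_tree(8)
        regions = make_region_labels((128, 128, 128), 5, seed=0)
        per_region = contrast_projection_map(a, b, regions)
        total_added = sum(v["added_length"] for v in per_region.values())
        whole = contrast_projection_map(
            a, b, np.ones((128, 128, 128), dtype=np.int32)
        )
        assert total_added == pytest.approx(whole[1]["added_length"], rel=0.01)
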