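"""Grounding engine: oracle backend, brute-force agreement, quantifiers,
connectives, instruction selection, full-structure extraction."""

import numpy as np
import pytest

from counterstream import grounding as gr
from counterstream.grounding import (
    GroundingState,
    PropertyConstraint,
    TargetEdge,
    TargetNode,
    TargetStructure,
    TargetValidationError,
    brute_force_ground,
    check_set_requirements,
    demo_goal_scene,
    demo_goal_target,
    extract_full_structure,
    ground,
    oracle_backend,
    sample_fully_visible_scene,
    select_next_instruction,
    target_from_json,
)
from counterstream.instructions import EXTRACT_NEXT
from counterstream.model import iou
from counterstream.scene_synth import SceneSpec, depth_order_key


def simple_target(cls="woman"):
    return TargetStructure(nodes=[TargetNode("n0", cls)], root="n0")


class TestOracleBackend:
    def test_extract_next_in_depth_order(self, small_scene):
        backend = oracle_backend(small_scene)
        ordered = sorted(small_scene.entities, key=depth_order_key)
        got = [backend.expand_next() for _ in ordered]
        assert [g[0] for g in got] == [e.class_label for e in ordered]
        for g, e in zip(got, ordered):
            assert iou(g[1], small_scene.masks[e.id] > 0) == 1.0

    def test_exhaustion_returns_none(self, small_scene):
        backend = oracle_backend(small_scene)
        for _ in small_scene.entities:
            assert backend.expand_next() is not None
        assert backend.expand_next() is None

    def test_elaborate_reads_ground_truth(self, small_scene):
        backend = oracle_backend(small_scene)
        person = next(e for e in small_scene.entities if e.kind == "person")
        mask = (small_scene.masks[person.id] > 0).astype(np.uint8)
        assert backend.elaborate_property("class", mask) == person.class_label
        assert backend.elaborate_property("outfit", mask) == person.properties["outfit"]

    def test_class_noise_corrupts_answers(self, small_scene):
        noisy = oracle_backend(small_scene, noise={"class": 1.0}, seed=0)
        clean = oracle_backend(small_scene)
        wrong = 0
        for _ in small_scene.entities:
            lab_n = noisy.expand_next()[0]
            lab_c = clean.expand_next()[0]
            wrong += lab_n != lab_c
        assert wrong >= 1  # rate-1 noise flips classes whenever an alternative exists

    def test_unresolvable_reference_returns_none(self, small_scene):
        backend = oracle_backend(small_scene)
        empty = np.zeros(small_scene.image.shape[:2], dtype=np.uint8)
        assert backend.expand_related("facing", empty) is None


class TestBruteForce:
    def test_single_node_match(self, small_scene):
        cls = small_scene.entities[0].class_label
        sat, wit = brute_force_ground(simple_target(cls), small_scene)
        assert sat and small_scene.entity(wit["n0"]).class_label == cls

    def test_edge_direction_respected(self):
        scene = demo_goal_scene()
        fwd = TargetStructure(
            nodes=[TargetNode("a", "woman"), TargetNode("b", "girl")],
            edges=[TargetEdge("facing", "a", "b")], root="a")
        # girl at orientation 180 faces the woman too; use a direction that
        # holds one way only: holding
        hold_fwd = TargetStructure(
            nodes=[TargetNode("a", "woman"), TargetNode("b", "bag")],
            edges=[TargetEdge("holding", "a", "b")], root="a")
        hold_rev = TargetStructure(
            nodes=[TargetNode("a", "woman"), TargetNode("b", "bag")],
            edges=[TargetEdge("holding", "b", "a")], root="a")
        assert brute_force_ground(fwd, scene)[0]
        assert brute_force_ground(hold_fwd, scene)[0]
        assert not brute_force_ground(hold_rev, scene)[0]

    def test_unsatisfiable_cycle(self):
        scene = demo_goal_scene()
        t = TargetStructure(
            nodes=[TargetNode("a", "woman"), TargetNode("b", "girl")],
            edges=[TargetEdge("in-front", "a", "b"), TargetEdge("in-front", "b", "a")],
            root="a")
        assert not brute_force_ground(t, scene)[0]

    def test_size_guard(self, small_scene):
        big = TargetStructure(nodes=[TargetNode(f"n{i}") for i in range(6)])
        with pytest.raises(ValueError, match="guarded"):
            brute_force_ground(big, small_scene)


class TestGround:
    def test_walkthrough_grounds_and_reports(self):
        scene = demo_goal_scene()
        res = ground(demo_goal_target(), oracle_backend(scene), budget=64)
        assert res.status == "grounded"
        assert res.report == {"held_class": "bag", "held_size": "large"}
        tasks = {t for i in res.instruction_trace for t in i.tasks}
        assert tasks <= {EXTRACT_NEXT, "facing", "holding", "class", "size"}

    def test_empty_scene_fails_with_extract_next_trace(self):
        from counterstream.scene_synth import Scene

        scene = Scene(entities=[], relations=[], image=np.zeros((8, 8, 3), np.uint8), masks={})
        res = ground(simple_target(), oracle_backend(scene), budget=8)
        assert res.status == "failed"
        assert all(i.tasks == (EXTRACT_NEXT,) for i in res.instruction_trace)

    def test_budget_exhaustion_flagged(self):
        scene = demo_goal_scene()
        res = ground(simple_target("streetlight"), oracle_backend(scene), budget=2)
        assert res.status == "failed" and res.failure_reason == "budget"

    def test_extraction_economy_vs_full_structure(self):
        scene = demo_goal_scene()
        res = ground(demo_goal_target(), oracle_backend(scene), budget=64)
        full = extract_full_structure(oracle_backend(scene), budget=64)
        assert res.status == "grounded"
        assert len(res.components) <= len(full.components)

    def test_trace_length_equals_backend_calls(self):
        scene = demo_goal_scene()
        backend = oracle_backend(scene)
        res = ground(demo_goal_target(), backend, budget=64)
        assert len(res.instruction_trace) == backend.calls

    @pytest.mark.parametrize("n_pairs", [120])
    def test_agreement_with_brute_force(self, n_pairs):
        rng = np.random.default_rng(99)
        agree = 0
        for i in range(n_pairs):
            spec = SceneSpec(n_persons=int(rng.integers(0, 3)), n_objects=int(rng.integers(0, 3)))
            scene = sample_fully_visible_scene(spec, seed=10_000 + i)
            if len(scene.entities) > 8:
                continue
            target = gr.sample_random_target(scene, rng, max_nodes=3)
            sat, wit = brute_force_ground(target, scene)
            res = ground(target, oracle_backend(scene), budget=10_000)
            assert (res.status == "grounded") == sat, f"pair {i}"
            if sat and res.status == "grounded":
                # every engine pairing satisfies the node constraints in truth
                for nid, ci in res.pairings.items():
                    node = target.node(nid)
                    if node.quantifier != "exists":
                        continue
                    comp = res.components[ci]
                    ent = next(e for e in scene.entities
                               if iou(scene.masks[e.id] > 0, comp.mask) >= 0.5)
                    if node.class_constraint:
                        assert ent.class_label == node.class_constraint
            agree += 1
        assert agree > 0


class TestQuantifiers:
    def test_check_set_requirements_semantics(self):
        assert check_set_requirements(TargetNode("n", quantifier="exists"), 1, 5)
        assert check_set_requirements(TargetNode("n", quantifier="all"), 3, 3)
        assert not check_set_requirements(TargetNode("n", quantifier="all"), 2, 3)
        assert check_set_requirements(TargetNode("n", quantifier="count", count=2), 2, 9)
        assert not check_set_requirements(TargetNode("n", quantifier="count", count=2), 3, 9)
        assert check_set_requirements(TargetNode("n", quantifier="how-many", report="k"), 0, 0) == 0

    def test_all_quantifier_over_scene(self):
        scene = demo_goal_scene()  # persons: woman, girl, man — all have outfit set
        t = TargetStructure(nodes=[TargetNode("p", "woman", quantifier="all",
                                              properties=[PropertyConstraint("outfit", 3)])])
        res = ground(t, oracle_backend(scene), budget=64)
        sat, _ = brute_force_ground(t, scene)
        assert sat and res.status == "grounded"

    def test_count_quantifier_exact(self):
        scene = demo_goal_scene()
        for n, want in ((1, True), (2, False)):
            t = TargetStructure(nodes=[TargetNode("p", "girl", quantifier="count", count=n)])
            assert (ground(t, oracle_backend(scene), budget=64).status == "grounded") == want

    def test_how_many_reports_count(self):
        scene = demo_goal_scene()
        t = TargetStructure(nodes=[TargetNode("p", "person-none", quantifier="how-many", report="n")])
        t.nodes[0].class_constraint = "boy"
        res = ground(t, oracle_backend(scene), budget=64)
        assert res.status == "grounded" and res.report["n"] == 0

    def test_connective_or_grounds_available_branch(self):
        scene = demo_goal_scene()
        t = TargetStructure(
            nodes=[TargetNode("a", "boy"), TargetNode("b", "tree")],
            connective={"op": "or", "args": ["a", "b"]})
        res = ground(t, oracle_backend(scene), budget=64)
        assert res.status == "grounded" and "b" in res.pairings and "a" not in res.pairings


class TestSelectNextInstruction:
    def test_fresh_state_emits_extract_next_with_empty_mask(self):
        t = simple_target()
        state = GroundingState(target=t, order=["n0"])
        instr = select_next_instruction(state)
        assert instr.tasks == (EXTRACT_NEXT,) and instr.arg_mode == "mask" and instr.arg is None

    def test_paired_node_with_unchecked_property(self):
        t = TargetStructure(nodes=[TargetNode("n0", "woman",
                                              properties=[PropertyConstraint("outfit", 1)])])
        from counterstream.grounding import ComponentRecord

        comp = ComponentRecord(0, "woman", mask=np.ones((4, 4), np.uint8))
        state = GroundingState(target=t, order=["n0"], pairings={"n0": 0}, components=[comp])
        instr = select_next_instruction(state)
        assert instr.tasks == ("outfit",)

    def test_all_done(self):
        t = TargetStructure(nodes=[TargetNode("n0", "woman")])
        from counterstream.grounding import ComponentRecord

        comp = ComponentRecord(0, "woman", mask=np.ones((4, 4), np.uint8))
        state = GroundingState(target=t, order=["n0"], pairings={"n0": 0}, components=[comp])
        assert select_next_instruction(state) == "done"


class TestFullStructure:
    def test_oracle_full_extraction_matches_ground_truth(self):
        spec = SceneSpec(n_persons=1, n_objects=2, p_held=0.0, p_carried=0.0, p_on=0.0)
        scene = sample_fully_visible_scene(spec, seed=77)
        full = extract_full_structure(oracle_backend(scene), budget=64,
                                      relation_names=["facing", "left", "in-front"])
        assert len(full.components) == len(scene.entities)
        ordered = sorted(scene.entities, key=depth_order_key)
        for comp, ent in zip(full.components, ordered):
            assert comp.class_label == ent.class_label
            for pname, val in comp.properties.items():
                assert val == gr._entity_property(ent, pname)
        # extracted relations match ground truth for the checked predicates
        idx_to_ent = {c.index: e for c, e in zip(full.components, ordered)}
        for c in full.components:
            for s, r, o in c.relations:
                assert scene.has_relation(idx_to_ent[s].id, r, idx_to_ent[o].id)

    def test_empty_scene_empty_structure(self):
        from counterstream.scene_synth import Scene

        scene = Scene(entities=[], relations=[], image=np.zeros((8, 8, 3), np.uint8), masks={})
        full = extract_full_structure(oracle_backend(scene), budget=8)
        assert full.status == "grounded" and full.components == [] and not full.partial

    def test_budget_one_partial_flag(self):
        scene = demo_goal_scene()
        full = extract_full_structure(oracle_backend(scene), budget=1)
        assert full.partial


class TestTargetDSL:
    def test_json_roundtrip_and_validation(self):
        obj = {
            "root": "a",
            "nodes": [
                {"id": "a", "class": "woman"},
                {"id": "b", "class": "girl", "quantifier": {"count": 2}},
            ],
            "edges": [{"relation": "facing", "src": "a", "dst": "b"}],
        }
        t = target_from_json(obj)
        assert t.node("b").quantifier == "count" and t.node("b").count == 2

    @pytest.mark.parametrize("mutate,msg", [
        (lambda o: o["edges"].append({"relation": "nope", "src": "a", "dst": "b"}), "relation"),
        (lambda o: o["nodes"].append({"id": "a"}), "duplicate"),
        (lambda o: o["nodes"][0].update({"quantifier": "some"}), "quantifier"),
        (lambda o: o.update({"root": "zz"}), "root"),
    ])
    def test_invalid_targets_rejected(self, mutate, msg):
        obj = {
            "root": "a",
            "nodes": [{"id": "a", "class": "woman"}, {"id": "b", "class": "girl"}],
            "edges": [{"relation": "facing", "src": "a", "dst": "b"}],
        }
        mutate(obj)
        with pytest.raises(TargetValidationError, match=msg):
            target_from_json(obj)
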