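"""Goal-directed structure extraction: grounding a target structure in a scene.

A *target structure* is a small goal graph: nodes with optional class and
property constraints (a property slot can instead be a *report slot* to be
filled from the image), quantifiers (``exists`` — the default, ``all``,
``count(n)``, ``how-many``), edges carrying relations between nodes, and an
optional and/or connective tree over the nodes.

The engine grounds the target by a recursive process that handles one node at
a time in depth-first order, issuing TD instructions to a perception backend:
*expansion* instructions add a new scene component (``extract-next``, or a
relation with an already-grounded reference component), and *elaboration*
instructions read properties or verify relations of existing components.
Candidates that fail a constraint are rejected with chronological
backtracking; the process stops when the target is grounded or no
alternatives are left to check.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .instructions import EXTRACT_NEXT, TDInstruction
from .model import iou
from .scene_synth import PREDICATES, Scene, SceneSpec, depth_order_key, sample_scene

PROPERTY_NAMES = ["outfit", "hairstyle", "sunglasses", "hat", "size", "color"]

QUANTIFIERS = ("exists", "all", "count", "how-many")


class TargetValidationError(ValueError):
    pass


@dataclass
class PropertyConstraint:
    name: str
    value: object = None  # required value, or None
    report: str | None = None  # report-slot name, or None


@dataclass
class TargetNode:
    id: str
    class_constraint: str | None = None
    properties: list[PropertyConstraint] = field(default_factory=list)
    quantifier: str = "exists"
    count: int | None = None  # for quantifier == "count"
    report: str | None = None  # for quantifier == "how-many"


@dataclass
class TargetEdge:
    relation: str
    src: str
    dst: str


@dataclass
class TargetStructure:
    nodes: list[TargetNode]
    edges: list[TargetEdge] = field(default_factory=list)
    root: str | None = None
    connective: object = None  # and/or tree: {"op": "and"|"or", "args": [node-id | tree, ...]}

    def node(self, nid: str) -> TargetNode:
        for n in self.nodes:
            if n.id == nid:
                return n
        raise KeyError(nid)

    def validate(self) -> None:
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise TargetValidationError("duplicate node ids")
        for n in self.nodes:
            if n.quantifier not in QUANTIFIERS:
                raise TargetValidationError(f"node {n.id}: unknown quantifier {n.quantifier!r}")
            if n.quantifier == "count" and (n.count is None or n.count < 0):
                raise TargetValidationError(f"node {n.id}: count quantifier needs a non-negative count")
            if n.quantifier == "how-many" and not n.report:
                raise TargetValidationError(f"node {n.id}: how-many quantifier needs a report slot")
            for p in n.properties:
                if p.name not in PROPERTY_NAMES and p.name != "class":
                    raise TargetValidationError(f"node {n.id}: unknown property {p.name!r}")
        for e in self.edges:
            if e.relation not in PREDICATES:
                raise TargetValidationError(f"edge {e.src}->{e.dst}: unknown relation {e.relation!r}")
            if e.src not in ids or e.dst not in ids:
                raise TargetValidationError(f"edge references missing node ({e.src}, {e.dst})")
            if self.node(e.src).quantifier != "exists" and self.node(e.dst).quantifier != "exists":
                raise TargetValidationError("edges between two set-quantified nodes are unsupported")
        if self.root is not None and self.root not in ids:
            raise TargetValidationError(f"root {self.root!r} is not a node id")


def target_from_json(obj: dict) -> TargetStructure:
    nodes = []
    for n in obj.get("nodes", []):
        if "id" not in n:
            raise TargetValidationError("node missing 'id'")
        q = n.get("quantifier", "exists")
        count = None
        if isinstance(q, dict):
            count = q.get("count")
            q = "count"
        nodes.append(
            TargetNode(
                id=n["id"],
                class_constraint=n.get("class"),
                properties=[
                    PropertyConstraint(p["name"], p.get("value"), p.get("report"))
                    for p in n.get("properties", [])
                ],
                quantifier=q,
                count=count if count is not None else n.get("count"),
                report=n.get("report"),
            )
        )
    edges = [TargetEdge(e["relation"], e["src"], e["dst"]) for e in obj.get("edges", [])]
    t = TargetStructure(nodes=nodes, edges=edges, root=obj.get("root"), connective=obj.get("connective"))
    t.validate()
    return t


def load_target(path: str | Path) -> TargetStructure:
    return target_from_json(json.loads(Path(path).read_text()))


# ------------------------------------------------------------------ components

@dataclass
class ComponentRecord:
    index: int
    class_label: str | None
    properties: dict = field(default_factory=dict)
    relations: list = field(default_factory=list)  # validated (subj_idx, rel, obj_idx)
    mask: np.ndarray | None = None
    paired_node: str | None = None


@dataclass
class ExtractedStructure:
    components: list[ComponentRecord] = field(default_factory=list)
    pairings: dict[str, object] = field(default_factory=dict)  # node id -> comp index | [indices]
    status: str = "failed"  # grounded | failed
    instruction_trace: list[TDInstruction] = field(default_factory=list)
    report: dict = field(default_factory=dict)
    failure_reason: str | None = None
    partial: bool = False

    def to_json(self) -> dict:
        return {
            "status": self.status,
            "failure_reason": self.failure_reason,
            "report": self.report,
            "pairings": self.pairings,
            "components": [
                {
                    "index": c.index,
                    "class": c.class_label,
                    "properties": c.properties,
                    "relations": c.relations,
                    "paired_node": c.paired_node,
                }
                for c in self.components
            ],
            "trace": [
                {"task": list(i.tasks), "arg_mode": i.arg_mode} for i in self.instruction_trace
            ],
        }


# ------------------------------------------------------------------ backends

class BudgetExhausted(Exception):
    pass


class PerceptionBackend:
    """Contract between the grounding engine and perception.

    ``expand_next`` returns not-yet-returned components in order of camera
    distance; ``expand_related`` returns components standing in a relation to
    a reference mask (direction ``"subject"``: returned component is the
    relation's subject; ``"object"``: its object); ``elaborate_property`` and
    ``elaborate_relation`` read out properties / verify relations of existing
    components.  ``calls`` counts every backend invocation.
    """

    def __init__(self):
        self.calls = 0

    def reset(self):
        self.calls = 0

    def expand_next(self, accumulated_mask):
        raise NotImplementedError

    def expand_related(self, relation, ref_mask, direction="subject"):
        raise NotImplementedError

    def elaborate_property(self, prop, mask):
        raise NotImplementedError

    def elaborate_relation(self, relation, subj_mask, obj_mask):
        raise NotImplementedError


def _entity_property(entity, name):
    if name == "class":
        return entity.class_label
    if name == "size":
        return entity.size_class
    if name == "color":
        return entity.color
    return entity.properties.get(name)


class OracleBackend(PerceptionBackend):
    """Simulates perfectly trained expansion/elaboration networks by reading
    scene ground truth; optional noise flips answers at the given rates."""

    def __init__(self, scene: Scene, noise: dict | None = None, seed: int = 0):
        super().__init__()
        self.scene = scene
        self.noise = noise or {}
        self.rng = np.random.default_rng(seed)
        self._ordered = sorted(scene.entities, key=depth_order_key)
        self._returned: set[int] = set()
        self._rel_cursor: dict[tuple, set[int]] = {}

    def reset(self):
        super().reset()
        self._returned.clear()
        self._rel_cursor.clear()

    def _mask(self, eid: int) -> np.ndarray:
        return (self.scene.masks[eid] > 0).astype(np.uint8)

    def _resolve(self, ref_mask) -> int | None:
        best, best_iou = None, 0.0
        for e in self.scene.entities:
            v = iou(self._mask(e.id), ref_mask)
            if v >= 0.5 and v > best_iou:
                best, best_iou = e.id, v
        return best

    def _maybe_flip_class(self, label, pool):
        p = self.noise.get("class", 0.0)
        if p and self.rng.random() < p:
            return str(self.rng.choice([c for c in pool if c != label] or [label]))
        return label

    def expand_next(self, accumulated_mask=None):
        self.calls += 1
        for e in self._ordered:
            if e.id in self._returned:
                continue
            self._returned.add(e.id)
            label = self._maybe_flip_class(e.class_label, [x.class_label for x in self.scene.entities])
            return label, self._mask(e.id), e.id
        return None

    def expand_related(self, relation, ref_mask, direction="subject"):
        self.calls += 1
        ref = self._resolve(ref_mask)
        if ref is None:
            return None
        key = (relation, ref, direction)
        seen = self._rel_cursor.setdefault(key, set())
        cands = []
        for r in self.scene.relations:
            if r.predicate != relation:
                continue
            if direction == "subject" and r.object_id == ref:
                cands.append(r.subject_id)
            elif direction == "object" and r.subject_id == ref:
                cands.append(r.object_id)
        for eid in sorted(cands, key=lambda i: depth_order_key(self.scene.entity(i))):
            if eid in seen:
                continue
            seen.add(eid)
            self._returned.add(eid)
            e = self.scene.entity(eid)
            label = self._maybe_flip_class(e.class_label, [x.class_label for x in self.scene.entities])
            return label, self._mask(eid), eid
        return None

    def elaborate_property(self, prop, mask):
        self.calls += 1
        eid = self._resolve(mask)
        if eid is None:
            return None
        val = _entity_property(self.scene.entity(eid), prop)
        p = self.noise.get("property", 0.0)
        if p and self.rng.random() < p and isinstance(val, bool):
            val = not val
        return val

    def elaborate_relation(self, relation, subj_mask, obj_mask):
        self.calls += 1
        s = self._resolve(subj_mask)
        o = self._resolve(obj_mask)
        if s is None or o is None:
            return False
        truth = self.scene.has_relation(s, relation, o)
        p = self.noise.get("relation", 0.0)
        if p and self.rng.random() < p:
            truth = not truth
        return truth


def oracle_backend(scene: Scene, noise: dict | None = None, seed: int = 0) -> OracleBackend:
    return OracleBackend(scene, noise=noise, seed=seed)


class NeuralBackend(PerceptionBackend):
    """Maps backend calls to TD instructions on a trained counterstream model.

    A returned mask is linked to scene entities only downstream, by IoU
    matching in evaluation code.  Relation verification is implemented the way
    the expansion pathway supports it: retrieve components related to the
    object reference and test the subject mask against them by IoU.
    """

    def __init__(self, model, class_space: str = "entity-class", mask_threshold: float = 0.5, max_extractions: int = 16):
        super().__init__()
        self.model = model  # fitted CounterstreamClassifier (guided)
        self.class_space = class_space
        self.mask_threshold = mask_threshold
        self.max_extractions = max_extractions
        self.image: np.ndarray | None = None
        self._accumulated: np.ndarray | None = None
        self._n_extracted = 0

    def attach(self, image: np.ndarray):
        self.image = image
        c, h, w = self.model.task_config.image_shape
        self._accumulated = np.zeros((h, w), dtype=np.float64)
        self._n_extracted = 0

    def expand_next(self, accumulated_mask=None):
        self.calls += 1
        if self.image is None:
            raise RuntimeError("NeuralBackend.attach(image) must be called first")
        if self._n_extracted >= self.max_extractions:
            return None
        instr = TDInstruction(EXTRACT_NEXT, "mask", self._accumulated.copy())
        out = self.model.forward(self.image, instr)
        mask = np.asarray(out.mask(self.mask_threshold)).reshape(self._accumulated.shape)
        label_idx = out.answer(EXTRACT_NEXT)
        label = self.model.class_names_[label_idx] if hasattr(self.model, "class_names_") else label_idx
        if mask.sum() == 0 or label == "none":
            return None
        self._n_extracted += 1
        self._accumulated = np.maximum(self._accumulated, mask)
        return label, mask.astype(np.uint8), None

    def expand_related(self, relation, ref_mask, direction="subject"):
        self.calls += 1
        if relation not in self.model.task_config.tasks:
            return None
        instr = TDInstruction(relation, "relation", (relation, np.asarray(ref_mask, dtype=np.float64)))
        out = self.model.forward(self.image, instr)
        mask = np.asarray(out.mask(self.mask_threshold)).reshape(ref_mask.shape)
        if mask.sum() == 0:
            return None
        label_idx = out.answer(relation)
        label = self.model.class_names_[label_idx] if hasattr(self.model, "class_names_") else label_idx
        return label, mask.astype(np.uint8), None

    def elaborate_property(self, prop, mask):
        self.calls += 1
        if prop not in self.model.task_config.tasks:
            return None
        instr = TDInstruction(prop, "mask", np.asarray(mask, dtype=np.float64))
        out = self.model.forward(self.image, instr)
        idx = out.answer(prop)
        values = getattr(self.model, "property_values_", {}).get(prop)
        return values[idx] if values else idx

    def elaborate_relation(self, relation, subj_mask, obj_mask):
        got = self.expand_related(relation, obj_mask, direction="subject")
        if got is None:
            return False
        _, mask, _ = got
        return iou(mask, subj_mask) >= 0.5


def neural_backend(model, **kw) -> NeuralBackend:
    return NeuralBackend(model, **kw)


# ------------------------------------------------------------------ connective models

def _connective_models(target: TargetStructure) -> list[list[str]]:
    """Enumerate (deterministically) the node subsets that satisfy the
    connective tree; with no connective, the single model is all nodes."""
    all_ids = [n.id for n in target.nodes]
    if target.connective is None:
        return [all_ids]

    def expand(tree) -> list[set[str]]:
        if isinstance(tree, str):
            return [{tree}]
        op = tree["op"]
        parts = [expand(a) for a in tree["args"]]
        if op == "and":
            models = [set()]
            for p in parts:
                models = [m | q for m in models for q in p]
        elif op == "or":
            models = [q for p in parts for q in p]
        else:
            raise TargetValidationError(f"unknown connective op {op!r}")
        out = []
        for m in models:
            if m not in out:
                out.append(m)
        return out

    return [[i for i in all_ids if i in m] for m in expand(target.connective)]


def _satisfies_tree(tree, grounded: set[str]) -> bool:
    if tree is None:
        return True
    if isinstance(tree, str):
        return tree in grounded
    if tree["op"] == "and":
        return all(_satisfies_tree(a, grounded) for a in tree["args"])
    return any(_satisfies_tree(a, grounded) for a in tree["args"])


def _dfs_order(target: TargetStructure, model: list[str]) -> list[str]:
    """Depth-first traversal over the target's edges (insertion order),
    starting at the root when present, else the first node of the model."""
    adj: dict[str, list[str]] = {nid: [] for nid in model}
    for e in target.edges:
        if e.src in adj and e.dst in adj:
            adj[e.src].append(e.dst)
            adj[e.dst].append(e.src)
    order: list[str] = []
    seen: set[str] = set()

    def visit(nid: str):
        seen.add(nid)
        order.append(nid)
        for nb in adj[nid]:
            if nb not in seen:
                visit(nb)

    start = target.root if target.root in adj else (model[0] if model else None)
    if start is not None:
        visit(start)
    for nid in model:
        if nid not in seen:
            visit(nid)
    return order


# ------------------------------------------------------------------ the engine

def check_set_requirements(node: TargetNode, matched: int, candidates: int):
    """Evaluate a node's set requirement given the number of matching
    components (and of class-matching candidates)."""
    if node.quantifier == "exists":
        return matched >= 1
    if node.quantifier == "all":
        return matched == candidates
    if node.quantifier == "count":
        return matched == node.count
    if node.quantifier == "how-many":
        return matched
    raise ValueError(node.quantifier)


@dataclass
class GroundingState:
    """Snapshot of the engine used by select_next_instruction."""

    target: TargetStructure
    order: list[str]
    pairings: dict[str, int] = field(default_factory=dict)
    checked_props: dict[str, set] = field(default_factory=dict)
    components: list[ComponentRecord] = field(default_factory=list)
    current: int = 0

    def accumulated_mask(self):
        masks = [c.mask for c in self.components if c.mask is not None]
        if not masks:
            return None
        out = masks[0].astype(np.uint8)
        for m in masks[1:]:
            out = np.maximum(out, m.astype(np.uint8))
        return out


def select_next_instruction(state: GroundingState):
    """The next TD instruction the recursive process would issue, or "done"."""
    if state.current >= len(state.order):
        return "done"
    nid = state.order[state.current]
    node = state.target.node(nid)
    if nid not in state.pairings:
        for e in state.target.edges:
            if e.dst == nid and e.src in state.pairings:
                ref = state.components[state.pairings[e.src]].mask
                return TDInstruction(e.relation, "relation", (e.relation, ref))
            if e.src == nid and e.dst in state.pairings:
                ref = state.components[state.pairings[e.dst]].mask
                return TDInstruction(e.relation, "relation", (e.relation, ref))
        acc = state.accumulated_mask()
        return TDInstruction(EXTRACT_NEXT, "mask", acc)
    checked = state.checked_props.get(nid, set())
    for p in node.properties:
        if p.name not in checked:
            return TDInstruction(p.name, "mask", state.components[state.pairings[nid]].mask)
    state.current += 1
    return select_next_instruction(state)


def ground(
    target: TargetStructure,
    backend: PerceptionBackend,
    budget: int = 64,
) -> ExtractedStructure:
    """Ground a target structure through a perception backend.

    Returns an ExtractedStructure with status ``grounded`` iff every target
    node (respecting quantifiers and connectives) was paired/validated, the
    ordered component store, the full instruction trace and the filled report
    slots.  The expansion budget bounds backend expansion calls; exhaustion
    yields status ``failed`` with reason ``"budget"``.
    """
    target.validate()
    result = ExtractedStructure()
    trace = result.instruction_trace
    components: list[ComponentRecord] = []
    expansions = {"n": 0}

    def spend():
        expansions["n"] += 1
        if budget is not None and expansions["n"] > budget:
            raise BudgetExhausted

    def acc_mask():
        masks = [c.mask for c in components if c.mask is not None]
        if not masks:
            return None
        out = masks[0].astype(np.uint8)
        for m in masks[1:]:
            out = np.maximum(out, m)
        return out

    def find_component(mask) -> ComponentRecord | None:
        for c in components:
            if c.mask is not None and iou(c.mask, mask) >= 0.5:
                return c
        return None

    def new_component(label, mask) -> ComponentRecord:
        existing = find_component(mask) if mask is not None else None
        if existing is not None:
            return existing
        c = ComponentRecord(index=len(components), class_label=label, mask=mask)
        components.append(c)
        return c

    def check_node_on(comp: ComponentRecord, node: TargetNode, pairings: dict, report: dict) -> bool:
        """Elaborate and validate class, properties and edges of `node`
        against component `comp` (edges only to already-paired nodes)."""
        if node.class_constraint is not None and comp.class_label != node.class_constraint:
            return False
        for p in node.properties:
            trace.append(TDInstruction(p.name, "mask", comp.mask))
            val = backend.elaborate_property(p.name, comp.mask)
            comp.properties[p.name] = val
            if p.value is not None and val != p.value:
                return False
            if p.report:
                report[p.report] = val
        for e in target_edges_for(node.id):
            other = e.dst if e.src == node.id else e.src
            if other not in pairings:
                continue
            if target.node(other).quantifier != "exists":
                continue
            ocomp = components[pairings[other]]
            subj = comp if e.src == node.id else ocomp
            obj = ocomp if e.src == node.id else comp
            trace.append(TDInstruction(e.relation, "relation", (e.relation, obj.mask)))
            ok = backend.elaborate_relation(e.relation, subj.mask, obj.mask)
            if ok:
                comp.relations.append((subj.index, e.relation, obj.index))
            else:
                return False
        return True

    def target_edges_for(nid: str):
        return [e for e in target.edges if e.src == nid or e.dst == nid]

    def candidate_stream(node: TargetNode, pairings: dict, tried: set):
        """Candidates for an exists node: any already-extracted, unpaired,
        untried component (the store is rescanned dynamically, so components
        extracted by deeper recursion levels are offered on backtracking);
        when none remains, expand via a relation to an already-paired node
        (the expansion fast path), falling back to extract-next until the
        scene is exhausted.  Every yielded candidate is fully re-verified."""
        gen_edge = None
        for e in target_edges_for(node.id):
            other = e.dst if e.src == node.id else e.src
            if other in pairings and target.node(other).quantifier == "exists":
                gen_edge = e
                break
        gen_exhausted = gen_edge is None
        while True:
            paired_idx = {v for v in pairings.values() if isinstance(v, int)}
            fresh = next(
                (c for c in components if c.index not in paired_idx and c.index not in tried),
                None,
            )
            if fresh is not None:
                yield fresh
                continue
            if not gen_exhausted:
                other = gen_edge.dst if gen_edge.src == node.id else gen_edge.src
                ref = components[pairings[other]].mask
                direction = "subject" if gen_edge.src == node.id else "object"
                spend()
                trace.append(TDInstruction(gen_edge.relation, "relation", (gen_edge.relation, ref)))
                got = backend.expand_related(gen_edge.relation, ref, direction)
                if got is None:
                    gen_exhausted = True
                    continue
                new_component(got[0], got[1])
                continue
            spend()
            trace.append(TDInstruction(EXTRACT_NEXT, "mask", acc_mask()))
            got = backend.expand_next(acc_mask())
            if got is None:
                return
            new_component(got[0], got[1])

    def enumerate_all(pairings: dict):
        """Drive extract-next to exhaustion so set-quantified nodes can be
        evaluated over every scene component."""
        while True:
            spend()
            trace.append(TDInstruction(EXTRACT_NEXT, "mask", acc_mask()))
            got = backend.expand_next(acc_mask())
            if got is None:
                return
            label, mask, _ = got
            new_component(label, mask)

    def recurse(order: list[str], i: int, pairings: dict, report: dict) -> bool:
        if i == len(order):
            return True
        node = target.node(order[i])
        if node.quantifier == "exists":
            tried: set[int] = set()
            for comp in candidate_stream(node, pairings, tried):
                tried.add(comp.index)
                snapshot = dict(report)
                if not check_node_on(comp, node, pairings, report):
                    report.clear()
                    report.update(snapshot)
                    continue
                pairings[node.id] = comp.index
                comp.paired_node = node.id
                if recurse(order, i + 1, pairings, report):
                    return True
                comp.paired_node = None
                del pairings[node.id]
                report.clear()
                report.update(snapshot)
            return False
        # set-quantified node: enumerate the scene, count matches
        enumerate_all(pairings)
        matched_idx = []
        candidates = 0
        for comp in components:
            if node.class_constraint is not None and comp.class_label != node.class_constraint:
                continue
            candidates += 1
            if check_node_on(comp, node, pairings, report):
                matched_idx.append(comp.index)
        verdict = check_set_requirements(node, len(matched_idx), candidates)
        if node.quantifier == "how-many":
            report[node.report] = verdict
            pairings[node.id] = matched_idx
            return recurse(order, i + 1, pairings, report)
        if verdict:
            pairings[node.id] = matched_idx
            return recurse(order, i + 1, pairings, report)
        return False

    try:
        for model in _connective_models(target):
            backend.reset()
            components.clear()
            trace_len = len(trace)
            pairings: dict = {}
            report: dict = {}
            order = _dfs_order(target, model)
            # set-quantified nodes are evaluated after all exists-nodes are
            # bound, mirroring the set-requirement tests of the procedure
            order = [n for n in order if target.node(n).quantifier == "exists"] + [
                n for n in order if target.node(n).quantifier != "exists"
            ]
            expansions["n"] = 0
            if recurse(order, 0, pairings, report):
                result.status = "grounded"
                result.pairings = pairings
                result.report = report
                break
            del trace[trace_len:]  # keep only the successful / last model's trace
    except BudgetExhausted:
        result.status = "failed"
        result.failure_reason = "budget"
    result.components = components
    return result


# ------------------------------------------------------------------ brute-force oracle

def brute_force_ground(target: TargetStructure, scene: Scene):
    """Exhaustive satisfiability check of a target against a ground-truth
    scene graph; independent of the instruction-driven engine.  Guarded to
    small instances (<= 8 entities, <= 5 nodes)."""
    target.validate()
    if len(scene.entities) > 8 or len(target.nodes) > 5:
        raise ValueError("brute_force_ground is guarded to <= 8 entities and <= 5 nodes")

    def prop_ok(entity, node: TargetNode) -> bool:
        if node.class_constraint is not None and entity.class_label != node.class_constraint:
            return False
        for p in node.properties:
            if p.value is not None and _entity_property(entity, p.name) != p.value:
                return False
        return True

    def rel_ok(e_subj, rel, e_obj) -> bool:
        return scene.has_relation(e_subj.id, rel, e_obj.id)

    for model in _connective_models(target):
        nodes = [target.node(nid) for nid in model]
        exists_nodes = [n for n in nodes if n.quantifier == "exists"]
        set_nodes = [n for n in nodes if n.quantifier != "exists"]
        ents = scene.entities
        for combo in itertools.permutations(ents, len(exists_nodes)):
            assign = {n.id: e for n, e in zip(exists_nodes, combo)}
            if not all(prop_ok(assign[n.id], n) for n in exists_nodes):
                continue
            ok = True
            for e in target.edges:
                if e.src in assign and e.dst in assign:
                    if not rel_ok(assign[e.src], e.relation, assign[e.dst]):
                        ok = False
                        break
            if not ok:
                continue
            # set-quantified nodes against the full scene
            sat = True
            report = {}
            for n in set_nodes:
                cands = [x for x in ents if n.class_constraint is None or x.class_label == n.class_constraint]
                matched = []
                for x in cands:
                    if not all(
                        p.value is None or _entity_property(x, p.name) == p.value for p in n.properties
                    ):
                        continue
                    edge_ok = True
                    for e in target.edges:
                        if e.src == n.id and e.dst in assign:
                            edge_ok &= rel_ok(x, e.relation, assign[e.dst])
                        elif e.dst == n.id and e.src in assign:
                            edge_ok &= rel_ok(assign[e.src], e.relation, x)
                    if edge_ok:
                        matched.append(x)
                verdict = check_set_requirements(n, len(matched), len(cands))
                if n.quantifier == "how-many":
                    report[n.report] = verdict
                elif not verdict:
                    sat = False
                    break
            if sat:
                witness = {nid: e.id for nid, e in assign.items()}
                return True, witness
        if not exists_nodes:
            # purely set-quantified target
            sat = True
            for n in set_nodes:
                cands = [x for x in ents if n.class_constraint is None or x.class_label == n.class_constraint]
                matched = [
                    x for x in cands
                    if all(p.value is None or _entity_property(x, p.name) == p.value for p in n.properties)
                ]
                verdict = check_set_requirements(n, len(matched), len(cands))
                if n.quantifier not in ("how-many",) and not verdict:
                    sat = False
            if sat:
                return True, {}
    return False, None


# ------------------------------------------------------------------ full structure

def extract_full_structure(
    backend: PerceptionBackend,
    budget: int = 64,
    property_names: list[str] | None = None,
    relation_names: list[str] | None = None,
) -> ExtractedStructure:
    """Extract the complete scene structure: loop extract-next to exhaustion,
    elaborate every property of each component, validate every relation among
    pairs of extracted components."""
    props = property_names if property_names is not None else PROPERTY_NAMES
    rels = relation_names if relation_names is not None else ["facing", "holding", "touching", "left", "in-front"]
    result = ExtractedStructure(status="grounded")
    trace = result.instruction_trace
    comps = result.components
    acc = None
    n_exp = 0
    while True:
        n_exp += 1
        if n_exp > budget:
            result.partial = True
            result.failure_reason = "budget"
            break
        trace.append(TDInstruction(EXTRACT_NEXT, "mask", acc))
        got = backend.expand_next(acc)
        if got is None:
            break
        label, mask, _ = got
        comps.append(ComponentRecord(index=len(comps), class_label=label, mask=mask))
        acc = mask.copy() if acc is None else np.maximum(acc, mask)
    for c in comps:
        for p in props:
            trace.append(TDInstruction(p, "mask", c.mask))
            val = backend.elaborate_property(p, c.mask)
            if val is not None:
                c.properties[p] = val
    for a in comps:
        for b in comps:
            if a.index == b.index:
                continue
            for r in rels:
                trace.append(TDInstruction(r, "relation", (r, b.mask)))
                if backend.elaborate_relation(r, a.mask, b.mask):
                    a.relations.append((a.index, r, b.index))
    return result


# ------------------------------------------------------------------ demo scene and goal

def demo_goal_scene(seed: int = 0) -> Scene:
    """A small constructed scene for the goal-directed walkthrough: a woman
    facing a girl and holding a bag, plus two distractors (a man closer to the
    camera and a tree in the background)."""
    from .scene_synth import Entity, RelationParams, derive_relations, render_scene

    woman = Entity(0, "person", "woman", (4.0, 4.0), orientation=0.0,
                   properties={"outfit": 3, "hairstyle": 2, "sunglasses": False, "hat": False})
    girl = Entity(1, "person", "girl", (6.5, 4.0), orientation=180.0,
                  properties={"outfit": 5, "hairstyle": 1, "sunglasses": False, "hat": True})
    bag = Entity(2, "held-object", "bag", (4.35, 3.95), orientation=0.0,
                 size_class="large", color="red", attachment=("holding", 0))
    man = Entity(3, "person", "man", (1.5, 2.0), orientation=90.0,
                 properties={"outfit": 1, "hairstyle": 4, "sunglasses": True, "hat": False})
    tree = Entity(4, "scene-object", "tree", (8.5, 7.0), size_class="large", color="green")
    ents = [woman, girl, bag, man, tree]
    rels = derive_relations(ents, RelationParams())
    img, masks = render_scene(ents)
    return Scene(entities=ents, relations=rels, image=img, masks=masks, seed=seed)


def demo_goal_target() -> TargetStructure:
    """The matching goal: find what the woman facing the girl is holding, and
    report the held object's class and size."""
    return TargetStructure(
        nodes=[
            TargetNode("woman", "woman"),
            TargetNode("girl", "girl"),
            TargetNode("held", None, properties=[
                PropertyConstraint("class", report="held_class"),
                PropertyConstraint("size", report="held_size"),
            ]),
        ],
        edges=[TargetEdge("facing", "woman", "girl"), TargetEdge("holding", "woman", "held")],
        root="woman",
    )


# ------------------------------------------------------------------ training data for the neural backend

def make_extraction_training_set(scenes: list[Scene], class_names: list[str]):
    """Build (X, y, masks, occurrence, task_config) for training a guided
    model on the ``extract-next`` expansion task.

    For a scene whose entities in camera-depth order are e1..en, step k
    presents the union of the first k masks as the location argument and asks
    for the class and mask of e_{k+1}; the terminal step has an empty target
    mask and the answer ``none``."""
    from .model import TaskConfig

    names = list(class_names) + ["none"]
    h, w = scenes[0].image.shape[:2]
    X, y, mlist, occ = [], [], [], []
    for scene in scenes:
        img = scene.image.astype(np.float32).transpose(2, 0, 1) / 255.0
        ordered = sorted(scene.entities, key=depth_order_key)
        present = np.zeros(len(names), dtype=np.float32)
        for e in ordered:
            present[names.index(e.class_label)] = 1.0
        acc = np.zeros((h, w), dtype=np.float32)
        for e in ordered:
            X.append((img, TDInstruction(EXTRACT_NEXT, "mask", acc.copy())))
            y.append(names.index(e.class_label))
            m = (scene.masks[e.id] > 0).astype(np.float32)
            mlist.append(m)
            occ.append(present.copy())
            acc = np.maximum(acc, m)
        X.append((img, TDInstruction(EXTRACT_NEXT, "mask", acc.copy())))
        y.append(names.index("none"))
        mlist.append(np.zeros((h, w), dtype=np.float32))
        occ.append(present.copy())
    tc = TaskConfig(
        image_shape=(3, h, w),
        tasks=[EXTRACT_NEXT],
        answer_spaces={"entity-class": len(names)},
        task_to_space={EXTRACT_NEXT: "entity-class"},
        occurrence_classes=len(names),
        arg_vocab=1,
    )
    return X, np.asarray(y), np.stack(mlist), np.stack(occ), tc, names


# ------------------------------------------------------------------ random targets (testing/benchmark)

def sample_random_target(scene: Scene, rng: np.random.Generator, max_nodes: int = 3) -> TargetStructure:
    """Sample a small plausible target for a scene's vocabulary: random class
    constraints (half the time from classes actually present), chained
    relation edges, occasionally a set quantifier.  Used by the
    oracle-equivalence benchmark."""
    from .scene_synth import HELD_CLASSES, PERSON_CLASSES, SCENE_OBJECT_CLASSES

    all_classes = PERSON_CLASSES + SCENE_OBJECT_CLASSES + HELD_CLASSES
    present = [e.class_label for e in scene.entities] or all_classes
    n_nodes = int(rng.integers(1, max_nodes + 1))
    nodes = []
    for i in range(n_nodes):
        pool = present if rng.random() < 0.6 else all_classes
        cls = str(rng.choice(pool)) if rng.random() < 0.85 else None
        props = []
        if rng.random() < 0.3:
            props.append(PropertyConstraint("size", str(rng.choice(["small", "large"]))))
        quant = "exists"
        count = None
        report = None
        if i == n_nodes - 1 and rng.random() < 0.25:
            quant = str(rng.choice(["all", "count", "how-many"]))
            if quant == "count":
                count = int(rng.integers(0, 3))
            if quant == "how-many":
                report = f"n_{i}"
        nodes.append(TargetNode(id=f"n{i}", class_constraint=cls, properties=props,
                                quantifier=quant, count=count, report=report))
    edges = []
    rel_pool = ["left", "right", "in-front", "behind", "facing", "touching", "closest", "holding"]
    for i in range(1, n_nodes):
        if rng.random() < 0.7:
            edges.append(TargetEdge(str(rng.choice(rel_pool)), f"n{i - 1}", f"n{i}"))
    t = TargetStructure(nodes=nodes, edges=edges, root="n0")
    t.validate()
    return t


def sample_fully_visible_scene(spec: SceneSpec, seed: int, max_tries: int = 50) -> Scene:
    """Sample a scene in which every entity has a nonempty visible mask
    (a fully occluded entity is unknowable to any perception backend)."""
    for k in range(max_tries):
        scene = sample_scene(spec, seed=seed * max_tries + k)
        if all(m.sum() > 0 for m in scene.masks.values()):
            return scene
    raise RuntimeError("could not sample a fully visible scene")
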