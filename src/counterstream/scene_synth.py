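"""Synthetic 2.5-D sprite scenes with full ground-truth annotation.

Scenes are sampled graph-first: entities (persons with outfits, hairstyles,
optional sunglasses/hat, optionally holding or carrying an object; scene
objects of five classes), then placements in a ground plane seen from a fixed
camera, then relations derived geometrically, then a layered-sprite rendering
(painter's algorithm, back-to-front in camera depth z) that yields an RGB
image, disjoint per-entity visible-pixel masks and a combined label map.

Coordinates: scene positions are (x lateral, z camera depth), z > 0, smaller z
closer to the camera.  Rasters are row-major, origin top-left; "left" means
smaller x from the camera's viewpoint.  Depth ties are broken by smaller x,
then smaller id.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

log = logging.getLogger(__name__)

PERSON_CLASSES = ["woman", "man", "girl", "boy"]
SCENE_OBJECT_CLASSES = ["bench", "chair", "trashcan", "streetlight", "tree"]
HELD_CLASSES = ["bag", "hammer", "tennis racket", "signal", "sword"]
CARRIED_CLASSES = ["backpack", "shoulder bag"]
COLORS = ["red", "green", "blue", "yellow", "gray"]
SIZE_CLASSES = ["small", "large"]
N_OUTFITS = 8
N_HAIRSTYLES = 4

PREDICATES = [
    "left", "right", "in-front", "behind", "facing", "touching",
    "closest", "obstructing", "holding", "carrying", "on",
]

SCHEMA_ID = "counterstream-scene/1"
CAMERA_CONVENTION = "z>0 is depth from camera; smaller z is closer; ties by smaller x then id"

# footprint radii in scene units, used for touching/obstructing/facing geometry
FOOTPRINT_RADIUS = {
    "woman": 0.40, "man": 0.42, "girl": 0.32, "boy": 0.34,
    "bench": 0.90, "chair": 0.50, "trashcan": 0.35, "streetlight": 0.20, "tree": 0.60,
    "bag": 0.18, "hammer": 0.15, "tennis racket": 0.20, "signal": 0.15, "sword": 0.18,
    "backpack": 0.22, "shoulder bag": 0.20,
}

_RGB = {
    "red": (200, 60, 50), "green": (60, 160, 70), "blue": (60, 90, 200),
    "yellow": (210, 200, 60), "gray": (130, 130, 130),
}


class PlacementError(RuntimeError):
    """Raised when entities cannot be placed under the separation constraint."""


class SceneValidationError(ValueError):
    """Raised when a serialized scene violates the schema; names the field."""


@dataclass
class Entity:
    id: int
    kind: str  # person | scene-object | held-object | carried-object
    class_label: str
    position: tuple[float, float]  # (x, z)
    orientation: float = 0.0  # degrees in the x-z plane
    size_class: str | None = None
    color: str | None = None
    properties: dict = field(default_factory=dict)
    attachment: tuple[str, int] | None = None  # (relation, parent entity id)

    @property
    def footprint(self) -> float:
        r = FOOTPRINT_RADIUS.get(self.class_label, 0.3)
        if self.size_class == "large":
            r *= 1.4
        return r


@dataclass
class RelationTriple:
    subject_id: int
    predicate: str
    object_id: int

    def as_list(self):
        return [self.subject_id, self.predicate, self.object_id]


@dataclass
class RelationParams:
    facing_tol_deg: float = 25.0
    touch_frac: float = 0.05  # of scene width
    obstruct_dist: float = 2.0
    corridor_width: float = 0.8  # ~ person footprint width
    scene_width: float = 10.0


@dataclass
class SceneSpec:
    n_persons: int = 2
    n_objects: int = 1
    bounds: tuple[float, float] = (10.0, 10.0)  # (width, depth)
    image_size: tuple[int, int] = (48, 64)  # (H, W)
    p_held: float = 0.5
    p_carried: float = 0.25
    p_on: float = 0.25
    min_separation: float = 1.4
    # class vocabularies (restrictable for scaled-down training demos)
    person_classes: tuple = tuple(PERSON_CLASSES)
    object_classes: tuple = tuple(SCENE_OBJECT_CLASSES)

    def __post_init__(self):
        if self.n_persons < 0 or self.n_objects < 0:
            raise ValueError("n_persons and n_objects must be >= 0")
        if self.bounds[0] <= 0 or self.bounds[1] <= 0:
            raise ValueError("bounds must be positive")


@dataclass
class Scene:
    entities: list[Entity]
    relations: list[RelationTriple]
    image: np.ndarray  # (H, W, 3) uint8
    masks: dict[int, np.ndarray]  # entity id -> (H, W) uint8 {0, 255}
    camera: str = CAMERA_CONVENTION
    seed: int = 0

    def entity(self, eid: int) -> Entity:
        for e in self.entities:
            if e.id == eid:
                return e
        raise KeyError(eid)

    def has_relation(self, s: int, pred: int, o: int) -> bool:
        return any(r.subject_id == s and r.predicate == pred and r.object_id == o for r in self.relations)

    def label_map(self) -> np.ndarray:
        h, w, _ = self.image.shape
        lab = np.full((h, w), -1, dtype=np.int32)
        for eid, m in self.masks.items():
            lab[m > 0] = eid
        return lab


def depth_order_key(e: Entity):
    """Sort key for camera-depth order: closer first; ties by x then id."""
    return (e.position[1], e.position[0], e.id)


# --------------------------------------------------------------------------- sampling

def sample_scene(spec: SceneSpec, seed: int = 0) -> Scene:
    """Sample a scene graph (entities, properties, placements, attachments),
    derive relations, then render. Deterministic for a fixed seed."""
    rng = np.random.default_rng(seed)
    entities: list[Entity] = []
    next_id = 0
    width, depth = spec.bounds

    def place(radius: float) -> tuple[float, float]:
        for _ in range(200):
            x = float(rng.uniform(radius, width - radius))
            z = float(rng.uniform(1.0, depth))
            if all(
                math.hypot(x - e.position[0], z - e.position[1]) >= spec.min_separation
                for e in entities
                if e.attachment is None
            ):
                return (x, z)
        raise PlacementError(
            f"could not place an entity with min_separation={spec.min_separation} "
            f"in bounds {spec.bounds} after 200 attempts (scene too crowded)"
        )

    for _ in range(spec.n_persons):
        cls = str(rng.choice(list(spec.person_classes)))
        pos = place(FOOTPRINT_RADIUS[cls])
        person = Entity(
            id=next_id,
            kind="person",
            class_label=cls,
            position=pos,
            orientation=float(rng.uniform(0, 360)),
            properties={
                "outfit": int(rng.integers(1, N_OUTFITS + 1)),
                "hairstyle": int(rng.integers(1, N_HAIRSTYLES + 1)),
                "sunglasses": bool(rng.random() < 0.5),
                "hat": bool(rng.random() < 0.5),
            },
        )
        next_id += 1
        entities.append(person)
        if rng.random() < spec.p_held:
            cls_h = str(rng.choice(HELD_CLASSES))
            ang = math.radians(person.orientation)
            hx = min(max(pos[0] + 0.3 * math.cos(ang), 0.1), width - 0.1)
            hz = max(pos[1] + 0.3 * math.sin(ang), 0.5)
            entities.append(
                Entity(
                    id=next_id, kind="held-object", class_label=cls_h,
                    position=(hx, hz - 0.05), orientation=person.orientation,
                    size_class=str(rng.choice(SIZE_CLASSES)), color=str(rng.choice(COLORS)),
                    attachment=("holding", person.id),
                )
            )
            next_id += 1
        if rng.random() < spec.p_carried:
            cls_c = str(rng.choice(CARRIED_CLASSES))
            entities.append(
                Entity(
                    id=next_id, kind="carried-object", class_label=cls_c,
                    position=(pos[0], pos[1] + 0.15), orientation=person.orientation,
                    size_class="small", color=str(rng.choice(COLORS)),
                    attachment=("carrying", person.id),
                )
            )
            next_id += 1

    for _ in range(spec.n_objects):
        cls = str(rng.choice(list(spec.object_classes)))
        pos = place(FOOTPRINT_RADIUS[cls])
        obj = Entity(
            id=next_id, kind="scene-object", class_label=cls, position=pos,
            orientation=0.0, size_class=str(rng.choice(SIZE_CLASSES)),
            color=str(rng.choice(COLORS)),
        )
        next_id += 1
        entities.append(obj)
        if cls in ("bench", "chair", "trashcan") and rng.random() < spec.p_on:
            cls_o = str(rng.choice(HELD_CLASSES))
            entities.append(
                Entity(
                    id=next_id, kind="held-object", class_label=cls_o,
                    position=(pos[0] + 0.1, pos[1] - 0.05), orientation=0.0,
                    size_class="small", color=str(rng.choice(COLORS)),
                    attachment=("on", obj.id),
                )
            )
            next_id += 1

    params = RelationParams(scene_width=width)
    relations = derive_relations(entities, params)
    image, masks = render_scene(entities, spec.image_size, spec.bounds)
    return Scene(entities=entities, relations=relations, image=image, masks=masks, seed=seed)


# --------------------------------------------------------------------------- relations

def derive_relations(entities: list[Entity], params: RelationParams | None = None) -> list[RelationTriple]:
    """Derive all holding ground-truth relation triples from entity geometry."""
    params = params or RelationParams()
    rels: list[RelationTriple] = []
    if len(entities) < 2:
        return rels
    touch_thr = params.touch_frac * params.scene_width

    def dist(a: Entity, b: Entity) -> float:
        return math.hypot(a.position[0] - b.position[0], a.position[1] - b.position[1])

    for a in entities:
        for b in entities:
            if a.id == b.id:
                continue
            # lateral / depth order
            if a.position[0] < b.position[0]:
                rels.append(RelationTriple(a.id, "left", b.id))
            elif a.position[0] > b.position[0]:
                rels.append(RelationTriple(a.id, "right", b.id))
            if a.position[1] < b.position[1]:
                rels.append(RelationTriple(a.id, "in-front", b.id))
            elif a.position[1] > b.position[1]:
                rels.append(RelationTriple(a.id, "behind", b.id))
            # facing: orientation ray of a intersects b's footprint within tolerance
            if a.kind == "person":
                d = dist(a, b)
                if d > 1e-9:
                    ang_to = math.degrees(math.atan2(b.position[1] - a.position[1], b.position[0] - a.position[0]))
                    diff = abs((ang_to - a.orientation + 180) % 360 - 180)
                    allow = params.facing_tol_deg + math.degrees(math.atan2(b.footprint, d))
                    if diff <= allow:
                        rels.append(RelationTriple(a.id, "facing", b.id))
            # touching (attached pairs are in contact by construction)
            attached = (a.attachment is not None and a.attachment[1] == b.id) or (
                b.attachment is not None and b.attachment[1] == a.id
            )
            if attached or dist(a, b) - a.footprint - b.footprint < touch_thr:
                rels.append(RelationTriple(a.id, "touching", b.id))
            # obstructing: a inside the oriented path corridor of person b
            if b.kind == "person":
                ang = math.radians(b.orientation)
                dx = a.position[0] - b.position[0]
                dz = a.position[1] - b.position[1]
                t = dx * math.cos(ang) + dz * math.sin(ang)
                perp = abs(-dx * math.sin(ang) + dz * math.cos(ang))
                if 0 < t <= params.obstruct_dist and perp <= params.corridor_width / 2 + a.footprint:
                    rels.append(RelationTriple(a.id, "obstructing", b.id))
        # closest: unique minimum-distance partner (ties by smaller id)
        others = [b for b in entities if b.id != a.id]
        best = min(others, key=lambda b: (dist(a, b), b.id))
        rels.append(RelationTriple(a.id, "closest", best.id))
    # attachments
    for e in entities:
        if e.attachment is not None:
            rel, parent = e.attachment
            if rel in ("holding", "carrying"):
                rels.append(RelationTriple(parent, rel, e.id))
            elif rel == "on":
                rels.append(RelationTriple(e.id, "on", parent))
    return rels


# --------------------------------------------------------------------------- rendering

def _project(e: Entity, hw: tuple[int, int], bounds: tuple[float, float]):
    h, w = hw
    width, depth = bounds
    x, z = e.position
    col = int(round(x / width * (w - 1)))
    y_bottom = int(round((h - 2) - (z / depth) * (h * 0.30)))
    # sprite pixel scale: proportional to image height, shrinking with depth
    scale = (h / 48.0) * 2.2 / (1.2 + z / depth * 2.0)
    return col, y_bottom, scale


def _stamp(canvas, labels, eid, rows, cols, color):
    h, w = labels.shape
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    keep = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    if not keep.all():
        lvl = logging.WARNING if keep.mean() < 0.5 else logging.DEBUG
        log.log(lvl, "sprite for entity %d clipped at canvas border", eid)
    rows, cols = rows[keep], cols[keep]
    canvas[rows, cols] = color
    labels[rows, cols] = eid


def _rect(r0, r1, c0, c1):
    rr, cc = np.mgrid[r0:r1, c0:c1]
    return rr.ravel(), cc.ravel()


def _disk(rc, cc_, rad):
    rr, cc = np.mgrid[rc - rad : rc + rad + 1, cc_ - rad : cc_ + rad + 1]
    keep = (rr - rc) ** 2 + (cc - cc_) ** 2 <= rad * rad
    return rr[keep].ravel(), cc[keep].ravel()


_PERSON_BASE = {"woman": (200, 60, 50), "man": (60, 90, 200), "girl": (230, 140, 40), "boy": (50, 180, 190)}


def _draw_entity(e: Entity, canvas, labels, hw, bounds):
    col, yb, s = _project(e, hw, bounds)
    cl = e.class_label
    if e.kind == "person":
        bh = max(int(round(12 * s)), 6)  # body height in px
        bw = max(int(round(4 * s)), 2)
        base = np.array(_PERSON_BASE[cl], dtype=float)
        outfit = e.properties.get("outfit", 1)
        body = tuple(np.clip(base * (0.55 + 0.06 * outfit), 0, 255).astype(int))
        _stamp(canvas, labels, e.id, *_rect(yb - bh, yb, col - bw // 2, col + (bw + 1) // 2), body)
        rad = max(int(round(2 * s)), 1)
        head_r = yb - bh - rad
        _stamp(canvas, labels, e.id, *_disk(head_r, col, rad), (235, 200, 170))
        hs = e.properties.get("hairstyle", 1)
        _stamp(canvas, labels, e.id, *_rect(head_r - rad - 1, head_r - rad + hs // 2, col - rad, col + rad + 1), (70, 45, 25))
        if e.properties.get("sunglasses"):
            _stamp(canvas, labels, e.id, *_rect(head_r, head_r + 1, col - rad, col + rad + 1), (10, 10, 10))
        if e.properties.get("hat"):
            _stamp(canvas, labels, e.id, *_rect(head_r - rad - 3, head_r - rad - 1, col - rad - 1, col + rad + 2), (90, 30, 90))
    elif cl == "tree":
        th = max(int(round(14 * s)), 7)
        _stamp(canvas, labels, e.id, *_rect(yb - th // 3, yb, col - 1, col + 2), (100, 70, 40))
        _stamp(canvas, labels, e.id, *_disk(yb - th // 3 - th // 4, col, max(th // 3, 2)), (40, 130, 50))
    elif cl == "streetlight":
        th = max(int(round(15 * s)), 8)
        _stamp(canvas, labels, e.id, *_rect(yb - th, yb, col, col + 1), (90, 90, 90))
        _stamp(canvas, labels, e.id, *_disk(yb - th, col + 1, 1), (250, 240, 120))
    else:
        color = _RGB.get(e.color or "gray", (130, 130, 130))
        size_mult = 1.4 if e.size_class == "large" else 1.0
        dims = {"bench": (4, 12), "chair": (6, 5), "trashcan": (6, 4),
                "bag": (3, 3), "hammer": (4, 2), "tennis racket": (5, 2),
                "signal": (4, 2), "sword": (6, 1), "backpack": (4, 3), "shoulder bag": (3, 3)}
        dh, dw = dims.get(cl, (4, 4))
        dh = max(int(round(dh * s * size_mult)), 2)
        dw = max(int(round(dw * s * size_mult)), 1)
        _stamp(canvas, labels, e.id, *_rect(yb - dh, yb, col - dw // 2, col + (dw + 1) // 2), color)


def render_scene(
    entities: list[Entity],
    image_size: tuple[int, int] = (48, 64),
    bounds: tuple[float, float] = (10.0, 10.0),
) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Composite sprites back-to-front by camera depth (painter's algorithm).

    Returns the RGB image and disjoint per-entity visible-pixel masks."""
    h, w = image_size
    canvas = np.zeros((h, w, 3), dtype=np.uint8)
    labels = np.full((h, w), -1, dtype=np.int32)
    # draw farthest first so nearer entities overwrite (occlude) them
    for e in sorted(entities, key=depth_order_key, reverse=True):
        _draw_entity(e, canvas, labels, (h, w), bounds)
    masks = {e.id: ((labels == e.id) * 255).astype(np.uint8) for e in entities}
    return canvas, masks


# --------------------------------------------------------------------------- serialization

def scene_to_json(scene: Scene) -> dict:
    return {
        "schema": SCHEMA_ID,
        "seed": scene.seed,
        "camera": scene.camera,
        "entities": [
            {
                "id": e.id,
                "kind": e.kind,
                "class": e.class_label,
                "pos": list(e.position),
                "orient": e.orientation,
                "size": e.size_class,
                "color": e.color,
                "props": e.properties,
                "attachment": list(e.attachment) if e.attachment else None,
            }
            for e in scene.entities
        ],
        "relations": [r.as_list() for r in scene.relations],
    }


def validate_scene_json(obj: dict) -> None:
    """Check the documented scene schema, naming the offending field."""
    for key in ("schema", "seed", "entities", "relations"):
        if key not in obj:
            raise SceneValidationError(f"missing required field '{key}'")
    ids = set()
    for i, e in enumerate(obj["entities"]):
        for key in ("id", "kind", "class", "pos"):
            if key not in e:
                raise SceneValidationError(f"entities[{i}]: missing field '{key}'")
        if e["id"] in ids:
            raise SceneValidationError(f"entities[{i}].id: duplicate id {e['id']}")
        ids.add(e["id"])
        if e["kind"] == "person":
            props = e.get("props", {})
            if not (1 <= props.get("outfit", 1) <= N_OUTFITS):
                raise SceneValidationError(f"entities[{i}].props.outfit: out of range 1..{N_OUTFITS}")
            if not (1 <= props.get("hairstyle", 1) <= N_HAIRSTYLES):
                raise SceneValidationError(f"entities[{i}].props.hairstyle: out of range 1..{N_HAIRSTYLES}")
        x, z = e["pos"]
        if z <= 0:
            raise SceneValidationError(f"entities[{i}].pos: z must be > 0 (in front of camera)")
    for i, r in enumerate(obj["relations"]):
        if not (isinstance(r, (list, tuple)) and len(r) == 3):
            raise SceneValidationError(f"relations[{i}]: expected [subject, predicate, object]")
        s, p, o = r
        if p not in PREDICATES:
            raise SceneValidationError(f"relations[{i}].predicate: unknown predicate '{p}'")
        if s not in ids or o not in ids:
            raise SceneValidationError(f"relations[{i}]: references missing entity id")
        if s == o:
            raise SceneValidationError(f"relations[{i}]: subject equals object")


def scene_from_json(obj: dict, image=None, masks=None) -> Scene:
    validate_scene_json(obj)
    entities = [
        Entity(
            id=e["id"], kind=e["kind"], class_label=e["class"],
            position=tuple(e["pos"]), orientation=e.get("orient", 0.0),
            size_class=e.get("size"), color=e.get("color"),
            properties=e.get("props", {}),
            attachment=tuple(e["attachment"]) if e.get("attachment") else None,
        )
        for e in obj["entities"]
    ]
    relations = [RelationTriple(*r) for r in obj["relations"]]
    if image is None:
        image = np.zeros((1, 1, 3), dtype=np.uint8)
    return Scene(
        entities=entities, relations=relations, image=image,
        masks=masks or {}, camera=obj.get("camera", CAMERA_CONVENTION), seed=obj["seed"],
    )


def write_scene(scene: Scene, path: str | Path) -> Path:
    """Serialize graph to JSON, image and masks to PNG under a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    (path / "scene.json").write_text(json.dumps(scene_to_json(scene), indent=1))
    Image.fromarray(scene.image).save(path / "image.png")
    mask_dir = path / "masks"
    mask_dir.mkdir(exist_ok=True)
    for eid, m in scene.masks.items():
        Image.fromarray(m).save(mask_dir / f"entity_{eid}.png")
    lab = scene.label_map()
    Image.fromarray((lab + 1).astype(np.uint8)).save(path / "labelmap.png")
    return path


def read_scene(path: str | Path) -> Scene:
    path = Path(path)
    obj = json.loads((path / "scene.json").read_text())
    validate_scene_json(obj)
    image = np.asarray(Image.open(path / "image.png").convert("RGB"))
    masks = {}
    for f in sorted((path / "masks").glob("entity_*.png")):
        eid = int(f.stem.split("_")[1])
        masks[eid] = np.asarray(Image.open(f))
    return scene_from_json(obj, image=image, masks=masks)


def scenes_equal(a: Scene, b: Scene) -> bool:
    if scene_to_json(a) != scene_to_json(b):
        return False
    if not np.array_equal(a.image, b.image):
        return False
    if set(a.masks) != set(b.masks):
        return False
    return all(np.array_equal(a.masks[k], b.masks[k]) for k in a.masks)
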