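"""Combinatorial-generalization task families.

Two families are generated, each with an exclusion-pair train/test split:

* **Character grids** — each image is a single row of distinct glyphs; queries
  are ``<left-of, x>`` / ``<right-of, x>`` asking for the neighbour of glyph
  ``x``.  One ordered arrangement of all classes is the *excluded sequence*:
  its successive pairs never appear in training queries.  A neighbour query is
  never asked at the row boundary that has no neighbour.
* **Persons** — each image contains two persons with several visual property
  types; queries are ``<property-type, person>``.  A set of
  (person, property-value) pairs is excluded: no training image shows an
  excluded person with an excluded value.

The noncombinatorial (NC) test uses fresh images/queries that instantiate no
excluded pair; every combinatorial-generalization (CG) test example
instantiates at least one.

Glyphs are synthetic: fixed templates distorted per-instance by a seeded
elastic deformation, small rotation and thickness jitter (a stand-in for
handwritten character sets; a loader for user-supplied bitmaps offers the
same interface).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .instructions import TDInstruction
from .model import TaskConfig

# --------------------------------------------------------------------------- glyphs

_T = {
    "A": (".###.", "#...#", "#...#", "#####", "#...#", "#...#", "#...#"),
    "B": ("####.", "#...#", "#...#", "####.", "#...#", "#...#", "####."),
    "C": (".####", "#....", "#....", "#....", "#....", "#....", ".####"),
    "D": ("###..", "#..#.", "#...#", "#...#", "#...#", "#..#.", "###.."),
    "E": ("#####", "#....", "#....", "####.", "#....", "#....", "#####"),
    "F": ("#####", "#....", "#....", "####.", "#....", "#....", "#...."),
    "G": (".####", "#....", "#....", "#.###", "#...#", "#...#", ".###."),
    "H": ("#...#", "#...#", "#...#", "#####", "#...#", "#...#", "#...#"),
    "I": ("#####", "..#..", "..#..", "..#..", "..#..", "..#..", "#####"),
    "J": ("..###", "...#.", "...#.", "...#.", "...#.", "#..#.", ".##.."),
    "K": ("#...#", "#..#.", "#.#..", "##...", "#.#..", "#..#.", "#...#"),
    "L": ("#....", "#....", "#....", "#....", "#....", "#....", "#####"),
    "M": ("#...#", "##.##", "#.#.#", "#.#.#", "#...#", "#...#", "#...#"),
    "N": ("#...#", "##..#", "#.#.#", "#..##", "#...#", "#...#", "#...#"),
    "O": (".###.", "#...#", "#...#", "#...#", "#...#", "#...#", ".###."),
    "P": ("####.", "#...#", "#...#", "####.", "#....", "#....", "#...."),
    "Q": (".###.", "#...#", "#...#", "#...#", "#.#.#", "#..#.", ".##.#"),
    "R": ("####.", "#...#", "#...#", "####.", "#.#..", "#..#.", "#...#"),
    "S": (".####", "#....", "#....", ".###.", "....#", "....#", "####."),
    "T": ("#####", "..#..", "..#..", "..#..", "..#..", "..#..", "..#.."),
    "U": ("#...#", "#...#", "#...#", "#...#", "#...#", "#...#", ".###."),
    "V": ("#...#", "#...#", "#...#", "#...#", "#...#", ".#.#.", "..#.."),
    "W": ("#...#", "#...#", "#...#", "#.#.#", "#.#.#", "##.##", "#...#"),
    "X": ("#...#", "#...#", ".#.#.", "..#..", ".#.#.", "#...#", "#...#"),
    "Y": ("#...#", "#...#", ".#.#.", "..#..", "..#..", "..#..", "..#.."),
    "Z": ("#####", "....#", "...#.", "..#..", ".#...", "#....", "#####"),
    "4": ("...#.", "..##.", ".#.#.", "#..#.", "#####", "...#.", "...#."),
    "7": ("#####", "....#", "...#.", "...#.", "..#..", "..#..", "..#.."),
    "0": (".###.", "#..##", "#..##", "#.#.#", "##..#", "##..#", ".###."),
}
GLYPH_NAMES = list(_T)  # 29 classes
N_GLYPH_CLASSES = len(GLYPH_NAMES)

CELL_H, CELL_W = 12, 8  # glyph cell in pixels


def _template_cell(class_index: int) -> np.ndarray:
    """Base glyph rendered centered in a (CELL_H, CELL_W) cell."""
    rows = _T[GLYPH_NAMES[class_index]]
    g = np.array([[1.0 if ch == "#" else 0.0 for ch in r] for r in rows])
    cell = np.zeros((CELL_H, CELL_W))
    r0 = (CELL_H - g.shape[0]) // 2
    c0 = (CELL_W - g.shape[1]) // 2
    cell[r0 : r0 + g.shape[0], c0 : c0 + g.shape[1]] = g
    return cell


def synth_glyph(class_index: int, seed: int, amplitude: float = 0.5) -> np.ndarray:
    """One distorted glyph instance: seeded elastic deformation, rotation up
    to +/-15 degrees and thickness jitter.  ``amplitude=0`` returns the base
    template cell unchanged; class identity is preserved (see
    :func:`classify_glyph`)."""
    if not 0 <= class_index < N_GLYPH_CLASSES:
        raise ValueError(f"class_index {class_index} out of range 0..{N_GLYPH_CLASSES - 1}")
    base = _template_cell(class_index)
    if amplitude == 0:
        return base
    rng = np.random.default_rng(seed)
    angle = float(rng.uniform(-15, 15)) * amplitude
    img = ndimage.rotate(base, angle, reshape=False, order=1)
    # smooth random displacement field
    dx = ndimage.gaussian_filter(rng.standard_normal(base.shape), 1.5) * 1.6 * amplitude
    dy = ndimage.gaussian_filter(rng.standard_normal(base.shape), 1.5) * 1.6 * amplitude
    yy, xx = np.mgrid[0 : base.shape[0], 0 : base.shape[1]]
    img = ndimage.map_coordinates(img, [yy + dy, xx + dx], order=1, mode="constant")
    if rng.random() < 0.3 * amplitude:
        img = ndimage.grey_dilation(img, size=(2, 1))
    out = (img >= 0.5).astype(np.float64)
    # ink speckle: one isolated background pixel, so distinct seeds give
    # distinct bitmaps even when the geometric draw is small
    free = np.argwhere(~ndimage.binary_dilation(out > 0, iterations=2))
    if len(free):
        out[tuple(free[int(rng.integers(len(free)))])] = 1.0
    return out


_TEMPLATES_FLAT = None


def classify_glyph(bitmap: np.ndarray) -> int:
    """Frozen nearest-template correlation classifier (generation-time QC).

    Isolated single pixels (ink speckle) are removed and correlation is taken
    over +/-1-pixel shifts, so speckle and positional jitter do not count
    against class identity."""
    global _TEMPLATES_FLAT
    if _TEMPLATES_FLAT is None:
        t = np.stack([_template_cell(i).ravel() for i in range(N_GLYPH_CLASSES)])
        _TEMPLATES_FLAT = t / np.linalg.norm(t, axis=1, keepdims=True)
    b = np.asarray(bitmap) > 0
    neighbours = ndimage.convolve(b.astype(int), np.ones((3, 3), int), mode="constant") - b
    bitmap = np.where(b & (neighbours == 0), 0.0, b.astype(float))
    best, arg = -1.0, -1
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            v = np.roll(bitmap, (dy, dx), axis=(0, 1)).ravel()
            n = np.linalg.norm(v)
            if n == 0:
                continue
            scores = _TEMPLATES_FLAT @ (v / n)
            if scores.max() > best:
                best, arg = float(scores.max()), int(scores.argmax())
    return arg


class UserGlyphSource:
    """Optional hook: user-supplied glyph bitmaps (e.g. real handwritten
    characters) behind the synthetic-glyph interface.  ``bitmaps[c]`` is a
    list of binary arrays for class ``c``; they are resized to the cell."""

    def __init__(self, bitmaps: dict[int, list[np.ndarray]]):
        self.bitmaps = bitmaps

    def __call__(self, class_index: int, seed: int, amplitude: float = 1.0) -> np.ndarray:
        pool = self.bitmaps[class_index]
        pick = pool[seed % len(pool)]
        z = ndimage.zoom(pick.astype(float), (CELL_H / pick.shape[0], CELL_W / pick.shape[1]), order=1)
        return (z >= 0.5).astype(np.float64)


# --------------------------------------------------------------------------- split types

@dataclass
class ExclusionSet:
    kind: str  # "person-property" | "successive-pair"
    pairs: frozenset


@dataclass
class TaskExample:
    image_ref: int
    i_task: str
    i_arg: int
    label: int
    contains_excluded: bool


@dataclass
class CGSplit:
    train: list[TaskExample]
    test_nc: list[TaskExample]
    test_cg: list[TaskExample]
    exclusion: ExclusionSet
    images: list = field(default_factory=list)  # per-image ground-truth specs
    family: str = "chargrid"
    params: dict = field(default_factory=dict)


# --------------------------------------------------------------------------- chargrid

def _chargrid_queries(arrangement: list[int]):
    """All legal (task, arg, label, pair) queries of a row arrangement.

    The pair is the ordered adjacency (left char, right char) the query
    instantiates.  No right-of at row end, no left-of at row start."""
    out = []
    m = len(arrangement)
    for pos, ch in enumerate(arrangement):
        if pos + 1 < m:
            out.append(("right-of", ch, arrangement[pos + 1], (ch, arrangement[pos + 1])))
        if pos > 0:
            out.append(("left-of", ch, arrangement[pos - 1], (arrangement[pos - 1], ch)))
    return out


def make_chargrid_dataset(
    n_images: int,
    n_classes: int = 24,
    chars_per_image: int | None = None,
    examples_per_image: int = 16,
    excluded_sequence: list[int] | None = None,
    seed: int = 0,
    n_test_nc: int = 2000,
    n_test_cg: int = 2000,
    extra_excluded_pairs: int = 0,
) -> CGSplit:
    """Generate a character-grid CG split.

    Every training query avoids the successive pairs of ``excluded_sequence``
    (one ordered arrangement of the class subset); every CG test query
    instantiates one.  Images are stored as arrangements (class-index rows)
    and rendered lazily by :func:`render_chargrid_image`.
    """
    if n_classes > N_GLYPH_CLASSES:
        raise ValueError(f"at most {N_GLYPH_CLASSES} glyph classes available")
    chars_per_image = chars_per_image or n_classes
    if chars_per_image > n_classes:
        raise ValueError("chars_per_image cannot exceed n_classes")
    rng = np.random.default_rng(seed)
    if excluded_sequence is None:
        excluded_sequence = list(rng.permutation(n_classes))
    excluded_sequence = [int(c) for c in excluded_sequence]
    if sorted(excluded_sequence) != list(range(n_classes)):
        raise ValueError("excluded_sequence must be a permutation of the class subset")
    excl_pairs = set(zip(excluded_sequence[:-1], excluded_sequence[1:]))
    # optional stress mode: enlarge the excluded fraction with random ordered pairs
    guard = 0
    while len(excl_pairs) < (n_classes - 1) + extra_excluded_pairs:
        guard += 1
        if guard > 100000:
            raise RuntimeError("cannot sample that many extra excluded pairs")
        a, b = rng.integers(n_classes, size=2)
        if a != b:
            excl_pairs.add((int(a), int(b)))
    excl_pairs = frozenset(excl_pairs)
    exclusion = ExclusionSet(kind="successive-pair", pairs=excl_pairs)

    images: list[list[int]] = []

    def sample_arrangement():
        chars = rng.choice(n_classes, size=chars_per_image, replace=False)
        return [int(c) for c in chars]

    train: list[TaskExample] = []
    for _ in range(n_images):
        for _attempt in range(100):
            arr = sample_arrangement()
            qs = [q for q in _chargrid_queries(arr) if q[3] not in excl_pairs]
            if len(qs) >= examples_per_image:
                break
        else:
            raise RuntimeError("could not sample an image with enough non-excluded queries")
        img_idx = len(images)
        images.append(arr)
        picks = rng.choice(len(qs), size=examples_per_image, replace=False)
        for k in picks:
            task, arg, label, _pair = qs[k]
            train.append(TaskExample(img_idx, task, arg, label, False))

    test_nc: list[TaskExample] = []
    while len(test_nc) < n_test_nc:
        arr = sample_arrangement()
        qs = [q for q in _chargrid_queries(arr) if q[3] not in excl_pairs]
        if not qs:
            continue
        img_idx = len(images)
        images.append(arr)
        task, arg, label, _pair = qs[int(rng.integers(len(qs)))]
        test_nc.append(TaskExample(img_idx, task, arg, label, False))

    test_cg: list[TaskExample] = []
    excl_list = sorted(excl_pairs)
    while len(test_cg) < n_test_cg:
        a, b = excl_list[int(rng.integers(len(excl_list)))]
        others = [c for c in range(n_classes) if c not in (a, b)]
        rest = [int(c) for c in rng.choice(others, size=chars_per_image - 2, replace=False)]
        pos = int(rng.integers(chars_per_image - 1))
        arr = rest[:pos] + [a, b] + rest[pos:]
        qs = [q for q in _chargrid_queries(arr) if q[3] in excl_pairs]
        img_idx = len(images)
        images.append(arr)
        task, arg, label, _pair = qs[int(rng.integers(len(qs)))]
        test_cg.append(TaskExample(img_idx, task, arg, label, True))

    return CGSplit(
        train=train, test_nc=test_nc, test_cg=test_cg, exclusion=exclusion,
        images=images, family="chargrid",
        params={
            "n_classes": n_classes, "chars_per_image": chars_per_image,
            "examples_per_image": examples_per_image, "seed": seed,
            "excluded_sequence": excluded_sequence,
        },
    )


def render_chargrid_image(arrangement: list[int], seed: int, amplitude: float = 0.5) -> np.ndarray:
    """Render a row arrangement to a (1, CELL_H, CELL_W * m) float image."""
    cells = [synth_glyph(c, seed * 1009 + i, amplitude) for i, c in enumerate(arrangement)]
    return np.concatenate(cells, axis=1)[None]


def chargrid_task_config(split: CGSplit) -> TaskConfig:
    n_classes = split.params["n_classes"]
    m = split.params["chars_per_image"]
    return TaskConfig(
        image_shape=(1, CELL_H, CELL_W * m),
        tasks=["left-of", "right-of"],
        answer_spaces={"char": n_classes},
        task_to_space={"left-of": "char", "right-of": "char"},
        occurrence_classes=n_classes,
        arg_vocab=n_classes,
    )


# --------------------------------------------------------------------------- persons

DEFAULT_PROPERTY_SPEC = {
    "appearance": 4,
    "hairstyle": 4,
    "glasses": 3,
    "outfit": 4,
    "hat": 2,
}

PERSON_TILE_H, PERSON_TILE_W = 16, 16

# a fixed palette; property value v of band b gets a distinct color
_PALETTE = np.array(
    [
        [220, 60, 60], [60, 180, 75], [65, 90, 220], [240, 200, 50],
        [145, 60, 190], [70, 210, 210], [230, 120, 40], [150, 150, 150],
        [120, 70, 20], [240, 120, 190], [30, 100, 60], [100, 100, 240],
    ],
    dtype=float,
) / 255.0


def sample_exclusions(n_pairs: int, n_person_identities: int, property_spec: dict, rng) -> frozenset:
    """Sample (person, property-type, value) exclusion triples, never
    exhausting a person's options for any property type."""
    names = list(property_spec)
    out = set()
    guard = 0
    while len(out) < n_pairs:
        guard += 1
        if guard > 10000:
            raise RuntimeError("could not sample exclusions without exhausting options")
        p = int(rng.integers(n_person_identities))
        t = names[int(rng.integers(len(names)))]
        v = int(rng.integers(property_spec[t]))
        cand = (p, t, v)
        if cand in out:
            continue
        used = sum(1 for (pp, tt, _vv) in out | {cand} if pp == p and tt == t)
        if used >= property_spec[t]:  # would exhaust person p's options for t
            continue
        out.add(cand)
    return frozenset(out)


@dataclass
class PersonsImageSpec:
    identities: tuple[int, int]  # (left slot, right slot)
    properties: tuple[dict, dict]


def make_persons_dataset(
    n_images: int,
    n_person_identities: int = 8,
    property_spec: dict | None = None,
    excluded_pairs=None,
    seed: int = 0,
    n_test_nc: int = 400,
    n_test_cg: int = 400,
) -> CGSplit:
    """Generate the two-person property-query CG split.

    ``excluded_pairs`` is a collection of (person, property-type, value)
    triples, or an int asking to sample that many.  No training image contains
    an excluded person/value co-occurrence; each CG test example queries one.
    """
    property_spec = dict(property_spec or DEFAULT_PROPERTY_SPEC)
    rng = np.random.default_rng(seed)
    if excluded_pairs is None:
        excluded_pairs = 6
    if isinstance(excluded_pairs, int):
        excluded_pairs = sample_exclusions(excluded_pairs, n_person_identities, property_spec, rng)
    excluded_pairs = frozenset(tuple(p) for p in excluded_pairs)
    for p, t, v in excluded_pairs:
        if t not in property_spec or not (0 <= v < property_spec[t]):
            raise ValueError(f"excluded pair ({p}, {t}, {v}) outside the property space")
        n_excl = sum(1 for (pp, tt, _vv) in excluded_pairs if pp == p and tt == t)
        if n_excl >= property_spec[t]:
            raise ValueError(f"excluded pairs exhaust person {p}'s options for property {t!r}")
    exclusion = ExclusionSet(kind="person-property", pairs=excluded_pairs)
    names = list(property_spec)

    def sample_props(identity: int, avoid_excluded: bool) -> dict:
        props = {}
        for t in names:
            vals = list(range(property_spec[t]))
            if avoid_excluded:
                vals = [v for v in vals if (identity, t, v) not in excluded_pairs]
            props[t] = int(rng.choice(vals))
        return props

    def sample_image(avoid_excluded: bool) -> PersonsImageSpec:
        ids = rng.choice(n_person_identities, size=2, replace=False)
        ids = (int(ids[0]), int(ids[1]))
        return PersonsImageSpec(ids, (sample_props(ids[0], avoid_excluded), sample_props(ids[1], avoid_excluded)))

    images: list[PersonsImageSpec] = []
    train: list[TaskExample] = []
    for _ in range(n_images):
        spec = sample_image(avoid_excluded=True)
        img_idx = len(images)
        images.append(spec)
        for slot in (0, 1):
            for t in names:
                train.append(
                    TaskExample(img_idx, t, spec.identities[slot], spec.properties[slot][t], False)
                )

    test_nc: list[TaskExample] = []
    while len(test_nc) < n_test_nc:
        spec = sample_image(avoid_excluded=True)
        img_idx = len(images)
        images.append(spec)
        slot = int(rng.integers(2))
        t = names[int(rng.integers(len(names)))]
        test_nc.append(TaskExample(img_idx, t, spec.identities[slot], spec.properties[slot][t], False))

    test_cg: list[TaskExample] = []
    excl_list = sorted(excluded_pairs)
    if not excl_list:
        warnings.warn("empty exclusion set: the CG test set is empty", stacklevel=2)
    while excl_list and len(test_cg) < n_test_cg:
        p, t, v = excl_list[int(rng.integers(len(excl_list)))]
        other = int(rng.choice([i for i in range(n_person_identities) if i != p]))
        slot = int(rng.integers(2))
        ids = (p, other) if slot == 0 else (other, p)
        props = [sample_props(ids[0], avoid_excluded=False), sample_props(ids[1], avoid_excluded=False)]
        props[slot][t] = v
        spec = PersonsImageSpec(ids, (props[0], props[1]))
        img_idx = len(images)
        images.append(spec)
        test_cg.append(TaskExample(img_idx, t, p, v, True))

    return CGSplit(
        train=train, test_nc=test_nc, test_cg=test_cg, exclusion=exclusion,
        images=images, family="persons",
        params={
            "n_person_identities": n_person_identities,
            "property_spec": property_spec,
            "seed": seed,
        },
    )


def render_persons_image(spec: PersonsImageSpec, property_spec: dict) -> np.ndarray:
    """Render a two-person image to (3, PERSON_TILE_H, 2*PERSON_TILE_W).

    Each person is a tile of horizontal bands: an identity band plus one band
    per property type; band colors encode the values (visually separable —
    the experiment measures composition, not fine recognition)."""
    names = list(property_spec)
    h, w = PERSON_TILE_H, PERSON_TILE_W
    img = np.zeros((3, h, 2 * w))
    n_bands = 1 + len(names)
    band_h = h // n_bands
    for slot in (0, 1):
        c0 = slot * w
        ident = spec.identities[slot]
        img[:, 0:band_h, c0 + 2 : c0 + w - 2] = _PALETTE[ident][:, None, None]
        for bi, t in enumerate(names, start=1):
            v = spec.properties[slot][t]
            r0 = bi * band_h
            # offset rows per band so bands are positionally and chromatically distinct
            img[:, r0 : r0 + band_h - 1, c0 + 2 : c0 + w - 2] = _PALETTE[(v + 2 * bi) % len(_PALETTE)][:, None, None]
    return img


def persons_task_config(split: CGSplit) -> TaskConfig:
    spec = split.params["property_spec"]
    return TaskConfig(
        image_shape=(3, PERSON_TILE_H, 2 * PERSON_TILE_W),
        tasks=list(spec),
        answer_spaces={t: n for t, n in spec.items()},
        task_to_space={t: t for t in spec},
        occurrence_classes=split.params["n_person_identities"],
        arg_vocab=split.params["n_person_identities"],
    )


# --------------------------------------------------------------------------- encoding for the model

def encode_chargrid(split: CGSplit, examples: list[TaskExample], amplitude: float = 0.5):
    """Materialize (X, y, masks, occurrence) for the estimator."""
    n_classes = split.params["n_classes"]
    m = split.params["chars_per_image"]
    seed = split.params["seed"]
    cache: dict[int, np.ndarray] = {}
    X, y = [], []
    masks = np.zeros((len(examples), CELL_H, CELL_W * m), dtype=np.float32)
    occ = np.zeros((len(examples), n_classes), dtype=np.float32)
    for i, ex in enumerate(examples):
        if ex.image_ref not in cache:
            cache[ex.image_ref] = render_chargrid_image(split.images[ex.image_ref], seed * 100003 + ex.image_ref, amplitude)
        img = cache[ex.image_ref]
        arr = split.images[ex.image_ref]
        X.append((img, TDInstruction(ex.i_task, "class", ex.i_arg)))
        y.append(ex.label)
        pos = arr.index(ex.i_arg)  # position of the reference char
        tgt = pos + 1 if ex.i_task == "right-of" else pos - 1
        masks[i, :, tgt * CELL_W : (tgt + 1) * CELL_W] = 1.0
        occ[i, arr] = 1.0
    return X, np.asarray(y), masks, occ


def encode_persons(split: CGSplit, examples: list[TaskExample]):
    spec = split.params["property_spec"]
    n_ids = split.params["n_person_identities"]
    cache: dict[int, np.ndarray] = {}
    X, y = [], []
    h, w = PERSON_TILE_H, PERSON_TILE_W
    masks = np.zeros((len(examples), h, 2 * w), dtype=np.float32)
    occ = np.zeros((len(examples), n_ids), dtype=np.float32)
    for i, ex in enumerate(examples):
        if ex.image_ref not in cache:
            cache[ex.image_ref] = render_persons_image(split.images[ex.image_ref], spec)
        ispec = split.images[ex.image_ref]
        X.append((cache[ex.image_ref], TDInstruction(ex.i_task, "class", ex.i_arg)))
        y.append(ex.label)
        slot = 0 if ispec.identities[0] == ex.i_arg else 1
        masks[i, :, slot * w : (slot + 1) * w] = 1.0
        occ[i, list(ispec.identities)] = 1.0
    return X, np.asarray(y), masks, occ


# --------------------------------------------------------------------------- validation

def _example_instantiates_excluded(split: CGSplit, ex: TaskExample) -> bool:
    if split.family == "chargrid":
        arr = split.images[ex.image_ref]
        pos = arr.index(ex.i_arg)
        if ex.i_task == "right-of":
            pair = (ex.i_arg, arr[pos + 1])
        else:
            pair = (arr[pos - 1], ex.i_arg)
        return pair in split.exclusion.pairs
    spec = split.images[ex.image_ref]
    slot = 0 if spec.identities[0] == ex.i_arg else 1
    return (ex.i_arg, ex.i_task, spec.properties[slot][ex.i_task]) in split.exclusion.pairs


def validate_split(split: CGSplit) -> dict:
    """Exhaustively re-check the CG-split invariants.

    Returns a report with per-subset counts, counts per excluded pair, and the
    ids of any offending examples."""
    violations = []
    per_pair: dict = {p: 0 for p in split.exclusion.pairs}
    for name, subset, want_excluded in (
        ("train", split.train, False),
        ("test_nc", split.test_nc, False),
        ("test_cg", split.test_cg, True),
    ):
        for i, ex in enumerate(subset):
            inst = _example_instantiates_excluded(split, ex)
            if ex.contains_excluded != inst:
                violations.append((name, i, "contains_excluded flag inconsistent with image"))
            if inst != want_excluded:
                violations.append((name, i, f"{'unexpected' if inst else 'missing'} excluded pair"))
            if name == "train":
                # label consistency with ground truth
                if split.family == "chargrid":
                    arr = split.images[ex.image_ref]
                    pos = arr.index(ex.i_arg)
                    truth = arr[pos + 1] if ex.i_task == "right-of" else arr[pos - 1]
                else:
                    spec = split.images[ex.image_ref]
                    slot = 0 if spec.identities[0] == ex.i_arg else 1
                    truth = spec.properties[slot][ex.i_task]
                if truth != ex.label:
                    violations.append((name, i, "label inconsistent with image ground truth"))
    for ex in split.test_cg:
        if split.family == "chargrid":
            arr = split.images[ex.image_ref]
            pos = arr.index(ex.i_arg)
            pair = (ex.i_arg, arr[pos + 1]) if ex.i_task == "right-of" else (arr[pos - 1], ex.i_arg)
            if pair in per_pair:
                per_pair[pair] += 1
        else:
            key = (ex.i_arg, ex.i_task, ex.label)
            if key in per_pair:
                per_pair[key] += 1
    return {
        "ok": not violations,
        "counts": {"train": len(split.train), "test_nc": len(split.test_nc), "test_cg": len(split.test_cg)},
        "per_excluded_pair": per_pair,
        "violations": violations,
    }
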