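# File formats

## Scene directory

Written by `write_scene` / `counterstream synth`, read back by `read_scene`:

```
scene_0000/
  scene.json      # the scene graph (schema below)
  image.png       # H x W RGB render
  labelmap.png    # combined label map: entity id + 1, 0 = background
  masks/entity_<id>.png   # one 8-bit PNG per entity, 0 background / 255 foreground
```

`scene.json` schema (`counterstream-scene/1`):

```json
{
  "schema": "counterstream-scene/1",
  "seed": 3,
  "camera": "z>0 is depth from camera; smaller z is closer; ties by smaller x then id",
  "entities": [
    {
      "id": 0,
      "kind": "person",            // person | scene-object | held-object | carried-object
      "class": "woman",
      "pos": [4.0, 4.0],           // (x lateral, z camera depth), z > 0
      "orient": 0.0,               // facing angle, degrees, in the x-z plane
      "size": null,                // "small" | "large" for objects
      "color": null,
      "props": {"outfit": 3, "hairstyle": 2, "sunglasses": false, "hat": false},
      "attachment": null           // ["holding"|"carrying"|"on", parent entity id]
    }
  ],
  "relations": [[0, "facing", 1]]  // [subject id, predicate, object id]
}
```

Validation (`validate_scene_json`) rejects unknown predicates, duplicate or
dangling entity ids, self-relations, person properties outside their stated
cardinalities (outfit 1–8, hairstyle 1–4) and non-positive depth, naming the
offending field.

## Target structure (goal) DSL

Read by `load_target` / `counterstream ground --target`:

```json
{
  "root": "woman",
  "nodes": [
    {"id": "woman", "class": "woman"},
    {"id": "girl",  "class": "girl"},
    {"id": "held",
     "properties": [
       {"name": "class", "report": "held_class"},   // report slot
       {"name": "size",  "value": "large"}          // hard constraint
     ]},
    {"id": "girls", "class": "girl", "quantifier": "how-many", "report": "n_girls"}
  ],
  "edges": [
    {"relation": "facing",  "src": "woman", "dst": "girl"},
    {"relation": "holding", "src": "woman", "dst": "held"}
  ],
  "connective": {"op": "and", "args": ["woman", {"op": "or", "args": ["girl", "held"]}]}
}
```

* `quantifier`: `"exists"` (default), `"all"`, `{"count": n}`, `"how-many"`
  (requires a `report` slot name).
* `properties[].name` ∈ {class, outfit, hairstyle, sunglasses, hat, size,
  color}; give either `value` (constraint) or `report` (slot to fill).
* Edges between two set-quantified nodes are rejected.
* `connective` is an optional and/or tree over node ids; without it, all
  nodes must be grounded.

## Task examples (JSONL)

`counterstream make-task` writes `train.jsonl`, `test_nc.jsonl`,
`test_cg.jsonl`, one example per line:

```json
{"image_ref": 17, "i_task": "right-of", "i_arg": 3, "label": 5, "contains_excluded": false}
```

`image_ref` indexes the split's image specs (chargrid: the row arrangement of
class indices; persons: the two identities and their property values), from
which images are rendered deterministically.

## Checkpoints

`save_checkpoint(clf, path)` writes `path.npz` (all parameter arrays) plus
`path.json` (estimator hyperparameters, the task config, and optional class
name / property value tables). `load_checkpoint(path)` restores a fitted
estimator.

## Run manifest

Every CLI command writes `manifest.json` into its output directory: the
command, its full config snapshot, seeds, package and numpy versions, a
timestamp, output paths and SHA-256 checksums of file inputs. Identical
manifests in deterministic mode reproduce identical outputs.
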