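# Methods

## The model

The core of the package is a *counterstream* pair of convolutional streams: a
bottom-up (BU) stream that maps an image to a top-level representation
`L^T`, and a top-down (TD) stream of mirrored structure that maps a learned
embedding of a *TD instruction* — a task selector `I_task` and an argument
`I_arg` — back down to image resolution. One inference cycle unfolds as
BU1 → TD → BU2:

1. **BU1** computes layer activations `a1, a2, a3` from the image and an
   occurrence prediction (which classes appear anywhere in the image) from
   `L^T = a3`.
2. **TD** receives `L^T` combined with the embedded instruction
   `(E_task, E_arg)` and propagates down through mirrored layers with
   bottom-up lateral inputs (1×1 projections of `a1, a2`), emitting a
   segmentation map of the instructed component at its bottom.
3. **BU2** re-runs the *same* convolution stack (BU1 and BU2 share every
   parameter — the recurrent network unfolded in time) on the image gated by
   the TD output: the input is multiplied by a sigmoid of the TD segmentation
   plus a learned projection of the lowest TD layer, and each BU2 layer is
   multiplied by a single-channel sigmoid gate computed from the
   corresponding TD layer. The answer to the instructed task is read from the
   top of BU2.

Instruction arguments come in three modes, mirroring the ways attention can
be allocated: a **location mask** (downsampled and injected at the TD input),
a **class index** (an embedding lookup), or a **relation to a reference
component** (a relation embedding plus the reference's mask). Compound
instructions are multi-hot task vectors; their embedding is the sum of the
single-task embeddings, so a model trained on single tasks can be queried
with several at once.

### Conditioning and gating choices

The exact form of the cross-stream connections was an open design point; the
package uses, at the TD input, (a) feature-wise affine modulation (FiLM) of
the `L^T` lateral by the instruction embedding — the multiplicative
interaction that lets channel sums act as a feature-matching map — and (b)
the embedding broadcast as extra channels, followed by two 3×3 convolutions.
The TD→BU2 gates are deliberately **single-channel (purely spatial)**: guidance
acts by selecting image regions, not by rewriting feature semantics, which is
both closer to a spatial-attention reading and empirically what makes the
answer head generalize — a multi-channel gate gives the head a side channel
to memorize instruction identity. Wiring the TD bottom (segmentation) output
directly into the BU2 input gate is what ties the supervised segmentation to
the selection the next pass actually uses; without it the segmentation can be
correct while the answer head still memorizes instruction→answer pairs.

### Losses

Three losses are available (weights configurable, default 1:1:1): a
multi-label occurrence cross-entropy at the top of BU1, a per-pixel binary
cross-entropy at the bottom of TD against the instructed component's mask
(with a positive-class weight, default 8, because target masks are sparse),
and the task cross-entropy at the top of BU2. The unguided baseline's TD
stream receives no instruction, so no instruction-dependent segmentation
target exists for it; it trains with the occurrence and task losses only.

### Baselines

*Unguided (readout selection)*: identical backbone, but the TD stream gets a
fixed learned input; the instruction embedding is concatenated only with the
top of BU2 and passed through a one-hidden-layer ReLU readout (late
selection). *BU-channel*: the instruction is embedded on a coarse grid,
upsampled to an image-sized plane and appended to the input as an extra
channel; the TD stream again gets a fixed input (guidance, but bottom-up).

## The grounding engine

A *target structure* is a goal graph: nodes with optional class and property
constraints (a property slot may instead be a report slot), quantifiers
(`exists`, `all`, `count(n)`, `how-many`), relation edges, and an optional
and/or connective tree. Grounding proceeds one node at a time in depth-first
order (root first; set-quantified nodes after all existential nodes),
issuing TD instructions to a perception backend: `extract-next` returns
not-yet-seen components in order of camera distance; a relation expansion
returns components standing in a given relation to an already-grounded
reference (passed as a mask); elaboration instructions read properties and
verify relations. Candidates failing a constraint are rejected with
chronological backtracking (most recent choice undone first); relation
expansion is a fast path and the engine falls back to `extract-next`
enumeration, so the search is exhaustive up to the expansion budget.
Quantifier semantics: `all` is scoped to components matching the node's class
constraint and is vacuously true over an empty set; `count(n)` means exactly
`n` matches; `how-many` always succeeds and writes the count into the report.
Existential nodes bind injectively. Edges between two set-quantified nodes
are rejected at validation. Connective trees are expanded into their minimal
node subsets, tried in deterministic order.

`brute_force_ground` is an independent exhaustive matcher over the
ground-truth scene graph (guarded to ≤ 8 entities, ≤ 5 nodes) used to verify
the engine; the two agree on satisfiability on every tested random instance.

### Backends

The **oracle backend** simulates perfectly trained expansion/elaboration
networks from ground truth: reference masks are resolved by IoU ≥ 0.5 against
entity masks, `extract-next` follows the depth order (ties: smaller x, then
smaller id), and optional noise rates flip answers. The **neural backend**
maps the same calls onto a trained guided model: segmentation logits are
thresholded at 0.5, the answer head supplies classes/properties, a predicted
`none` class or empty mask terminates extraction, and relation verification
reuses the expansion pathway (retrieve components related to the reference,
match by IoU).

## Synthetic data

### Scenes

Scenes are sampled graph-first — persons (4 classes; outfit 1–8, hairstyle
1–4, optional sunglasses and hat; optionally holding one of 5 object classes
or carrying one of 2) and scene objects (5 classes, small/large, colored) are
placed on a ground plane with a minimum-separation constraint — then
relations are derived geometrically, then the scene is rendered as layered
2.5-D sprites composited back-to-front in camera depth (painter's algorithm),
yielding an RGB image and **disjoint visible-pixel masks**. Relations: `left`
/`right` from lateral order, `in-front`/`behind` from depth order, `facing`
when the subject's orientation ray passes within ±25° of the object (plus the
object's angular footprint), `touching` when footprint gap < 0.05 × scene
width (attached pairs touch by construction), `closest` as the unique
nearest partner (ties by smaller id), `obstructing` when an entity lies in a
person's oriented path corridor (length 2 scene units, width 0.8 + the
blocker's footprint), and `holding`/`carrying`/`on` from attachments. The
facing tolerance, touching threshold and corridor are config keys; no source
values exist for them, so the defaults above are package choices.

What the sprites do **not** emulate: articulated pose, lighting, texture,
perspective foreshortening beyond a depth-dependent scale, and amodal extent
(a fully occluded entity has an empty mask and is unknowable to any
perception; scene-consuming tests sample scenes with all masks nonempty).

### Character grids

Each image is one row of distinct glyph cells (12×8 px per glyph). Glyphs are
synthetic: 29 fixed 5×7 templates distorted per instance by seeded elastic
deformation, rotation up to ±15° (scaled by an amplitude parameter, default
0.5), occasional thickness dilation, and one pixel of positional jitter. At
the default amplitude a frozen shift-tolerant template-correlation check
classifies ≥ 99% of instances correctly, so class identity is preserved while
bitmaps vary. A loader for user-supplied glyph bitmaps offers the same
interface. Queries are `<left-of, x>` / `<right-of, x>`; the training split
excludes all successive pairs of one ordered arrangement of the classes
(query-level exclusion), never queries a missing neighbour at row ends, and
the CG test queries only excluded adjacencies.

### Persons

Each image contains two persons drawn as tiles of horizontal bands: an
identity band plus one band per property type (defaults: appearance 4,
hairstyle 4, glasses 3, outfit 4, hat 2 — five types, so 1,600 images × 2
persons × 5 properties = 16,000 training examples at the published size).
Band colors encode values; values are visually separable by design because
the experiment measures composition, not fine-grained recognition. Exclusion
is image-level: no training image shows an excluded (person, property-value)
pair; every CG test example queries one.

## The combinatorial-generalization protocol

Per fold, a fresh dataset with a freshly sampled exclusion set is generated;
the model trains until a convergence criterion (improvement of the monitored
NC accuracy < 1 point over a trailing window) or an epoch cap; NC and CG
accuracies are logged per epoch; summaries are rolling-window means per fold
with cross-fold mean and SD. Variants being compared consume identical
datasets, fold seeds and hyperparameter candidates; the hyperparameter grid
is optimizer {SGD+momentum, Adam} × learning rate {0.0001, 0.001, 0.002,
0.05, 0.1, 0.2} × batch size {10, 32, 48} × weight decay {0.0001, 0.0002},
sampled uniformly without replacement.

### Scaling table

Everything trains on one CPU; the desk-scale defaults shrink the published
set-ups while keeping their structure (published sizes remain available for
example-count accounting under `size="sufficient"`):

| task | classes | image | train images × examples | test NC/CG | backbone | epochs (cap) |
|---|---|---|---|---|---|---|
| chargrid6 scaled | 6 | 12×48×1 | 150 × 5 | 100/100 | 3 conv layers, 8/16/16 ch | 60 |
| chargrid24-analog scaled | 10 (8 per image) | 12×64×1 | 200 × 6 | 100/100 | same | 50 |
| persons scaled | 8 identities, 5 properties | 16×32×3 | 150 × 10 | 100/100 | same | 50 |

Default training hyperparameters for the scaled tasks are Adam, learning
rate 0.002, batch size 10, weight decay 0.0001 (all members of the grid).
With these conditions the guided model reaches ≈ 100% NC on the scaled
character grids and CG typically ≥ 90% (the convergence criterion monitors NC,
so early stopping can occasionally leave CG around 75% in a fold); the
unguided model's CG stays at ≈ 0% (it memorizes
the pair statistics available in training queries), and its NC also remains
far below the guided model's at this data scale — the published experiments
show the unguided variant eventually reaching high NC with substantially
larger training sets, which is out of desk-scale budget.

### What passing tests do and do not show

The scaled experiments demonstrate the *mechanism* — early instruction
guidance producing combinatorial generalization where late readout selection
fails — under synthetic, visually separable stimuli. They do not reproduce
the published accuracy/IoU values on rendered 3-D scenes or handwritten
characters, and say nothing about photorealistic robustness.

## Numerical choices and degenerate inputs

* All tensors are float32; the autodiff core is gradient-checked in float64.
* IoU of two empty masks is defined as 1.0.
* Segmentation masks are thresholded at probability 0.5.
* Depth ties are broken by smaller x, then smaller id, everywhere.
* `convergence_check(history, window, threshold)` is false for histories
  shorter than `window + 1`.
* A summary window longer than the history collapses to a single point.
* Divergent training (non-finite loss) aborts with a diagnostic.
* The expansion budget defaults to 64 calls; exhaustion yields a `failed`
  grounding with reason `"budget"`.

## Known limitations

* The BU-channel variant is implemented and structurally tested, but at desk
  scale it does not reach combinatorial generalization within any tried
  budget — consistent with the published observation that this variant needs
  substantially more training examples. Its scaled CG comparison is therefore
  not asserted by the test suite.
* One BU→TD→BU cycle per instruction; multi-cycle refinement is not
  implemented.
* Natural-language goals, goal-free default-priority exploration and
  nonvisual knowledge integration are out of scope.
* The grounding engine is exhaustive only up to its expansion budget;
  adversarially deep targets can exhaust it.
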