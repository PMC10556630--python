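"""Top-down instruction types.

A TD instruction is the control signal of the counterstream model: a *task
selector* (which learned task to perform — a property to read out, a relation
to verify, or ``extract-next``) together with an *argument* that says what to
apply the task to.  The argument can be given in three modes, mirroring the
three ways attention can be allocated: a location mask (spatial attention), a
class index (object-based attention), or a relation to an already-located
reference component.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

ARG_MODES = ("mask", "class", "relation")

EXTRACT_NEXT = "extract-next"


@dataclass
class TDInstruction:
    """Task selector plus argument specifier.

    Parameters
    ----------
    task:
        A task name, or a tuple of task names for a compound instruction
        (multi-hot task vector requesting several properties at once).
    arg_mode:
        One of ``"mask"``, ``"class"``, ``"relation"``.
    arg:
        ``mask`` mode: binary raster (H, W) or ``None`` for the empty mask;
        ``class`` mode: class name or index into the argument vocabulary;
        ``relation`` mode: ``(relation_name, reference_mask)``.
    """

    task: str | tuple[str, ...]
    arg_mode: str = "mask"
    arg: object = None

    def __post_init__(self):
        if isinstance(self.task, str):
            if not self.task:
                raise ValueError("instruction task must be non-empty")
        else:
            self.task = tuple(self.task)
            if len(self.task) == 0:
                raise ValueError("instruction needs at least one task (all-zero i_task rejected)")
        if self.arg_mode not in ARG_MODES:
            raise ValueError(f"unknown arg_mode {self.arg_mode!r}; expected one of {ARG_MODES}")
        if self.arg_mode == "relation":
            if not (isinstance(self.arg, tuple) and len(self.arg) == 2):
                raise ValueError("relation argument must be (relation_name, reference_mask)")

    @property
    def tasks(self) -> tuple[str, ...]:
        return (self.task,) if isinstance(self.task, str) else self.task

    @property
    def is_compound(self) -> bool:
        return len(self.tasks) > 1


@dataclass
class InstructionEmbedding:
    """Learned dense embeddings (e_task, e_arg) of one TD instruction."""

    e_task: np.ndarray
    e_arg: np.ndarray


@dataclass
class GuidedOutput:
    """Outputs of one guided BU1 -> TD -> BU2 cycle.

    ``occurrence_logits`` come from the top of the first bottom-up pass (which
    classes are present anywhere in the image), ``segmentation_logits`` from
    the bottom of the top-down pass (the instructed component's mask), and
    ``task_logits`` from the top of the second bottom-up pass (the answer),
    one logit vector per active task.
    """

    occurrence_logits: np.ndarray
    segmentation_logits: np.ndarray
    task_logits: dict[str, np.ndarray] = field(default_factory=dict)

    def answer(self, task: str) -> int:
        return int(np.argmax(self.task_logits[task]))

    def mask(self, threshold: float = 0.5) -> np.ndarray:
        prob = 1.0 / (1.0 + np.exp(-np.clip(self.segmentation_logits, -60, 60)))
        return (prob >= threshold).astype(np.uint8)


def one_hot(indices: Sequence[int], n: int) -> np.ndarray:
    out = np.zeros((len(indices), n))
    out[np.arange(len(indices)), np.asarray(indices, dtype=int)] = 1.0
    return out
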