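"""The BU-TD counterstream network and its sklearn-style estimator.

The network is a pair of small residual-free convolutional streams running in
opposite directions.  A bottom-up (BU) stream maps the image to a top-level
representation; a top-down (TD) stream of mirrored structure maps the embedded
instruction, combined with the BU top level, back to image resolution, where a
segmentation map is read out.  A second bottom-up pass (BU2) then runs *in the
context of the TD activation*: at every layer the TD activation multiplicatively
gates the BU2 features, so the instruction can suppress non-instructed content
before the answer is read out at the top of BU2.  BU1 and BU2 are the same
network unfolded in time and share every parameter.

Three model variants share the backbone:

``guided``      instruction enters at the top of the TD stream (early selection),
``unguided``    instruction is concatenated only to the top of BU2 and answered
                through a two-layer readout (late selection); the TD stream
                receives a fixed, instruction-independent input,
``bu_channel``  instruction is embedded into an image-sized plane and appended
                to the input as an extra channel (guidance, but bottom-up).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import NotFittedError

from . import autodiff as ad
from .autodiff import (
    Tensor, avg_pool2d, bce_with_logits, concat, conv2d, relu, sigmoid,
    softmax_cross_entropy, spatial_mean, take_rows, upsample2x,
)
from .instructions import GuidedOutput, InstructionEmbedding, TDInstruction

MODES = ("guided", "unguided", "bu_channel")


@dataclass
class TaskConfig:
    """Static description of a task family the network is trained on."""

    image_shape: tuple[int, int, int]  # (C, H, W); H, W divisible by 4
    tasks: list[str]
    answer_spaces: dict[str, int]
    task_to_space: dict[str, str]
    occurrence_classes: int
    arg_vocab: int = 1  # class-mode argument vocabulary size
    relations: list[str] = field(default_factory=list)

    def __post_init__(self):
        c, h, w = self.image_shape
        if h % 4 or w % 4:
            raise ValueError("image height and width must be divisible by 4")
        for t in self.tasks:
            if t not in self.task_to_space:
                raise ValueError(f"task {t!r} has no answer space")


def iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection-over-union of two binary masks; 1.0 when both are empty."""
    a = np.asarray(mask_a)
    b = np.asarray(mask_b)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    a = a.astype(bool)
    b = b.astype(bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


class CounterstreamNet:
    """Parameter container and forward passes (all three variants)."""

    def __init__(
        self,
        config: TaskConfig,
        mode: str = "guided",
        channels: tuple[int, int, int] = (8, 16, 16),
        embed_dim: int = 12,
        hidden_readout: int = 64,
        td_laterals: bool = True,
        head_pool: str = "flatten",
        seed: int = 0,
    ):
        if mode not in MODES:
            raise ValueError(f"unknown mode {mode!r}")
        if head_pool not in ("flatten", "avg"):
            raise ValueError(f"unknown head_pool {head_pool!r}")
        self.config = config
        self.mode = mode
        self.channels = channels
        self.embed_dim = embed_dim
        self.td_laterals = td_laterals
        self.head_pool = head_pool
        rng = np.random.default_rng(seed)
        c_in, h, w = config.image_shape
        if mode == "bu_channel":
            c_in += 1
        c1, c2, c3 = channels
        d = embed_dim
        self.h4, self.w4 = h // 4, w // 4
        self.flat_dim = c3 * self.h4 * self.w4
        self._params: dict[str, Tensor] = {}

        def p(name, shape, fan_in=None):
            fan = fan_in if fan_in is not None else int(np.prod(shape[1:])) or shape[0]
            t = Tensor(rng.normal(0.0, np.sqrt(2.0 / fan), size=shape), requires_grad=True)
            self._params[name] = t
            return t

        def zeros(name, shape):
            t = Tensor(np.zeros(shape), requires_grad=True)
            self._params[name] = t
            return t

        # shared BU stack (used by BU1 and BU2 — weight sharing by identity)
        self.w1, self.b1 = p("w1", (c1, c_in, 3, 3)), zeros("b1", (c1,))
        self.w2, self.b2 = p("w2", (c2, c1, 3, 3)), zeros("b2", (c2,))
        self.w3, self.b3 = p("w3", (c3, c2, 3, 3)), zeros("b3", (c3,))
        # occurrence head (top of BU1)
        self.w_occ = p("w_occ", (self.flat_dim, config.occurrence_classes), fan_in=self.flat_dim)
        self.b_occ = zeros("b_occ", (config.occurrence_classes,))
        # instruction embeddings
        K = len(config.tasks)
        self.E_task = p("E_task", (K, d), fan_in=K)
        self.E_arg = p("E_arg", (max(config.arg_vocab, 1), d), fan_in=max(config.arg_vocab, 1))
        nrel = max(len(config.relations), 1)
        self.E_rel = p("E_rel", (nrel, d), fan_in=nrel)
        # FiLM modulation of L^T by the embedded instruction
        self.W_gamma, self.b_gamma = zeros("W_gamma", (2 * d, c3)), zeros("b_gamma", (c3,))
        self.W_beta, self.b_beta = p("W_beta", (2 * d, c3), fan_in=2 * d), zeros("b_beta", (c3,))
        # location-mask argument pathway (downsampled mask injected at TD input)
        self.w_mask = p("w_mask", (c3, 1, 1, 1), fan_in=1)
        # TD stream: instruction enters the TD input by feature-wise affine
        # modulation of the L^T lateral (whose channel sums act as a
        # feature-matching map) plus broadcast instruction channels
        self.P3 = p("P3", (c3, c3, 1, 1))
        self.bP3 = zeros("bP3", (c3,))
        self.Wt3, self.bt3 = p("Wt3", (c3, c3 + 2 * d, 3, 3)), zeros("bt3", (c3,))
        self.Wt3b, self.bt3b = p("Wt3b", (c3, c3, 3, 3)), zeros("bt3b", (c3,))
        self.Wu2, self.bu2 = p("Wu2", (c2, c3, 3, 3)), zeros("bu2_b", (c2,))
        self.L2 = p("L2", (c2, c2, 1, 1))
        self.Wu1, self.bu1 = p("Wu1", (c1, c2, 3, 3)), zeros("bu1_b", (c1,))
        self.L1 = p("L1", (c1, c1, 1, 1))
        self.W_seg, self.b_seg = p("W_seg", (1, c1, 1, 1)), zeros("b_seg", (1,))
        # TD -> BU2 gates: single-channel (purely spatial) multiplicative
        # selection, biased open at init so BU2 starts close to BU1
        self.G0, self.g0b = p("G0", (1, c1, 1, 1)), Tensor(np.full((1,), 2.0), requires_grad=True)
        self.G1, self.g1b = p("G1", (1, c1, 1, 1)), Tensor(np.full((1,), 2.0), requires_grad=True)
        self.G2, self.g2b = p("G2", (1, c2, 1, 1)), Tensor(np.full((1,), 2.0), requires_grad=True)
        self.G3, self.g3b = p("G3", (1, c3, 1, 1)), Tensor(np.full((1,), 2.0), requires_grad=True)
        for nm, t in (("g0b", self.g0b), ("g1b", self.g1b), ("g2b", self.g2b), ("g3b", self.g3b)):
            self._params[nm] = t
        # answer heads, one per answer space (top of BU2); spatially pooled
        # heads are position-invariant (useful when targets appear anywhere)
        head_in = c3 if head_pool == "avg" else self.flat_dim
        self.heads: dict[str, tuple[Tensor, Tensor]] = {}
        for name, size in config.answer_spaces.items():
            self.heads[name] = (
                p(f"head_{name}_w", (head_in, size), fan_in=head_in),
                zeros(f"head_{name}_b", (size,)),
            )
        if mode in ("unguided", "bu_channel"):
            # fixed (learned but instruction-independent) TD input
            self.e_const = zeros("e_const", (1, 2 * d))
        if mode == "unguided":
            rd_in = self.flat_dim + 2 * d
            self.Wr1, self.br1 = p("Wr1", (rd_in, hidden_readout), fan_in=rd_in), zeros("br1", (hidden_readout,))
            self.readouts: dict[str, tuple[Tensor, Tensor]] = {}
            for name, size in config.answer_spaces.items():
                self.readouts[name] = (
                    p(f"readout_{name}_w", (hidden_readout, size), fan_in=hidden_readout),
                    zeros(f"readout_{name}_b", (size,)),
                )
            self.W_maskvec = p("W_maskvec", (self.h4 * self.w4, d), fan_in=self.h4 * self.w4)
        if mode == "bu_channel":
            # instruction plane: embedded on a coarse grid and upsampled to
            # image size, so the channel is locally smooth and readable by
            # small convolution kernels
            self.W_plane = p("W_plane", (2 * d, self.h4 * self.w4), fan_in=2 * d)

    # -- parameter access ---------------------------------------------------
    def parameters(self) -> list[Tensor]:
        return list(self._params.values())

    @property
    def bu_params(self) -> list[Tensor]:
        """Parameters of the shared bottom-up stack (BU1 and BU2 alike)."""
        return [self.w1, self.b1, self.w2, self.b2, self.w3, self.b3]

    def backbone_parameter_count(self) -> int:
        """Size of the backbone: everything except answer/readout heads and
        the instruction embedding maps."""
        skip = {"E_task", "E_arg", "E_rel", "W_maskvec", "W_plane", "e_const"}
        n = 0
        for name, t in self._params.items():
            if name in skip or name.startswith(("head_", "readout_", "Wr1", "br1")):
                continue
            n += t.data.size
        return n

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self._params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self._params[k].data = np.asarray(v, dtype=ad.DTYPE)

    # -- instruction embedding ------------------------------------------------
    def _task_indices(self, instr: TDInstruction) -> list[int]:
        try:
            return [self.config.tasks.index(t) for t in instr.tasks]
        except ValueError as e:
            raise ValueError(f"unknown task in instruction: {e}") from e

    def embed_instruction(self, instr: TDInstruction) -> InstructionEmbedding:
        """Embed one TD instruction (compound tasks sum their embeddings)."""
        idx = self._task_indices(instr)
        it = np.zeros((1, len(self.config.tasks)))
        it[0, idx] = 1.0
        e_task = it @ self.E_task.data
        d = self.embed_dim
        if instr.arg_mode == "class":
            ia = np.zeros((1, self.E_arg.shape[0]))
            ia[0, int(instr.arg)] = 1.0
            e_arg = ia @ self.E_arg.data
        elif instr.arg_mode == "relation":
            rel, _ = instr.arg
            e_arg = self.E_rel.data[[self.config.relations.index(rel)]]
        else:
            e_arg = np.zeros((1, d))
        return InstructionEmbedding(e_task=e_task[0], e_arg=e_arg[0])

    # -- stream passes ---------------------------------------------------------
    def _bu_pass(self, x: Tensor):
        a1 = relu(conv2d(x, self.w1, self.b1, stride=1, pad=1))
        a2 = relu(conv2d(a1, self.w2, self.b2, stride=2, pad=1))
        a3 = relu(conv2d(a2, self.w3, self.b3, stride=2, pad=1))
        return a1, a2, a3

    def _td_pass(self, a1, a2, a3, e: Tensor, mask_small: Tensor | None):
        B = a3.shape[0]
        c3 = self.channels[2]
        gamma = e @ self.W_gamma + self.b_gamma
        beta = e @ self.W_beta + self.b_beta
        h = conv2d(a3, self.P3, self.bP3)
        h = h * (gamma + 1.0).reshape(B, c3, 1, 1) + beta.reshape(B, c3, 1, 1)
        if mask_small is not None:
            h = h + conv2d(mask_small, self.w_mask)
        # broadcast the embedded instruction as channels at the TD input
        ones = Tensor(np.ones((B, 2 * self.embed_dim, self.h4, self.w4), dtype=e.data.dtype))
        eplane = ones * e.reshape(B, 2 * self.embed_dim, 1, 1)
        t3 = relu(conv2d(concat([h, eplane], axis=1), self.Wt3, self.bt3, stride=1, pad=1))
        t3 = relu(conv2d(t3, self.Wt3b, self.bt3b, stride=1, pad=1))
        t2 = relu(conv2d(upsample2x(t3), self.Wu2, self.bu2, stride=1, pad=1) + conv2d(a2, self.L2))
        t1 = relu(conv2d(upsample2x(t2), self.Wu1, self.bu1, stride=1, pad=1) + conv2d(a1, self.L1))
        seg = conv2d(t1, self.W_seg, self.b_seg)
        return t1, t2, t3, seg

    def _bu2_pass(self, x: Tensor, t1, t2, t3, seg):
        if not self.td_laterals:
            return self._bu_pass(x)[2]
        # the TD stream's bottom output (the instructed segmentation) gates the
        # image for the second BU pass; per-layer gates from the TD activations
        xg = x * sigmoid(seg + conv2d(t1, self.G0, self.g0b))
        a1 = relu(conv2d(xg, self.w1, self.b1, stride=1, pad=1)) * sigmoid(conv2d(t1, self.G1, self.g1b))
        a2 = relu(conv2d(a1, self.w2, self.b2, stride=2, pad=1)) * sigmoid(conv2d(t2, self.G2, self.g2b))
        a3 = relu(conv2d(a2, self.w3, self.b3, stride=2, pad=1)) * sigmoid(conv2d(t3, self.G3, self.g3b))
        return a3

    # -- batched forward --------------------------------------------------------
    def forward_batch(
        self,
        images: np.ndarray,
        it: np.ndarray,
        arg_mode: str,
        arg_class: np.ndarray | None = None,
        arg_masks: np.ndarray | None = None,
        arg_rel: np.ndarray | None = None,
    ) -> dict:
        """Run one full BU1 -> TD -> BU2 cycle on a batch.

        ``images``: (B, C, H, W); ``it``: (B, K) multi-hot task selector;
        class args as (B, V) one-hot, mask args as (B, 1, H, W) rasters,
        relation args as ((B, R) one-hot, reference masks in ``arg_masks``).
        """
        cfg = self.config
        B = images.shape[0]
        if images.shape[1:] != tuple(cfg.image_shape):
            raise ValueError(f"image batch shape {images.shape[1:]} != configured {cfg.image_shape}")
        d = self.embed_dim
        e_task = Tensor(it) @ self.E_task
        mask_small = None
        if arg_mode == "class":
            e_arg = Tensor(arg_class) @ self.E_arg
        elif arg_mode == "relation":
            e_arg = Tensor(arg_rel) @ self.E_rel
            if arg_masks is not None:
                mask_small = avg_pool2d(Tensor(arg_masks), 4)
        elif arg_mode == "mask":
            e_arg = Tensor(np.zeros((B, d)))
            if arg_masks is not None:
                mask_small = avg_pool2d(Tensor(arg_masks), 4)
        else:
            raise ValueError(arg_mode)
        e_instr = concat([e_task, e_arg], axis=1)

        x = Tensor(images)
        if self.mode == "bu_channel":
            plane = (e_instr @ self.W_plane).reshape(B, 1, self.h4, self.w4)
            plane = upsample2x(upsample2x(plane))
            x = concat([x, plane], axis=1)
        a1, a2, a3 = self._bu_pass(x)
        flat1 = a3.reshape(B, self.flat_dim)
        occ = flat1 @ self.w_occ + self.b_occ

        if self.mode == "guided":
            e_td = e_instr
        else:
            e_td = Tensor(np.ones((B, 1))) @ self.e_const  # broadcast learned constant
            mask_small = None
        t1, t2, t3, seg = self._td_pass(a1, a2, a3, e_td, mask_small)
        a3p = self._bu2_pass(x, t1, t2, t3, seg)
        flat2 = a3p.reshape(B, self.flat_dim)
        head_in = spatial_mean(a3p) if self.head_pool == "avg" else flat2

        spaces: dict[str, Tensor] = {}
        if self.mode == "unguided":
            if arg_mode == "mask" and arg_masks is not None:
                pooled = avg_pool2d(Tensor(arg_masks), 4).reshape(B, self.h4 * self.w4)
                e_arg = pooled @ self.W_maskvec
            r = relu(concat([flat2, e_task, e_arg], axis=1) @ self.Wr1 + self.br1)
            for name, (wr, br) in self.readouts.items():
                spaces[name] = r @ wr + br
        else:
            for name, (wh, bh) in self.heads.items():
                spaces[name] = head_in @ wh + bh
        return {"occ": occ, "seg": seg, "spaces": spaces, "bu1_top": a3, "bu2_top": a3p}

    # -- single-example forwards --------------------------------------------------
    def _encode_single(self, image: np.ndarray, instr: TDInstruction):
        cfg = self.config
        c, h, w = cfg.image_shape
        img = np.asarray(image, dtype=np.float64)
        if img.ndim == 2:
            img = img[None]
        if img.shape != (c, h, w):
            raise ValueError(f"image shape {img.shape} != configured {(c, h, w)}")
        it = np.zeros((1, len(cfg.tasks)))
        it[0, self._task_indices(instr)] = 1.0
        arg_class = arg_rel = arg_masks = None
        mode = instr.arg_mode
        if mode == "class":
            arg_class = np.zeros((1, self.E_arg.shape[0]))
            arg_class[0, int(instr.arg)] = 1.0
        elif mode == "relation":
            rel, ref = instr.arg
            arg_rel = np.zeros((1, self.E_rel.shape[0]))
            arg_rel[0, cfg.relations.index(rel)] = 1.0
            if ref is not None:
                arg_masks = self._check_mask(ref)
        else:
            if instr.arg is not None:
                arg_masks = self._check_mask(instr.arg)
            else:
                arg_masks = np.zeros((1, 1, h, w))
        return img[None], it, mode, arg_class, arg_masks, arg_rel

    def _check_mask(self, mask) -> np.ndarray:
        c, h, w = self.config.image_shape
        m = np.asarray(mask, dtype=np.float64)
        if m.shape != (h, w):
            raise ValueError(f"argument mask shape {m.shape} != image shape {(h, w)}")
        return m[None, None]

    def forward(self, image: np.ndarray, instr: TDInstruction) -> GuidedOutput:
        img, it, mode, ac, am, ar = self._encode_single(image, instr)
        out = self.forward_batch(img, it, mode, ac, am, ar)
        task_logits = {}
        for t in instr.tasks:
            space = self.config.task_to_space[t]
            task_logits[t] = out["spaces"][space].data[0]
        return GuidedOutput(
            occurrence_logits=out["occ"].data[0],
            segmentation_logits=out["seg"].data[0, 0],
            task_logits=task_logits,
        )


# -- losses ---------------------------------------------------------------------

@dataclass
class LossBundle:
    occurrence: float
    segmentation: float
    task: float
    total: float


def compute_losses(out: GuidedOutput, targets: dict, weights=(1.0, 1.0, 1.0)) -> LossBundle:
    """Evaluate the three training losses on a single guided output.

    ``targets``: ``occurrence`` — binary per-class presence vector; ``mask`` —
    binary raster matching the segmentation logits; ``answer`` — ``(task,
    label)``.  A loss with nonzero weight whose target is missing is an error.
    """
    w_occ, w_seg, w_task = weights
    occ = seg = task = 0.0
    if w_occ:
        if "occurrence" not in targets:
            raise ValueError("occurrence loss enabled but no occurrence target given")
        occ = float(bce_with_logits(Tensor(out.occurrence_logits), targets["occurrence"]).data)
    if w_seg:
        if "mask" not in targets:
            raise ValueError("segmentation loss enabled but no mask target given")
        seg = float(bce_with_logits(Tensor(out.segmentation_logits), targets["mask"]).data)
    if w_task:
        if "answer" not in targets:
            raise ValueError("task loss enabled but no answer target given")
        tname, label = targets["answer"]
        logits = Tensor(out.task_logits[tname][None, :])
        task = float(softmax_cross_entropy(logits, [int(label)]).data)
    total = w_occ * occ + w_seg * seg + w_task * task
    return LossBundle(occurrence=occ, segmentation=seg, task=task, total=total)


# -- estimator ---------------------------------------------------------------------

class CounterstreamClassifier(BaseEstimator, ClassifierMixin):
    """Instruction-conditioned classifier over the counterstream backbone.

    ``X`` is a sequence of ``(image, TDInstruction)`` pairs and ``y`` the
    integer answer within each instruction's answer space.  Extra supervision
    (per-example segmentation target masks, per-example class-occurrence
    vectors) is passed to :meth:`fit` as keyword arguments.
    """

    def __init__(
        self,
        task_config: TaskConfig | None = None,
        mode: str = "guided",
        channels: tuple[int, int, int] = (8, 16, 16),
        embed_dim: int = 12,
        hidden_readout: int = 64,
        optimizer: str = "adam",
        lr: float = 1e-3,
        momentum: float = 0.9,
        batch_size: int = 32,
        weight_decay: float = 1e-4,
        max_epochs: int = 40,
        loss_weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
        seg_pos_weight: float = 4.0,
        td_laterals: bool = True,
        head_pool: str = "flatten",
        convergence_window: int | None = None,
        convergence_threshold: float = 1.0,
        monitor: str = "nc",
        random_state: int = 0,
    ):
        self.task_config = task_config
        self.mode = mode
        self.channels = channels
        self.embed_dim = embed_dim
        self.hidden_readout = hidden_readout
        self.optimizer = optimizer
        self.lr = lr
        self.momentum = momentum
        self.batch_size = batch_size
        self.weight_decay = weight_decay
        self.max_epochs = max_epochs
        self.loss_weights = loss_weights
        self.seg_pos_weight = seg_pos_weight
        self.td_laterals = td_laterals
        self.head_pool = head_pool
        self.convergence_window = convergence_window
        self.convergence_threshold = convergence_threshold
        self.monitor = monitor
        self.random_state = random_state

    # -- encoding -------------------------------------------------------------
    def _encode(self, X):
        cfg = self.task_config
        c, h, w = cfg.image_shape
        n = len(X)
        images = np.zeros((n, c, h, w), dtype=np.float32)
        it = np.zeros((n, len(cfg.tasks)), dtype=np.float32)
        modes = set()
        arg_class = np.zeros((n, max(cfg.arg_vocab, 1)), dtype=np.float32)
        arg_rel = np.zeros((n, max(len(cfg.relations), 1)), dtype=np.float32)
        arg_masks = None
        space_idx = np.zeros(n, dtype=np.int64)
        space_names = list(cfg.answer_spaces)
        for i, (img, instr) in enumerate(X):
            img = np.asarray(img)
            if img.ndim == 2:
                img = img[None]
            images[i] = img
            for t in instr.tasks:
                it[i, cfg.tasks.index(t)] = 1.0
            space_idx[i] = space_names.index(cfg.task_to_space[instr.tasks[0]])
            modes.add(instr.arg_mode)
            if instr.arg_mode == "class":
                arg_class[i, int(instr.arg)] = 1.0
            elif instr.arg_mode == "relation":
                rel, ref = instr.arg
                arg_rel[i, cfg.relations.index(rel)] = 1.0
                if ref is not None:
                    if arg_masks is None:
                        arg_masks = np.zeros((n, 1, h, w), dtype=np.float32)
                    arg_masks[i, 0] = ref
            else:
                if instr.arg is not None:
                    if arg_masks is None:
                        arg_masks = np.zeros((n, 1, h, w), dtype=np.float32)
                    arg_masks[i, 0] = instr.arg
        if len(modes) > 1:
            raise ValueError("mixed argument modes within one batch are not supported")
        mode = modes.pop() if modes else "mask"
        if mode == "mask" and arg_masks is None:
            arg_masks = np.zeros((n, 1, h, w), dtype=np.float32)
        return images, it, mode, arg_class, arg_masks, arg_rel, space_idx, space_names

    # -- training ---------------------------------------------------------------
    def fit(self, X, y, masks=None, occurrence=None, eval_sets=None):
        if self.task_config is None:
            raise ValueError("task_config is required to fit")
        y = np.asarray(y, dtype=np.int64)
        self.classes_ = np.unique(y)
        self.net_ = CounterstreamNet(
            self.task_config,
            mode=self.mode,
            channels=self.channels,
            embed_dim=self.embed_dim,
            hidden_readout=self.hidden_readout,
            td_laterals=self.td_laterals,
            head_pool=self.head_pool,
            seed=self.random_state,
        )
        enc = self._encode(X)
        images, it, arg_mode, arg_class, arg_masks, arg_rel, space_idx, space_names = enc
        n = len(y)
        w_occ, w_seg, w_task = self.loss_weights
        if self.mode == "unguided":
            w_seg = 0.0  # no instruction-dependent TD target exists
        if masks is not None:
            masks = np.asarray(masks, dtype=np.float32)
        if occurrence is not None:
            occurrence = np.asarray(occurrence, dtype=np.float32)
        if self.optimizer == "adam":
            opt = ad.Adam(self.net_.parameters(), lr=self.lr, weight_decay=self.weight_decay)
        elif self.optimizer in ("sgd", "sgd-momentum"):
            opt = ad.SGD(self.net_.parameters(), lr=self.lr, momentum=self.momentum, weight_decay=self.weight_decay)
        else:
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        rng = np.random.default_rng(self.random_state)
        history: list[dict] = []
        from .experiments import convergence_check  # local import avoids cycle

        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            nb = 0
            for lo in range(0, n, self.batch_size):
                idx = order[lo : lo + self.batch_size]
                out = self.net_.forward_batch(
                    images[idx], it[idx], arg_mode, arg_class[idx],
                    None if arg_masks is None else arg_masks[idx], arg_rel[idx],
                )
                loss = Tensor(0.0)
                if w_task:
                    for si, sname in enumerate(space_names):
                        rows = np.where(space_idx[idx] == si)[0]
                        if len(rows) == 0:
                            continue
                        ce = softmax_cross_entropy(take_rows(out["spaces"][sname], rows), y[idx][rows])
                        loss = loss + (w_task * len(rows) / len(idx)) * ce
                if w_occ and occurrence is not None:
                    loss = loss + w_occ * bce_with_logits(out["occ"], occurrence[idx].astype(np.float64))
                if w_seg and masks is not None:
                    B = len(idx)
                    tgt = masks[idx].reshape(B, 1, *masks.shape[1:])
                    loss = loss + w_seg * bce_with_logits(out["seg"], tgt, pos_weight=self.seg_pos_weight)
                if not np.isfinite(loss.data):
                    raise RuntimeError(f"training diverged: loss={loss.data!r} at epoch {epoch}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data)
                nb += 1
            row = {"epoch": epoch, "loss": epoch_loss / max(nb, 1)}
            if eval_sets:
                for name, (Xe, ye) in eval_sets.items():
                    row[f"{name}_acc"] = 100.0 * self.score(Xe, ye)
            history.append(row)
            if self.convergence_window and eval_sets and f"{self.monitor}_acc" in row:
                series = [r[f"{self.monitor}_acc"] for r in history]
                if convergence_check(series, self.convergence_window, self.convergence_threshold):
                    break
        import pandas as pd

        self.history_ = pd.DataFrame(history)
        self.n_features_in_ = int(np.prod(self.task_config.image_shape))
        return self

    # -- inference -----------------------------------------------------------------
    def _batched_logits(self, X):
        if not hasattr(self, "net_"):
            raise NotFittedError("this CounterstreamClassifier is not fitted yet")
        enc = self._encode(X)
        images, it, arg_mode, arg_class, arg_masks, arg_rel, space_idx, space_names = enc
        n = len(X)
        preds = np.zeros(n, dtype=np.int64)
        probas = [None] * n
        bs = max(self.batch_size, 64)
        for lo in range(0, n, bs):
            sl = slice(lo, min(lo + bs, n))
            out = self.net_.forward_batch(
                images[sl], it[sl], arg_mode, arg_class[sl],
                None if arg_masks is None else arg_masks[sl], arg_rel[sl],
            )
            for j in range(sl.stop - sl.start):
                sname = space_names[space_idx[lo + j]]
                z = out["spaces"][sname].data[j]
                ez = np.exp(z - z.max())
                probas[lo + j] = ez / ez.sum()
                preds[lo + j] = int(np.argmax(z))
        return preds, probas

    def predict(self, X):
        return self._batched_logits(X)[0]

    def predict_proba(self, X):
        return self._batched_logits(X)[1]

    def forward(self, image, instr: TDInstruction) -> GuidedOutput:
        if not hasattr(self, "net_"):
            raise NotFittedError("this CounterstreamClassifier is not fitted yet")
        return self.net_.forward(image, instr)


# -- thin functional wrappers ---------------------------------------------------------

def guided_forward(net: CounterstreamNet, image, instr: TDInstruction) -> GuidedOutput:
    if net.mode != "guided":
        raise ValueError("guided_forward requires a net built with mode='guided'")
    return net.forward(image, instr)


def unguided_forward(net: CounterstreamNet, image, instr: TDInstruction) -> dict[str, np.ndarray]:
    if net.mode != "unguided":
        raise ValueError("unguided_forward requires mode='unguided'")
    return net.forward(image, instr).task_logits


def bu_channel_forward(net: CounterstreamNet, image, instr: TDInstruction) -> GuidedOutput:
    if net.mode != "bu_channel":
        raise ValueError("bu_channel_forward requires mode='bu_channel'")
    return net.forward(image, instr)


def embed_instruction(net: CounterstreamNet, instr: TDInstruction) -> InstructionEmbedding:
    return net.embed_instruction(instr)
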