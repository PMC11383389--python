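"""Mean-teacher cross-domain training loop.

Each step: (1) supervised dice on a weak-augmented labeled HD batch; (2) the
teacher predicts weak-augmented low-quality scans, the EDD scores how
target-like those predictions look, and the CSS gates (confidence + domain
score) build a per-pixel selection mask; (3) the student predicts a
strong-augmented view of the same weak-augmented scans and is self-trained on
the gated pseudo-labels; (4) with the EDD frozen, the adversarial term pushes
the student's source predictions toward the target side; (5) the combined loss
updates the student; (6) the teacher follows by EMA; (7) the EDD is updated to
separate the (teacher-ensembled) target output space from the source output
space, segmentor outputs detached.

Published defaults: 250 epochs, Adam lr 6e-4 divided by 10 at epoch 150, batch
4 + 4, EDD Adam lr 6e-5, lambda1 = 1.5, lambda2 = 0.5; CSS presets
(alpha, beta1, beta2) = (0.85, 0.1, 0.9) for the sublayer subtask and
(0.85, 0.15, 0.85) for the vessel subtask.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .augment import AugmentConfig, strong_augment, weak_augment
from .data import BScan
from .losses import (
    GateThresholds,
    LossWeights,
    adapt_loss,
    edd_loss,
    make_pseudo_labels,
    selection_mask,
    source_loss,
    target_loss,
    total_loss,
)
from .models import (
    SegmentorConfig,
    TeacherState,
    build_edd,
    build_segmentor,
    edd_forward,
    forward_segmentor,
    make_teacher,
    upsample_scores,
)
from .nn import Adam, SGD, Tensor, concat

__all__ = ["TrainConfig", "TrainState", "init_state", "train_step", "fit",
           "train_both_subtasks", "lr_at_epoch"]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 250
    lr: float = 6e-4
    lr_drop_epoch: int = 150
    lr_drop_factor: float = 10.0
    batch_size: int = 4
    edd_lr: float = 6e-5
    weights: LossWeights = field(default_factory=LossWeights)
    layer_gates: GateThresholds = field(default_factory=GateThresholds.layer_preset)
    vessel_gates: GateThresholds = field(default_factory=GateThresholds.vessel_preset)
    ema_decay: float = 0.999
    optimizer: str = "adam"
    subtask: str = "multi"  # multi | vessel | layer
    #: source-supervised warm-up epochs before the target and adaptation
    #: branches engage; the teacher must be source-trained before its
    #: pseudo-labels and the EDD's target exemplars mean anything
    warmup_epochs: int = 0
    seed: int = 0
    segmentor: SegmentorConfig = field(default_factory=SegmentorConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    checkpoint_every: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr <= 0:
            raise ValueError("lr must be positive")


def lr_at_epoch(config: TrainConfig, epoch: int) -> float:
    """Step schedule: base lr, divided by `lr_drop_factor` from `lr_drop_epoch`."""
    if epoch >= config.lr_drop_epoch:
        return config.lr / config.lr_drop_factor
    return config.lr


@dataclass
class TrainState:
    student: object
    teacher: TeacherState
    edd: object
    opt: object
    edd_opt: object
    rng: np.random.Generator
    config: TrainConfig
    epoch: int = 0
    step: int = 0
    history: list = field(default_factory=list)


def _edd_channels(config: TrainConfig) -> int:
    if config.subtask == "multi":
        return 5
    return 2 if config.subtask == "vessel" else 3


def init_state(config: TrainConfig) -> TrainState:
    ss = np.random.SeedSequence(config.seed)
    init_rng, edd_rng, loop_rng = (np.random.default_rng(c) for c in ss.spawn(3))
    student = build_segmentor(config.segmentor, init_rng, subtask=config.subtask)
    teacher = make_teacher(student, config.ema_decay)
    edd = build_edd(_edd_channels(config), edd_rng)
    opt_cls = Adam if config.optimizer == "adam" else SGD
    opt = opt_cls(student.parameters(), lr=config.lr)
    edd_opt = opt_cls(edd.parameters(), lr=config.edd_lr) if config.edd_lr > 0 else None
    return TrainState(student, teacher, edd, opt, edd_opt,
                      np.random.default_rng(ss.spawn(1)[0]), config)


def _stack_batch(batch: list[BScan], config: TrainConfig, rng,
                 with_masks: bool) -> tuple:
    augmented = [weak_augment(s, config.augment, rng) for s in batch]
    x = np.stack([a.image for a in augmented]).astype(np.float32)
    if not with_masks:
        return x, augmented
    vessel = np.stack([a.vessel_mask for a in augmented])
    layers = np.stack([a.sublayer_mask for a in augmented])
    return x, vessel, layers, augmented


def _edd_input(pm) -> Tensor:
    """Concatenate emitted heads into the EDD's output-space input."""
    heads = [h for h in (pm.layer_probs, pm.vessel_probs) if h is not None]
    heads = [h if isinstance(h, Tensor) else Tensor(np.asarray(h, np.float32))
             for h in heads]
    return heads[0] if len(heads) == 1 else concat(heads, axis=1)


def _head_iter(pm, config: TrainConfig):
    if pm.layer_probs is not None:
        yield "layer", pm.layer_probs, config.layer_gates
    if pm.vessel_probs is not None:
        yield "vessel", pm.vessel_probs, config.vessel_gates


def train_step(state: TrainState, source_batch: list[BScan],
               target_batch: list[BScan]) -> dict:
    """One optimization step over one source batch + one target batch."""
    cfg = state.config
    rng = state.rng
    state.opt.zero_grad()
    state.student.zero_grad()
    state.edd.zero_grad()

    # (1) supervised source branch
    x_s, vessel_gt, layer_gt, _ = _stack_batch(source_batch, cfg, rng, True)
    pm_s = forward_segmentor(state.student, x_s)
    ls = source_loss(pm_s, vessel_gt, layer_gt)

    lt = Tensor(np.float32(0.0))
    la = Tensor(np.float32(0.0))
    record = {"step": state.step, "epoch": state.epoch}
    s_t = None
    warm = state.epoch < cfg.warmup_epochs
    use_target = cfg.weights.lambda1 != 0 and not warm
    train_edd = cfg.edd_lr > 0 and state.edd_opt is not None and not warm

    if use_target or train_edd:
        x_t, _ = _stack_batch(target_batch, cfg, rng, False)
        pm_t_teacher = forward_segmentor(state.teacher.model, x_t).numpy()
        teacher_edd_in = _edd_input(pm_t_teacher).detach()
        # one EDD pass serves both CSS gating and the later Le update: the
        # EDD's weights do not change in between (La runs with it frozen)
        _, s_t = edd_forward(state.edd, teacher_edd_in)

    if use_target:
        # (2) pseudo-labels + CSS gating on the teacher's weak-view prediction
        s_maps = np.stack([
            upsample_scores(s_t.data[i, 0], x_t.shape[-2:])
            for i in range(s_t.data.shape[0])
        ])
        # (3) student on the strong-augmented view, masked self-training
        x_strong = np.stack([strong_augment(im, cfg.augment, rng) for im in x_t])
        pm_t_student = forward_segmentor(state.student, x_strong)
        fractions = []
        for name, head, gates in _head_iter(pm_t_student, cfg):
            teacher_head = (pm_t_teacher.layer_probs if name == "layer"
                            else pm_t_teacher.vessel_probs)
            pseudo, maxprob = make_pseudo_labels(teacher_head)
            sel = selection_mask(maxprob, s_maps, gates)
            head_loss, stats = target_loss(head, pseudo, sel)
            lt = lt + head_loss
            fractions.append(stats["selection_fraction"])
            record[f"gate_fraction_{name}"] = stats["selection_fraction"]
        record["gate_fraction"] = float(np.mean(fractions))

    adversarial = cfg.weights.lambda2 != 0 and not warm
    if adversarial:
        # (4) adversarial adaptation on the student's source prediction; the
        # EDD stays frozen through the backward pass so it receives no
        # gradient from La
        state.edd.freeze()
        _, s_s = edd_forward(state.edd, _edd_input(pm_s))
        la = adapt_loss(s_s)

    # (5) combined update of the student
    loss = total_loss(ls, lt, la, cfg.weights)
    loss.backward()
    if adversarial:
        state.edd.unfreeze()
    state.opt.step()

    # (6) teacher follows by EMA
    from .models import ema_update
    ema_update(state.teacher, state.student, cfg.ema_decay)

    # (7) discriminator update, segmentor outputs detached
    if train_edd:
        state.edd.zero_grad()
        _, s_s2 = edd_forward(state.edd, _edd_input(pm_s.numpy()))
        le = edd_loss(s_t, s_s2)
        le.backward()
        state.edd_opt.step()
        record["le"] = le.item()

    record.update(ls=ls.item(), lt=lt.item(), la=la.item(), total=loss.item())
    state.history.append(record)
    state.step += 1
    return record


class _Cycler:
    """Shuffled index stream over a dataset; reshuffles at each exhaustion."""

    def __init__(self, n: int, rng: np.random.Generator):
        self.n = n
        self.rng = rng
        self.order = rng.permutation(n)
        self.pos = 0

    def take(self, k: int) -> list[int]:
        out = []
        while len(out) < k:
            if self.pos >= self.n:
                self.order = self.rng.permutation(self.n)
                self.pos = 0
            out.append(int(self.order[self.pos]))
            self.pos += 1
        return out


def fit(source: list[BScan], target: list[BScan], config: TrainConfig,
        out_dir: Path | None = None) -> TrainState:
    """Full training loop; deterministic for a fixed seed on one platform."""
    if not source or not target:
        raise ValueError("both source and target sets must be nonempty")
    state = init_state(config)
    src_cycle = _Cycler(len(source), state.rng)
    tgt_cycle = _Cycler(len(target), state.rng)
    iters = int(np.ceil(max(len(source), len(target)) / config.batch_size))
    for epoch in range(config.epochs):
        state.epoch = epoch
        state.opt.lr = lr_at_epoch(config, epoch)
        for _ in range(iters):
            sb = [source[i] for i in src_cycle.take(config.batch_size)]
            tb = [target[i] for i in tgt_cycle.take(config.batch_size)]
            train_step(state, sb, tb)
        if out_dir is not None and config.checkpoint_every and \
                (epoch + 1) % config.checkpoint_every == 0:
            from dataclasses import asdict

            from .models import save_checkpoint
            Path(out_dir).mkdir(parents=True, exist_ok=True)
            save_checkpoint(Path(out_dir) / f"epoch_{epoch + 1:04d}.npz",
                            state.student, state.teacher, state.edd, asdict(config))
    if out_dir is not None:
        from dataclasses import asdict

        from .models import save_checkpoint
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_checkpoint(out / "final.npz", state.student, state.teacher, state.edd,
                        asdict(config))
        with open(out / "history.jsonl", "w") as fh:
            for rec in state.history:
                fh.write(json.dumps(rec) + "\n")
    return state


def train_both_subtasks(source: list[BScan], target: list[BScan],
                        config: TrainConfig, out_dir: Path | None = None
                        ) -> tuple[TrainState, TrainState]:
    """Train the vessel and sublayer segmentors separately with their presets.

    Returns (vessel_state, layer_state); compose their heads for angiography.
    """
    vessel_cfg = replace(config, subtask="vessel")
    layer_cfg = replace(config, subtask="layer")
    vessel_state = fit(source, target, vessel_cfg,
                       None if out_dir is None else Path(out_dir) / "vessel")
    layer_state = fit(source, target, layer_cfg,
                      None if out_dir is None else Path(out_dir) / "layer")
    return vessel_state, layer_state
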