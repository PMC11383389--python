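"""Model contracts: subtask segmentors, prediction composition, the EDD
discriminator, the EMA teacher and checkpointing.

The segmentation task is decomposed into a binary vessel subtask and a 3-class
sublayer subtask; the final {background, SV, HV} probability map is their
per-pixel product.  The EDD scores how target-like a prediction map looks
(sigmoid score, 0 = source-like); its coarse score map is bilinearly upsampled
when per-pixel gating needs image resolution.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .nn import (
    EDD,
    Adam,
    MultiTaskSegmentor,
    SingleTaskSegmentor,
    Tensor,
    conv_output_size,
    crop2d,
    softmax,
)
from .nn.layers import EDD_CHANNELS, EDD_KERNEL, EDD_PADDING, EDD_STRIDES, Module

__all__ = [
    "SegmentorConfig",
    "ProbabilityMaps",
    "TeacherState",
    "build_segmentor",
    "build_edd",
    "forward_segmentor",
    "compose_predictions",
    "predict_labels",
    "edd_forward",
    "edd_output_shape",
    "upsample_scores",
    "ema_update",
    "predict_probs",
    "make_predictor",
    "make_teacher",
    "save_checkpoint",
    "load_checkpoint",
    "read_checkpoint_meta",
]


@dataclass(frozen=True)
class SegmentorConfig:
    backbone: str = "unet"
    base_width: int = 16
    depth: int = 3
    in_channels: int = 1
    multi_task: bool = True  # shared trunk emitting both heads
    vessel_channels: int = 2
    layer_channels: int = 3


@dataclass
class ProbabilityMaps:
    """Softmax outputs of the two heads (batch, channel, H, W).

    Either field may be None when a single-subtask segmentor ran.  Values may
    be autodiff Tensors (training) or plain arrays (inference).
    """

    layer_probs: object = None
    vessel_probs: object = None

    def numpy(self) -> "ProbabilityMaps":
        def _np(v):
            return v.data if isinstance(v, Tensor) else v
        return ProbabilityMaps(_np(self.layer_probs), _np(self.vessel_probs))


@dataclass
class TeacherState:
    """EMA copy of the student; never optimizer-updated, never differentiated."""

    model: Module
    ema_decay: float = 0.999


def build_segmentor(config: SegmentorConfig, rng: np.random.Generator,
                    subtask: str = "multi") -> Module:
    if config.backbone != "unet":
        raise ValueError(f"unknown backbone {config.backbone!r} (plug-ins register here)")
    if subtask == "multi":
        model = MultiTaskSegmentor(config.in_channels, rng,
                                   base=config.base_width, depth=config.depth)
    elif subtask == "vessel":
        model = SingleTaskSegmentor(config.in_channels, config.vessel_channels, rng,
                                    base=config.base_width, depth=config.depth)
    elif subtask == "layer":
        model = SingleTaskSegmentor(config.in_channels, config.layer_channels, rng,
                                    base=config.base_width, depth=config.depth)
    else:
        raise ValueError(f"unknown subtask {subtask!r}")
    model.subtask = subtask
    return model


def build_edd(in_channels: int, rng: np.random.Generator) -> EDD:
    return EDD(in_channels, rng)


def make_teacher(student: Module, ema_decay: float = 0.999) -> TeacherState:
    teacher = copy.deepcopy(student)
    teacher.freeze()  # gradients never flow into the teacher
    return TeacherState(model=teacher, ema_decay=ema_decay)


# ---------------------------------------------------------------------------
# forward passes
# ---------------------------------------------------------------------------

def _pad_to_multiple(x: np.ndarray, m: int) -> tuple[np.ndarray, tuple[int, int]]:
    h, w = x.shape[2], x.shape[3]
    ph = (-h) % m
    pw = (-w) % m
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="edge")
    return x, (h, w)


def forward_segmentor(model: Module, images: np.ndarray) -> ProbabilityMaps:
    """Run a segmentor on a batch (N, H, W) or (N, C, H, W).

    Pads internally to the backbone's divisibility requirement and crops the
    logits back, then softmax-normalizes each emitted head.
    """
    x = np.asarray(images, dtype=np.float32)
    if x.ndim == 3:
        x = x[:, None]
    x, (h, w) = _pad_to_multiple(x, 2 ** model.depth)
    out = model(Tensor(x))
    heads = out if isinstance(out, tuple) else (out,)
    probs = []
    for logit in heads:
        if not np.isfinite(logit.data).all():
            raise FloatingPointError("non-finite activations in segmentor head")
        if logit.data.shape[2] != h or logit.data.shape[3] != w:
            logit = crop2d(logit, 0, 0, h, w)
        probs.append(softmax(logit, axis=1))
    if isinstance(out, tuple):
        return ProbabilityMaps(layer_probs=probs[0], vessel_probs=probs[1])
    if model.n_classes == 2:
        return ProbabilityMaps(vessel_probs=probs[0])
    return ProbabilityMaps(layer_probs=probs[0])


def compose_predictions(layer_probs: np.ndarray, vessel_probs: np.ndarray) -> np.ndarray:
    """Compose subtask probabilities into the 3-class {bg, SV, HV} map.

    P(SV) = P(vessel) * P(SL); P(HV) = P(vessel) * P(HL);
    P(bg) = 1 - P(SV) - P(HV), renormalized against numeric drift.
    """
    layer_probs = np.asarray(layer_probs, dtype=np.float32)
    vessel_probs = np.asarray(vessel_probs, dtype=np.float32)
    if layer_probs.shape[-2:] != vessel_probs.shape[-2:]:
        raise ValueError("spatial shape mismatch between heads")
    ax = 0 if layer_probs.ndim == 3 else 1
    pl = np.moveaxis(layer_probs, ax, 0)
    pv = np.moveaxis(vessel_probs, ax, 0)
    sv = pv[1] * pl[1]
    hv = pv[1] * pl[2]
    bg = 1.0 - sv - hv
    composed = np.stack([bg, sv, hv])
    total = composed.sum(axis=0)
    drift = np.abs(total - 1.0)
    if drift.max() > 1e-6:
        composed = composed / total
    return np.moveaxis(composed, 0, ax).astype(np.float32)


def predict_labels(probs: np.ndarray, axis: int | None = None) -> np.ndarray:
    """Per-pixel argmax; ties resolve to the lowest class index."""
    probs = np.asarray(probs)
    if axis is None:
        axis = 0 if probs.ndim == 3 else 1
    return probs.argmax(axis=axis).astype(np.uint8)


def edd_forward(edd: EDD, prediction_map) -> tuple[Tensor, Tensor]:
    """Discriminator forward: returns (logits, sigmoid domain-score map S)."""
    x = prediction_map if isinstance(prediction_map, Tensor) else Tensor(
        np.asarray(prediction_map, dtype=np.float32))
    if x.ndim == 3:
        x = Tensor(x.data[None]) if not x._parents else x.reshape(1, *x.shape)
    logits = edd(x)
    return logits, logits.sigmoid()


def edd_output_shape(height: int, width: int) -> tuple[int, int]:
    """Conv-arithmetic spatial size of the EDD logit map."""
    h, w = height, width
    for s in EDD_STRIDES:
        h = conv_output_size(h, EDD_KERNEL, s, EDD_PADDING)
        w = conv_output_size(w, EDD_KERNEL, s, EDD_PADDING)
    return h, w


def upsample_scores(scores: np.ndarray, target_shape: tuple[int, int]) -> np.ndarray:
    """Bilinear (align-corners) upsampling of a coarse score map to pixel grid.

    Being a convex combination of inputs, the output range stays within the
    input range, so gate thresholds keep their meaning.
    """
    s = np.asarray(scores, dtype=np.float64)
    if s.ndim != 2:
        raise ValueError("expected a 2-D score map")
    th, tw = target_shape
    if th < s.shape[0] or tw < s.shape[1]:
        raise ValueError("target shape must be >= score-map shape")
    rows = np.linspace(0, s.shape[0] - 1, th)
    cols = np.linspace(0, s.shape[1] - 1, tw)
    r0 = np.floor(rows).astype(int)
    c0 = np.floor(cols).astype(int)
    r1 = np.minimum(r0 + 1, s.shape[0] - 1)
    c1 = np.minimum(c0 + 1, s.shape[1] - 1)
    fr = (rows - r0)[:, None]
    fc = (cols - c0)[None, :]
    out = (s[np.ix_(r0, c0)] * (1 - fr) * (1 - fc)
           + s[np.ix_(r1, c0)] * fr * (1 - fc)
           + s[np.ix_(r0, c1)] * (1 - fr) * fc
           + s[np.ix_(r1, c1)] * fr * fc)
    return out.astype(np.float32)


def ema_update(teacher: TeacherState, student: Module, decay: float | None = None) -> TeacherState:
    """teacher <- decay * teacher + (1 - decay) * student, parameter-wise."""
    decay = teacher.ema_decay if decay is None else decay
    tp = teacher.model.parameters()
    sp = student.parameters()
    if len(tp) != len(sp):
        raise ValueError("teacher/student parameter inventories differ")
    for t, s in zip(tp, sp):
        if t.data.shape != s.data.shape:
            raise ValueError(f"parameter shape mismatch {t.data.shape} vs {s.data.shape}")
        t.data = (decay * t.data + (1.0 - decay) * s.data).astype(np.float32)
    return teacher


# ---------------------------------------------------------------------------
# inference conveniences
# ---------------------------------------------------------------------------

def predict_probs(model: Module, image: np.ndarray) -> ProbabilityMaps:
    """Single-image inference returning plain numpy probability maps (C, H, W)."""
    pm = forward_segmentor(model, image[None]).numpy()
    def _sq(v):
        return None if v is None else v[0]
    return ProbabilityMaps(_sq(pm.layer_probs), _sq(pm.vessel_probs))


def make_predictor(multi_model: Module | None = None,
                   layer_model: Module | None = None,
                   vessel_model: Module | None = None):
    """Build `image -> (layer_probs, vessel_probs)` from trained segmentors."""
    if multi_model is not None:
        def predictor(image):
            pm = predict_probs(multi_model, image)
            return pm.layer_probs, pm.vessel_probs
    elif layer_model is not None and vessel_model is not None:
        def predictor(image):
            return (predict_probs(layer_model, image).layer_probs,
                    predict_probs(vessel_model, image).vessel_probs)
    else:
        raise ValueError("provide multi_model or both subtask models")
    return predictor


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(path: Path, student: Module, teacher: TeacherState | None,
                    edd: EDD | None, config: dict):
    arrays = {}
    for i, a in enumerate(student.state_arrays()):
        arrays[f"student_{i}"] = a
    if teacher is not None:
        for i, a in enumerate(teacher.model.state_arrays()):
            arrays[f"teacher_{i}"] = a
    if edd is not None:
        for i, a in enumerate(edd.state_arrays()):
            arrays[f"edd_{i}"] = a
    meta = {"version": CHECKPOINT_VERSION, "config": config,
            "has_teacher": teacher is not None, "has_edd": edd is not None,
            "ema_decay": None if teacher is None else teacher.ema_decay}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def read_checkpoint_meta(path: Path) -> dict:
    with np.load(path) as z:
        return json.loads(bytes(z["__meta__"]).decode())


def load_checkpoint(path: Path, student: Module, teacher: TeacherState | None = None,
                    edd: EDD | None = None) -> dict:
    """Restore parameters in place; returns the stored config/meta dict."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        def _collect(prefix):
            keys = sorted((k for k in z.files if k.startswith(prefix)),
                          key=lambda k: int(k.rsplit("_", 1)[1]))
            return [z[k] for k in keys]
        student.load_state_arrays(_collect("student_"))
        if teacher is not None and meta["has_teacher"]:
            teacher.model.load_state_arrays(_collect("teacher_"))
        if edd is not None and meta["has_edd"]:
            edd.load_state_arrays(_collect("edd_"))
    return meta
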