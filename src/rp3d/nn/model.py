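"""The 3-D Inception-ResNet recurrence-volume classifier.

Layout (lead axis = depth D, recurrence axes = H, W; the input volume
is a single feature channel):

* Stem — 3x3x3 (stride 1,2,2), max-pool, 1x1x1, 1x1x7, 1x7x1, 3x3x3,
  max-pool. The two pools and the strided conv shrink only H and W;
  the lead axis is mixed by the 3x3x3 kernels but never pooled (3
  leads in VCG mode leave no room).
* Inception-ResNet A blocks — 1x1x1 and 3x3x3 branches, concatenated,
  linearly projected back to the trunk width and added as a scaled
  residual (scale 0.2 by default, the usual stabilizer).
* Reduction A — parallel max-pool / strided 3x3x3 branches, halving
  H and W and widening the trunk.
* B blocks — 1x1x1 branch plus a 1x1x7 -> 1x7x1 asymmetric branch.
* Reduction B.
* C blocks — 1x1x1 branch plus 1x1x3 -> 1x3x1 asymmetric branch.
* Head — 3-D global average pooling, dropout, dense, softmax.

Kernel inventory and block ordering are fixed; per-stage widths and
block repeat counts are configuration, since only the kernel shapes
of the reference architecture are pinned down. ``tiny_config`` is the
desk-scale preset used throughout the tests; ``paper_scale_config``
targets a tens-of-millions-parameter build of the same shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
from pathlib import Path

import numpy as np

from .layers import (BatchNorm3d, Conv3d, Dense, Dropout, GlobalAvgPool3d,
                     Layer, MaxPool3d, ReLU, Sequential)

__all__ = ["ModelConfig", "tiny_config", "paper_scale_config", "build_model",
           "count_parameters", "predict", "Classifier", "softmax"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture knobs. ``input_shape`` is (leads, H, W)."""

    input_shape: tuple[int, int, int] = (3, 64, 64)
    n_classes: int = 4
    stem_widths: tuple[int, int, int] = (8, 12, 16)
    block_widths: tuple[int, int, int] = (8, 12, 16)      # A, B, C
    reduction_widths: tuple[int, int] = (16, 24)          # Reduction A, B
    block_repeats: tuple[int, int, int] = (1, 1, 1)       # nA, nB, nC
    residual_scale: float = 0.2
    dropout: float = 0.2
    head_init: str = "random"                             # random | zero
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError(f"n_classes must be >= 2, got {self.n_classes}")
        if not 0 < self.residual_scale <= 1:
            raise ValueError(f"residual_scale must be in (0, 1], got {self.residual_scale}")
        for w in (*self.stem_widths, *self.block_widths, *self.reduction_widths):
            if w < 1:
                raise ValueError(f"all widths must be >= 1, got {w}")
        if any(r < 0 for r in self.block_repeats):
            raise ValueError(f"block_repeats must be >= 0, got {self.block_repeats}")
        if self.head_init not in ("random", "zero"):
            raise ValueError(f"head_init must be 'random' or 'zero', got {self.head_init!r}")


def tiny_config(input_shape=(3, 64, 64), **overrides) -> ModelConfig:
    """Desk-scale preset: trains on a CPU in minutes."""
    return ModelConfig(input_shape=tuple(input_shape), **overrides)


def paper_scale_config(input_shape=(12, 128, 128), **overrides) -> ModelConfig:
    """A full-size build of the same architecture (order of tens of
    millions of parameters). Width/repeat choices follow the usual
    Inception-ResNet-v2 proportions; exact parameter-count parity with
    any published build is not claimed.
    """
    kw = dict(stem_widths=(64, 96, 192), block_widths=(96, 160, 224),
              reduction_widths=(256, 288), block_repeats=(5, 10, 5),
              dropout=0.2)
    kw.update(overrides)
    return ModelConfig(input_shape=tuple(input_shape), **kw)


def _conv_bn_relu(c_in, c_out, kernel, rng, dtype, name, stride=1, padding="same"):
    return Sequential(
        Conv3d(c_in, c_out, kernel, stride=stride, padding=padding, bias=False,
               rng=rng, dtype=dtype, name=f"{name}.conv"),
        BatchNorm3d(c_out, dtype=dtype, name=f"{name}.bn"),
        ReLU(),
        name=name,
    )


class InceptionResidual(Layer):
    """Multi-branch block with a scaled additive residual shortcut.

    branch outputs are concatenated on the channel axis, linearly
    projected back to the trunk width (1x1x1 conv, bias, no BN/ReLU)
    and added to the input as ``x + scale * proj``; ReLU follows.
    """

    def __init__(self, branches: list[Sequential], proj: Conv3d, scale: float,
                 name: str = "incres"):
        self.branches = branches
        self.proj = proj
        self.scale = scale
        self.name = name

    def forward(self, x, training=False):
        outs = [b.forward(x, training) for b in self.branches]
        self._splits = np.cumsum([o.shape[1] for o in outs])[:-1]
        cat = np.concatenate(outs, axis=1)
        y = x + self.scale * self.proj.forward(cat, training)
        self._mask = y > 0
        return y * self._mask

    def backward(self, grad):
        grad = grad * self._mask
        dcat = self.proj.backward(self.scale * grad)
        dx = grad.copy()
        for branch, dpart in zip(self.branches, np.split(dcat, self._splits, axis=1)):
            dx += branch.backward(np.ascontiguousarray(dpart))
        return dx

    def parameters(self):
        for b in self.branches:
            yield from b.parameters()
        yield from self.proj.parameters()

    def set_rng(self, rng):
        for b in self.branches:
            b.set_rng(rng)


class Reduction(Layer):
    """Parallel downsampling branches concatenated on channels."""

    def __init__(self, branches: list[Layer], name: str = "reduction"):
        self.branches = branches
        self.name = name

    def forward(self, x, training=False):
        outs = [b.forward(x, training) for b in self.branches]
        shapes = {o.shape[2:] for o in outs}
        if len(shapes) != 1:
            raise ValueError(f"{self.name}: branch output shapes disagree "
                             f"({shapes}); use even H/W at reductions")
        self._splits = np.cumsum([o.shape[1] for o in outs])[:-1]
        return np.concatenate(outs, axis=1)

    def backward(self, grad):
        parts = np.split(grad, self._splits, axis=1)
        dx = None
        for branch, dpart in zip(self.branches, parts):
            g = branch.backward(np.ascontiguousarray(dpart))
            dx = g if dx is None else dx + g
        return dx

    def parameters(self):
        for b in self.branches:
            yield from b.parameters()

    def set_rng(self, rng):
        for b in self.branches:
            b.set_rng(rng)


class Classifier:
    """Config + layer stack + the softmax prediction surface."""

    def __init__(self, cfg: ModelConfig, net: Sequential):
        self.cfg = cfg
        self.net = net
        self._rng = np.random.default_rng(0)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Logits [N, n_classes] from volumes [N, D, H, W] or [N, 1, D, H, W]."""
        x = np.asarray(x, dtype=self.net_dtype)
        if x.ndim == 4:
            x = x[:, None]
        if x.shape[2:] != tuple(self.cfg.input_shape):
            raise ValueError(f"expected volumes of shape {self.cfg.input_shape}, "
                             f"got {x.shape[2:]}")
        return self.net.forward(x, training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.net.backward(grad)

    def parameters(self):
        return self.net.parameters()

    def set_rng(self, rng: np.random.Generator) -> None:
        self._rng = rng
        self.net.set_rng(rng)

    @property
    def net_dtype(self):
        return np.dtype(self.cfg.dtype)

    # --- persistence -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: value for name, value, _ in self.parameters()}
        for i, layer in enumerate(_walk(self.net)):
            if isinstance(layer, BatchNorm3d):
                state[f"__bn{i}.mean"] = layer.running_mean
                state[f"__bn{i}.var"] = layer.running_var
        return state

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for name, value, _ in self.parameters():
            value[...] = state[name]
        for i, layer in enumerate(_walk(self.net)):
            if isinstance(layer, BatchNorm3d):
                layer.running_mean[...] = state[f"__bn{i}.mean"]
                layer.running_var[...] = state[f"__bn{i}.var"]

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path, __config=json.dumps(asdict(self.cfg)),
                 **{k: v for k, v in self.state_dict().items()})
        return path

    @classmethod
    def load(cls, path: str | Path) -> "Classifier":
        with np.load(Path(path), allow_pickle=False) as data:
            cfg_raw = json.loads(str(data["__config"]))
            for key in ("input_shape", "stem_widths", "block_widths",
                        "reduction_widths", "block_repeats"):
                cfg_raw[key] = tuple(cfg_raw[key])
            cfg = ModelConfig(**cfg_raw)
            model = build_model(cfg, seed=0)
            model.load_state({k: data[k] for k in data.files if k != "__config"})
        return model


def _walk(layer: Layer):
    yield layer
    for attr in ("layers", "branches"):
        for child in getattr(layer, attr, []):
            yield from _walk(child)
    if hasattr(layer, "proj"):
        yield from _walk(layer.proj)


def _a_block(c, w, scale, rng, dtype, name):
    branches = [
        _conv_bn_relu(c, w, 1, rng, dtype, f"{name}.b0"),
        Sequential(_conv_bn_relu(c, w, 1, rng, dtype, f"{name}.b1a"),
                   _conv_bn_relu(w, w, 3, rng, dtype, f"{name}.b1b")),
        Sequential(_conv_bn_relu(c, w, 1, rng, dtype, f"{name}.b2a"),
                   _conv_bn_relu(w, w, 3, rng, dtype, f"{name}.b2b"),
                   _conv_bn_relu(w, w, 3, rng, dtype, f"{name}.b2c")),
    ]
    proj = Conv3d(3 * w, c, 1, rng=rng, dtype=dtype, name=f"{name}.proj")
    return InceptionResidual(branches, proj, scale, name=name)


def _b_block(c, w, scale, rng, dtype, name):
    branches = [
        _conv_bn_relu(c, w, 1, rng, dtype, f"{name}.b0"),
        Sequential(_conv_bn_relu(c, w, 1, rng, dtype, f"{name}.b1a"),
                   _conv_bn_relu(w, w, (1, 1, 7), rng, dtype, f"{name}.b1b"),
                   _conv_bn_relu(w, w, (1, 7, 1), rng, dtype, f"{name}.b1c")),
    ]
    proj = Conv3d(2 * w, c, 1, rng=rng, dtype=dtype, name=f"{name}.proj")
    return InceptionResidual(branches, proj, scale, name=name)


def _c_block(c, w, scale, rng, dtype, name):
    branches = [
        _conv_bn_relu(c, w, 1, rng, dtype, f"{name}.b0"),
        Sequential(_conv_bn_relu(c, w, 1, rng, dtype, f"{name}.b1a"),
                   _conv_bn_relu(w, w, (1, 1, 3), rng, dtype, f"{name}.b1b"),
                   _conv_bn_relu(w, w, (1, 3, 1), rng, dtype, f"{name}.b1c")),
    ]
    proj = Conv3d(2 * w, c, 1, rng=rng, dtype=dtype, name=f"{name}.proj")
    return InceptionResidual(branches, proj, scale, name=name)


def build_model(cfg: ModelConfig, seed: int = 0) -> Classifier:
    """Assemble the classifier with He-initialized weights.

    Raises a shape error naming the offending stage if H/W collapse
    below 1 before the head (the stem divides H and W by 8).
    """
    rng = np.random.default_rng(seed)
    dtype = np.dtype(cfg.dtype)
    s1, s2, s3 = cfg.stem_widths
    wa, wb, wc = cfg.block_widths
    ra, rb = cfg.reduction_widths
    nA, nB, nC = cfg.block_repeats
    scale = cfg.residual_scale

    stages: list[Layer] = [
        _conv_bn_relu(1, s1, 3, rng, dtype, "stem.conv1", stride=(1, 2, 2)),
        MaxPool3d((1, 2, 2), name="stem.pool1"),
        _conv_bn_relu(s1, s2, 1, rng, dtype, "stem.conv2"),
        _conv_bn_relu(s2, s2, (1, 1, 7), rng, dtype, "stem.conv3"),
        _conv_bn_relu(s2, s2, (1, 7, 1), rng, dtype, "stem.conv4"),
        _conv_bn_relu(s2, s3, 3, rng, dtype, "stem.conv5"),
        MaxPool3d((1, 2, 2), name="stem.pool2"),
    ]
    c = s3
    for i in range(nA):
        stages.append(_a_block(c, wa, scale, rng, dtype, f"incresA{i}"))
    if nA or nB or nC:
        stages.append(Reduction([
            MaxPool3d((1, 2, 2), name="redA.pool"),
            _conv_bn_relu(c, ra, 3, rng, dtype, "redA.b1", stride=(1, 2, 2)),
            Sequential(_conv_bn_relu(c, ra, 1, rng, dtype, "redA.b2a"),
                       _conv_bn_relu(ra, ra, 3, rng, dtype, "redA.b2b"),
                       _conv_bn_relu(ra, ra, 3, rng, dtype, "redA.b2c",
                                     stride=(1, 2, 2))),
        ], name="reductionA"))
        c = c + 2 * ra
    for i in range(nB):
        stages.append(_b_block(c, wb, scale, rng, dtype, f"incresB{i}"))
    if nB or nC:
        stages.append(Reduction([
            MaxPool3d((1, 2, 2), name="redB.pool"),
            Sequential(_conv_bn_relu(c, rb, 1, rng, dtype, "redB.b1a"),
                       _conv_bn_relu(rb, rb, 3, rng, dtype, "redB.b1b",
                                     stride=(1, 2, 2))),
            Sequential(_conv_bn_relu(c, rb, 1, rng, dtype, "redB.b2a"),
                       _conv_bn_relu(rb, rb, (1, 1, 7), rng, dtype, "redB.b2b"),
                       _conv_bn_relu(rb, rb, (1, 7, 1), rng, dtype, "redB.b2c"),
                       _conv_bn_relu(rb, rb, 3, rng, dtype, "redB.b2d",
                                     stride=(1, 2, 2))),
        ], name="reductionB"))
        c = c + 2 * rb
    for i in range(nC):
        stages.append(_c_block(c, wc, scale, rng, dtype, f"incresC{i}"))
    stages += [
        GlobalAvgPool3d(),
        Dropout(cfg.dropout),
        Dense(c, cfg.n_classes, rng=rng, dtype=dtype,
              zero_init=(cfg.head_init == "zero"), name="head"),
    ]
    model = Classifier(cfg, Sequential(*stages, name="rp3d"))
    # Fail fast on geometries the stem cannot survive.
    model.forward(np.zeros((1, *cfg.input_shape), dtype=dtype))
    return model


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def count_parameters(model) -> int:
    """Number of trainable scalars (frozen layers excluded)."""
    return int(sum(v.size for _, v, _ in model.parameters()))


def predict(model: Classifier, volumes: np.ndarray, batch_size: int = 64
            ) -> tuple[np.ndarray, np.ndarray]:
    """Eval-mode class probabilities and argmax labels.

    Probabilities are softmax rows summing to 1; ties break toward
    the lowest class index (argmax convention).
    """
    vols = np.asarray(volumes)
    probs = []
    for i in range(0, len(vols), batch_size):
        probs.append(softmax(model.forward(vols[i:i + batch_size], training=False)))
    p = np.concatenate(probs) if probs else np.zeros((0, model.cfg.n_classes))
    return p, p.argmax(axis=1)
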