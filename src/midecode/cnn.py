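"""Mega Block CNN architectures for spectrogram-image decoding.

Two fixed families are provided:

* ``arch1`` (intra-subject): conv16(3x3)/BN/ReLU -> maxpool(3x3, s2) ->
  conv32 -> maxpool -> conv64 -> avgpool(8x8, s1) -> dense -> softmax(2).
* ``arch2`` (inter-subject): three *Mega Blocks* — conv/BN/ReLU blocks with
  9, 18, 36 filters (kernels 5x5, 3x3, 3x3) each repeated 1-5 times with
  identical hyperparameters — interleaved with the same pooling stack.

Convolutions use "same" zero padding and stride 1; max pooling uses
ceil-mode output sizing (windows may overhang, padded with -inf).  Under
these conventions a 40x32x3 input flattens to 192 features for arch1 and
108 for arch2, independent of the Mega Block repeat counts.

The numeric model (`CNNModel`) is a self-contained numpy implementation
with explicit forward/backward passes; it exists so the optimizer update
rules operate on raw parameter arrays and every gradient is inspectable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

INPUT_SHAPE = (40, 32, 3)
N_CLASSES = 2
MAX_REPEATS = 5


class ShapeError(ValueError):
    """A layer's output would have a non-positive dimension."""


# ---------------------------------------------------------------------------
# declarative specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConvBlockSpec:
    """conv -> batch norm -> ReLU with same padding, stride (1, 1)."""

    n_filters: int
    kernel: tuple[int, int]
    stride: tuple[int, int] = (1, 1)
    l2: float = 0.0
    batch_norm_epsilon: float = 1e-5

    def __post_init__(self) -> None:
        if self.n_filters < 1:
            raise ValueError("n_filters must be >= 1")
        if any(k % 2 == 0 or k < 1 for k in self.kernel):
            raise ValueError(f"kernel dims must be odd, got {self.kernel}")


@dataclass(frozen=True)
class MegaBlock:
    """A conv block repeated 1-5 times with identical hyperparameters."""

    block: ConvBlockSpec
    repeats: int = 1

    def __post_init__(self) -> None:
        if not 1 <= self.repeats <= MAX_REPEATS:
            raise ValueError(
                f"Mega Block repeats must be in 1..{MAX_REPEATS}, "
                f"got {self.repeats}"
            )


@dataclass(frozen=True)
class MaxPoolSpec:
    kernel: tuple[int, int] = (3, 3)
    stride: tuple[int, int] = (2, 2)


@dataclass(frozen=True)
class AvgPoolSpec:
    kernel: tuple[int, int] = (8, 8)
    stride: tuple[int, int] = (1, 1)


Stage = Union[MegaBlock, MaxPoolSpec, AvgPoolSpec]


@dataclass(frozen=True)
class ArchitectureSpec:
    """Full network description ending in avgpool -> dense -> softmax."""

    stages: tuple[Stage, ...]
    input_shape: tuple[int, int, int] = INPUT_SHAPE
    n_classes: int = N_CLASSES
    name: str = "custom"

    def __post_init__(self) -> None:
        if not self.stages or not isinstance(self.stages[-1], AvgPoolSpec):
            raise ValueError("architecture must end with an average-pool stage "
                             "(followed by the implicit dense/softmax head)")

    @property
    def flatten_size(self) -> int:
        return int(np.prod(shape_trace(self)[-1][1]))

    def to_dict(self) -> dict:
        """Human-readable serialization (round-trips via from_dict)."""
        stages = []
        for st in self.stages:
            if isinstance(st, MegaBlock):
                stages.append({
                    "type": "mega_block", "repeats": st.repeats,
                    "n_filters": st.block.n_filters,
                    "kernel": list(st.block.kernel), "l2": st.block.l2,
                    "batch_norm_epsilon": st.block.batch_norm_epsilon,
                })
            elif isinstance(st, MaxPoolSpec):
                stages.append({"type": "maxpool", "kernel": list(st.kernel),
                               "stride": list(st.stride)})
            else:
                stages.append({"type": "avgpool", "kernel": list(st.kernel),
                               "stride": list(st.stride)})
        return {"name": self.name, "input_shape": list(self.input_shape),
                "n_classes": self.n_classes, "stages": stages}

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        stages: list[Stage] = []
        for st in d["stages"]:
            if st["type"] == "mega_block":
                stages.append(MegaBlock(
                    ConvBlockSpec(st["n_filters"], tuple(st["kernel"]),
                                  l2=st.get("l2", 0.0),
                                  batch_norm_epsilon=st.get(
                                      "batch_norm_epsilon", 1e-5)),
                    repeats=st["repeats"]))
            elif st["type"] == "maxpool":
                stages.append(MaxPoolSpec(tuple(st["kernel"]), tuple(st["stride"])))
            else:
                stages.append(AvgPoolSpec(tuple(st["kernel"]), tuple(st["stride"])))
        return cls(stages=tuple(stages), input_shape=tuple(d["input_shape"]),
                   n_classes=d.get("n_classes", N_CLASSES),
                   name=d.get("name", "custom"))


#: default weight-decay coefficient for arch1 conv/dense weights
ARCH1_L2 = 0.0014


def build_architecture(variant: str,
                       repeats: Sequence[int] | None = None,
                       l2: float = ARCH1_L2) -> ArchitectureSpec:
    """Construct one of the two reference architectures.

    ``arch1`` ignores ``repeats``; ``arch2`` takes the three Mega Block
    repeat counts (r1, r2, r3), each in 1..5.
    """
    if variant == "arch1":
        stages: tuple[Stage, ...] = (
            MegaBlock(ConvBlockSpec(16, (3, 3), l2=l2)),
            MaxPoolSpec(),
            MegaBlock(ConvBlockSpec(32, (3, 3), l2=l2)),
            MaxPoolSpec(),
            MegaBlock(ConvBlockSpec(64, (3, 3), l2=l2)),
            AvgPoolSpec(),
        )
        return ArchitectureSpec(stages=stages, name="arch1")
    if variant == "arch2":
        if repeats is None:
            repeats = (1, 1, 1)
        if len(repeats) != 3:
            raise ValueError("arch2 needs three Mega Block repeat counts")
        r1, r2, r3 = (int(r) for r in repeats)
        stages = (
            MegaBlock(ConvBlockSpec(9, (5, 5), l2=l2), repeats=r1),
            MaxPoolSpec(),
            MegaBlock(ConvBlockSpec(18, (3, 3), l2=l2), repeats=r2),
            MaxPoolSpec(),
            MegaBlock(ConvBlockSpec(36, (3, 3), l2=l2), repeats=r3),
            AvgPoolSpec(),
        )
        return ArchitectureSpec(stages=stages, name=f"arch2[{r1},{r2},{r3}]")
    raise ValueError(f"unknown variant {variant!r}; expected 'arch1' or 'arch2'")


# ---------------------------------------------------------------------------
# shape tracing and parameter audit
# ---------------------------------------------------------------------------

def _pool_out(size: int, kernel: int, stride: int) -> int:
    # ceil-mode output sizing
    return int(np.ceil((size - kernel) / stride)) + 1


def shape_trace(arch: ArchitectureSpec) -> list[tuple[str, tuple[int, ...]]]:
    """Per-layer output shapes (H, W, C), ending at the flatten point.

    Raises :class:`ShapeError` naming the first layer whose output would
    collapse below one along any axis.
    """
    h, w, c = arch.input_shape
    trace: list[tuple[str, tuple[int, ...]]] = [("input", (h, w, c))]
    for i, st in enumerate(arch.stages):
        if isinstance(st, MegaBlock):
            for r in range(st.repeats):
                # same padding, stride 1: spatial dims unchanged
                c = st.block.n_filters
                trace.append((f"stage{i}.conv{r}", (h, w, c)))
        else:
            kind = "maxpool" if isinstance(st, MaxPoolSpec) else "avgpool"
            if isinstance(st, MaxPoolSpec):
                h2 = _pool_out(h, st.kernel[0], st.stride[0])
                w2 = _pool_out(w, st.kernel[1], st.stride[1])
            else:  # valid average pooling
                h2 = (h - st.kernel[0]) // st.stride[0] + 1
                w2 = (w - st.kernel[1]) // st.stride[1] + 1
            if h2 < 1 or w2 < 1:
                raise ShapeError(
                    f"stage{i} ({kind}) output {h2}x{w2} from input {h}x{w}")
            h, w = h2, w2
            trace.append((f"stage{i}.{kind}", (h, w, c)))
    trace.append(("flatten", (h * w * c,)))
    return trace


def parameter_audit(arch: ArchitectureSpec) -> list[tuple[str, int]]:
    """Per-layer trainable parameter counts.

    Convention: conv kernels + biases, batch-norm scale + offset, dense
    weights + biases — every tensor the optimizer updates.  Running batch
    statistics are buffers, not parameters.
    """
    rows: list[tuple[str, int]] = []
    c_in = arch.input_shape[2]
    for i, st in enumerate(arch.stages):
        if isinstance(st, MegaBlock):
            kh, kw = st.block.kernel
            for r in range(st.repeats):
                f = st.block.n_filters
                rows.append((f"stage{i}.conv{r}", kh * kw * c_in * f + f))
                rows.append((f"stage{i}.bn{r}", 2 * f))
                c_in = f
    flat = int(np.prod(shape_trace(arch)[-1][1]))
    rows.append(("dense", flat * arch.n_classes + arch.n_classes))
    return rows


def count_parameters(arch: ArchitectureSpec) -> int:
    """Total trainable parameters under the audited convention."""
    return sum(n for _, n in parameter_audit(arch))


# ---------------------------------------------------------------------------
# numeric layers
# ---------------------------------------------------------------------------

def _conv2d_same(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Stride-1 'same' cross-correlation.  x: (N,H,W,Cin), w: (kh,kw,Cin,Cout)."""
    kh, kw = w.shape[:2]
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    cols = sliding_window_view(xp, (kh, kw), axis=(1, 2))  # N,H,W,C,kh,kw
    n, h, wd = cols.shape[:3]
    cols = cols.reshape(n * h * wd, -1)  # flattened (C, kh, kw) order
    wmat = w.transpose(2, 0, 1, 3).reshape(-1, w.shape[3])
    return (cols @ wmat).reshape(n, h, wd, w.shape[3])


class _Conv:
    def __init__(self, kh, kw, c_in, c_out, l2, rng, dtype):
        fan_in = kh * kw * c_in
        bound = 1.0 / np.sqrt(fan_in)
        self.w = rng.uniform(-bound, bound, (kh, kw, c_in, c_out)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.l2 = l2
        self.params = [self.w, self.b]

    def forward(self, x, training):
        self._x = x
        return _conv2d_same(x, self.w) + self.b

    def backward(self, dout):
        x = self._x
        kh, kw, c_in, c_out = self.w.shape
        ph, pw = kh // 2, kw // 2
        xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
        cols = sliding_window_view(xp, (kh, kw), axis=(1, 2))
        n, h, wd = cols.shape[:3]
        cols = cols.reshape(n * h * wd, -1)
        dmat = dout.reshape(n * h * wd, c_out)
        dw = (cols.T @ dmat).reshape(c_in, kh, kw, c_out).transpose(1, 2, 0, 3)
        db = dmat.sum(axis=0)
        # dx: same-padded correlation with the 180-degree-rotated kernel
        w_rot = self.w[::-1, ::-1].transpose(0, 1, 3, 2)
        dx = _conv2d_same(dout, w_rot)
        self.grads = [dw.astype(self.w.dtype), db.astype(self.b.dtype)]
        return dx


class _BatchNorm:
    """Channel-wise batch normalization over (N, H, W)."""

    def __init__(self, c, eps, dtype):
        self.gamma = np.ones(c, dtype=dtype)
        self.beta = np.zeros(c, dtype=dtype)
        self.eps = eps
        self.momentum = 0.9
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.params = [self.gamma, self.beta]

    def forward(self, x, training):
        axes = (0, 1, 2)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(
                self.running_mean.dtype)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(
                self.running_var.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._training = training
        return self.gamma * self._xhat + self.beta

    def backward(self, dout):
        axes = (0, 1, 2)
        xhat, std = self._xhat, self._std
        dgamma = (dout * xhat).sum(axis=axes)
        dbeta = dout.sum(axis=axes)
        self.grads = [dgamma.astype(self.gamma.dtype),
                      dbeta.astype(self.beta.dtype)]
        dxhat = dout * self.gamma
        if not self._training:
            return dxhat / std
        m = np.prod([dout.shape[a] for a in axes])
        return (dxhat - dxhat.mean(axis=axes)
                - xhat * (dxhat * xhat).mean(axis=axes)) / std


class _ReLU:
    params: list = []

    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        self.grads = []
        return dout * self._mask


class _MaxPool:
    """Ceil-mode max pooling; overhanging windows padded with -inf."""

    def __init__(self, kernel, stride):
        self.kh, self.kw = kernel
        self.sh, self.sw = stride
        self.params = []

    def forward(self, x, training):
        n, h, w, c = x.shape
        oh = _pool_out(h, self.kh, self.sh)
        ow = _pool_out(w, self.kw, self.sw)
        hp = (oh - 1) * self.sh + self.kh
        wp = (ow - 1) * self.sw + self.kw
        xp = np.full((n, hp, wp, c), -np.inf, dtype=x.dtype)
        xp[:, :h, :w, :] = x
        wins = sliding_window_view(xp, (self.kh, self.kw), axis=(1, 2))
        wins = wins[:, ::self.sh, ::self.sw]  # N,oh,ow,C,kh,kw
        flat = wins.reshape(n, oh, ow, c, self.kh * self.kw)
        self._argmax = flat.argmax(axis=-1)
        self._in_shape = (n, h, w, c)
        self._pad_shape = (n, hp, wp, c)
        return flat.max(axis=-1)

    def backward(self, dout):
        n, h, w, c = self._in_shape
        dxp = np.zeros(self._pad_shape, dtype=dout.dtype)
        oh, ow = dout.shape[1:3]
        ni, oi, oj, ci = np.indices((n, oh, ow, c))
        ri = oi * self.sh + self._argmax // self.kw
        rj = oj * self.sw + self._argmax % self.kw
        np.add.at(dxp, (ni, ri, rj, ci), dout)
        self.grads = []
        return dxp[:, :h, :w, :]


class _AvgPool:
    """Valid average pooling (the 8x8 stride-1 head: 10x8 -> 3x1)."""

    def __init__(self, kernel, stride):
        self.kh, self.kw = kernel
        self.sh, self.sw = stride
        self.params = []

    def forward(self, x, training):
        n, h, w, c = x.shape
        oh = (h - self.kh) // self.sh + 1
        ow = (w - self.kw) // self.sw + 1
        out = np.empty((n, oh, ow, c), dtype=x.dtype)
        for i in range(oh):
            for j in range(ow):
                out[:, i, j] = x[:, i * self.sh:i * self.sh + self.kh,
                                 j * self.sw:j * self.sw + self.kw].mean(axis=(1, 2))
        self._in_shape = x.shape
        return out

    def backward(self, dout):
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        oh, ow = dout.shape[1:3]
        scale = 1.0 / (self.kh * self.kw)
        for i in range(oh):
            for j in range(ow):
                dx[:, i * self.sh:i * self.sh + self.kh,
                   j * self.sw:j * self.sw + self.kw] += (
                    dout[:, i, j][:, None, None, :] * scale)
        self.grads = []
        return dx


class _Flatten:
    params: list = []

    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        self.grads = []
        return dout.reshape(self._shape)


class _Dense:
    def __init__(self, n_in, n_out, l2, rng, dtype):
        bound = 1.0 / np.sqrt(n_in)
        self.w = rng.uniform(-bound, bound, (n_in, n_out)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.l2 = l2
        self.params = [self.w, self.b]

    def forward(self, x, training):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout):
        self.grads = [(self._x.T @ dout).astype(self.w.dtype),
                      dout.sum(axis=0).astype(self.b.dtype)]
        return dout @ self.w.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class CNNModel:
    """Instantiated network: ordered layers with parameters and gradients."""

    def __init__(self, arch: ArchitectureSpec, rng: np.random.Generator,
                 dtype=np.float32):
        self.arch = arch
        self.dtype = np.dtype(dtype)
        shape_trace(arch)  # validate before allocating
        self.layers: list = []
        c_in = arch.input_shape[2]
        for st in arch.stages:
            if isinstance(st, MegaBlock):
                kh, kw = st.block.kernel
                for _ in range(st.repeats):
                    self.layers.append(_Conv(kh, kw, c_in, st.block.n_filters,
                                             st.block.l2, rng, self.dtype))
                    self.layers.append(_BatchNorm(st.block.n_filters,
                                                  st.block.batch_norm_epsilon,
                                                  self.dtype))
                    self.layers.append(_ReLU())
                    c_in = st.block.n_filters
            elif isinstance(st, MaxPoolSpec):
                self.layers.append(_MaxPool(st.kernel, st.stride))
            else:
                self.layers.append(_AvgPool(st.kernel, st.stride))
        self.layers.append(_Flatten())
        flat = int(np.prod(shape_trace(arch)[-1][1]))
        head_l2 = next((st.block.l2 for st in arch.stages
                        if isinstance(st, MegaBlock)), 0.0)
        self.layers.append(_Dense(flat, arch.n_classes, head_l2, rng, self.dtype))

    # -- parameter plumbing -------------------------------------------------
    @property
    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def set_parameters(self, new: Sequence[np.ndarray]) -> None:
        it = iter(new)
        for layer in self.layers:
            for i in range(len(layer.params)):
                arr = next(it)
                layer.params[i][...] = arr
        # rebind named attributes (params hold the live arrays already)

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def l2_penalty_terms(self) -> list[tuple[np.ndarray, float]]:
        """(weight array, coefficient) pairs for conv/dense kernels only."""
        out = []
        for layer in self.layers:
            if isinstance(layer, (_Conv, _Dense)) and layer.l2:
                out.append((layer.w, layer.l2))
        return out

    # -- passes -------------------------------------------------------------
    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1:] != self.arch.input_shape:
            raise ValueError(f"expected images of shape {self.arch.input_shape}, "
                             f"got {x.shape[1:]}")
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits.astype(self.dtype)
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 3:
            x = x[None]
        out = [softmax(self.forward_logits(x[i:i + batch_size]))
               for i in range(0, len(x), batch_size)]
        return np.concatenate(out, axis=0)


def forward_classify(model: CNNModel, images: np.ndarray) -> np.ndarray:
    """Per-class probabilities for a batch of 40x32x3 images."""
    return model.predict_proba(images)
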