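"""Optimizers and training loop.

The two update rules are implemented exactly as written:

SGD with momentum (no dampening, no Nesterov)::

    v_{t+1} = mu * v_t - eta * g_t
    theta_{t+1} = theta_t + v_{t+1}

Adam with bias correction::

    m_t = beta1 * m_{t-1} + (1 - beta1) * g_t
    v_t = beta2 * v_{t-1} + (1 - beta2) * g_t^2
    theta_{t+1} = theta_t - eta * mhat_t / (sqrt(vhat_t) + eps)

where mhat = m / (1 - beta1^t), vhat = v / (1 - beta2^t) and eps is added
to the square-rooted bias-corrected second moment.

Both operate on a flat list of parameter arrays and return updated copies
plus the new optimizer state, so single steps can be checked against hand
iteration on scalars.

`fit` trains a :class:`~midecode.cnn.CNNModel` on labeled segment images:
seeded shuffled mini-batches, L2 weight decay on conv/dense kernels, a
piecewise-constant learning-rate schedule (drop by ``lr_drop_factor``
every ``lr_drop_period`` epochs), and a held-out validation monitor split
(no early stopping).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .cnn import ArchitectureSpec, CNNModel, softmax

ParamList = list[np.ndarray]


class TrainingDiverged(RuntimeError):
    """Loss became non-finite during training."""


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def cross_entropy_loss(predicted: np.ndarray, targets: np.ndarray,
                       tol: float = 1e-6) -> float:
    """Mean negative log-likelihood  -(1/N) sum_i sum_j t_ij ln y_ij.

    ``predicted`` must be row-normalized probabilities, ``targets`` one-hot
    rows of the same shape.  Returns 0 iff every row puts mass 1 on its
    true class; a uniform two-class prediction costs ln 2 per sample.
    """
    predicted = np.asarray(predicted, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    if predicted.shape != targets.shape:
        raise ValueError(f"shape mismatch {predicted.shape} vs {targets.shape}")
    rowsum = predicted.sum(axis=-1)
    if np.any(np.abs(rowsum - 1.0) > tol) or np.any(predicted < -tol):
        raise ValueError("predictions are not normalized probabilities")
    eps = np.finfo(np.float64).tiny
    return float(-(targets * np.log(np.maximum(predicted, eps))).sum()
                 / predicted.shape[0])


def _as_list(x) -> tuple[ParamList, bool]:
    if isinstance(x, (list, tuple)):
        return [np.asarray(a, dtype=np.float64) if np.isscalar(a) else a
                for a in x], False
    return [np.asarray(x)], True


# ---------------------------------------------------------------------------
# SGDM
# ---------------------------------------------------------------------------

@dataclass
class SGDMState:
    learning_rate: float
    momentum: float = 0.9
    velocity: ParamList | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")


def sgdm_step(params, grads, state: SGDMState):
    """One momentum update; returns (new_params, new_state)."""
    plist, single = _as_list(params)
    glist, _ = _as_list(grads)
    if len(plist) != len(glist) or any(
            p.shape != g.shape for p, g in zip(plist, glist)):
        raise ValueError("parameter/gradient shapes do not match")
    vel = state.velocity
    if vel is None:
        vel = [np.zeros_like(p) for p in plist]
    new_vel = [state.momentum * v - state.learning_rate * g
               for v, g in zip(vel, glist)]
    new_params = [p + v for p, v in zip(plist, new_vel)]
    new_state = SGDMState(state.learning_rate, state.momentum, new_vel)
    return (new_params[0] if single else new_params), new_state


# ---------------------------------------------------------------------------
# Adam
# ---------------------------------------------------------------------------

@dataclass
class AdamState:
    learning_rate: float
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    t: int = 0
    m: ParamList | None = None
    v: ParamList | None = None


def adam_step(params, grads, state: AdamState):
    """One Adam update; returns (new_params, new_state)."""
    plist, single = _as_list(params)
    glist, _ = _as_list(grads)
    if len(plist) != len(glist) or any(
            p.shape != g.shape for p, g in zip(plist, glist)):
        raise ValueError("parameter/gradient shapes do not match")
    m = state.m if state.m is not None else [np.zeros_like(p) for p in plist]
    v = state.v if state.v is not None else [np.zeros_like(p) for p in plist]
    t = state.t + 1
    b1, b2 = state.beta1, state.beta2
    new_m = [b1 * mi + (1 - b1) * g for mi, g in zip(m, glist)]
    new_v = [b2 * vi + (1 - b2) * g * g for vi, g in zip(v, glist)]
    bc1 = 1 - b1 ** t
    bc2 = 1 - b2 ** t
    new_params = [
        p - state.learning_rate * (mi / bc1) / (np.sqrt(vi / bc2) + state.epsilon)
        for p, mi, vi in zip(plist, new_m, new_v)
    ]
    new_state = replace(state, t=t, m=new_m, v=new_v)
    return (new_params[0] if single else new_params), new_state


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adam"            # 'sgdm' or 'adam'
    epochs: int = 15
    batch_size: int = 50
    learning_rate: float = 0.01
    momentum: float = 0.9
    lr_drop_factor: float = 0.1        # piecewise-constant schedule
    lr_drop_period: int = 20           # in epochs
    l2: float | None = None            # None -> use the architecture's values
    validation_size: int = 500
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0 < self.lr_drop_factor <= 1:
            raise ValueError("lr_drop_factor must be in (0, 1]")
        if self.optimizer not in ("sgdm", "adam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


def one_hot(labels: np.ndarray, n_classes: int = 2) -> np.ndarray:
    out = np.zeros((len(labels), n_classes))
    out[np.arange(len(labels)), labels] = 1.0
    return out


def _epoch_lr(config: TrainConfig, epoch: int) -> float:
    drops = epoch // max(config.lr_drop_period, 1)
    return config.learning_rate * config.lr_drop_factor ** drops


def fit(arch: ArchitectureSpec, images: np.ndarray, labels: np.ndarray,
        config: TrainConfig) -> tuple[CNNModel, dict]:
    """Train a CNN on segment images with integer class labels (0/1).

    Returns the trained model and a history dict with per-epoch
    ``train_loss``, ``val_loss``, ``val_error`` and ``lr`` arrays.
    Segment images inherit their trial's label upstream (all 11 windows of
    a training trial carry the same class).
    """
    images = np.asarray(images)
    labels = np.asarray(labels, dtype=np.int64)
    if len(images) == 0:
        raise ValueError("no training data")
    if len(images) != len(labels):
        raise ValueError("images and labels disagree in length")
    rng = np.random.default_rng(config.seed)
    model = CNNModel(arch, rng, dtype=config.dtype)
    if config.l2 is not None:
        for layer in model.layers:
            if hasattr(layer, "l2"):
                layer.l2 = config.l2

    n = len(images)
    n_val = min(config.validation_size, n // 5)
    val_idx = rng.choice(n, size=n_val, replace=False) if n_val else np.array([], int)
    train_mask = np.ones(n, dtype=bool)
    train_mask[val_idx] = False
    tr_idx = np.flatnonzero(train_mask)
    x_val, y_val = images[val_idx], labels[val_idx]

    if config.optimizer == "sgdm":
        state: SGDMState | AdamState = SGDMState(config.learning_rate,
                                                 config.momentum)
    else:
        state = AdamState(config.learning_rate)

    history = {"train_loss": [], "val_loss": [], "val_error": [], "lr": []}
    for epoch in range(config.epochs):
        lr = _epoch_lr(config, epoch)
        state = replace(state, learning_rate=lr)
        order = rng.permutation(len(tr_idx))
        epoch_loss, n_seen = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            batch = tr_idx[order[start:start + config.batch_size]]
            xb, yb = images[batch], labels[batch]
            logits = model.forward_logits(xb, training=True)
            probs = softmax(logits.astype(np.float64))
            t = one_hot(yb, arch.n_classes)
            loss = cross_entropy_loss(probs, t)
            for warr, lam in model.l2_penalty_terms():
                loss += 0.5 * lam * float((warr.astype(np.float64) ** 2).sum())
            if not np.isfinite(loss):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}, batch {start // config.batch_size}: "
                    f"lr={lr}, optimizer={config.optimizer}")
            model.backward((probs - t) / len(batch))
            grads = model.gradients()
            params = model.parameters
            # weight decay on conv/dense kernels only
            decayed = {id(w): lam for w, lam in model.l2_penalty_terms()}
            grads = [g + decayed[id(p)] * p if id(p) in decayed else g
                     for p, g in zip(params, grads)]
            if config.optimizer == "sgdm":
                new_params, state = sgdm_step(params, grads, state)
            else:
                new_params, state = adam_step(params, grads, state)
            model.set_parameters(new_params)
            epoch_loss += loss * len(batch)
            n_seen += len(batch)
        history["train_loss"].append(epoch_loss / max(n_seen, 1))
        history["lr"].append(lr)
        if n_val:
            pv = model.predict_proba(x_val)
            history["val_loss"].append(
                cross_entropy_loss(pv, one_hot(y_val, arch.n_classes)))
            history["val_error"].append(
                float(np.mean(pv.argmax(axis=1) != y_val)))
        else:
            history["val_loss"].append(float("nan"))
            history["val_error"].append(float("nan"))
    return model, history


# ---------------------------------------------------------------------------
# training artifacts
# ---------------------------------------------------------------------------

def write_training_log(history: dict, path) -> None:
    """Per-epoch losses and learning rate as tab-delimited text."""
    from pathlib import Path
    lines = ["epoch\ttrain_loss\tval_loss\tval_error\tlr"]
    for e in range(len(history["train_loss"])):
        lines.append(f"{e}\t{history['train_loss'][e]:.8g}\t"
                     f"{history['val_loss'][e]:.8g}\t"
                     f"{history['val_error'][e]:.8g}\t{history['lr'][e]:.8g}")
    Path(path).write_text("\n".join(lines) + "\n")


def save_checkpoint(model: CNNModel, path) -> None:
    """Serialize a trained model: architecture config (JSON) plus every
    parameter and batch-norm running buffer."""
    import json
    from .cnn import _BatchNorm
    arrays = {f"param_{i}": p for i, p in enumerate(model.parameters)}
    bn = [l for l in model.layers if isinstance(l, _BatchNorm)]
    for i, layer in enumerate(bn):
        arrays[f"bn_mean_{i}"] = layer.running_mean
        arrays[f"bn_var_{i}"] = layer.running_var
    np.savez(path, arch=json.dumps(model.arch.to_dict()),
             dtype=str(model.dtype), **arrays)


def load_checkpoint(path) -> CNNModel:
    """Rebuild a model saved with :func:`save_checkpoint`."""
    import json
    from .cnn import _BatchNorm
    data = np.load(path, allow_pickle=False)
    arch = ArchitectureSpec.from_dict(json.loads(str(data["arch"])))
    model = CNNModel(arch, np.random.default_rng(0), dtype=str(data["dtype"]))
    model.set_parameters([data[f"param_{i}"]
                          for i in range(len(model.parameters))])
    bn = [l for l in model.layers if isinstance(l, _BatchNorm)]
    for i, layer in enumerate(bn):
        layer.running_mean[...] = data[f"bn_mean_{i}"]
        layer.running_var[...] = data[f"bn_var_{i}"]
    return model
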