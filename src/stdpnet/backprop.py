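"""Spike-based gradient-descent fine-tuning.

The non-differentiable spike train of each neuron is low-pass filtered
into an activation

    a_j = sum_k exp(-(T - t_k) / tau_p),

evaluated once at the end of the presentation window (T = last step,
t_k = spike steps, tau_p = 100 ms by default).  Its surrogate
(pseudo-)derivative adds a unity term to the time derivative of the
filtered train,

    a'_j = 1 + sum_k (-1/tau_p) exp(-(T - t_k) / tau_p),

which never saturates, so gradients do not vanish.  The output error is
the max-normalized output activation minus the one-hot label, the loss is
half the sum of squared errors, and error gradients are backpropagated
recursively:

    delta_L = e . a'_L
    delta_h = (W_h delta_{h+1}) . a'_h
    dW_l    = (a_l / max a_l) outer delta_{l+1}

Convolutional weight gradients average the per-position products over all
output-map positions sharing a kernel weight; pooling layers route each
pooled unit's gradient uniformly to its 2x2 source window scaled by the
fixed pooling weight 0.25 and contribute no a' factor.  Updates are plain
constant-rate SGD on mini-batch-averaged gradients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .encoding import ImageSample, SpikeRaster, poisson_encode
from .network import (
    ForwardRecord,
    LayerParams,
    SpikingNetwork,
    forward_pass,
    POOL_WEIGHT,
)

__all__ = [
    "ActivationTrace",
    "BPConfig",
    "accumulate_activation",
    "output_error",
    "mse_loss",
    "backward_pass",
    "sgd_update",
    "train_supervised",
    "TrainLogRow",
]

EPS_NORM = 1e-9


@dataclass
class ActivationTrace:
    """Low-pass-filtered activation and its pseudo-derivative per unit."""

    a: np.ndarray
    a_prime: np.ndarray


@dataclass
class BPConfig:
    """Supervised fine-tuning hyperparameters.

    Defaults follow the full-scale training recipe: activation decay
    tau_p = 100 ms, mini-batches of 100 samples encoded at 500 Hz,
    presentations of 100 ms in the first epoch and 50 ms thereafter, and a
    constant learning rate (0.4 for the shallow topology; 0.18 or 0.35 for
    the deep one).
    """

    eta_bp: float = 0.4
    tau_p_ms: float = 100.0
    batch_size: int = 100
    present_ms_first_epoch: float = 100.0
    present_ms: float = 50.0
    max_rate_hz: float = 500.0
    dt_ms: float = 1.0

    def __post_init__(self) -> None:
        for name in ("eta_bp", "tau_p_ms", "batch_size", "present_ms_first_epoch",
                     "present_ms", "max_rate_hz", "dt_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def accumulate_activation(
    spikes: np.ndarray | SpikeRaster,
    tau_p_ms: float = 100.0,
    dt_ms: float = 1.0,
) -> ActivationTrace:
    """Low-pass filter a spike train into (a, a'), evaluated at the last step.

    ``spikes`` has time on the last axis.  Units that never spiked get
    a = 0 and a' = 1 (the unity term alone).
    """
    if isinstance(spikes, SpikeRaster):
        dt_ms = spikes.dt_ms
        spikes = spikes.spikes
    s = np.asarray(spikes, dtype=float)
    n_steps = s.shape[-1]
    # exp(-(T - t_k) dt / tau_p) for every step, weighted by the spike indicator
    lags = (n_steps - 1 - np.arange(n_steps)) * dt_ms / tau_p_ms
    kernel = np.exp(-lags)
    a = s @ kernel
    a_prime = 1.0 - a * (dt_ms / tau_p_ms)
    return ActivationTrace(a=a, a_prime=a_prime)


def output_error(act_out: ActivationTrace, label: np.ndarray) -> np.ndarray:
    """Normalized output activation minus the one-hot target label."""
    label = np.asarray(label, dtype=float)
    a = act_out.a
    if a.shape != label.shape:
        raise ValueError(f"activation shape {a.shape} != label shape {label.shape}")
    return a / max(a.max(), EPS_NORM) - label


def mse_loss(e: np.ndarray) -> float:
    """Half the sum of squared output errors."""
    e = np.asarray(e, dtype=float)
    return 0.5 * float(np.sum(e * e))


def _normalized(a: np.ndarray) -> np.ndarray:
    return a / max(a.max(), EPS_NORM)


def _unpool(delta: np.ndarray, window: int) -> np.ndarray:
    """Route pooled-unit gradients uniformly to their source window x 0.25."""
    up = np.repeat(np.repeat(delta, window, axis=1), window, axis=2)
    return up * POOL_WEIGHT


def backward_pass(
    net: SpikingNetwork,
    record: ForwardRecord,
    label: np.ndarray,
    tau_p_ms: float = 100.0,
) -> tuple[list[np.ndarray | None], float, np.ndarray]:
    """Backpropagate the output error through a recorded forward pass.

    Returns ``(grads, loss, error)`` where ``grads[i]`` is the weight
    gradient of trainable layer ``i`` (``None`` for pool layers).  The
    record must come from ``forward_pass(..., record=True)`` on the same
    parameters.
    """
    if record.currents and all(c is None for c in record.currents):
        raise ValueError("backward_pass needs a record produced with record=True")
    dt = record.dt_ms
    acts = [accumulate_activation(s, tau_p_ms, dt) for s in record.spikes]
    label = np.asarray(label, dtype=float)
    e = output_error(acts[-1], label)
    loss = mse_loss(e)

    grads: list[np.ndarray | None] = [None] * len(net.params)
    delta = e * acts[-1].a_prime  # error gradient at the output layer
    # walk layers top -> bottom; delta always refers to the layer's output units
    for i in range(len(net.params) - 1, -1, -1):
        p = net.params[i]
        a_pre = acts[i]  # activation of the layer's input units
        if p.kind == "fc":
            pre = _normalized(a_pre.a).reshape(-1)
            grads[i] = np.outer(pre, delta)
            if i > 0:
                delta = p.weights @ delta  # back through the weights
                below = net.params[i - 1]
                if below.kind in ("conv", "fc"):
                    delta = delta.reshape(a_pre.a.shape) * a_pre.a_prime
                else:  # pool output: stateless, no a' factor
                    delta = delta.reshape(a_pre.a.shape)
        elif p.kind == "pool":
            delta = _unpool(delta, p.pool_window)
            if i > 0 and net.params[i - 1].kind == "conv":
                delta = delta * a_pre.a_prime
        else:  # conv
            k = p.kernel_size
            pre = _normalized(a_pre.a)  # (in_maps, h, w)
            windows = sliding_window_view(pre, (k, k), axis=(1, 2))
            # average over output positions sharing each kernel weight
            n_pos = delta.shape[1] * delta.shape[2]
            grads[i] = np.einsum("ixypq,oxy->oipq", windows, delta, optimize=True) / n_pos
            if i > 0:
                # transpose convolution: full correlation with flipped kernels
                dpad = np.pad(delta, ((0, 0), (k - 1, k - 1), (k - 1, k - 1)))
                dwin = sliding_window_view(dpad, (k, k), axis=(1, 2))
                flipped = p.weights[:, :, ::-1, ::-1]
                delta = np.einsum("ouvpq,oipq->iuv", dwin, flipped, optimize=True)
                below = net.params[i - 1]
                if below.kind in ("conv", "fc"):
                    delta = delta * a_pre.a_prime
    return grads, loss, e


def sgd_update(
    params: list[LayerParams],
    grads: list[np.ndarray | None],
    eta_bp: float,
) -> list[LayerParams]:
    """Constant-rate gradient descent step w <- w - eta * dw, in place."""
    if eta_bp <= 0:
        raise ValueError("eta_bp must be positive")
    for p, g in zip(params, grads):
        if g is None:
            continue
        if g.shape != p.weights.shape:
            raise ValueError(f"gradient shape {g.shape} != weights {p.weights.shape}")
        p.weights = p.weights - eta_bp * g
    return params


@dataclass
class TrainLogRow:
    iteration: int
    epoch: int
    loss: float
    batch_error: float


def train_supervised(
    net: SpikingNetwork,
    samples: list[ImageSample],
    cfg: BPConfig,
    rng: np.random.Generator,
    n_iterations: int | None = None,
    n_epochs: int = 1,
    first_epoch_samples: list[ImageSample] | None = None,
    stop_fn=None,
) -> list[TrainLogRow]:
    """End-to-end supervised fine-tuning over mini-batches, in place.

    Per mini-batch: each sample is Poisson-encoded (fresh spikes every
    presentation), forward-propagated with recording, backpropagated, and
    the per-sample gradients are averaged before one SGD step on every
    trainable layer (conv and fc).  Presentations last
    ``present_ms_first_epoch`` during the first epoch and ``present_ms``
    afterwards.  ``first_epoch_samples`` optionally restricts the first
    epoch (e.g. excluding the pre-training subset).  ``stop_fn(log)`` may
    end training early; ``n_iterations`` caps the total number of batches.

    Returns the per-iteration log (loss and mini-batch training error).
    """
    n_classes = net.n_classes
    log: list[TrainLogRow] = []
    iteration = 0
    for epoch in range(n_epochs):
        pool = samples if (epoch > 0 or first_epoch_samples is None) else first_epoch_samples
        if not pool:
            raise ValueError("empty training sample pool")
        present = cfg.present_ms_first_epoch if epoch == 0 else cfg.present_ms
        order = rng.permutation(len(pool))
        for start in range(0, len(order), cfg.batch_size):
            batch = [pool[j] for j in order[start : start + cfg.batch_size]]
            grad_sum: list[np.ndarray | None] = [None] * len(net.params)
            loss_sum = 0.0
            n_correct = 0
            for sample in batch:
                raster = poisson_encode(sample, cfg.max_rate_hz, present, cfg.dt_ms, rng)
                rec = forward_pass(net, raster, record=True)
                grads, loss, _ = backward_pass(net, rec, _one_hot(sample.label, n_classes),
                                               cfg.tau_p_ms)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite loss at iteration {iteration}"
                    )
                loss_sum += loss
                counts = rec.output_spikes.sum(axis=-1)
                if int(np.argmax(counts)) == sample.label:
                    n_correct += 1
                for li, g in enumerate(grads):
                    if g is None:
                        continue
                    grad_sum[li] = g if grad_sum[li] is None else grad_sum[li] + g
            scale = 1.0 / len(batch)
            grads_avg = [None if g is None else g * scale for g in grad_sum]
            sgd_update(net.params, grads_avg, cfg.eta_bp)
            iteration += 1
            row = TrainLogRow(
                iteration=iteration,
                epoch=epoch,
                loss=loss_sum * scale,
                batch_error=1.0 - n_correct / len(batch),
            )
            log.append(row)
            if n_iterations is not None and iteration >= n_iterations:
                return log
            if stop_fn is not None and stop_fn(log):
                return log
    return log


def _one_hot(label: int, n: int) -> np.ndarray:
    v = np.zeros(n)
    v[label] = 1.0
    return v
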