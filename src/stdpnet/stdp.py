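"""Weight-dependent positive STDP, homeostasis and layer-wise pre-training.

The unsupervised rule potentiates a synapse when its pre-synaptic neuron
fired shortly before the post-synaptic spike and depresses it otherwise:

    dw = eta_stdp * (trace - chi_offset) * (w_max - w) * (w - w_min)

where ``trace`` is a per-pre-neuron exponential trace that resets to 1 on a
pre-spike and decays with time constant ``tau_pre`` (1.5 ms by default), so
its value at the post-spike equals exp((t_pre - t_post)/tau_pre).  Updates
fire only at post-spike instants; with multiple post-spikes in a feature
map at one step, the per-location kernel updates are averaged.  The
(w_max - w)(w - w_min) factor makes updates soft-bounded and largest at the
middle of the weight range.

Homeostatic threshold adaptation keeps feature maps competitive: a map's
shared firing threshold is incremented whenever the map fires and relaxes
exponentially toward its initialization value while silent.

The greedy pre-training loop trains convolutional layers bottom-up, one at
a time, freezing each layer (kernels and adapted thresholds) before moving
to the next; fully-connected parameters are never touched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .encoding import ImageSample, poisson_encode
from .network import (
    LayerParams,
    SpikingNetwork,
    conv_currents,
    conv_forward_step,
    pool_spike_train,
)

__all__ = [
    "STDPConfig",
    "HomeostasisConfig",
    "PreTrace",
    "update_trace",
    "stdp_delta",
    "apply_conv_stdp",
    "adapt_thresholds",
    "pretrain_layer",
    "pretrain_all",
]


@dataclass
class STDPConfig:
    """Parameters of the weight-dependent positive STDP rule.

    ``w_min``/``w_max`` default to the layer's initialization range
    (+-sqrt(3/fan_in)) when left as ``None``, so STDP keeps weights on the
    initialization scale.
    """

    eta_stdp: float = 0.002
    tau_pre_ms: float = 1.5
    chi_offset: float = 0.4
    w_min: float | None = None
    w_max: float | None = None

    def __post_init__(self) -> None:
        if self.eta_stdp <= 0:
            raise ValueError("eta_stdp must be positive")
        if not 0.0 < self.chi_offset < 1.0:
            raise ValueError("chi_offset must lie strictly inside (0, 1)")
        if self.tau_pre_ms <= 0:
            raise ValueError("tau_pre_ms must be positive")
        if self.w_min is not None and self.w_max is not None and self.w_min >= self.w_max:
            raise ValueError("w_min must be < w_max")

    def bounds_for(self, params: LayerParams) -> tuple[float, float]:
        """Weight bounds, defaulting to the layer's init range."""
        scale = float(np.sqrt(3.0 / params.fan_in))
        lo = -scale if self.w_min is None else self.w_min
        hi = scale if self.w_max is None else self.w_max
        return lo, hi


@dataclass
class HomeostasisConfig:
    """Per-feature-map firing-threshold adaptation.

    ``theta_plus_rel`` is the increment per post-spike step as a fraction
    of the layer's initial threshold; thresholds relax exponentially toward
    that initial value (the floor) with constant ``tau_theta_ms`` while the
    map is silent, and never fall below it.
    """

    theta_plus_rel: float = 0.05
    tau_theta_ms: float = 100.0

    def __post_init__(self) -> None:
        if self.theta_plus_rel < 0:
            raise ValueError("theta_plus_rel must be >= 0")
        if self.tau_theta_ms <= 0:
            raise ValueError("tau_theta_ms must be positive")


@dataclass
class PreTrace:
    """Exponentially decaying trace, one value in [0, 1] per pre-unit."""

    values: np.ndarray

    @classmethod
    def zeros(cls, shape: tuple[int, ...]) -> "PreTrace":
        return cls(values=np.zeros(shape))


def update_trace(
    trace: PreTrace,
    pre_spikes: np.ndarray,
    dt_ms: float = 1.0,
    tau_pre_ms: float = 1.5,
) -> PreTrace:
    """Advance the pre-synaptic trace by one step, in place.

    Units that spike reset to exactly 1 (regardless of history); all others
    decay by exp(-dt/tau_pre).
    """
    if tau_pre_ms <= 0:
        raise ValueError("tau_pre_ms must be positive")
    s = np.asarray(pre_spikes)
    if s.shape != trace.values.shape:
        raise ValueError(f"pre-spike shape {s.shape} != trace shape {trace.values.shape}")
    trace.values = np.where(s > 0, 1.0, trace.values * np.exp(-dt_ms / tau_pre_ms))
    return trace


def stdp_delta(trace_value, w, cfg: STDPConfig, w_min: float, w_max: float):
    """The raw weight change dw for given trace value(s) and weight(s).

    Positive when the trace exceeds ``chi_offset`` (a recent pre-spike),
    negative otherwise; zero at either weight bound.  Pure function; the
    caller clamps the updated weight to [w_min, w_max].
    """
    trace_value = np.asarray(trace_value, dtype=float)
    w = np.asarray(w, dtype=float)
    return cfg.eta_stdp * (trace_value - cfg.chi_offset) * (w_max - w) * (w - w_min)


def apply_conv_stdp(
    params: LayerParams,
    post_spike_map: np.ndarray,
    trace: PreTrace,
    cfg: STDPConfig,
) -> LayerParams:
    """Apply one step of STDP to a conv layer's kernels, in place.

    For each output map with at least one post-spike this step, the
    per-kernel-coordinate deltas are computed at every spiking location
    (using the trace value of the pre-unit under that coordinate), averaged
    over the spiking locations, added to the kernel and clamped to the
    weight bounds.  Maps without post-spikes are untouched.
    """
    post = np.asarray(post_spike_map)
    k = params.kernel_size
    n_out, n_in = params.weights.shape[:2]
    if post.ndim != 3 or post.shape[0] != n_out:
        raise ValueError(
            f"post-spike map shape {post.shape} incompatible with {n_out} output maps"
        )
    h_out, w_out = post.shape[1:]
    if trace.values.shape != (n_in, h_out + k - 1, w_out + k - 1):
        raise ValueError(
            f"trace shape {trace.values.shape} incompatible with layer geometry"
        )
    counts = post.reshape(n_out, -1).sum(axis=1)
    if not counts.any():
        return params
    w_min, w_max = cfg.bounds_for(params)
    # (in, h_out, w_out, k, k) windows of the trace planes
    windows = sliding_window_view(trace.values, (k, k), axis=(1, 2))
    # mean trace over spiking locations, per output map and kernel coordinate
    mean_trace = np.einsum("oxy,ixypq->oipq", post.astype(float), windows, optimize=True)
    active = counts > 0
    mean_trace[active] /= counts[active, None, None, None]
    w = params.weights
    delta = stdp_delta(mean_trace, w, cfg, w_min, w_max)
    delta[~active] = 0.0
    params.weights = np.clip(w + delta, w_min, w_max)
    return params


def adapt_thresholds(
    thresholds: np.ndarray,
    post_spike_maps: np.ndarray,
    homeo: HomeostasisConfig,
    theta_floor: np.ndarray,
    dt_ms: float = 1.0,
) -> np.ndarray:
    """One homeostasis step on per-map thresholds ``(maps, 1, 1)``.

    Maps that fired this step (any unit) gain ``theta_plus``; silent maps
    relax toward their floor: theta <- floor + (theta - floor) * exp(-dt/tau).
    """
    post = np.asarray(post_spike_maps)
    fired = post.reshape(post.shape[0], -1).any(axis=1).reshape(-1, 1, 1)
    theta_plus = homeo.theta_plus_rel * theta_floor
    decay = np.exp(-dt_ms / homeo.tau_theta_ms)
    relaxed = theta_floor + (thresholds - theta_floor) * decay
    out = np.where(fired, thresholds + theta_plus, relaxed)
    return np.maximum(out, theta_floor)


def _propagate_frozen(
    net: SpikingNetwork, raster_spikes: np.ndarray, upto: int, dt_ms: float
) -> np.ndarray:
    """Run the (frozen) layers below ``upto`` on a full spike train."""
    from .network import _lif_run

    x = raster_spikes
    for p in net.params[:upto]:
        if p.kind == "conv":
            x = _lif_run(conv_currents(x, p), p.thresholds, net.spec.tau_m_ms, dt_ms)
        elif p.kind == "pool":
            x = pool_spike_train(x, p.pool_window)
        else:
            raise ValueError("pre-training input path crossed an FC layer")
    return x


def pretrain_layer(
    net: SpikingNetwork,
    layer_index: int,
    samples: list[ImageSample],
    stdp_cfg: STDPConfig,
    homeo_cfg: HomeostasisConfig,
    rng: np.random.Generator,
    present_ms: float = 25.0,
    max_rate_hz: float = 200.0,
    dt_ms: float = 1.0,
) -> SpikingNetwork:
    """Pre-train one convolutional layer with STDP + homeostasis, in place.

    Each sample is Poisson-encoded and propagated through the frozen lower
    layers; the target layer is then stepped for ``present_ms`` with kernel
    updates at post-spike instants and per-map threshold adaptation at
    every step.  Membrane potentials, traces and thresholds carry over
    between steps within a presentation; potentials and traces reset
    between samples, adapted thresholds persist.
    """
    target = net.params[layer_index]
    if target.kind != "conv":
        raise ValueError(f"layer {layer_index} is {target.kind!r}, not conv")
    theta_floor = target.alpha * np.sqrt(3.0 / target.fan_in) * np.ones_like(target.thresholds)
    decay_m = np.exp(-dt_ms / net.spec.tau_m_ms)
    for sample in samples:
        raster = poisson_encode(sample, max_rate_hz, present_ms, dt_ms, rng)
        pre = _propagate_frozen(net, raster.spikes, layer_index, dt_ms)
        trace = PreTrace.zeros(pre.shape[:-1])
        v = np.zeros((target.n_out, pre.shape[1] - target.kernel_size + 1,
                      pre.shape[2] - target.kernel_size + 1))
        for t in range(pre.shape[-1]):
            update_trace(trace, pre[..., t], dt_ms, stdp_cfg.tau_pre_ms)
            current = conv_forward_step(pre[..., t], target)
            v = v * decay_m + current
            post = (v >= target.thresholds).astype(np.uint8)
            v = np.where(post, 0.0, v)
            if post.any():
                apply_conv_stdp(target, post, trace, stdp_cfg)
            target.thresholds = adapt_thresholds(
                target.thresholds, post, homeo_cfg, theta_floor, dt_ms
            )
    return net


def pretrain_all(
    net: SpikingNetwork,
    samples: list[ImageSample],
    stdp_cfg: STDPConfig,
    homeo_cfg: HomeostasisConfig,
    rng: np.random.Generator,
    present_ms: float = 25.0,
    max_rate_hz: float = 200.0,
    dt_ms: float = 1.0,
) -> SpikingNetwork:
    """Greedy bottom-up pre-training of all convolutional layers, in place.

    After each conv layer is trained its kernels and adapted thresholds are
    frozen; its spiking output (through pooling) feeds the next conv layer.
    FC parameters are never modified.
    """
    for idx in net.conv_layer_indices():
        pretrain_layer(
            net, idx, samples, stdp_cfg, homeo_cfg, rng,
            present_ms=present_ms, max_rate_hz=max_rate_hz, dt_ms=dt_ms,
        )
    return net
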