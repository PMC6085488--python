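"""Discrete-time LIF layers and the convolutional network machinery.

The neuron model is the leaky integrate-and-fire unit

    tau_m dV/dt = -V + I(t),

discretized with the exact per-step decay factor ``exp(-dt/tau_m)`` (stable
for any dt, unlike forward-Euler).  The per-step order of operations is
decay -> integrate -> compare -> reset: a unit whose updated potential
reaches its firing threshold emits a binary spike and is reset to zero.
At most one spike per unit per time step.

Topology machinery: valid-mode stride-1 convolution with weight sharing,
non-overlapping 2x2 spatial pooling (fixed weight 0.25, firing threshold
0.8 — an AND gate over the window), and fully-connected propagation on the
row-major flattening of the final pooled maps.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .encoding import SpikeRaster

__all__ = [
    "LIFLayerState",
    "LayerParams",
    "NetworkSpec",
    "SpikingNetwork",
    "ForwardRecord",
    "SimulationError",
    "parse_topology",
    "lif_step",
    "conv_forward_step",
    "pool_forward_step",
    "init_weights",
    "init_thresholds",
    "forward_pass",
]

POOL_WEIGHT = 0.25
POOL_THRESHOLD = 0.8
DEFAULT_ALPHA_CONV = 5.0
DEFAULT_ALPHA_FC = 3.0


class SimulationError(RuntimeError):
    """Non-finite signal encountered during simulation."""


@dataclass
class LIFLayerState:
    """Membrane potentials and firing thresholds of one LIF layer.

    ``thresholds`` broadcasts against ``v_mem``: a conv layer typically has
    one threshold per feature map (shape ``(maps, 1, 1)``), an FC layer one
    per unit.
    """

    v_mem: np.ndarray
    thresholds: np.ndarray
    tau_m_ms: float = 10.0

    def __post_init__(self) -> None:
        self.v_mem = np.asarray(self.v_mem, dtype=float)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if (self.thresholds <= 0).any():
            raise ValueError("firing thresholds must be strictly positive")
        if self.tau_m_ms <= 0:
            raise ValueError("tau_m_ms must be positive")


def lif_step(
    state: LIFLayerState,
    input_current: np.ndarray,
    dt_ms: float = 1.0,
    context: str = "",
) -> np.ndarray:
    """Advance one LIF layer by one time step, in place.

    Order of operations: exponential decay, current integration, threshold
    comparison, reset-to-zero of spiking units.  Returns the binary spike
    array.
    """
    current = np.asarray(input_current, dtype=float)
    if current.shape != state.v_mem.shape:
        raise ValueError(
            f"input current shape {current.shape} != state shape {state.v_mem.shape}"
        )
    if not np.isfinite(current).all():
        raise SimulationError(f"non-finite input current{' at ' + context if context else ''}")
    state.v_mem = state.v_mem * np.exp(-dt_ms / state.tau_m_ms) + current
    spikes = state.v_mem >= state.thresholds
    state.v_mem = np.where(spikes, 0.0, state.v_mem)
    return spikes.astype(np.uint8)


# ---------------------------------------------------------------------------
# Layer parameters and topology

@dataclass
class LayerParams:
    """One layer of the topology: conv (trainable kernels), pool, or fc.

    Conv weights have shape ``(out_maps, in_maps, k, k)``; fc weights
    ``(n_pre, n_post)``.  Pool layers carry no weights (fixed 2x2 window,
    weight 0.25, threshold 0.8).
    """

    kind: str  # "conv" | "pool" | "fc"
    weights: np.ndarray | None = None
    kernel_size: int = 0
    stride: int = 1
    pool_window: int = 2
    n_out: int = 0
    thresholds: np.ndarray | None = None
    alpha: float = 0.0
    fan_in: int = 0

    def copy(self) -> "LayerParams":
        return LayerParams(
            kind=self.kind,
            weights=None if self.weights is None else self.weights.copy(),
            kernel_size=self.kernel_size,
            stride=self.stride,
            pool_window=self.pool_window,
            n_out=self.n_out,
            thresholds=None if self.thresholds is None else self.thresholds.copy(),
            alpha=self.alpha,
            fan_in=self.fan_in,
        )


_TOPOLOGY_TOKEN = re.compile(
    r"^(?:(?P<h>\d+)x(?P<w>\d+)|(?P<nc>\d+)c(?P<k>\d+)|(?P<pw>\d+)p|(?P<nfc>\d+)fc)$",
    re.IGNORECASE,
)


@dataclass
class NetworkSpec:
    """Parsed topology plus initialization metadata.

    ``layers`` holds ``(kind, params)`` tuples straight from the topology
    string, e.g. ``28x28-36C5-2P-10FC`` (input, conv with 36 maps of 5x5
    kernels, 2x2 pooling, 10-way fully-connected classifier).
    """

    input_shape: tuple[int, int]
    layers: list[dict]
    init_scheme: str = "lee"
    alpha_conv: float = DEFAULT_ALPHA_CONV
    alpha_fc: float = DEFAULT_ALPHA_FC
    tau_m_ms: float = 10.0
    topology: str = ""

    @property
    def n_classes(self) -> int:
        last = self.layers[-1]
        if last["kind"] != "fc":
            raise ValueError("topology must end in an FC layer")
        return last["n"]


def parse_topology(
    topology: str,
    init_scheme: str = "lee",
    alpha_conv: float = DEFAULT_ALPHA_CONV,
    alpha_fc: float = DEFAULT_ALPHA_FC,
    tau_m_ms: float = 10.0,
) -> NetworkSpec:
    """Parse a topology string like ``"28x28-20C5-2P-50C5-2P-200FC-10FC"``.

    Tokens (case-insensitive): ``<H>x<W>`` input, ``<N>C<k>`` convolution
    with N maps of k x k kernels, ``<w>P`` non-overlapping w x w pooling,
    ``<N>FC`` fully-connected layer of N units.  Validates shape chaining.
    """
    if init_scheme not in ("lee", "glorot"):
        raise ValueError(f"unknown initialization scheme {init_scheme!r}")
    tokens = [tok.strip() for tok in topology.replace("−", "-").split("-") if tok.strip()]
    if not tokens:
        raise ValueError("empty topology string")
    layers: list[dict] = []
    input_shape: tuple[int, int] | None = None
    for i, tok in enumerate(tokens):
        m = _TOPOLOGY_TOKEN.match(tok)
        if not m:
            raise ValueError(f"cannot parse topology token {tok!r}")
        if m.group("h"):
            if i != 0:
                raise ValueError("input size token must come first")
            input_shape = (int(m.group("h")), int(m.group("w")))
        elif m.group("nc"):
            layers.append({"kind": "conv", "n": int(m.group("nc")), "k": int(m.group("k"))})
        elif m.group("pw"):
            layers.append({"kind": "pool", "w": int(m.group("pw"))})
        else:
            layers.append({"kind": "fc", "n": int(m.group("nfc"))})
    if input_shape is None:
        raise ValueError("topology must start with an <H>x<W> input token")
    if not layers or layers[-1]["kind"] != "fc":
        raise ValueError("topology must end with an FC (classifier) layer")
    spec = NetworkSpec(
        input_shape=input_shape,
        layers=layers,
        init_scheme=init_scheme,
        alpha_conv=alpha_conv,
        alpha_fc=alpha_fc,
        tau_m_ms=tau_m_ms,
        topology=topology,
    )
    layer_shapes(spec)  # validates chaining
    return spec


def layer_shapes(spec: NetworkSpec) -> list[tuple]:
    """Output shape of every layer: (maps, h, w) for conv/pool, (n,) for fc."""
    maps, h, w = 1, *spec.input_shape
    shapes: list[tuple] = []
    flat = None
    for layer in spec.layers:
        if layer["kind"] == "conv":
            if flat is not None:
                raise ValueError("conv layer after FC layer is not supported")
            k = layer["k"]
            if k > h or k > w:
                raise ValueError(f"kernel size {k} exceeds input plane {h}x{w}")
            maps, h, w = layer["n"], h - k + 1, w - k + 1
            shapes.append((maps, h, w))
        elif layer["kind"] == "pool":
            if flat is not None:
                raise ValueError("pool layer after FC layer is not supported")
            pw = layer["w"]
            if h % pw or w % pw:
                raise ValueError(f"pooling window {pw} does not divide plane {h}x{w}")
            h, w = h // pw, w // pw
            shapes.append((maps, h, w))
        else:
            n_pre = maps * h * w if flat is None else flat
            flat = layer["n"]
            shapes.append((layer["n"],))
    return shapes


# ---------------------------------------------------------------------------
# Initialization

def init_weights(spec: NetworkSpec, rng: np.random.Generator) -> list[LayerParams]:
    """Draw initial weights for every trainable layer.

    ``lee`` scheme: uniform in +-sqrt(3 / fan_in); ``glorot``: uniform in
    +-sqrt(6 / (fan_in + fan_out)).  Pool layers get fixed parameters.
    """
    params: list[LayerParams] = []
    maps, h, w = 1, *spec.input_shape
    flat: int | None = None
    for layer in spec.layers:
        if layer["kind"] == "conv":
            n, k = layer["n"], layer["k"]
            fan_in = maps * k * k
            fan_out = n * k * k
            bound = _init_bound(spec.init_scheme, fan_in, fan_out)
            weights = rng.uniform(-bound, bound, size=(n, maps, k, k))
            params.append(
                LayerParams(
                    kind="conv", weights=weights, kernel_size=k, stride=1,
                    n_out=n, alpha=spec.alpha_conv, fan_in=fan_in,
                )
            )
            maps, h, w = n, h - k + 1, w - k + 1
        elif layer["kind"] == "pool":
            params.append(LayerParams(kind="pool", pool_window=layer["w"], n_out=maps))
            h, w = h // layer["w"], w // layer["w"]
        else:
            n_pre = maps * h * w if flat is None else flat
            n = layer["n"]
            bound = _init_bound(spec.init_scheme, n_pre, n)
            weights = rng.uniform(-bound, bound, size=(n_pre, n))
            params.append(
                LayerParams(kind="fc", weights=weights, n_out=n,
                            alpha=spec.alpha_fc, fan_in=n_pre)
            )
            flat = n
    return params


def _init_bound(scheme: str, fan_in: int, fan_out: int) -> float:
    if scheme == "lee":
        return float(np.sqrt(3.0 / fan_in))
    if scheme == "glorot":
        return float(np.sqrt(6.0 / (fan_in + fan_out)))
    raise ValueError(f"unknown initialization scheme {scheme!r}")


def init_thresholds(spec: NetworkSpec, params: list[LayerParams]) -> None:
    """Set firing thresholds v_th = alpha * sqrt(3 / fan_in), in place.

    Conv layers use ``spec.alpha_conv`` (default 5), fully-connected layers
    ``spec.alpha_fc`` (default 3); conv thresholds are shared per feature
    map (shape ``(maps, 1, 1)``), fc thresholds per unit.
    """
    for p in params:
        if p.kind == "pool":
            continue
        alpha = p.alpha
        if alpha <= 0:
            raise ValueError("threshold constant alpha must be positive")
        v_th = alpha * np.sqrt(3.0 / p.fan_in)
        if p.kind == "conv":
            p.thresholds = np.full((p.n_out, 1, 1), v_th)
        else:
            p.thresholds = np.full((p.n_out,), v_th)


@dataclass
class SpikingNetwork:
    """A topology spec bound to concrete layer parameters."""

    spec: NetworkSpec
    params: list[LayerParams]

    @classmethod
    def build(
        cls,
        topology: str,
        rng: np.random.Generator,
        init_scheme: str = "lee",
        alpha_conv: float = DEFAULT_ALPHA_CONV,
        alpha_fc: float = DEFAULT_ALPHA_FC,
        tau_m_ms: float = 10.0,
    ) -> "SpikingNetwork":
        spec = parse_topology(topology, init_scheme, alpha_conv, alpha_fc, tau_m_ms)
        params = init_weights(spec, rng)
        init_thresholds(spec, params)
        return cls(spec=spec, params=params)

    def copy(self) -> "SpikingNetwork":
        return SpikingNetwork(spec=self.spec, params=[p.copy() for p in self.params])

    @property
    def n_classes(self) -> int:
        return self.spec.n_classes

    def conv_layer_indices(self) -> list[int]:
        return [i for i, p in enumerate(self.params) if p.kind == "conv"]


# ---------------------------------------------------------------------------
# Forward propagation

def conv_forward_step(pre_spikes: np.ndarray, params: LayerParams) -> np.ndarray:
    """Input current of a conv layer for one instantaneous spike plane.

    Valid-mode (no padding) stride-1 cross-correlation of the binary spike
    plane ``(in_maps, h, w)`` with each kernel, summed over input maps.
    """
    s = np.asarray(pre_spikes, dtype=float)
    k = params.kernel_size
    if s.ndim != 3 or s.shape[0] != params.weights.shape[1]:
        raise ValueError(
            f"pre-spike shape {s.shape} incompatible with kernels {params.weights.shape}"
        )
    if s.shape[1] < k or s.shape[2] < k:
        raise ValueError("spike plane smaller than kernel")
    windows = sliding_window_view(s, (k, k), axis=(1, 2))  # (in, h', w', k, k)
    return np.einsum("ixypq,oipq->oxy", windows, params.weights, optimize=True)


def conv_currents(pre_spikes_t: np.ndarray, params: LayerParams) -> np.ndarray:
    """Conv input currents for a whole spike train ``(in, h, w, T)`` at once."""
    s = np.asarray(pre_spikes_t, dtype=float)
    k = params.kernel_size
    windows = sliding_window_view(s, (k, k), axis=(1, 2))  # (in, h', w', T, k, k)
    return np.einsum("ixytpq,oipq->oxyt", windows, params.weights, optimize=True)


def pool_forward_step(pre_spikes: np.ndarray, window: int = 2) -> np.ndarray:
    """Spatial pooling of an instantaneous spike plane.

    Each non-overlapping ``window x window`` region sums its spikes with
    weight 0.25 and emits a spike iff the sum exceeds 0.8 — for the default
    2x2 window, iff all four inputs spike.
    """
    s = np.asarray(pre_spikes)
    maps, h, w = s.shape
    if h % window or w % window:
        raise ValueError(f"spatial dims {h}x{w} not divisible by pool window {window}")
    blocks = s.reshape(maps, h // window, window, w // window, window)
    summed = POOL_WEIGHT * blocks.sum(axis=(2, 4))
    return (summed > POOL_THRESHOLD).astype(np.uint8)


def pool_spike_train(pre_spikes_t: np.ndarray, window: int = 2) -> np.ndarray:
    """Pooling applied across a whole spike train ``(maps, h, w, T)``."""
    s = np.asarray(pre_spikes_t)
    maps, h, w, t = s.shape
    blocks = s.reshape(maps, h // window, window, w // window, window, t)
    summed = POOL_WEIGHT * blocks.sum(axis=(2, 4))
    return (summed > POOL_THRESHOLD).astype(np.uint8)


def _lif_run(
    currents: np.ndarray, thresholds: np.ndarray, tau_m_ms: float, dt_ms: float,
    context: str = "",
) -> np.ndarray:
    """Sequentially integrate a full current train (…, T) through LIF units."""
    if not np.isfinite(currents).all():
        raise SimulationError(f"non-finite input current in {context or 'layer'}")
    decay = np.exp(-dt_ms / tau_m_ms)
    v = np.zeros(currents.shape[:-1])
    spikes = np.empty(currents.shape, dtype=np.uint8)
    for t in range(currents.shape[-1]):
        v = v * decay + currents[..., t]
        fired = v >= thresholds
        v = np.where(fired, 0.0, v)
        spikes[..., t] = fired
    return spikes


@dataclass
class ForwardRecord:
    """Per-layer signals retained for the backward pass.

    ``spikes[0]`` is the input raster; ``spikes[i+1]`` the output spike
    train of layer ``i``.  ``currents[i]`` holds the input current train of
    trainable layer ``i`` when recording is enabled (``None`` for pool
    layers).
    """

    spikes: list[np.ndarray]
    currents: list[np.ndarray | None]
    dt_ms: float

    @property
    def n_steps(self) -> int:
        return self.spikes[0].shape[-1]

    @property
    def output_spikes(self) -> np.ndarray:
        return self.spikes[-1]


def forward_pass(
    net: SpikingNetwork,
    raster: SpikeRaster,
    record: bool = False,
    dt_ms: float | None = None,
) -> ForwardRecord:
    """Propagate a spike raster through every layer for every time step.

    Layers are stepped input -> output; because there is no feedback, each
    layer consumes its predecessor's full spike train.  Pooling layers are
    stateless spike-to-spike maps; the first FC layer flattens the final
    pooled maps row-major by (map, row, column).
    """
    dt = raster.dt_ms if dt_ms is None else dt_ms
    x = raster.spikes
    if x.shape[1:3] != net.spec.input_shape:
        raise ValueError(
            f"raster spatial shape {x.shape[1:3]} != input layer {net.spec.input_shape}"
        )
    tau_m = net.spec.tau_m_ms
    spikes_per_layer: list[np.ndarray] = [x]
    currents_per_layer: list[np.ndarray | None] = []
    for i, p in enumerate(net.params):
        ctx = f"layer {i} ({p.kind})"
        if p.kind == "conv":
            current = conv_currents(x, p)
            x = _lif_run(current, p.thresholds, tau_m, dt, ctx)
        elif p.kind == "pool":
            current = None
            x = pool_spike_train(x, p.pool_window)
        else:  # fc
            flat = x.reshape(-1, x.shape[-1])  # (n_pre, T), row-major
            current = p.weights.T @ flat
            x = _lif_run(current, p.thresholds, tau_m, dt, ctx)
        spikes_per_layer.append(x)
        currents_per_layer.append(current if record else None)
    return ForwardRecord(spikes=spikes_per_layer, currents=currents_per_layer, dt_ms=dt)
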