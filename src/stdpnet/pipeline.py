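"""Full semi-supervised runs: pre-train, fine-tune, evaluate.

A run builds and initializes a network, optionally pre-trains its
convolutional layers with STDP on a fraction of the training data (encoded
at 200 Hz for 25 ms per sample), fine-tunes all trainable layers with
spike-based backpropagation (500 Hz; 100 ms presentations in the first
epoch, 50 ms afterwards), and evaluates by presenting each test image for
200 ms and predicting the output unit with the most spikes.

Three independently seeded random streams (weight init, spike encoding,
data ordering) make ablations exactly paired: a pre-trained and a purely
supervised run can share identical initial weights and identical input
spike sequences.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict, dataclass, replace

import numpy as np
import yaml

from .backprop import BPConfig, TrainLogRow, accumulate_activation, train_supervised
from .encoding import ImageSample, generate_patterns, poisson_encode
from .network import SpikingNetwork, forward_pass
from .stdp import HomeostasisConfig, STDPConfig, pretrain_all

__all__ = [
    "RunConfig",
    "EvalReport",
    "RunResult",
    "infer",
    "nll_cost",
    "evaluate",
    "run_semisupervised",
    "compare_pretraining",
    "iterations_to_error",
    "save_checkpoint",
    "load_checkpoint",
    "write_metrics_csv",
]

NLL_EPS = 1e-9


@dataclass
class RunConfig:
    """Everything needed to reproduce a run bit-for-bit.

    Durations and rates default to the full-scale recipe (pre-training
    25 ms at 200 Hz; fine-tuning 100/50 ms at 500 Hz; inference 200 ms at
    500 Hz); toy runs scale them down explicitly.
    """

    topology: str = "28x28-36C5-2P-10FC"
    init_scheme: str = "lee"
    alpha_conv: float = 5.0
    alpha_fc: float = 3.0
    tau_m_ms: float = 10.0
    dt_ms: float = 1.0
    # seeds for the three independent random streams
    seed_weights: int = 1
    seed_encoding: int = 2
    seed_data: int = 3
    # STDP pre-training
    pretrain: bool = True
    pretrain_fraction: float = 0.1
    eta_stdp: float = 0.002
    tau_pre_ms: float = 1.5
    chi_offset: float = 0.4
    theta_plus_rel: float = 0.05
    tau_theta_ms: float = 100.0
    stdp_present_ms: float = 25.0
    stdp_max_rate_hz: float = 200.0
    # supervised fine-tuning
    eta_bp: float = 0.4
    tau_p_ms: float = 100.0
    batch_size: int = 100
    present_ms_first_epoch: float = 100.0
    present_ms: float = 50.0
    bp_max_rate_hz: float = 500.0
    n_epochs: int = 1
    n_iterations: int | None = None
    # inference
    infer_ms: float = 200.0
    infer_max_rate_hz: float = 500.0
    # synthetic dataset (used when no external data are supplied)
    n_classes: int = 3
    image_size: tuple[int, int] = (8, 8)
    samples_per_class: int = 100
    test_per_class: int = 20
    noise_level: float = 0.1

    def to_yaml(self) -> str:
        d = asdict(self)
        d["image_size"] = list(d["image_size"])
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text)
        d["image_size"] = tuple(d["image_size"])
        return cls(**d)

    def stdp_config(self) -> STDPConfig:
        return STDPConfig(eta_stdp=self.eta_stdp, tau_pre_ms=self.tau_pre_ms,
                          chi_offset=self.chi_offset)

    def homeo_config(self) -> HomeostasisConfig:
        return HomeostasisConfig(theta_plus_rel=self.theta_plus_rel,
                                 tau_theta_ms=self.tau_theta_ms)

    def bp_config(self) -> BPConfig:
        return BPConfig(eta_bp=self.eta_bp, tau_p_ms=self.tau_p_ms,
                        batch_size=self.batch_size,
                        present_ms_first_epoch=self.present_ms_first_epoch,
                        present_ms=self.present_ms,
                        max_rate_hz=self.bp_max_rate_hz, dt_ms=self.dt_ms)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


@dataclass
class EvalReport:
    """Aggregate evaluation: error rate, confusion counts, mean NLL."""

    error: float
    confusion: np.ndarray  # (true, predicted) counts
    mean_nll: float
    n_samples: int

    def to_dict(self) -> dict:
        return {
            "error": self.error,
            "confusion": self.confusion.tolist(),
            "mean_nll": self.mean_nll,
            "n_samples": self.n_samples,
        }


def infer(
    net: SpikingNetwork,
    image: ImageSample,
    rng: np.random.Generator,
    duration_ms: float = 200.0,
    max_rate_hz: float = 500.0,
    dt_ms: float = 1.0,
    decision: str = "spike_count",
) -> tuple[int, np.ndarray]:
    """Classify one image; returns (predicted class, output spike counts).

    The prediction is the argmax of output-unit spike counts over the
    inference window (``decision="activation"`` uses the low-pass-filtered
    activation instead); ties resolve to the lowest class index.
    """
    raster = poisson_encode(image, max_rate_hz, duration_ms, dt_ms, rng)
    rec = forward_pass(net, raster)
    counts = rec.output_spikes.sum(axis=-1).astype(float)
    if decision == "activation":
        score = accumulate_activation(rec.output_spikes, dt_ms=dt_ms).a
    elif decision == "spike_count":
        score = counts
    else:
        raise ValueError(f"unknown decision rule {decision!r}")
    return int(np.argmax(score)), counts


def nll_cost(output_rates: np.ndarray, label: np.ndarray, eps: float = NLL_EPS) -> float:
    """Negative log-likelihood of the one-hot label under normalized rates.

    ``output_rates`` is normalized to a probability distribution over the
    classes (sum-normalization; an all-zero vector falls back to uniform),
    clipped to [eps, 1-eps].  Returns the non-negative cross-entropy
    -sum_i [x_i log p_i + (1 - x_i) log(1 - p_i)].
    """
    r = np.asarray(output_rates, dtype=float)
    label = np.asarray(label, dtype=float)
    total = r.sum()
    p = r / total if total > 0 else np.full_like(r, 1.0 / r.size)
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.sum(label * np.log(p) + (1.0 - label) * np.log(1.0 - p)))


def evaluate(
    net: SpikingNetwork,
    samples: list[ImageSample],
    rng: np.random.Generator,
    duration_ms: float = 200.0,
    max_rate_hz: float = 500.0,
    dt_ms: float = 1.0,
) -> EvalReport:
    """Run inference on every sample; aggregate confusion, error, mean NLL."""
    if not samples:
        raise ValueError("cannot evaluate on an empty sample set")
    n = net.n_classes
    confusion = np.zeros((n, n), dtype=int)
    nll_sum = 0.0
    for sample in samples:
        pred, counts = infer(net, sample, rng, duration_ms, max_rate_hz, dt_ms)
        confusion[sample.label, pred] += 1
        onehot = np.zeros(n)
        onehot[sample.label] = 1.0
        nll_sum += nll_cost(counts, onehot)
    n_total = len(samples)
    error = 1.0 - np.trace(confusion) / n_total
    return EvalReport(error=float(error), confusion=confusion,
                      mean_nll=nll_sum / n_total, n_samples=n_total)


@dataclass
class RunResult:
    net: SpikingNetwork
    report: EvalReport
    train_log: list[TrainLogRow]
    config: RunConfig


def _split_dataset(cfg: RunConfig):
    """Synthetic train/test split from the generator streams."""
    rng_data = np.random.default_rng(cfg.seed_data)
    train = generate_patterns(cfg.n_classes, cfg.image_size,
                              cfg.samples_per_class, cfg.noise_level, rng_data)
    test = generate_patterns(cfg.n_classes, cfg.image_size,
                             cfg.test_per_class, cfg.noise_level, rng_data)
    return train, test


def run_semisupervised(
    cfg: RunConfig,
    train_samples: list[ImageSample] | None = None,
    test_samples: list[ImageSample] | None = None,
    stop_fn=None,
    initial_net: SpikingNetwork | None = None,
) -> RunResult:
    """Execute the full pipeline: build, pre-train, fine-tune, evaluate.

    With ``cfg.pretrain`` false the STDP phase is skipped (the purely
    supervised baseline); supplying ``initial_net`` replays a run from an
    existing initialization so paired comparisons share the same weights.
    """
    if train_samples is None or test_samples is None:
        gen_train, gen_test = _split_dataset(cfg)
        train_samples = train_samples if train_samples is not None else gen_train
        test_samples = test_samples if test_samples is not None else gen_test
    rng_w = np.random.default_rng(cfg.seed_weights)
    rng_enc = np.random.default_rng(cfg.seed_encoding)
    rng_data = np.random.default_rng(cfg.seed_data + 1)  # shuffling stream

    net = initial_net.copy() if initial_net is not None else SpikingNetwork.build(
        cfg.topology, rng_w, cfg.init_scheme, cfg.alpha_conv, cfg.alpha_fc, cfg.tau_m_ms
    )

    first_epoch_samples: list[ImageSample] | None = None
    if cfg.pretrain:
        n_pre = max(1, int(round(cfg.pretrain_fraction * len(train_samples))))
        pre_idx = rng_data.choice(len(train_samples), size=n_pre, replace=False)
        pre_set = set(int(i) for i in pre_idx)
        pretrain_all(net, [train_samples[i] for i in sorted(pre_set)],
                     cfg.stdp_config(), cfg.homeo_config(), rng_enc,
                     present_ms=cfg.stdp_present_ms,
                     max_rate_hz=cfg.stdp_max_rate_hz, dt_ms=cfg.dt_ms)
        first_epoch_samples = [s for i, s in enumerate(train_samples) if i not in pre_set]

    log = train_supervised(
        net, train_samples, cfg.bp_config(), _CombinedRng(rng_data, rng_enc),
        n_iterations=cfg.n_iterations, n_epochs=cfg.n_epochs,
        first_epoch_samples=first_epoch_samples, stop_fn=stop_fn,
    )
    report = evaluate(net, test_samples, rng_enc, cfg.infer_ms,
                      cfg.infer_max_rate_hz, cfg.dt_ms)
    return RunResult(net=net, report=report, train_log=log, config=cfg)


class _CombinedRng:
    """Route shuffling draws and encoding draws to their own streams."""

    def __init__(self, rng_order: np.random.Generator, rng_encode: np.random.Generator):
        self._order = rng_order
        self._encode = rng_encode

    def permutation(self, n):
        return self._order.permutation(n)

    def random(self, *args, **kwargs):
        return self._encode.random(*args, **kwargs)


def iterations_to_error(
    log: list[TrainLogRow], threshold: float = 0.05, window: int = 5
) -> int | None:
    """First iteration whose trailing-``window`` mean batch error <= threshold."""
    errors = [row.batch_error for row in log]
    for i in range(len(errors)):
        lo = max(0, i - window + 1)
        if np.mean(errors[lo : i + 1]) <= threshold:
            return log[i].iteration
    return None


def compare_pretraining(
    cfg: RunConfig,
    seeds: list[int],
    threshold: float = 0.05,
    max_iterations: int = 500,
) -> dict:
    """Paired pre-trained vs purely supervised runs over a seed list.

    Both runs of a pair share identical weight initialization and seeds
    (only the STDP phase differs).  Returns per-seed iterations-to-
    threshold and the medians (runs that never reach the threshold count
    as ``max_iterations``).
    """
    rows = []
    for seed in seeds:
        base = replace(cfg, seed_weights=seed, seed_encoding=seed + 10_000,
                       seed_data=seed + 20_000, n_iterations=max_iterations)
        stop = lambda log: iterations_to_error(log, threshold) is not None
        res_pre = run_semisupervised(replace(base, pretrain=True), stop_fn=stop)
        res_sup = run_semisupervised(replace(base, pretrain=False), stop_fn=stop)
        it_pre = iterations_to_error(res_pre.train_log, threshold)
        it_sup = iterations_to_error(res_sup.train_log, threshold)
        rows.append({
            "seed": seed,
            "iters_pretrained": it_pre if it_pre is not None else max_iterations,
            "iters_supervised": it_sup if it_sup is not None else max_iterations,
            "error_pretrained": res_pre.report.error,
            "error_supervised": res_sup.report.error,
        })
    return {
        "per_seed": rows,
        "median_pretrained": float(np.median([r["iters_pretrained"] for r in rows])),
        "median_supervised": float(np.median([r["iters_supervised"] for r in rows])),
    }


# ---------------------------------------------------------------------------
# Persistence

def write_metrics_csv(log: list[TrainLogRow], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["iteration", "epoch", "loss", "batch_error"])
        for row in log:
            writer.writerow([row.iteration, row.epoch,
                             repr(row.loss), repr(row.batch_error)])


def save_checkpoint(net: SpikingNetwork, cfg: RunConfig, path) -> None:
    """Portable checkpoint: layer names, weights, thresholds, config hash."""
    arrays = {}
    meta = {"topology": net.spec.topology, "config_hash": cfg.config_hash(),
            "layers": []}
    for i, p in enumerate(net.params):
        meta["layers"].append(p.kind)
        if p.weights is not None:
            arrays[f"w{i}"] = p.weights
        if p.thresholds is not None:
            arrays[f"th{i}"] = p.thresholds
    arrays["_meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path, cfg: RunConfig) -> SpikingNetwork:
    with np.load(path) as data:
        meta = json.loads(bytes(data["_meta"]).decode())
        net = SpikingNetwork.build(meta["topology"], np.random.default_rng(0),
                                   cfg.init_scheme, cfg.alpha_conv, cfg.alpha_fc,
                                   cfg.tau_m_ms)
        for i, p in enumerate(net.params):
            if f"w{i}" in data:
                p.weights = data[f"w{i}"]
            if f"th{i}" in data:
                p.thresholds = data[f"th{i}"]
    return net
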