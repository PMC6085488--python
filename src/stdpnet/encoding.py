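"""Image-to-spike encoding, synthetic pattern datasets and IDX file I/O.

The input layer of the network rate-codes pixel intensities as Poisson
spike trains: at every simulation time step each pixel independently emits
a spike with probability ``intensity * max_rate * dt`` (the standard
discrete-time Bernoulli approximation of a Poisson process).  Intensities
live in [0, 1]; an intensity of 1 fires at ``max_rate_hz`` on average.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImageSample",
    "SpikeRaster",
    "IDXFormatError",
    "poisson_encode",
    "generate_patterns",
    "read_idx",
    "write_idx",
]


@dataclass(frozen=True)
class ImageSample:
    """A grayscale image with intensities in [0, 1] and an integer label."""

    pixels: np.ndarray
    label: int

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {px.shape}")
        if px.size and (px.min() < 0.0 or px.max() > 1.0):
            raise ValueError("pixel intensities must lie in [0, 1]")
        if int(self.label) < 0:
            raise ValueError("label must be a non-negative class index")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "label", int(self.label))


@dataclass
class SpikeRaster:
    """Binary spike tensor over (channels, height, width, time_steps).

    ``dt_ms`` is the duration of one simulation time step.  A flattened
    view ``(units, time_steps)`` is available via :meth:`as_units`.
    """

    spikes: np.ndarray
    dt_ms: float = 1.0

    def __post_init__(self) -> None:
        s = np.asarray(self.spikes)
        if not np.isin(s, (0, 1)).all():
            raise ValueError("spike raster entries must be 0 or 1")
        self.spikes = s.astype(np.uint8)
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be positive")

    @property
    def n_steps(self) -> int:
        return self.spikes.shape[-1]

    @property
    def duration_ms(self) -> float:
        return self.n_steps * self.dt_ms

    def as_units(self) -> np.ndarray:
        """Flatten the spatial axes to (units, time_steps), row-major."""
        return self.spikes.reshape(-1, self.spikes.shape[-1])


def _n_steps(duration_ms: float, dt_ms: float) -> int:
    if dt_ms <= 0 or duration_ms <= 0:
        raise ValueError("duration_ms and dt_ms must be positive")
    steps = duration_ms / dt_ms
    n = round(steps)
    if abs(steps - n) > 1e-9 or n < 1:
        raise ValueError(
            f"dt_ms={dt_ms} does not divide duration_ms={duration_ms}"
        )
    return int(n)


def poisson_encode(
    image: ImageSample | np.ndarray,
    max_rate_hz: float,
    duration_ms: float,
    dt_ms: float = 1.0,
    rng: np.random.Generator | None = None,
) -> SpikeRaster:
    """Rate-code an image into a Bernoulli/Poisson spike raster.

    Per time step each pixel spikes independently with probability
    ``intensity * max_rate_hz * dt_ms / 1000``.  Draws are made pixel-first
    in row-major order, then over time (a single uniform array of shape
    ``(H, W, T)``), so rasters are reproducible across platforms for a
    fixed seeded ``rng``.
    """
    pixels = image.pixels if isinstance(image, ImageSample) else np.asarray(image, float)
    if rng is None:
        rng = np.random.default_rng()
    if max_rate_hz <= 0:
        raise ValueError("max_rate_hz must be positive")
    p_max = max_rate_hz * dt_ms / 1000.0
    if p_max > 1.0 + 1e-12:
        raise ValueError(
            f"max_rate_hz={max_rate_hz} at dt_ms={dt_ms} implies per-step "
            f"spike probability {p_max:.3f} > 1"
        )
    n = _n_steps(duration_ms, dt_ms)
    prob = pixels[..., None] * p_max  # (H, W, T) after broadcast
    u = rng.random(pixels.shape + (n,))
    spikes = (u < prob).astype(np.uint8)
    return SpikeRaster(spikes[None, ...], dt_ms=dt_ms)  # single input channel


# ---------------------------------------------------------------------------
# Synthetic pattern datasets

def _bar_templates(h: int, w: int) -> list[np.ndarray]:
    """High-intensity oriented bar / cross / ring templates on an h x w grid."""
    thick = max(1, h // 4)
    mid = h // 2 - thick // 2
    midw = w // 2 - thick // 2
    t = []
    hbar = np.zeros((h, w))
    hbar[mid : mid + thick, :] = 1.0
    t.append(hbar)
    vbar = np.zeros((h, w))
    vbar[:, midw : midw + thick] = 1.0
    t.append(vbar)
    diag = np.zeros((h, w))
    for i in range(h):
        j = int(round(i * (w - 1) / max(1, h - 1)))
        diag[i, max(0, j - thick + 1) : j + 1] = 1.0
    t.append(diag)
    anti = diag[:, ::-1].copy()
    t.append(anti)
    ring = np.zeros((h, w))
    ring[0, :] = ring[-1, :] = ring[:, 0] = ring[:, -1] = 1.0
    t.append(ring)
    block = np.zeros((h, w))
    q = max(1, h // 3)
    block[q : h - q, q : w - q] = 1.0
    t.append(block)
    return t


def class_templates(n_classes: int, image_size: tuple[int, int]) -> list[np.ndarray]:
    """Return the fixed noiseless template for each class."""
    h, w = image_size
    pool = _bar_templates(h, w)
    if n_classes > len(pool):
        raise ValueError(
            f"at most {len(pool)} distinct templates available for {h}x{w} images"
        )
    return pool[:n_classes]


def generate_patterns(
    n_classes: int,
    image_size: tuple[int, int],
    samples_per_class: int,
    noise_level: float,
    rng: np.random.Generator | None = None,
) -> list[ImageSample]:
    """Generate a class-balanced synthetic pattern dataset.

    Each class has a fixed high-intensity template (oriented bars, a cross
    diagonal, a ring, a block); each sample adds i.i.d. uniform pixel noise
    of amplitude ``noise_level`` and clips to [0, 1].  Samples are returned
    grouped by class (class 0 first); shuffle downstream if needed.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if not 0.0 <= noise_level <= 1.0:
        raise ValueError("noise_level must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng()
    templates = class_templates(n_classes, tuple(image_size))
    samples: list[ImageSample] = []
    for label, tpl in enumerate(templates):
        for _ in range(samples_per_class):
            if noise_level > 0:
                noise = rng.uniform(-noise_level, noise_level, size=tpl.shape)
                px = np.clip(tpl + noise, 0.0, 1.0)
            else:
                px = tpl.copy()
            samples.append(ImageSample(px, label))
    return samples


# ---------------------------------------------------------------------------
# IDX (MNIST) file format

class IDXFormatError(ValueError):
    """Raised when a file does not conform to the IDX container format."""


_IDX_DTYPES = {
    0x08: np.dtype(">u1"),
    0x09: np.dtype(">i1"),
    0x0B: np.dtype(">i2"),
    0x0C: np.dtype(">i4"),
    0x0D: np.dtype(">f4"),
    0x0E: np.dtype(">f8"),
}


def read_idx(path, normalize: bool = True) -> np.ndarray:
    """Read an IDX-format array (the MNIST container format).

    The header is big-endian: two zero bytes, a dtype code, the rank, then
    one uint32 per dimension.  With ``normalize`` (default), unsigned-byte
    data are scaled to [0, 1] by dividing by 255; other dtypes and label
    files (rank 1) are returned as numbers.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 4:
        raise IDXFormatError(f"{path}: truncated IDX header ({len(raw)} bytes)")
    zeros, dtype_code, rank = raw[0] << 8 | raw[1], raw[2], raw[3]
    if zeros != 0:
        raise IDXFormatError(f"{path}: bad magic number {raw[:4].hex()}")
    if dtype_code not in _IDX_DTYPES:
        raise IDXFormatError(f"{path}: unknown IDX dtype code 0x{dtype_code:02x}")
    dtype = _IDX_DTYPES[dtype_code]
    header_len = 4 + 4 * rank
    if len(raw) < header_len:
        raise IDXFormatError(f"{path}: truncated dimension header")
    dims = struct.unpack(f">{rank}I", raw[4:header_len])
    expected = int(np.prod(dims)) * dtype.itemsize if rank else dtype.itemsize
    payload = raw[header_len:]
    if len(payload) != expected:
        raise IDXFormatError(
            f"{path}: payload has {len(payload)} bytes, header implies {expected}"
        )
    arr = np.frombuffer(payload, dtype=dtype).reshape(dims)
    if normalize and dtype_code == 0x08 and rank >= 2:
        return arr.astype(np.float64) / 255.0
    return arr.astype(arr.dtype.newbyteorder("="))


def write_idx(path, array: np.ndarray) -> None:
    """Write an array in IDX format (unsigned-byte payload)."""
    arr = np.ascontiguousarray(array, dtype=np.uint8)
    with open(path, "wb") as fh:
        fh.write(bytes([0, 0, 0x08, arr.ndim]))
        fh.write(struct.pack(f">{arr.ndim}I", *arr.shape))
        fh.write(arr.tobytes())
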