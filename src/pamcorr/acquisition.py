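"""Depth-resolved A-line simulation and MAP reconstruction.

An OR-PAM acquisition records, at every lateral raster position, a
depth-resolved time signal (A-line) whose amplitude tracks local optical
absorption.  This module simulates such volumes from a 2-D phantom — each
absorbing pixel emits a bipolar photoacoustic pulse modeled as the first
derivative of a Gaussian — and reconstructs the standard maximum-amplitude
projection (MAP): per A-line, the envelope is obtained as the magnitude of
the analytic signal (Hilbert transform) and the maximum over depth becomes
the image pixel.

The pulse is amplitude-normalized so a source of absorption ``a`` produces a
peak signal magnitude of exactly ``a`` at integer sample offsets ±sigma from
the pulse center.  Depth indexing is in samples; physical depth calibration
is metadata only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import hilbert as _scipy_hilbert

from .phantom import PhantomImage

__all__ = [
    "RawVolume",
    "MAPImage",
    "simulate_volume",
    "hilbert_envelope",
    "map_project",
    "write_volume",
    "read_volume",
    "write_map_tiff",
]


@dataclass(frozen=True)
class RawVolume:
    """3-D stack of A-lines indexed (slow-axis row Y, fast-axis column X, depth)."""

    samples: np.ndarray
    sampling_rate_hz: float = 250e6
    pulse_center_freq_hz: float = 10e6

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=np.float64)
        if arr.ndim != 3:
            raise ValueError(f"volume must be 3-D, got shape {arr.shape}")
        if arr.shape[2] < 8:
            raise ValueError("depth dimension must have at least 8 samples")
        if not np.all(np.isfinite(arr)):
            raise ValueError("volume samples must be finite")
        if self.sampling_rate_hz <= 0 or self.pulse_center_freq_hz <= 0:
            raise ValueError("rates must be positive")
        object.__setattr__(self, "samples", arr)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.samples.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class MAPImage:
    """Maximum-amplitude-projection image; envelope magnitudes, hence >= 0."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError("MAP image must be 2-D")
        if not np.all(np.isfinite(px)):
            raise ValueError("MAP pixels must be finite")
        if px.min() < 0:
            raise ValueError("MAP pixels must be non-negative")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def _bipolar_pulse(t: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian first-derivative pulse, normalized to peak magnitude 1 at t = ±sigma."""
    return -(t / sigma) * np.exp(0.5 - t * t / (2.0 * sigma * sigma))


def simulate_volume(
    phantom: PhantomImage,
    n_depth: int = 64,
    depth_jitter: int = 4,
    pulse_width: int = 4,
    noise_sigma: float = 0.0,
    seed: int = 0,
    sampling_rate_hz: float = 250e6,
    pulse_center_freq_hz: float = 10e6,
) -> RawVolume:
    """Simulate a noiseless-or-noisy A-line volume from a phantom.

    Each pixel with absorption ``a > 0`` places one bipolar pulse of width
    ``pulse_width`` (the Gaussian sigma, in samples) at depth
    ``n_depth//2 + u`` with ``u`` uniform on [-depth_jitter, depth_jitter];
    zero-mean Gaussian noise of std ``noise_sigma`` is added everywhere.
    Deterministic under ``seed``.
    """
    if pulse_width < 1:
        raise ValueError("pulse_width must be >= 1 sample")
    if n_depth < 4 * pulse_width:
        raise ValueError("n_depth must be at least 4 x pulse_width")
    if depth_jitter < 0 or noise_sigma < 0:
        raise ValueError("depth_jitter and noise_sigma must be non-negative")

    rng = np.random.default_rng(seed)
    height, width = phantom.shape
    amp = phantom.pixels
    centers = n_depth // 2 + rng.integers(
        -depth_jitter, depth_jitter + 1, size=(height, width)
    )
    t = np.arange(n_depth, dtype=np.float64)
    # pulse evaluated per pixel at t - center; vectorized over the image
    tt = t[None, None, :] - centers[:, :, None]
    vol = amp[:, :, None] * _bipolar_pulse(tt, float(pulse_width))
    vol[amp == 0, :] = 0.0
    if noise_sigma > 0:
        vol = vol + rng.normal(0.0, noise_sigma, size=vol.shape)
    return RawVolume(
        samples=vol,
        sampling_rate_hz=sampling_rate_hz,
        pulse_center_freq_hz=pulse_center_freq_hz,
    )


def hilbert_envelope(signal: np.ndarray) -> np.ndarray:
    """Envelope |analytic signal| = sqrt(s^2 + H(s)^2) of a 1-D signal.

    Uses the discrete analytic-signal construction on the full record (no
    windowing); edge samples carry the usual circular-transform distortion.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if signal.ndim != 1:
        raise ValueError("hilbert_envelope expects a 1-D signal")
    if signal.size < 8:
        raise ValueError("signal must have at least 8 samples")
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal must be finite")
    return np.abs(_scipy_hilbert(signal))


def map_project(volume: RawVolume) -> MAPImage:
    """Project the per-A-line envelope maximum along depth to a MAP image."""
    analytic = _scipy_hilbert(volume.samples, axis=2)
    envelope = np.abs(analytic)
    return MAPImage(pixels=envelope.max(axis=2))


# ---------------------------------------------------------------------------
# Volume / MAP IO


def write_volume(path: str | Path, volume: RawVolume) -> None:
    """Write a volume as HDF5 (`/volume` + rate attributes) or multi-page TIFF.

    The TIFF layout stores one page per slow-axis row, each page X x depth.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            ds = f.create_dataset("volume", data=volume.samples.astype(np.float32))
            ds.attrs["sampling_rate_hz"] = volume.sampling_rate_hz
            ds.attrs["pulse_center_freq_hz"] = volume.pulse_center_freq_hz
    elif suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, volume.samples.astype(np.float32))
    else:
        raise ValueError(f"unsupported volume extension: {suffix!r}")


def read_volume(path: str | Path) -> RawVolume:
    """Read a volume written by :func:`write_volume`."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            ds = f["volume"]
            return RawVolume(
                samples=np.asarray(ds, dtype=np.float64),
                sampling_rate_hz=float(ds.attrs.get("sampling_rate_hz", 250e6)),
                pulse_center_freq_hz=float(ds.attrs.get("pulse_center_freq_hz", 10e6)),
            )
    if suffix in (".tif", ".tiff"):
        import tifffile

        return RawVolume(samples=np.asarray(tifffile.imread(path), dtype=np.float64))
    raise ValueError(f"unsupported volume extension: {suffix!r}")


def write_map_tiff(path: str | Path, image: MAPImage) -> None:
    """Write a MAP image as 32-bit float TIFF."""
    import tifffile

    tifffile.imwrite(Path(path), image.pixels.astype(np.float32))
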