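"""Three-layer convolutional network for MAP-image motion correction.

The restoration model is a fully convolutional network mapping a corrupted
MAP image to its motion-free counterpart:

    G1 = relu(W1 * I  + B1)        (feature extraction)
    G2 = relu(W2 * G1 + B2)        (nonlinear mapping)
    O  =      W3 * G2 + B3         (reconstruction; no nonlinearity)

with kernels W1: [k, k, 1, C], W2: [k, k, C, C], W3: [k, k, C, 1] and biases
of length C, C, 1; the default configuration is k = 5, C = 64.  All
convolutions use stride 1 and zero "same" padding so the output spatial
shape equals the input's.  ``*`` is implemented as cross-correlation (no
kernel flip), the standard deep-learning convention; with learned weights
the two are equivalent.

Training minimizes the mean squared error

    L(phi) = (1/n) sum_i || M(X_i; phi) - T_i ||^2

over (corrupted X, clean T) pairs, where ||.||^2 is the per-pair sum of
squared pixel differences (a per-pixel mean variant is available behind
``loss_reduction`` since it only rescales the gradient).  Optimization is
plain mini-batch gradient descent with standard backpropagation; a momentum
variant is available but off by default.

Everything here is plain numpy: convolutions run as im2col + BLAS matrix
multiplies and gradients are derived analytically (and checked against
finite differences in the test suite).
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .acquisition import MAPImage
from .phantom import PhantomImage

__all__ = [
    "NetworkParams",
    "TrainingConfig",
    "LossHistory",
    "TrainingDivergedError",
    "relu",
    "conv2d_same",
    "forward",
    "mse_loss",
    "train",
    "correct_image",
    "save_checkpoint",
    "load_checkpoint",
]


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"training loss became non-finite at epoch {epoch}")


@dataclass(frozen=True)
class NetworkParams:
    """The full parameter set phi = {W1, W2, W3, B1, B2, B3}.

    Kernels are stored [k, k, C_in, C_out]; ``k`` and ``C`` are derived from
    the stored shapes and must be mutually consistent.
    """

    W1: np.ndarray
    W2: np.ndarray
    W3: np.ndarray
    B1: np.ndarray
    B2: np.ndarray
    B3: np.ndarray

    def __post_init__(self) -> None:
        for name in ("W1", "W2", "W3", "B1", "B2", "B3"):
            arr = np.asarray(getattr(self, name))
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            object.__setattr__(self, name, arr)
        k = self.W1.shape[0]
        C = self.W1.shape[3]
        expected = {
            "W1": (k, k, 1, C),
            "W2": (k, k, C, C),
            "W3": (k, k, C, 1),
            "B1": (C,),
            "B2": (C,),
            "B3": (1,),
        }
        for name, shape in expected.items():
            got = getattr(self, name).shape
            if got != shape:
                raise ValueError(f"{name} has shape {got}, expected {shape}")

    @property
    def kernel_size(self) -> int:
        return self.W1.shape[0]

    @property
    def channels(self) -> int:
        return self.W1.shape[3]

    @property
    def n_parameters(self) -> int:
        """Total scalar parameter count (105,729 for the default k=5, C=64)."""
        return sum(
            getattr(self, name).size
            for name in ("W1", "W2", "W3", "B1", "B2", "B3")
        )

    @classmethod
    def initialize(
        cls,
        kernel_size: int = 5,
        channels: int = 64,
        init_std: float = 0.01,
        seed: int = 0,
        dtype=np.float64,
        scheme: str = "gaussian",
    ) -> "NetworkParams":
        """Seeded parameter initialization.

        ``scheme="gaussian"`` draws all weights from N(0, init_std^2) with
        zero biases.  ``scheme="identity"`` adds delta (center-tap) kernels
        on top of the same Gaussian noise so the network starts as an exact
        identity map for non-negative inputs; restoration training then only
        has to learn the repair residual, which converges far faster than
        growing an identity out of small random weights.
        """
        if kernel_size < 1 or channels < 1:
            raise ValueError("kernel_size and channels must be positive")
        if init_std <= 0:
            raise ValueError("init_std must be positive")
        if scheme not in ("gaussian", "identity"):
            raise ValueError("scheme must be 'gaussian' or 'identity'")
        rng = np.random.default_rng(seed)
        k, C = kernel_size, channels
        W1 = rng.normal(0, init_std, (k, k, 1, C))
        W2 = rng.normal(0, init_std, (k, k, C, C))
        W3 = rng.normal(0, init_std, (k, k, C, 1))
        if scheme == "identity":
            center = (k - 1) // 2
            W1[center, center, 0, :] += 1.0
            W2[center, center, :, :] += np.eye(C)
            W3[center, center, :, 0] += 1.0 / C
        return cls(
            W1=W1.astype(dtype),
            W2=W2.astype(dtype),
            W3=W3.astype(dtype),
            B1=np.zeros(C, dtype=dtype),
            B2=np.zeros(C, dtype=dtype),
            B3=np.zeros(1, dtype=dtype),
        )


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of gradient-descent training.

    ``loss_reduction`` selects the per-pair reduction inside the MSE loss:
    ``"per_pair_sum"`` sums squared differences over each image pair before
    averaging over pairs; ``"per_pixel_mean"`` averages over pixels too
    (rescaling the gradient by 1/(H*W)).
    """

    learning_rate: float = 2e-5
    n_epochs: int = 100
    batch_size: int = 16
    init_std: float = 0.01
    seed: int = 0
    optimizer: str = "plain_gd"
    momentum: float = 0.9
    kernel_size: int = 5
    channels: int = 64
    loss_reduction: str = "per_pair_sum"
    init_scheme: str = "gaussian"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.n_epochs < 1 or self.batch_size < 1:
            raise ValueError("n_epochs and batch_size must be positive")
        if self.init_std <= 0:
            raise ValueError("init_std must be positive")
        if self.optimizer not in ("plain_gd", "momentum_gd"):
            raise ValueError("optimizer must be 'plain_gd' or 'momentum_gd'")
        if self.loss_reduction not in ("per_pair_sum", "per_pixel_mean"):
            raise ValueError(
                "loss_reduction must be 'per_pair_sum' or 'per_pixel_mean'"
            )
        if self.init_scheme not in ("gaussian", "identity"):
            raise ValueError("init_scheme must be 'gaussian' or 'identity'")


@dataclass(frozen=True)
class LossHistory:
    """Per-epoch mean training loss."""

    losses: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "losses", tuple(float(x) for x in self.losses))
        if any(x < 0 for x in self.losses):
            raise ValueError("losses must be non-negative")

    def __len__(self) -> int:
        return len(self.losses)

    def __getitem__(self, i):
        return self.losses[i]

    def save_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as f:
            writer = csv.writer(f)
            writer.writerow(["epoch", "loss"])
            for epoch, loss in enumerate(self.losses):
                writer.writerow([epoch, repr(loss)])


def relu(z: np.ndarray) -> np.ndarray:
    """Rectified linear unit, elementwise max(0, z)."""
    return np.maximum(np.asarray(z), 0)


def _same_pads(k: int) -> tuple[int, int]:
    """(before, after) zero-pad amounts for stride-1 same-shape output.

    Odd k pads symmetrically; even k pads one less before than after
    (e.g. k = 4 -> 1 top/left, 2 bottom/right).
    """
    return (k - 1) // 2, k // 2


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """Unfold a batch [B, H, W, C_in] into columns [B*H*W, k*k*C_in].

    Column ordering matches a kernel stored [k, k, C_in, C_out] flattened to
    [k*k*C_in, C_out].
    """
    before, after = _same_pads(k)
    xp = np.pad(x, ((0, 0), (before, after), (before, after), (0, 0)))
    win = sliding_window_view(xp, (k, k), axis=(1, 2))  # [B, H, W, C, k, k]
    B, H, W = x.shape[:3]
    return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
        B * H * W, k * k * x.shape[3]
    )


def _conv_forward(x: np.ndarray, kernel: np.ndarray, bias: np.ndarray):
    """Batched same-padding cross-correlation; returns (output, im2col cache)."""
    k, _, c_in, c_out = kernel.shape
    cols = _im2col(x, k)
    out = cols @ kernel.reshape(k * k * c_in, c_out) + bias
    B, H, W = x.shape[:3]
    return out.reshape(B, H, W, c_out), cols


def _conv_backward(dY: np.ndarray, cols: np.ndarray, kernel: np.ndarray,
                   x_shape: tuple):
    """Gradients of a same-padding cross-correlation layer.

    Returns (dX, dKernel, dBias) for upstream gradient dY [B, H, W, C_out].
    """
    k, _, c_in, c_out = kernel.shape
    B, H, W = x_shape[:3]
    dYf = dY.reshape(B * H * W, c_out)
    d_bias = dYf.sum(axis=0)
    d_kernel = (cols.T @ dYf).reshape(k, k, c_in, c_out)
    dcols = (dYf @ kernel.reshape(k * k * c_in, c_out).T).reshape(
        B, H, W, k, k, c_in
    )
    before, _ = _same_pads(k)
    dXp = np.zeros((B, H + k - 1, W + k - 1, c_in), dtype=dY.dtype)
    for a in range(k):
        for b in range(k):
            dXp[:, a : a + H, b : b + W, :] += dcols[:, :, :, a, b, :]
    dX = dXp[:, before : before + H, before : before + W, :]
    return dX, d_kernel, d_bias


def conv2d_same(
    input: np.ndarray, kernel: np.ndarray, bias: np.ndarray
) -> np.ndarray:
    """Stride-1, zero-padded "same" 2-D convolution (cross-correlation).

    ``input`` is [H, W, C_in] (or [H, W], treated as one channel), ``kernel``
    [k, k, C_in, C_out], ``bias`` [C_out]; the output is [H, W, C_out] — the
    spatial shape is preserved exactly.  Even kernel sizes pad asymmetrically
    (one less at the top/left).
    """
    x = np.asarray(input, dtype=np.float64)
    if x.ndim == 2:
        x = x[:, :, None]
    if x.ndim != 3:
        raise ValueError("input must be [H, W, C_in]")
    kernel = np.asarray(kernel, dtype=np.float64)
    bias = np.asarray(bias, dtype=np.float64)
    if kernel.ndim != 4 or kernel.shape[0] != kernel.shape[1]:
        raise ValueError("kernel must be [k, k, C_in, C_out] with square spatial size")
    if kernel.shape[2] != x.shape[2]:
        raise ValueError(
            f"kernel expects {kernel.shape[2]} input channels, image has {x.shape[2]}"
        )
    if bias.shape != (kernel.shape[3],):
        raise ValueError("bias length must equal C_out")
    out, _ = _conv_forward(x[None], kernel, bias)
    return out[0]


def _forward_batch(x: np.ndarray, params: NetworkParams, keep_cache: bool):
    """Run the three-layer network on a batch [B, H, W, 1].

    Returns (output [B, H, W, 1], cache) where the cache holds the im2col
    matrices and pre-activations needed for backpropagation.
    """
    z1, cols1 = _conv_forward(x, params.W1, params.B1)
    g1 = np.maximum(z1, 0)
    z2, cols2 = _conv_forward(g1, params.W2, params.B2)
    g2 = np.maximum(z2, 0)
    out, cols3 = _conv_forward(g2, params.W3, params.B3)
    if not keep_cache:
        return out, None
    return out, (x.shape, z1, cols1, g1.shape, z2, cols2, g2.shape, cols3)


def forward(image: np.ndarray, params: NetworkParams) -> np.ndarray:
    """Apply the network to a single 2-D image; output has the same shape."""
    img = np.asarray(image, dtype=np.asarray(params.W1).dtype)
    if img.ndim != 2:
        raise ValueError("forward expects a 2-D image")
    if not np.all(np.isfinite(img)):
        raise ValueError("image must be finite")
    out, _ = _forward_batch(img[None, :, :, None], params, keep_cache=False)
    return out[0, :, :, 0]


def _as_pixels(image) -> np.ndarray:
    if isinstance(image, (PhantomImage, MAPImage)):
        return image.pixels
    return np.asarray(image, dtype=np.float64)


def mse_loss(
    outputs: Sequence[np.ndarray],
    targets: Sequence[np.ndarray],
    reduction: str = "per_pair_sum",
) -> float:
    """Mean-squared-error loss over a set of image pairs.

    ``per_pair_sum`` (default): (1/n) sum_i ||O_i - T_i||^2 with the norm
    taken as the SUM of squared pixel differences of pair i.
    ``per_pixel_mean`` divides each pair's sum by its pixel count as well.
    """
    outputs = [_as_pixels(o) for o in outputs]
    targets = [_as_pixels(t) for t in targets]
    if len(outputs) == 0 or len(outputs) != len(targets):
        raise ValueError("need equal-length, non-empty output/target sequences")
    total = 0.0
    for o, t in zip(outputs, targets):
        if o.shape != t.shape:
            raise ValueError(f"shape mismatch: {o.shape} vs {t.shape}")
        sq = float(np.sum((o - t) ** 2))
        if reduction == "per_pixel_mean":
            sq /= o.size
        elif reduction != "per_pair_sum":
            raise ValueError(f"unknown reduction {reduction!r}")
        total += sq
    return total / len(outputs)


def _loss_and_grads(
    params: NetworkParams,
    x: np.ndarray,
    t: np.ndarray,
    reduction: str = "per_pair_sum",
):
    """Batch loss and analytic parameter gradients via backpropagation.

    ``x`` and ``t`` are [B, H, W]; the loss is the batch mean of the per-pair
    reduction, matching :func:`mse_loss` on the same batch.
    """
    B, H, W = x.shape
    xb = x[:, :, :, None]
    out, cache = _forward_batch(xb, params, keep_cache=True)
    resid = out - t[:, :, :, None]
    scale = 1.0 / B
    if reduction == "per_pixel_mean":
        scale /= H * W
    loss = float(np.sum(resid.astype(np.float64) ** 2) * scale)
    if not np.isfinite(loss):
        # no usable gradients from an overflowed forward pass
        return loss, {}
    d_out = (2.0 * scale) * resid

    x_shape, z1, cols1, g1_shape, z2, cols2, g2_shape, cols3 = cache
    d_g2, dW3, dB3 = _conv_backward(d_out, cols3, params.W3, g2_shape)
    d_z2 = d_g2 * (z2 > 0)
    d_g1, dW2, dB2 = _conv_backward(d_z2, cols2, params.W2, g1_shape)
    d_z1 = d_g1 * (z1 > 0)
    _, dW1, dB1 = _conv_backward(d_z1, cols1, params.W1, x_shape)
    grads = {"W1": dW1, "W2": dW2, "W3": dW3, "B1": dB1, "B2": dB2, "B3": dB3}
    return loss, grads


def _extract_pair_arrays(dataset, dtype) -> tuple[np.ndarray, np.ndarray]:
    xs, ts = [], []
    for item in dataset:
        corrupted = _as_pixels(item[0])
        clean = _as_pixels(item[1])
        if corrupted.shape != clean.shape:
            raise ValueError("corrupted/clean shape mismatch in dataset")
        peak = max(float(corrupted.max()), float(clean.max()), 1e-12)
        xs.append((corrupted / peak).astype(dtype))
        ts.append((clean / peak).astype(dtype))
    if not xs:
        raise ValueError("dataset must be non-empty")
    shapes = {a.shape for a in xs}
    if len(shapes) != 1:
        raise ValueError(f"all dataset images must share one shape, got {shapes}")
    return np.stack(xs), np.stack(ts)


def train(
    dataset: Sequence,
    config: TrainingConfig,
) -> tuple[NetworkParams, LossHistory]:
    """Train the network with (mini-batch) gradient descent.

    ``dataset`` is a sequence of (corrupted, clean) pairs (PhantomImage,
    MAPImage or bare arrays; extra tuple fields are ignored).  Parameters are
    initialized from ``config.seed`` (Gaussian weights of std
    ``config.init_std``, zero biases) and updated for ``config.n_epochs``
    epochs; the recorded per-epoch loss is the mean of the batch losses
    evaluated before each update.  Deterministic given the seed.

    Internally the batch pipeline runs in float32 (the BLAS-backed im2col
    path); returned parameters keep that dtype.

    Raises :class:`TrainingDivergedError` if the loss becomes non-finite.
    """
    x, t = _extract_pair_arrays(dataset, np.float32)
    n = x.shape[0]
    if config.batch_size > n:
        raise ValueError(
            f"batch_size {config.batch_size} exceeds dataset size {n}"
        )
    params = NetworkParams.initialize(
        config.kernel_size, config.channels, config.init_std,
        seed=config.seed, dtype=np.float32, scheme=config.init_scheme,
    )
    values = {name: getattr(params, name).copy()
              for name in ("W1", "W2", "W3", "B1", "B2", "B3")}
    velocity = {name: np.zeros_like(v) for name, v in values.items()}
    rng = np.random.default_rng(config.seed + 1)

    losses = []
    for epoch in range(config.n_epochs):
        order = rng.permutation(n) if config.batch_size < n else np.arange(n)
        epoch_losses = []
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            try:
                current = NetworkParams(**values)
            except ValueError as exc:  # parameters blew up to inf/nan
                raise TrainingDivergedError(epoch) from exc
            loss, grads = _loss_and_grads(
                current, x[idx], t[idx], config.loss_reduction
            )
            if not np.isfinite(loss):
                raise TrainingDivergedError(epoch)
            epoch_losses.append(loss)
            for name, g in grads.items():
                if config.optimizer == "momentum_gd":
                    velocity[name] = config.momentum * velocity[name] + g
                    values[name] -= config.learning_rate * velocity[name]
                else:
                    values[name] -= config.learning_rate * g
        losses.append(float(np.mean(epoch_losses)))
    return NetworkParams(**values), LossHistory(losses=tuple(losses))


def correct_image(image, params: NetworkParams):
    """Motion-correct one image with a trained network.

    The input is max-normalized to [0, 1], passed through the network, the
    output clipped to [0, 1], and the original scale restored.  An all-zero
    image is returned unchanged (documented no-op).  The return value has
    the same type as the input.
    """
    px = _as_pixels(image)
    peak = float(px.max())
    if peak <= 0:
        out = px.copy()
    else:
        out = forward((px / peak).astype(np.float64), params)
        out = np.clip(out, 0.0, 1.0) * peak
    out = out.astype(np.float64)
    if isinstance(image, PhantomImage):
        return PhantomImage(pixels=np.clip(out, 0.0, 1.0),
                            pixel_size_um=image.pixel_size_um)
    if isinstance(image, MAPImage):
        return MAPImage(pixels=out)
    return out


# ---------------------------------------------------------------------------
# Checkpoint IO


def save_checkpoint(
    path: str | Path,
    params: NetworkParams,
    config: TrainingConfig | None = None,
) -> None:
    """Write parameters to HDF5 (datasets W1..B3, attrs k and C).

    If ``config`` is given, a JSON sidecar ``<path>.json`` records the
    training configuration.
    """
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        for name in ("W1", "W2", "W3", "B1", "B2", "B3"):
            f.create_dataset(name, data=getattr(params, name))
        f.attrs["k"] = params.kernel_size
        f.attrs["C"] = params.channels
    if config is not None:
        Path(str(path) + ".json").write_text(json.dumps(asdict(config), indent=2))


def load_checkpoint(path: str | Path) -> NetworkParams:
    """Load parameters written by :func:`save_checkpoint`."""
    import h5py

    with h5py.File(Path(path), "r") as f:
        return NetworkParams(
            **{name: np.asarray(f[name]) for name in
               ("W1", "W2", "W3", "B1", "B2", "B3")}
        )


def load_training_config(checkpoint_path: str | Path) -> TrainingConfig | None:
    """Load the JSON sidecar written next to a checkpoint, if present."""
    sidecar = Path(str(Path(checkpoint_path)) + ".json")
    if not sidecar.exists():
        return None
    return TrainingConfig(**json.loads(sidecar.read_text()))
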