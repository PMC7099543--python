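import numpy as np
import pytest

import pamcorr as pc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_phantom():
    return pc.generate_vessel_phantom(32, 32, 4, (2, 4), 0.3, seed=11)


@pytest.fixture
def tiny_params():
    """A small random network (k=3, C=2) for fast forward/backward checks."""
    return pc.NetworkParams.initialize(kernel_size=3, channels=2,
                                       init_std=0.1, seed=5)


def brute_force_conv2d_same(x, kernel, bias):
    """Triple-loop multiply-accumulate oracle for stride-1 same-padding
    cross-correlation; written independently of the library's im2col path.

    Even kernel sizes offset the window so that one less pad row/column is
    used at the top/left than at the bottom/right.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 2:
        x = x[:, :, None]
    k = kernel.shape[0]
    before = (k - 1) // 2
    H, W, c_in = x.shape
    c_out = kernel.shape[3]
    out = np.zeros((H, W, c_out))
    for i in range(H):
        for j in range(W):
            for co in range(c_out):
                acc = bias[co]
                for a in range(k):
                    for b in range(k):
                        ii, jj = i + a - before, j + b - before
                        if 0 <= ii < H and 0 <= jj < W:
                            for ci in range(c_in):
                                acc += x[ii, jj, ci] * kernel[a, b, ci, co]
                out[i, j, co] = acc
    return out


@pytest.fixture
def conv_oracle():
    return brute_force_conv2d_same
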