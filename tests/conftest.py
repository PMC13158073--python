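"""Shared fixtures and independent brute-force oracles.

The naive convolution implementations here are deliberate nested-loop
re-derivations of the definitions; they never touch the package's im2col
path and serve as the ground truth the fast implementations are checked
against.
"""

import numpy as np
import pytest

from dgfinet import ModelConfig, PhantomSpec, make_dataset, write_dataset
from dgfinet.pipeline import TrainConfig


def naive_conv2d(x, w, b=None, dilation=1, groups=1):
    """Direct stride-1 same-padded grouped 2-D correlation."""
    B, C, H, W = x.shape
    Cout, Cg, k, _ = w.shape
    G = groups
    pad = dilation * (k - 1) // 2
    out = np.zeros((B, Cout, H, W), dtype=np.float64)
    for bb in range(B):
        for co in range(Cout):
            g = co // (Cout // G)
            for i in range(H):
                for j in range(W):
                    acc = 0.0
                    for cg in range(Cg):
                        ci = g * Cg + cg
                        for a in range(k):
                            for d in range(k):
                                ii = i + dilation * (a - k // 2)
                                jj = j + dilation * (d - k // 2)
                                if 0 <= ii < H and 0 <= jj < W:
                                    acc += x[bb, ci, ii, jj] * w[co, cg, a, d]
                    out[bb, co, i, j] = acc
            if b is not None:
                out[bb, co] += b[co]
    return out


def naive_conv1d(s, w, b=0.0):
    """Direct same-padded 1-D correlation of a [B, C] channel descriptor."""
    B, C = s.shape
    k = len(w)
    out = np.zeros((B, C), dtype=np.float64)
    for bb in range(B):
        for c in range(C):
            acc = 0.0
            for a in range(k):
                cc = c + a - k // 2
                if 0 <= cc < C:
                    acc += s[bb, cc] * w[a]
            out[bb, c] = acc + b
    return out


def naive_counts(pred, target, threshold=0.5):
    """Pixel-loop confusion counting."""
    tp = fp = fn = tn = 0
    for p, t in zip(np.ravel(pred), np.ravel(target)):
        pb = p >= threshold
        tb = t >= 0.5
        if pb and tb:
            tp += 1
        elif pb and not tb:
            fp += 1
        elif tb:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


@pytest.fixture(scope="session")
def tiny_model_cfg():
    """Two-stage config small enough for second-scale tests."""
    return ModelConfig(num_stages=2, stage_widths=[4, 8], bottleneck_width=16)


@pytest.fixture(scope="session")
def small_full_cfg():
    """The scaled-down full-variant configuration used by the harness tests."""
    return ModelConfig(stage_widths=[8, 16, 32, 64], bottleneck_width=128,
                       use_ecrb=True, use_agfrb=True, use_dgfi=True,
                       use_lrm=True)


@pytest.fixture(scope="session")
def phantom_dataset_dir(tmp_path_factory):
    """16 phantoms at 64 x 64 written as PNG pairs with a 10/3/3 manifest."""
    out = tmp_path_factory.mktemp("phantoms")
    samples, split = make_dataset(
        16, PhantomSpec(image_size=64), (0.625, 0.1875, 0.1875), seed=11
    )
    write_dataset(samples, split, out, overwrite=True)
    return out


@pytest.fixture
def toy_train_cfg():
    return TrainConfig(epochs=2, batch_size=8, image_size=64, seed=3)
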