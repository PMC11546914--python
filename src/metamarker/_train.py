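"""JIT-compiled minibatch Adam loop for the denoising autoencoder.

The network is tiny (tens to hundreds of units) but an ensemble run takes
hundreds of thousands of minibatch steps, so per-step overhead dominates.
The epoch loop is compiled with explicit loops arranged so that every
innermost loop walks contiguous memory: the encoder weights arrive as
``W1r`` with shape (hidden, features) and the decoder as ``W2r`` with shape
(features, hidden), i.e. both transposed relative to the mathematical
orientation.  All randomness (the per-epoch shuffles) is drawn outside and
passed in, keeping training deterministic for a given seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def adam_train(W1r, b1, W2r, b2, noisy, clean, perms, batch_size, lr):
    """Train in place; ``perms`` holds one row-permutation per epoch.

    Forward pass: relu(relu(x W1 + b1) W2 + b2) with W1 = W1r.T, W2 = W2r.T;
    loss: mean squared error against the clean target.  Adam with
    bias-corrected moments (beta1=0.9, beta2=0.999, eps=1e-8).  Returns the
    mean minibatch loss of the final epoch.
    """
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    n_obs, n_f = noisy.shape
    n_h = W1r.shape[0]
    mW1 = np.zeros_like(W1r); vW1 = np.zeros_like(W1r)
    mb1 = np.zeros_like(b1); vb1 = np.zeros_like(b1)
    mW2 = np.zeros_like(W2r); vW2 = np.zeros_like(W2r)
    mb2 = np.zeros_like(b2); vb2 = np.zeros_like(b2)
    x = np.empty((batch_size, n_f))
    tgt = np.empty((batch_size, n_f))
    h_pre = np.empty((batch_size, n_h))
    h = np.empty((batch_size, n_h))
    g_out = np.empty((batch_size, n_f))
    g_h = np.empty((batch_size, n_h))
    gW1 = np.empty_like(W1r); gb1 = np.empty_like(b1)
    gW2 = np.empty_like(W2r); gb2 = np.empty_like(b2)
    t = 0
    epoch_loss = 0.0
    for ep in range(perms.shape[0]):
        perm = perms[ep]
        total = 0.0
        n_batches = 0
        for start in range(0, n_obs, batch_size):
            end = min(start + batch_size, n_obs)
            bs = end - start
            for i in range(bs):
                r = perm[start + i]
                for k in range(n_f):
                    x[i, k] = noisy[r, k]
                    tgt[i, k] = clean[r, k]
            # forward: hidden layer
            for i in range(bs):
                for j in range(n_h):
                    s = b1[j]
                    for k in range(n_f):
                        s += x[i, k] * W1r[j, k]
                    h_pre[i, j] = s
                    h[i, j] = s if s > 0.0 else 0.0
            # forward: output layer; gradient passes the output rectifier
            batch_loss = 0.0
            inv = 2.0 / (bs * n_f)
            for i in range(bs):
                for k in range(n_f):
                    s = b2[k]
                    for j in range(n_h):
                        s += h[i, j] * W2r[k, j]
                    out = s if s > 0.0 else 0.0
                    diff = out - tgt[i, k]
                    batch_loss += diff * diff
                    g_out[i, k] = inv * diff if s > 0.0 else 0.0
            total += batch_loss / (bs * n_f)
            n_batches += 1
            # backward
            gW1[:] = 0.0
            gW2[:] = 0.0
            for k in range(n_f):
                s = 0.0
                for i in range(bs):
                    s += g_out[i, k]
                gb2[k] = s
            for i in range(bs):
                for k in range(n_f):
                    c = g_out[i, k]
                    if c != 0.0:
                        for j in range(n_h):
                            gW2[k, j] += c * h[i, j]
            for i in range(bs):
                for j in range(n_h):
                    g_h[i, j] = 0.0
                for k in range(n_f):
                    c = g_out[i, k]
                    if c != 0.0:
                        for j in range(n_h):
                            g_h[i, j] += c * W2r[k, j]
                for j in range(n_h):
                    if h_pre[i, j] <= 0.0:
                        g_h[i, j] = 0.0
            for j in range(n_h):
                s = 0.0
                for i in range(bs):
                    s += g_h[i, j]
                gb1[j] = s
            for i in range(bs):
                for j in range(n_h):
                    c = g_h[i, j]
                    if c != 0.0:
                        for k in range(n_f):
                            gW1[j, k] += c * x[i, k]
            # Adam update with bias correction
            t += 1
            c1 = 1.0 - beta1**t
            c2 = 1.0 - beta2**t
            for j in range(n_h):
                for k in range(n_f):
                    g = gW1[j, k]
                    mW1[j, k] = beta1 * mW1[j, k] + (1 - beta1) * g
                    vW1[j, k] = beta2 * vW1[j, k] + (1 - beta2) * g * g
                    W1r[j, k] -= lr * (mW1[j, k] / c1) / (np.sqrt(vW1[j, k] / c2) + eps)
            for j in range(n_h):
                g = gb1[j]
                mb1[j] = beta1 * mb1[j] + (1 - beta1) * g
                vb1[j] = beta2 * vb1[j] + (1 - beta2) * g * g
                b1[j] -= lr * (mb1[j] / c1) / (np.sqrt(vb1[j] / c2) + eps)
            for k in range(n_f):
                for j in range(n_h):
                    g = gW2[k, j]
                    mW2[k, j] = beta1 * mW2[k, j] + (1 - beta1) * g
                    vW2[k, j] = beta2 * vW2[k, j] + (1 - beta2) * g * g
                    W2r[k, j] -= lr * (mW2[k, j] / c1) / (np.sqrt(vW2[k, j] / c2) + eps)
            for k in range(n_f):
                g = gb2[k]
                mb2[k] = beta1 * mb2[k] + (1 - beta1) * g
                vb2[k] = beta2 * vb2[k] + (1 - beta2) * g * g
                b2[k] -= lr * (mb2[k] / c1) / (np.sqrt(vb2[k] / c2) + eps)
        epoch_loss = total / n_batches
    return epoch_loss
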