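"""Independent reference implementations used to check the package.

Everything here is written as literal scalar loops over the defining
equations, deliberately avoiding the package's vectorised code paths.
"""

from __future__ import annotations

import math

import numpy as np


def gru_scalar_loop(x, M_z, M_s, M_r, N_z, N_s, N_r, b_z, b_s, b_r, h0):
    """Hidden states of a GRU computed element by element from the four gate
    equations."""
    L, D = x.shape
    H = len(b_z)
    h = [float(v) for v in h0]
    states = []
    sig = lambda v: 1.0 / (1.0 + math.exp(-v))
    for t in range(L):
        z, r, cand, h_new = [0.0] * H, [0.0] * H, [0.0] * H, [0.0] * H
        for i in range(H):
            az = br = bs = 0.0
            az = sum(M_z[d][i] * x[t][d] for d in range(D)) + sum(
                N_z[j][i] * h[j] for j in range(H)
            ) + b_z[i]
            ar = sum(M_r[d][i] * x[t][d] for d in range(D)) + sum(
                N_r[j][i] * h[j] for j in range(H)
            ) + b_r[i]
            z[i] = sig(az)
            r[i] = sig(ar)
        for i in range(H):
            ns = sum(N_s[j][i] * h[j] for j in range(H))
            a = sum(M_s[d][i] * x[t][d] for d in range(D)) + r[i] * ns + b_s[i]
            cand[i] = math.tanh(a)
        for i in range(H):
            h_new[i] = z[i] * cand[i] + (1.0 - z[i]) * h[i]
        h = h_new
        states.append(list(h))
    return np.array(states)


def amsgrad_scalar_loop(x0, grads, lr, b1, b2, eps):
    """Bias-corrected AMSGrad on one scalar parameter, step by step."""
    x, m, v, vhat = float(x0), 0.0, 0.0, 0.0
    xs = []
    for t, g in enumerate(grads, start=1):
        m = b1 * m + (1 - b1) * g
        v = b2 * v + (1 - b2) * g * g
        m_hat = m / (1 - b1**t)
        v_hat = v / (1 - b2**t)
        vhat = max(vhat, v_hat)
        x -= lr * m_hat / (math.sqrt(vhat) + eps)
        xs.append(x)
    return xs


def rank_by_enumeration(decisions):
    """1 + number of +1 entries, counted one by one."""
    count = 0
    for d in decisions:
        if d == 1:
            count += 1
    return 1 + count


def confusion_by_recount(predicted, truth):
    tp = fp = tn = fn = 0
    for p, t in zip(predicted, truth):
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    return tp, fp, tn, fn


def mae_mse_by_summation(pred, truth):
    n = len(pred)
    sa = sum(abs(p - t) for p, t in zip(pred, truth))
    ss = sum((p - t) ** 2 for p, t in zip(pred, truth))
    return sa / n, ss / n


def two_term_cross_entropy(probs_true_class):
    """Mean -log probability assigned to the true class, item by item."""
    return sum(-math.log(p) for p in probs_true_class) / len(probs_true_class)
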