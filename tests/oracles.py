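"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is written with explicit Python loops and scalar arithmetic,
deliberately sharing no code with the package implementation.
"""

import math

import numpy as np


def conv2d_loops(x, weight, bias=None, stride=1, groups=1):
    """Explicit-loop 2-D convolution with 'same' zero padding.

    x: (N, C_in, H, W); weight: (C_out, C_in/groups, k, k).
    """
    n, cin, h, w = x.shape
    cout, cpg, k, _ = weight.shape
    p = k // 2
    ho = (h + 2 * p - k) // stride + 1
    wo = (w + 2 * p - k) // stride + 1
    xp = np.zeros((n, cin, h + 2 * p, w + 2 * p), dtype=np.float64)
    xp[:, :, p:p + h, p:p + w] = x
    out = np.zeros((n, cout, ho, wo), dtype=np.float64)
    copg = cout // groups
    for b in range(n):
        for oc in range(cout):
            g = oc // copg
            for oy in range(ho):
                for ox in range(wo):
                    acc = 0.0
                    for ic in range(cpg):
                        for ky in range(k):
                            for kx in range(k):
                                acc += (weight[oc, ic, ky, kx]
                                        * xp[b, g * cpg + ic,
                                             oy * stride + ky, ox * stride + kx])
                    out[b, oc, oy, ox] = acc
            if bias is not None:
                out[b, oc] += bias[oc]
    return out


def relu_scalar(a):
    return np.where(a > 0, a, 0.0)


def sigmoid_scalar(a):
    return 1.0 / (1.0 + np.exp(-np.asarray(a, dtype=np.float64)))


def mscfe_loops(x, weights, biases, stride):
    """Parallel convolutions (kernel order as given) + ReLU, concatenated."""
    outs = [relu_scalar(conv2d_loops(x, w, b, stride=stride))
            for w, b in zip(weights, biases)]
    return np.concatenate(outs, axis=1)


def dwb_loops(x, dw_weight, dw_bias, pw_weight, pw_bias, stride=1):
    """Depthwise conv -> identity batch norm -> ReLU -> pointwise -> ReLU."""
    cin = x.shape[1]
    y = conv2d_loops(x, dw_weight, dw_bias, stride=stride, groups=cin)
    y = relu_scalar(y)
    z = conv2d_loops(y, pw_weight, pw_bias, stride=1)
    return relu_scalar(z)


def channel_attention_scalars(x, w1, b1, w2, b2):
    """Scalar-arithmetic channel attention: sigma(MLP(max) + MLP(avg))."""
    n, c, h, w = x.shape
    att = np.zeros((n, c))
    for b in range(n):
        mx = [x[b, ch].max() for ch in range(c)]
        av = [x[b, ch].mean() for ch in range(c)]
        def mlp(v):
            hidden = [max(0.0, sum(w1[j, i] * v[i] for i in range(c)) + b1[j])
                      for j in range(w1.shape[0])]
            return [sum(w2[o, j] * hidden[j] for j in range(len(hidden))) + b2[o]
                    for o in range(c)]
        s = np.array(mlp(mx)) + np.array(mlp(av))
        att[b] = sigmoid_scalar(s)
    out = x * att[:, :, None, None]
    return att, out


def spatial_attention_loops(x, conv_weight, conv_bias):
    """Channel max/avg pool -> 7x7 conv -> sigmoid -> broadcast multiply."""
    n, c, h, w = x.shape
    mx = x.max(axis=1)
    av = x.mean(axis=1)
    cat = np.stack([mx, av], axis=1)
    z = conv2d_loops(cat, conv_weight, conv_bias)
    att = sigmoid_scalar(z)
    return att[:, 0], x * att


def auc_pair_counting(y_true, scores):
    """AUC by exhaustive positive/negative pair comparison; ties count 1/2."""
    pos = [s for s, y in zip(scores, y_true) if y == 1]
    neg = [s for s, y in zip(scores, y_true) if y == 0]
    if not pos or not neg:
        raise ValueError("both classes required")
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def gradcam_toy_expected(a1, a2, w1, w2):
    """Closed-form Grad-CAM for logit = w1*mean(A1) + w2*mean(A2)."""
    hw = a1.size
    cam = relu_scalar((w1 * a1 + w2 * a2) / hw)
    lo, hi = cam.min(), cam.max()
    if hi > lo:
        return (cam - lo) / (hi - lo)
    return np.zeros_like(cam)
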