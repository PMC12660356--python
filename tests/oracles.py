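"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is written straight from the operation definitions with
plain Python loops (or one-line closed forms) and never calls into the
package's autodiff engine.
"""

import numpy as np


def conv_loop(x, w, b=None, stride=1, pad=0):
    """Four-nested-loop dense cross-correlation. x:(C,H,W), w:(O,C,kh,kw)."""
    c, h, wd = x.shape
    o, _, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    hout = (h + 2 * pad - kh) // stride + 1
    wout = (wd + 2 * pad - kw) // stride + 1
    out = np.zeros((o, hout, wout))
    for oc in range(o):
        for i in range(hout):
            for j in range(wout):
                acc = 0.0
                for ic in range(c):
                    for r in range(kh):
                        for cc in range(kw):
                            acc += xp[ic, i * stride + r, j * stride + cc] * w[oc, ic, r, cc]
                out[oc, i, j] = acc + (0.0 if b is None else b[oc])
    return out


def depthwise_loop(x, w, b=None, stride=1, pad=0):
    """Per-channel cross-correlation. x:(C,H,W), w:(C,kh,kw)."""
    c, h, wd = x.shape
    _, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    hout = (h + 2 * pad - kh) // stride + 1
    wout = (wd + 2 * pad - kw) // stride + 1
    out = np.zeros((c, hout, wout))
    for ch in range(c):
        for i in range(hout):
            for j in range(wout):
                acc = 0.0
                for r in range(kh):
                    for cc in range(kw):
                        acc += xp[ch, i * stride + r, j * stride + cc] * w[ch, r, cc]
                out[ch, i, j] = acc + (0.0 if b is None else b[ch])
    return out


def bn_eval(x, gamma, beta, rmean, rvar, eps=1e-5):
    """Evaluation-mode batch norm on a (C,H,W) map."""
    out = np.empty_like(x, dtype=float)
    for c in range(x.shape[0]):
        out[c] = gamma[c] * (x[c] - rmean[c]) / np.sqrt(rvar[c] + eps) + beta[c]
    return out


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def bilinear_up(x, scale):
    """align_corners=False bilinear upsampling of a (C,H,W) map."""
    c, h, w = x.shape
    out = np.zeros((c, h * scale, w * scale))
    for i in range(h * scale):
        for j in range(w * scale):
            sy = (i + 0.5) / scale - 0.5
            sx = (j + 0.5) / scale - 0.5
            y0 = min(max(int(np.floor(sy)), 0), h - 1)
            x0 = min(max(int(np.floor(sx)), 0), w - 1)
            y1 = min(y0 + 1, h - 1)
            x1 = min(x0 + 1, w - 1)
            ty = min(max(sy - np.floor(sy), 0.0), 1.0)
            tx = min(max(sx - np.floor(sx), 0.0), 1.0)
            if sy < 0 or sy > h - 1:
                ty = 0.0
            if sx < 0 or sx > w - 1:
                tx = 0.0
            out[:, i, j] = ((1 - ty) * ((1 - tx) * x[:, y0, x0] + tx * x[:, y0, x1])
                            + ty * ((1 - tx) * x[:, y1, x0] + tx * x[:, y1, x1]))
    return out


def avgpool_loop(x, k=3, stride=2, pad=1):
    """Zero-padded average pooling (padding counted in the mean)."""
    c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    hout = (h + 2 * pad - k) // stride + 1
    wout = (w + 2 * pad - k) // stride + 1
    out = np.zeros((c, hout, wout))
    for ch in range(c):
        for i in range(hout):
            for j in range(wout):
                out[ch, i, j] = xp[ch, i * stride:i * stride + k,
                                   j * stride:j * stride + k].mean()
    return out


def channel_attention_oracle(fm, beta):
    """Gram matrix, row softmax, weighted channel sum, scaled residual."""
    c, h, w = fm.shape
    a = fm.reshape(c, h * w)
    gram = np.zeros((c, c))
    for i in range(c):
        for j in range(c):
            gram[i, j] = float(a[i] @ a[j])
    attn = np.zeros_like(gram)
    for i in range(c):
        e = np.exp(gram[i] - gram[i].max())
        attn[i] = e / e.sum()
    out = np.zeros_like(a)
    for j in range(c):
        for i in range(c):
            out[j] += attn[j, i] * a[i]
    return (beta * out + a).reshape(c, h, w)


def position_attention_oracle(fm, beta):
    """Pixel-affinity softmax attention with identity projections."""
    c, h, w = fm.shape
    a = fm.reshape(c, h * w)
    hw = h * w
    energy = np.zeros((hw, hw))
    for i in range(hw):
        for j in range(hw):
            energy[i, j] = float(a[:, i] @ a[:, j])
    pw = np.zeros_like(energy)
    for i in range(hw):
        e = np.exp(energy[i] - energy[i].max())
        pw[i] = e / e.sum()
    out = np.zeros_like(a)
    for j in range(hw):
        for i in range(hw):
            out[:, j] += pw[j, i] * a[:, i]
    return (beta * out + a).reshape(c, h, w)


def _conv_params(m):
    return (m.weight.data, None if m.bias is None else m.bias.data, m.stride, m.pad)


def attention_gate_oracle(gate, x, g):
    """Straight-line eval-mode re-evaluation of an AttentionGate module."""
    if g.shape[1] != x.shape[1]:
        g = bilinear_up(g, x.shape[1] // g.shape[1])
    wx, bx, s, p = _conv_params(gate.wx)
    wg, bg, _, _ = _conv_params(gate.wg)
    sx = conv_loop(x, wx, bx, s, p)
    sg = conv_loop(g, wg, bg, s, p)
    ssum = sx + sg
    if gate.variant == "modified":
        ssum = bn_eval(ssum, gate.bn.gamma.data, gate.bn.beta.data,
                       gate.bn.running_mean, gate.bn.running_var, gate.bn.eps)
    ssum = np.maximum(ssum, 0.0)  # dropout is disabled in eval mode
    wp, bp, s, p = _conv_params(gate.psi)
    alpha = sigmoid(conv_loop(ssum, wp, bp, s, p))
    return x * alpha


def _block_chain(x, dw_or_conv, bn, pw, depthwise):
    if depthwise:
        w, b = dw_or_conv.weight.data, dw_or_conv.bias.data
        y = depthwise_loop(x, w, b, dw_or_conv.stride, dw_or_conv.pad)
    else:
        y = conv_loop(x, *_conv_params(dw_or_conv))
    y = bn_eval(y, bn.gamma.data, bn.beta.data, bn.running_mean, bn.running_var, bn.eps)
    return conv_loop(y, *_conv_params(pw))


def ffc_fuse_oracle(fuse, fm_orig, fm_small):
    """Straight-line eval-mode re-evaluation of an FFCFuse module."""
    p1 = _block_chain(fm_orig, fuse.position1.dw, fuse.position1.bn,
                      fuse.position1.pw, depthwise=True)
    c2 = conv_loop(fm_orig, *_conv_params(fuse.context2.down1))
    c2 = conv_loop(c2, *_conv_params(fuse.context2.down2))
    c2 = bn_eval(c2, fuse.context2.bn.gamma.data, fuse.context2.bn.beta.data,
                 fuse.context2.bn.running_mean, fuse.context2.bn.running_var,
                 fuse.context2.bn.eps)
    c2 = sigmoid(bilinear_up(conv_loop(c2, *_conv_params(fuse.context2.pw)), 4))
    os_out = p1 * c2

    c1 = sigmoid(_block_chain(fm_small, fuse.context1.dw, fuse.context1.bn,
                              fuse.context1.pw, depthwise=True))
    p2 = bilinear_up(fm_small, 4)
    p2 = conv_loop(p2, *_conv_params(fuse.position2.down))
    p2 = bn_eval(p2, fuse.position2.bn.gamma.data, fuse.position2.bn.beta.data,
                 fuse.position2.bn.running_mean, fuse.position2.bn.running_var,
                 fuse.position2.bn.eps)
    p2 = avgpool_loop(conv_loop(p2, *_conv_params(fuse.position2.pw)), 3, 2, 1)
    ss_out = c1 * p2
    return os_out + 4.0 * bilinear_up(ss_out, 4)


def paired_t_oracle(diffs, confidence=0.95):
    """Spreadsheet-style evaluation of the paired-test formulas."""
    from scipy import stats
    d = np.asarray(diffs, dtype=float)
    n = d.size
    mean = d.sum() / n
    var = ((d - mean) ** 2).sum() / (n - 1)
    sd = var ** 0.5
    t = mean / (sd / n ** 0.5)
    p = 2 * stats.t.sf(abs(t), n - 1)
    tcrit = stats.t.ppf(0.5 + confidence / 2, n - 1)
    half = tcrit * sd / n ** 0.5
    return {"mean": mean, "var": var, "sd": sd, "t": t, "dof": n - 1,
            "p": p, "ci": (mean - half, mean + half)}
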