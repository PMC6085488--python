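"""Independent brute-force reference implementations used as test oracles.

Everything here is written with explicit index loops, straight from the
defining equations, and deliberately shares no code with the vectorized
implementations in ``stdpnet``.
"""

from __future__ import annotations

import math

import numpy as np


def conv_current_loops(spikes: np.ndarray, kernels: np.ndarray) -> np.ndarray:
    """Valid cross-correlation via a quintuple loop: (in,h,w) x (o,i,k,k)."""
    n_in, h, w = spikes.shape
    n_out, _, k, _ = kernels.shape
    out = np.zeros((n_out, h - k + 1, w - k + 1))
    for o in range(n_out):
        for x in range(h - k + 1):
            for y in range(w - k + 1):
                acc = 0.0
                for i in range(n_in):
                    for p in range(k):
                        for q in range(k):
                            acc += kernels[o, i, p, q] * spikes[i, x + p, y + q]
                out[o, x, y] = acc
    return out


def activation_loops(spikes: np.ndarray, tau_p: float, dt: float = 1.0):
    """(a, a') at the final step, one unit at a time, term by term."""
    s = spikes.reshape(-1, spikes.shape[-1])
    n_steps = s.shape[-1]
    a = np.zeros(s.shape[0])
    ap = np.ones(s.shape[0])
    for j in range(s.shape[0]):
        for t in range(n_steps):
            if s[j, t]:
                term = math.exp(-(n_steps - 1 - t) * dt / tau_p)
                a[j] += term
                ap[j] += -term * dt / tau_p
    return a.reshape(spikes.shape[:-1]), ap.reshape(spikes.shape[:-1])


def stdp_kernel_update_loops(
    weights: np.ndarray,
    post: np.ndarray,
    trace: np.ndarray,
    eta: float,
    chi: float,
    w_min: float,
    w_max: float,
) -> np.ndarray:
    """Per-location STDP deltas averaged over spiking positions, then clamp."""
    n_out, n_in, k, _ = weights.shape
    new = weights.copy()
    for o in range(n_out):
        locs = [(x, y) for x in range(post.shape[1]) for y in range(post.shape[2])
                if post[o, x, y]]
        if not locs:
            continue
        for i in range(n_in):
            for p in range(k):
                for q in range(k):
                    deltas = []
                    for (x, y) in locs:
                        tr = trace[i, x + p, y + q]
                        deltas.append(
                            eta * (tr - chi)
                            * (w_max - weights[o, i, p, q])
                            * (weights[o, i, p, q] - w_min)
                        )
                    updated = weights[o, i, p, q] + sum(deltas) / len(deltas)
                    new[o, i, p, q] = min(w_max, max(w_min, updated))
    return new


def backward_loops(net, record, label: np.ndarray, tau_p: float):
    """Index-by-index backpropagation through fc / pool / conv layers.

    Returns the list of weight gradients (None for pool layers), following
    the recursion: delta_out = e . a', delta_h = (W delta) . a', fc grads
    as outer products of max-normalized input activations, conv grads
    averaged over output positions sharing a kernel weight, pool routing
    uniform at weight 0.25 with no derivative factor.
    """
    eps = 1e-9
    dt = record.dt_ms
    acts = [activation_loops(s, tau_p, dt) for s in record.spikes]
    a_out, ap_out = acts[-1]
    e = a_out / max(a_out.max(), eps) - np.asarray(label, float)
    delta = e * ap_out
    grads = [None] * len(net.params)
    for idx in range(len(net.params) - 1, -1, -1):
        p = net.params[idx]
        a_pre, ap_pre = acts[idx]
        below_spiking = idx > 0 and net.params[idx - 1].kind in ("conv", "fc")
        if p.kind == "fc":
            pre = (a_pre / max(a_pre.max(), eps)).reshape(-1)
            g = np.zeros_like(p.weights)
            for r in range(g.shape[0]):
                for c in range(g.shape[1]):
                    g[r, c] = pre[r] * delta[c]
            grads[idx] = g
            if idx > 0:
                nd = np.zeros(g.shape[0])
                for r in range(g.shape[0]):
                    for c in range(g.shape[1]):
                        nd[r] += p.weights[r, c] * delta[c]
                nd = nd.reshape(a_pre.shape)
                delta = nd * ap_pre if below_spiking else nd
        elif p.kind == "pool":
            w = p.pool_window
            maps, hp, wp = delta.shape
            nd = np.zeros((maps, hp * w, wp * w))
            for m in range(maps):
                for x in range(hp):
                    for y in range(wp):
                        for u in range(w):
                            for v in range(w):
                                nd[m, w * x + u, w * y + v] = 0.25 * delta[m, x, y]
            delta = nd * ap_pre if below_spiking else nd
        else:  # conv
            k = p.kernel_size
            n_out, n_in = p.weights.shape[:2]
            pre = a_pre / max(a_pre.max(), eps)
            hp, wp = delta.shape[1:]
            g = np.zeros_like(p.weights)
            for o in range(n_out):
                for i in range(n_in):
                    for kp in range(k):
                        for kq in range(k):
                            acc = 0.0
                            for x in range(hp):
                                for y in range(wp):
                                    acc += pre[i, x + kp, y + kq] * delta[o, x, y]
                            g[o, i, kp, kq] = acc / (hp * wp)
            grads[idx] = g
            if idx > 0:
                h_in = hp + k - 1
                w_in = wp + k - 1
                nd = np.zeros((n_in, h_in, w_in))
                for i in range(n_in):
                    for u in range(h_in):
                        for v in range(w_in):
                            acc = 0.0
                            for o in range(n_out):
                                for kp in range(k):
                                    for kq in range(k):
                                        x, y = u - kp, v - kq
                                        if 0 <= x < hp and 0 <= y < wp:
                                            acc += p.weights[o, i, kp, kq] * delta[o, x, y]
                            nd[i, u, v] = acc
                delta = nd * ap_pre if below_spiking else nd
    return grads
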