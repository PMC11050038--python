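"""Compiled inner loop for online back-propagation training.

The per-pattern update is tiny (tens of multiply-adds), so a Python-level
loop dominates runtime at the epoch counts typical for Stage II; the loop is
therefore compiled with numba.  The mathematics is identical to
:func:`cpbpe.bpe.backprop_step`, and the test suite checks one-epoch
equivalence between the two routes.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def train_bpe_online(X, y, w_h, w_o, dw_h, dw_o, orders, eta, mu, sigmoid_out):
    """Online backprop with momentum over a fixed presentation schedule.

    X : (m, n) scaled inputs;  y : (m,) scaled targets.
    w_h : (n+1, h) hidden weights, last row the bias;  w_o : (h+1,) output
    weights, last entry the bias.  dw_h/dw_o hold the previous updates
    (momentum state).  orders : (epochs, m) int64 presentation schedule.
    All weight and momentum arrays are updated in place.  Returns the
    per-epoch RMSE trace of the outputs observed during each pass.
    """
    epochs, m = orders.shape
    n = X.shape[1]
    h = w_h.shape[1]
    trace = np.empty(epochs)
    hid = np.empty(h)
    for e in range(epochs):
        sse = 0.0
        for ii in range(m):
            s = orders[e, ii]
            # forward pass
            for j in range(h):
                z = w_h[n, j]
                for i in range(n):
                    z += w_h[i, j] * X[s, i]
                hid[j] = 1.0 / (1.0 + np.exp(-z))
            z = w_o[h]
            for j in range(h):
                z += w_o[j] * hid[j]
            if sigmoid_out:
                out = 1.0 / (1.0 + np.exp(-z))
                delta_o = (out - y[s]) * out * (1.0 - out)
            else:
                out = z
                delta_o = out - y[s]
            err = out - y[s]
            sse += err * err
            # hidden-layer updates use the pre-update output weights
            for j in range(h):
                dh = delta_o * w_o[j] * hid[j] * (1.0 - hid[j])
                for i in range(n):
                    d = -eta * dh * X[s, i] + mu * dw_h[i, j]
                    dw_h[i, j] = d
                    w_h[i, j] += d
                d = -eta * dh + mu * dw_h[n, j]
                dw_h[n, j] = d
                w_h[n, j] += d
            for j in range(h):
                d = -eta * delta_o * hid[j] + mu * dw_o[j]
                dw_o[j] = d
                w_o[j] += d
            d = -eta * delta_o + mu * dw_o[h]
            dw_o[h] = d
            w_o[h] += d
        trace[e] = np.sqrt(sse / m)
    return trace
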