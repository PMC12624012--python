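"""Minimal NumPy feedforward machinery: MLPs, Adam, and the double-backprop
used by the WGAN-GP gradient penalty.

The networks here are small (two or three hidden layers, widths <= 128), so
explicit NumPy forward/backward passes are fast and fully deterministic
under a seeded generator.  All hidden activations are piecewise linear
(ReLU / LeakyReLU), whose second derivative vanishes almost everywhere;
the gradient-penalty backward pass therefore treats the activation-slope
matrices as constants, which is the exact a.e. derivative.
"""

from __future__ import annotations

import numpy as np


class Adam:
    """Standard Adam with bias correction; operates on a flat parameter list."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class MLP:
    """Fully connected net with piecewise-linear hidden activations.

    ``dims`` is ``[d_in, h_1, ..., h_L, d_out]``; the output layer is linear.
    ``slope`` selects the hidden activation: 0.0 gives ReLU, e.g. 0.2 gives
    LeakyReLU(0.2).
    """

    def __init__(self, dims, slope: float, rng: np.random.Generator):
        self.dims = list(dims)
        self.slope = slope
        self.Ws = []
        self.bs = []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            std = np.sqrt(2.0 / fan_in)
            self.Ws.append(rng.normal(0.0, std, size=(fan_in, fan_out)))
            self.bs.append(np.zeros(fan_out))

    @property
    def params(self):
        return self.Ws + self.bs

    def _act(self, a):
        return np.where(a > 0, a, self.slope * a)

    def _act_slope(self, a):
        return np.where(a > 0, 1.0, self.slope)

    def forward(self, x, dropout_rate=0.0, rng=None, train=False):
        """Returns (output, cache).  Inverted dropout on hidden activations."""
        h = x
        hs, slopes, masks = [x], [], []
        n_layers = len(self.Ws)
        for l, (W, b) in enumerate(zip(self.Ws, self.bs)):
            a = h @ W + b
            if l < n_layers - 1:
                slopes.append(self._act_slope(a))
                h = self._act(a)
                if train and dropout_rate > 0:
                    mask = (rng.random(h.shape) >= dropout_rate) / (1 - dropout_rate)
                    h = h * mask
                    masks.append(mask)
                else:
                    masks.append(None)
                hs.append(h)
            else:
                h = a
        return h, (hs, slopes, masks)

    def backward(self, cache, dout):
        """Backprop an upstream gradient; returns (param_grads, dx)."""
        hs, slopes, masks = cache
        gW = [None] * len(self.Ws)
        gb = [None] * len(self.bs)
        delta = dout
        for l in range(len(self.Ws) - 1, -1, -1):
            gW[l] = hs[l].T @ delta
            gb[l] = delta.sum(axis=0)
            if l > 0:
                delta = delta @ self.Ws[l].T
                if masks[l - 1] is not None:
                    delta = delta * masks[l - 1]
                delta = delta * slopes[l - 1]
        dx = delta @ self.Ws[0].T if len(self.Ws) == 1 else delta @ self.Ws[0].T
        return gW + gb, dx

    # -- input gradient and penalty double-backprop (scalar-output nets) ----

    def input_gradient(self, x):
        """Per-sample gradient of the scalar output w.r.t. the input.

        Returns ``(g, pcache)`` where ``g`` has the shape of ``x`` and
        ``pcache`` carries the backward vectors needed by
        :meth:`penalty_param_grads`.
        """
        if self.dims[-1] != 1:
            raise ValueError("input_gradient requires a scalar-output net")
        _, (hs, slopes, _m) = self.forward(x)
        B = x.shape[0]
        vs = [None] * len(self.Ws)  # vs[l] = v for layer l (post-activation grads)
        v = np.ones((B, 1))
        for l in range(len(self.Ws) - 1, 0, -1):
            v = (v @ self.Ws[l].T) * slopes[l - 1]
            vs[l - 1] = v
        g = v @ self.Ws[0].T
        return g, (vs, slopes)

    def penalty_param_grads(self, pcache, u):
        """Gradients of sum_b <u_b, g_b> w.r.t. the weights.

        ``u`` is the upstream gradient on the input-gradient ``g`` (already
        including any 1/B averaging).  Activation-slope matrices are treated
        as constants (exact a.e. for piecewise-linear activations), so the
        biases receive no gradient.
        """
        vs, slopes = pcache
        gW = [np.zeros_like(W) for W in self.Ws]
        gb = [np.zeros_like(b) for b in self.bs]
        B = u.shape[0]
        gW[0] = u.T @ vs[0]
        dv = u @ self.Ws[0]
        for l in range(1, len(self.Ws)):
            dpre = dv * slopes[l - 1]
            v_next = vs[l] if l < len(self.Ws) - 1 else np.ones((B, 1))
            gW[l] = dpre.T @ v_next
            dv = dpre @ self.Ws[l]
        return gW + gb
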