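"""LSTM cell arithmetic for scalar-input channels, with analytic backprop.

Each biomarker (and the screening-age channel) feeds its own LSTM whose
input at every step is a single standardized value.  Gates follow the
standard formulation: candidate ``c~ = tanh(h U_c + y W_c + b_c)``, input /
forget / output gates sigmoid of the analogous affine maps, cell update
``c = f * c_prev + i * c~`` and hidden state ``h = o * tanh(c)``.

Weight shapes for hidden size H: input weights W* are (H,) (scalar input),
recurrent kernels U* are (H, H), biases b* are (H,).

The backward pass is hand-derived backpropagation-through-time over the
cached gate activations; gradients are exact, which the training loop's
Adam updates and the numerical-gradient tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ChannelWeights", "lstm_step", "forward_sequence",
           "backward_sequence", "forward_padded", "sigmoid"]


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class ChannelWeights:
    """Parameters of one scalar-input LSTM channel."""

    Wc: np.ndarray
    Wi: np.ndarray
    Wf: np.ndarray
    Wo: np.ndarray
    Uc: np.ndarray
    Ui: np.ndarray
    Uf: np.ndarray
    Uo: np.ndarray
    bc: np.ndarray
    bi: np.ndarray
    bf: np.ndarray
    bo: np.ndarray

    @property
    def H(self) -> int:
        return self.bc.size

    def names(self):
        return ("Wc", "Wi", "Wf", "Wo", "Uc", "Ui", "Uf", "Uo",
                "bc", "bi", "bf", "bo")

    @classmethod
    def zeros(cls, H: int) -> "ChannelWeights":
        z, Z = np.zeros(H), np.zeros((H, H))
        return cls(Wc=z.copy(), Wi=z.copy(), Wf=z.copy(), Wo=z.copy(),
                   Uc=Z.copy(), Ui=Z.copy(), Uf=Z.copy(), Uo=Z.copy(),
                   bc=z.copy(), bi=z.copy(), bf=z.copy(), bo=z.copy())

    @classmethod
    def initialize(cls, H: int, rng) -> "ChannelWeights":
        """Glorot-uniform input weights, random orthogonal recurrent kernels,
        zero biases."""
        limit = np.sqrt(6.0 / (1 + H))

        def glorot():
            return rng.uniform(-limit, limit, size=H)

        def orthogonal():
            q, r = np.linalg.qr(rng.standard_normal((H, H)))
            return q * np.sign(np.diag(r))  # fix sign for a uniform Haar draw

        return cls(Wc=glorot(), Wi=glorot(), Wf=glorot(), Wo=glorot(),
                   Uc=orthogonal(), Ui=orthogonal(), Uf=orthogonal(),
                   Uo=orthogonal(),
                   bc=np.zeros(H), bi=np.zeros(H), bf=np.zeros(H),
                   bo=np.zeros(H))


def lstm_step(h_prev, c_prev, y_in, w: ChannelWeights):
    """One LSTM step; returns (h, c, cache) with cache for backprop."""
    h_prev = np.asarray(h_prev, dtype=float)
    c_prev = np.asarray(c_prev, dtype=float)
    if h_prev.shape != (w.H,) or c_prev.shape != (w.H,):
        raise ValueError(f"state shapes must be ({w.H},)")
    ctilde = np.tanh(h_prev @ w.Uc + y_in * w.Wc + w.bc)
    i = sigmoid(h_prev @ w.Ui + y_in * w.Wi + w.bi)
    f = sigmoid(h_prev @ w.Uf + y_in * w.Wf + w.bf)
    o = sigmoid(h_prev @ w.Uo + y_in * w.Wo + w.bo)
    c = f * c_prev + i * ctilde
    tanh_c = np.tanh(c)
    h = o * tanh_c
    cache = (h_prev, c_prev, float(y_in), ctilde, i, f, o, tanh_c)
    return h, c, cache


def forward_sequence(seq, w: ChannelWeights):
    """Run a channel over a 1-D input sequence; returns (h_T, caches)."""
    h = np.zeros(w.H)
    c = np.zeros(w.H)
    caches = []
    for y in np.asarray(seq, dtype=float):
        h, c, cache = lstm_step(h, c, y, w)
        caches.append(cache)
    return h, caches


def forward_padded(seq_padded, mask, w: ChannelWeights):
    """Forward over a padded sequence, skipping masked steps.

    Equivalent to :func:`forward_sequence` on the unmasked entries; padded
    steps leave the state untouched, so appending padding never changes the
    output.
    """
    seq_padded = np.asarray(seq_padded, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    h = np.zeros(w.H)
    c = np.zeros(w.H)
    for y, m in zip(seq_padded, mask):
        if m:
            h, c, _ = lstm_step(h, c, y, w)
    return h


def backward_sequence(caches, w: ChannelWeights, dh_T):
    """Backprop-through-time given d(loss)/d(h_T); returns gradient dict."""
    grads = {name: np.zeros_like(getattr(w, name)) for name in w.names()}
    dh = np.asarray(dh_T, dtype=float).copy()
    dc = np.zeros(w.H)
    for cache in reversed(caches):
        h_prev, c_prev, y_in, ctilde, i, f, o, tanh_c = cache
        do = dh * tanh_c
        dc = dc + dh * o * (1.0 - tanh_c**2)
        df = dc * c_prev
        di = dc * ctilde
        dctilde = dc * i
        da_o = do * o * (1.0 - o)
        da_f = df * f * (1.0 - f)
        da_i = di * i * (1.0 - i)
        da_c = dctilde * (1.0 - ctilde**2)
        grads["Wo"] += y_in * da_o
        grads["Wf"] += y_in * da_f
        grads["Wi"] += y_in * da_i
        grads["Wc"] += y_in * da_c
        grads["Uo"] += np.outer(h_prev, da_o)
        grads["Uf"] += np.outer(h_prev, da_f)
        grads["Ui"] += np.outer(h_prev, da_i)
        grads["Uc"] += np.outer(h_prev, da_c)
        grads["bo"] += da_o
        grads["bf"] += da_f
        grads["bi"] += da_i
        grads["bc"] += da_c
        dh = (da_o @ w.Uo.T + da_f @ w.Uf.T + da_i @ w.Ui.T + da_c @ w.Uc.T)
        dc = dc * f
    return grads
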