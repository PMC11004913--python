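"""MCMC convergence diagnostics."""

from __future__ import annotations

import numpy as np

__all__ = ["gelman_rubin"]


def gelman_rubin(chains) -> float:
    """Potential scale reduction factor R-hat for one scalar parameter.

    ``chains`` is an (m, n) array of m >= 2 equal-length chains.  Computes
    the classic between/within form: with W the mean within-chain variance
    and B/n the variance of chain means,

        R-hat = sqrt( ((n-1)/n * W + B/n) / W ).

    Two identical chains give sqrt((n-1)/n); diverged chains give values
    far above 1.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need at least two equal-length chains")
    m, n = chains.shape
    if n < 2:
        raise ValueError("chains must have length >= 2")
    W = chains.var(axis=1, ddof=1).mean()
    B_over_n = chains.mean(axis=1).var(ddof=1)
    if W == 0.0:
        return 1.0 if B_over_n == 0.0 else np.inf
    var_plus = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_plus / W))
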