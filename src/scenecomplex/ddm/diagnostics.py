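"""MCMC convergence and posterior-mass hypothesis tests."""

from __future__ import annotations

import numpy as np

__all__ = ["gelman_rubin", "posterior_prob_tests"]


def gelman_rubin(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor (R-hat).

    ``chains`` is (n_chains, n_draws).  Each chain is split in half, the
    between-half variance is compared with the within-half variance;
    values near 1 indicate the chains sample the same distribution.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    if chains.shape[1] < 10:
        raise ValueError("chains too short (need >= 10 draws)")
    n = chains.shape[1] // 2
    halves = np.concatenate([chains[:, :n], chains[:, n : 2 * n]], axis=0)
    m = halves.shape[0]
    within = halves.var(axis=1, ddof=1)
    W = within.mean()
    if W == 0:
        raise ValueError("zero within-chain variance (constant chains)")
    B = n * halves.mean(axis=1).var(ddof=1)
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def posterior_prob_tests(
    trace,
    parameter: str,
    reference: str | float = 0.0,
) -> float:
    """Posterior-mass 'p value' for a parameter.

    Against zero (or any scalar): the fraction of posterior draws on the
    non-dominant side of the reference — i.e. the mass crossing it.
    Against another parameter (by name): the fraction of draws of
    ``parameter`` lying beyond the *mean* of the reference parameter's
    posterior, on the side opposite to where ``parameter``'s own mean
    lies relative to that mean.
    """
    d1 = np.asarray(trace[parameter], dtype=float).ravel()
    if isinstance(reference, str):
        ref_val = float(np.mean(np.asarray(trace[reference], dtype=float)))
    else:
        ref_val = float(reference)
    if np.mean(d1) >= ref_val:
        return float(np.mean(d1 < ref_val))
    return float(np.mean(d1 > ref_val))
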