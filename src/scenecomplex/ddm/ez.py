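"""EZ-diffusion closed-form estimates.

Moment-based inversion of the simple DDM (no inter-trial variabilities,
unbiased start): accuracy, RT variance and RT mean of a single
condition map analytically onto drift rate, boundary separation and
non-decision time.  Used as an independent cross-check of the MCMC
sampler rather than as the primary estimator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["ez_estimates"]


def ez_estimates(
    trials: pd.DataFrame,
    correct_col: str = "correct",
    rt_col: str = "rt",
    s: float = 1.0,
) -> tuple[float, float, float]:
    """Return (v_hat, a_hat, t_er_hat) for a single cell of trials.

    ``trials`` needs a boolean accuracy column and RTs in seconds.
    Accuracy must lie strictly between 0.5 and 1 (the standard edge
    corrections are deliberately not applied).  RT mean and variance are
    taken over correct trials, per the usual formulation.
    """
    acc = float(np.mean(trials[correct_col].astype(bool)))
    if not 0.5 < acc < 1.0:
        raise ValueError(f"accuracy must be strictly in (0.5, 1), got {acc}")
    rt_correct = trials.loc[trials[correct_col].astype(bool), rt_col].to_numpy(float)
    mrt = float(np.mean(rt_correct))
    vrt = float(np.var(rt_correct, ddof=1))
    if vrt <= 0:
        raise ValueError("zero RT variance")

    L = np.log(acc / (1.0 - acc))  # logit of accuracy
    x = L * (L * acc**2 - L * acc + acc - 0.5) / vrt
    v = np.sign(acc - 0.5) * s * x**0.25
    a = s**2 * L / v
    y = -v * a / s**2
    mdt = (a / (2.0 * v)) * (1.0 - np.exp(y)) / (1.0 + np.exp(y))
    t_er = mrt - mdt
    return float(v), float(a), float(t_er)
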