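"""Wiener first-passage-time density and absorption probability.

The density of the decision time at the lower boundary of a Wiener
process with drift ``v``, boundary separation ``a`` and relative start
``w`` is evaluated with the dual series representation: a small-time
expansion (sum over image charges) and a large-time expansion (sine
series), switching automatically to whichever needs fewer terms for the
requested absolute error.  The upper-boundary density follows by the
reflection v -> -v, w -> 1 - w.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DDMParams",
    "wfpt_logpdf",
    "wfpt_density",
    "wfpt_density_marginal",
    "choice_probability",
]

_MAX_TERMS = 64


@dataclass(frozen=True)
class DDMParams:
    """Parameters of the (extended) drift-diffusion model.

    v       drift rate (evidence units / s)
    a       boundary separation (> 0)
    z_rel   relative starting point in (0, 1); absolute start z_rel * a
    t_er    non-decision time (s)
    eta     across-trial sd of drift
    s_z     across-trial range of the starting point (absolute units)
    s_t     across-trial range of non-decision time (s)
    s       diffusion coefficient (fixed at 1 by convention)
    """

    v: float
    a: float
    z_rel: float = 0.5
    t_er: float = 0.0
    eta: float = 0.0
    s_z: float = 0.0
    s_t: float = 0.0
    s: float = 1.0

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError("boundary separation a must be > 0")
        if not 0 < self.z_rel < 1:
            raise ValueError("z_rel must lie strictly in (0, 1)")
        if self.t_er < 0 or self.eta < 0 or self.s_z < 0 or self.s_t < 0:
            raise ValueError("t_er, eta, s_z, s_t must be >= 0")
        if self.s_z >= 2 * min(self.z_rel, 1 - self.z_rel) * self.a:
            raise ValueError("s_z too large: starting point can leave (0, a)")
        if self.t_er < self.s_t / 2:
            raise ValueError("t_er must be >= s_t / 2")
        if not self.s > 0:
            raise ValueError("diffusion coefficient must be > 0")


def _fpt_lower_std(tau: np.ndarray, w: np.ndarray, err: float) -> np.ndarray:
    """Standardised (a=1, v=0) lower-boundary FPT density f(tau; w)."""
    tau = np.asarray(tau, dtype=float)
    w = np.broadcast_to(np.asarray(w, dtype=float), tau.shape)
    out = np.zeros_like(tau)
    ok = tau > 0
    if not np.any(ok):
        return out
    t = tau[ok]
    ww = w[ok]

    # number of terms for each expansion (per element)
    with np.errstate(divide="ignore", invalid="ignore"):
        arg_s = 2.0 * np.sqrt(2.0 * np.pi * t) * err
        ks = np.where(
            arg_s < 1.0,
            2.0 + np.sqrt(np.maximum(-2.0 * t * np.log(np.maximum(arg_s, 1e-300)), 0.0)),
            2.0,
        )
        ks = np.maximum(ks, np.sqrt(t) + 1.0)
        arg_l = np.pi * t * err
        kl = np.where(
            arg_l < 1.0,
            np.sqrt(np.maximum(-2.0 * np.log(np.maximum(arg_l, 1e-300)), 0.0)
                    / (np.pi ** 2 * t)),
            1.0 / (np.pi * np.sqrt(t)),
        )
        kl = np.maximum(kl, 1.0 / (np.pi * np.sqrt(t)))

    use_small = ks < kl
    dens = np.zeros_like(t)

    if np.any(use_small):
        ts, ws = t[use_small], ww[use_small]
        K = int(min(_MAX_TERMS, np.ceil((np.max(ks[use_small]) - 1) / 2) + 1))
        acc = np.zeros_like(ts)
        for k in range(-K, K + 1):
            u = ws + 2.0 * k
            acc += u * np.exp(-(u * u) / (2.0 * ts))
        dens[use_small] = acc / np.sqrt(2.0 * np.pi * ts ** 3)

    use_large = ~use_small
    if np.any(use_large):
        tl, wl = t[use_large], ww[use_large]
        K = int(min(_MAX_TERMS, np.ceil(np.max(kl[use_large]))))
        acc = np.zeros_like(tl)
        for k in range(1, K + 1):
            acc += k * np.exp(-(k * k) * np.pi ** 2 * tl / 2.0) * np.sin(k * np.pi * wl)
        dens[use_large] = np.pi * acc

    out[ok] = np.maximum(dens, 0.0)
    return out


def wfpt_logpdf(
    t, v, a, w=0.5, boundary: str = "lower", err: float = 1e-6, s: float = 1.0
) -> np.ndarray:
    """Vectorised log first-passage density at the requested boundary.

    ``t`` is decision time (RT minus non-decision time); t <= 0 maps to
    -inf.  Arrays broadcast.  This is the eta = s_z = s_t = 0 kernel
    used directly by the hierarchical sampler.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float) / s
    a = np.asarray(a, dtype=float) / s
    w = np.asarray(w, dtype=float)
    if boundary == "upper":
        v, w = -v, 1.0 - w
    elif boundary != "lower":
        raise ValueError("boundary must be 'upper' or 'lower'")
    t, v, a, w = np.broadcast_arrays(t, v, a, w)
    tau = np.where(t > 0, t, np.nan) / (a * a)
    fstd = _fpt_lower_std(np.nan_to_num(tau, nan=-1.0), w, err)
    with np.errstate(divide="ignore"):
        logf = (
            np.log(fstd)
            - 2.0 * np.log(a)
            - v * a * w
            - (v * v) * t / 2.0
        )
    return np.where(t > 0, logf, -np.inf)


def wfpt_density(
    t, params: DDMParams, boundary: str = "lower", tol: float = 1e-6
) -> np.ndarray:
    """First-passage-time density of the decision time at one boundary.

    Requires eta = s_z = s_t = 0 (inter-trial variabilities are handled
    by :func:`wfpt_density_marginal`).  Guaranteed absolute error
    ``tol`` in the series truncation.  t <= 0 returns 0 by convention.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if params.eta != 0 or params.s_z != 0 or params.s_t != 0:
        raise ValueError(
            "wfpt_density requires eta = s_z = s_t = 0; "
            "use wfpt_density_marginal for inter-trial variabilities"
        )
    logf = wfpt_logpdf(
        t, params.v, params.a, params.z_rel, boundary=boundary, err=tol, s=params.s
    )
    return np.exp(logf)


def wfpt_density_marginal(
    t,
    params: DDMParams,
    boundary: str = "lower",
    tol: float = 1e-6,
    n_nodes: int = 21,
) -> np.ndarray:
    """Density marginalised over inter-trial variabilities.

    Drift variability (eta) is integrated with Gauss-Hermite quadrature;
    starting-point range (s_z) with Gauss-Legendre.  Non-decision-time
    range (s_t) is not handled here because this density is a function
    of decision time, on which t_er variability acts as a shift of the
    observed RT, not of the decision time.
    """
    t = np.asarray(t, dtype=float)
    base = DDMParams(v=params.v, a=params.a, z_rel=params.z_rel, s=params.s)
    dens = None
    if params.eta > 0:
        nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
        weights = weights / np.sqrt(2 * np.pi)
        acc = np.zeros_like(t)
        for x, wt in zip(nodes, weights):
            acc += wt * np.exp(
                wfpt_logpdf(t, params.v + params.eta * x, params.a,
                            params.z_rel, boundary, tol, params.s)
            )
        dens = acc
    else:
        dens = np.exp(
            wfpt_logpdf(t, params.v, params.a, params.z_rel, boundary, tol, params.s)
        )
    if params.s_z > 0:
        half = params.s_z / (2.0 * params.a)  # relative half-range
        nodes, weights = np.polynomial.legendre.leggauss(max(7, n_nodes // 3))
        acc = np.zeros_like(t)
        for x, wt in zip(nodes, weights):
            w_i = params.z_rel + half * x
            if params.eta > 0:
                hn, hw = np.polynomial.hermite_e.hermegauss(n_nodes)
                hw = hw / np.sqrt(2 * np.pi)
                inner = np.zeros_like(t)
                for hx, hwt in zip(hn, hw):
                    inner += hwt * np.exp(
                        wfpt_logpdf(t, params.v + params.eta * hx, params.a,
                                    w_i, boundary, tol, params.s)
                    )
            else:
                inner = np.exp(
                    wfpt_logpdf(t, params.v, params.a, w_i, boundary, tol, params.s)
                )
            acc += (wt / 2.0) * inner
        dens = acc
    return dens


def choice_probability(params: DDMParams) -> float:
    """Probability that the accumulator is absorbed at the upper boundary.

    Closed form for drifted Brownian motion started at z = z_rel * a
    between absorbing barriers 0 and a:

        P(upper) = (1 - exp(-2 v z / s^2)) / (1 - exp(-2 v a / s^2))

    with the v -> 0 limit P(upper) = z_rel.  Requires eta = s_z = 0.
    """
    if params.eta != 0 or params.s_z != 0:
        raise ValueError("choice_probability requires eta = s_z = 0")
    v, a, w, s = params.v, params.a, params.z_rel, params.s
    x = 2.0 * v * a / (s * s)
    if abs(x) < 1e-9:
        return float(w)
    # numerically stable: divide num and denom by exp(-x*w)
    with np.errstate(over="ignore"):
        p = np.expm1(-x * w) / np.expm1(-x)
    return float(np.clip(p, 0.0, 1.0))
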