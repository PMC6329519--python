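"""Hierarchical Bayesian estimation of drift-diffusion parameters.

Subject-level drift rates (one per drift-factor cell), boundary
separations (one per boundary-factor cell, sampled in log space) and
non-decision times are drawn around group-level means with group-level
spreads.  Estimation is Metropolis-within-Gibbs on the Wiener
first-passage-time likelihood: subject parameters move by adaptive
random-walk Metropolis (step sizes tuned during burn-in only), group
means and variances by conjugate Gibbs updates (normal /
inverse-gamma).

Response coding: the upper boundary is the "target" response.  For a
target-present (animal) stimulus the nominal drift is +v of its
condition, for a target-absent stimulus -v; the optional trial-level
regressor modulates the drift magnitude, v_i = v_cond + w_cond * x_i,
before the stimulus sign is applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .diagnostics import gelman_rubin
from .ez import ez_estimates
from .wfpt import wfpt_logpdf

__all__ = ["ModelSpec", "MCMCConfig", "PosteriorTrace", "fit_hierarchical", "fit_regression"]

_RT_FLOOR = 1e-4  # clamp on rt - t_er, seconds
_TER_BOUNDS = (0.01, 1.0)


@dataclass(frozen=True)
class ModelSpec:
    """Which factors each DDM parameter varies over.

    ``drift_factors`` / ``boundary_factors`` name columns of the trial
    table whose cell combinations get their own group-level drift /
    boundary parameter.  ``regression`` optionally names a trial-level
    predictor column; its weight varies over ``drift_factors`` cells.
    """

    drift_factors: Sequence[str] = ("condition",)
    boundary_factors: Sequence[str] = ("condition", "instruction")
    regression: str | None = None


@dataclass(frozen=True)
class MCMCConfig:
    chains: int = 3
    draws: int = 2000
    burn: int = 500
    thin: int = 1
    seed: int = 0


@dataclass
class PosteriorTrace:
    """Posterior draws keyed by parameter name, shaped (chains, draws).

    Group-level means carry bare names ("v_HIGH", "a_MED_speed",
    "t_er", "w_LOW"); group spreads are prefixed "sigma_".  Subject
    draws live in ``subject_draws`` keyed the same way with shape
    (chains, draws, subjects).  ``trace[name]`` returns the pooled
    (chains * draws,) sample.
    """

    draws: dict[str, np.ndarray]
    subject_draws: dict[str, np.ndarray]
    rhat: dict[str, float]
    subjects: list
    seed: int
    config: dict
    converged: bool = True

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in self.draws:
            raise KeyError(
                f"unknown parameter {name!r}; available: {sorted(self.draws)}"
            )
        return self.draws[name].reshape(-1)

    def __contains__(self, name: str) -> bool:
        return name in self.draws

    def max_rhat(self) -> float:
        return max(self.rhat.values())

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, arr in self.draws.items():
            flat = arr.reshape(-1)
            rows.append(
                {
                    "parameter": name,
                    "mean": flat.mean(),
                    "sd": flat.std(ddof=1),
                    "q2.5": np.percentile(flat, 2.5),
                    "q97.5": np.percentile(flat, 97.5),
                    "rhat": self.rhat[name],
                }
            )
        return pd.DataFrame(rows)

    def save(self, path: str | Path) -> None:
        """Write draws as an .npz array container plus a JSON sidecar."""
        path = Path(path)
        np.savez(
            path.with_suffix(".npz"),
            **{k: v for k, v in self.draws.items()},
            **{f"subject__{k}": v for k, v in self.subject_draws.items()},
        )
        meta = {
            "parameters": sorted(self.draws),
            "rhat": self.rhat,
            "subjects": [str(s) for s in self.subjects],
            "seed": self.seed,
            "config": self.config,
            "converged": self.converged,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def _cell_labels(trials: pd.DataFrame, factors: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """Integer cell index per trial plus 'level[_level]' cell names."""
    if not factors:
        return np.zeros(len(trials), dtype=int), [""]
    combo = trials[list(factors)].astype(str).agg("_".join, axis=1)
    # stable, meaningful ordering: LOW/MED/HIGH then speed/accurate, else lexicographic
    order = {"LOW": 0, "MED": 1, "HIGH": 2, "speed": 0, "accurate": 1}
    names = sorted(combo.unique(), key=lambda s: tuple(order.get(p, p) for p in s.split("_")))
    lookup = {nm: i for i, nm in enumerate(names)}
    return combo.map(lookup).to_numpy(), names


def _prepare(trials: pd.DataFrame, spec: ModelSpec):
    req = {"subject", "rt", "choice", "category"} | set(spec.drift_factors) | set(
        spec.boundary_factors
    )
    missing = req - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    if (trials["rt"] <= 0).any():
        raise ValueError("all RTs must be > 0")
    subjects = sorted(trials["subject"].unique())
    if len(subjects) < 2:
        raise ValueError("hierarchical fit needs >= 2 subjects")
    subj_idx = trials["subject"].map({s: j for j, s in enumerate(subjects)}).to_numpy()
    drift_cell, drift_names = _cell_labels(trials, spec.drift_factors)
    bound_cell, bound_names = _cell_labels(trials, spec.boundary_factors)
    for j, s in enumerate(subjects):
        mask = subj_idx == j
        if len(np.unique(drift_cell[mask])) < len(drift_names) or len(
            np.unique(bound_cell[mask])
        ) < len(bound_names):
            raise ValueError(f"subject {s}: empty factor cells")
    sign = np.where(trials["category"].to_numpy() == "animal", 1.0, -1.0)
    is_upper = trials["choice"].to_numpy() == "target"
    if not set(trials["choice"].unique()) <= {"target", "non-target"}:
        raise ValueError("choice must be response-coded as target / non-target")
    rt = trials["rt"].to_numpy(float)
    return subjects, subj_idx, drift_cell, drift_names, bound_cell, bound_names, sign, is_upper, rt


class _Sampler:
    """One-chain Metropolis-within-Gibbs state machine."""

    def __init__(self, data, amp, rng, init_jitter):
        (self.subjects, self.js, self.dc, self.dnames, self.bc, self.bnames,
         self.sign, self.upper, self.rt) = data
        self.amp = amp  # trial regressor, None when absent
        self.J = len(self.subjects)
        self.nD = len(self.dnames)
        self.nB = len(self.bnames)
        self.rng = rng

        # crude per-subject initial values from EZ closed forms, jittered per chain
        v0, a0, t0 = 1.0, 1.5, 0.3
        df = pd.DataFrame({
            "subject": self.js, "rt": self.rt,
            "correct": np.where(self.sign > 0, self.upper, ~self.upper),
        })
        v_init = np.full((self.J, self.nD), v0)
        a_init = np.full((self.J, self.nB), a0)
        t_init = np.full(self.J, t0)
        for j in range(self.J):
            sub = df[df["subject"] == j]
            try:
                v_ez, a_ez, t_ez = ez_estimates(sub)
                v_init[j, :] = abs(v_ez)
                a_init[j, :] = np.clip(a_ez, 0.3, 4.0)
                t_init[j] = np.clip(t_ez, 0.05, 0.9 * sub["rt"].min())
            except (ValueError, FloatingPointError):
                t_init[j] = min(t0, 0.9 * sub["rt"].min())
        self.v = v_init + init_jitter * rng.standard_normal((self.J, self.nD))
        self.la = np.log(a_init) + init_jitter * rng.standard_normal((self.J, self.nB))
        self.t_er = np.clip(
            t_init + 0.02 * init_jitter * rng.standard_normal(self.J),
            _TER_BOUNDS[0], None,
        )
        self.w = (
            np.zeros((self.J, self.nD)) + 0.05 * init_jitter * rng.standard_normal((self.J, self.nD))
            if amp is not None else None
        )

        # group-level state
        self.mu_v = self.v.mean(axis=0)
        self.s2_v = np.full(self.nD, 0.25)
        self.mu_la = self.la.mean(axis=0)
        self.s2_la = np.full(self.nB, 0.04)
        self.mu_t = float(np.clip(self.t_er.mean(), *_TER_BOUNDS))
        self.s2_t = 0.01
        if self.w is not None:
            self.mu_w = self.w.mean(axis=0)
            self.s2_w = np.full(self.nD, 0.01)

        # adaptive RW scales
        self.step_v = np.full(self.nD, 0.15)
        self.step_la = np.full(self.nB, 0.1)
        self.step_t = 0.02
        self.step_w = np.full(self.nD, 0.05) if self.w is not None else None

        self.trial_ll = self._loglik_trials(np.arange(len(self.rt)))

    # ---- likelihood ----
    def _loglik_trials(self, idx, v=None, la=None, t_er=None, w=None) -> np.ndarray:
        v = self.v if v is None else v
        la = self.la if la is None else la
        t_er = self.t_er if t_er is None else t_er
        js, dc, bc = self.js[idx], self.dc[idx], self.bc[idx]
        mag = v[js, dc]
        if self.amp is not None:
            wm = self.w if w is None else w
            mag = mag + wm[js, dc] * self.amp[idx]
        mu = self.sign[idx] * mag
        drift = np.where(self.upper[idx], -mu, mu)  # reflect for upper responses
        a = np.exp(la[js, bc])
        t = np.maximum(self.rt[idx] - t_er[js], _RT_FLOOR)
        return wfpt_logpdf(t, drift, a, 0.5, boundary="lower", err=1e-6)

    def _mh_block(self, idx, ll_new, delta_prior):
        """Per-subject accept/reject for a block proposal on trials idx."""
        delta_ll = np.bincount(
            self.js[idx], weights=ll_new - self.trial_ll[idx], minlength=self.J
        )
        log_alpha = delta_ll + delta_prior
        accept = np.log(self.rng.uniform(size=self.J)) < log_alpha
        upd = accept[self.js[idx]]
        self.trial_ll[idx[upd]] = ll_new[upd]
        return accept

    # ---- one iteration ----
    def step(self, adapt: bool):
        rng = self.rng
        acc_stats = {}

        for c in range(self.nD):
            idx = np.flatnonzero(self.dc == c)
            prop = self.v.copy()
            prop[:, c] = self.v[:, c] + self.step_v[c] * rng.standard_normal(self.J)
            ll_new = self._loglik_trials(idx, v=prop)
            dp = (
                -((prop[:, c] - self.mu_v[c]) ** 2 - (self.v[:, c] - self.mu_v[c]) ** 2)
                / (2 * self.s2_v[c])
            )
            acc = self._mh_block(idx, ll_new, dp)
            self.v[acc, c] = prop[acc, c]
            acc_stats[("v", c)] = acc.mean()

        for b in range(self.nB):
            idx = np.flatnonzero(self.bc == b)
            prop = self.la.copy()
            prop[:, b] = self.la[:, b] + self.step_la[b] * rng.standard_normal(self.J)
            ll_new = self._loglik_trials(idx, la=prop)
            dp = (
                -((prop[:, b] - self.mu_la[b]) ** 2 - (self.la[:, b] - self.mu_la[b]) ** 2)
                / (2 * self.s2_la[b])
            )
            acc = self._mh_block(idx, ll_new, dp)
            self.la[acc, b] = prop[acc, b]
            acc_stats[("a", b)] = acc.mean()

        idx = np.arange(len(self.rt))
        prop_t = self.t_er + self.step_t * rng.standard_normal(self.J)
        ok = (prop_t > _TER_BOUNDS[0]) & (prop_t < _TER_BOUNDS[1])
        prop_t = np.where(ok, prop_t, self.t_er)
        ll_new = self._loglik_trials(idx, t_er=prop_t)
        dp = np.where(
            ok,
            -((prop_t - self.mu_t) ** 2 - (self.t_er - self.mu_t) ** 2) / (2 * self.s2_t),
            -np.inf,
        )
        acc = self._mh_block(idx, ll_new, dp)
        self.t_er[acc] = prop_t[acc]
        acc_stats[("t", 0)] = acc.mean()

        if self.w is not None:
            for c in range(self.nD):
                idx = np.flatnonzero(self.dc == c)
                prop = self.w.copy()
                prop[:, c] = self.w[:, c] + self.step_w[c] * rng.standard_normal(self.J)
                ll_new = self._loglik_trials(idx, w=prop)
                dp = (
                    -((prop[:, c] - self.mu_w[c]) ** 2 - (self.w[:, c] - self.mu_w[c]) ** 2)
                    / (2 * self.s2_w[c])
                )
                acc = self._mh_block(idx, ll_new, dp)
                self.w[acc, c] = prop[acc, c]
                acc_stats[("w", c)] = acc.mean()

        self._gibbs_group()
        if adapt:
            self._adapt(acc_stats)

    def _gibbs_group(self):
        rng = self.rng

        def update(theta, prior_mu, prior_s2, a0=2.0, b0=0.02):
            J = theta.shape[0]
            s2 = np.atleast_1d(np.asarray(self._cur_s2))
            # conjugate normal update of the mean
            prec = J / s2 + 1.0 / prior_s2
            mean = (theta.sum(axis=0) / s2 + prior_mu / prior_s2) / prec
            mu = mean + rng.standard_normal(mean.shape) / np.sqrt(prec)
            # conjugate inverse-gamma update of the variance
            resid = ((theta - mu) ** 2).sum(axis=0)
            s2_new = 1.0 / rng.gamma(a0 + J / 2.0, 1.0 / (b0 + resid / 2.0))
            return mu, s2_new

        self._cur_s2 = self.s2_v
        self.mu_v, self.s2_v = update(self.v, 0.0, 4.0)
        self._cur_s2 = self.s2_la
        self.mu_la, self.s2_la = update(self.la, np.log(1.5), 0.25)
        self._cur_s2 = self.s2_t
        mu_t, s2_t = update(self.t_er[:, None], 0.3, 0.25)
        self.mu_t = float(np.clip(mu_t[0], *_TER_BOUNDS))
        self.s2_t = float(s2_t[0])
        if self.w is not None:
            self._cur_s2 = self.s2_w
            self.mu_w, self.s2_w = update(self.w, 0.0, 1.0)

    def _adapt(self, acc_stats, target=0.44):
        for (kind, i), rate in acc_stats.items():
            factor = float(np.exp(0.5 * (rate - target)))
            if kind == "v":
                self.step_v[i] = np.clip(self.step_v[i] * factor, 1e-3, 2.0)
            elif kind == "a":
                self.step_la[i] = np.clip(self.step_la[i] * factor, 1e-3, 1.0)
            elif kind == "t":
                self.step_t = float(np.clip(self.step_t * factor, 1e-4, 0.2))
            elif kind == "w":
                self.step_w[i] = np.clip(self.step_w[i] * factor, 1e-3, 1.0)

    def state(self):
        out = {}
        for c, nm in enumerate(self.dnames):
            out[f"v_{nm}"] = self.mu_v[c]
            out[f"sigma_v_{nm}"] = np.sqrt(self.s2_v[c])
        for b, nm in enumerate(self.bnames):
            key = f"a_{nm}" if nm else "a"
            out[key] = float(np.exp(self.mu_la[b] + self.s2_la[b] / 2.0))
            out[f"sigma_{key}"] = np.sqrt(self.s2_la[b])
        out["t_er"] = self.mu_t
        out["sigma_t_er"] = np.sqrt(self.s2_t)
        if self.w is not None:
            for c, nm in enumerate(self.dnames):
                out[f"w_{nm}"] = self.mu_w[c]
                out[f"sigma_w_{nm}"] = np.sqrt(self.s2_w[c])
        return out

    def subject_state(self):
        out = {}
        for c, nm in enumerate(self.dnames):
            out[f"v_{nm}"] = self.v[:, c].copy()
        for b, nm in enumerate(self.bnames):
            out[f"a_{nm}" if nm else "a"] = np.exp(self.la[:, b])
        out["t_er"] = self.t_er.copy()
        if self.w is not None:
            for c, nm in enumerate(self.dnames):
                out[f"w_{nm}"] = self.w[:, c].copy()
        return out


def _run_chains(trials, spec, mcmc, amp):
    data = _prepare(trials, spec)
    subjects = data[0]
    n_keep = mcmc.draws // mcmc.thin
    group_names = None
    group_store = None
    subj_store = None

    for chain in range(mcmc.chains):
        rng = np.random.default_rng((mcmc.seed * 1000 + chain * 7 + 1) % (2**31))
        sampler = _Sampler(data, amp, rng, init_jitter=0.25 * (chain + 1) / mcmc.chains)
        kept = 0
        for it in range(mcmc.burn + mcmc.draws):
            sampler.step(adapt=it < mcmc.burn)
            if it >= mcmc.burn and (it - mcmc.burn) % mcmc.thin == 0 and kept < n_keep:
                g = sampler.state()
                s = sampler.subject_state()
                if group_names is None:
                    group_names = sorted(g)
                    group_store = {
                        k: np.empty((mcmc.chains, n_keep)) for k in group_names
                    }
                    subj_store = {
                        k: np.empty((mcmc.chains, n_keep, len(subjects))) for k in s
                    }
                for k in group_names:
                    group_store[k][chain, kept] = g[k]
                for k, vals in s.items():
                    subj_store[k][chain, kept] = vals
                kept += 1

    rhat = {k: gelman_rubin(v) for k, v in group_store.items()}
    trace = PosteriorTrace(
        draws=group_store,
        subject_draws=subj_store,
        rhat=rhat,
        subjects=list(subjects),
        seed=mcmc.seed,
        config={
            "chains": mcmc.chains,
            "draws": mcmc.draws,
            "burn": mcmc.burn,
            "thin": mcmc.thin,
            "drift_factors": list(spec.drift_factors),
            "boundary_factors": list(spec.boundary_factors),
            "regression": spec.regression,
        },
        converged=all(r <= 1.1 for r in rhat.values()),
    )
    return trace


def fit_hierarchical(
    trials: pd.DataFrame,
    spec: ModelSpec | None = None,
    mcmc: MCMCConfig | None = None,
) -> PosteriorTrace:
    """Fit the hierarchical DDM to a response-coded trial table.

    Drift varies over ``spec.drift_factors`` cells (default: the three
    complexity conditions), boundary over ``spec.boundary_factors``
    (default: condition x instruction), non-decision time by subject
    only.  Returns a :class:`PosteriorTrace` carrying group-level
    draws, subject draws and split-chain R-hat per group parameter; if
    any R-hat exceeds 1.1 the trace is flagged ``converged=False`` but
    still returned.
    """
    spec = spec or ModelSpec()
    mcmc = mcmc or MCMCConfig()
    if spec.regression is not None:
        raise ValueError("use fit_regression for models with a trial-level predictor")
    return _run_chains(trials, spec, mcmc, amp=None)


def fit_regression(
    trials: pd.DataFrame,
    spec: ModelSpec | None = None,
    mcmc: MCMCConfig | None = None,
    standardize: bool = True,
) -> PosteriorTrace:
    """Hierarchical DDM with a trial-level linear drift regressor.

    Each trial's drift magnitude is v_cond + w_cond * x_i where x_i is
    the predictor named by ``spec.regression`` (default column
    'erp_amp'), z-scored within subject unless ``standardize=False``.
    Both instructions are pooled; the boundary varies over
    ``spec.boundary_factors`` (default: instruction only, mirroring a
    speed/accuracy manipulation).
    """
    spec = spec or ModelSpec(
        drift_factors=("condition",),
        boundary_factors=("instruction",),
        regression="erp_amp",
    )
    if spec.regression is None:
        spec = ModelSpec(spec.drift_factors, spec.boundary_factors, "erp_amp")
    mcmc = mcmc or MCMCConfig()
    col = spec.regression
    if col not in trials.columns:
        raise ValueError(f"regression predictor column {col!r} missing")
    amp = trials[col].to_numpy(float).copy()
    if np.ptp(amp) == 0:
        raise ValueError("constant regression predictor: weight unidentifiable")
    if standardize:
        for s in trials["subject"].unique():
            m = (trials["subject"] == s).to_numpy()
            mu, sd = amp[m].mean(), amp[m].std()
            if sd == 0:
                raise ValueError(f"subject {s}: constant predictor, unidentifiable")
            amp[m] = (amp[m] - mu) / sd
    return _run_chains(trials, spec, mcmc, amp=amp)
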