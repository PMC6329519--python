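"""Pipeline orchestration.

Ties the stages together in the analysis order of the study design:
stimulus statistics -> complexity binning and matched sampling ->
behavioral statistics -> hierarchical DDM -> ERP difference waves and
FDR masks -> ERP-on-drift regression, writing per-stage CSV outputs and
a Markdown report.  Every output is stamped with a hash of the
configuration; identical config + inputs give identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import neurostats, sampling, synthetic
from .ddm import MCMCConfig, ModelSpec, fit_hierarchical, fit_regression, posterior_prob_tests
from .neurostats import (
    DEFAULT_POOL,
    EpochArray,
    difference_waves,
    divergence_onset,
    fdr_mask,
    filter_rts,
    pointwise_tests,
    pool_electrodes,
    rm_anova,
    window_amplitude,
)

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("scenecomplex.workflow")


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of a full pipeline run.

    ``data_dir`` must contain a study in the layout written by
    :func:`scenecomplex.synthetic.gen_study` (stats.csv, trials.csv,
    epochs.npz/.json, truth.json).  All stochastic stages derive their
    seeds from ``seed``.
    """

    data_dir: str = "data"
    out_dir: str = "results"
    seed: int = 0
    # sampling
    n_per_category: int = 80
    # DDM
    chains: int = 3
    draws: int = 2000
    burn: int = 500
    thin: int = 1
    # ERP
    pool: tuple[str, ...] = DEFAULT_POOL
    alpha: float = 0.01
    window: tuple[float, float] = (220.0, 325.0)
    min_run: int = 5
    # behavior
    rt_floor: float = 0.150
    rt_sd_mult: float = 3.0

    def config_hash(self) -> str:
        # analysis parameters only; paths do not change the science
        payload = {
            k: v for k, v in asdict(self).items()
            if k not in ("data_dir", "out_dir")
        }
        payload = json.dumps(payload, sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        for key in ("pool", "window"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _stage_sample(cfg: PipelineConfig, out: Path) -> dict:
    stats_df = pd.read_csv(Path(cfg.data_dir) / "stats.csv")
    labels = sampling.assign_complexity(stats_df)
    labeled = stats_df.assign(condition=labels)
    counts = labels.value_counts().to_dict()
    stim = sampling.match_categories(
        labeled, n_per_category=cfg.n_per_category, seed=cfg.seed
    )
    stim.records.assign(config_hash=cfg.config_hash()).to_csv(
        out / "stimulus_set.csv", index=False
    )
    report = stim.match_report.to_frame()
    report.to_csv(out / "match_report.csv", index=False)
    return {
        "bin_counts": counts,
        "n_stimuli": int(len(stim.records)),
        "max_abs_t": stim.match_report.max_abs_t(),
        "min_p": stim.match_report.min_p(),
    }


def _stage_behavior(cfg: PipelineConfig, out: Path) -> dict:
    trials = pd.read_csv(Path(cfg.data_dir) / "trials.csv")
    filtered, removed = filter_rts(trials, floor=cfg.rt_floor, sd_mult=cfg.rt_sd_mult)
    cells_rt = (
        filtered[filtered["correct"]]
        .groupby(["subject", "condition", "instruction"], as_index=False)["rt"]
        .mean()
    )
    cells_acc = (
        filtered.groupby(["subject", "condition", "instruction"], as_index=False)[
            "correct"
        ]
        .mean()
        .rename(columns={"correct": "accuracy"})
    )
    rt_anova = rm_anova(
        cells_rt, dv="rt", within=["condition", "instruction"],
        posthoc_factor="condition",
    )
    acc_anova = rm_anova(
        cells_acc, dv="accuracy", within=["condition", "instruction"],
        posthoc_factor="condition",
    )
    cells_rt.merge(cells_acc).assign(config_hash=cfg.config_hash()).to_csv(
        out / "behavior_cells.csv", index=False
    )
    rt_anova.effects.assign(dv="rt").pipe(
        lambda a: pd.concat([a, acc_anova.effects.assign(dv="accuracy")])
    ).to_csv(out / "behavior_anova.csv", index=False)
    return {
        "removed_fraction": removed,
        "rt_effects": rt_anova.effects.to_dict(orient="records"),
        "accuracy_effects": acc_anova.effects.to_dict(orient="records"),
    }


def _stage_ddm(cfg: PipelineConfig, out: Path, filtered: pd.DataFrame) -> dict:
    mcmc = MCMCConfig(
        chains=cfg.chains, draws=cfg.draws, burn=cfg.burn, thin=cfg.thin,
        seed=cfg.seed + 1,
    )
    trace = fit_hierarchical(
        filtered, ModelSpec(boundary_factors=("instruction",)), mcmc
    )
    trace.summary().assign(config_hash=cfg.config_hash()).to_csv(
        out / "ddm_posterior.csv", index=False
    )
    trace.save(out / "ddm_trace")
    return {
        "max_rhat": trace.max_rhat(),
        "converged": trace.converged,
        "p_vHIGH_lt_vMED": float(np.mean(trace["v_HIGH"] < trace["v_MED"])),
        "p_vHIGH_lt_vLOW": float(np.mean(trace["v_HIGH"] < trace["v_LOW"])),
        "p_aACC_gt_aSPEED": float(np.mean(trace["a_accurate"] > trace["a_speed"])),
    }


def _stage_erp(cfg: PipelineConfig, out: Path) -> tuple[dict, pd.DataFrame]:
    epochs = EpochArray.load(Path(cfg.data_dir) / "epochs")
    pooled = pool_electrodes(epochs, cfg.pool)
    waves = difference_waves(pooled)
    pvals = pointwise_tests(waves)
    mask = fdr_mask(pvals, alpha=cfg.alpha, times=pooled.times)
    onsets = {
        f"{instr}/{contrast}": divergence_onset(m, mask.times, cfg.min_run)
        for (instr, contrast), m in mask.mask.items()
    }
    rows = []
    for (instr, cond), wv in waves.items():
        for t, mu, se in zip(wv.times, wv.mean, wv.sem):
            rows.append(
                {"instruction": instr, "condition": cond, "time_ms": t,
                 "mean": mu, "sem": se}
            )
    pd.DataFrame(rows).to_csv(out / "difference_waves.csv", index=False)
    mrows = []
    for (instr, contrast), m in mask.mask.items():
        for t, sig, p in zip(mask.times, m, mask.pvals[(instr, contrast)]):
            mrows.append(
                {"instruction": instr, "contrast": contrast, "time_ms": t,
                 "p": p, "significant": bool(sig)}
            )
    pd.DataFrame(mrows).to_csv(out / "erp_mask.csv", index=False)

    amp = window_amplitude(pooled, cfg.window)
    trials = pooled.labels.copy()
    trials["erp_amp"] = amp
    info = {
        "q_threshold": mask.q_threshold,
        "onsets_ms": onsets,
    }
    return info, trials


def _stage_regression(cfg: PipelineConfig, out: Path, trials: pd.DataFrame) -> dict:
    mcmc = MCMCConfig(
        chains=cfg.chains, draws=cfg.draws, burn=cfg.burn, thin=cfg.thin,
        seed=cfg.seed + 2,
    )
    trace = fit_regression(trials, mcmc=mcmc)
    trace.summary().assign(config_hash=cfg.config_hash()).to_csv(
        out / "regression_posterior.csv", index=False
    )
    trace.save(out / "regression_trace")
    return {
        "max_rhat": trace.max_rhat(),
        "w_means": {c: float(np.mean(trace[f"w_{c}"])) for c in ("LOW", "MED", "HIGH")},
        "p_wHIGH_vs_zero": posterior_prob_tests(trace, "w_HIGH", 0.0),
        "p_wHIGH_lt_wLOW": float(np.mean(trace["w_HIGH"] < trace["w_LOW"])),
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages in order; returns the summary dictionary.

    Writes per-stage CSVs plus report.md and report.json under
    ``cfg.out_dir``.  A stage failure aborts with the stage name in the
    raised error.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed}
    stages = []

    def run_stage(name, fn, *args):
        log.info("stage %s starting", name)
        try:
            return fn(cfg, out, *args)
        except Exception as err:
            raise RuntimeError(f"pipeline stage '{name}' failed: {err}") from err

    summary["sampling"] = run_stage("sampling", _stage_sample)
    summary["behavior"] = run_stage("behavior", _stage_behavior)

    trials = pd.read_csv(Path(cfg.data_dir) / "trials.csv")
    filtered, _ = filter_rts(trials, floor=cfg.rt_floor, sd_mult=cfg.rt_sd_mult)
    summary["ddm"] = run_stage("ddm", _stage_ddm, filtered)
    erp_info, trials_amp = run_stage("erp", _stage_erp)
    summary["erp"] = erp_info
    filtered_amp, _ = filter_rts(
        trials_amp, floor=cfg.rt_floor, sd_mult=cfg.rt_sd_mult
    )
    summary["regression"] = run_stage("regression", _stage_regression, filtered_amp)

    (out / "report.json").write_text(json.dumps(summary, indent=2, default=str))
    (out / "report.md").write_text(_render_report(summary))
    return summary


def _render_report(summary: dict) -> str:
    s = summary
    lines = [
        "# Scene-complexity pipeline report",
        f"config hash: {s['config_hash']}  seed: {s['seed']}",
        "",
        "## Stimulus sampling",
        f"- complexity bins: {s['sampling']['bin_counts']}",
        f"- matched stimuli: {s['sampling']['n_stimuli']} "
        f"(max |t| = {s['sampling']['max_abs_t']:.3f}, min p = {s['sampling']['min_p']:.3f})",
        "",
        "## Behavior",
        f"- RT filter removed fraction: {s['behavior']['removed_fraction']:.4f}",
        "",
        "## Drift-diffusion model",
        f"- max R-hat: {s['ddm']['max_rhat']:.3f} (converged: {s['ddm']['converged']})",
        f"- P(v_HIGH < v_MED) = {s['ddm']['p_vHIGH_lt_vMED']:.3f}",
        f"- P(v_HIGH < v_LOW) = {s['ddm']['p_vHIGH_lt_vLOW']:.3f}",
        f"- P(a_accurate > a_speed) = {s['ddm']['p_aACC_gt_aSPEED']:.3f}",
        "",
        "## ERP difference waves",
        f"- FDR q threshold: {s['erp']['q_threshold']:.5f}",
        "- divergence onsets (ms): "
        + ", ".join(f"{k}: {v}" for k, v in s["erp"]["onsets_ms"].items()),
        "",
        "## ERP-drift regression",
        f"- posterior means of w: {s['regression']['w_means']}",
        f"- p(w_HIGH vs 0) = {s['regression']['p_wHIGH_vs_zero']:.4f}",
        f"- P(w_HIGH < w_LOW) = {s['regression']['p_wHIGH_lt_wLOW']:.3f}",
        "",
    ]
    return "\n".join(lines)
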