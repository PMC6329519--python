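"""Behavioral and ERP statistics.

Behavioral side: RT filtering (fast-guess floor and per-subject 3-SD
ceiling), repeated-measures ANOVA with partial eta squared, and Sidak
post-hoc correction.  ERP side: electrode pooling, animal vs non-animal
difference waves, point-wise one-sample and paired t-tests, a
Benjamini-Hochberg FDR mask over the full family (instructions x
contrasts x timepoints), divergence-onset detection and single-trial
window amplitudes (the 220-325 ms feedback window by default).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EpochArray",
    "DifferenceWave",
    "SignificanceMask",
    "AnovaResult",
    "DEFAULT_POOL",
    "filter_rts",
    "rm_anova",
    "sidak_adjust",
    "pool_electrodes",
    "difference_waves",
    "pointwise_tests",
    "fdr_mask",
    "divergence_onset",
    "window_amplitude",
]

#: Occipital / peri-occipital electrode pool over visual cortex.
DEFAULT_POOL = ("Oz", "POz", "O1", "O2", "PO3", "PO4", "PO7", "PO8")


# --------------------------------------------------------------------------
# containers


@dataclass
class EpochArray:
    """Epoched EEG: voltages (trials x channels x time) with labels.

    ``times`` is in ms relative to stimulus onset; ``labels`` is a
    DataFrame with one row per trial (subject, condition, category,
    instruction, ... columns as available).
    """

    voltages: np.ndarray
    times: np.ndarray
    channels: Sequence[str]
    sfreq: float
    labels: pd.DataFrame
    units: str = "uV"

    def __post_init__(self) -> None:
        v = np.asarray(self.voltages, dtype=float)
        if v.ndim != 3:
            raise ValueError("voltages must be trials x channels x time")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("time axis must be strictly increasing")
        if len(self.channels) != len(set(self.channels)):
            raise ValueError("channel names must be unique")
        if v.shape[1] != len(self.channels) or v.shape[2] != len(self.times):
            raise ValueError("voltage shape inconsistent with channels/times")
        if len(self.labels) != v.shape[0]:
            raise ValueError("labels must cover every trial")
        self.voltages = v
        self.times = np.asarray(self.times, dtype=float)

    @property
    def n_trials(self) -> int:
        return self.voltages.shape[0]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), voltages=self.voltages, times=self.times)
        meta = {
            "channels": list(self.channels),
            "sfreq": self.sfreq,
            "units": self.units,
            "labels": self.labels.to_dict(orient="list"),
        }
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "EpochArray":
        path = Path(path)
        arrs = np.load(path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            voltages=arrs["voltages"],
            times=arrs["times"],
            channels=meta["channels"],
            sfreq=meta["sfreq"],
            labels=pd.DataFrame(meta["labels"]),
            units=meta["units"],
        )


@dataclass(frozen=True)
class DifferenceWave:
    """Grand-average animal minus non-animal wave with between-subject SEM."""

    mean: np.ndarray
    sem: np.ndarray
    times: np.ndarray
    n_subjects: int
    condition: str
    instruction: str
    subject_waves: np.ndarray | None = None  # subjects x time

    def __post_init__(self) -> None:
        if len(self.mean) != len(self.times) or len(self.sem) != len(self.times):
            raise ValueError("mean/sem length must match the time axis")
        if np.any(self.sem < 0):
            raise ValueError("sem must be non-negative")


@dataclass(frozen=True)
class SignificanceMask:
    """FDR decision per family member (instruction, contrast, timepoint)."""

    mask: Mapping[tuple[str, str], np.ndarray]
    pvals: Mapping[tuple[str, str], np.ndarray]
    times: np.ndarray
    q_threshold: float
    alpha: float

    def for_contrast(self, instruction: str, contrast: str) -> np.ndarray:
        return self.mask[(instruction, contrast)]


@dataclass(frozen=True)
class AnovaResult:
    """RM-ANOVA effects plus Sidak-adjusted post-hoc pairwise t-tests."""

    effects: pd.DataFrame     # effect, F, df1, df2, p, partial_eta_sq
    posthoc: pd.DataFrame | None = None


# --------------------------------------------------------------------------
# behavior


def filter_rts(
    trials: pd.DataFrame,
    floor: float = 0.150,
    sd_mult: float = 3.0,
    rt_col: str = "rt",
    subject_col: str = "subject",
    min_trials: int = 10,
) -> tuple[pd.DataFrame, float]:
    """Remove fast guesses and per-subject slow outliers.

    First drops rt < ``floor`` (seconds), then — per subject, on the
    floor-passed rows — drops rt > mean + ``sd_mult`` * sd.  Returns the
    filtered table and the overall removed fraction; per-subject
    fractions are in ``attrs['removed_per_subject']`` and subjects left
    with fewer than ``min_trials`` rows in ``attrs['flagged_subjects']``.
    """
    if (trials[rt_col] <= 0).any():
        raise ValueError("all RTs must be > 0")
    kept_parts = []
    removed_per_subject = {}
    for subj, grp in trials.groupby(subject_col, sort=False):
        above_floor = grp[grp[rt_col] >= floor]
        mu, sd = above_floor[rt_col].mean(), above_floor[rt_col].std(ddof=1)
        ceiling = mu + sd_mult * sd if np.isfinite(sd) else np.inf
        kept = above_floor[above_floor[rt_col] <= ceiling]
        kept_parts.append(kept)
        removed_per_subject[subj] = 1.0 - len(kept) / len(grp)
    out = pd.concat(kept_parts)
    out.attrs["removed_per_subject"] = removed_per_subject
    out.attrs["flagged_subjects"] = [
        s for s, g in out.groupby(subject_col) if len(g) < min_trials
    ]
    removed_fraction = 1.0 - len(out) / len(trials)
    return out, removed_fraction


def rm_anova(
    cell_means: pd.DataFrame,
    dv: str,
    within: Sequence[str],
    subject: str = "subject",
    posthoc_factor: str | None = None,
) -> AnovaResult:
    """Repeated-measures ANOVA on a complete balanced subject x cell table.

    Classical within-subject decomposition for one or two within
    factors: each effect is tested against its own subject-by-effect
    interaction.  Partial eta squared is SS_effect / (SS_effect +
    SS_error).  A perfectly null effect (both sums of squares zero)
    reports F = 0.  When ``posthoc_factor`` is given, all pairwise
    paired t-tests on the (collapsed) levels of that factor are
    returned with Sidak-adjusted p-values.
    """
    within = list(within)
    if len(within) not in (1, 2):
        raise ValueError("rm_anova supports 1 or 2 within-subject factors")
    counts = cell_means.groupby([subject] + within).size()
    if (counts != 1).any():
        raise ValueError("cell_means must contain exactly one row per subject x cell")
    n_cells = int(np.prod([cell_means[f].nunique() for f in within]))
    per_subj = cell_means.groupby(subject).size()
    if (per_subj != n_cells).any():
        raise ValueError("missing cells: every subject needs every factor combination")

    # data cube: subjects x levels(A) [x levels(B)]
    wide = cell_means.set_index([subject] + within)[dv].unstack(within)
    y = wide.to_numpy(dtype=float)
    n_subj = y.shape[0]
    if len(within) == 1:
        cube = y[:, :, None]
        a_lv, b_lv = y.shape[1], 1
    else:
        a_lv = cell_means[within[0]].nunique()
        b_lv = cell_means[within[1]].nunique()
        # unstack ordering: columns are (A level, B level) pairs
        cube = y.reshape(n_subj, a_lv, b_lv)

    grand = cube.mean()
    m_s = cube.mean(axis=(1, 2))
    m_a = cube.mean(axis=(0, 2))
    m_b = cube.mean(axis=(0, 1))
    m_sa = cube.mean(axis=2)
    m_sb = cube.mean(axis=1)
    m_ab = cube.mean(axis=0)

    def effect_row(name, ss_eff, df1, ss_err, df2):
        if ss_eff <= 1e-12 and ss_err <= 1e-12:
            f = 0.0
        elif ss_err <= 1e-12:
            f = np.inf
        else:
            f = (ss_eff / df1) / (ss_err / df2)
        p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
        eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        return {"effect": name, "F": f, "df1": df1, "df2": df2, "p": p,
                "partial_eta_sq": eta}

    rows = []
    ss_a = n_subj * b_lv * np.sum((m_a - grand) ** 2)
    ss_sa = b_lv * np.sum(
        (m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2
    )
    rows.append(
        effect_row(within[0], ss_a, a_lv - 1, ss_sa, (a_lv - 1) * (n_subj - 1))
    )
    if len(within) == 2:
        ss_b = n_subj * a_lv * np.sum((m_b - grand) ** 2)
        ss_sb = a_lv * np.sum(
            (m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2
        )
        rows.append(
            effect_row(within[1], ss_b, b_lv - 1, ss_sb, (b_lv - 1) * (n_subj - 1))
        )
        ss_ab = n_subj * np.sum(
            (m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2
        )
        resid = (
            cube
            - m_sa[:, :, None]
            - m_sb[:, None, :]
            - m_ab[None, :, :]
            + m_s[:, None, None]
            + m_a[None, :, None]
            + m_b[None, None, :]
            - grand
        )
        ss_sab = np.sum(resid**2)
        rows.append(
            effect_row(
                f"{within[0]}:{within[1]}",
                ss_ab,
                (a_lv - 1) * (b_lv - 1),
                ss_sab,
                (a_lv - 1) * (b_lv - 1) * (n_subj - 1),
            )
        )
    effects = pd.DataFrame(rows)

    posthoc = None
    if posthoc_factor is not None:
        collapsed = (
            cell_means.groupby([subject, posthoc_factor])[dv].mean().unstack()
        )
        levels = list(collapsed.columns)
        pairs = list(itertools.combinations(levels, 2))
        rows = []
        for l1, l2 in pairs:
            t, p = stats.ttest_rel(collapsed[l1], collapsed[l2])
            rows.append(
                {"level_1": l1, "level_2": l2, "t": float(t),
                 "df": len(collapsed) - 1, "p_raw": float(p)}
            )
        posthoc = pd.DataFrame(rows)
        posthoc["p_sidak"] = sidak_adjust(posthoc["p_raw"].to_numpy(), len(pairs))
    return AnovaResult(effects=effects, posthoc=posthoc)


def sidak_adjust(p: np.ndarray | float, m: int) -> np.ndarray | float:
    """Sidak family-wise adjustment: 1 - (1 - p)^m, clipped to 1."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr < 0) | (p_arr > 1)):
        raise ValueError("p values must lie in [0, 1]")
    adj = -np.expm1(m * np.log1p(-np.minimum(p_arr, 1.0 - 1e-16)))
    adj = np.minimum(np.where(p_arr >= 1.0, 1.0, adj), 1.0)
    return float(adj) if np.isscalar(p) else adj


# --------------------------------------------------------------------------
# ERP


def pool_electrodes(
    epochs: EpochArray, names: Sequence[str] = DEFAULT_POOL
) -> EpochArray:
    """Average the named channels into a single pooled channel."""
    missing = [n for n in names if n not in epochs.channels]
    if missing:
        raise ValueError(f"channels not present: {missing}")
    idx = [list(epochs.channels).index(n) for n in names]
    pooled = epochs.voltages[:, idx, :].mean(axis=1, keepdims=True)
    return EpochArray(
        voltages=pooled,
        times=epochs.times,
        channels=[f"pool({','.join(names)})"],
        sfreq=epochs.sfreq,
        labels=epochs.labels,
        units=epochs.units,
    )


def difference_waves(
    epochs: EpochArray,
    conditions: Sequence[str] = ("LOW", "MED", "HIGH"),
    instructions: Sequence[str] | None = None,
) -> dict[tuple[str, str], DifferenceWave]:
    """Subject-level mean(animal) - mean(non-animal) per condition cell.

    Expects pooled (single-channel) epochs.  Returns one
    :class:`DifferenceWave` per (instruction, condition), keyed by that
    pair; the per-subject waves are retained for point-wise testing.
    If the labels carry no instruction column a single "all" level is
    used.
    """
    if epochs.voltages.shape[1] != 1:
        raise ValueError("pool electrodes before computing difference waves")
    lab = epochs.labels
    if instructions is None:
        instructions = (
            sorted(lab["instruction"].unique()) if "instruction" in lab else ["all"]
        )
    data = epochs.voltages[:, 0, :]
    subjects = sorted(lab["subject"].unique())
    out = {}
    for instr in instructions:
        imask = (
            np.ones(len(lab), bool)
            if instr == "all"
            else (lab["instruction"] == instr).to_numpy()
        )
        for cond in conditions:
            cmask = (lab["condition"] == cond).to_numpy() & imask
            waves = []
            for s in subjects:
                smask = cmask & (lab["subject"] == s).to_numpy()
                a = smask & (lab["category"] == "animal").to_numpy()
                na = smask & (lab["category"] == "non-animal").to_numpy()
                if a.sum() == 0 or na.sum() == 0:
                    raise ValueError(
                        f"subject {s}, {instr}/{cond}: empty category cell"
                    )
                waves.append(data[a].mean(axis=0) - data[na].mean(axis=0))
            waves = np.asarray(waves)
            out[(instr, cond)] = DifferenceWave(
                mean=waves.mean(axis=0),
                sem=waves.std(axis=0, ddof=1) / np.sqrt(len(subjects)),
                times=epochs.times,
                n_subjects=len(subjects),
                condition=cond,
                instruction=instr,
                subject_waves=waves,
            )
    return out


PAIRED_CONTRASTS = (("HIGH", "LOW"), ("HIGH", "MED"), ("MED", "LOW"))


def pointwise_tests(
    waves: dict[tuple[str, str], DifferenceWave]
) -> dict[tuple[str, str], np.ndarray]:
    """Per-timepoint p series for every family member.

    One-sample two-tailed t vs 0 per condition ("HIGH", ...) and paired
    t for each condition contrast ("HIGH-LOW", ...), separately per
    instruction.
    """
    pvals: dict[tuple[str, str], np.ndarray] = {}
    instructions = sorted({k[0] for k in waves})
    for instr in instructions:
        conds = [k[1] for k in waves if k[0] == instr]
        if any(waves[(instr, c)].n_subjects < 3 for c in conds):
            raise ValueError("point-wise tests need >= 3 subjects")
        for cond in conds:
            sw = waves[(instr, cond)].subject_waves
            _, p = stats.ttest_1samp(sw, 0.0, axis=0)
            pvals[(instr, cond)] = p
        for c1, c2 in PAIRED_CONTRASTS:
            if c1 in conds and c2 in conds:
                _, p = stats.ttest_rel(
                    waves[(instr, c1)].subject_waves,
                    waves[(instr, c2)].subject_waves,
                    axis=0,
                )
                pvals[(instr, f"{c1}-{c2}")] = p
    return pvals


def fdr_mask(
    pvals: dict[tuple[str, str], np.ndarray],
    alpha: float = 0.01,
    times: np.ndarray | None = None,
) -> SignificanceMask:
    """Benjamini-Hochberg step-up over the concatenated test family.

    The family is all instructions x contrasts x timepoints in one
    vector, as a single correction; the reported ``q_threshold`` is the
    largest p-value that still passes (0 when nothing passes).
    """
    if not pvals:
        raise ValueError("empty p-value family")
    keys = sorted(pvals)
    flat = np.concatenate([np.asarray(pvals[k], float) for k in keys])
    reject, _, _, _ = multipletests(flat, alpha=alpha, method="fdr_bh")
    q_threshold = float(flat[reject].max()) if reject.any() else 0.0
    mask = {}
    start = 0
    for k in keys:
        n = len(pvals[k])
        mask[k] = reject[start : start + n]
        start += n
    if times is None:
        times = np.arange(len(pvals[keys[0]]), dtype=float)
    return SignificanceMask(
        mask=mask, pvals=dict(pvals), times=np.asarray(times, float),
        q_threshold=q_threshold, alpha=alpha,
    )


def divergence_onset(
    mask: np.ndarray, times: np.ndarray, min_run: int = 5
) -> float | None:
    """Earliest post-stimulus time starting >= min_run significant samples.

    Only timepoints at or after 0 ms are considered; returns None when
    no sufficiently long run exists.  ``min_run`` of 5 samples at 256 Hz
    is ~20 ms, guarding against isolated false positives.
    """
    mask = np.asarray(mask, bool)
    times = np.asarray(times, float)
    if mask.shape != times.shape:
        raise ValueError("mask and time axis must align")
    valid = times >= 0
    m = mask & valid
    run = 0
    for i in range(len(m)):
        run = run + 1 if m[i] else 0
        if run == min_run:
            return float(times[i - min_run + 1])
    return None


def window_amplitude(
    epochs: EpochArray, window: tuple[float, float] = (220.0, 325.0)
) -> np.ndarray:
    """Per-trial mean pooled amplitude over a time window (ms, inclusive)."""
    lo, hi = window
    if lo < epochs.times[0] or hi > epochs.times[-1]:
        raise ValueError(
            f"window [{lo}, {hi}] outside epoch span "
            f"[{epochs.times[0]}, {epochs.times[-1]}]"
        )
    if epochs.voltages.shape[1] != 1:
        raise ValueError("pool electrodes before computing window amplitudes")
    sel = (epochs.times >= lo) & (epochs.times <= hi)
    return epochs.voltages[:, 0, sel].mean(axis=1)
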