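"""Complexity-stratified stimulus sampling.

Images are binned into LOW / MED / HIGH complexity conditions by
percentiles of a 1-D complexity score (the mean of the rank-percentiles
of CE and SC), then an equal number of target (animal) and non-target
(non-animal) images is selected per condition such that the two
categories are statistically indistinguishable in both CE and SC —
assessed with equal-variance two-sample t-tests and Wilcoxon rank-sum
tests.  Matching within condition is what licenses interpreting any
later target/non-target neural difference as feedback rather than a
feed-forward stimulus confound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ComplexityBounds",
    "MatchReport",
    "StimulusSet",
    "MatchCriteria",
    "complexity_score",
    "assign_complexity",
    "match_categories",
    "matching_diagnostics",
]

CONDITIONS = ("LOW", "MED", "HIGH")
CATEGORIES = ("animal", "non-animal")


@dataclass(frozen=True)
class ComplexityBounds:
    """Percentile bands defining the three complexity conditions.

    Defaults follow the lower/upper 25% and the central 35% band
    ([32.5, 67.5]); with 25+35+25 < 100 there are unassigned gaps.
    """

    low_upper: float = 25.0
    med_center_width: float = 35.0
    high_lower: float = 75.0

    def __post_init__(self) -> None:
        if not (0 < self.low_upper < 50 < self.high_lower < 100):
            raise ValueError("need 0 < low_upper < 50 < high_lower < 100")
        lo, hi = self.med_band
        if lo < self.low_upper or hi > self.high_lower:
            raise ValueError("MED band overlaps LOW or HIGH band")

    @property
    def med_band(self) -> tuple[float, float]:
        half = self.med_center_width / 2.0
        return (50.0 - half, 50.0 + half)


@dataclass(frozen=True)
class MatchReport:
    """Animal vs non-animal matching diagnostics per condition and statistic.

    ``table`` maps (condition, statistic) -> dict with t, p_t, df,
    wilcoxon_z, p_wilcoxon.
    """

    table: Mapping[tuple[str, str], dict]

    def max_abs_t(self) -> float:
        return max(abs(v["t"]) for v in self.table.values())

    def min_p(self) -> float:
        return min(min(v["p_t"], v["p_wilcoxon"]) for v in self.table.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"condition": c, "statistic": s, **vals}
            for (c, s), vals in self.table.items()
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class StimulusSet:
    """Matched stimuli: image_id, condition, category, ce, sc records."""

    records: pd.DataFrame
    match_report: MatchReport
    seed: int | None = None

    def __post_init__(self) -> None:
        req = {"image_id", "condition", "category", "ce", "sc"}
        missing = req - set(self.records.columns)
        if missing:
            raise ValueError(f"stimulus records missing columns: {sorted(missing)}")
        if self.records["image_id"].duplicated().any():
            raise ValueError("an image appears more than once in the stimulus set")
        counts = self.records.groupby(["condition", "category"]).size()
        for cond in self.records["condition"].unique():
            per_cat = counts.loc[cond]
            if per_cat.nunique() != 1:
                raise ValueError(f"unequal category counts in condition {cond}")

    @property
    def n_per_condition(self) -> pd.Series:
        return self.records.groupby("condition").size()


@dataclass(frozen=True)
class MatchCriteria:
    max_abs_t: float = 0.2
    min_p: float = 0.5
    max_iter: int = 10_000


def complexity_score(stats_df: pd.DataFrame) -> np.ndarray:
    """1-D complexity score: mean of the rank-percentiles of ce and sc.

    Rank-percentiles put both statistics on a common [0, 100] scale so
    neither dominates; equal weights reproduce the diagonal low-to-high
    structure of the joint CE/SC space.  Ties are broken by stable input
    order (pandas 'first' ranking).
    """
    pct = lambda col: 100.0 * (stats_df[col].rank(method="first") - 1) / (len(stats_df) - 1)
    return ((pct("ce") + pct("sc")) / 2.0).to_numpy()


def assign_complexity(
    stats_df: pd.DataFrame, bounds: ComplexityBounds | None = None
) -> pd.Series:
    """Label each image LOW / MED / HIGH / UNASSIGNED by score percentile.

    Percentiles are linear-interpolation empirical percentiles over the
    full bank.  LOW is strictly below the low_upper percentile, HIGH
    strictly above the high_lower percentile, MED the closed central
    band; images falling in the gaps stay UNASSIGNED.
    """
    bounds = bounds or ComplexityBounds()
    if len(stats_df) < 20:
        raise ValueError(f"need >= 20 images to bin, got {len(stats_df)}")
    for col in ("ce", "sc"):
        if not np.all(np.isfinite(stats_df[col])):
            raise ValueError(f"non-finite {col} values")
    if np.ptp(stats_df["ce"]) == 0 and np.ptp(stats_df["sc"]) == 0:
        raise ValueError("degenerate complexity distribution: all scores equal")
    score = complexity_score(stats_df)
    lo_cut = np.percentile(score, bounds.low_upper)
    hi_cut = np.percentile(score, bounds.high_lower)
    med_lo, med_hi = np.percentile(score, bounds.med_band)
    labels = np.full(len(score), "UNASSIGNED", dtype=object)
    labels[score < lo_cut] = "LOW"
    labels[(score >= med_lo) & (score <= med_hi)] = "MED"
    labels[score > hi_cut] = "HIGH"
    return pd.Series(labels, index=stats_df.index, name="condition")


def _two_sample_tests(x: np.ndarray, y: np.ndarray) -> dict:
    t, p_t = stats.ttest_ind(x, y, equal_var=True)
    if np.isnan(t):  # zero pooled variance, identical groups
        t, p_t = 0.0, 1.0
    z, p_w = stats.ranksums(x, y)
    return {
        "t": float(t),
        "p_t": float(p_t),
        "df": int(len(x) + len(y) - 2),
        "wilcoxon_z": float(z),
        "p_wilcoxon": float(p_w),
    }


def matching_diagnostics(stimulus_set: StimulusSet | pd.DataFrame) -> MatchReport:
    """Recompute the animal vs non-animal t / rank-sum tests per condition."""
    df = (
        stimulus_set.records
        if isinstance(stimulus_set, StimulusSet)
        else stimulus_set
    )
    table = {}
    for cond, grp in df.groupby("condition"):
        a = grp[grp["category"] == "animal"]
        na = grp[grp["category"] == "non-animal"]
        if len(a) < 2 or len(na) < 2:
            raise ValueError(f"condition {cond}: need >= 2 images per category")
        for stat in ("ce", "sc"):
            table[(cond, stat)] = _two_sample_tests(
                a[stat].to_numpy(), na[stat].to_numpy()
            )
    return MatchReport(table=table)


def _match_cost(df: pd.DataFrame, idx_a: np.ndarray, idx_na: np.ndarray) -> float:
    """Sum over ce/sc of |standardized mean difference| between selections."""
    cost = 0.0
    for stat in ("ce", "sc"):
        va = df.loc[idx_a, stat].to_numpy()
        vn = df.loc[idx_na, stat].to_numpy()
        pooled = np.std(np.concatenate([va, vn])) + 1e-12
        cost += abs(va.mean() - vn.mean()) / pooled
        # also penalise dispersion mismatch so the rank-sum test passes
        cost += 0.5 * abs(va.std() - vn.std()) / pooled
    return cost


def _greedy_pairs(
    df: pd.DataFrame, a_idx: np.ndarray, na_idx: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-neighbour pairing in standardized (ce, sc) space."""
    feats = df[["ce", "sc"]].to_numpy()
    mu, sd = feats.mean(axis=0), feats.std(axis=0) + 1e-12
    z = (feats - mu) / sd
    pos = {ix: k for k, ix in enumerate(df.index)}
    za = np.array([z[pos[i]] for i in a_idx])
    zn = np.array([z[pos[i]] for i in na_idx])
    dists = np.linalg.norm(za[:, None, :] - zn[None, :, :], axis=2)
    sel_a, sel_na = [], []
    used_a, used_na = np.zeros(len(a_idx), bool), np.zeros(len(na_idx), bool)
    flat = np.argsort(dists, axis=None)
    for f in flat:
        i, j = np.unravel_index(f, dists.shape)
        if used_a[i] or used_na[j]:
            continue
        used_a[i], used_na[j] = True, True
        sel_a.append(a_idx[i])
        sel_na.append(na_idx[j])
        if len(sel_a) == n:
            break
    return np.array(sel_a), np.array(sel_na)


def match_categories(
    labeled_stats: pd.DataFrame,
    n_per_category: int = 80,
    criteria: MatchCriteria | None = None,
    seed: int = 0,
) -> StimulusSet:
    """Select matched animal / non-animal images within every condition.

    Starts from greedy nearest-neighbour pairing in standardized
    (ce, sc) space, then applies seeded stochastic single-image swaps
    that are accepted when they reduce the mean/dispersion mismatch,
    until the t and rank-sum criteria are met in every condition or
    ``max_iter`` swap attempts are exhausted (then raises, carrying the
    best report found).

    ``labeled_stats`` needs columns image_id, condition, category, ce, sc.
    """
    criteria = criteria or MatchCriteria()
    rng = np.random.default_rng(seed)
    selections: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    pools: dict[str, tuple[pd.DataFrame, np.ndarray, np.ndarray]] = {}

    for cond in CONDITIONS:
        grp = labeled_stats[labeled_stats["condition"] == cond]
        a_idx = grp.index[grp["category"] == "animal"].to_numpy()
        na_idx = grp.index[grp["category"] == "non-animal"].to_numpy()
        if len(a_idx) < n_per_category or len(na_idx) < n_per_category:
            raise ValueError(
                f"condition {cond}: need >= {n_per_category} candidates per "
                f"category, have {len(a_idx)} animal / {len(na_idx)} non-animal"
            )
        sel_a, sel_na = _greedy_pairs(grp, a_idx, na_idx, n_per_category)
        selections[cond] = (sel_a, sel_na)
        pools[cond] = (grp, a_idx, na_idx)

    def build_set() -> pd.DataFrame:
        parts = []
        for cond, (sel_a, sel_na) in selections.items():
            parts.append(labeled_stats.loc[np.concatenate([sel_a, sel_na])])
        return pd.concat(parts)[["image_id", "condition", "category", "ce", "sc"]]

    def passes(report: MatchReport) -> bool:
        return (
            report.max_abs_t() <= criteria.max_abs_t
            and report.min_p() >= criteria.min_p
        )

    best_report = matching_diagnostics(build_set())
    if passes(best_report):
        return StimulusSet(build_set().reset_index(drop=True), best_report, seed)

    for _ in range(criteria.max_iter):
        cond = CONDITIONS[rng.integers(len(CONDITIONS))]
        grp, a_idx, na_idx = pools[cond]
        sel_a, sel_na = selections[cond]
        side = rng.integers(2)
        sel, pool = (sel_a, a_idx) if side == 0 else (sel_na, na_idx)
        outside = np.setdiff1d(pool, sel)
        if outside.size == 0:
            continue
        k = rng.integers(len(sel))
        cand = outside[rng.integers(outside.size)]
        old_cost = _match_cost(grp, sel_a, sel_na)
        new_sel = sel.copy()
        new_sel[k] = cand
        if side == 0:
            new_cost = _match_cost(grp, new_sel, sel_na)
        else:
            new_cost = _match_cost(grp, sel_a, new_sel)
        if new_cost < old_cost:
            if side == 0:
                selections[cond] = (new_sel, sel_na)
            else:
                selections[cond] = (sel_a, new_sel)
            report = matching_diagnostics(build_set())
            if passes(report):
                return StimulusSet(build_set().reset_index(drop=True), report, seed)
            best_report = report

    raise RuntimeError(
        "matching criteria unreachable within max_iter; best report: "
        f"max|t|={best_report.max_abs_t():.3f}, min p={best_report.min_p():.3f}"
    )
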