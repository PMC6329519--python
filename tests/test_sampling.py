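"""Complexity binning and matched stimulus sampling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scenecomplex.sampling import (
    ComplexityBounds,
    MatchCriteria,
    assign_complexity,
    complexity_score,
    match_categories,
    matching_diagnostics,
)


def _stats_frame(scores):
    # monotone ce/sc so the complexity score reproduces the given ranks
    scores = np.asarray(scores, dtype=float)
    return pd.DataFrame(
        {"image_id": [f"i{i}" for i in range(len(scores))], "ce": scores, "sc": scores}
    )


class TestAssignComplexity:
    def test_default_bounds_on_1000_distinct_scores(self):
        df = _stats_frame(np.arange(1000))
        labels = assign_complexity(df)
        counts = labels.value_counts()
        assert counts["LOW"] == 250
        assert counts["MED"] == 350
        assert counts["HIGH"] == 250
        assert counts["UNASSIGNED"] == 150

    def test_matches_brute_force_rank_oracle(self):
        rng = np.random.default_rng(11)
        scores = rng.permutation(rng.uniform(0, 1, 437))
        df = _stats_frame(scores)
        labels = assign_complexity(df)
        score = complexity_score(df)
        # oracle: exact percentile cut-offs recomputed independently
        lo, hi = np.percentile(score, [25, 75])
        med_lo, med_hi = np.percentile(score, [32.5, 67.5])
        expect = np.where(
            score < lo, "LOW",
            np.where(score > hi, "HIGH",
                     np.where((score >= med_lo) & (score <= med_hi), "MED",
                              "UNASSIGNED")),
        )
        assert (labels.to_numpy() == expect).all()

    def test_degenerate_and_tiny_inputs_rejected(self):
        with pytest.raises(ValueError):
            assign_complexity(_stats_frame(np.ones(100)))
        with pytest.raises(ValueError):
            assign_complexity(_stats_frame(np.arange(4)))

    def test_bounds_validation(self):
        with pytest.raises(ValueError):
            ComplexityBounds(low_upper=60)
        with pytest.raises(ValueError):
            ComplexityBounds(med_center_width=60)  # overlaps LOW/HIGH


def _labeled_bank(n_per_cat=120, sep=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for cond, mu in (("LOW", 0.0), ("MED", 1.0), ("HIGH", 2.0)):
        for cat, off in (("animal", 0.0), ("non-animal", sep)):
            ce = rng.normal(mu + off, 0.3, n_per_cat)
            sc = rng.normal(mu + off, 0.3, n_per_cat)
            for c, s in zip(ce, sc):
                rows.append(
                    {"image_id": f"{cond}-{cat}-{len(rows)}", "condition": cond,
                     "category": cat, "ce": c, "sc": s}
                )
    return pd.DataFrame(rows)


class TestMatchCategories:
    def test_identical_multisets_match_perfectly(self):
        rows = []
        vals = np.linspace(1, 2, 30)
        for cond in ("LOW", "MED", "HIGH"):
            for cat in ("animal", "non-animal"):
                for i, v in enumerate(vals):
                    rows.append(
                        {"image_id": f"{cond}{cat}{i}", "condition": cond,
                         "category": cat, "ce": v, "sc": v}
                    )
        stim = match_categories(pd.DataFrame(rows), n_per_category=30, seed=0)
        assert stim.match_report.max_abs_t() == 0.0

    def test_overlapping_gaussians_meet_criteria_with_df(self):
        stim = match_categories(_labeled_bank(seed=1), n_per_category=80, seed=2)
        rep = matching_diagnostics(stim)
        assert all(v["df"] == 158 for v in rep.table.values())
        assert rep.min_p() > 0.5
        # recompute one cell with the scipy oracle
        grp = stim.records[stim.records["condition"] == "LOW"]
        a = grp[grp["category"] == "animal"]["ce"]
        na = grp[grp["category"] == "non-animal"]["ce"]
        t, p = stats.ttest_ind(a, na)
        assert np.isclose(t, rep.table[("LOW", "ce")]["t"])

    def test_condition_labels_preserved(self):
        bank = _labeled_bank(seed=3)
        stim = match_categories(bank, n_per_category=50, seed=4)
        merged = stim.records.merge(
            bank, on="image_id", suffixes=("", "_orig")
        )
        assert (merged["condition"] == merged["condition_orig"]).all()

    def test_disjoint_supports_unmatchable(self):
        bank = _labeled_bank(n_per_cat=30, sep=100.0, seed=5)
        with pytest.raises(RuntimeError):
            match_categories(
                bank, n_per_category=30,
                criteria=MatchCriteria(max_iter=200), seed=6,
            )

    def test_insufficient_candidates_rejected(self):
        with pytest.raises(ValueError):
            match_categories(_labeled_bank(n_per_cat=10), n_per_category=50, seed=0)

    def test_seeded_determinism(self):
        bank = _labeled_bank(seed=7)
        s1 = match_categories(bank, 40, seed=9)
        s2 = match_categories(bank, 40, seed=9)
        pd.testing.assert_frame_equal(s1.records, s2.records)


class TestMatchingDiagnostics:
    def test_idempotent_on_own_output(self):
        stim = match_categories(_labeled_bank(seed=8), n_per_category=40, seed=0)
        r1 = matching_diagnostics(stim)
        r2 = matching_diagnostics(stim)
        assert r1.table == r2.table

    def test_identical_groups_give_t_zero_p_one(self):
        df = pd.DataFrame(
            {
                "image_id": list("abcdef"),
                "condition": ["LOW"] * 6,
                "category": ["animal"] * 3 + ["non-animal"] * 3,
                "ce": [1, 2, 3, 1, 2, 3],
                "sc": [1, 2, 3, 1, 2, 3],
            }
        )
        rep = matching_diagnostics(df)
        assert rep.table[("LOW", "ce")]["t"] == 0.0
        assert rep.table[("LOW", "ce")]["p_t"] == 1.0

    def test_textbook_two_sample_t(self):
        df = pd.DataFrame(
            {
                "image_id": list("abcdefgh"),
                "condition": ["LOW"] * 8,
                "category": ["animal"] * 4 + ["non-animal"] * 4,
                "ce": [1, 2, 3, 4, 2, 3, 4, 5],
                "sc": [1, 2, 3, 4, 2, 3, 4, 5],
            }
        )
        rep = matching_diagnostics(df)
        # pooled sd = sqrt(5/3), t = -1 / (sqrt(5/3) * sqrt(1/2))
        expected = -1.0 / (np.sqrt(5.0 / 3.0) * np.sqrt(0.5))
        assert np.isclose(rep.table[("LOW", "ce")]["t"], expected)
        assert rep.table[("LOW", "ce")]["df"] == 6

    def test_go_subset_sample_size_gives_df_118(self):
        stim = match_categories(_labeled_bank(seed=10), n_per_category=60, seed=1)
        rep = matching_diagnostics(stim)
        assert all(v["df"] == 118 for v in rep.table.values())
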