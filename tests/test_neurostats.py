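"""Behavioral statistics and ERP difference-wave machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scenecomplex.neurostats import (
    EpochArray,
    difference_waves,
    divergence_onset,
    fdr_mask,
    filter_rts,
    pointwise_tests,
    pool_electrodes,
    rm_anova,
    sidak_adjust,
    window_amplitude,
)


class TestFilterRts:
    def test_hand_computed_case(self):
        df = pd.DataFrame(
            {"subject": "s0", "rt": [0.10, 0.30, 0.32, 0.35, 0.40]}
        )
        out, removed = filter_rts(df)
        # 0.10 falls to the 150 ms floor; the rest survive the 3-SD rule
        assert sorted(out["rt"]) == [0.30, 0.32, 0.35, 0.40]
        assert removed == pytest.approx(0.2)

    def test_tight_distribution_untouched(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"subject": "s0", "rt": rng.uniform(0.2, 0.6, 500)})
        out, removed = filter_rts(df)
        assert removed == 0.0

    def test_ceiling_computed_per_subject(self):
        df = pd.DataFrame(
            {
                "subject": ["a"] * 50 + ["b"] * 50,
                "rt": np.r_[np.full(49, 0.3), 5.0, np.linspace(1.0, 5.0, 50)],
            }
        )
        out, _ = filter_rts(df)
        # 5.0 is an outlier for subject a (tight around 0.3) but not for
        # subject b, whose RTs are widely dispersed
        assert 5.0 not in out[out["subject"] == "a"]["rt"].values
        assert 5.0 in out[out["subject"] == "b"]["rt"].values

    def test_nonpositive_rt_rejected(self):
        with pytest.raises(ValueError):
            filter_rts(pd.DataFrame({"subject": "s", "rt": [0.3, -0.1]}))


class TestRmAnova:
    def test_null_effect_gives_zero_f(self):
        df = pd.DataFrame(
            {
                "subject": np.repeat([f"s{i}" for i in range(5)], 2),
                "cond": ["A", "B"] * 5,
                "y": np.repeat(np.arange(5.0), 2),
            }
        )
        res = rm_anova(df, dv="y", within=["cond"])
        assert res.effects["F"].iloc[0] == 0.0
        assert res.effects["partial_eta_sq"].iloc[0] == 0.0

    def test_two_level_factor_equals_squared_paired_t(self):
        df = pd.DataFrame(
            {
                "subject": ["s0", "s0", "s1", "s1", "s2", "s2"],
                "cond": ["A", "B"] * 3,
                "y": [1.0, 2.0, 2.0, 4.0, 3.0, 3.0],
            }
        )
        res = rm_anova(df, dv="y", within=["cond"])
        t, _ = stats.ttest_rel([1, 2, 3], [2, 4, 3])
        assert res.effects["F"].iloc[0] == pytest.approx(t**2)
        assert res.effects["df1"].iloc[0] == 1
        assert res.effects["df2"].iloc[0] == 2

    def test_two_factor_design_dfs(self):
        rng = np.random.default_rng(1)
        rows = []
        for s in range(26):
            for cond in ("LOW", "MED", "HIGH"):
                for instr in ("speed", "accurate"):
                    rows.append(
                        {"subject": f"s{s}", "condition": cond,
                         "instruction": instr,
                         "y": rng.normal(1.0 + 0.2 * (cond == "HIGH"), 0.1)}
                    )
        res = rm_anova(
            pd.DataFrame(rows), dv="y", within=["condition", "instruction"],
            posthoc_factor="condition",
        )
        eff = res.effects.set_index("effect")
        assert (eff.loc["condition", ["df1", "df2"]] == [2, 50]).all()
        assert (eff.loc["instruction", ["df1", "df2"]] == [1, 25]).all()
        assert res.posthoc["df"].eq(25).all()
        assert (res.posthoc["p_sidak"] >= res.posthoc["p_raw"] - 1e-12).all()

    def test_agrees_with_statsmodels_anovarm(self):
        # independent route: statsmodels AnovaRM on the same random table
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(21)
        rows = [
            {"subject": f"s{s}", "A": a, "B": b,
             "y": rng.normal(float(a == "a1") * 0.4, 1.0)}
            for s in range(12)
            for a in ("a0", "a1", "a2")
            for b in ("b0", "b1")
        ]
        df = pd.DataFrame(rows)
        ours = rm_anova(df, dv="y", within=["A", "B"]).effects.set_index("effect")
        theirs = AnovaRM(df, depvar="y", subject="subject", within=["A", "B"]).fit()
        tbl = theirs.anova_table
        assert ours.loc["A", "F"] == pytest.approx(tbl.loc["A", "F Value"])
        assert ours.loc["B", "F"] == pytest.approx(tbl.loc["B", "F Value"])
        assert ours.loc["A:B", "F"] == pytest.approx(tbl.loc["A:B", "F Value"])
        assert ours.loc["A", "p"] == pytest.approx(tbl.loc["A", "Pr > F"])

    def test_missing_cells_rejected(self):
        df = pd.DataFrame(
            {"subject": ["s0", "s0", "s1"], "cond": ["A", "B", "A"],
             "y": [1.0, 2.0, 3.0]}
        )
        with pytest.raises(ValueError):
            rm_anova(df, dv="y", within=["cond"])


class TestSidak:
    def test_closed_form_values(self):
        assert sidak_adjust(0.0, 5) == 0.0
        assert sidak_adjust(0.02, 3) == pytest.approx(0.058808)
        assert sidak_adjust(0.5, 1) == pytest.approx(0.5)

    def test_monotone_and_below_bonferroni(self):
        p = np.linspace(0, 1, 101)
        for m in (1, 3, 10):
            adj = sidak_adjust(p, m)
            assert np.all(adj >= p - 1e-12)
            assert np.all(adj <= np.minimum(1.0, m * p) + 1e-12)


def _make_epochs(voltages, times=None, channels=None, labels=None):
    n_tr, n_ch, n_t = voltages.shape
    return EpochArray(
        voltages=voltages,
        times=np.arange(n_t) * 4.0 - 100.0 if times is None else times,
        channels=[f"ch{i}" for i in range(n_ch)] if channels is None else channels,
        sfreq=250.0,
        labels=labels
        if labels is not None
        else pd.DataFrame({"subject": ["s0"] * n_tr}),
    )


class TestEpochArray:
    def test_invariants_enforced(self):
        v = np.zeros((2, 2, 5))
        with pytest.raises(ValueError):
            _make_epochs(v, times=np.array([0.0, 1, 1, 2, 3]))
        with pytest.raises(ValueError):
            _make_epochs(v, channels=["a", "a"])
        with pytest.raises(ValueError):
            _make_epochs(v, labels=pd.DataFrame({"subject": ["s0"]}))

    def test_save_load_roundtrip(self, tmp_path):
        rng = np.random.default_rng(2)
        ep = _make_epochs(rng.standard_normal((3, 2, 10)))
        ep.save(tmp_path / "ep")
        back = EpochArray.load(tmp_path / "ep")
        assert np.allclose(back.voltages, ep.voltages)
        assert list(back.channels) == list(ep.channels)


class TestPooling:
    def test_single_channel_pool_is_identity(self):
        rng = np.random.default_rng(3)
        ep = _make_epochs(rng.standard_normal((4, 3, 12)))
        pooled = pool_electrodes(ep, ["ch1"])
        assert np.allclose(pooled.voltages[:, 0], ep.voltages[:, 1])

    def test_opposite_channels_cancel(self):
        x = np.random.default_rng(4).standard_normal((5, 1, 20))
        v = np.concatenate([x, -x], axis=1)
        pooled = pool_electrodes(_make_epochs(v), ["ch0", "ch1"])
        assert np.allclose(pooled.voltages, 0.0)

    def test_equals_brute_force_mean(self):
        rng = np.random.default_rng(5)
        v = rng.standard_normal((6, 8, 30))
        ep = _make_epochs(v)
        pooled = pool_electrodes(ep, [f"ch{i}" for i in range(8)])
        assert np.allclose(pooled.voltages[:, 0], v.mean(axis=1))

    def test_missing_channel_listed(self):
        ep = _make_epochs(np.zeros((2, 2, 5)))
        with pytest.raises(ValueError, match="nope"):
            pool_electrodes(ep, ["ch0", "nope"])


def _diffwave_epochs(offset_fn, n_subjects=8, n_per_cat=10, noise=0.0, seed=0):
    """Pooled single-channel epochs: animal trials carry offset_fn(times)."""
    rng = np.random.default_rng(seed)
    times = np.arange(-100.0, 500.0, 4.0)
    rows, volts = [], []
    for s in range(n_subjects):
        for cat in ("animal", "non-animal"):
            for _ in range(n_per_cat):
                base = noise * rng.standard_normal(len(times))
                if cat == "animal":
                    base = base + offset_fn(times)
                volts.append(base[None, :])
                rows.append(
                    {"subject": f"s{s}", "condition": "HIGH",
                     "instruction": "speed", "category": cat}
                )
    return EpochArray(
        voltages=np.asarray(volts),
        times=times,
        channels=["pool"],
        sfreq=250.0,
        labels=pd.DataFrame(rows),
    )


class TestDifferenceWaves:
    def test_identical_categories_give_zero_wave(self):
        ep = _diffwave_epochs(lambda t: np.zeros_like(t), noise=0.0)
        waves = difference_waves(ep, conditions=("HIGH",))
        wv = waves[("speed", "HIGH")]
        assert np.allclose(wv.mean, 0.0) and np.allclose(wv.sem, 0.0)

    def test_injected_late_offset_recovered(self):
        ep = _diffwave_epochs(lambda t: 2.0 * (t >= 220), noise=0.1, seed=6)
        wv = difference_waves(ep, conditions=("HIGH",))[("speed", "HIGH")]
        assert np.allclose(wv.mean[wv.times >= 220], 2.0, atol=0.15)
        assert np.allclose(wv.mean[wv.times < 220], 0.0, atol=0.15)

    def test_sem_shrinks_with_subject_count(self):
        sems = []
        for n in (8, 32):
            ep = _diffwave_epochs(
                lambda t: np.zeros_like(t), n_subjects=n, noise=1.0, seed=7
            )
            wv = difference_waves(ep, conditions=("HIGH",))[("speed", "HIGH")]
            sems.append(wv.sem.mean())
        assert sems[1] < sems[0]
        assert sems[0] / sems[1] == pytest.approx(2.0, rel=0.3)

    def test_unpooled_epochs_rejected(self):
        ep = _make_epochs(np.zeros((2, 2, 5)))
        with pytest.raises(ValueError):
            difference_waves(ep)


class TestPointwiseTests:
    def test_null_p_values_uniform(self):
        # 12 subjects of pure noise, many replicated timepoints
        rng = np.random.default_rng(8)
        sw = rng.standard_normal((12, 40_000))
        _, p = stats.ttest_1samp(sw, 0.0, axis=0)
        ks = stats.kstest(p, "uniform")
        assert ks.pvalue > 0.01

    def test_constant_difference_gives_tiny_p(self):
        ep = _diffwave_epochs(lambda t: np.ones_like(t), noise=0.05, seed=9)
        waves = difference_waves(ep, conditions=("HIGH",))
        p = pointwise_tests(waves)[("speed", "HIGH")]
        assert np.all(p < 1e-6)

    def test_paired_equals_one_sample_on_difference(self):
        rng = np.random.default_rng(10)
        a = rng.standard_normal((10, 50))
        b = rng.standard_normal((10, 50))
        _, p_paired = stats.ttest_rel(a, b, axis=0)
        _, p_onesample = stats.ttest_1samp(a - b, 0.0, axis=0)
        assert np.allclose(p_paired, p_onesample)


class TestFdrMask:
    def test_matches_brute_force_bh_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            n = int(rng.integers(10, 5000))
            p = rng.uniform(0, 1, n) ** rng.uniform(0.5, 3)
            mask = fdr_mask({("all", "x"): p}, alpha=0.05)
            got = mask.for_contrast("all", "x")
            # oracle: sort-and-scan step-up rule
            order = np.argsort(p)
            thresh = 0.05 * (np.arange(1, n + 1)) / n
            passing = np.nonzero(p[order] <= thresh)[0]
            expect = np.zeros(n, bool)
            if passing.size:
                expect[order[: passing.max() + 1]] = True
            assert np.array_equal(got, expect)

    def test_all_ones_give_empty_mask(self):
        mask = fdr_mask({("all", "x"): np.ones(100)})
        assert not mask.for_contrast("all", "x").any()
        assert mask.q_threshold == 0.0

    def test_q_threshold_is_largest_passing_p(self):
        p = np.array([0.0001, 0.002, 0.2, 0.9])
        mask = fdr_mask({("all", "x"): p}, alpha=0.05)
        passed = p[mask.for_contrast("all", "x")]
        assert mask.q_threshold == passed.max()

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            fdr_mask({})


class TestDivergenceOnset:
    def test_empty_mask_gives_none(self):
        times = np.arange(-100.0, 500.0, 4.0)
        assert divergence_onset(np.zeros_like(times, bool), times) is None

    def test_onset_at_first_sustained_sample(self):
        times = np.arange(-100.0, 500.0, 4.0)
        mask = times >= 240.0
        assert divergence_onset(mask, times) == times[np.argmax(mask)]

    def test_short_runs_ignored(self):
        times = np.arange(0.0, 400.0, 4.0)
        mask = np.zeros_like(times, bool)
        mask[10:13] = True  # 3-sample blip < min_run
        assert divergence_onset(mask, times, min_run=5) is None

    def test_prestimulus_significance_not_counted(self):
        times = np.arange(-100.0, 100.0, 4.0)
        mask = np.ones_like(times, bool)
        assert divergence_onset(mask, times) == 0.0

    def test_misaligned_mask_rejected(self):
        with pytest.raises(ValueError):
            divergence_onset(np.zeros(5, bool), np.zeros(6))


class TestWindowAmplitude:
    def test_constant_epoch_returns_constant(self):
        ep = _make_epochs(np.full((3, 1, 150), 2.5), times=np.arange(150) * 4.0 - 100)
        assert np.allclose(window_amplitude(ep), 2.5)

    def test_linear_ramp_equals_sample_mean(self):
        times = np.arange(150) * 4.0 - 100
        ramp = np.tile(times, (2, 1, 1))
        ep = _make_epochs(ramp.astype(float), times=times)
        sel = (times >= 220) & (times <= 325)
        assert np.allclose(window_amplitude(ep), times[sel].mean())

    def test_order_and_length_preserved(self):
        rng = np.random.default_rng(12)
        v = rng.standard_normal((7, 1, 150))
        ep = _make_epochs(v, times=np.arange(150) * 4.0 - 100)
        amp = window_amplitude(ep)
        assert amp.shape == (7,)
        sel = (ep.times >= 220) & (ep.times <= 325)
        assert np.allclose(amp, v[:, 0, sel].mean(axis=1))

    def test_window_outside_epoch_rejected(self):
        ep = _make_epochs(np.zeros((2, 1, 50)), times=np.arange(50) * 4.0 - 100)
        with pytest.raises(ValueError):
            window_amplitude(ep, window=(220.0, 325.0))
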