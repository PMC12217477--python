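"""Assumption-gated statistics, SNK post hoc, and regressions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as st

import photomotor as pm
from photomotor.signal_processing import ProcessedSignal
from photomotor.stats import (
    bout_window_means,
    compare_epoch_windows,
    habituation_regression,
    paired_group_comparison,
    rm_anova_oneway,
    snk_posthoc,
    speed_binned_regression,
)
from photomotor.behavior import BoutSet

from conftest import make_speed_trace

# critical studentized-range values, alpha = 0.05, from published tables
Q_TABLE = {(2, 10): 3.151, (3, 10): 3.877, (2, 18): 2.971, (3, 18): 3.609}


class TestRMAnova:
    def test_matches_statsmodels_anova_rm(self, rng):
        from statsmodels.stats.anova import AnovaRM

        x = rng.standard_normal((12, 4)) + np.array([0.0, 0.3, 0.1, -0.2])
        f, df1, df2, p, _ = rm_anova_oneway(x)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 4),
                "cond": np.tile(np.arange(4), 12),
                "y": x.ravel(),
            }
        )
        ref = AnovaRM(long, "y", "subject", within=["cond"]).fit()
        assert f == pytest.approx(float(ref.anova_table["F Value"].iloc[0]), rel=1e-9)
        assert p == pytest.approx(float(ref.anova_table["Pr > F"].iloc[0]), abs=1e-12)
        assert (df1, df2) == (3, 33)

    def test_identical_windows_give_p_one(self):
        x = np.tile(np.arange(5.0)[:, None], (1, 3))
        res = compare_epoch_windows(x, branch="parametric")
        assert res.p_value == 1.0
        assert res.posthoc is None


class TestBranching:
    def test_heavy_tails_select_friedman(self, rng):
        x = st.cauchy.rvs(size=(12, 3), random_state=123)
        res = compare_epoch_windows(x)
        assert res.branch == "nonparametric"
        assert res.test_name.startswith("Friedman")

    def test_well_behaved_normal_selects_rm_anova(self):
        # fixed data known to satisfy both assumption gates
        x = np.array(
            [
                [0.1, 0.4, -0.2],
                [-0.3, 0.2, 0.1],
                [0.5, -0.1, 0.3],
                [-0.2, 0.3, -0.4],
                [0.4, -0.3, 0.2],
                [0.0, 0.1, -0.1],
                [-0.5, 0.5, 0.4],
                [0.2, -0.4, -0.3],
                [0.3, 0.0, 0.5],
                [-0.1, -0.2, 0.0],
            ]
        )
        res = compare_epoch_windows(x)
        assert res.branch == "parametric"
        assert res.assumption_p["levene"] > 0.05

    def test_branch_decision_is_deterministic(self, rng):
        x = rng.standard_normal((10, 3))
        assert compare_epoch_windows(x).branch == compare_epoch_windows(x).branch

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="3"):
            compare_epoch_windows(np.zeros((2, 3)))

    def test_missing_cells_dropped_listwise(self, rng):
        x = rng.standard_normal((6, 3))
        x[0, 1] = np.nan
        with pytest.warns(UserWarning, match="missing"):
            res = compare_epoch_windows(x, branch="parametric")
        assert res.n == 5


class TestSNK:
    def _oracle_decisions(self, x):
        """Independent SNK oracle: direct table lookup on 3 groups.

        Stepwise on ordered means: the 3-span range uses q(3, df), the
        2-span sub-ranges q(2, df); sub-ranges of a non-significant range
        are non-significant."""
        n, k = x.shape
        assert k == 3
        _, _, df_err, _, ms_err = rm_anova_oneway(x)
        se = np.sqrt(ms_err / n)
        m = np.sort(x.mean(axis=0))
        full = (m[2] - m[0]) / se > Q_TABLE[(3, df_err)]
        out = {(0, 2): full}
        for pair in ((0, 1), (1, 2)):
            q = (m[pair[1]] - m[pair[0]]) / se
            out[pair] = full and (q > Q_TABLE[(2, df_err)])
        return out

    @pytest.mark.parametrize("seed", range(12))
    def test_three_group_decisions_match_table_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 10 if seed % 2 else 10
        shift = rng.uniform(0.0, 2.0, 3)
        x = rng.standard_normal((n, 3)) + shift
        _, _, df_err, _, ms_err = rm_anova_oneway(x)
        got = snk_posthoc(x, ms_err, df_err, labels=[0, 1, 2])
        oracle = self._oracle_decisions(x)
        order = np.argsort(x.mean(axis=0))
        for _, row in got.iterrows():
            i = int(np.where(order == row["group_a"])[0][0])
            j = int(np.where(order == row["group_b"])[0][0])
            assert bool(row["significant"]) == oracle[(min(i, j), max(i, j))]

    def test_posthoc_only_after_significant_omnibus(self, rng):
        null = rng.standard_normal((10, 3)) * 0.001
        strong = rng.standard_normal((10, 3)) + np.array([0.0, 3.0, 6.0])
        assert compare_epoch_windows(strong, branch="parametric").posthoc is not None
        weak = compare_epoch_windows(null, branch="parametric")
        if weak.p_value >= 0.05:
            assert weak.posthoc is None

    def test_rank_posthoc_flags_large_shift(self, rng):
        x = rng.standard_normal((15, 3)) + np.array([0.0, 0.0, 5.0])
        res = compare_epoch_windows(x, branch="nonparametric")
        assert res.posthoc is not None
        top = res.posthoc[res.posthoc["span"] == 3].iloc[0]
        assert bool(top["significant"])


class TestPaired:
    def test_identical_samples_degenerate(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = paired_group_comparison(a, a)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_constant_shift_detected_reliably(self, rng):
        hits = 0
        for _ in range(100):
            b = rng.standard_normal(8)
            a = b + 5.0 + rng.standard_normal(8)  # 5 x noise SD effect
            hits += paired_group_comparison(a, b).p_value < 0.05
        assert hits >= 95

    def test_outlier_routes_to_wilcoxon(self):
        b = np.array([0.0, 0.1, -0.1, 0.05, -0.05, 0.02, 0.3, -0.2])
        a = b + np.array([0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 50.0])
        res = paired_group_comparison(a, b)
        assert res.test_name == "Wilcoxon signed-rank"
        assert res.branch == "nonparametric"

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            paired_group_comparison([1.0, 2.0], [2.0, 3.0])


class TestSpeedRegression:
    def _session(self, slope, rng, n_bouts=40, noise=0.0, centered=False):
        fps, rate, dur = 20.0, 100.0, float(40 * n_bouts)
        speeds = np.zeros(int(dur * fps))
        bouts = []
        for k in range(n_bouts):
            onset = 10.0 + 40.0 * k
            if centered:  # speeds at bin centers: regression is exact
                v = 4.5 + float(k % 10)
            else:
                v = rng.uniform(4.0, 15.0)
            i0 = int(onset * fps)
            # plateau one frame past the bout so interpolated z is constant
            # over the half-open bout window
            speeds[i0 : i0 + 31] = v
            bouts.append((onset, onset + 1.5))
        speed = make_speed_trace(speeds, fps)
        t = np.arange(int(dur * rate)) / rate
        z = slope * np.interp(t, speed.time, np.nan_to_num(speeds))
        if noise:
            z = z + rng.normal(0, noise, z.size)
        sig = ProcessedSignal(z=z, rate=rate)
        return BoutSet.from_intervals(bouts, "locomotion", "detected"), sig, speed

    def test_exact_linear_coupling_recovered(self, rng):
        bouts, sig, speed = self._session(0.1, rng, centered=True)
        res = speed_binned_regression(bouts, sig, speed)
        assert res.slope == pytest.approx(0.1, rel=1e-6)
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_binning_assignment(self):
        per_bout = pd.DataFrame({"mean_speed": [3.2, 3.7, 4.1]})
        idx = np.floor(per_bout["mean_speed"].to_numpy() / 1.0).astype(int)
        counts = pd.Series(idx).value_counts().to_dict()
        assert counts == {3: 2, 4: 1}

    def test_null_coupling_p_values_uniformish(self, rng):
        # under independence the regression should rarely reject
        hits = 0
        reps = 100
        for _ in range(reps):
            bouts, sig, speed = self._session(0.0, rng, n_bouts=25, noise=1.0)
            res = speed_binned_regression(bouts, sig, speed)
            hits += res.p_value < 0.05
        assert hits <= 12

    def test_too_few_bins_rejected(self, rng):
        bouts, sig, speed = self._session(0.1, rng, n_bouts=2)
        with pytest.raises(ValueError, match="bins"):
            speed_binned_regression(bouts, sig, speed)


class TestHabituation:
    def test_exact_line_percent_change(self):
        tbl = pd.DataFrame(
            {
                "mouse": 1,
                "trial_index": np.arange(1, 10),
                "value": np.arange(10.0, 1.0, -1.0),
            }
        )
        res = habituation_regression(tbl)
        assert res.slope == pytest.approx(-1.0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.percent_change(1, 9) == pytest.approx(-80.0)

    def test_constant_means_flat_line(self):
        tbl = pd.DataFrame(
            {"mouse": 1, "trial_index": np.arange(1, 8), "value": 2.0}
        )
        res = habituation_regression(tbl)
        assert res.slope == pytest.approx(0.0)
        assert res.percent_change(1, 7) == pytest.approx(0.0)

    def test_averages_across_mice_before_fitting(self):
        tbl = pd.DataFrame(
            {
                "mouse": [1, 2] * 3,
                "trial_index": [1, 1, 2, 2, 3, 3],
                "value": [1.0, 3.0, 2.0, 2.0, 3.0, 1.0],
            }
        )
        res = habituation_regression(tbl)  # per-index means all 2.0
        assert res.slope == pytest.approx(0.0)


def test_bout_window_means_uses_half_open_interval():
    sig = ProcessedSignal(z=np.arange(200) / 100.0, rate=100.0)
    speed = make_speed_trace(np.full(40, 6.0))
    bouts = BoutSet.from_intervals([(0.5, 1.0)], "locomotion", "detected")
    out = bout_window_means(bouts, sig, speed)
    assert out["mean_z"][0] == pytest.approx(np.mean(np.arange(50, 100) / 100.0))
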